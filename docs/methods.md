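# Methods

This note documents the statistical models, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the published
procedures leave the choice open.

## Coordinates and interval arithmetic

All coordinates are 0-based half-open (BED convention). Union,
intersection and subtraction are linear sweeps over coordinate-sorted
arrays; their contract is defined against per-base boolean oracles
(`tests/conftest.py`), which the test suite enforces on randomized
contigs. Chromosome names are compared by exact string match;
`strip_chr_prefix` is available when sources mix `chr1`/`1` naming, but
no silent aliasing is ever applied.

Tag counting assigns each tag to the single region containing its
midpoint — an unambiguous rule that never splits or double-counts a
tag. Normalized enrichment defaults to an RPKM-like unit,
raw / (region kb × library millions); a plain per-million mode is
available since the original description ("normalized tag enrichment")
does not pin the region-length term down. Both the assignment rule and
the normalization are config-exposed rather than asserted as the unique
truth.

## Chromatin state

Promoter/enhancer exclusivity is whole-peak: an H3K4me3 peak touching
any H3K4me1 peak (≥1 bp) is removed entirely, and vice versa. This
keeps peak identity intact and reads "non-overlapping bound regions" as
region selection rather than base subtraction. Commonality across
samples is base-level intersection, so a common region is contained in
a candidate of every sample.

Activity is a two-input decision: active ⇔ H3K27ac evidence present ∧
H3K27me3 evidence absent. A region carrying both marks is inactive —
the active class is defined by *low* H3K27me3, so repression dominates.
The default evidence mode is peak overlap (≥1 bp), a reproducible
binarization given that no enrichment cutoffs were published; an
enrichment-cutoff mode (H3K27ac ≥ `h3k27ac_min`, H3K27me3 <
`h3k27me3_max` on normalized enrichment) is retained for sensitivity
analysis. In the orchestrated pipeline, acetylation evidence is the
intersection of H3K27ac peaks across samples (activity must be shared)
while repression is the union of H3K27me3 peaks (repression anywhere
disqualifies).

Gene association: a gene qualifies when the distance from the nearest
region edge to its TSS base is strictly below the window (default
50 kb) and its expression summed over samples is strictly above the
gate (enhancers 100 RPKM, promoters 0.5 RPKM). All qualifying genes are
associated; ties are not broken.

## Exact rank tests

Both tests use mid-ranks for ties and two-sided p = 2·min(lower tail,
upper tail), capped at 1 — the standard doubling convention for
discrete nulls. Exact null distributions are computed by
generating-function dynamic programming over the rank multiset (ranks
doubled so mid-ranks stay integral). This enumerates, without
materializing, all 2ⁿ sign assignments (signed-rank, used for n ≤ 25
non-zero pairs) or all C(n, n_a) label assignments (rank-sum, used for
n ≤ 20 total). Beyond those sizes a tie-corrected normal approximation
with continuity correction takes over. Zero differences are dropped
before ranking; an all-zero comparison carries no evidence and returns
p = 1 with a warning rather than an error.

Two consequences worth knowing at the discovery design of 5 vs 10
samples: the smallest attainable two-sided p is 2/3003 ≈ 6.66·10⁻⁴, so
the stringent CpG cutoff 0.0007 is passable only by complete group
separation; and because the null is discrete, realized type-I error at
any α is at or below nominal.

## Negative-binomial differential count test

Counts K_ij are modeled NB with mean s_j·μ_g and dispersion α_i:
Var K = s_j μ + α s_j² μ². Size factors are DESeq-style
median-of-ratios over regions with all-sample nonzero counts.
Per-region dispersion is estimated by method of moments within each
group from the normalized counts (α̂_g = (v_g − ξ_g m_g)/m_g², where
ξ_g is the mean reciprocal size factor, the Poisson term), pooled
across the two groups by degrees of freedom, then shrunk toward the
genome-wide median dispersion with a scalar prior of 20 df and floored
at 10⁻⁸. The Wald statistic compares group means of normalized counts
with the model variance propagated to the means, referred to a t
distribution with (n_a + n_b − 2) + 20 df.

The shrinkage/reference choice is deliberate: with ~4 samples per group
a raw per-region moment estimate is so noisy that a normal reference
visibly mis-calibrates the null, while a t with only n_a+n_b−2 df
over-corrects and costs tail power. A scalar prior (no mean-dispersion
regression — deliberately simpler than DESeq's fitted trend) restores
calibration: on 10,000 null NB regions the p-value distribution's KS
distance from uniform is ≈0.015, and planted 4-fold changes at 5 vs 5
samples are recovered essentially completely at the published double
threshold. Reported log2 fold changes use a pseudocount of 0.5
normalized counts. Selection ("discriminating regions") requires
q < 0.01 (Benjamini–Hochberg, via statsmodels) ∧ p < 0.0002 ∧ the
requested sign.

## Fold-change > 3×SD rule

Occupancy changes between a control and a treated enrichment column are
called in log2 space: r_i = log₂((y_i + c)/(x_i + c)), gain when
r_i > mean(r) + k·SD(r), loss when below the mirror bound (sample SD,
k = 3 by default). Both columns are first expressed relative to their
pooled mean, and the pseudocount c = 1 is in those pooled-mean units.
This makes the calls exactly invariant to a common rescaling of both
columns (units cancel) while preserving cross-column differences, and
gives exact gain↔loss symmetry when the columns are swapped. A
zero-spread ratio distribution yields no calls, with a warning.

## Methylation signature

Processing order follows the published sequence: CG-context filter →
strand combining → coverage ≥ 5 → completeness across discovery
samples → exact rank-sum test. Strand combining merges the forward call
at position i with the reverse call at i+1 into one dyad addressed at
i, summing counts; unpaired calls pass through (a lone reverse call is
re-addressed to its dyad's forward base). Methylated and total counts
are conserved exactly, which the tests audit. The "coverage > 4" and
"coverage ≥ 5" phrasings are the same integer rule.

The supervised test compares beta values between the 5-sample high-risk
group and the 10-sample comparison group per CpG; p < 0.005 defines the
signature, p < 0.0007 the stringent set, and the final set additionally
requires a non-missing beta in every one of the 181 AML cohort columns
(a CpG absent from the cohort matrix counts as missing). Direction is
hypo when the high-risk mean beta is lower. Array-derived (450K-style)
betas enter the matrix directly alongside sequencing-derived betas; no
cross-platform adjustment is applied, matching the published pooling.

## Variant cascade

Three conjunctive stages (quality: DP ≥ 20 ∧ Phred ≥ 40; functional:
missense ∧ driver ∧ MAF ≤ 0.05; confirmed: ≥ 1 evidence track), all
boundaries inclusive. A variant missing from the frequency panel is
treated as rare and passes the MAF gate — absence from 1000G implies
below-threshold frequency. Records lacking DP or QUAL cannot be
evaluated and are rejected as "incomplete", tallied separately.
Consequence class, driver status, MAF and confirmations are consumed as
VCF INFO annotations (CSQ_CLASS, DRIVER, MAF, CONFIRM); no calling,
consequence prediction or pileup recomputation is done here. Because
every stage is a pure predicate, survivors are stage-order independent;
the attrition table reconciles exactly with input and output counts.
The number of confirming tracks required is configurable
(`min_confirmations`, default 1 — the published text does not state a
count).

## Synthetic data

The generator emulates the study design, not the genome: 2 high-risk
ChIP samples, a 5-vs-10 methylation discovery split, a 181-column AML
cohort matrix, two 5-Mb contigs, 1,000 regulatory loci and 1,000 CpGs
by default (sizes small enough for sub-minute full runs; the acceptance
script scales the null-calibration experiments to 10,000 features).

- **Peaks** sit on an even locus grid (1 kb wide, alternating
  promoter/enhancer), with per-sample edge jitter of ±100 bp and a
  configurable fraction of loci where the two candidate marks collide
  (removing them from candidacy, by construction). Activity truth is
  realized by placing H3K27ac on active loci and H3K27me3 / both /
  neither on inactive ones, covering the full decision table.
- **Counts** are negative-binomial (mean 100, dispersion 0.05) with
  log-normal region effects, relative library depths uniform within
  ±30% (normalized to mean 1), and a planted 5% of regions boosted
  4-fold in the high-risk samples.
- **Methylomes** are beta-binomial: a latent per-CpG, per-sample beta
  drawn around the group mean with concentration 30, strand coverages
  Poisson with mean 15 each (≈30 per dyad), binomial methylated counts
  per strand. Base methylation is bimodal as in real methylomes;
  planted CpGs (5%) separate the group means by Δβ = 0.5. AML cohort
  columns get independent 1% missingness.
- **Variants** are constructed, not sampled: each cascade stage has at
  least one record failing only that stage, one record is incomplete,
  one fails multiple stages, and the designated survivors pass
  everything.

What the generator does *not* emulate — and what passing tests
therefore cannot show: real peak-width and inter-peak distance
distributions, spatial correlation of methylation, copy-number and
mappability artifacts, batch effects between sequencing- and
array-derived betas, or any linkage between the chromatin, methylation
and variant layers. Recovery rates measured here characterize the
implementation under the modeled noise, not expected performance on
patient data — in particular, the published headline counts (22
hyperacetylated regions, 1,817/399/1,418 and 23 signature CpGs, etc.)
depend on the patient cohorts and are not reproduction targets.

Everything is driven by one integer seed through per-component
`numpy` Generators; identical seeds give byte-identical bundles, and
the pipeline itself is deterministic (wall times go to the log, never
into output files), so double runs are digest-identical.

## Degenerate inputs and tie-breaks

- Empty interval collections are legal everywhere except
  `intersect_all([])` (ill-defined) and single-sample commonality
  (explicitly rejected with guidance).
- `size_factors` requires at least one region with nonzero counts in
  every sample; otherwise the median-of-ratios is undefined and the
  call fails loudly.
- A selected CpG with exactly zero mean beta difference is classified
  hyper with a warning; it cannot occur at the published thresholds
  with 5-vs-10 exact testing.
- BH q-values come from `statsmodels.multipletests(method="fdr_bh")`,
  verified in tests against a hand step-up recomputation.

## Known limitations

- The NB test supports exactly two groups and no covariates; no GLM
  design matrices, no batch terms.
- No DMR merging: the methylation signature is per-CpG.
- bedGraph is the only signal-track format (no bigWig/BAM); peaks are
  inputs, never called here.
- The activity classification is two-state; no multi-state
  (ChromHMM-style) segmentation.
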