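"""Synthetic study bundles with planted, recoverable truth.

Generates every input the pipeline consumes — per-sample histone-mark
peak sets, negative-binomial region tag counts, stranded beta-binomial
CpG methylomes, a large cohort beta matrix with missingness, a gene
annotation with expression, and a small variant file — together with a
truth table recording exactly which effects were planted.  The defaults
mirror the study design: 2 high-risk APL ChIP samples, a 5-vs-10
methylation discovery comparison, a 181-sample AML cohort matrix, and
the published effect regimes (log2 fold change 2 in counts, beta shift
0.5 at planted CpGs, mean CpG coverage ~30).

Everything is driven by one integer seed; two bundles generated with
the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatin import GeneAnnotation
from .intervals import GenomicInterval, PeakSet, RegionCountTable, write_bed
from .methylation import (
    CytosineCall,
    MethylationMatrix,
    combine_symmetric_cpgs,
    filter_coverage,
)
from .variants import VariantRecord, write_vcf

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "generate_peaks",
    "generate_counts",
    "generate_methylome",
    "generate_variants",
    "generate_bundle",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    # cohort structure
    n_hrapl: int = 2  # high-risk APL ChIP samples (discovery pair)
    n_hrapl_meth: int = 5  # methylation discovery group (incl. cohort-derived)
    n_apl: int = 10
    n_aml: int = 181
    contigs: tuple[tuple[str, int], ...] = (
        ("chr1", 5_000_000),
        ("chr2", 5_000_000),
    )
    # regulatory loci / peaks
    n_regions: int = 1_000
    region_width: int = 1_000
    peak_overlap_fraction: float = 0.0  # loci where the two marks collide
    active_fraction: float = 0.6
    peak_jitter: int = 100  # per-sample edge jitter, bp
    # region tag counts
    nb_mean: float = 100.0
    nb_dispersion: float = 0.05
    count_log2fc: float = 2.0
    frac_planted_regions: float = 0.05
    library_size_spread: float = 0.3  # library factors uniform in 1 +/- spread
    # methylome
    n_cpgs: int = 1_000
    frac_planted_cpgs: float = 0.05
    delta_beta: float = 0.5
    coverage_mean: float = 30.0  # combined dyad coverage
    beta_precision: float = 30.0  # beta-binomial concentration (a+b)
    aml_missing_rate: float = 0.01
    # variants
    n_variant_survivors: int = 3
    # genes
    n_genes: int = 60

    def __post_init__(self) -> None:
        for name in ("peak_overlap_fraction", "active_fraction",
                     "frac_planted_regions", "frac_planted_cpgs",
                     "aml_missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0 or self.beta_precision <= 0:
            raise ValueError("dispersion/precision must be > 0")
        if any(length <= 0 for _, length in self.contigs):
            raise ValueError("contig lengths must be > 0")

    @property
    def hrapl_chip_samples(self) -> list[str]:
        return [f"hrAPL_{i + 1}" for i in range(self.n_hrapl)]

    @property
    def hrapl_meth_samples(self) -> list[str]:
        return [f"hrAPL_{i + 1}" for i in range(self.n_hrapl_meth)]

    @property
    def apl_samples(self) -> list[str]:
        return [f"APL_{i + 1}" for i in range(self.n_apl)]

    @property
    def aml_samples(self) -> list[str]:
        return [f"AML_{i + 1}" for i in range(self.n_aml)]


@dataclass
class TruthTable:
    """What was planted, for recovery scoring."""

    promoter_loci: list[GenomicInterval] = field(default_factory=list)
    enhancer_loci: list[GenomicInterval] = field(default_factory=list)
    overlap_loci: list[GenomicInterval] = field(default_factory=list)
    active_loci: dict[str, bool] = field(default_factory=dict)  # "chrom:start-end"
    planted_region_idx: list[int] = field(default_factory=list)  # hrAPL-high
    planted_cpgs: dict[tuple[str, int], str] = field(default_factory=dict)
    variant_survivors: list[tuple[str, int]] = field(default_factory=list)
    variant_stage_drops: dict[str, int] = field(default_factory=dict)


def _locus_grid(config: SimulationConfig) -> list[GenomicInterval]:
    """Evenly spaced candidate loci across the contigs."""
    total_len = sum(length for _, length in config.contigs)
    spacing = total_len // max(config.n_regions, 1)
    if spacing < 4 * config.region_width:
        raise ValueError(
            f"contigs too small for {config.n_regions} loci of width "
            f"{config.region_width}"
        )
    loci: list[GenomicInterval] = []
    remaining = config.n_regions
    for chrom, length in config.contigs:
        n_here = min(remaining, length // spacing)
        for i in range(n_here):
            start = i * spacing + spacing // 4
            loci.append(GenomicInterval(chrom, start, start + config.region_width))
        remaining -= n_here
    if remaining > 0:
        raise ValueError("contigs too small for the requested locus count")
    return loci


def generate_peaks(
    config: SimulationConfig,
) -> tuple[dict[tuple[str, str], PeakSet], TruthTable]:
    """Per-sample, per-mark peak sets with planted promoter/enhancer truth.

    Even loci are promoters (H3K4me3), odd loci enhancers (H3K4me1);
    a ``peak_overlap_fraction`` of loci additionally receives an
    overlapping peak of the opposite mark, which removes them from the
    candidate sets.  Active loci get an H3K27ac peak; inactive loci get
    H3K27me3 only, both marks, or neither, exercising the full activity
    decision table.
    """
    rng = np.random.default_rng(config.seed)
    loci = _locus_grid(config)
    truth = TruthTable()
    n = len(loci)
    overlap_mask = np.zeros(n, dtype=bool)
    n_overlap = int(round(config.peak_overlap_fraction * n))
    if n_overlap:
        overlap_mask[rng.choice(n, size=n_overlap, replace=False)] = True
    active_mask = rng.random(n) < config.active_fraction
    # inactive loci: 0 = me3 only, 1 = both marks, 2 = neither
    inactive_kind = rng.integers(0, 3, size=n)

    peaks: dict[tuple[str, str], PeakSet] = {}
    samples = config.hrapl_chip_samples
    for sample in samples:
        me3_ivs, me1_ivs, ac_ivs, k27me3_ivs = [], [], [], []
        for i, locus in enumerate(loci):
            j1, j2 = rng.integers(-config.peak_jitter, config.peak_jitter + 1, 2)
            iv = GenomicInterval(locus.chrom, max(0, locus.start + j1),
                                 locus.end + j2)
            promoter = i % 2 == 0
            (me3_ivs if promoter else me1_ivs).append(iv)
            if overlap_mask[i]:
                # opposite mark invading half of the locus
                half = GenomicInterval(
                    locus.chrom, locus.start + len(locus) // 2,
                    locus.end + len(locus) // 2,
                )
                (me1_ivs if promoter else me3_ivs).append(half)
            if active_mask[i]:
                ac_ivs.append(iv)
            else:
                kind = inactive_kind[i]
                if kind == 0:
                    k27me3_ivs.append(iv)
                elif kind == 1:
                    ac_ivs.append(iv)
                    k27me3_ivs.append(iv)
        peaks[(sample, "H3K4me3")] = PeakSet(sample, "H3K4me3", tuple(me3_ivs))
        peaks[(sample, "H3K4me1")] = PeakSet(sample, "H3K4me1", tuple(me1_ivs))
        peaks[(sample, "H3K27ac")] = PeakSet(sample, "H3K27ac", tuple(ac_ivs))
        peaks[(sample, "H3K27me3")] = PeakSet(sample, "H3K27me3", tuple(k27me3_ivs))

    for i, locus in enumerate(loci):
        if overlap_mask[i]:
            truth.overlap_loci.append(locus)
            continue
        (truth.promoter_loci if i % 2 == 0 else truth.enhancer_loci).append(locus)
        truth.active_loci[str(locus)] = bool(active_mask[i])
    return peaks, truth


def generate_counts(
    config: SimulationConfig,
    regions: list[GenomicInterval] | None = None,
) -> tuple[RegionCountTable, list[str], TruthTable]:
    """Negative-binomial region x sample tag counts with planted gains.

    Per-region base means are log-normal around ``nb_mean`` (expectation
    preserved); sample library factors vary uniformly within
    ``1 +/- library_size_spread``; a ``frac_planted_regions`` fraction
    of regions receives ``count_log2fc`` extra fold enrichment in the
    high-risk samples.  Returns the raw/normalized table, the per-sample
    group labels, and the truth table of planted indices.
    """
    rng = np.random.default_rng(config.seed + 1)
    if regions is None:
        regions = _locus_grid(config)
    n = len(regions)
    samples = config.hrapl_chip_samples + config.apl_samples
    groups = ["hrAPL"] * config.n_hrapl + ["APL"] * config.n_apl
    sigma = 0.5
    base_mean = config.nb_mean * rng.lognormal(-sigma**2 / 2, sigma, size=n)
    lib = rng.uniform(1 - config.library_size_spread,
                      1 + config.library_size_spread, size=len(samples))
    lib /= lib.mean()  # factors are relative depths; mean depth is nb_mean
    n_planted = int(round(config.frac_planted_regions * n))
    planted = np.sort(rng.choice(n, size=n_planted, replace=False))
    fold = np.ones((n, len(samples)))
    hr_cols = np.array([g == "hrAPL" for g in groups])
    fold[np.ix_(planted, np.where(hr_cols)[0])] = 2.0 ** config.count_log2fc
    mu = base_mean[:, None] * lib[None, :] * fold
    r = 1.0 / config.nb_dispersion  # NB size parameter
    raw = rng.negative_binomial(r, r / (r + mu)).astype(float)
    # normalized enrichment: per-kb per-million within each sample column
    lengths_kb = np.array([len(iv) / 1e3 for iv in regions])
    lib_tags = raw.sum(axis=0)
    normalized = raw / lengths_kb[:, None] / (np.maximum(lib_tags, 1) / 1e6)[None, :]
    table = RegionCountTable(regions=list(regions), samples=samples,
                             raw=raw, normalized=normalized)
    truth = TruthTable(planted_region_idx=[int(i) for i in planted])
    return table, groups, truth


def _beta_binomial_beta(rng, mu, precision, coverage):
    """Draw (meth, total) from a beta-binomial with mean mu."""
    mu = np.clip(mu, 1e-3, 1 - 1e-3)
    p = rng.beta(mu * precision, (1 - mu) * precision)
    meth = rng.binomial(coverage, p)
    return meth


def generate_methylome(
    config: SimulationConfig,
) -> tuple[dict[str, list[CytosineCall]], MethylationMatrix, TruthTable]:
    """Stranded CpG methylomes plus the cohort beta matrix.

    Each CpG dyad has a latent methylation level; per sample, a true
    beta is drawn from a Beta distribution around the group mean
    (concentration ``beta_precision``), strand coverages are Poisson
    with mean ``coverage_mean / 2`` each, and methylated counts are
    binomial — i.e. beta-binomial, overdispersed noise.  Planted CpGs
    shift the high-risk group mean by +/- ``delta_beta``.  The cohort
    matrix carries the combined discovery betas plus ``n_aml`` AML
    columns with ``aml_missing_rate`` missing cells.
    """
    rng = np.random.default_rng(config.seed + 2)
    # CpG positions on a fixed grid (even positions, >= 2 bp apart)
    positions: list[tuple[str, int]] = []
    per_contig = int(np.ceil(config.n_cpgs / len(config.contigs)))
    for chrom, length in config.contigs:
        step = max(2, (length - 100) // max(per_contig, 1))
        for i in range(per_contig):
            pos = 50 + i * step
            if pos + 1 >= length:
                break
            positions.append((chrom, pos))
    positions = positions[: config.n_cpgs]
    n = len(positions)

    # base methylation: bimodal, as in real methylomes
    low = rng.random(n) < 0.5
    base_mu = np.where(low, rng.beta(2, 8, n), rng.beta(8, 2, n))
    n_planted = int(round(config.frac_planted_cpgs * n))
    planted = np.sort(rng.choice(n, size=n_planted, replace=False))
    hypo = rng.random(n_planted) < 0.5  # hrAPL lower than APL
    apl_mu = base_mu.copy()
    hr_mu = base_mu.copy()
    half = config.delta_beta / 2.0
    apl_mu[planted] = np.where(hypo, 0.5 + half, 0.5 - half)
    hr_mu[planted] = np.where(hypo, 0.5 - half, 0.5 + half)

    truth = TruthTable()
    for k, idx in enumerate(planted):
        chrom, pos = positions[idx]
        truth.planted_cpgs[(chrom, pos)] = "hypo" if hypo[k] else "hyper"

    samples = config.hrapl_meth_samples + config.apl_samples
    sample_mu = {
        s: (hr_mu if s.startswith("hrAPL") else apl_mu) for s in samples
    }
    calls: dict[str, list[CytosineCall]] = {}
    combined_beta: dict[str, np.ndarray] = {}
    for sample in samples:
        mu = np.clip(sample_mu[sample], 1e-3, 1 - 1e-3)
        p_true = rng.beta(mu * config.beta_precision,
                          (1 - mu) * config.beta_precision)
        cov_f = rng.poisson(config.coverage_mean / 2.0, n)
        cov_r = rng.poisson(config.coverage_mean / 2.0, n)
        meth_f = rng.binomial(cov_f, p_true)
        meth_r = rng.binomial(cov_r, p_true)
        sample_calls: list[CytosineCall] = []
        beta_col = np.full(n, np.nan)
        for i, (chrom, pos) in enumerate(positions):
            if cov_f[i] > 0:
                sample_calls.append(CytosineCall(
                    chrom, pos, "+", "CG", int(meth_f[i]), int(cov_f[i])))
            if cov_r[i] > 0:
                sample_calls.append(CytosineCall(
                    chrom, pos + 1, "-", "CG", int(meth_r[i]), int(cov_r[i])))
            total = cov_f[i] + cov_r[i]
            if total >= 5:
                beta_col[i] = (meth_f[i] + meth_r[i]) / total
        calls[sample] = sample_calls
        combined_beta[sample] = beta_col

    # AML cohort columns: APL-like means, own noise, missingness
    cohort_cols = dict(combined_beta)
    for sample in config.aml_samples:
        mu = np.clip(apl_mu, 1e-3, 1 - 1e-3)
        beta = rng.beta(mu * config.beta_precision,
                        (1 - mu) * config.beta_precision)
        missing = rng.random(n) < config.aml_missing_rate
        beta = np.where(missing, np.nan, beta)
        cohort_cols[sample] = beta
    idx = pd.MultiIndex.from_tuples(positions, names=["chrom", "pos"])
    betas = pd.DataFrame(cohort_cols, index=idx)
    groups = {s: "hrAPL" for s in config.hrapl_meth_samples}
    groups.update({s: "APL" for s in config.apl_samples})
    groups.update({s: "AML" for s in config.aml_samples})
    cohort = MethylationMatrix(betas=betas, groups=groups)
    return calls, cohort, truth


def generate_variants(
    config: SimulationConfig,
) -> tuple[list[VariantRecord], TruthTable]:
    """A small variant set spanning every branch of the filter cascade.

    Each stage has at least one record failing only that stage, one
    record is incomplete (missing depth), one fails several stages, and
    ``n_variant_survivors`` records pass everything.
    """
    rng = np.random.default_rng(config.seed + 3)
    chrom = config.contigs[0][0]
    bases = np.array(list("ACGT"))

    def _passing(pos: int, **overrides) -> VariantRecord:
        ref, alt = rng.choice(bases, size=2, replace=False)
        fields = dict(
            chrom=chrom, pos=pos, ref=str(ref), alt=str(alt),
            depth=int(rng.integers(20, 80)),
            quality=float(rng.integers(40, 90)),
            consequence="missense",
            maf=float(np.round(rng.uniform(0, 0.05), 4)),
            gene_id=f"GENE{pos % 97}",
            is_driver=True,
            confirmations=frozenset({"RNA-seq"}),
        )
        fields.update(overrides)
        return VariantRecord(**fields)

    pos = iter(range(10_000, 10_000 + 100 * 50, 100))
    records: list[VariantRecord] = []
    drops = {"quality": 0, "functional": 0, "confirmed": 0}
    survivors: list[VariantRecord] = []
    for _ in range(config.n_variant_survivors):
        v = _passing(next(pos), confirmations=frozenset({"RNA-seq", "ChIP-seq"}))
        survivors.append(v)
        records.append(v)
    # single-stage failures
    records.append(_passing(next(pos), depth=int(rng.integers(1, 20))))
    records.append(_passing(next(pos), quality=float(rng.integers(0, 40))))
    records.append(_passing(next(pos), depth=None, quality=None))  # incomplete
    drops["quality"] += 3
    records.append(_passing(next(pos), consequence="synonymous"))
    records.append(_passing(next(pos), is_driver=False))
    records.append(_passing(next(pos), maf=0.2))
    records.append(_passing(next(pos), maf=None))  # missing MAF: retained
    survivors.append(records[-1])
    drops["functional"] += 3
    records.append(_passing(next(pos), confirmations=frozenset()))
    drops["confirmed"] += 1
    # multi-stage failure: dropped at the first failing stage (quality)
    records.append(_passing(next(pos), depth=5, consequence="synonymous",
                            confirmations=frozenset()))
    drops["quality"] += 1
    truth = TruthTable(
        variant_survivors=[(v.chrom, v.pos) for v in survivors],
        variant_stage_drops=drops,
    )
    return records, truth


# ---------------------------------------------------------------------------
# bundle writing


def _mark_filename(mark: str) -> str:
    return mark.replace("/", "_")


def generate_bundle(config: SimulationConfig, outdir) -> dict:
    """Write a complete on-disk study bundle and return its manifest.

    Layout: ``peaks/<sample>.<mark>.bed``, ``regions.bed``,
    ``counts.tsv`` (long format), ``chip_groups.tsv``,
    ``methylation/<sample>.calls.tsv``, ``cohort_matrix.tsv``,
    ``sample_groups.tsv``, ``variants.vcf``, ``genes/tss.tsv``,
    ``genes/expression.tsv``, ``truth/*.tsv`` and ``manifest.json``.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "peaks").mkdir(exist_ok=True)
        (outdir / "methylation").mkdir(exist_ok=True)
        (outdir / "genes").mkdir(exist_ok=True)
        (outdir / "truth").mkdir(exist_ok=True)
    except OSError as exc:
        raise ValueError(f"output directory not writable: {exc}") from exc

    manifest: dict = {
        "config": dataclasses.asdict(config),
        "files": {},
    }

    def _register(key: str, relpath: str) -> Path:
        manifest["files"][key] = relpath
        return outdir / relpath

    peaks, peak_truth = generate_peaks(config)
    for (sample, mark), ps in sorted(peaks.items()):
        rel = f"peaks/{sample}.{_mark_filename(mark)}.bed"
        write_bed(_register(f"peaks:{sample}:{mark}", rel), ps.intervals)

    regions = _locus_grid(config)
    table, chip_groups, count_truth = generate_counts(config, regions)
    write_bed(_register("regions", "regions.bed"), regions)
    rows = []
    for i, iv in enumerate(regions):
        for j, s in enumerate(table.samples):
            rows.append((f"region_{i}", s, int(table.raw[i, j])))
    pd.DataFrame(rows, columns=["region_id", "sample", "raw_count"]).to_csv(
        _register("counts", "counts.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        {"sample": table.samples, "group": chip_groups}
    ).to_csv(_register("chip_groups", "chip_groups.tsv"), sep="\t", index=False)

    calls, cohort, meth_truth = generate_methylome(config)
    for sample, sample_calls in calls.items():
        rel = f"methylation/{sample}.calls.tsv"
        with open(_register(f"calls:{sample}", rel), "w") as fh:
            fh.write("chrom\tpos\tstrand\tcontext\tmeth_count\ttotal_count\n")
            for c in sample_calls:
                fh.write(f"{c.chrom}\t{c.pos}\t{c.strand}\t{c.context}\t"
                         f"{c.meth_count}\t{c.total_count}\n")
    cohort_out = cohort.betas.copy()
    cohort_out.index = [f"{c}:{p}" for c, p in cohort_out.index]
    cohort_out.index.name = "cpg_id"
    cohort_out.to_csv(_register("cohort_matrix", "cohort_matrix.tsv"),
                      sep="\t", float_format="%.6g")
    pd.DataFrame(
        {"sample": list(cohort.groups), "group": list(cohort.groups.values())}
    ).to_csv(_register("sample_groups", "sample_groups.tsv"),
             sep="\t", index=False)

    variant_records, var_truth = generate_variants(config)
    write_vcf(_register("variants", "variants.vcf"), variant_records)

    genes = _generate_genes(config, regions)
    with open(_register("gene_tss", "genes/tss.tsv"), "w") as fh:
        fh.write("gene_id\tchrom\ttss_pos\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.tss.chrom}\t{g.tss.start}\t+\n")
    with open(_register("gene_expression", "genes/expression.tsv"), "w") as fh:
        fh.write("gene_id\tsample\trpkm\n")
        for g in genes:
            for sample, rpkm in sorted(g.expression_rpkm.items()):
                fh.write(f"{g.gene_id}\t{sample}\t{rpkm:.4f}\n")

    # truth files
    with open(_register("truth_regions", "truth/planted_regions.tsv"), "w") as fh:
        fh.write("region_id\tdirection\n")
        for i in count_truth.planted_region_idx:
            fh.write(f"region_{i}\tgain\n")
    with open(_register("truth_cpgs", "truth/planted_cpgs.tsv"), "w") as fh:
        fh.write("chrom\tpos\tdirection\n")
        for (chrom, p), d in sorted(meth_truth.planted_cpgs.items()):
            fh.write(f"{chrom}\t{p}\t{d}\n")
    with open(_register("truth_variants", "truth/variant_survivors.tsv"), "w") as fh:
        fh.write("chrom\tpos\n")
        for chrom, p in sorted(var_truth.variant_survivors):
            fh.write(f"{chrom}\t{p}\n")
    with open(_register("truth_loci", "truth/loci.tsv"), "w") as fh:
        fh.write("chrom\tstart\tend\tclass\tactive\n")
        for iv in peak_truth.promoter_loci:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tpromoter\t"
                     f"{int(peak_truth.active_loci[str(iv)])}\n")
        for iv in peak_truth.enhancer_loci:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tenhancer\t"
                     f"{int(peak_truth.active_loci[str(iv)])}\n")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _generate_genes(
    config: SimulationConfig, regions: list[GenomicInterval]
) -> list[GeneAnnotation]:
    """Genes with TSS near a subset of loci; expression straddles the gates."""
    rng = np.random.default_rng(config.seed + 4)
    samples = config.hrapl_chip_samples + config.apl_samples
    genes = []
    n = min(config.n_genes, len(regions))
    picks = rng.choice(len(regions), size=n, replace=False)
    for k, idx in enumerate(sorted(picks)):
        iv = regions[idx]
        offset = int(rng.integers(-80_000, 80_000))
        pos = max(0, iv.end + offset)
        # half highly expressed, half low, straddling the RPKM-sum gates
        high = k % 2 == 0
        rpkm = {
            s: float(np.round(rng.uniform(10, 40) if high else rng.uniform(0, 0.04), 4))
            for s in samples
        }
        genes.append(GeneAnnotation(
            gene_id=f"GENE{k:03d}",
            tss=GenomicInterval(iv.chrom, pos, pos + 1),
            expression_rpkm=rpkm,
        ))
    return genes
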