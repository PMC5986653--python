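"""Differential-enrichment statistics for region count data.

This module hosts every statistic the pipeline applies to histone-mark
tag counts and methylation beta values:

- :func:`signed_rank_test` — paired two-sided Wilcoxon signed-rank, exact
  for up to 25 non-zero pairs (before/after treatment comparisons at
  fusion-protein binding sites);
- :func:`rank_sum_test` — two-sided Wilcoxon rank-sum (Mann-Whitney),
  exact for up to 20 total observations (pairwise group comparisons and
  the CpG signature test);
- :func:`changed_regions_fc_sd` — the FC > k x STDEV gain/loss caller for
  treatment-induced occupancy changes;
- :func:`size_factors` / :func:`nb_differential_test` — median-of-ratios
  normalization and a negative-binomial Wald test for discriminating
  hyperacetylated regions, filtered by :func:`discriminating_regions`
  with the double FDR < 0.01 and p < 0.0002 threshold.

Exact null distributions are computed by generating-function dynamics
over the (doubled) mid-rank multiset, which enumerates all sign patterns
or label assignments without materializing them; mid-ranks make the exact
branch valid under ties, which large-sample tie-corrected normal
approximations take over beyond the exact-size limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, RegionCountTable

__all__ = [
    "DifferentialResult",
    "DifferentialThresholds",
    "signed_rank_test",
    "rank_sum_test",
    "fc_sd_calls",
    "changed_regions_fc_sd",
    "size_factors",
    "nb_differential_test",
    "discriminating_regions",
    "bh_fdr",
]

EXACT_SIGNED_RANK_MAX = 25  # non-zero pairs
EXACT_RANK_SUM_MAX = 20  # total observations
DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class DifferentialResult:
    region: GenomicInterval | int
    log2fc: float
    statistic: float
    p_value: float
    q_value: float
    direction: str  # gain | loss | none
    selected: bool


@dataclass(frozen=True)
class DifferentialThresholds:
    """Selection cutoffs for the differential analyses.

    Defaults are the published values: FDR < 0.01 with raw p < 0.0002 for
    discriminating hyperacetylated regions, p < 0.01 for pairwise boxplot
    comparisons, and a 3-standard-deviation fold-change rule for
    treatment-changed regions.
    """

    fdr_max: float = 0.01
    p_max: float = 0.0002
    pairwise_p: float = 0.01
    fc_sd_mult: float = 3.0

    def __post_init__(self) -> None:
        for name in ("fdr_max", "p_max", "pairwise_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.fc_sd_mult <= 0:
            raise ValueError("fc_sd_mult must be > 0")


# ---------------------------------------------------------------------------
# exact rank-test machinery


def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks scaled by 2 so ties produce integers (e.g. 1.5 -> 3)."""
    r = 2.0 * sps.rankdata(values, method="average")
    d = np.rint(r).astype(np.int64)
    if not np.allclose(r, d):  # pragma: no cover - mid-ranks are k/2
        raise AssertionError("mid-ranks are not half-integers")
    return d


@lru_cache(maxsize=4096)
def _subset_ranksum_distribution(
    doubled_ranks: tuple[int, ...], k: int
) -> tuple[np.ndarray, float]:
    """Counts of size-k subsets of ``doubled_ranks`` by doubled rank sum.

    Returns (counts indexed by sum, total number of subsets C(n, k)).
    Equivalent to enumerating every label assignment of the rank-sum null.
    """
    total = int(sum(doubled_ranks))
    table = np.zeros((k + 1, total + 1))
    table[0, 0] = 1.0
    for r in doubled_ranks:
        for kk in range(k, 0, -1):
            table[kk, r:] += table[kk - 1, : total + 1 - r]
    counts = table[k]
    return counts, float(counts.sum())


@lru_cache(maxsize=4096)
def _signed_rank_distribution(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Counts of W+ (doubled scale) over all 2^n sign assignments."""
    total = int(sum(doubled_ranks))
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return counts


def _two_sided_from_distribution(
    counts: np.ndarray, total: float, observed: int
) -> float:
    """Two-sided p as twice the smaller tail, capped at 1 (discrete null)."""
    cdf = counts[: observed + 1].sum() / total
    sf = counts[observed:].sum() / total
    return float(min(1.0, 2.0 * min(cdf, sf)))


def signed_rank_test(
    before: Sequence[float], after: Sequence[float]
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped before ranking.  With <= 25 non-zero
    pairs the p-value is exact (all sign assignments of the mid-ranked
    absolute differences); beyond that a tie-corrected normal
    approximation with continuity correction is used.  Returns
    ``(W_plus, p)`` where W+ is the rank sum of positive differences.
    If every difference is zero the test carries no evidence: p = 1.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before and after must be paired (equal length)")
    d = after - before
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    dbl = _doubled_midranks(np.abs(d))
    w_plus_dbl = int(dbl[d > 0].sum())
    w_plus = w_plus_dbl / 2.0
    if n <= EXACT_SIGNED_RANK_MAX:
        counts = _signed_rank_distribution(tuple(sorted(dbl.tolist())))
        p = _two_sided_from_distribution(counts, 2.0**n, w_plus_dbl)
        return w_plus, p
    # normal approximation on W+ with tie correction
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(dbl, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return w_plus, 1.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def rank_sum_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    With n_a + n_b <= 20 the p-value is exact: the null distribution of
    the group-a rank sum is computed over all C(n, n_a) label
    assignments, with mid-ranks for ties.  Larger samples use the
    tie-corrected normal approximation with continuity correction.
    Returns ``(W_a, p)`` where W_a is the rank sum of group a.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    dbl = _doubled_midranks(np.concatenate([a, b]))
    w_dbl = int(dbl[:n_a].sum())
    w = w_dbl / 2.0
    if n <= EXACT_RANK_SUM_MAX:
        counts, total = _subset_ranksum_distribution(
            tuple(sorted(dbl.tolist())), n_a
        )
        return w, _two_sided_from_distribution(counts, total, w_dbl)
    mean = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(dbl, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return w, 1.0
    z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# FC > k x STDEV gain/loss calling


def fc_sd_calls(
    log_ratios: np.ndarray, fc_sd_mult: float = 3.0
) -> np.ndarray:
    """Directions ('gain'/'loss'/'none') for log-ratios vs mean +/- k*SD.

    The gain and loss thresholds are the mean of the log-ratio
    distribution plus/minus ``fc_sd_mult`` sample standard deviations.
    A zero-spread distribution yields no calls.
    """
    r = np.asarray(log_ratios, dtype=float)
    out = np.full(r.size, "none", dtype=object)
    if r.size < 2:
        return out
    m = r.mean()
    s = r.std(ddof=1)
    if s == 0:
        warnings.warn("zero spread in log-ratios; no changed regions", stacklevel=2)
        return out
    out[r > m + fc_sd_mult * s] = "gain"
    out[r < m - fc_sd_mult * s] = "loss"
    return out


def changed_regions_fc_sd(
    control: np.ndarray,
    treated: np.ndarray,
    fc_sd_mult: float = 3.0,
    pseudocount: float = 1.0,
    regions: Sequence[GenomicInterval | int] | None = None,
) -> list[DifferentialResult]:
    """Call treatment-gained/lost regions by the FC > k x STDEV rule.

    Both normalized-enrichment columns are first expressed relative to
    their pooled mean, so the calls are exactly invariant to a common
    rescaling of the inputs; ``pseudocount`` (in pooled-mean units) then
    stabilizes the log2 ratio at low-signal regions.  A region is a gain
    when its log2 ratio exceeds the distribution mean by more than
    ``fc_sd_mult`` standard deviations, a loss when it falls below by
    the same margin.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.shape != treated.shape:
        raise ValueError("control and treated must cover the same regions")
    if np.any(control < 0) or np.any(treated < 0):
        raise ValueError("normalized enrichment must be non-negative")
    pooled_mean = np.concatenate([control, treated]).mean()
    scale = pooled_mean if pooled_mean > 0 else 1.0
    r = np.log2((treated / scale + pseudocount) / (control / scale + pseudocount))
    dirs = fc_sd_calls(r, fc_sd_mult)
    if regions is None:
        regions = list(range(control.size))
    return [
        DifferentialResult(
            region=reg,
            log2fc=float(r[i]),
            statistic=float(r[i]),
            p_value=float("nan"),
            q_value=float("nan"),
            direction=str(dirs[i]),
            selected=dirs[i] != "none",
        )
        for i, reg in enumerate(regions)
    ]


# ---------------------------------------------------------------------------
# negative-binomial differential test (median-of-ratios + Wald)


def size_factors(raw: np.ndarray | RegionCountTable) -> np.ndarray:
    """Median-of-ratios size factors.

    For each sample, the factor is the median over all-sample-nonzero
    regions of the ratio between that sample's count and the region's
    geometric mean across samples.
    """
    mat = raw.raw if isinstance(raw, RegionCountTable) else np.asarray(raw, float)
    if mat.ndim != 2:
        raise ValueError("count matrix must be 2-D (regions x samples)")
    nz = np.all(mat > 0, axis=1)
    if not nz.any():
        raise ValueError(
            "no region has nonzero counts in every sample; "
            "size factors are undefined"
        )
    logs = np.log(mat[nz])
    log_geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo, axis=0))
    return factors


def nb_differential_test(
    table: RegionCountTable,
    groups: Sequence[str],
    numerator: str | None = None,
    log2fc_pseudocount: float = 0.5,
    dispersion_prior_df: float = 20.0,
) -> list[DifferentialResult]:
    """Two-group negative-binomial Wald test on raw region counts.

    Counts are normalized by median-of-ratios size factors; each
    region's dispersion is estimated by method of moments within each
    group, pooled across groups, then shrunk toward the genome-wide
    median dispersion with a scalar prior of ``dispersion_prior_df``
    degrees of freedom (floored at 1e-8).  The Wald statistic compares
    group means of normalized counts with the NB variance
    ``mu/s + alpha*mu^2`` propagated to the means, and is referred to a
    t distribution with n_a + n_b - 2 + prior df degrees of freedom to
    account for the residual uncertainty of the shrunk variance
    estimate.  ``numerator`` names the group whose enrichment makes
    log2fc positive (default: the second group label in order of
    appearance).  q-values are Benjamini-Hochberg.
    """
    groups = list(groups)
    if len(groups) != len(table.samples):
        raise ValueError("groups must label every sample")
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly two group labels, got {labels}")
    if numerator is None:
        numerator = labels[1]
    if numerator not in labels:
        raise ValueError(f"numerator {numerator!r} not among group labels")
    denominator = labels[0] if numerator == labels[1] else labels[1]
    idx_num = np.array([g == numerator for g in groups])
    idx_den = ~idx_num
    n_num, n_den = int(idx_num.sum()), int(idx_den.sum())
    if n_num < 2 or n_den < 2:
        raise ValueError(
            "each group needs >=2 samples for a dispersion estimate "
            f"(got {denominator}:{n_den}, {numerator}:{n_num})"
        )
    s = size_factors(table.raw)
    norm = table.raw / s

    def _group_stats(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        sub = norm[:, mask]
        return sub.mean(axis=1), sub.var(axis=1, ddof=1), float((1.0 / s[mask]).mean())

    m_num, v_num, xi_num = _group_stats(idx_num)
    m_den, v_den, xi_den = _group_stats(idx_den)

    def _mom_alpha(m: np.ndarray, v: np.ndarray, xi: float) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - xi * m) / np.square(m)
        return np.where(m > 0, a, 0.0)

    a_num = _mom_alpha(m_num, v_num, xi_num)
    a_den = _mom_alpha(m_den, v_den, xi_den)
    df = n_num + n_den - 2
    alpha = ((n_num - 1) * a_num + (n_den - 1) * a_den) / df
    if dispersion_prior_df > 0 and alpha.size > 1:
        alpha_prior = float(np.median(alpha))
        alpha = (dispersion_prior_df * alpha_prior + df * alpha) / (
            dispersion_prior_df + df
        )
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    var_mean_num = (xi_num * m_num + alpha * np.square(m_num)) / n_num
    var_mean_den = (xi_den * m_den + alpha * np.square(m_den)) / n_den
    delta = m_num - m_den
    se = np.sqrt(var_mean_num + var_mean_den)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * sps.t.sf(np.abs(tstat), df=df + max(dispersion_prior_df, 0.0))
    p = np.where(se == 0, np.where(delta == 0, 1.0, 0.0), p)
    p = np.clip(p, 0.0, 1.0)
    q = bh_fdr(p)
    c = log2fc_pseudocount
    log2fc = np.log2((m_num + c) / (m_den + c))
    return [
        DifferentialResult(
            region=table.regions[i] if table.regions else i,
            log2fc=float(log2fc[i]),
            statistic=float(tstat[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
            direction="none",
            selected=False,
        )
        for i in range(norm.shape[0])
    ]


def discriminating_regions(
    results: Sequence[DifferentialResult],
    thresholds: DifferentialThresholds = DifferentialThresholds(),
    direction: str = "gain",
) -> list[DifferentialResult]:
    """Select regions passing the double FDR + raw-p threshold.

    A region is discriminating when q < fdr_max, p < p_max, and its
    log2 fold change points in the requested direction (gain = higher
    in the numerator group, i.e. hyperacetylated in the high-risk
    samples for the published comparison).
    """
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    out = []
    for res in results:
        fc_ok = res.log2fc > 0 if direction == "gain" else res.log2fc < 0
        if res.q_value < thresholds.fdr_max and res.p_value < thresholds.p_max and fc_ok:
            out.append(replace(res, direction=direction, selected=True))
    return out


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
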