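"""WGBS CpG processing and the supervised methylation-signature test.

The processing chain mirrors a bisulfite pipeline downstream of
methylation calling: keep CG-context cytosines only, combine the
forward- and reverse-strand calls of each symmetric CpG dyad into one
site, require combined coverage >= 5, restrict to CpGs measured in every
discovery sample, and test each CpG's beta values between the high-risk
group (5 samples) and the comparison group (10 samples) with the exact
two-sided rank-sum test.  Signature CpGs pass p < 0.005; the most
discriminating subset passes p < 0.0007 — at 5-vs-10 group sizes only a
complete beta separation can reach that cut-off (minimum attainable
p = 2/3003) — and is finally restricted to CpGs with a beta value in
every column of the 181-sample AML cohort matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import rank_sum_test

__all__ = [
    "CytosineCall",
    "CpGSite",
    "MethylationMatrix",
    "SignatureCpG",
    "filter_cg_context",
    "combine_symmetric_cpgs",
    "filter_coverage",
    "build_matrix",
    "supervised_cpg_test",
    "refine_against_cohort",
    "classify_direction",
    "read_cpg_calls",
    "read_cohort_matrix",
    "write_signature_tsv",
]

logger = logging.getLogger(__name__)

COVERAGE_MIN = 5
PRIMARY_P = 0.005
STRINGENT_P = 0.0007
CONTEXTS = ("CG", "CHH", "CXG")


@dataclass(frozen=True)
class CytosineCall:
    """One strand-specific cytosine methylation call."""

    chrom: str
    pos: int  # 0-based position of the cytosine
    strand: str  # '+' | '-'
    context: str  # CG | CHH | CXG
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(
                f"unknown context {self.context!r} at {self.chrom}:{self.pos}"
            )
        if self.total_count <= 0:
            raise ValueError("total_count must be positive")
        if not 0 <= self.meth_count <= self.total_count:
            raise ValueError("meth_count must be in [0, total_count]")


@dataclass(frozen=True)
class CpGSite:
    """A strand-combined CpG dyad, addressed by its forward-strand C."""

    chrom: str
    pos: int
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.total_count <= 0:
            raise ValueError("total_count must be positive")
        if not 0 <= self.meth_count <= self.total_count:
            raise ValueError("meth_count must be in [0, total_count]")

    @property
    def beta(self) -> float:
        return self.meth_count / self.total_count


@dataclass
class MethylationMatrix:
    """CpG x sample beta matrix with per-sample group labels.

    ``betas`` is indexed by (chrom, pos) with one column per sample;
    NaN marks a missing measurement.  ``groups`` maps each sample to
    hrAPL / APL / AML (or any study-specific label).
    """

    betas: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.betas.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        vals = self.betas.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.betas.columns if self.groups[s] == group]


@dataclass(frozen=True)
class SignatureCpG:
    chrom: str
    pos: int
    p_value: float
    mean_diff: float  # mean(high-risk beta) - mean(comparison beta)
    direction: str  # hypo | hyper


def filter_cg_context(calls: Iterable[CytosineCall]) -> list[CytosineCall]:
    """Keep CG-context calls only (non-CpG methylation is excluded)."""
    return [c for c in calls if c.context == "CG"]


def combine_symmetric_cpgs(calls: Iterable[CytosineCall]) -> list[CpGSite]:
    """Merge forward/reverse calls of each CpG dyad into one site.

    A forward-strand call at position i pairs with a reverse-strand call
    at i+1; their methylated and total counts are summed.  Unpaired
    calls pass through with their own counts (a lone reverse call is
    addressed by its dyad's forward position, i-1).  Total methylated
    and total read counts are conserved exactly.
    """
    seen: set[tuple[str, int, str]] = set()
    forward: dict[tuple[str, int], CytosineCall] = {}
    reverse: dict[tuple[str, int], CytosineCall] = {}
    for c in calls:
        if c.context != "CG":
            raise ValueError(f"non-CG call at {c.chrom}:{c.pos} ({c.context})")
        key = (c.chrom, c.pos, c.strand)
        if key in seen:
            raise ValueError(f"duplicate call at {c.chrom}:{c.pos} strand {c.strand}")
        seen.add(key)
        (forward if c.strand == "+" else reverse)[(c.chrom, c.pos)] = c
    sites: list[CpGSite] = []
    used_rev: set[tuple[str, int]] = set()
    for (chrom, pos), fwd in forward.items():
        rev = reverse.get((chrom, pos + 1))
        if rev is not None:
            used_rev.add((chrom, pos + 1))
            sites.append(
                CpGSite(chrom, pos, fwd.meth_count + rev.meth_count,
                        fwd.total_count + rev.total_count)
            )
        else:
            sites.append(CpGSite(chrom, pos, fwd.meth_count, fwd.total_count))
    for (chrom, pos), rev in reverse.items():
        if (chrom, pos) not in used_rev:
            sites.append(CpGSite(chrom, pos - 1, rev.meth_count, rev.total_count))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def filter_coverage(
    sites: Iterable[CpGSite], min_total: int = COVERAGE_MIN
) -> list[CpGSite]:
    """Keep CpG sites with combined coverage >= ``min_total`` (default 5)."""
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    return [s for s in sites if s.total_count >= min_total]


def build_matrix(
    per_sample_sites: Mapping[str, Sequence[CpGSite]],
    groups: Mapping[str, str],
    discovery_groups: tuple[str, str] = ("hrAPL", "APL"),
) -> MethylationMatrix:
    """Assemble the beta matrix, keeping CpGs measured in all discovery samples.

    Samples belonging to ``discovery_groups`` must have a beta at a CpG
    for the row to be retained; columns from other groups (e.g. the AML
    cohort) may still be missing there.
    """
    present = {g for s, g in groups.items() if s in per_sample_sites}
    if len(present & set(discovery_groups)) < 2:
        raise ValueError(
            f"need samples from both discovery groups {discovery_groups}"
        )
    columns = {}
    for sample, sites in per_sample_sites.items():
        if sample not in groups:
            raise ValueError(f"sample {sample!r} has no group label")
        if len(sites) == 0:
            raise ValueError(f"sample {sample!r} has zero surviving CpGs")
        idx = pd.MultiIndex.from_tuples(
            [(s.chrom, s.pos) for s in sites], names=["chrom", "pos"]
        )
        columns[sample] = pd.Series([s.beta for s in sites], index=idx)
    betas = pd.DataFrame(columns)
    discovery_cols = [
        s for s in betas.columns if groups[s] in discovery_groups
    ]
    betas = betas[betas[discovery_cols].notna().all(axis=1)]
    betas = betas.sort_index()
    return MethylationMatrix(betas=betas, groups=dict(groups))


def supervised_cpg_test(
    matrix: MethylationMatrix,
    primary: float = PRIMARY_P,
    stringent: float = STRINGENT_P,
    groups: tuple[str, str] = ("hrAPL", "APL"),
) -> tuple[list[SignatureCpG], list[SignatureCpG]]:
    """Per-CpG exact rank-sum test between the two discovery groups.

    Returns ``(signature, stringent_set)``: CpGs with two-sided p below
    ``primary`` (default 0.005) and below ``stringent`` (default
    0.0007).  Direction is hypo when the first group's mean beta is
    below the second group's, hyper otherwise.
    """
    cols_a = matrix.samples_in_group(groups[0])
    cols_b = matrix.samples_in_group(groups[1])
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"each group needs >=2 samples ({groups[0]}:{len(cols_a)}, "
            f"{groups[1]}:{len(cols_b)})"
        )
    a = matrix.betas[cols_a].to_numpy(dtype=float)
    b = matrix.betas[cols_b].to_numpy(dtype=float)
    signature: list[SignatureCpG] = []
    stringent_set: list[SignatureCpG] = []
    for i, (chrom, pos) in enumerate(matrix.betas.index):
        _, p = rank_sum_test(a[i], b[i])
        if p >= primary:
            continue
        mean_diff = float(a[i].mean() - b[i].mean())
        direction = "hypo" if mean_diff < 0 else "hyper"
        if mean_diff == 0:
            warnings.warn(
                f"selected CpG {chrom}:{pos} has zero mean difference; "
                "classified hyper",
                stacklevel=2,
            )
        cpg = SignatureCpG(str(chrom), int(pos), float(p), mean_diff, direction)
        signature.append(cpg)
        if p < stringent:
            stringent_set.append(cpg)
    return signature, stringent_set


def refine_against_cohort(
    stringent_set: Sequence[SignatureCpG],
    cohort: MethylationMatrix,
    cohort_group: str = "AML",
) -> list[SignatureCpG]:
    """Keep CpGs with a beta value in every cohort (AML) column.

    A CpG absent from the cohort matrix altogether counts as missing.
    """
    aml_cols = cohort.samples_in_group(cohort_group)
    if not aml_cols:
        raise ValueError(f"cohort matrix has no {cohort_group!r} columns")
    complete = cohort.betas[aml_cols].notna().all(axis=1)
    complete_idx = set(complete.index[complete])
    return [c for c in stringent_set if (c.chrom, c.pos) in complete_idx]


def classify_direction(
    signature: Sequence[SignatureCpG],
) -> tuple[list[SignatureCpG], list[SignatureCpG]]:
    """Partition a signature into (hypomethylated, hypermethylated)."""
    hypo = [c for c in signature if c.direction == "hypo"]
    hyper = [c for c in signature if c.direction == "hyper"]
    return hypo, hyper


# ---------------------------------------------------------------------------
# I/O


def read_cpg_calls(path) -> list[CytosineCall]:
    """Read per-sample cytosine calls.

    Native dialect (TSV with header): chrom, pos, strand, context,
    meth_count, total_count.  Bismark-coverage-style files (6 columns,
    no header: chrom, start, end, beta%, meth, unmeth) are detected and
    read as forward-strand CG calls.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("chrom"):
        df = pd.read_csv(path, sep="\t")
        return [
            CytosineCall(
                str(r.chrom), int(r.pos), str(r.strand), str(r.context),
                int(r.meth_count), int(r.total_count),
            )
            for r in df.itertuples(index=False)
        ]
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "beta_pct", "meth", "unmeth"],
    )
    return [
        CytosineCall(
            str(r.chrom), int(r.start), "+", "CG",
            int(r.meth), int(r.meth) + int(r.unmeth),
        )
        for r in df.itertuples(index=False)
    ]


def read_cohort_matrix(matrix_path, groups_path) -> MethylationMatrix:
    """Read a cohort beta matrix (cpg_id = chrom:pos rows) + group labels."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    chrom_pos = [cid.rsplit(":", 1) for cid in df.index.astype(str)]
    df.index = pd.MultiIndex.from_tuples(
        [(c, int(p)) for c, p in chrom_pos], names=["chrom", "pos"]
    )
    gdf = pd.read_csv(groups_path, sep="\t")
    groups = {str(r.sample): str(r.group) for r in gdf.itertuples(index=False)}
    return MethylationMatrix(betas=df.astype(float), groups=groups)


def write_signature_tsv(
    path,
    signature: Sequence[SignatureCpG],
    stringent_set: Sequence[SignatureCpG] = (),
    final_set: Sequence[SignatureCpG] = (),
) -> None:
    stringent_keys = {(c.chrom, c.pos) for c in stringent_set}
    final_keys = {(c.chrom, c.pos) for c in final_set}
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tp_value\tmean_diff\tdirection\tin_stringent\tin_final\n")
        for c in signature:
            key = (c.chrom, c.pos)
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.p_value:.6g}\t{c.mean_diff:.6g}\t"
                f"{c.direction}\t{int(key in stringent_keys)}\t{int(key in final_keys)}\n"
            )
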