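"""Promoter/enhancer definition, activity classification and gene linking.

The two-class chromatin scheme: H3K4me3 peaks that do not touch any
H3K4me1 peak are promoter candidates, H3K4me1 peaks that do not touch any
H3K4me3 peak are enhancer candidates (whole-peak exclusivity).  Candidates
common to all samples are kept, then marked active or inactive from
H3K27ac (activity) and H3K27me3 (repression): active requires the
acetylation criterion AND the absence of the repression criterion —
a region carrying both marks is called inactive, since activity is
defined by low H3K27me3.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    PeakSet,
    intersect_all,
    merge_intervals,
)

__all__ = [
    "RegulatoryRegion",
    "GeneAnnotation",
    "ActivityThresholds",
    "define_candidate_regions",
    "common_regions",
    "classify_activity",
    "associate_regions_to_genes",
]

logger = logging.getLogger(__name__)

ENHANCER_DISTANCE_MAX = 50_000  # bp, enhancer-to-TSS window
ENHANCER_RPKM_SUM_MIN = 100.0
PROMOTER_RPKM_SUM_MIN = 0.5


@dataclass
class RegulatoryRegion:
    interval: GenomicInterval
    region_class: str  # promoter | enhancer
    activity: str = "inactive"  # active | inactive
    supporting_samples: list[str] = field(default_factory=list)
    associated_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.region_class not in ("promoter", "enhancer"):
            raise ValueError(f"unknown region_class {self.region_class!r}")
        if self.activity not in ("active", "inactive"):
            raise ValueError(f"unknown activity {self.activity!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's TSS position and per-sample expression (RPKM)."""

    gene_id: str
    tss: GenomicInterval  # 1-bp interval at the transcription start
    expression_rpkm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.tss) != 1:
            raise ValueError("tss must be a 1-bp interval")
        if any(v < 0 for v in self.expression_rpkm.values()):
            raise ValueError("RPKM values must be non-negative")

    @property
    def rpkm_sum(self) -> float:
        return float(sum(self.expression_rpkm.values()))


@dataclass(frozen=True)
class ActivityThresholds:
    """How H3K27ac / H3K27me3 evidence is binarized.

    ``peak-overlap`` mode calls a criterion met when the region shares
    >=1 bp with the mark's peak set; ``enrichment-cutoff`` mode compares
    normalized enrichment against the two cutoffs.
    """

    mode: str = "peak-overlap"
    h3k27ac_min: float = 1.0
    h3k27me3_max: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("peak-overlap", "enrichment-cutoff"):
            raise ValueError(f"unknown activity mode {self.mode!r}")
        if self.h3k27ac_min < 0 or self.h3k27me3_max < 0:
            raise ValueError("activity thresholds must be >= 0")


class _OverlapIndex:
    """Sorted-array >=1bp overlap lookup against a merged interval set."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for iv in merge_intervals(intervals):
            starts, ends = self._by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def overlaps(self, iv: GenomicInterval) -> bool:
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect_right(starts, iv.end - 1)  # last interval starting before iv.end
        return i > 0 and ends[i - 1] > iv.start


def define_candidate_regions(
    h3k4me3: PeakSet, h3k4me1: PeakSet
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Mutually exclusive promoter and enhancer candidates of one sample.

    A peak of either mark that overlaps any peak of the other mark (by
    >=1 bp) is discarded whole: promoter candidates are the surviving
    H3K4me3 peaks, enhancer candidates the surviving H3K4me1 peaks.
    """
    if h3k4me3.mark != "H3K4me3" or h3k4me1.mark != "H3K4me1":
        raise ValueError(
            f"expected marks H3K4me3/H3K4me1, got {h3k4me3.mark}/{h3k4me1.mark}"
        )
    if h3k4me3.sample_id != h3k4me1.sample_id:
        raise ValueError("peak sets must come from the same sample")
    me1_index = _OverlapIndex(h3k4me1.intervals)
    me3_index = _OverlapIndex(h3k4me3.intervals)
    promoters = [iv for iv in h3k4me3.intervals if not me1_index.overlaps(iv)]
    enhancers = [iv for iv in h3k4me1.intervals if not me3_index.overlaps(iv)]
    return promoters, enhancers


def common_regions(
    candidates_per_sample: Sequence[Iterable[GenomicInterval]],
) -> list[GenomicInterval]:
    """Bases covered by a candidate region in every sample."""
    if len(candidates_per_sample) < 2:
        raise ValueError(
            "commonality needs >=2 samples; with a single sample use its "
            "candidate set directly"
        )
    return intersect_all([list(c) for c in candidates_per_sample])


def classify_activity(
    regions: Sequence[GenomicInterval],
    region_class: str,
    h3k27ac: PeakSet | np.ndarray,
    h3k27me3: PeakSet | np.ndarray,
    thresholds: ActivityThresholds = ActivityThresholds(),
    supporting_samples: Sequence[str] = (),
) -> list[RegulatoryRegion]:
    """Mark regions active or inactive from H3K27ac / H3K27me3 evidence.

    Active requires the H3K27ac criterion met AND the H3K27me3 criterion
    not met; everything else (neither mark, repression only, or both
    marks) is inactive.  In ``enrichment-cutoff`` mode ``h3k27ac`` and
    ``h3k27me3`` are normalized-enrichment vectors aligned with
    ``regions`` (e.g. RegionCountTable columns).
    """
    if thresholds.mode == "peak-overlap":
        if not isinstance(h3k27ac, PeakSet) or not isinstance(h3k27me3, PeakSet):
            raise ValueError("peak-overlap mode requires PeakSet evidence")
        ac_index = _OverlapIndex(h3k27ac.intervals)
        me3_index = _OverlapIndex(h3k27me3.intervals)
        ac_met = [ac_index.overlaps(r) for r in regions]
        me3_met = [me3_index.overlaps(r) for r in regions]
    else:
        if isinstance(h3k27ac, PeakSet) or isinstance(h3k27me3, PeakSet):
            raise ValueError(
                "enrichment-cutoff mode requires normalized enrichment "
                "vectors (RegionCountTable columns), not peak sets"
            )
        ac = np.asarray(h3k27ac, dtype=float)
        me3 = np.asarray(h3k27me3, dtype=float)
        if ac.shape != (len(regions),) or me3.shape != (len(regions),):
            raise ValueError("enrichment vectors must align with regions")
        ac_met = list(ac >= thresholds.h3k27ac_min)
        me3_met = list(me3 >= thresholds.h3k27me3_max)
    return [
        RegulatoryRegion(
            interval=r,
            region_class=region_class,
            activity="active" if (a and not m) else "inactive",
            supporting_samples=list(supporting_samples),
        )
        for r, a, m in zip(regions, ac_met, me3_met)
    ]


def _region_tss_distance(region: GenomicInterval, tss: GenomicInterval) -> int:
    """Distance from the nearest region edge to the TSS base (0 if inside)."""
    pos = tss.start
    if region.start <= pos < region.end:
        return 0
    return pos - region.end + 1 if pos >= region.end else region.start - pos


def associate_regions_to_genes(
    regions: Sequence[RegulatoryRegion],
    annotation: Sequence[GeneAnnotation],
    distance_max: int = ENHANCER_DISTANCE_MAX,
    rpkm_sum_min: float = ENHANCER_RPKM_SUM_MIN,
) -> list[RegulatoryRegion]:
    """Fill ``associated_genes``: TSS within ``distance_max`` of the region
    (strict) and expression RPKM summed over samples above ``rpkm_sum_min``
    (strict).  All qualifying genes are associated.  Mutates and returns
    ``regions``.

    Published gates: enhancers use distance < 50 kb with RPKM sum > 100;
    promoters use RPKM sum > 0.5.
    """
    if distance_max <= 0:
        raise ValueError("distance_max must be > 0")
    if not annotation:
        logger.warning("empty gene annotation: no associations made")
    expressed = [g for g in annotation if g.rpkm_sum > rpkm_sum_min]
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in expressed:
        by_chrom.setdefault(g.tss.chrom, []).append((g.tss.start, g.gene_id))
    for c in by_chrom:
        by_chrom[c].sort()
    for region in regions:
        region.associated_genes = []
        genes = by_chrom.get(region.interval.chrom, [])
        for pos, gene_id in genes:
            tss = GenomicInterval(region.interval.chrom, pos, pos + 1)
            if _region_tss_distance(region.interval, tss) < distance_max:
                region.associated_genes.append(gene_id)
    return list(regions)


# ---------------------------------------------------------------------------
# I/O helpers


def read_gene_annotation(tss_path, expression_path) -> list[GeneAnnotation]:
    """Load genes from a TSS table and a long-format expression table.

    ``tss_path``: TSV with columns gene_id, chrom, tss_pos, strand.
    ``expression_path``: TSV with columns gene_id, sample, rpkm.
    """
    tss = pd.read_csv(tss_path, sep="\t")
    expr = pd.read_csv(expression_path, sep="\t")
    rpkm: dict[str, dict[str, float]] = {}
    for row in expr.itertuples(index=False):
        rpkm.setdefault(str(row.gene_id), {})[str(row.sample)] = float(row.rpkm)
    genes = []
    for row in tss.itertuples(index=False):
        gid = str(row.gene_id)
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                tss=GenomicInterval(str(row.chrom), int(row.tss_pos), int(row.tss_pos) + 1),
                expression_rpkm=rpkm.get(gid, {}),
            )
        )
    return genes


def write_regions_bed(path, regions: Sequence[RegulatoryRegion]) -> None:
    """BED6 with name = class:activity, score 0, strand '.'."""
    with open(path, "w") as fh:
        for r in regions:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{r.region_class}:{r.activity}\t0\t.\n"
            )


def write_associations_tsv(path, regions: Sequence[RegulatoryRegion]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tregion_class\tactivity\tgenes\n")
        for r in regions:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.region_class}\t"
                f"{r.activity}\t{','.join(r.associated_genes)}\n"
            )
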