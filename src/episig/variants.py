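"""The variant-reduction cascade applied to WGBS-derived SNP calls.

Three conjunctive stages: sequencing quality (read depth >= 20 and
Phred-scaled quality >= 40), functional relevance (missense consequence,
known cancer driver gene, population minor-allele frequency <= 5%), and
independent confirmation in companion RNA-seq / ChIP-seq evidence.
Because every stage is a pure predicate, the surviving set is
independent of stage order; the cascade additionally reports a
per-stage attrition table.

Consequence class, MAF, driver status and confirmations are consumed as
input annotations (INFO keys CSQ_CLASS, MAF, DRIVER, CONFIRM of a VCF);
a variant absent from the frequency panel (missing MAF) is treated as
rare and retained by the MAF gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
import pysam

__all__ = [
    "VariantRecord",
    "FilterThresholds",
    "filter_quality",
    "filter_functional",
    "filter_confirmed",
    "run_cascade",
    "read_vcf",
    "write_vcf",
]

logger = logging.getLogger(__name__)

CONFIRMATION_TRACKS = ("RNA-seq", "ChIP-seq")


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    depth: int | None = None  # DP
    quality: float | None = None  # Phred-scaled
    consequence: str = "other"  # missense | synonymous | other
    maf: float | None = None  # missing = absent from the panel
    gene_id: str = ""
    is_driver: bool = False
    confirmations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.quality is not None and self.quality < 0:
            raise ValueError("quality must be >= 0")
        if self.maf is not None and not 0 <= self.maf <= 1:
            raise ValueError("maf must be in [0, 1]")


@dataclass(frozen=True)
class FilterThresholds:
    """Cascade cutoffs; defaults are the published values."""

    dp_min: int = 20
    phred_min: float = 40.0
    maf_max: float = 0.05
    require_missense: bool = True
    require_driver: bool = True
    min_confirmations: int = 1

    def __post_init__(self) -> None:
        if min(self.dp_min, self.phred_min, self.maf_max, self.min_confirmations) < 0:
            raise ValueError("thresholds must be non-negative")


def partition_quality(
    variants: Sequence[VariantRecord], thresholds: FilterThresholds
) -> tuple[list[VariantRecord], list[VariantRecord], list[VariantRecord]]:
    """Split into (kept, failed, incomplete) by DP/Phred thresholds.

    Records lacking depth or quality cannot be evaluated; they are
    rejected with reason "incomplete" and counted separately from
    threshold failures.
    """
    kept, failed, incomplete = [], [], []
    for v in variants:
        if v.depth is None or v.quality is None:
            incomplete.append(v)
        elif v.depth >= thresholds.dp_min and v.quality >= thresholds.phred_min:
            kept.append(v)
        else:
            failed.append(v)
    if incomplete:
        logger.warning("%d records rejected as incomplete (missing DP/QUAL)",
                       len(incomplete))
    return kept, failed, incomplete


def filter_quality(
    variants: Sequence[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[VariantRecord]:
    """Keep variants with depth >= dp_min and Phred quality >= phred_min."""
    kept, _, _ = partition_quality(variants, thresholds)
    return kept


def filter_functional(
    variants: Sequence[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[VariantRecord]:
    """Keep missense driver-gene variants at MAF <= maf_max (missing = rare)."""
    out = []
    for v in variants:
        if thresholds.require_missense and v.consequence != "missense":
            continue
        if thresholds.require_driver and not v.is_driver:
            continue
        if v.maf is not None and v.maf > thresholds.maf_max:
            continue
        out.append(v)
    return out


def filter_confirmed(
    variants: Sequence[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[VariantRecord]:
    """Keep variants confirmed in >= min_confirmations companion tracks."""
    return [v for v in variants
            if len(v.confirmations) >= thresholds.min_confirmations]


STAGES = (
    ("quality", filter_quality),
    ("functional", filter_functional),
    ("confirmed", filter_confirmed),
)


def run_cascade(
    variants: Sequence[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Apply quality -> functional -> confirmed and tally attrition.

    Returns the surviving variants and a table with one row per stage
    (stage, n_in, n_out, n_dropped); survivors are a subset of the
    input, and dropped counts reconcile exactly with the totals.
    """
    rows = []
    current = list(variants)
    for name, fn in STAGES:
        n_in = len(current)
        current = fn(current, thresholds)
        rows.append({"stage": name, "n_in": n_in, "n_out": len(current),
                     "n_dropped": n_in - len(current)})
    return current, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF I/O (uncompressed VCF text via pysam)

_HEADER_LINES = [
    ('INFO', 'DP', '1', 'Integer', 'Read depth'),
    ('INFO', 'CSQ_CLASS', '1', 'String', 'Consequence class (missense/synonymous/other)'),
    ('INFO', 'MAF', '1', 'Float', 'Minor allele frequency (1000G)'),
    ('INFO', 'DRIVER', '0', 'Flag', 'Variant lies in a known cancer driver gene'),
    ('INFO', 'GENE', '1', 'String', 'Gene identifier'),
    ('INFO', 'CONFIRM', '.', 'String', 'Confirming evidence tracks'),
]


def _build_header(contigs: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for kind, name, number, vtype, desc in _HEADER_LINES:
        header.add_meta(
            kind,
            items=[("ID", name), ("Number", number), ("Type", vtype),
                   ("Description", desc)],
        )
    for c in contigs:
        header.contigs.add(c)
    return header


def read_vcf(path) -> list[VariantRecord]:
    """Read VariantRecords from a VCF (DP/QUAL + the cascade INFO keys)."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            confirm = info.get("CONFIRM")
            if confirm is None:
                confirmations: frozenset[str] = frozenset()
            elif isinstance(confirm, tuple):
                confirmations = frozenset(str(c) for c in confirm)
            else:
                confirmations = frozenset([str(confirm)])
            maf = info.get("MAF")
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else ".",
                    depth=int(info["DP"]) if "DP" in info else None,
                    quality=float(rec.qual) if rec.qual is not None else None,
                    consequence=str(info.get("CSQ_CLASS", "other")),
                    maf=float(maf) if maf is not None else None,
                    gene_id=str(info.get("GENE", "")),
                    is_driver=bool(info.get("DRIVER", False)),
                    confirmations=confirmations,
                )
            )
    return out


def write_vcf(path, variants: Sequence[VariantRecord]) -> None:
    """Write VariantRecords as uncompressed VCF v4.x."""
    contigs = sorted({v.chrom for v in variants})
    header = _build_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
            rec = vf.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos,
                alleles=(v.ref, v.alt), qual=v.quality,
            )
            if v.depth is not None:
                rec.info["DP"] = v.depth
            rec.info["CSQ_CLASS"] = v.consequence
            if v.maf is not None:
                rec.info["MAF"] = v.maf
            if v.is_driver:
                rec.info["DRIVER"] = True
            if v.gene_id:
                rec.info["GENE"] = v.gene_id
            if v.confirmations:
                rec.info["CONFIRM"] = tuple(sorted(v.confirmations))
            vf.write(rec)


def write_attrition_tsv(path, attrition: pd.DataFrame) -> None:
    attrition.to_csv(path, sep="\t", index=False)
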