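"""Genomic interval arithmetic, BED/bedGraph I/O and normalized tag counting.

Coordinates are 0-based half-open throughout (BED convention): an interval
``chr1:0-10`` covers bases 0..9.  Chromosome names are compared by exact
string match; :func:`strip_chr_prefix` can be applied up front when inputs
mix ``chr1`` / ``1`` naming.

The three set operations (:func:`merge_intervals`, :func:`intersect_all`,
:func:`subtract`) are the primitives every downstream stage consumes; they
are implemented as linear sweeps over coordinate-sorted arrays and are
checked against per-base bitmap oracles in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "SignalTrack",
    "RegionCountTable",
    "merge_intervals",
    "intersect_all",
    "subtract",
    "count_tags_normalized",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "strip_chr_prefix",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic range ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("GenomicInterval.chrom must be nonempty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


VALID_MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K9/14ac", "H3K27me3", "PML")


@dataclass(frozen=True)
class PeakSet:
    """Peaks of one histone mark (or factor) in one sample.

    Intervals are merged and sorted on construction, so a PeakSet is always
    a disjoint, coordinate-ordered cover of the bound bases.
    """

    sample_id: str
    mark: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "intervals", tuple(merge_intervals(self.intervals))
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)


@dataclass(frozen=True)
class SignalTrack:
    """Per-interval tag counts (or coverage) plus the library size.

    ``library_size`` is the total number of mapped tags in the experiment
    and is the denominator of per-million normalization; it need not equal
    the sum of the stored values (values may cover only part of the genome,
    or be per-base coverage).
    """

    intervals: tuple[GenomicInterval, ...]
    values: tuple[float, ...]
    library_size: int

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.values):
            raise ValueError("intervals and values must have equal length")
        if any(v < 0 for v in self.values):
            raise ValueError("SignalTrack values must be non-negative")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")


@dataclass
class RegionCountTable:
    """Region x sample raw tag counts and normalized enrichment.

    ``regions`` may be ``None`` for anonymous rows (e.g. simulation
    studies); downstream results then carry row indices instead of
    intervals.
    """

    regions: list[GenomicInterval] | None
    samples: list[str]
    raw: np.ndarray
    normalized: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape[1] != len(self.samples):
            raise ValueError("raw shape must be (n_regions, n_samples)")
        if self.regions is not None and len(self.regions) != self.raw.shape[0]:
            raise ValueError("raw shape must be (n_regions, n_samples)")
        if self.normalized is None:
            self.normalized = self.raw.copy()
        self.normalized = np.asarray(self.normalized, dtype=float)
        if self.normalized.shape != self.raw.shape:
            raise ValueError("raw and normalized must have identical shape")

    def column(self, sample: str) -> np.ndarray:
        return self.normalized[:, self.samples.index(sample)]

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        mat = self.normalized if normalized else self.raw
        idx = [str(r) for r in self.regions]
        return pd.DataFrame(mat, index=idx, columns=self.samples)


# ---------------------------------------------------------------------------
# set operations


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, np.ndarray]:
    """Group into a {chrom: (n,2) sorted array} mapping, validating records."""
    groups: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        if not isinstance(iv, GenomicInterval):
            iv = GenomicInterval(*iv)  # validates
        groups.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: np.array(sorted(pairs), dtype=np.int64)
        for c, pairs in groups.items()
    }


def _emit(chrom: str, arr: Sequence[tuple[int, int]]) -> list[GenomicInterval]:
    return [GenomicInterval(chrom, int(s), int(e)) for s, e in arr if s < e]


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Collapse an interval collection into its sorted disjoint union.

    Touching intervals (end == next start) are merged, so the result covers
    exactly the union of input bases with the fewest possible records.
    """
    out: list[GenomicInterval] = []
    groups = _by_chrom(intervals)
    for chrom in sorted(groups):
        merged: list[tuple[int, int]] = []
        for s, e in groups[chrom]:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out.extend(_emit(chrom, merged))
    return out


def _intersect_pair(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of two merged, sorted interval lists (two-pointer sweep)."""
    ga, gb = _by_chrom(a), _by_chrom(b)
    out: list[GenomicInterval] = []
    for chrom in sorted(set(ga) & set(gb)):
        xa, xb = ga[chrom], gb[chrom]
        i = j = 0
        hits: list[tuple[int, int]] = []
        while i < len(xa) and j < len(xb):
            s = max(xa[i, 0], xb[j, 0])
            e = min(xa[i, 1], xb[j, 1])
            if s < e:
                hits.append((s, e))
            if xa[i, 1] <= xb[j, 1]:
                i += 1
            else:
                j += 1
        out.extend(_emit(chrom, hits))
    return out


def intersect_all(
    peak_sets: Sequence[PeakSet | Iterable[GenomicInterval]],
) -> list[GenomicInterval]:
    """Maximal intervals covered by *every* input set (common regions)."""
    if len(peak_sets) == 0:
        raise ValueError("intersect_all requires at least one peak set")
    current = None
    for ps in peak_sets:
        ivs = list(ps.intervals if isinstance(ps, PeakSet) else ps)
        merged = merge_intervals(ivs)
        current = merged if current is None else _intersect_pair(current, merged)
        if not current:
            return []
    return current


def subtract(
    a: PeakSet | Iterable[GenomicInterval],
    b: PeakSet | Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Bases of ``a`` not covered by ``b`` (base-level A AND NOT B)."""
    a_ivs = merge_intervals(a.intervals if isinstance(a, PeakSet) else a)
    gb = _by_chrom(b.intervals if isinstance(b, PeakSet) else b)
    # merge b per chrom
    gb = {c: _by_chrom(merge_intervals(_emit(c, arr)))[c] for c, arr in gb.items()}
    out: list[GenomicInterval] = []
    for iv in a_ivs:
        cuts = gb.get(iv.chrom)
        if cuts is None:
            out.append(iv)
            continue
        pos = iv.start
        pieces: list[tuple[int, int]] = []
        for s, e in cuts:
            if e <= pos:
                continue
            if s >= iv.end:
                break
            if s > pos:
                pieces.append((pos, min(s, iv.end)))
            pos = max(pos, e)
            if pos >= iv.end:
                break
        if pos < iv.end:
            pieces.append((pos, iv.end))
        out.extend(_emit(iv.chrom, pieces))
    return out


def overlaps_any(
    query: GenomicInterval, targets: Iterable[GenomicInterval]
) -> bool:
    """True if ``query`` shares >=1 base with any target interval."""
    for t in targets:
        if t.chrom == query.chrom and t.start < query.end and query.start < t.end:
            return True
    return False


# ---------------------------------------------------------------------------
# tag counting


def count_tags_normalized(
    regions: Sequence[GenomicInterval],
    track: SignalTrack,
    mode: str = "rpkm",
) -> tuple[np.ndarray, np.ndarray]:
    """Raw and normalized tag counts of a signal track over regions.

    A track record contributes its full value to the single region that
    contains its midpoint (``(start + end) // 2``); records whose midpoint
    falls in no region are ignored.  Normalization is either

    - ``"rpkm"``: raw / (region length in kb x library size in millions), or
    - ``"per-million"``: raw / (library size in millions).

    Returns ``(raw, normalized)`` arrays aligned with ``regions``.
    """
    if mode not in ("rpkm", "per-million"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if track.library_size <= 0:
        raise ValueError("library_size must be > 0")
    raw = np.zeros(len(regions), dtype=float)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end, idx))
    for c in by_chrom:
        by_chrom[c].sort()
    for iv, val in zip(track.intervals, track.values):
        mid = (iv.start + iv.end) // 2
        rows = by_chrom.get(iv.chrom)
        if not rows:
            continue
        # binary search on the sorted region starts of this chromosome
        lo, hi = 0, len(rows)
        while lo < hi:
            m = (lo + hi) // 2
            if rows[m][0] <= mid:
                lo = m + 1
            else:
                hi = m
        if lo > 0:
            s, e, idx = rows[lo - 1]
            if s <= mid < e:
                raw[idx] += val
    lib_m = track.library_size / 1e6
    if mode == "rpkm":
        lengths_kb = np.array([len(r) / 1e3 for r in regions])
        normalized = raw / (lengths_kb * lib_m)
    else:
        normalized = raw / lib_m
    return raw, normalized


# ---------------------------------------------------------------------------
# I/O


def strip_chr_prefix(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Normalize ``chrN`` contig names to ``N`` for cross-source joins."""
    out = []
    for iv in intervals:
        chrom = iv.chrom[3:] if iv.chrom.lower().startswith("chr") else iv.chrom
        out.append(GenomicInterval(chrom, iv.start, iv.end))
    return out


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 (0-based half-open); columns past the third are ignored."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(path, intervals: Iterable[GenomicInterval], names=None) -> None:
    """Write BED3 (or BED6 with name column, score 0, strand '.')."""
    with open(path, "w") as fh:
        if names is None:
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        else:
            for iv, name in zip(intervals, names):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\n")


def read_bedgraph(path, library_size: int | None = None) -> SignalTrack:
    """Read a bedGraph into a SignalTrack.

    If ``library_size`` is not given it defaults to the rounded sum of the
    track values (appropriate when the track holds genome-wide tag counts).
    """
    ivs: list[GenomicInterval] = []
    vals: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            ivs.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            vals.append(float(parts[3]))
    if library_size is None:
        library_size = max(1, int(round(math.fsum(vals))))
    return SignalTrack(tuple(ivs), tuple(vals), library_size)
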