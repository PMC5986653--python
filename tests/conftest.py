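import numpy as np
import pytest

from episig.intervals import GenomicInterval


def bitmap(intervals, length, chrom="chr1"):
    """Per-base boolean cover of ``chrom`` — the oracle for set operations."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def intervals_from_bitmap(mask, chrom="chr1"):
    """Maximal runs of True back to intervals (matches merged output)."""
    out = []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for s, e in zip(edges[::2], edges[1::2]):
        out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def random_intervals(rng, n, length, chrom="chr1", max_width=None):
    max_width = max_width or max(2, length // 10)
    starts = rng.integers(0, length - 1, size=n)
    widths = rng.integers(1, max_width, size=n)
    return [
        GenomicInterval(chrom, int(s), int(min(s + w, length)))
        for s, w in zip(starts, widths)
        if s < min(s + w, length)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small but complete synthetic study bundle shared across tests."""
    from episig.simulate import SimulationConfig, generate_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    config = SimulationConfig(seed=123, n_regions=200, n_cpgs=300)
    manifest = generate_bundle(config, outdir)
    return config, outdir, manifest
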