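"""Pipeline orchestration: configuration, the three analyses, run report.

Ties the stage modules together into the three study analyses —
chromatin-state definition with activity classification and gene
association, differential count statistics with discriminating-region
selection, the supervised CpG methylation signature, and the variant
filter cascade — all reading a study bundle directory (as written by
:mod:`episig.simulate`, or any directory with the same layout) and
writing per-analysis tables plus a machine-readable run report.

All stages are deterministic given their inputs; rerunning a pipeline
on the same bundle reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin, methylation, variants
from .chromatin import ActivityThresholds
from .differential import (
    DifferentialThresholds,
    changed_regions_fc_sd,
    discriminating_regions,
    nb_differential_test,
)
from .intervals import (
    GenomicInterval,
    PeakSet,
    RegionCountTable,
    intersect_all,
    merge_intervals,
    read_bed,
    write_bed,
)
from .variants import FilterThresholds

logger = logging.getLogger(__name__)

ANALYSES = ("chromatin", "diff", "methylation", "variants")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``bundle_dir`` must contain the study inputs (see
    :func:`episig.simulate.generate_bundle` for the layout);
    ``output_dir`` is created if needed.  Threshold defaults are the
    published values.
    """

    bundle_dir: Path
    output_dir: Path
    seed: int = 0
    activity: ActivityThresholds = field(default_factory=ActivityThresholds)
    differential: DifferentialThresholds = field(
        default_factory=DifferentialThresholds
    )
    filters: FilterThresholds = field(default_factory=FilterThresholds)
    meth_primary_p: float = methylation.PRIMARY_P
    meth_stringent_p: float = methylation.STRINGENT_P
    coverage_min: int = methylation.COVERAGE_MIN

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bundle_dir"] = str(self.bundle_dir)
        d["output_dir"] = str(self.output_dir)
        return d


#: inputs each analysis requires inside the bundle directory
_REQUIRED_INPUTS = {
    "chromatin": ["peaks", "genes/tss.tsv", "genes/expression.tsv"],
    "diff": ["regions.bed", "counts.tsv", "chip_groups.tsv"],
    "methylation": ["methylation", "cohort_matrix.tsv", "sample_groups.tsv"],
    "variants": ["variants.vcf"],
}


def validate_config(
    raw: dict | PipelineConfig, analyses: tuple[str, ...] = ANALYSES
) -> PipelineConfig:
    """Check paths and thresholds, injecting defaults for omitted keys.

    ``raw`` may be a dict (e.g. parsed YAML) with keys ``bundle_dir``,
    ``output_dir``, ``seed`` and a flat ``thresholds`` mapping
    (fdr_max, p_max, fc_sd_mult, meth_primary_p, meth_stringent_p,
    coverage_min, dp_min, phred_min, maf_max, min_confirmations,
    activity_mode, h3k27ac_min, h3k27me3_max).
    """
    if isinstance(raw, PipelineConfig):
        config = raw
    else:
        if "bundle_dir" not in raw:
            raise ValueError("config missing required key: bundle_dir")
        if "output_dir" not in raw:
            raise ValueError("config missing required key: output_dir")
        thr = dict(raw.get("thresholds") or {})

        def _take(cls, mapping):
            kwargs = {k: thr[v] for k, v in mapping.items() if v in thr}
            return cls(**kwargs)

        config = PipelineConfig(
            bundle_dir=Path(raw["bundle_dir"]),
            output_dir=Path(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            activity=_take(ActivityThresholds, {
                "mode": "activity_mode", "h3k27ac_min": "h3k27ac_min",
                "h3k27me3_max": "h3k27me3_max"}),
            differential=_take(DifferentialThresholds, {
                "fdr_max": "fdr_max", "p_max": "p_max",
                "pairwise_p": "pairwise_p", "fc_sd_mult": "fc_sd_mult"}),
            filters=_take(FilterThresholds, {
                "dp_min": "dp_min", "phred_min": "phred_min",
                "maf_max": "maf_max",
                "min_confirmations": "min_confirmations"}),
            meth_primary_p=float(thr.get("meth_primary_p", methylation.PRIMARY_P)),
            meth_stringent_p=float(
                thr.get("meth_stringent_p", methylation.STRINGENT_P)),
            coverage_min=int(thr.get("coverage_min", methylation.COVERAGE_MIN)),
        )
    if not config.bundle_dir.is_dir():
        raise ValueError(f"bundle_dir does not exist: {config.bundle_dir}")
    for analysis in analyses:
        for rel in _REQUIRED_INPUTS[analysis]:
            if not (config.bundle_dir / rel).exists():
                raise ValueError(
                    f"missing input for analysis {analysis!r}: "
                    f"{config.bundle_dir / rel}"
                )
    if not 0 < config.meth_primary_p <= 1 or not 0 < config.meth_stringent_p <= 1:
        raise ValueError("methylation p cutoffs must be in (0, 1]")
    if config.coverage_min < 1:
        raise ValueError("coverage_min must be >= 1")
    return config


def load_config_file(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


# ---------------------------------------------------------------------------
# bundle readers


def _load_peaks(bundle_dir: Path) -> dict[str, dict[str, PeakSet]]:
    """Read peaks/<sample>.<mark>.bed into {sample: {mark: PeakSet}}."""
    out: dict[str, dict[str, PeakSet]] = {}
    for path in sorted((bundle_dir / "peaks").glob("*.bed")):
        stem = path.name[: -len(".bed")]
        sample, mark_safe = stem.split(".", 1)
        mark = mark_safe.replace("H3K9_14ac", "H3K9/14ac")
        out.setdefault(sample, {})[mark] = PeakSet(
            sample, mark, tuple(read_bed(path))
        )
    if not out:
        raise ValueError(f"no peak files found under {bundle_dir / 'peaks'}")
    return out


def _load_counts(bundle_dir: Path) -> tuple[RegionCountTable, list[str]]:
    regions = read_bed(bundle_dir / "regions.bed")
    long = pd.read_csv(bundle_dir / "counts.tsv", sep="\t")
    wide = long.pivot(index="region_id", columns="sample", values="raw_count")
    order = [f"region_{i}" for i in range(len(regions))]
    wide = wide.loc[order]
    groups_df = pd.read_csv(bundle_dir / "chip_groups.tsv", sep="\t")
    samples = [str(s) for s in groups_df["sample"]]
    wide = wide[samples]
    raw = wide.to_numpy(dtype=float)
    lengths_kb = np.array([len(iv) / 1e3 for iv in regions])
    lib = np.maximum(raw.sum(axis=0), 1) / 1e6
    normalized = raw / lengths_kb[:, None] / lib[None, :]
    table = RegionCountTable(regions=regions, samples=samples,
                             raw=raw, normalized=normalized)
    return table, [str(g) for g in groups_df["group"]]


# ---------------------------------------------------------------------------
# analyses


def run_chromatin(config: PipelineConfig, outdir: Path) -> dict[str, float]:
    peaks = _load_peaks(config.bundle_dir)
    promoters_per_sample, enhancers_per_sample = [], []
    for sample, marks in sorted(peaks.items()):
        if "H3K4me3" not in marks or "H3K4me1" not in marks:
            raise ValueError(f"sample {sample} lacks H3K4me3/H3K4me1 peaks")
        prom, enh = chromatin.define_candidate_regions(
            marks["H3K4me3"], marks["H3K4me1"]
        )
        promoters_per_sample.append(prom)
        enhancers_per_sample.append(enh)
    if len(peaks) >= 2:
        common_prom = chromatin.common_regions(promoters_per_sample)
        common_enh = chromatin.common_regions(enhancers_per_sample)
    else:
        common_prom = list(promoters_per_sample[0])
        common_enh = list(enhancers_per_sample[0])
    samples = sorted(peaks)
    # activity evidence: acetylation must be common to all samples,
    # repression counts if present in any sample
    ac_common = intersect_all([peaks[s]["H3K27ac"] for s in samples])
    me3_any = merge_intervals(
        iv for s in samples for iv in peaks[s]["H3K27me3"].intervals
    )
    ac_ps = PeakSet("common", "H3K27ac", tuple(ac_common))
    me3_ps = PeakSet("common", "H3K27me3", tuple(me3_any))
    prom_regions = chromatin.classify_activity(
        common_prom, "promoter", ac_ps, me3_ps, config.activity, samples
    )
    enh_regions = chromatin.classify_activity(
        common_enh, "enhancer", ac_ps, me3_ps, config.activity, samples
    )
    genes = chromatin.read_gene_annotation(
        config.bundle_dir / "genes/tss.tsv",
        config.bundle_dir / "genes/expression.tsv",
    )
    chromatin.associate_regions_to_genes(
        enh_regions, genes,
        distance_max=chromatin.ENHANCER_DISTANCE_MAX,
        rpkm_sum_min=chromatin.ENHANCER_RPKM_SUM_MIN,
    )
    chromatin.associate_regions_to_genes(
        prom_regions, genes,
        distance_max=chromatin.ENHANCER_DISTANCE_MAX,
        rpkm_sum_min=chromatin.PROMOTER_RPKM_SUM_MIN,
    )
    all_regions = prom_regions + enh_regions
    chromatin.write_regions_bed(outdir / "regions_classified.bed", all_regions)
    chromatin.write_associations_tsv(outdir / "gene_associations.tsv", all_regions)
    return {
        "n_samples": len(peaks),
        "n_common_promoters": len(common_prom),
        "n_common_enhancers": len(common_enh),
        "n_active_promoters": sum(r.activity == "active" for r in prom_regions),
        "n_active_enhancers": sum(r.activity == "active" for r in enh_regions),
        "n_regions_with_genes": sum(bool(r.associated_genes) for r in all_regions),
    }


def run_diff(config: PipelineConfig, outdir: Path) -> dict[str, float]:
    table, groups = _load_counts(config.bundle_dir)
    results = nb_differential_test(table, groups, numerator="hrAPL")
    selected = discriminating_regions(results, config.differential, "gain")
    sel_set = {str(r.region) for r in selected}
    df = pd.DataFrame({
        "region": [str(r.region) for r in results],
        "log2fc": [r.log2fc for r in results],
        "statistic": [r.statistic for r in results],
        "p_value": [r.p_value for r in results],
        "q_value": [r.q_value for r in results],
        "selected": [str(r.region) in sel_set for r in results],
    })
    df.to_csv(outdir / "differential.tsv", sep="\t", index=False,
              float_format="%.6g")
    write_bed(outdir / "discriminating_regions.bed",
              [r.region for r in selected])
    # FC > k x STDEV gain/loss between group mean enrichments
    hr = table.normalized[:, [g == "hrAPL" for g in groups]].mean(axis=1)
    apl = table.normalized[:, [g == "APL" for g in groups]].mean(axis=1)
    fc_results = changed_regions_fc_sd(
        apl, hr, config.differential.fc_sd_mult, regions=table.regions
    )
    fc_df = pd.DataFrame({
        "region": [str(r.region) for r in fc_results],
        "log2_ratio": [r.log2fc for r in fc_results],
        "direction": [r.direction for r in fc_results],
    })
    fc_df.to_csv(outdir / "fc_sd_calls.tsv", sep="\t", index=False,
                 float_format="%.6g")
    n_gain = sum(r.direction == "gain" for r in fc_results)
    n_loss = sum(r.direction == "loss" for r in fc_results)
    return {
        "n_regions": len(results),
        "n_discriminating": len(selected),
        "fc_sd_gain": n_gain,
        "fc_sd_loss": n_loss,
    }


def run_methylation(config: PipelineConfig, outdir: Path) -> dict[str, float]:
    cohort = methylation.read_cohort_matrix(
        config.bundle_dir / "cohort_matrix.tsv",
        config.bundle_dir / "sample_groups.tsv",
    )
    per_sample: dict[str, list] = {}
    for path in sorted((config.bundle_dir / "methylation").glob("*.calls.tsv")):
        sample = path.name[: -len(".calls.tsv")]
        calls = methylation.read_cpg_calls(path)
        cg = methylation.filter_cg_context(calls)
        sites = methylation.combine_symmetric_cpgs(cg)
        per_sample[sample] = methylation.filter_coverage(
            sites, config.coverage_min
        )
    matrix = methylation.build_matrix(per_sample, cohort.groups)
    signature, stringent = methylation.supervised_cpg_test(
        matrix, config.meth_primary_p, config.meth_stringent_p
    )
    final = methylation.refine_against_cohort(stringent, cohort)
    hypo, hyper = methylation.classify_direction(signature)
    methylation.write_signature_tsv(
        outdir / "cpg_signature.tsv", signature, stringent, final
    )
    write_bed(
        outdir / "final_cpgs.bed",
        [GenomicInterval(c.chrom, c.pos, c.pos + 2) for c in final],
    )
    return {
        "n_cpgs_tested": int(matrix.betas.shape[0]),
        "n_signature": len(signature),
        "n_hypo": len(hypo),
        "n_hyper": len(hyper),
        "n_stringent": len(stringent),
        "n_final": len(final),
    }


def run_variants(config: PipelineConfig, outdir: Path) -> dict[str, float]:
    records = variants.read_vcf(config.bundle_dir / "variants.vcf")
    survivors, attrition = variants.run_cascade(records, config.filters)
    variants.write_vcf(outdir / "variants_filtered.vcf", survivors)
    variants.write_attrition_tsv(outdir / "variant_attrition.tsv", attrition)
    return {
        "n_input_variants": len(records),
        "n_surviving_variants": len(survivors),
    }


_RUNNERS = {
    "chromatin": run_chromatin,
    "diff": run_diff,
    "methylation": run_methylation,
    "variants": run_variants,
}


def run_pipeline(
    config: PipelineConfig, analyses: tuple[str, ...] = ANALYSES
) -> pd.DataFrame:
    """Run the requested analyses in order and write the run report.

    Returns the report as a DataFrame (analysis, key, value); the same
    table is written to ``<output_dir>/report.tsv``.  Per-stage wall
    times go to the log, not the report, so reruns on identical inputs
    are byte-identical.
    """
    unknown = set(analyses) - set(ANALYSES)
    if unknown:
        raise ValueError(f"unknown analyses: {sorted(unknown)}")
    config.output_dir.mkdir(parents=True, exist_ok=True)
    rows: list[tuple[str, str, float]] = []
    for name in ANALYSES:  # fixed dependency order
        if name not in analyses:
            continue
        outdir = config.output_dir / name
        outdir.mkdir(exist_ok=True)
        t0 = time.monotonic()
        try:
            counts = _RUNNERS[name](config, outdir)
        except Exception:
            logger.exception("analysis %s failed", name)
            raise
        logger.info("analysis %s done in %.1fs", name, time.monotonic() - t0)
        rows.extend((name, k, float(v)) for k, v in counts.items())
    report = pd.DataFrame(rows, columns=["analysis", "key", "value"])
    report.to_csv(config.output_dir / "report.tsv", sep="\t", index=False)
    return report
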