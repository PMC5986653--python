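"""CpG processing chain and the supervised methylation-signature test."""

import numpy as np
import pandas as pd
import pytest

from episig.methylation import (
    CpGSite,
    CytosineCall,
    MethylationMatrix,
    build_matrix,
    classify_direction,
    combine_symmetric_cpgs,
    filter_cg_context,
    filter_coverage,
    read_cpg_calls,
    refine_against_cohort,
    supervised_cpg_test,
)


def call(pos, strand="+", meth=3, total=5, context="CG", chrom="chr1"):
    return CytosineCall(chrom, pos, strand, context, meth, total)


class TestContextFilter:
    def test_mixed_contexts(self):
        calls = [call(1), call(10, context="CHH"), call(20, context="CXG"), call(30)]
        kept = filter_cg_context(calls)
        assert [c.pos for c in kept] == [1, 30]

    def test_all_non_cpg_gives_empty(self):
        assert filter_cg_context([call(1, context="CHH")]) == []

    def test_unknown_context_rejected_at_construction(self):
        with pytest.raises(ValueError, match="unknown context"):
            call(5, context="CHG")

    def test_random_contexts_match_label_count(self, rng):
        contexts = rng.choice(["CG", "CHH", "CXG"], size=200)
        calls = [call(2 * i, context=c) for i, c in enumerate(contexts)]
        assert len(filter_cg_context(calls)) == int((contexts == "CG").sum())


class TestStrandCombining:
    def test_paired_dyad_sums_counts(self):
        sites = combine_symmetric_cpgs(
            [call(100, "+", 3, 5), call(101, "-", 2, 5)]
        )
        assert sites == [CpGSite("chr1", 100, 5, 10)]
        assert sites[0].beta == pytest.approx(0.5)

    def test_unpaired_forward_passthrough(self):
        sites = combine_symmetric_cpgs([call(100, "+", 3, 5)])
        assert sites == [CpGSite("chr1", 100, 3, 5)]
        assert sites[0].beta == pytest.approx(0.6)

    def test_unpaired_reverse_addressed_by_dyad_forward_base(self):
        sites = combine_symmetric_cpgs([call(101, "-", 2, 4)])
        assert sites == [CpGSite("chr1", 100, 2, 4)]

    def test_duplicate_call_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            combine_symmetric_cpgs([call(100, "+"), call(100, "+")])

    def test_conservation_of_counts(self, rng):
        calls = []
        for i in range(300):
            pos = 10 * i
            cov_f, cov_r = rng.integers(0, 30, 2)
            if cov_f:
                calls.append(call(pos, "+", int(rng.integers(0, cov_f + 1)), int(cov_f)))
            if cov_r:
                calls.append(call(pos + 1, "-", int(rng.integers(0, cov_r + 1)), int(cov_r)))
        sites = combine_symmetric_cpgs(calls)
        assert sum(s.meth_count for s in sites) == sum(c.meth_count for c in calls)
        assert sum(s.total_count for s in sites) == sum(c.total_count for c in calls)


class TestCoverageFilter:
    def test_boundary_is_inclusive_five(self):
        sites = [CpGSite("chr1", 0, 1, 4), CpGSite("chr1", 10, 1, 5)]
        kept = filter_coverage(sites)
        assert [s.pos for s in kept] == [10]

    def test_empty_input(self):
        assert filter_coverage([]) == []

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            filter_coverage([], min_total=0)

    def test_survivors_match_bruteforce(self, rng):
        sites = [
            CpGSite("chr1", i, 0, int(t))
            for i, t in enumerate(rng.integers(1, 15, 100))
        ]
        kept = filter_coverage(sites, 7)
        assert len(kept) == sum(s.total_count >= 7 for s in sites)


def site_map(samples_betas, coverage=20):
    """{sample: [CpGSite...]} from {sample: {pos: beta}}."""
    out = {}
    for sample, by_pos in samples_betas.items():
        out[sample] = [
            CpGSite("chr1", pos, int(round(beta * coverage)), coverage)
            for pos, beta in sorted(by_pos.items())
        ]
    return out


class TestBuildMatrix:
    GROUPS = {"hr1": "hrAPL", "hr2": "hrAPL", "a1": "APL", "a2": "APL"}

    def test_incomplete_cpg_excluded(self):
        betas = {
            "hr1": {100: 0.5, 200: 0.5},
            "hr2": {100: 0.5, 200: 0.5},
            "a1": {100: 0.5, 200: 0.5},
            "a2": {100: 0.5},  # missing CpG 200
        }
        matrix = build_matrix(site_map(betas), self.GROUPS)
        assert list(matrix.betas.index) == [("chr1", 100)]

    def test_complete_cpg_included(self):
        betas = {s: {100: 0.4} for s in self.GROUPS}
        matrix = build_matrix(site_map(betas), self.GROUPS)
        assert matrix.betas.shape == (1, 4)

    def test_unlabeled_sample_rejected(self):
        betas = {"hr1": {1: 0.1}, "a1": {1: 0.1}, "mystery": {1: 0.1}}
        with pytest.raises(ValueError, match="mystery"):
            build_matrix(site_map(betas), self.GROUPS)

    def test_empty_sample_rejected(self):
        per_sample = site_map({s: {100: 0.5} for s in self.GROUPS})
        per_sample["a1"] = []
        with pytest.raises(ValueError, match="a1"):
            build_matrix(per_sample, self.GROUPS)

    def test_random_missingness_matches_completeness_scan(self, rng):
        positions = list(range(0, 1000, 10))
        betas = {}
        for s in self.GROUPS:
            keep = rng.random(len(positions)) > 0.2
            betas[s] = {p: 0.5 for p, k in zip(positions, keep) if k}
        matrix = build_matrix(site_map(betas), self.GROUPS)
        expected = {
            p for p in positions if all(p in betas[s] for s in self.GROUPS)
        }
        assert {pos for _, pos in matrix.betas.index} == expected


def make_matrix(hr, apl, aml=None, positions=None):
    """Matrix from per-group beta arrays of shape (n_cpgs, n_samples)."""
    hr, apl = np.asarray(hr, float), np.asarray(apl, float)
    cols = {f"hr{i}": hr[:, i] for i in range(hr.shape[1])}
    cols.update({f"apl{i}": apl[:, i] for i in range(apl.shape[1])})
    groups = {c: ("hrAPL" if c.startswith("hr") else "APL") for c in cols}
    if aml is not None:
        aml = np.asarray(aml, float)
        cols.update({f"aml{i}": aml[:, i] for i in range(aml.shape[1])})
        groups.update({f"aml{i}": "AML" for i in range(aml.shape[1])})
    n = hr.shape[0]
    positions = positions or [("chr1", 10 * i) for i in range(n)]
    betas = pd.DataFrame(
        cols, index=pd.MultiIndex.from_tuples(positions, names=["chrom", "pos"])
    )
    return MethylationMatrix(betas=betas, groups=groups)


class TestSupervisedTest:
    def test_complete_separation_reaches_stringent_cutoff(self):
        hr = np.full((1, 5), 0.1)
        hr += np.arange(5) * 0.01  # break ties within the group
        apl = np.full((1, 10), 0.8) + np.arange(10) * 0.01
        matrix = make_matrix(hr, apl)
        signature, stringent = supervised_cpg_test(matrix)
        assert len(signature) == 1 and len(stringent) == 1
        assert signature[0].p_value == pytest.approx(2.0 / 3003.0)
        assert signature[0].direction == "hypo"

    def test_identical_groups_not_selected(self):
        hr = np.tile(np.linspace(0.2, 0.8, 5), (1, 1))
        apl = np.tile(np.linspace(0.2, 0.8, 10), (1, 1))
        matrix = make_matrix(hr, apl)
        signature, stringent = supervised_cpg_test(matrix)
        assert signature == [] and stringent == []

    def test_single_overlap_cannot_reach_stringent_at_5v10(self, rng):
        # swap one value across groups: no longer completely separated
        for _ in range(20):
            hr = np.sort(rng.uniform(0, 0.4, (1, 5)))
            apl = np.sort(rng.uniform(0.5, 1.0, (1, 10)))
            hr2, apl2 = hr.copy(), apl.copy()
            hr2[0, -1], apl2[0, 0] = apl[0, 0], hr[0, -1]
            matrix = make_matrix(hr2, apl2)
            signature, stringent = supervised_cpg_test(matrix)
            assert stringent == []

    def test_small_group_rejected(self):
        matrix = make_matrix(np.full((2, 1), 0.1), np.full((2, 10), 0.9))
        with pytest.raises(ValueError, match=">=2 samples"):
            supervised_cpg_test(matrix)

    def test_column_order_invariance(self, rng):
        hr = rng.uniform(0, 1, (50, 5))
        apl = rng.uniform(0, 1, (50, 10))
        matrix = make_matrix(hr, apl)
        shuffled = MethylationMatrix(
            betas=matrix.betas[list(rng.permutation(matrix.betas.columns))],
            groups=matrix.groups,
        )
        sig_a, _ = supervised_cpg_test(matrix)
        sig_b, _ = supervised_cpg_test(shuffled)
        assert [(c.chrom, c.pos, c.p_value) for c in sig_a] == [
            (c.chrom, c.pos, c.p_value) for c in sig_b
        ]


class TestCohortRefinement:
    def test_missing_in_one_cohort_column_drops_cpg(self):
        hr = np.full((2, 5), 0.05) + np.arange(5) * 0.01
        apl = np.full((2, 10), 0.9) + np.arange(10) * 0.005
        aml = np.full((2, 181), 0.5)
        aml[1, 42] = np.nan  # one missing AML beta
        matrix = make_matrix(hr, apl, aml)
        signature, stringent = supervised_cpg_test(matrix)
        assert len(stringent) == 2
        final = refine_against_cohort(stringent, matrix)
        assert [(c.chrom, c.pos) for c in final] == [("chr1", 0)]

    def test_no_missingness_keeps_all(self):
        hr = np.full((2, 5), 0.05) + np.arange(5) * 0.01
        apl = np.full((2, 10), 0.9) + np.arange(10) * 0.005
        matrix = make_matrix(hr, apl, np.full((2, 20), 0.5))
        _, stringent = supervised_cpg_test(matrix)
        assert refine_against_cohort(stringent, matrix) == stringent

    def test_no_cohort_columns_rejected(self):
        matrix = make_matrix(np.full((1, 5), 0.1), np.full((1, 10), 0.9))
        with pytest.raises(ValueError, match="AML"):
            refine_against_cohort([], matrix)


class TestDirections:
    def test_partition_is_exhaustive_and_disjoint(self, rng):
        hr = rng.uniform(0, 1, (300, 5))
        apl = rng.uniform(0, 1, (300, 10))
        # plant strong effects so some CpGs are selected
        hr[:30] = rng.uniform(0, 0.1, (30, 5))
        apl[:30] = rng.uniform(0.8, 1.0, (30, 10))
        matrix = make_matrix(hr, apl)
        signature, _ = supervised_cpg_test(matrix)
        hypo, hyper = classify_direction(signature)
        assert len(hypo) + len(hyper) == len(signature)
        assert {id(c) for c in hypo}.isdisjoint({id(c) for c in hyper})
        for c in hypo:
            assert c.mean_diff < 0
        for c in hyper:
            assert c.mean_diff >= 0


class TestIO:
    def test_native_dialect_round_trip(self, tmp_path):
        path = tmp_path / "x.calls.tsv"
        path.write_text(
            "chrom\tpos\tstrand\tcontext\tmeth_count\ttotal_count\n"
            "chr1\t100\t+\tCG\t3\t5\n"
            "chr1\t101\t-\tCG\t2\t5\n"
        )
        calls = read_cpg_calls(path)
        assert calls == [call(100, "+", 3, 5), call(101, "-", 2, 5)]

    def test_bismark_coverage_dialect(self, tmp_path):
        path = tmp_path / "x.cov"
        path.write_text("chr1\t100\t100\t60.0\t3\t2\n")
        calls = read_cpg_calls(path)
        assert calls == [call(100, "+", 3, 5)]
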