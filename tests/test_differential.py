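"""Rank tests vs enumeration oracles, FC rule, size factors, NB test, FDR."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from episig.differential import (
    DifferentialResult,
    DifferentialThresholds,
    bh_fdr,
    changed_regions_fc_sd,
    discriminating_regions,
    fc_sd_calls,
    nb_differential_test,
    rank_sum_test,
    signed_rank_test,
    size_factors,
)
from episig.intervals import RegionCountTable


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the DP implementations)


def oracle_rank_sum_p(a, b):
    """Enumerate every C(n, n_a) label assignment of the mid-ranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n, n_a = len(pooled), len(a)
    observed = ranks[:n_a].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n_a)]
    total = len(sums)
    eps = 1e-9
    cdf = sum(s <= observed + eps for s in sums) / total
    sf = sum(s >= observed - eps for s in sums) / total
    return min(1.0, 2.0 * min(cdf, sf))


def oracle_signed_rank_p(before, after):
    """Enumerate all 2^n sign assignments of the non-zero differences."""
    d = np.asarray(after, float) - np.asarray(before, float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=d.size)
    ]
    total = len(sums)
    eps = 1e-9
    cdf = sum(s <= observed + eps for s in sums) / total
    sf = sum(s >= observed - eps for s in sums) / total
    return min(1.0, 2.0 * min(cdf, sf))


class TestSignedRank:
    def test_five_concordant_pairs(self):
        before = np.zeros(5)
        after = np.arange(1.0, 6.0)
        w, p = signed_rank_test(before, after)
        assert w == 15.0
        assert p == pytest.approx(0.0625)

    def test_no_evidence_when_identical(self):
        with pytest.warns(UserWarning, match="p = 1"):
            _, p = signed_rank_test([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            signed_rank_test([1.0], [1.0, 2.0])

    def test_matches_enumeration_oracle_small_n(self, rng):
        for n in range(1, 13):
            for _ in range(4):
                before = rng.integers(0, 4, n).astype(float)
                after = rng.integers(0, 4, n).astype(float)
                _, p = signed_rank_test(before, after)
                assert p == pytest.approx(oracle_signed_rank_p(before, after))

    def test_agrees_with_scipy_exact_without_ties(self, rng):
        d = rng.normal(0.3, 1.0, 15)
        _, p = signed_rank_test(np.zeros(15), d)
        expected = sps.wilcoxon(d, method="exact").pvalue
        assert p == pytest.approx(expected)

    def test_planted_shift_detected_at_scale(self, rng):
        # ~2,700 paired binding-site measurements with a 0.5 SD mean shift
        n = 2723
        before = rng.normal(0.0, 1.0, n)
        after = before + rng.normal(0.5, 1.0, n)
        _, p = signed_rank_test(before, after)
        assert p < 0.01

    def test_large_sample_approximation_is_calibratedish(self, rng):
        # null: p should not be tiny
        before = rng.normal(size=60)
        after = before + rng.normal(scale=1.0, size=60)
        _, p = signed_rank_test(before, after)
        assert 0.0 < p <= 1.0


class TestRankSum:
    def test_complete_separation_5v10(self):
        _, p = rank_sum_test(np.arange(1, 6), np.arange(6, 16))
        assert p == pytest.approx(2.0 / 3003.0)

    def test_identical_constant_groups(self):
        _, p = rank_sum_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_matches_enumeration_oracle_small_n(self, rng):
        for n_a in range(1, 6):
            for n_b in range(1, 7):
                a = rng.integers(0, 5, n_a).astype(float)
                b = rng.integers(0, 5, n_b).astype(float)
                _, p = rank_sum_test(a, b)
                assert p == pytest.approx(oracle_rank_sum_p(a, b)), (a, b)

    def test_agrees_with_scipy_exact_without_ties(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=9)
        _, p = rank_sum_test(a, b)
        expected = sps.mannwhitneyu(a, b, method="exact",
                                    alternative="two-sided").pvalue
        assert p == pytest.approx(expected)

    def test_type_one_error_controlled(self, rng):
        # discrete exact test is conservative at both published alphas
        reps = 4000
        a = rng.normal(size=(reps, 5))
        b = rng.normal(size=(reps, 10))
        p = np.array([rank_sum_test(a[i], b[i])[1] for i in range(reps)])
        for alpha in (0.01, 0.005):
            rate = float((p < alpha).mean())
            mc_tol = 3.0 * np.sqrt(alpha * (1 - alpha) / reps)
            assert rate <= alpha + mc_tol

    def test_large_sample_branch_matches_scipy_asymptotic(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(size=12)
        _, p = rank_sum_test(a, b)
        expected = sps.mannwhitneyu(
            a, b, method="asymptotic", alternative="two-sided", use_continuity=True
        ).pvalue
        assert p == pytest.approx(expected, rel=1e-6)


class TestFcSdRule:
    def test_zero_spread_gives_no_calls(self):
        with pytest.warns(UserWarning, match="zero spread"):
            calls = fc_sd_calls(np.ones(10))
        assert all(c == "none" for c in calls)

    def test_single_outlier_is_gain(self):
        r = np.concatenate([np.zeros(100), [10.0]])
        calls = fc_sd_calls(r)
        # m ~= 0.099, s ~= 0.995 -> threshold ~= 3.08 < 10
        assert list(calls).count("gain") == 1
        assert calls[-1] == "gain"
        assert list(calls).count("loss") == 0

    def test_matches_bruteforce_recomputation(self, rng):
        for _ in range(100):
            control = rng.gamma(2.0, 5.0, 200)
            treated = rng.gamma(2.0, 5.0, 200)
            results = changed_regions_fc_sd(control, treated)
            scale = np.concatenate([control, treated]).mean()
            r = np.log2((treated / scale + 1) / (control / scale + 1))
            m, s = r.mean(), r.std(ddof=1)
            for i, res in enumerate(results):
                if r[i] > m + 3 * s:
                    expected = "gain"
                elif r[i] < m - 3 * s:
                    expected = "loss"
                else:
                    expected = "none"
                assert res.direction == expected
                assert res.selected == (expected != "none")

    def test_swap_symmetry(self, rng):
        control = rng.gamma(2.0, 5.0, 300)
        treated = control * rng.lognormal(0, 0.5, 300)
        fwd = changed_regions_fc_sd(control, treated)
        rev = changed_regions_fc_sd(treated, control)
        flip = {"gain": "loss", "loss": "gain", "none": "none"}
        assert [r.direction for r in rev] == [flip[r.direction] for r in fwd]

    def test_scale_invariance(self, rng):
        control = rng.gamma(2.0, 5.0, 300)
        treated = control * rng.lognormal(0, 0.4, 300)
        base = [r.direction for r in changed_regions_fc_sd(control, treated)]
        for k in (0.001, 7.3, 1e4):
            scaled = [
                r.direction
                for r in changed_regions_fc_sd(control * k, treated * k)
            ]
            assert scaled == base


class TestSizeFactors:
    def test_identical_columns_equal_factors(self):
        mat = np.tile(np.array([[10.0], [20.0], [5.0]]), (1, 4))
        np.testing.assert_allclose(size_factors(mat), np.ones(4))

    def test_doubled_column_closed_form(self):
        a = np.array([10.0, 40.0, 100.0])
        mat = np.column_stack([a, 2 * a])
        np.testing.assert_allclose(
            size_factors(mat), [1 / np.sqrt(2), np.sqrt(2)]
        )
        normalized = mat / size_factors(mat)
        np.testing.assert_allclose(normalized[:, 0], normalized[:, 1])

    def test_matches_direct_formula(self, rng):
        mat = rng.poisson(50, size=(100, 6)).astype(float)
        mat[rng.integers(0, 100, 10), rng.integers(0, 6, 10)] = 0
        factors = size_factors(mat)
        nz = np.all(mat > 0, axis=1)
        geo = np.exp(np.log(mat[nz]).mean(axis=1))
        expected = np.median(mat[nz] / geo[:, None], axis=0)
        np.testing.assert_allclose(factors, expected)

    def test_no_common_nonzero_region_rejected(self):
        mat = np.array([[0.0, 5.0], [5.0, 0.0]])
        with pytest.raises(ValueError, match="size factors"):
            size_factors(mat)


def make_table(raw):
    raw = np.asarray(raw, float)
    return RegionCountTable(
        regions=None, samples=[f"s{j}" for j in range(raw.shape[1])], raw=raw
    )


class TestNbDifferential:
    def test_identical_counts_give_p_one(self):
        raw = np.tile(np.array([[30.0], [90.0], [10.0]]), (1, 6))
        results = nb_differential_test(make_table(raw), ["A"] * 3 + ["B"] * 3)
        assert all(r.p_value == 1.0 for r in results)

    def test_small_group_rejected(self):
        raw = np.ones((5, 3)) * 10
        with pytest.raises(ValueError, match=">=2 samples"):
            nb_differential_test(make_table(raw), ["A", "B", "B"])

    def test_planted_fold_change_recovered(self, rng):
        n, n_planted = 500, 25
        mu, disp = 100.0, 0.05
        r = 1.0 / disp
        lib = rng.uniform(0.7, 1.3, 10)
        base = mu * rng.lognormal(-0.125, 0.5, n)
        fold = np.ones((n, 10))
        planted = rng.choice(n, n_planted, replace=False)
        fold[np.ix_(planted, np.arange(5, 10))] = 4.0
        m = base[:, None] * lib[None, :] * fold
        raw = rng.negative_binomial(r, r / (r + m)).astype(float)
        results = nb_differential_test(
            make_table(raw), ["A"] * 5 + ["B"] * 5, numerator="B"
        )
        q = np.array([x.q_value for x in results])
        recovered = (q[planted] < 0.01).mean()
        assert recovered >= 0.9

    def test_null_p_roughly_uniform(self, rng):
        n = 2000
        r = 1.0 / 0.05
        lib = rng.uniform(0.7, 1.3, 10)
        m = 100.0 * lib[None, :] * np.ones((n, 1))
        raw = rng.negative_binomial(r, r / (r + m)).astype(float)
        results = nb_differential_test(make_table(raw), ["A"] * 5 + ["B"] * 5)
        p = np.array([x.p_value for x in results])
        assert sps.kstest(p, "uniform").statistic < 0.05


class TestDiscriminatingRegions:
    def test_all_null_empty(self):
        results = [
            DifferentialResult(i, 1.0, 0.0, 1.0, 1.0, "none", False)
            for i in range(10)
        ]
        assert discriminating_regions(results) == []

    def test_matches_filter_oracle(self, rng):
        results = []
        for i in range(200):
            p = float(rng.uniform(0, 0.001)) if i % 3 else float(rng.uniform(0, 1))
            q = min(1.0, p * float(rng.uniform(1, 30)))
            fc = float(rng.normal())
            results.append(DifferentialResult(i, fc, 0.0, p, q, "none", False))
        thr = DifferentialThresholds()
        selected = {r.region for r in discriminating_regions(results, thr, "gain")}
        expected = {
            r.region
            for r in results
            if r.q_value < 0.01 and r.p_value < 0.0002 and r.log2fc > 0
        }
        assert selected == expected
        # losses are the mirror set
        selected_loss = {
            r.region for r in discriminating_regions(results, thr, "loss")
        }
        expected_loss = {
            r.region
            for r in results
            if r.q_value < 0.01 and r.p_value < 0.0002 and r.log2fc < 0
        }
        assert selected_loss == expected_loss

    def test_selected_flag_and_direction_consistent(self):
        res = DifferentialResult(0, 2.0, 5.0, 1e-6, 1e-5, "none", False)
        out = discriminating_regions([res])
        assert out[0].selected and out[0].direction == "gain"


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.05]).tolist() == [0.05]

    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_matches_hand_step_up(self, rng):
        p = rng.uniform(size=50)
        order = np.argsort(p)
        m = len(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_fdr(p), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])
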