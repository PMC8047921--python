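import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dielprot.jtk import (JtkConfig, exact_null, jtk_matrix, jtk_test,
                          kendall_s, permutation_fdr, reference_wave, sf_abs)


def enumerate_null(tie_sizes):
    """Brute-force null pmf of S: all n! permutations of distinct values
    against a reference with the given tie-group sizes."""
    ref = np.concatenate([[g] * s for g, s in enumerate(tie_sizes)]).astype(float)
    n = ref.size
    counts = {}
    for perm in itertools.permutations(range(n)):
        v = np.asarray(perm, dtype=float)
        s = kendall_s(v, ref)
        counts[s] = counts.get(s, 0) + 1
    total = sum(counts.values())
    return {s: c / total for s, c in counts.items()}


class TestReferenceWave:
    def test_cosine_extremes(self):
        r = reference_wave(24, 0, [0, 6, 12, 18])
        assert np.argmax(r) == 0 and np.argmin(r) == 2

    def test_full_period_lag_shift_identical_ranks(self):
        t = np.array([1.0, 5.0, 9.5, 14.0, 20.0])
        r1 = reference_wave(24, 3, t)
        r2 = reference_wave(24, 27, t)
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_replicates_share_rank(self):
        r = reference_wave(24, 0, [6, 6, 12])
        assert r[0] == r[1]


class TestKendallS:
    def test_maximal_concordance_and_reversal(self):
        ref = np.arange(5.0)
        assert kendall_s(np.arange(5.0), ref) == 10
        assert kendall_s(np.arange(5.0)[::-1], ref) == -10

    def test_missing_excluded_matches_subseries(self):
        ref = np.arange(5.0)
        v = np.array([3.0, np.nan, 1.0, 4.0, 2.0])
        keep = ~np.isnan(v)
        assert kendall_s(v, ref) == kendall_s(v[keep], ref[keep])

    def test_pairwise_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=6)
        r = rng.normal(size=6)
        v[2] = np.nan
        expected = 0
        for j in range(6):
            for k in range(j + 1, 6):
                if np.isnan(v[j]) or np.isnan(v[k]):
                    continue
                expected += int(np.sign(v[k] - v[j]) * np.sign(r[k] - r[j]))
        assert kendall_s(v, r) == expected

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=12,
                    unique=True))
    def test_antisymmetry_under_value_reversal(self, vals):
        ref = np.arange(len(vals), dtype=float)
        v = np.asarray(vals)
        assert kendall_s(v, ref) == -kendall_s(v[::-1], ref)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            kendall_s([np.nan, 1.0], [1.0, 2.0])


class TestExactNull:
    def test_three_points_no_ties(self):
        s, pmf = exact_null([1, 1, 1])
        lookup = dict(zip(s.tolist(), pmf.tolist()))
        assert lookup[3] == pytest.approx(1 / 6)
        assert lookup[-3] == pytest.approx(1 / 6)
        assert lookup[1] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("ties", [(1, 1, 1, 1), (2, 2), (3, 1, 2),
                                      (2, 2, 2), (1, 4), (2, 1, 1, 1)])
    def test_sums_to_one_and_symmetric(self, ties):
        s, pmf = exact_null(ties)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(pmf, pmf[::-1], atol=1e-14)

    @pytest.mark.parametrize("ties", [(1, 1, 1, 1), (2, 1, 2), (3, 3),
                                      (2, 2, 1, 1), (1, 2, 3)])
    def test_matches_full_enumeration(self, ties):
        s, pmf = exact_null(ties)
        expect = enumerate_null(ties)
        got = {int(sv): p for sv, p in zip(s, pmf) if p > 0}
        assert set(got) == set(expect)
        for k in expect:
            assert got[k] == pytest.approx(expect[k], abs=1e-12)

    def test_untied_tail_matches_scipy_kendalltau(self):
        """For an untied reference the exact two-sided tail equals the
        exact Kendall tau p-value."""
        rng = np.random.default_rng(4)
        for n in (5, 7, 8):
            v = rng.normal(size=n)
            ref = np.arange(n, dtype=float)
            s = kendall_s(v, ref)
            p_ours = sf_abs([1] * n, s)
            p_scipy = stats.kendalltau(v, ref, method="exact").pvalue
            assert p_ours == pytest.approx(p_scipy, rel=1e-10)


class TestJtkTest:
    def test_noiseless_cosine_recovers_reference(self):
        t = np.arange(0, 24, 3.0)  # 8 distinct hours
        v = np.cos(2 * np.pi * t / 24)
        cfg = JtkConfig(bonferroni=False)
        res = jtk_test(t, v, cfg)
        assert res.best_period == 24.0
        assert res.best_lag == 0.0
        assert res.tau == 1.0
        # p equals the exact null tail at the maximal S for that reference
        ref = reference_wave(res.best_period, res.best_lag, t)
        _, tie_sizes = np.unique(np.round(ref, 9), return_counts=True)
        assert res.p == pytest.approx(sf_abs(tuple(tie_sizes), res.s_statistic))

    def test_constant_series_p_one(self):
        t = np.arange(0, 24, 4.0)
        res = jtk_test(t, np.full_like(t, 2.5))
        assert res.p == 1.0 and res.s_statistic == 0

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 24, 10))
        v = rng.normal(size=10)
        r1 = jtk_test(t, v)
        r2 = jtk_test(t, np.exp(3 * v) + 7)
        assert r1.p == r2.p and r1.s_statistic == r2.s_statistic
        assert r1.best_lag == r2.best_lag

    def test_bonferroni_scales_p(self):
        t = np.sort(np.random.default_rng(5).uniform(0, 24, 9))
        v = np.cos(2 * np.pi * t / 24) + 0.3 * np.random.default_rng(6).normal(size=9)
        p_raw = jtk_test(t, v, JtkConfig(bonferroni=False)).p
        p_adj = jtk_test(t, v, JtkConfig(bonferroni=True)).p
        assert p_adj == pytest.approx(min(1.0, p_raw * 24))

    def test_replicate_time_stamps_are_tied(self):
        # two replicates per time: their within-pair order cannot matter
        t = np.repeat([0.0, 6.0, 12.0, 18.0], 2)
        rng = np.random.default_rng(8)
        v = rng.normal(size=8)
        res1 = jtk_test(t, v)
        v_swapped = v.copy()
        v_swapped[0], v_swapped[1] = v[1], v[0]
        res2 = jtk_test(t, v_swapped)
        assert res1.s_statistic == res2.s_statistic

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            jtk_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestJtkMatrix:
    def test_agrees_with_per_series_path(self):
        rng = np.random.default_rng(9)
        t = np.sort(rng.uniform(0, 24, 12))
        V = rng.normal(size=(40, 12))
        V[rng.random(V.shape) < 0.1] = np.nan
        ok_rows = (~np.isnan(V)).sum(axis=1) >= 3
        frame = pd.DataFrame(V[ok_rows])
        res = jtk_matrix(frame, t)
        for i, (_, row) in enumerate(res.iterrows()):
            single = jtk_test(t, frame.iloc[i].to_numpy())
            assert row["S"] == single.s_statistic
            assert row["p"] == pytest.approx(single.p, rel=1e-12)
            assert row["best_lag"] == single.best_lag
            assert row["tau"] == pytest.approx(single.tau, rel=1e-12)


class TestPermutationFdr:
    def test_null_data_saturates(self):
        rng = np.random.default_rng(10)
        t = np.sort(rng.uniform(0, 24, 12))
        V = pd.DataFrame(rng.normal(size=(300, 12)))
        cfg = JtkConfig(p_threshold=0.2, seed=0)
        out = permutation_fdr(V, t, cfg, n_permutations=5)
        assert out["n_observed_passing"] > 0
        assert 0.5 < out["fdr"] < 2.0

    def test_perfect_signal_near_zero(self):
        rng = np.random.default_rng(11)
        t = np.sort(rng.uniform(0, 24, 14))
        phases = rng.uniform(0, 24, 60)
        V = pd.DataFrame(np.cos(2 * np.pi * (t[None, :] - phases[:, None]) / 24))
        out = permutation_fdr(V, t, JtkConfig(seed=1), n_permutations=5)
        assert out["n_observed_passing"] == 60
        assert out["fdr"] < 0.05

    def test_zero_passers_reported_as_undefined(self):
        rng = np.random.default_rng(12)
        t = np.sort(rng.uniform(0, 24, 8))
        V = pd.DataFrame(rng.normal(size=(5, 8)))
        out = permutation_fdr(V, t, JtkConfig(p_threshold=1e-9, seed=2),
                              n_permutations=2)
        assert out["n_observed_passing"] == 0
        assert np.isnan(out["fdr"])
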