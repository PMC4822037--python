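import numpy as np
import pandas as pd
import pytest

from angiomir import (
    ValidationError,
    cutpoint_scan,
    dichotomize_at_percentile,
    km_estimate,
    logrank_test,
    percentile_grid,
)
from angiomir.survival import _logrank_chi2_batch


class TestKmEstimate:
    def test_uncensored_staircase(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_at_one(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert len(curve.event_times) == 0

    def test_censored_at_tied_event_time_counted_at_risk(self):
        # two events and one censoring, all at t=1: S(1) = 1 - 2/3
        curve = km_estimate([1, 1, 1], [1, 1, 0])
        assert curve.at_risk.tolist() == [3]
        assert curve.survival[0] == pytest.approx(1 / 3)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(0)
        t = rng.exponential(5, 60).round(2) + 0.01
        e = rng.integers(0, 2, 60)
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for u, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(u).iloc[0]), abs=1e-10
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t, e = [1, 2, 3, 4], [1, 1, 0, 1]
        res = logrank_test(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_worked_example_chi_square_49_over_17(self):
        # A events at 1, 2; B events at 3, 4; O_A=2, E_A=5/6, V=17/36
        res = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert res.chi_square == pytest.approx(49 / 17)
        assert res.observed == pytest.approx((2.0, 2.0))
        assert res.expected[0] == pytest.approx(5 / 6)
        assert res.p_value == pytest.approx(0.0896, abs=5e-4)

    def test_zero_events_flagged(self):
        res = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert not res.ok

    def test_label_swap_leaves_chi_square_unchanged(self):
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(5, 20), rng.exponential(8, 25)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-10)

    def test_matches_lifelines_on_random_data(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(2)
        for _ in range(10):
            na, nb = int(rng.integers(5, 30)), int(rng.integers(5, 30))
            ta, tb = rng.exponential(5, na), rng.exponential(3, nb)
            ea, eb = rng.integers(0, 2, na), rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            mine = logrank_test(ta, ea, tb, eb)
            ref = ll_logrank(ta, tb, ea, eb)
            assert mine.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
            assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_exact_permutation_p_on_worked_example(self):
        # with 4 subjects there are only C(4,2)=6 label assignments; the
        # observed split and its mirror attain the maximal statistic, so the
        # exact permutation p is 2/6
        from itertools import combinations

        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1.0, 1.0, 1.0, 1.0])
        obs = _logrank_chi2_batch(t, e, np.array([[True, True, False, False]]))[0]
        groups = np.zeros((6, 4), dtype=bool)
        for b, pair in enumerate(combinations(range(4), 2)):
            groups[b, list(pair)] = True
        chi = _logrank_chi2_batch(t, e, groups)
        assert np.mean(chi >= obs - 1e-12) == pytest.approx(1 / 3)

    def test_chi_square_p_tracks_permutation_p_at_moderate_n(self):
        rng = np.random.default_rng(3)
        n = 40
        t = rng.exponential(5, n)
        e = rng.integers(0, 2, n).astype(float)
        e[0] = 1.0
        g0 = np.zeros(n, dtype=bool)
        g0[: n // 2] = True
        obs = _logrank_chi2_batch(t, e, g0[None, :])[0]
        B = 4000
        groups = np.array([rng.permutation(g0) for _ in range(B)])
        chi = _logrank_chi2_batch(t, e, groups)
        p_perm = np.mean(chi >= obs - 1e-12)
        from scipy.stats import chi2

        assert abs(p_perm - chi2.sf(obs, 1)) < 0.05


class TestDichotomize:
    def test_percentile_030_on_1_to_10(self):
        v = pd.Series(np.arange(1.0, 11.0), index=[f"s{i}" for i in range(10)])
        split = dichotomize_at_percentile(v, 0.3)
        assert split.cut == pytest.approx(3.7)
        assert set(split.low_ids) == {"s0", "s1", "s2"}

    def test_median_split_is_five_five(self):
        v = pd.Series(np.arange(1.0, 11.0), index=[f"s{i}" for i in range(10)])
        split = dichotomize_at_percentile(v, 0.5)
        assert len(split.low_ids) == 5 and len(split.high_ids) == 5

    def test_constant_vector_flagged_undefined(self):
        v = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        split = dichotomize_at_percentile(v, 0.5)
        assert not split.ok


def _toy_survival(n, seed, theta=0.0, marker=None):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n) if marker is None else marker
    rate = 0.1 * np.exp(theta * x)
    t = rng.exponential(1 / rate)
    c = np.minimum(rng.exponential(25, n), 15.0)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    samples = [f"s{i}" for i in range(n)]
    clin = pd.DataFrame({"sample": samples, "time": time, "event": event})
    return pd.Series(x, index=samples), clin


class TestCutpointScan:
    def test_default_grid_has_51_percentiles(self):
        assert len(percentile_grid()) == 51
        values, clin = _toy_survival(80, 0)
        scan = cutpoint_scan(values, clin)
        assert len(scan.percentiles) == 51

    def test_optimal_p_is_minimum_and_at_most_median_split(self):
        for seed in range(20):
            values, clin = _toy_survival(60, seed)
            scan = cutpoint_scan(values, clin)
            assert scan.optimal_p == np.nanmin(scan.p_values)
            p_median = scan.p_values[np.where(scan.percentiles == 0.5)[0][0]]
            assert scan.optimal_p <= p_median + 1e-15

    def test_tie_broken_toward_smaller_percentile(self):
        values, clin = _toy_survival(40, 7)
        scan = cutpoint_scan(values, clin)
        first = np.nanargmin(scan.p_values)
        assert scan.optimal_percentile == scan.percentiles[first]

    def test_constant_marker_is_error(self):
        _, clin = _toy_survival(20, 1)
        values = pd.Series(np.ones(20), index=clin["sample"])
        with pytest.raises(ValidationError, match="no valid split"):
            cutpoint_scan(values, clin)

    def test_strong_marker_flagged_with_small_adjusted_p(self):
        values, clin = _toy_survival(200, 3, theta=1.0)
        scan = cutpoint_scan(-values, clin, n_permutations=99, seed=0)
        assert scan.flagged
        assert scan.adjusted_p <= 0.05

    def test_scan_matches_scalar_logrank_at_each_percentile(self):
        values, clin = _toy_survival(50, 11, theta=0.5)
        scan = cutpoint_scan(values, clin)
        clin_idx = clin.set_index("sample")
        for k in (0, 17, 25, 50):
            split = dichotomize_at_percentile(values, scan.percentiles[k])
            lo = clin_idx.loc[list(split.low_ids)]
            hi = clin_idx.loc[list(split.high_ids)]
            ref = logrank_test(lo["time"], lo["event"], hi["time"], hi["event"])
            assert scan.chi_squares[k] == pytest.approx(ref.chi_square, rel=1e-9)
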