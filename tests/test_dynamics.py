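"""Tests of normalisation, interpolation, phase detection and statistics."""

import itertools
import warnings

import numpy as np
import pytest

from spherokin.dynamics import (
    ComparisonResult,
    PhaseAnnotation,
    ShrinkageSeries,
    TrajectoryRejected,
    cohort_summary,
    compare_conditions,
    detect_phases,
    holm_adjust,
    interpolate_missing,
    normalize,
    rank_sum_test,
    shrinkage_rate,
    significance_stars,
)
from spherokin.trajectories import AreaTrajectory, NormalizedTrajectory


def make_traj(areas, missing=None, interval_minutes=30.0, well="w"):
    areas = np.asarray(areas, dtype=float)
    times = np.arange(len(areas)) * interval_minutes / 60.0
    return AreaTrajectory(well_id=well, times_h=times, areas=areas,
                          missing=missing, interval_minutes=interval_minutes)


def exact_ranksum_pvalue(a, b):
    """Full-enumeration oracle for the two-sided rank-sum test (no ties)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n = len(a)
    w_obs = ranks[:n].sum()
    mean_w = n * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            count += 1
    return count / total


class TestInterpolation:
    def test_linear_gap_filled_exactly(self):
        t = np.arange(10) * 0.5
        areas = 100.0 - 4.0 * t
        missing = np.zeros(10, dtype=bool)
        missing[[4, 5]] = True
        areas_obs = areas.copy()
        areas_obs[missing] = np.nan
        traj = make_traj(areas_obs, missing)
        out = interpolate_missing(traj, degree=1)
        np.testing.assert_allclose(out.areas, areas, atol=1e-9)
        assert out.interpolated[4] and out.interpolated[5]
        assert not out.missing.any()

    @pytest.mark.parametrize(
        "coeffs",
        [
            [-4.0, 100.0],                      # linear decay
            [0.4, -8.0, 100.0],                 # quadratic
            [0.05, 0.2, -9.0, 100.0],           # cubic
        ],
    )
    def test_polynomial_ground_truth_zero_residual(self, coeffs):
        t = np.arange(20) * 0.5
        areas = np.polyval(coeffs, t) + 200.0
        assert np.all(areas > 0)
        missing = np.zeros(20, dtype=bool)
        missing[[8, 9, 10]] = True
        obs = areas.copy()
        obs[missing] = np.nan
        out = interpolate_missing(make_traj(obs, missing), degree=3)
        np.testing.assert_allclose(out.areas, areas, atol=1e-6)

    def test_four_consecutive_missing_rejects_well(self):
        areas = np.linspace(100, 50, 12)
        missing = np.zeros(12, dtype=bool)
        missing[3:7] = True  # 4 in a row: disqualified
        obs = np.where(missing, np.nan, areas)
        with pytest.raises(TrajectoryRejected):
            interpolate_missing(make_traj(obs, missing))

    def test_three_consecutive_missing_is_still_repairable(self):
        areas = np.linspace(100, 50, 12)
        missing = np.zeros(12, dtype=bool)
        missing[3:6] = True
        obs = np.where(missing, np.nan, areas)
        out = interpolate_missing(make_traj(obs, missing))
        assert not out.missing.any()

    def test_no_missing_identity(self):
        traj = make_traj(np.linspace(100, 60, 8))
        out = interpolate_missing(traj)
        np.testing.assert_array_equal(out.areas, traj.areas)
        assert not out.interpolated.any()

    def test_missing_frame_zero_is_an_error(self):
        areas = np.array([np.nan, 90.0, 80.0])
        with pytest.raises(ValueError, match="frame 0"):
            interpolate_missing(make_traj(areas))


class TestNormalize:
    def test_definition(self):
        traj = make_traj([100.0, 90.0, 80.0])
        nt = normalize(traj)
        np.testing.assert_allclose(nt.na, [1.0, 0.9, 0.8])

    def test_constant_trajectory_all_ones(self):
        nt = normalize(make_traj([55.0] * 6))
        np.testing.assert_allclose(nt.na, 1.0)

    def test_zero_anchor_rejected(self):
        with pytest.raises(ValueError):
            normalize(make_traj([0.0, 10.0]))


class TestCohortSummary:
    def test_identical_replicates_zero_sem(self):
        nts = [normalize(make_traj([100, 80, 60])) for _ in range(5)]
        df = cohort_summary(nts)
        np.testing.assert_allclose(df["sem_na"], 0.0)
        np.testing.assert_allclose(df["mean_na"], [1.0, 0.8, 0.6])

    def test_two_member_sem(self):
        a = normalize(make_traj([100.0, 80.0]))
        b = normalize(make_traj([100.0, 60.0]))
        df = cohort_summary([a, b])
        assert df["mean_na"].iloc[1] == pytest.approx(0.7)
        assert df["sem_na"].iloc[1] == pytest.approx(0.1)

    def test_single_replicate_warns_and_reports_zero(self):
        with pytest.warns(UserWarning, match="SEM undefined"):
            df = cohort_summary([normalize(make_traj([100, 90]))])
        np.testing.assert_allclose(df["sem_na"], 0.0)


class TestShrinkageRate:
    def test_constant_na_zero_rates(self):
        rates = shrinkage_rate(np.ones(10))
        np.testing.assert_allclose(rates.rates, 0.0)

    def test_constant_decrement(self):
        na = 1.0 - 0.02 * np.arange(20)
        rates = shrinkage_rate(na)
        np.testing.assert_allclose(rates.rates, 0.02)

    def test_growth_gives_negative_rates(self):
        na = 1.0 + 0.01 * np.arange(5)
        rates = shrinkage_rate(na)
        assert np.all(rates.rates < 0)

    def test_right_edge_timestamps_and_length(self):
        na = np.linspace(1.0, 0.5, 7)
        rates = shrinkage_rate(na, interval_minutes=30.0)
        assert len(rates.rates) == 6
        np.testing.assert_allclose(rates.times_h, np.arange(1, 7) * 0.5)

    def test_composition_with_normalize_constant_is_zero(self):
        nt = normalize(make_traj([42.0] * 8))
        rates = shrinkage_rate(nt)
        np.testing.assert_allclose(rates.rates, 0.0)


def rates_series(values, interval_minutes=30.0):
    values = np.asarray(values, dtype=float)
    times = np.arange(1, len(values) + 1) * interval_minutes / 60.0
    return ShrinkageSeries(times_h=times, rates=values,
                           interval_minutes=interval_minutes)


class TestDetectPhases:
    def test_transition_at_18_5_hours(self):
        # fast aggregation for 37 intervals, then sub-threshold: the
        # aggregation phase completes at 18.5 h
        values = np.concatenate([np.full(37, 0.02), np.full(59, 0.005)])
        ann = detect_phases(rates_series(values))
        assert ann.aggregation_end_h == pytest.approx(18.5)
        assert ann.growth_start_h is None

    def test_rates_above_threshold_never_transition(self):
        ann = detect_phases(rates_series(np.full(50, 0.05)))
        assert ann.aggregation_end_h is None

    def test_short_dip_does_not_count(self):
        values = np.full(40, 0.02)
        values[10:12] = 0.001  # only 2 intervals below threshold
        ann = detect_phases(rates_series(values))
        assert ann.aggregation_end_h is None

    def test_three_interval_dip_counts(self):
        values = np.full(40, 0.02)
        values[10:13] = 0.001
        ann = detect_phases(rates_series(values))
        assert ann.aggregation_end_h == pytest.approx(10 * 0.5)

    def test_growth_requires_negative_run(self):
        values = np.concatenate([np.full(20, 0.02), np.full(10, 0.002),
                                 np.full(10, -0.004)])
        ann = detect_phases(rates_series(values))
        assert ann.aggregation_end_h == pytest.approx(10.0)
        assert ann.growth_start_h == pytest.approx(15.0)
        assert ann.aggregation_end_h < ann.growth_start_h

    def test_prepending_fast_intervals_shifts_times(self):
        base = np.concatenate([np.full(10, 0.02), np.full(20, 0.001)])
        shifted = np.concatenate([np.full(7, 0.05), base])
        t0 = detect_phases(rates_series(base)).aggregation_end_h
        t1 = detect_phases(rates_series(shifted)).aggregation_end_h
        assert t1 == pytest.approx(t0 + 7 * 0.5)

    def test_non_uniform_grid_rejected(self):
        series = ShrinkageSeries(times_h=np.array([0.5, 1.0, 2.5]),
                                 rates=np.zeros(3))
        with pytest.raises(ValueError, match="uniform"):
            detect_phases(series)

    def test_persistence_scales_with_interval(self):
        # 1.5 h on a 15-min grid needs 6 consecutive intervals
        values = np.full(30, 0.02)
        values[5:10] = 0.0  # 5 intervals: not enough
        ann = detect_phases(rates_series(values, interval_minutes=15.0))
        assert ann.aggregation_end_h is None
        values[5:11] = 0.0
        ann = detect_phases(rates_series(values, interval_minutes=15.0))
        assert ann.aggregation_end_h == pytest.approx(5 * 0.25)


class TestRankSumAndHolm:
    def test_exact_small_sample_example(self):
        _, p = rank_sum_test(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert p == pytest.approx(1.0 / 3.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_pvalues_match_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 7, size=2)
        a = rng.permutation(np.arange(1.0, n + m + 1))[:n]
        b = np.setdiff1d(np.arange(1.0, n + m + 1), a)
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(exact_ranksum_pvalue(a, b), abs=1e-12)

    def test_identical_cohorts_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            _, p = rank_sum_test(np.array([1.0, 1.0, 1.0]),
                                 np.array([1.0, 1.0]))
        assert p == 1.0

    def test_holm_definitional_example(self):
        adjusted = holm_adjust([0.01, 0.04])
        np.testing.assert_allclose(adjusted, [0.02, 0.04])

    def test_holm_monotone_and_never_below_raw(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.random(6)
            adj = holm_adjust(p)
            assert np.all(adj >= p - 1e-15)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_holm_matches_definitional_computation(self):
        rng = np.random.default_rng(5)
        p = rng.random(6)
        # definitional step-down computation
        order = np.argsort(p)
        m = len(p)
        stepped = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            stepped[idx] = min(1.0, running)
        np.testing.assert_allclose(holm_adjust(p), stepped, atol=1e-12)

    def test_stars_thresholds(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.0005) == "***"


class TestCompareConditions:
    def _cohort(self, offsets, n=6, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            areas = 100.0 * (1.0 - offsets * np.arange(5) / 10.0)
            areas[1:] += rng.normal(0, 0.5, 4)
            out.append(normalize(make_traj(np.maximum(areas, 1.0))))
        return out

    def test_distinct_conditions_detected(self):
        a = self._cohort(0.8, seed=1)
        b = self._cohort(0.1, seed=2)
        results = compare_conditions(a, b, times_h=[1.0, 2.0])
        assert all(r.p_adjusted >= r.p_raw for r in results)
        assert results[-1].p_adjusted < 0.05

    def test_identical_cohorts_not_significant(self):
        a = [normalize(make_traj([100, 80, 60])) for _ in range(4)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            results = compare_conditions(a, a, times_h=[0.5, 1.0])
        assert all(r.stars == "ns" for r in results)
        assert all(r.p_adjusted == 1.0 for r in results)

    def test_requires_two_members(self):
        a = [normalize(make_traj([100, 80]))]
        with pytest.raises(ValueError):
            compare_conditions(a, a, times_h=[0.5])


class TestPhaseAnnotationInvariant:
    def test_aggregation_after_growth_rejected(self):
        with pytest.raises(ValueError):
            PhaseAnnotation(aggregation_end_h=20.0, growth_start_h=10.0)
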