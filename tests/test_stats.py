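import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.transform import Rotation

from flywalk.simulator import PHENOTYPES, PhenotypeModel, SimConfig, simulate_cohort, truth_candidates
from flywalk.stats import (
    CohortSummary,
    cohort_summary,
    compare_groups,
    decline_rate,
    fractional_signal_difference,
    persistence_length,
    speed_histogram,
    speeds,
    turn_tightness,
)
from flywalk.tracking import Trajectory, link_frames


def traj_from_points(points, dt=0.1):
    points = np.asarray(points, dtype=float)
    return Trajectory(id=0, times=np.arange(len(points)) * dt, positions=points)


L_PATH = traj_from_points([(0, 0, 0), (1, 0, 0), (1, 1, 0)])
STRAIGHT = traj_from_points([(0, 0, i) for i in range(11)])
LOOP = traj_from_points([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0), (0, 0, 0)])
ZIGZAG = traj_from_points([(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0), (2, 2, 0)])
REVERSAL = traj_from_points([(0, 0, 0), (1, 0, 0), (0, 0, 0), (1, 0, 0)])


class TestSpeeds:
    def test_uniform_motion(self):
        t = traj_from_points([(0, 0, 2 * i) for i in range(5)], dt=0.1)
        np.testing.assert_allclose(speeds(t), 20.0)

    def test_stationary(self):
        t = traj_from_points([(1, 1, 1)] * 4)
        np.testing.assert_allclose(speeds(t), 0.0)

    def test_varying_steps(self):
        t = traj_from_points([(0, 0, 0), (1, 0, 0), (3, 0, 0), (6, 0, 0)], dt=0.5)
        np.testing.assert_allclose(speeds(t), [2.0, 4.0, 6.0])

    def test_duplicate_timestamps_rejected(self):
        t = traj_from_points([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        t.times = np.array([0.0, 0.1, 0.1 + 1e-18])
        with pytest.raises(ValueError):
            speeds(t)


class TestPersistenceLength:
    @pytest.mark.parametrize(
        "traj,expected",
        [(STRAIGHT, 1.0), (LOOP, 0.0), (L_PATH, math.sqrt(2) / 2)],
    )
    def test_known_paths(self, traj, expected):
        assert persistence_length(traj) == pytest.approx(expected)

    def test_zero_total_distance_undefined(self):
        assert persistence_length(traj_from_points([(0, 0, 0)] * 3)) is None


class TestTurnTightness:
    @pytest.mark.parametrize(
        "traj,expected", [(STRAIGHT, 1.0), (ZIGZAG, 0.0), (REVERSAL, -1.0)]
    )
    def test_known_paths(self, traj, expected):
        assert turn_tightness(traj) == pytest.approx(expected)

    def test_zero_length_steps_skipped(self):
        t = traj_from_points([(0, 0, 0), (1, 0, 0), (1, 0, 0), (2, 0, 0)])
        assert turn_tightness(t) == pytest.approx(1.0)

    def test_fewer_than_two_nonzero_steps_undefined(self):
        assert turn_tightness(traj_from_points([(0, 0, 0), (0, 0, 0), (1, 0, 0)])) is None

    def test_unnormalized_variant(self):
        t = traj_from_points([(0, 0, 0), (2, 0, 0), (4, 0, 0)])
        assert turn_tightness(t, normalized=False) == pytest.approx(4.0)


class TestDescriptorBounds:
    @given(
        pts=arrays(
            float,
            st.tuples(st.integers(3, 12), st.just(3)),
            elements=st.floats(-20, 20),
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_on_arbitrary_paths(self, pts):
        t = traj_from_points(pts)
        p = persistence_length(t)
        if p is not None:
            assert 0.0 <= p <= 1.0
        tt = turn_tightness(t)
        if tt is not None:
            assert -1.0 <= tt <= 1.0
        assert (speeds(t) >= 0.0).all()


class TestRigidMotionInvariance:
    def test_descriptors_invariant_speed_scales(self):
        rng = np.random.default_rng(31)
        base = traj_from_points(np.cumsum(rng.normal(0, 1, (20, 3)), axis=0))
        p0, t0 = persistence_length(base), turn_tightness(base)
        s0 = speeds(base)
        for _ in range(100):
            R = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(0, 50, 3)
            moved = Trajectory(
                id=0, times=base.times, positions=base.positions @ R.T + shift
            )
            assert persistence_length(moved) == pytest.approx(p0, abs=1e-9)
            assert turn_tightness(moved) == pytest.approx(t0, abs=1e-9)
            np.testing.assert_allclose(speeds(moved), s0, atol=1e-9)
        scaled = Trajectory(id=0, times=base.times, positions=base.positions * 3.0)
        np.testing.assert_allclose(speeds(scaled), 3.0 * s0, rtol=1e-12)


class TestSpeedHistogram:
    def test_single_value(self):
        edges, density = speed_histogram([7.1] * 10)
        width = edges[1] - edges[0]
        assert (density > 0).sum() == 1
        assert density.max() == pytest.approx(1.0 / width)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(0)
        edges, density = speed_histogram(rng.uniform(0, 25, 500))
        width = np.diff(edges)
        assert float((density * width).sum()) == pytest.approx(1.0)

    def test_uniform_is_flat(self):
        rng = np.random.default_rng(1)
        edges, density = speed_histogram(rng.uniform(0, 20, 200_000))
        np.testing.assert_allclose(density, 0.05, atol=0.005)

    def test_overflow_in_last_bin(self):
        edges, density = speed_histogram([25.0])
        assert density[-1] > 0
        assert (density[:-1] == 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            speed_histogram([])


def make_cohort(mu, n_traj, seed, age=2.0, duration=15.0):
    model = PhenotypeModel(label="synthetic", mu0=mu, fall_rate=0.0)
    trajs = []
    s = seed
    while len(trajs) < n_traj:
        cfg = SimConfig(seed=s, duration=duration, tap_times=(0.0,), n_flies=10)
        truth = simulate_cohort(model, age, cfg)
        trajs.extend(link_frames(truth_candidates(truth)))
        s += 1
    return trajs[:n_traj]


class TestCohortSummary:
    def test_single_trajectory_equals_its_stats(self):
        t = traj_from_points([(0, 0, 0), (1, 0, 0), (2, 1, 0), (2, 1, 1)])
        s = cohort_summary([t], cohort="c", age_days=2.0)
        assert s.mean_speed == pytest.approx(float(np.mean(speeds(t))))
        assert s.mean_persistence == pytest.approx(persistence_length(t))
        assert s.mean_turn_tightness == pytest.approx(turn_tightness(t))
        assert s.n_trajectories == 1

    def test_parameter_recovery_two_speeds(self):
        for mu in (10.0, 5.0):
            trajs = make_cohort(mu, n_traj=50, seed=int(mu))
            s = cohort_summary(trajs)
            assert abs(s.mean_speed - mu) / mu < 0.05

    def test_undefined_persistence_excluded_but_counted(self):
        good = traj_from_points([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        still = traj_from_points([(5, 5, 5)] * 3)
        s = cohort_summary([good, still])
        assert s.n_trajectories == 2
        assert s.mean_persistence == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])

    def test_programmed_decline_monotone_in_estimates(self):
        model = PHENOTYPES["abeta42_arctic"]
        means = []
        for age in (2.0, 7.0, 14.0):
            cfg = SimConfig(seed=7, duration=15.0, tap_times=(0.0,))
            truth = simulate_cohort(model, age, cfg)
            trajs = link_frames(truth_candidates(truth))
            means.append(cohort_summary(trajs).mean_speed if trajs else 0.0)
        assert means[0] > means[1] > means[2]


class TestDeclineRate:
    def _summary(self, age, mean):
        return CohortSummary(
            cohort="c", age_days=age, hist_edges=np.linspace(0, 20, 41),
            hist_density=np.full(40, 1 / 20), mean_speed=mean, mean_max_speed=mean,
            mean_persistence=None, mean_turn_tightness=None,
            n_trajectories=1, n_steps=10,
        )

    def test_constant_speed_zero_slope(self):
        assert decline_rate([self._summary(a, 8.0) for a in (2, 5, 8)]) == pytest.approx(0.0)

    def test_two_ages_rejected(self):
        with pytest.raises(ValueError):
            decline_rate([self._summary(2, 8.0), self._summary(5, 6.0)])

    def test_recovers_programmed_slope(self):
        # mu0=10 mm/s with 5%/day decline from day 0: slope -0.5 mm/s/day
        model = PhenotypeModel(label="declining", mu0=10.0, decline=0.05, fall_rate=0.0)
        summaries = []
        for age in (2.0, 5.0, 8.0, 11.0, 14.0):
            trajs = []
            for seed in range(4):
                cfg = SimConfig(seed=1000 + int(age) * 10 + seed, duration=15.0,
                                tap_times=(0.0,), n_flies=10)
                truth = simulate_cohort(model, age, cfg)
                trajs.extend(link_frames(truth_candidates(truth)))
            summaries.append(cohort_summary(trajs, age_days=age))
        slope = decline_rate(summaries)
        assert slope == pytest.approx(-0.5, abs=0.1)


class TestFractionalSignalDifference:
    def _summary(self, mean, age=2.0):
        return CohortSummary(
            cohort="c", age_days=age, hist_edges=np.linspace(0, 20, 41),
            hist_density=np.full(40, 1 / 20), mean_speed=mean, mean_max_speed=mean,
            mean_persistence=0.5, mean_turn_tightness=0.8,
            n_trajectories=1, n_steps=10,
        )

    def test_identical_cohorts(self):
        assert fractional_signal_difference(self._summary(10), self._summary(10)) == 0.0

    def test_halved_speed(self):
        assert fractional_signal_difference(self._summary(10), self._summary(5)) == pytest.approx(0.5)

    def test_faster_test_cohort_negative(self):
        assert fractional_signal_difference(self._summary(5), self._summary(10)) < 0

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            fractional_signal_difference(self._summary(0.0), self._summary(5))

    def test_age_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fractional_signal_difference(self._summary(10, age=2), self._summary(5, age=7))


class TestCompareGroups:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0]
        _, p = compare_groups(a, a)
        assert p > 0.9

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_type_one_error_rate(self):
        # same distribution: p < 0.05 in ~5% of repeats
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(10, 2, 15)
            b = rng.normal(10, 2, 15)
            _, p = compare_groups(a, b)
            rejections += p < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.02

    def test_power_on_separated_cohorts(self):
        # 10 vs 5 mm/s cohorts of 30 trajectories: p < 0.001 almost always
        rng = np.random.default_rng(3)
        significant = 0
        for _ in range(20):
            a = rng.normal(10, 1.5, 30)
            b = rng.normal(5, 1.5, 30)
            _, p = compare_groups(a, b)
            significant += p < 0.001
        assert significant >= 19
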