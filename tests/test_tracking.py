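"""Linking, MSD computation and power-law fitting."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffent import tracking
from diffent.tracking import MSDCurve, Trajectory

from conftest import make_fbm_trajectories


def det_table(frames_positions):
    """Build a detection table from {frame: [(x, y), ...]}."""
    rows = [(f, x, y) for f, pts in frames_positions.items() for x, y in pts]
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um"])


def optimal_assignment_cost(prev_pts, next_pts, max_disp):
    """Exhaustive minimal total linking distance (oracle, <= 5 objects)."""
    n = min(len(prev_pts), len(next_pts))
    best = np.inf
    for perm in permutations(range(len(next_pts)), n):
        cost, feasible = 0.0, True
        for i, j in enumerate(perm):
            d = np.hypot(*(np.array(prev_pts[i]) - np.array(next_pts[j])))
            if d > max_disp:
                feasible = False
                break
            cost += d
        if feasible:
            best = min(best, cost)
    return best


class TestLink:
    def test_well_separated_objects_recovered_exactly(self):
        drift = [(0.0, 0.0), (10.0, 10.0)]
        dets = det_table({f: [(x + 0.1 * f, y) for x, y in drift]
                          for f in range(10)})
        trajs = tracking.link(dets, max_disp=0.5, min_len=5, dt_frame=0.3)
        assert len(trajs) == 2
        for tr in trajs:
            assert len(tr) == 10
            steps = np.diff(tr.xy[:, 0])
            assert np.allclose(steps, 0.1)

    def test_missing_detection_splits_trajectory(self):
        pos = {f: [(0.1 * f, 0.0)] for f in range(10) if f != 5}
        trajs = tracking.link(det_table(pos), max_disp=0.5, min_len=2)
        assert len(trajs) == 2

    def test_min_len_filter(self):
        pos = {0: [(0, 0)], 1: [(0.1, 0)]}
        assert tracking.link(det_table(pos), max_disp=1.0, min_len=3) == []

    def test_invalid_max_disp(self):
        with pytest.raises(ValueError):
            tracking.link(det_table({0: [(0, 0)]}), max_disp=0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_greedy_cost_near_optimal(self, seed):
        """Greedy linking cost is within 1.2x of the exhaustive optimum,
        and exact when objects are separated by more than 2 max_disp."""
        rng = np.random.default_rng(seed)
        max_disp = 1.0
        prev_pts = [tuple(p) for p in rng.uniform(0, 20, size=(5, 2))]
        next_pts = [(x + rng.uniform(-0.5, 0.5), y + rng.uniform(-0.5, 0.5))
                    for x, y in prev_pts]
        dets = det_table({0: prev_pts, 1: next_pts})
        trajs = tracking.link(dets, max_disp=max_disp, min_len=2)
        greedy_cost = sum(np.hypot(*(tr.xy[1] - tr.xy[0])) for tr in trajs)
        opt = optimal_assignment_cost(prev_pts, next_pts, max_disp)
        assert greedy_cost <= opt * 1.2 + 1e-12
        spacing = min(np.hypot(*(np.array(a) - np.array(b)))
                      for i, a in enumerate(prev_pts)
                      for b in prev_pts[i + 1:])
        if spacing > 2 * max_disp:
            assert greedy_cost == pytest.approx(opt)


class TestComputeMSD:
    def test_stationary_particle(self):
        tr = Trajectory(0, np.arange(5) * 0.3, np.zeros((5, 2)))
        curve = tracking.compute_msd([tr], k_max=3)
        assert np.allclose(curve.msd, 0.0)

    def test_ballistic_drift(self):
        xy = np.column_stack([np.arange(10, dtype=float), np.zeros(10)])
        tr = Trajectory(0, np.arange(10, dtype=float), xy)
        curve = tracking.compute_msd([tr], k_max=5, dt_frame=1.0)
        assert np.allclose(curve.msd, np.arange(1, 6) ** 2)

    def test_two_point_345(self):
        tr = Trajectory(0, np.array([0.0, 0.3]), np.array([[0, 0], [3, 4]]))
        curve = tracking.compute_msd([tr], k_max=1)
        assert curve.msd[0] == pytest.approx(25.0)

    def test_long_lags_omitted(self):
        tr = Trajectory(0, np.arange(4) * 0.3,
                        np.arange(8, dtype=float).reshape(4, 2))
        curve = tracking.compute_msd([tr], k_max=10)
        assert curve.lags.size == 3

    def test_n_obs_non_increasing(self):
        trajs = make_fbm_trajectories(0.02, 0.8, 5, n_steps=30, seed=3)
        curve = tracking.compute_msd(trajs, k_max=10)
        assert all(a >= b for a, b in zip(curve.n_obs, curve.n_obs[1:]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        """Vectorized MSD equals an explicit double loop over index pairs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 25))
        tr = Trajectory(0, np.arange(n) * 0.3, rng.normal(size=(n, 2)))
        curve = tracking.compute_msd([tr], k_max=10)
        oracle = tracking.msd_brute_force(tr, k_max=10)
        assert np.allclose(curve.msd, oracle[np.isfinite(oracle)])


class TestFitPowerLaw:
    def test_noise_free_identifiability(self):
        lags = np.arange(1, 11) * 0.3
        curve = MSDCurve(lags, 4 * 0.02 * lags ** 0.8, np.ones(10, int), 1)
        fit = tracking.fit_power_law(curve, n_dims=2)
        assert abs(fit.k_alpha - 0.02) < 1e-10
        assert abs(fit.alpha - 0.8) < 1e-10

    def test_ballistic_curve(self):
        lags = np.arange(1, 11) * 0.3
        curve = MSDCurve(lags, lags ** 2, np.ones(10, int), 1)
        fit = tracking.fit_power_law(curve, n_dims=2)
        assert fit.alpha == pytest.approx(2.0, abs=1e-8)
        assert fit.k_alpha == pytest.approx(0.25, abs=1e-8)

    def test_unit_rescaling_invariance(self):
        """um -> nm multiplies K by 1e6 and leaves alpha unchanged."""
        trajs = make_fbm_trajectories(0.02, 0.8, 50, seed=8)
        curve = tracking.compute_msd(trajs, k_max=10)
        fit_um = tracking.fit_power_law(curve)
        curve_nm = MSDCurve(curve.lags, curve.msd * 1e6, curve.n_obs,
                            curve.n_trajectories)
        fit_nm = tracking.fit_power_law(curve_nm)
        assert fit_nm.alpha == pytest.approx(fit_um.alpha, rel=1e-8)
        assert fit_nm.k_alpha == pytest.approx(fit_um.k_alpha * 1e6, rel=1e-8)

    def test_needs_three_positive_lags(self):
        curve = MSDCurve(np.array([0.3, 0.6]), np.array([0.1, 0.2]),
                         np.array([1, 1]), 1)
        with pytest.raises(ValueError):
            tracking.fit_power_law(curve)

    def test_recovery_bias_shrinks_with_trajectory_count(self):
        """|alpha bias| decreases monotonically with ensemble size."""
        biases = []
        for n_traj in (20, 50, 200):
            errs = []
            for seed in range(8):
                trajs = make_fbm_trajectories(0.02, 0.8, n_traj,
                                              seed=100 * n_traj + seed)
                fit = tracking.fit_power_law(tracking.compute_msd(trajs))
                errs.append(fit.alpha - 0.8)
            biases.append(abs(np.mean(errs)) + np.std(errs))
        assert biases[0] > biases[1] > biases[2]


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path):
        trajs = make_fbm_trajectories(0.02, 0.8, 3, n_steps=10, seed=1)
        path = tmp_path / "t.csv"
        tracking.trajectories_to_csv(trajs, path, cell_id="c0")
        back = tracking.trajectories_from_csv(path)
        assert len(back) == 3
        for a, b in zip(trajs, back):
            assert np.allclose(a.xy, b.xy)
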