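"""MSD estimator, long-time D extraction, and the linear slowdown (κ) fit."""

import numpy as np
import pytest

from crowdiff.analysis import (
    KappaModel,
    NotConvergedWarning,
    SlowdownCurve,
    compute_msd,
    fit_kappa,
    long_time_d,
)
from crowdiff.bd import Trajectory
from crowdiff.pgste import generate_free_walk, generate_slowdown_table


def _toy_trajectory(unwrapped, dt=1.0):
    n_frames, n_particles = unwrapped.shape[:2]
    return Trajectory(
        box_edge=1e9,
        labels=np.array(["p"] * n_particles, dtype=object),
        radii=np.ones(n_particles),
        times=np.arange(n_frames) * dt,
        wrapped=unwrapped % 1e9,
        unwrapped=unwrapped,
    )


def brute_force_msd(unwrapped, max_lag):
    """Independent double-loop MSD oracle over all frame pairs."""
    n_frames, n_particles = unwrapped.shape[:2]
    msd = np.zeros(max_lag + 1)
    for lag in range(1, max_lag + 1):
        acc, cnt = 0.0, 0
        for t0 in range(n_frames - lag):
            for p in range(n_particles):
                acc += np.sum((unwrapped[t0 + lag, p] - unwrapped[t0, p]) ** 2)
                cnt += 1
        msd[lag] = acc / cnt
    return msd


class TestComputeMSD:
    def test_stationary_trajectory_msd_zero(self):
        traj = _toy_trajectory(np.zeros((10, 3, 3)))
        msd = compute_msd(traj)
        assert np.all(msd.msd == 0.0)

    def test_ballistic_closed_form(self):
        v = np.array([1.0, -2.0, 0.5])
        t = np.arange(30, dtype=float)
        unwrapped = (t[:, None] * v)[:, None, :]
        msd = compute_msd(_toy_trajectory(unwrapped), max_lag_fraction=0.5)
        expected = np.sum(v**2) * msd.lag_times**2
        assert msd.msd == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        unwrapped = rng.normal(size=(18, 4, 3)).cumsum(axis=0)
        traj = _toy_trajectory(unwrapped)
        msd = compute_msd(traj, max_lag_fraction=0.5)
        oracle = brute_force_msd(unwrapped, len(msd.msd) - 1)
        assert msd.msd[1:] == pytest.approx(oracle[1:], rel=1e-12)

    def test_absent_species_raises(self):
        traj = _toy_trajectory(np.zeros((5, 2, 3)))
        with pytest.raises(KeyError):
            compute_msd(traj, "ghost")

    def test_free_walk_recovers_generator_d(self):
        traj = generate_free_walk(100.0, n_steps=20_000, dt=1e-3, seed=0, n_particles=20)
        msd = compute_msd(traj, max_lag_fraction=0.1)
        d_est, se = long_time_d(msd, n_blocks=10)
        assert abs(d_est - 100.0) < 3 * se


class TestLongTimeD:
    def test_exact_line_recovered_noiselessly(self):
        tau = np.arange(101, dtype=float)
        curve = compute_msd(_toy_trajectory(np.zeros((101, 1, 3))), max_lag_fraction=0.5)
        curve.msd = 6.0 * 7.5 * curve.lag_times
        curve._positions = None
        d, se = long_time_d(curve)
        assert d == pytest.approx(7.5, rel=1e-12)
        assert se == 0.0

    def test_subdiffusive_curve_warns(self):
        tau = np.arange(101, dtype=float)
        curve = compute_msd(_toy_trajectory(np.zeros((101, 1, 3))), max_lag_fraction=0.5)
        curve.msd = 10.0 * np.sqrt(curve.lag_times)  # exponent 0.5
        curve._positions = None
        with pytest.warns(NotConvergedWarning):
            long_time_d(curve)

    def test_too_few_window_points_rejected(self):
        curve = compute_msd(_toy_trajectory(np.zeros((8, 1, 3))), max_lag_fraction=0.5)
        with pytest.raises(ValueError, match="window"):
            long_time_d(curve)


class TestKappaFit:
    def test_exact_linear_data_kappa_half(self):
        phi = np.array([0.0, 0.1, 0.2, 0.3])
        res = fit_kappa(SlowdownCurve(phi, 1 - 0.5 * phi))
        assert res.kappa == pytest.approx(0.5, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_exact_self_crowding_kappa_two(self):
        phi = np.array([0.0, 0.05, 0.1, 0.15])
        res = fit_kappa(SlowdownCurve(phi, 1 - 2.0 * phi))
        assert res.kappa == pytest.approx(2.0, abs=1e-12)

    def test_anchor_inserted_when_absent(self):
        phi = np.array([0.1, 0.2, 0.3])
        model = KappaModel(SlowdownCurve(phi, 1 - 1.3 * phi))
        assert model.phi[0] == 0.0 and model.d_ratio[0] == 1.0
        assert model.fit().kappa == pytest.approx(1.3, abs=1e-12)

    def test_recovery_calibration_200_replicates(self):
        """κ̂ is unbiased and its SE honest under the generator's noise."""
        kappa_true, noise = 1.3, 0.01
        hats, ses = [], []
        for seed in range(200):
            curve = generate_slowdown_table(
                "linear_phi", {"kappa": kappa_true, "phi_max": 0.4},
                n_points=5, noise_sd=noise, seed=seed,
            )
            res = fit_kappa(curve)
            hats.append(res.kappa)
            ses.append(res.kappa_se)
        hats = np.asarray(hats)
        bias_se = hats.std(ddof=1) / np.sqrt(len(hats))
        assert abs(hats.mean() - kappa_true) < 2 * bias_se
        # CI coverage at nominal 95%
        lo = hats - 1.96 * np.asarray(ses)
        hi = hats + 1.96 * np.asarray(ses)
        coverage = np.mean((lo <= kappa_true) & (kappa_true <= hi))
        assert 0.90 <= coverage <= 0.99

    def test_kappa_invariant_to_uniform_sigma_rescale(self):
        phi = np.array([0.1, 0.2, 0.3, 0.4])
        d = 1 - 0.9 * phi + np.array([0.01, -0.02, 0.015, -0.005])
        sig = np.array([0.01, 0.02, 0.01, 0.03])
        k1 = fit_kappa(SlowdownCurve(phi, d, sig)).kappa
        k2 = fit_kappa(SlowdownCurve(phi, d, 10 * sig)).kappa
        assert k1 == pytest.approx(k2, rel=1e-12)

    def test_identical_abscissa_rejected(self):
        with pytest.raises(ValueError):
            KappaModel(SlowdownCurve(np.array([0.2, 0.2, 0.2]), np.array([0.9, 0.8, 0.85])))

    def test_summary_mentions_kappa(self):
        phi = np.array([0.0, 0.1, 0.2])
        text = fit_kappa(SlowdownCurve(phi, 1 - 0.7 * phi)).summary()
        assert "kappa" in text and "R^2" in text
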