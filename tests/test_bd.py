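"""Brownian-dynamics propagation: hard-core enforcement, determinism,
free-diffusion calibration at small scale."""

import numpy as np
import pytest

from crowdiff.bd import (
    BDParams,
    default_timestep,
    euler_step,
    resolve_overlaps,
    run_trajectory,
)
from crowdiff.builder import MixtureSpec, build_mixture
from crowdiff.core import Configuration, PeriodicBox, Species, sse_diffusivity


def _free_config(n=20, radius=1.0, edge=60.0, seed=0):
    spec = MixtureSpec(
        crowder=Species("crowder", 5.1, 0),
        tracers=[Species("tracer", radius, n)],
        target_phi_occ=0.0, box_edge=edge, seed=seed,
    )
    return build_mixture(spec)


class TestResolveOverlaps:
    def test_valid_input_returned_unchanged(self, two_species_config):
        out = resolve_overlaps(two_species_config)
        assert out is two_species_config

    def test_symmetric_pair_pushed_to_contact(self):
        config = Configuration(
            PeriodicBox(30.0), ["a", "a"],
            np.array([[10.0, 5.0, 5.0], [11.5, 5.0, 5.0]]), np.array([1.0, 1.0]),
            check_overlaps=False,
        )
        out = resolve_overlaps(config)
        d = out.positions[1] - out.positions[0]
        assert np.linalg.norm(d) == pytest.approx(2.0, abs=1e-12)
        # equal radii: the midpoint is preserved
        mid = (out.positions[0] + out.positions[1]) / 2
        assert mid == pytest.approx(np.array([10.75, 5.0, 5.0]), abs=1e-12)

    def test_displacement_shared_by_mobility(self):
        # radii 1 and 3 -> D0 ratio 3:1 -> displacement magnitudes 3:1
        config = Configuration(
            PeriodicBox(40.0), ["s", "b"],
            np.array([[10.0, 10.0, 10.0], [13.0, 10.0, 10.0]]), np.array([1.0, 3.0]),
            check_overlaps=False,
        )
        out = resolve_overlaps(config)
        move_small = np.linalg.norm(out.positions[0] - config.positions[0])
        move_big = np.linalg.norm(out.positions[1] - config.positions[1])
        assert move_small / move_big == pytest.approx(3.0, rel=1e-9)
        gap = np.linalg.norm(out.positions[1] - out.positions[0])
        assert gap == pytest.approx(4.0, abs=1e-12)


class TestEulerStep:
    def test_tiny_timestep_barely_moves(self):
        config = _free_config()
        params = BDParams(timestep=1e-15, n_steps=1)
        out = euler_step(config, params, np.random.default_rng(0))
        assert np.max(np.abs(out.positions - config.positions)) < 1e-4

    def test_oversized_timestep_refused(self):
        config = _free_config(radius=0.5)
        d0 = sse_diffusivity(0.5)
        bad_dt = (0.2 * 0.5) ** 2 / (2 * d0)  # RMS step = 0.2 × radius
        with pytest.raises(ValueError, match="timestep"):
            euler_step(config, BDParams(timestep=bad_dt, n_steps=1), np.random.default_rng(0))

    def test_step_restores_hard_cores(self, overlap_oracle):
        spec = MixtureSpec(
            crowder=Species("crowder", 5.1, 40),
            tracers=[Species("tracer", 0.8, 20)],
            target_phi_occ=0.3, seed=1,
        )
        config = build_mixture(spec)
        params = BDParams(timestep=default_timestep(config), n_steps=1)
        rng = np.random.default_rng(5)
        for _ in range(5):
            config = euler_step(config, params, rng)
            assert overlap_oracle(config.positions, config.radii, config.box.edge) == []


class TestRunTrajectory:
    def test_zero_steps_yields_initial_frame_only(self):
        config = _free_config()
        traj = run_trajectory(config, BDParams(timestep=1e-5, n_steps=0))
        assert traj.n_frames == 1
        assert np.array_equal(traj.wrapped[0], config.positions)

    def test_seed_determinism(self):
        config = _free_config()
        params = BDParams(timestep=1e-5, n_steps=200, sampling_interval=20, seed=42)
        a = run_trajectory(config, params)
        b = run_trajectory(config, params)
        assert np.array_equal(a.unwrapped, b.unwrapped)
        assert np.array_equal(a.wrapped, b.wrapped)

    def test_wrapped_and_unwrapped_agree_modulo_box(self):
        config = _free_config(n=10, radius=0.5, edge=20.0)
        params = BDParams(timestep=default_timestep(config), n_steps=2000,
                          sampling_interval=100, seed=3)
        traj = run_trajectory(config, params)
        diff = (traj.unwrapped - traj.wrapped) / traj.box_edge
        assert np.allclose(diff, np.round(diff), atol=1e-9)

    def test_no_overlap_in_any_stored_frame(self, overlap_oracle):
        spec = MixtureSpec(
            crowder=Species("crowder", 5.1, 40),
            tracers=[Species("tracer", 0.8, 20)],
            target_phi_occ=0.2, seed=2,
        )
        config = build_mixture(spec)
        params = BDParams(timestep=default_timestep(config), n_steps=1000,
                          sampling_interval=100, seed=4)
        traj = run_trajectory(config, params)
        for f in range(traj.n_frames):
            assert overlap_oracle(traj.wrapped[f], traj.radii, traj.box_edge) == []

    def test_free_particle_recovers_sse_d(self):
        """Single-species free diffusion: MSD slope/6 matches the input D0."""
        from crowdiff.analysis import compute_msd, long_time_d

        config = _free_config(n=50, radius=1.0, edge=80.0, seed=6)
        d0 = sse_diffusivity(1.0)
        params = BDParams(timestep=default_timestep(config), n_steps=20_000,
                          sampling_interval=40, seed=7)
        traj = run_trajectory(config, params)
        msd = compute_msd(traj, "tracer", max_lag_fraction=0.12)
        d_est, se = long_time_d(msd, n_blocks=10)
        assert abs(d_est - d0) < 3 * se

    def test_two_free_species_d_ratio_follows_inverse_radii(self):
        from crowdiff.analysis import compute_msd, long_time_d

        spec = MixtureSpec(
            crowder=Species("crowder", 5.1, 0),
            tracers=[Species("small", 0.5, 150), Species("big", 2.0, 150)],
            target_phi_occ=0.0, box_edge=80.0, seed=8,
        )
        config = build_mixture(spec)
        params = BDParams(timestep=default_timestep(config), n_steps=40_000,
                          sampling_interval=40, seed=9)
        traj = run_trajectory(config, params)
        d_small, _ = long_time_d(compute_msd(traj, "small", max_lag_fraction=0.05), n_blocks=10)
        d_big, _ = long_time_d(compute_msd(traj, "big", max_lag_fraction=0.05), n_blocks=10)
        assert d_small / d_big == pytest.approx(2.0 / 0.5, rel=0.05)

    def test_crowding_slows_tracers_relative_to_free_control(self):
        """At φ_occ = 0.10 tracers diffuse measurably slower than free ones."""
        from crowdiff.pipeline import simulate_d_ratio

        r_free, se_free = simulate_d_ratio(0.0, 0.8, n_tracers=50, n_steps=20_000,
                                           sampling_interval=40, seed=12)
        r_crowd, se_crowd = simulate_d_ratio(0.10, 0.8, n_tracers=50, n_crowders=60,
                                             n_steps=20_000, sampling_interval=40, seed=13)
        assert r_crowd < r_free + 3 * np.hypot(se_free, se_crowd)
        assert r_crowd < 1.0
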