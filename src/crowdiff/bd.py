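"""Overdamped Brownian dynamics of hard-sphere mixtures, without
hydrodynamic interactions.

The solvent enters implicitly: each particle performs a forward-Euler
Brownian step with per-axis displacement variance 2·D0·dt, where D0 is
its dilute-limit (SSE) diffusivity.  Hard cores are enforced by an
elastic displacement correction in the spirit of Heyes and Melrose —
after every step, overlapping pairs are pushed apart along their centre
line exactly to contact, sharing the displacement in proportion to the
particles' mobilities, iterated until no overlap remains.  This scheme
preserves diffusive scaling at small time steps without introducing a
soft potential.

Inertia, rotations, torques and hydrodynamic coupling are all outside
the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core import (
    Configuration,
    PhysicalEnvironment,
    find_overlaps,
    sse_diffusivity,
)

__all__ = ["BDParams", "Trajectory", "euler_step", "resolve_overlaps", "run_trajectory"]

#: noise chunk length (steps) passed to the propagation kernel at a time
_CHUNK_STEPS = 512
_MAX_SWEEPS = 100


@dataclass
class BDParams:
    """Parameters of a Brownian-dynamics run.

    The timestep must keep every species' RMS free displacement
    √(2·D0·dt) at or below one tenth of the smallest radius in the
    system; :func:`default_timestep` picks dt so the *largest* D0 gives
    an RMS displacement of 0.05 × the smallest radius.
    """

    timestep: float  # µs
    n_steps: int
    sampling_interval: int = 1
    seed: int = 0
    env: PhysicalEnvironment = field(default_factory=PhysicalEnvironment)
    equilibration_steps: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0 or self.n_steps < 0 or self.sampling_interval < 1:
            raise ValueError("timestep > 0, n_steps >= 0, sampling_interval >= 1 required")

    def validate_for(self, config: Configuration) -> None:
        r_min = float(np.min(config.radii))
        d_max = sse_diffusivity(r_min, self.env)  # smallest particle diffuses fastest
        rms = np.sqrt(2.0 * d_max * self.timestep)
        if rms > 0.1 * r_min:
            raise ValueError(
                f"timestep too large: RMS free displacement {rms:.3g} nm exceeds "
                f"0.1 × smallest radius ({0.1 * r_min:.3g} nm)"
            )


def default_timestep(config: Configuration, env: PhysicalEnvironment | None = None,
                     fraction: float = 0.05) -> float:
    """dt such that the fastest species' RMS free step is `fraction` × smallest radius."""
    env = env or PhysicalEnvironment()
    r_min = float(np.min(config.radii))
    d_max = sse_diffusivity(r_min, env)
    return (fraction * r_min) ** 2 / (2.0 * d_max)


@dataclass
class Trajectory:
    """Time-ordered configurations with an unwrapped-coordinate track.

    `wrapped` and `unwrapped` have shape (n_frames, N, 3); the unwrapped
    coordinates accumulate true displacements (no periodic jumps) and are
    the input to mean-squared-displacement analysis.
    """

    box_edge: float
    labels: np.ndarray
    radii: np.ndarray
    times: np.ndarray
    wrapped: np.ndarray
    unwrapped: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame(self, i: int) -> Configuration:
        from .core import PeriodicBox

        return Configuration(
            PeriodicBox(self.box_edge), self.labels, self.wrapped[i], self.radii,
            check_overlaps=False,
        )

    def select(self, species) -> np.ndarray:
        """Boolean particle mask for a species label (or list of labels)."""
        if isinstance(species, str):
            species = [species]
        unknown = set(species) - set(self.labels.tolist())
        if unknown:
            raise KeyError(f"unknown species label(s): {sorted(unknown)}")
        return np.isin(self.labels, list(species))


def _weights(config: Configuration, env: PhysicalEnvironment) -> np.ndarray:
    """Dilute-limit diffusivity per particle (mobility weights, nm²/µs)."""
    return np.array([sse_diffusivity(r, env) for r in config.radii])


def resolve_overlaps(config: Configuration, env: PhysicalEnvironment | None = None,
                     max_sweeps: int = _MAX_SWEEPS) -> Configuration:
    """Restore the hard cores of a configuration.

    Overlapping pairs are moved apart along their centre line exactly to
    contact, each particle taking a share of the displacement proportional
    to its dilute-limit diffusivity; sweeps repeat until convergence.
    Overlap-free input is returned unchanged (bitwise).
    """
    env = env or PhysicalEnvironment()
    pos = config.positions.copy()
    weights = _weights(config, env)
    sweeps = _kernels.resolve_overlaps_sweeps(pos, config.radii, weights,
                                              config.box.edge, max_sweeps)
    if sweeps < 0:
        raise RuntimeError(
            f"overlap resolution did not converge in {max_sweeps} sweeps "
            "(timestep or packing fraction too large)"
        )
    if sweeps == 0:
        return config  # untouched input
    return Configuration(config.box, config.labels, pos, config.radii, check_overlaps=False)


def euler_step(config: Configuration, params: BDParams,
               rng: np.random.Generator) -> Configuration:
    """One forward-Euler Brownian step followed by hard-core restoration.

    Each particle is displaced by an independent Gaussian vector with
    per-axis variance 2·D0·dt.  For trajectory generation prefer
    :func:`run_trajectory`, which runs the same update in a compiled loop
    and maintains the unwrapped track.
    """
    params.validate_for(config)
    weights = _weights(config, params.env)
    sigma = np.sqrt(2.0 * weights * params.timestep)
    noise = rng.normal(0.0, 1.0, size=(config.n_particles, 3)) * sigma[:, None]
    pos = (config.positions + noise) % config.box.edge
    moved = Configuration(config.box, config.labels, pos, config.radii, check_overlaps=False)
    return resolve_overlaps(moved, params.env)


def run_trajectory(config: Configuration, params: BDParams) -> Trajectory:
    """Propagate `config` for ``params.n_steps`` steps, recording every
    ``params.sampling_interval``-th frame (plus the initial frame).

    An optional equilibration segment (``params.equilibration_steps``) is
    run first and not recorded; the unwrapped track starts after it.
    Deterministic for a given seed.
    """
    params.validate_for(config)
    rng = np.random.default_rng(params.seed)
    weights = _weights(config, params.env)
    sigma = np.sqrt(2.0 * weights * params.timestep)
    edge = config.box.edge
    n = config.n_particles
    pos = config.positions.copy()
    unwrapped = pos.copy()

    def _advance(n_steps: int, record_from: int | None):
        frames_w, frames_u = [], []
        done = 0
        while done < n_steps:
            take = min(_CHUNK_STEPS, n_steps - done)
            noise = rng.normal(0.0, 1.0, size=(take, n, 3)) * sigma[None, :, None]
            # record frame-by-frame within the chunk when sampling
            for s in range(take):
                ok = _kernels.propagate_chunk(pos, unwrapped, config.radii, weights,
                                              noise[s : s + 1], edge, _MAX_SWEEPS)
                if ok < 0:
                    raise RuntimeError(
                        "overlap resolution did not converge; reduce the timestep"
                    )
                step_index = done + s + 1
                if record_from is not None and step_index % params.sampling_interval == 0:
                    frames_w.append(pos.copy())
                    frames_u.append(unwrapped.copy())
            done += take
        return frames_w, frames_u

    if params.equilibration_steps > 0:
        _advance(params.equilibration_steps, record_from=None)
        unwrapped[:] = pos  # restart the unwrapped track post-equilibration

    frames_w = [pos.copy()]
    frames_u = [unwrapped.copy()]
    fw, fu = _advance(params.n_steps, record_from=0)
    frames_w += fw
    frames_u += fu
    n_rec = len(frames_w)
    times = np.arange(n_rec) * params.sampling_interval * params.timestep
    return Trajectory(
        box_edge=edge,
        labels=config.labels.copy(),
        radii=config.radii.copy(),
        times=times,
        wrapped=np.array(frames_w),
        unwrapped=np.array(frames_u),
        metadata={
            "seed": params.seed,
            "timestep_us": params.timestep,
            "n_steps": params.n_steps,
            "sampling_interval": params.sampling_interval,
            "equilibration_steps": params.equilibration_steps,
            "temperature_K": params.env.temperature,
            "solvent_viscosity_mPas": params.env.solvent_viscosity,
            "d0_by_species": {
                lab: sse_diffusivity(float(config.radii[config.labels == lab][0]), params.env)
                for lab in dict.fromkeys(config.labels.tolist())
            },
        },
    )


def check_trajectory_overlap_free(traj: Trajectory) -> bool:
    """Exhaustive pair scan of every stored frame (testing utility)."""
    for i in range(traj.n_frames):
        if find_overlaps(traj.wrapped[i], traj.radii, traj.box_edge):
            return False
    return True
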