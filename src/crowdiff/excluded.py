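"""Excluded volume and effective-medium (Maxwell–Garnett) predictors.

A tracer of radius R_H cannot place its centre within R_c + R_H of any
crowder centre, so the volume fraction it effectively "sees" is the
excluded volume fraction φ_ex ≥ φ_occ.  φ_ex is estimated here by
Monte-Carlo insertion (the fraction of uniformly random trial points
that overlap a crowder) and by two closed forms:

    cubic:   φ_ex = φ_occ · (1 + R_H/R_c)³      (neglects overlap of
                                                 exclusion shells; valid
                                                 at low φ_occ)
    linear:  φ_ex = φ_occ · (1 + 3·R_H/R_c)     (first order in R_H/R_c)

Feeding the linear form into the point-tracer Maxwell–Garnett slowdown
D/D0 = 1 − φ_ex/2 yields the linear law D/D0 = 1 − κ·φ_occ with
κ(R_H) = 0.5·(1 + 3·R_H/R_c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import Configuration

__all__ = [
    "ExcludedVolumeEstimate",
    "phi_ex_mc",
    "phi_ex_cubic",
    "phi_ex_linear",
    "mg_diffusivity",
    "kappa_linear_theory",
]


@dataclass
class ExcludedVolumeEstimate:
    """Monte-Carlo estimate of the excluded volume fraction."""

    phi_ex: float
    se: float
    n_insertions: int
    n_configs: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_ex <= 1.0:
            raise ValueError("phi_ex must lie in [0, 1]")
        if self.se < 0:
            raise ValueError("se must be >= 0")


def phi_ex_mc(
    configs: list[Configuration] | Configuration,
    tracer_radius: float,
    n_insertions: int = 1_000_000,
    seed: int = 0,
) -> ExcludedVolumeEstimate:
    """Excluded volume fraction by Monte-Carlo insertion.

    For each configuration, `n_insertions` centres are drawn uniformly in
    the box; the estimate is the fraction overlapping any crowder
    (minimum image).  The configurations must contain crowders only.
    With two or more configurations the standard error is taken over
    configurations; with one, it is the binomial standard error.
    """
    if isinstance(configs, Configuration):
        configs = [configs]
    if not configs:
        raise ValueError("need at least one configuration")
    if tracer_radius < 0:
        raise ValueError("tracer_radius must be >= 0")
    if n_insertions < 1_000:
        warnings.warn(
            f"n_insertions = {n_insertions} is small; estimate will be noisy",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    fractions = []
    for config in configs:
        points = rng.uniform(0.0, config.box.edge, size=(n_insertions, 3))
        hits = _kernels.count_insertion_overlaps(
            points, config.positions, config.radii, float(tracer_radius), config.box.edge
        )
        fractions.append(hits / n_insertions)
    phi = float(np.mean(fractions))
    if len(fractions) >= 2:
        se = float(np.std(fractions, ddof=1) / np.sqrt(len(fractions)))
    else:
        se = float(np.sqrt(max(phi * (1.0 - phi), 1e-12) / n_insertions))
    return ExcludedVolumeEstimate(
        phi_ex=phi, se=se, n_insertions=n_insertions, n_configs=len(configs)
    )


def phi_ex_cubic(phi_occ: float, r_h: float, r_c: float) -> float:
    """Closed-form φ_ex neglecting exclusion-shell overlaps: φ_occ·(1 + R_H/R_c)³."""
    _check(phi_occ, r_h, r_c)
    return phi_occ * (1.0 + r_h / r_c) ** 3


def phi_ex_linear(phi_occ: float, r_h: float, r_c: float) -> float:
    """First-order (in R_H/R_c) approximation: φ_occ·(1 + 3·R_H/R_c)."""
    _check(phi_occ, r_h, r_c)
    return phi_occ * (1.0 + 3.0 * r_h / r_c)


def _check(phi_occ: float, r_h: float, r_c: float) -> None:
    if phi_occ < 0 or r_h < 0:
        raise ValueError("phi_occ and r_h must be >= 0")
    if r_c <= 0:
        raise ValueError("r_c must be > 0")


def mg_diffusivity(phi_ex: float) -> float:
    """Point-tracer Maxwell–Garnett slowdown: D/D0 = 1 − φ_ex/2.

    The effective-medium treatment of transport among immobile
    impermeable inclusions reduces, in the linear slowdown form, to a
    slope of 1/2 in the excluded volume fraction.
    """
    if not 0.0 <= phi_ex <= 1.0:
        raise ValueError(f"phi_ex must lie in [0, 1], got {phi_ex}")
    return 1.0 - 0.5 * phi_ex


def kappa_linear_theory(r_h: float, r_c: float) -> float:
    """Slowdown parameter of the linear excluded-volume theory.

    κ(R_H) = 0.5·(1 + 3·R_H/R_c): the Maxwell–Garnett slope 1/2 applied
    to the linearized excluded volume.  Self-crowding (R_H = R_c) gives
    κ = 2; a point tracer gives κ = 1/2.
    """
    if r_c <= 0:
        raise ValueError("r_c must be > 0")
    if r_h < 0:
        raise ValueError("r_h must be >= 0")
    return 0.5 * (1.0 + 3.0 * r_h / r_c)
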