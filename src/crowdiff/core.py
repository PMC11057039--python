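"""Core domain types and the Stokes–Sutherland–Einstein (SSE) relation.

The SSE equation D = k_B·T / (6π·η·R_H) links a particle's diffusion
coefficient to its hydrodynamic radius and the viscosity of the medium.
All quantities here use the package's internal units (nm, µs, K, mPa·s;
D in nm²/µs = 1e-12 m²/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import AVOGADRO_PER_MOL, BOLTZMANN_J_PER_K

__all__ = [
    "Species",
    "PeriodicBox",
    "PhysicalEnvironment",
    "Configuration",
    "sse_diffusivity",
    "hydrodynamic_radius_from_d",
    "volume_fraction",
    "concentration_from_volume_fraction",
    "occupied_fraction",
    "sphere_volume",
    "minimum_image",
    "find_overlaps",
]

#: absolute slack (nm) for the hard-core overlap predicate; pairs pushed
#: exactly to contact must not be re-flagged by floating-point rounding.
OVERLAP_TOL_NM = 1e-9


@dataclass(frozen=True)
class Species:
    """A particle kind: label, hydrodynamic radius (nm) and copy number."""

    label: str
    radius: float
    count: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"species {self.label!r}: radius must be > 0, got {self.radius}")
        if self.count < 0:
            raise ValueError(f"species {self.label!r}: count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class PeriodicBox:
    """Cubic simulation cell, periodic in all three axes. Edge in nm."""

    edge: float

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError(f"box edge must be > 0, got {self.edge}")

    @property
    def volume(self) -> float:
        return self.edge**3

    def validate_for(self, radii: np.ndarray) -> None:
        """Require edge > 2 × the largest particle diameter in the system."""
        if len(radii) and self.edge <= 4.0 * float(np.max(radii)):
            raise ValueError(
                f"box edge {self.edge} nm must exceed twice the largest particle "
                f"diameter ({4.0 * float(np.max(radii))} nm)"
            )


@dataclass(frozen=True)
class PhysicalEnvironment:
    """Temperature (K) and solvent viscosity (mPa·s) of the medium.

    The default viscosity, 0.89 mPa·s, is that of water at 298 K; it is a
    configuration choice, not a measured input.
    """

    temperature: float = 298.0
    solvent_viscosity: float = 0.89
    boltzmann_constant: float = BOLTZMANN_J_PER_K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.solvent_viscosity <= 0:
            raise ValueError("solvent viscosity must be > 0 mPa·s")


def sse_diffusivity(radius: float, env: PhysicalEnvironment = PhysicalEnvironment()) -> float:
    """Dilute-limit diffusion coefficient from the SSE relation, nm²/µs.

    D = k_B·T / (6π·η·R_H).  `radius` in nm.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    # SI: k_B [J/K] * T [K] / (6π * η [Pa·s] * R [m]) -> m²/s
    d_si = env.boltzmann_constant * env.temperature / (
        6.0 * math.pi * env.solvent_viscosity * 1e-3 * radius * 1e-9
    )
    return d_si * 1e12  # m²/s -> nm²/µs


def hydrodynamic_radius_from_d(
    diffusivity: float, env: PhysicalEnvironment = PhysicalEnvironment()
) -> float:
    """Hydrodynamic radius (nm) from a diffusivity (nm²/µs): exact SSE inverse."""
    if diffusivity <= 0:
        raise ValueError(f"diffusivity must be > 0, got {diffusivity}")
    d_si = diffusivity * 1e-12
    r_m = env.boltzmann_constant * env.temperature / (
        6.0 * math.pi * env.solvent_viscosity * 1e-3 * d_si
    )
    return r_m * 1e9


def sphere_volume(radius: float | np.ndarray) -> float | np.ndarray:
    """Volume of a sphere, same length unit cubed as the input."""
    return 4.0 / 3.0 * np.pi * np.asarray(radius, dtype=float) ** 3


def volume_fraction(concentration_mM: float, radius: float) -> float:
    """Occupied volume fraction of spheres of `radius` nm at `concentration_mM`.

    φ_occ = c·N_A·(4/3)πR³; 1 mM = 1 mol/m³.  Returned as a decimal.
    """
    if concentration_mM < 0:
        raise ValueError("concentration must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    v_m3 = 4.0 / 3.0 * math.pi * (radius * 1e-9) ** 3
    return concentration_mM * AVOGADRO_PER_MOL * v_m3


def concentration_from_volume_fraction(phi_occ: float, radius: float) -> float:
    """Inverse of :func:`volume_fraction`: concentration in mM for a given φ_occ."""
    if phi_occ < 0:
        raise ValueError("volume fraction must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    v_m3 = 4.0 / 3.0 * math.pi * (radius * 1e-9) ** 3
    return phi_occ / (AVOGADRO_PER_MOL * v_m3)


class Configuration:
    """Positions and radii of all particles in a periodic cubic box.

    Parameters
    ----------
    box : PeriodicBox
    labels : sequence of str, per-particle species label
    positions : (N, 3) array, nm, wrapped into [0, edge)
    radii : (N,) array, nm
    """

    def __init__(self, box, labels, positions, radii, check_overlaps: bool = True):
        self.box = box
        self.labels = np.asarray(labels, dtype=object)
        self.positions = np.ascontiguousarray(positions, dtype=float)
        self.radii = np.ascontiguousarray(radii, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (N, 3)")
        if self.radii.shape != (len(self.labels),):
            raise ValueError("radii must be (N,)")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be > 0")
        box.validate_for(self.radii)
        self.positions %= box.edge
        if check_overlaps:
            bad = find_overlaps(self.positions, self.radii, box.edge)
            if len(bad):
                i, j = bad[0]
                raise ValueError(
                    f"configuration contains {len(bad)} overlapping pair(s); "
                    f"first: particles {i} and {j}"
                )

    @property
    def n_particles(self) -> int:
        return len(self.radii)

    def species_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def mask(self, labels) -> np.ndarray:
        """Boolean mask selecting the given species label(s)."""
        if isinstance(labels, str):
            labels = [labels]
        unknown = set(labels) - set(self.labels.tolist())
        if unknown:
            raise KeyError(f"unknown species label(s): {sorted(unknown)}")
        return np.isin(self.labels, list(labels))

    def copy(self) -> "Configuration":
        return Configuration(
            self.box, self.labels.copy(), self.positions.copy(), self.radii.copy(),
            check_overlaps=False,
        )


def minimum_image(delta: np.ndarray, edge: float) -> np.ndarray:
    """Map displacement vectors into the minimum-image convention."""
    return delta - edge * np.round(delta / edge)


def find_overlaps(positions: np.ndarray, radii: np.ndarray, edge: float) -> list[tuple[int, int]]:
    """All overlapping pairs (minimum image), by direct O(N²) scan.

    A pair overlaps when its centre distance falls below the sum of radii
    minus a 1e-9 nm slack.
    """
    n = len(radii)
    out: list[tuple[int, int]] = []
    if n < 2:
        return out
    # chunk the row dimension so the scan stays O(N·chunk) in memory
    chunk = max(1, int(4e6 // max(n, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = positions[start:stop, None, :] - positions[None, :, :]
        d = minimum_image(d, edge)
        dist2 = (d**2).sum(axis=-1)
        contact = radii[start:stop, None] + radii[None, :] - OVERLAP_TOL_NM
        rows, cols = np.nonzero(dist2 < contact**2)
        for r, j in zip(rows, cols):
            i = start + int(r)
            if i < int(j):
                out.append((i, int(j)))
    return out


def occupied_fraction(config: Configuration, species_subset=None) -> float:
    """Fraction of the box volume occupied by the hard cores of a species subset.

    With `species_subset=None` all particles count.
    """
    if species_subset is None:
        sel = np.ones(config.n_particles, dtype=bool)
    else:
        if isinstance(species_subset, str):
            species_subset = [species_subset]
        if len(species_subset) == 0:
            return 0.0
        sel = config.mask(species_subset)
    return float(np.sum(sphere_volume(config.radii[sel]))) / config.box.volume
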