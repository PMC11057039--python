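"""Numba kernels for the hot loops.

All kernels operate on plain float64 arrays in nm / µs units and are
deterministic: random displacements are drawn outside (numpy Generator)
and passed in, so reproducibility is governed solely by the numpy seed.
"""

from __future__ import annotations

import numba
import numpy as np

#: absolute slack (nm) for the overlap predicate, matching core.OVERLAP_TOL_NM
_TOL = 1e-9


@numba.njit(cache=True)
def resolve_overlaps_sweeps(pos, radii, weights, edge, max_sweeps):
    """Iteratively push overlapping pairs apart to contact (minimum image).

    Each overlapping pair is separated along its centre line exactly to
    contact; the displacement is shared between the two particles in
    proportion to `weights` (mobility-proportional: weights are the
    dilute-limit diffusivities).  Sweeps repeat until no overlap remains.

    Returns the number of sweeps performed, or -1 if `max_sweeps` was
    reached with overlaps still present.  `pos` is modified in place and
    kept wrapped into [0, edge).
    """
    n = pos.shape[0]
    for sweep in range(max_sweeps):
        n_overlaps = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                dx -= edge * np.rint(dx / edge)
                dy -= edge * np.rint(dy / edge)
                dz -= edge * np.rint(dz / edge)
                contact = radii[i] + radii[j]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < (contact - _TOL) * (contact - _TOL):
                    n_overlaps += 1
                    d = np.sqrt(d2)
                    if d < 1e-12:
                        # coincident centres: separate along x
                        dx, dy, dz, d = contact, 0.0, 0.0, contact
                    gap = contact - d
                    wtot = weights[i] + weights[j]
                    fi = weights[i] / wtot
                    fj = weights[j] / wtot
                    ux, uy, uz = dx / d, dy / d, dz / d
                    pos[i, 0] -= ux * gap * fi
                    pos[i, 1] -= uy * gap * fi
                    pos[i, 2] -= uz * gap * fi
                    pos[j, 0] += ux * gap * fj
                    pos[j, 1] += uy * gap * fj
                    pos[j, 2] += uz * gap * fj
        if n_overlaps == 0:
            # wrap once at the end of the resolution
            for i in range(n):
                for k in range(3):
                    pos[i, k] = pos[i, k] % edge
            return sweep
    return -1


@numba.njit(cache=True)
def propagate_chunk(pos, unwrapped, radii, weights, noise, edge, max_sweeps):
    """Advance the system by `noise.shape[0]` forward-Euler steps.

    `noise` has shape (n_steps, N, 3) and already carries the per-particle
    Gaussian displacements (std = sqrt(2·D0·dt) per axis).  After each step
    the hard cores are restored by the elastic displacement correction.
    The unwrapped tracker accumulates the *final* displacement of each step
    (Brownian move + correction), so wrapped and unwrapped positions agree
    modulo the box.

    Returns 0 on success, -1 if overlap resolution failed to converge.
    """
    n_steps = noise.shape[0]
    n = pos.shape[0]
    prev = np.empty((n, 3))
    for s in range(n_steps):
        for i in range(n):
            for k in range(3):
                prev[i, k] = pos[i, k]
                pos[i, k] += noise[s, i, k]
        ok = resolve_overlaps_sweeps(pos, radii, weights, edge, max_sweeps)
        if ok < 0:
            return -1
        for i in range(n):
            for k in range(3):
                d = pos[i, k] - prev[i, k]
                d -= edge * np.rint(d / edge)
                unwrapped[i, k] += d
    return 0


@numba.njit(cache=True)
def count_insertion_overlaps(points, crowder_pos, crowder_radii, tracer_radius, edge):
    """Number of trial points overlapping any crowder (minimum image)."""
    n_pts = points.shape[0]
    n_cr = crowder_pos.shape[0]
    n_overlap = 0
    for p in range(n_pts):
        hit = False
        for c in range(n_cr):
            dx = points[p, 0] - crowder_pos[c, 0]
            dy = points[p, 1] - crowder_pos[c, 1]
            dz = points[p, 2] - crowder_pos[c, 2]
            dx -= edge * np.rint(dx / edge)
            dy -= edge * np.rint(dy / edge)
            dz -= edge * np.rint(dz / edge)
            contact = crowder_radii[c] + tracer_radius
            if dx * dx + dy * dy + dz * dz < contact * contact:
                hit = True
                break
        if hit:
            n_overlap += 1
    return n_overlap


@numba.njit(cache=True)
def first_nonoverlapping(candidates, pos, radii, n_existing, new_radius, edge):
    """Index of the first candidate point clearing all existing particles, or -1."""
    n_cand = candidates.shape[0]
    for c in range(n_cand):
        ok = True
        for i in range(n_existing):
            dx = candidates[c, 0] - pos[i, 0]
            dy = candidates[c, 1] - pos[i, 1]
            dz = candidates[c, 2] - pos[i, 2]
            dx -= edge * np.rint(dx / edge)
            dy -= edge * np.rint(dy / edge)
            dz -= edge * np.rint(dz / edge)
            contact = radii[i] + new_radius
            if dx * dx + dy * dy + dz * dz < (contact - _TOL) * (contact - _TOL):
                ok = False
                break
        if ok:
            return c
    return -1
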