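"""File formats: species tables (CSV), configurations (extended XYZ), JSON sidecars.

The extended-XYZ flavour used here stores the cubic box edge on the comment
line (``edge_nm=<value>``) and one extra per-atom column with the particle
radius in nm::

    <N>
    edge_nm=57.0
    crowder 1.23 4.56 7.89 5.1
    ...

Standard XYZ readers that ignore trailing columns remain compatible.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Configuration, PeriodicBox, Species

__all__ = [
    "read_species_csv",
    "write_species_csv",
    "read_xyz",
    "write_xyz",
    "write_json",
    "read_json",
]


def read_species_csv(path, box_edge: float | None = None) -> list[Species]:
    """Read a species table.

    The table must carry ``label,radius_nm`` and either ``count`` or
    ``concentration_mM`` (mutually exclusive).  Converting concentrations to
    counts requires `box_edge` (nm); counts are rounded to the nearest
    integer.
    """
    df = pd.read_csv(path, comment="#")
    required = {"label", "radius_nm"}
    if not required.issubset(df.columns):
        raise ValueError(f"species CSV must have columns {sorted(required)}")
    has_count = "count" in df.columns
    has_conc = "concentration_mM" in df.columns
    if has_count == has_conc:
        raise ValueError("species CSV needs exactly one of 'count' or 'concentration_mM'")
    species = []
    for _, row in df.iterrows():
        if has_count:
            n = int(row["count"])
        else:
            if box_edge is None:
                raise ValueError("box_edge is required to convert concentration_mM to counts")
            # c [mM] = c [mol/m³]; N = c·N_A·V_box
            from .constants import AVOGADRO_PER_MOL

            n = int(round(row["concentration_mM"] * AVOGADRO_PER_MOL * (box_edge * 1e-9) ** 3))
        species.append(Species(label=str(row["label"]), radius=float(row["radius_nm"]), count=n))
    return species


def write_species_csv(path, species: list[Species]) -> None:
    pd.DataFrame(
        {
            "label": [s.label for s in species],
            "radius_nm": [s.radius for s in species],
            "count": [s.count for s in species],
        }
    ).to_csv(path, index=False)


def write_xyz(path, config: Configuration, comment_extra: str = "") -> None:
    """Write one configuration as extended XYZ (label, x, y, z, radius)."""
    lines = [str(config.n_particles), f"edge_nm={config.box.edge!r} {comment_extra}".rstrip()]
    for lab, pos, rad in zip(config.labels, config.positions, config.radii):
        lines.append(f"{lab} {pos[0]:.10g} {pos[1]:.10g} {pos[2]:.10g} {rad:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> Configuration:
    """Read one extended-XYZ configuration written by :func:`write_xyz`."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0])
    m = re.search(r"edge_nm=([0-9eE+.\-]+)", lines[1])
    if m is None:
        raise ValueError("comment line must carry edge_nm=<value>")
    edge = float(m.group(1))
    labels, positions, radii = [], [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        labels.append(parts[0])
        positions.append([float(p) for p in parts[1:4]])
        radii.append(float(parts[4]))
    return Configuration(
        PeriodicBox(edge), labels, np.array(positions), np.array(radii), check_overlaps=False
    )


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
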