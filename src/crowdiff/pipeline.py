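"""Config-driven orchestration of the package's computational experiments.

Each experiment is described by one JSON config (see `RunConfig`); the
run executes build → simulate → analyze → fit and writes CSV/JSON
outputs plus a provenance log (seeds, config hash, timings).

Experiments
-----------
phi_sweep      BD runs over a φ_occ grid at fixed tracer radius; κ fit.
size_sweep     φ sweeps for several tracer radii; κ(R_H) table.
phiex_compare  MC excluded volume vs closed forms over an R_H grid.
cytoplasm      polydisperse cytoplasm build + BD + per-species D/D0.
nanovisc_fit   nanoviscosity fit of a (R_H, D/D0) CSV.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import SlowdownCurve, compute_msd, fit_kappa, long_time_d
from .bd import BDParams, default_timestep, run_trajectory
from .builder import (
    CompositionTable,
    MixtureSpec,
    build_cytoplasm,
    build_mixture,
    default_cytoplasm_composition,
)
from .core import PhysicalEnvironment, Species, occupied_fraction, sse_diffusivity
from .excluded import kappa_linear_theory, mg_diffusivity, phi_ex_cubic, phi_ex_linear, phi_ex_mc
from .io import read_species_csv, write_json, write_xyz
from .nanovisc import fit_nanovisc

__all__ = ["RunConfig", "run_experiment"]

EXPERIMENTS = ("phi_sweep", "size_sweep", "phiex_compare", "cytoplasm", "nanovisc_fit")


@dataclass
class RunConfig:
    """One experiment's configuration (JSON-serializable)."""

    experiment: str
    out_dir: str
    seed: int = 0
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)

    def digest(self) -> str:
        blob = json.dumps(
            {"experiment": self.experiment, "seed": self.seed, "parameters": self.parameters},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate_d_ratio(
    phi: float,
    r_h: float,
    *,
    r_c: float = 5.1,
    n_crowders: int = 100,
    n_tracers: int = 50,
    n_steps: int = 100_000,
    sampling_interval: int = 100,
    equilibration_steps: int = 2_000,
    max_lag_fraction: float = 0.12,
    n_blocks: int = 10,
    free_box_edge: float | None = None,
    seed: int = 0,
    env: PhysicalEnvironment | None = None,
    dt_fraction: float = 0.05,
    total_time_us: float | None = None,
    equilibration_time_us: float | None = None,
    window_end_us: float | None = None,
    n_frames_target: int = 1000,
) -> tuple[float, float]:
    """Build, BD-simulate and analyze one mixture; return (D/D0, SE).

    At φ = 0 the run is a free-diffusion control (tracers only).  When
    the tracer radius equals the crowder radius (self-crowding), the
    crowders themselves are the measured species — adding a separate
    tracer population of the same size would inflate the total crowding.

    Run length can be given either in steps (``n_steps`` etc.) or in
    physical time (``total_time_us``, ``equilibration_time_us``,
    ``window_end_us``); the time-based form takes precedence and sizes
    the step counts from the stability-limited timestep, which is useful
    when comparing tracers of very different mobility.
    """
    env = env or PhysicalEnvironment()
    self_crowding = phi > 0 and abs(r_h - r_c) < 1e-12
    if phi <= 0:
        edge = free_box_edge if free_box_edge is not None else 40.0 * r_h + 20.0
        spec = MixtureSpec(
            crowder=Species("crowder", r_c, 0),
            tracers=[Species("tracer", r_h, n_tracers)],
            target_phi_occ=0.0, box_edge=edge, seed=seed,
        )
        species = "tracer"
        equilibration_steps = 0
    elif self_crowding:
        spec = MixtureSpec(
            crowder=Species("crowder", r_c, n_crowders + n_tracers),
            tracers=[], target_phi_occ=phi, seed=seed,
        )
        species = "crowder"
    else:
        spec = MixtureSpec(
            crowder=Species("crowder", r_c, n_crowders),
            tracers=[Species("tracer", r_h, n_tracers)],
            target_phi_occ=phi, seed=seed,
        )
        species = "tracer"
    config = build_mixture(spec)
    dt = default_timestep(config, env, fraction=dt_fraction)
    if total_time_us is not None:
        n_steps = max(int(round(total_time_us / dt)), 1)
        sampling_interval = max(1, n_steps // n_frames_target)
        if equilibration_time_us is not None and phi > 0:
            equilibration_steps = int(round(equilibration_time_us / dt))
        if window_end_us is not None:
            max_lag_fraction = min(window_end_us / total_time_us, 1.0)
    params = BDParams(
        timestep=dt, n_steps=n_steps, sampling_interval=sampling_interval,
        seed=seed + 1, env=env, equilibration_steps=equilibration_steps,
    )
    traj = run_trajectory(config, params)
    msd = compute_msd(traj, species, max_lag_fraction=max_lag_fraction)
    d_est, d_se = long_time_d(msd, n_blocks=n_blocks)
    d0 = sse_diffusivity(r_h, env)
    return d_est / d0, d_se / d0


def simulate_slowdown_curve(
    r_h: float,
    phi_grid,
    n_replicates: int = 1,
    seed: int = 0,
    env: PhysicalEnvironment | None = None,
    **kwargs,
) -> SlowdownCurve:
    """(φ_occ, D/D0) curve from BD runs; replicate seeds are averaged.

    With ≥ 3 replicates the per-point uncertainty is the standard error
    of the replicate mean — the replicate scatter captures
    between-realization variance that within-run particle blocks cannot
    see.  With fewer replicates the within-run block errors are
    propagated instead.
    """
    ratios, ses = [], []
    for k, phi in enumerate(phi_grid):
        reps = []
        for r in range(n_replicates):
            reps.append(simulate_d_ratio(
                float(phi), r_h, seed=seed + 1_000 * k + 10_000_000 * r, env=env, **kwargs
            ))
        vals = np.array([v for v, _ in reps])
        errs = np.array([s for _, s in reps])
        ratios.append(vals.mean())
        if n_replicates >= 3:
            ses.append(float(np.std(vals, ddof=1) / np.sqrt(len(vals))))
        else:
            ses.append(float(np.sqrt(np.sum(errs**2)) / len(reps)))
    return SlowdownCurve(np.array(phi_grid, float), np.array(ratios), np.array(ses))


def _phi_sweep_curve(p: dict, r_h: float, seed: int, env: PhysicalEnvironment) -> SlowdownCurve:
    return simulate_slowdown_curve(
        r_h,
        p.get("phi_grid", [0.1, 0.2, 0.3]),
        n_replicates=int(p.get("n_replicates", 1)),
        seed=seed,
        env=env,
        r_c=float(p.get("r_c", 5.1)),
        n_crowders=int(p.get("n_crowders", 100)),
        n_tracers=int(p.get("n_tracers", 50)),
        n_steps=int(p.get("n_steps", 100_000)),
        sampling_interval=int(p.get("sampling_interval", 100)),
        equilibration_steps=int(p.get("equilibration_steps", 2_000)),
    )


def run_experiment(config: RunConfig) -> dict:
    """Execute one experiment end to end; returns the result bundle dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    p = config.parameters
    env = PhysicalEnvironment(
        temperature=p.get("temperature_K", 298.0),
        solvent_viscosity=p.get("solvent_viscosity_mPas", 0.89),
    )
    bundle: dict = {"experiment": config.experiment, "config_hash": config.digest(),
                    "seed": config.seed}
    try:
        if config.experiment == "phi_sweep":
            r_h = float(p.get("r_h", 0.8))
            curve = _phi_sweep_curve(p, r_h, config.seed, env)
            res = fit_kappa(curve)
            df = curve.to_frame()
            df.insert(0, "config_hash", config.digest())
            df.to_csv(out / "slowdown_curve.csv", index=False)
            write_json(out / "kappa_fit.json", {**res.to_dict(), "r_h": r_h,
                                                "config_hash": config.digest()})
            bundle.update(curve=curve, kappa_fit=res)

        elif config.experiment == "size_sweep":
            rows = []
            for i, r_h in enumerate(p.get("r_h_grid", [0.8, 2.5, 5.1])):
                curve = _phi_sweep_curve(p, float(r_h), config.seed + 100_000 * i, env)
                res = fit_kappa(curve)
                rows.append({"r_h_nm": r_h, "kappa": res.kappa, "kappa_se": res.kappa_se,
                             "r_squared": res.r_squared})
            df = pd.DataFrame(rows)
            df.insert(0, "config_hash", config.digest())
            df.to_csv(out / "kappa_vs_rh.csv", index=False)
            bundle.update(kappa_table=df)

        elif config.experiment == "phiex_compare":
            r_c = float(p.get("r_c", 5.1))
            phi = float(p.get("phi_occ", 0.1))
            n_crowders = int(p.get("n_crowders", 100))
            n_ins = int(p.get("n_insertions", 100_000))
            spec = MixtureSpec(crowder=Species("crowder", r_c, n_crowders),
                               target_phi_occ=phi, seed=config.seed)
            cfg = build_mixture(spec)
            rows = []
            for r_h in p.get("r_h_grid", [0.0, 0.8, 2.5, 5.1]):
                est = phi_ex_mc(cfg, float(r_h), n_ins, seed=config.seed + 7)
                rows.append({
                    "r_h_nm": r_h,
                    "phi_ex_mc": est.phi_ex,
                    "phi_ex_mc_se": est.se,
                    "phi_ex_cubic": phi_ex_cubic(phi, float(r_h), r_c),
                    "phi_ex_linear": phi_ex_linear(phi, float(r_h), r_c),
                    "d_ratio_mg_mc": mg_diffusivity(min(est.phi_ex, 1.0)),
                    "kappa_linear": kappa_linear_theory(float(r_h), r_c),
                })
            df = pd.DataFrame(rows)
            df.insert(0, "config_hash", config.digest())
            df.to_csv(out / "phiex_compare.csv", index=False)
            bundle.update(phiex_table=df)

        elif config.experiment == "cytoplasm":
            if "composition_csv" in p:
                table = CompositionTable(read_species_csv(p["composition_csv"]))
            else:
                table = default_cytoplasm_composition()
            metabolite = Species(p.get("metabolite_label", "metabolite"),
                                 float(p.get("metabolite_radius", 0.8)),
                                 int(p.get("n_metabolites", 50)))
            target = float(p.get("target_phi_occ", 0.426))
            cfg = build_cytoplasm(table, metabolite, target, seed=config.seed)
            write_xyz(out / "cytoplasm_initial.xyz", cfg,
                      comment_extra=f"config_hash={config.digest()}")
            dt = default_timestep(cfg, env)
            params = BDParams(timestep=dt, n_steps=int(p.get("n_steps", 20_000)),
                              sampling_interval=int(p.get("sampling_interval", 50)),
                              seed=config.seed + 1, env=env,
                              equilibration_steps=int(p.get("equilibration_steps", 1_000)))
            traj = run_trajectory(cfg, params)
            rows = []
            for lab in dict.fromkeys(cfg.labels.tolist()):
                radius = float(cfg.radii[cfg.labels == lab][0])
                msd = compute_msd(traj, lab)
                try:
                    d_est, d_se = long_time_d(msd)
                except ValueError:
                    continue
                d0 = sse_diffusivity(radius, env)
                rows.append({"label": lab, "r_h_nm": radius,
                             "d_ratio": d_est / d0, "sigma": d_se / d0})
            df = pd.DataFrame(rows)
            df.insert(0, "config_hash", config.digest())
            df.to_csv(out / "cytoplasm_slowdown.csv", index=False)
            bundle.update(slowdown_table=df, phi_occ_macromolecules=occupied_fraction(
                cfg, [s.label for s in table.species]))

        elif config.experiment == "nanovisc_fit":
            df = pd.read_csv(p["curve_csv"])
            curve = SlowdownCurve(df["r_h_nm"].to_numpy(), df["d_ratio"].to_numpy(),
                                  df["sigma"].to_numpy() if "sigma" in df else None,
                                  abscissa_name="r_h_nm")
            res = fit_nanovisc(curve, fix_a=p.get("fix_a"),
                               phi_occ=float(p.get("phi_occ", 0.426)))
            write_json(out / "nanovisc_fit.json",
                       {**res.to_dict(), "config_hash": config.digest()})
            bundle.update(nanovisc_fit=res)

    except Exception as exc:
        raise RuntimeError(f"experiment {config.experiment!r} failed: {exc}") from exc

    log = {
        "experiment": config.experiment,
        "config_hash": config.digest(),
        "seed": config.seed,
        "parameters": p,
        "elapsed_s": round(time.time() - t0, 3),
    }
    write_json(out / "provenance.json", log)
    bundle["provenance"] = log
    return bundle
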