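"""Synthetic PGSTE-NMR data and Stejskal–Tanner fitting, plus generators
with known ground truth for calibrating the analysis chain.

In a pulsed-gradient stimulated-echo experiment the normalized signal of
a species with self-diffusion coefficient D decays with gradient
strength g as

    I/I0 = exp[-D * gamma^2 * g^2 * delta^2 * (Delta - delta/3)],

the Stejskal–Tanner attenuation (gamma: gyromagnetic ratio; delta:
gradient pulse duration; Delta: diffusion delay).  The generators here
emulate such attenuation tables with additive Gaussian noise, free
random walks of known D, and noisy slowdown curves with recorded truth —
the synthetic stand-ins for raw spectra used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .bd import Trajectory
from .constants import GAMMA_1H
from .analysis import SlowdownCurve
from .nanovisc import NanoviscParams, d_ratio_nanovisc

__all__ = [
    "PGSTEAcquisition",
    "AttenuationSeries",
    "stejskal_tanner",
    "simulate_series",
    "StejskalTannerModel",
    "StejskalTannerResults",
    "fit_attenuation",
    "generate_slowdown_table",
    "generate_free_walk",
]


@dataclass
class PGSTEAcquisition:
    """PGSTE acquisition parameters.

    gamma in rad s⁻¹ T⁻¹ (¹H default), delta and Delta in ms, gradient
    strengths in T/m.  Defaults are plausible modern-spectrometer values;
    they are configuration, not measured constants.
    """

    gamma: float = GAMMA_1H
    delta: float = 2.0  # ms
    Delta: float = 100.0  # ms
    gradients: np.ndarray = field(
        default_factory=lambda: np.linspace(0.005, 0.5, 16)
    )

    def __post_init__(self) -> None:
        self.gradients = np.asarray(self.gradients, dtype=float)
        if self.delta >= self.Delta:
            raise ValueError("delta must be smaller than Delta")
        if len(self.gradients) < 5:
            raise ValueError("need at least 5 gradient values")
        if np.any(self.gradients < 0) or np.any(np.diff(self.gradients) <= 0):
            raise ValueError("gradients must be non-negative and strictly increasing")

    def b_factor(self, g) -> np.ndarray:
        """γ²·g²·δ²·(Δ − δ/3) in s/m² for gradient strength(s) g (T/m)."""
        delta_s = self.delta * 1e-3
        Delta_s = self.Delta * 1e-3
        return self.gamma**2 * np.asarray(g, dtype=float) ** 2 * delta_s**2 * (
            Delta_s - delta_s / 3.0
        )


@dataclass
class AttenuationSeries:
    """Normalized PGSTE intensities per gradient, with noise level and truth."""

    acquisition: PGSTEAcquisition
    signal: np.ndarray
    noise_sd: float = 0.0
    truth: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"g_T_per_m": self.acquisition.gradients, "intensity": self.signal}
        )


def stejskal_tanner(g, acq: PGSTEAcquisition, d: float):
    """Stejskal–Tanner attenuation exp(−b·D) for diffusivity d in m²/s."""
    if d < 0:
        raise ValueError("diffusivity must be >= 0")
    out = np.exp(-d * acq.b_factor(g))
    return float(out) if np.ndim(out) == 0 else out


def simulate_series(d_true: float, acq: PGSTEAcquisition | None = None,
                    noise_sd: float = 0.0, seed: int = 0) -> AttenuationSeries:
    """Synthetic attenuation series: model curve plus additive Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    acq = acq or PGSTEAcquisition()
    rng = np.random.default_rng(seed)
    clean = stejskal_tanner(acq.gradients, acq, d_true)
    signal = clean + rng.normal(0.0, noise_sd, size=len(acq.gradients))
    return AttenuationSeries(
        acquisition=acq, signal=signal, noise_sd=noise_sd,
        truth={"d_true_m2_per_s": d_true, "seed": seed},
    )


class StejskalTannerModel:
    """Nonlinear least-squares fit of the attenuation model I0·exp(−b·D).

    Initialization comes from the log-linear fit of ln I against b; the
    amplitude I0 absorbs normalization error and is reported alongside D.
    """

    def __init__(self, series: AttenuationSeries):
        self.series = series
        if len(series.signal) < 5:
            raise ValueError("need at least 5 gradient points")
        if np.sum(series.signal > 0) < 3:
            raise ValueError("too few positive intensities to fit an exponential decay")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, acq: PGSTEAcquisition) -> "StejskalTannerModel":
        return cls(AttenuationSeries(acquisition=acq, signal=df["intensity"].to_numpy()))

    def fit(self) -> "StejskalTannerResults":
        b = self.series.acquisition.b_factor(self.series.acquisition.gradients)
        y = self.series.signal
        pos = y > 0
        # log-linear initialization
        slope, intercept = np.polyfit(b[pos], np.log(y[pos]), 1)
        d0 = max(-slope, 1e-16)
        i0 = float(np.exp(intercept))

        def resid(theta):
            log_d, amp = theta
            return amp * np.exp(-np.exp(log_d) * b) - y

        sol = optimize.least_squares(resid, [np.log(d0), i0], xtol=1e-14, ftol=1e-14)
        log_d, amp = sol.x
        d_hat = float(np.exp(log_d))
        n, p = len(y), 2
        s2 = 2.0 * sol.cost / max(n - p, 1)
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * s2
        # delta method: var(D) = D² var(log D)
        d_se = float(d_hat * np.sqrt(max(cov[0, 0], 0.0)))
        return StejskalTannerResults(
            model=self, d=d_hat, d_se=d_se, i0=float(amp),
            i0_se=float(np.sqrt(max(cov[1, 1], 0.0))), n_obs=n,
        )


@dataclass
class StejskalTannerResults:
    """Fitted self-diffusion coefficient (m²/s) from a PGSTE series."""

    model: StejskalTannerModel
    d: float
    d_se: float
    i0: float
    i0_se: float
    n_obs: int

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy import stats

        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return self.d - z * self.d_se, self.d + z * self.d_se

    def predict(self, g) -> np.ndarray:
        return self.i0 * stejskal_tanner(g, self.model.series.acquisition, self.d)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        return "\n".join(
            [
                "Stejskal-Tanner fit:  I = I0 * exp(-b(g) * D)",
                "-" * 58,
                f"n gradients:  {self.n_obs:>6d}",
                f"D [m^2/s]:    {self.d:>12.5g} +/- {self.d_se:.3g}",
                f"95% CI:       [{lo:.5g}, {hi:.5g}]",
                f"I0:           {self.i0:>12.5g} +/- {self.i0_se:.3g}",
            ]
        )


def fit_attenuation(series: AttenuationSeries) -> tuple[float, float]:
    """Fit D (m²/s) and its SE from an attenuation series."""
    res = StejskalTannerModel(series).fit()
    return res.d, res.d_se


def generate_slowdown_table(kind: str, truth: dict, n_points: int = 8,
                            noise_sd: float = 0.0, seed: int = 0) -> SlowdownCurve:
    """Noisy slowdown curves with known ground truth.

    kind="linear_phi": D/D0 = 1 − κ·φ over a φ grid (truth: kappa,
    optionally phi_max).  kind="nanovisc_rh": the nanoviscosity law over
    an R_H grid (truth: NanoviscParams fields, optionally r_h_max).
    The generating parameters are recorded in the curve's `truth`.
    """
    rng = np.random.default_rng(seed)
    if kind == "linear_phi":
        phi_max = truth.get("phi_max", 0.4)
        phi = np.linspace(0.0, phi_max, n_points)
        clean = 1.0 - truth["kappa"] * phi
        curve = SlowdownCurve(
            phi, clean + rng.normal(0.0, noise_sd, n_points),
            sigma=np.full(n_points, noise_sd) if noise_sd > 0 else None,
            abscissa_name="phi_occ",
        )
    elif kind == "nanovisc_rh":
        r_max = truth.get("r_h_max", 13.0)
        r_h = np.geomspace(truth.get("r_h_min", 0.5), r_max, n_points)
        params = truth["params"] if "params" in truth else NanoviscParams(
            a=truth["a"], b=truth["b"], xi=truth["xi"], r_c_eff=truth["r_c_eff"],
            r_min=truth.get("r_min", 0.0),
        )
        clean = d_ratio_nanovisc(r_h, params)
        curve = SlowdownCurve(
            r_h, clean + rng.normal(0.0, noise_sd, n_points),
            sigma=np.full(n_points, noise_sd) if noise_sd > 0 else None,
            abscissa_name="r_h_nm",
        )
    else:
        raise ValueError(f"unknown generator kind {kind!r}")
    curve.truth = dict(truth, noise_sd=noise_sd, seed=seed)
    return curve


def generate_free_walk(d_true: float, n_steps: int = 100_000, dt: float = 1e-4,
                       seed: int = 0, n_particles: int = 1) -> Trajectory:
    """Free Gaussian random walk(s) of known diffusivity (nm²/µs).

    Per-axis step variance is 2·D·dt, so the MSD obeys 6·D·t exactly in
    expectation — the calibration oracle for the MSD/long-time-D chain.
    Positions are unwrapped; a huge notional box is attached so the
    trajectory container stays valid.
    """
    if d_true <= 0 or n_steps < 1 or dt <= 0:
        raise ValueError("d_true, n_steps and dt must be positive")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * d_true * dt), size=(n_steps, n_particles, 3))
    unwrapped = np.concatenate(
        [np.zeros((1, n_particles, 3)), np.cumsum(steps, axis=0)], axis=0
    )
    edge = max(1e6, 100.0 * float(np.abs(unwrapped).max()))
    return Trajectory(
        box_edge=edge,
        labels=np.array(["walker"] * n_particles, dtype=object),
        radii=np.ones(n_particles),
        times=np.arange(n_steps + 1) * dt,
        wrapped=unwrapped % edge,
        unwrapped=unwrapped,
        metadata={"d_true": d_true, "seed": seed, "generator": "free_walk"},
    )
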