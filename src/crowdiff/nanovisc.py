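"""Length-scale-dependent ("nano")viscosity models of crowding slowdown.

A tracer of hydrodynamic radius R_H experiences an effective viscosity
interpolating between the solvent viscosity (tiny tracers slip through
the intercrowder gaps) and the macroscopic viscosity (large tracers drag
the whole medium).  The phenomenological law used here is

    D/D0 = eta_0 / eta(R_H) = exp[-b (R_eff / xi)^a],

where xi is the characteristic intercrowder gap, R_eff an effective
radius interpolating between R_H (small tracers) and the crowder radius
R_c (large tracers), and a, b are order-unity constants.  For hard-sphere
crowders the gap is xi = R_g * psi_rcp * (1 - phi_occ)/phi_occ with
psi_rcp = phi/(1-phi) at random close packing (phi ~= 0.638).

An optional "minimal length" R_min shifts R_eff so it does not vanish
for point tracers; with R_min > 0 and a = 1 the model linearizes, at
small R_H and small phi_occ, to the linear slowdown law with a slope
kappa depending linearly on R_H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .constants import PHI_RCP

__all__ = [
    "NanoviscParams",
    "psi_rcp",
    "xi_hard_sphere",
    "r_eff_standard",
    "r_eff_modified",
    "d_ratio_nanovisc",
    "NanoviscosityModel",
    "NanoviscosityResults",
    "fit_nanovisc",
]


def psi_rcp() -> float:
    """φ/(1−φ) evaluated at random close packing (φ ≈ 0.638) — ≈ 1.76."""
    return PHI_RCP / (1.0 - PHI_RCP)


def xi_hard_sphere(r_g: float, phi_occ: float) -> float:
    """Intercrowder gap of a hard-sphere medium: ξ = R_g·ψ_rcp·(1−φ)/φ (nm)."""
    if not 0.0 < phi_occ < 1.0:
        raise ValueError(f"phi_occ must lie in (0, 1), got {phi_occ}")
    return r_g * psi_rcp() * (1.0 - phi_occ) / phi_occ


def r_eff_standard(r_h, r_c: float, interpolant: str = "quadrature"):
    """Effective radius interpolating between R_H (small) and R_c (large).

    The default quadrature interpolant is R_H·R_c/√(R_H² + R_c²); a
    harmonic-type alternative R_H·R_c/(R_H + R_c) shares both limits.
    The limits — R_eff → R_H for R_H ≪ R_c and → R_c for R_H ≫ R_c —
    are the contract; the interpolant in between is a modelling choice.
    """
    r_h = np.asarray(r_h, dtype=float)
    if r_c <= 0:
        raise ValueError("r_c must be > 0")
    if interpolant == "quadrature":
        out = r_h * r_c / np.sqrt(r_h**2 + r_c**2)
    elif interpolant == "harmonic":
        out = r_h * r_c / (r_h + r_c)
    else:
        raise ValueError(f"unknown interpolant {interpolant!r}")
    return float(out) if out.ndim == 0 else out


def r_eff_modified(r_h, r_c: float, r_min: float = 0.0, interpolant: str = "quadrature"):
    """R_eff with a minimal length: evaluated at R_H + R_min.

    Keeps R_eff > 0 as R_H → 0 so point tracers still feel the medium;
    reduces to :func:`r_eff_standard` when r_min = 0.
    """
    if r_min < 0:
        raise ValueError("r_min must be >= 0")
    return r_eff_standard(np.asarray(r_h, dtype=float) + r_min, r_c, interpolant)


@dataclass
class NanoviscParams:
    """Parameters of the nanoviscosity slowdown model.

    a : stretching exponent (order unity)
    b : prefactor (order unity)
    xi : intercrowder gap, nm
    r_c_eff : effective crowder radius entering R_eff, nm
    r_min : minimal length added to R_H inside R_eff, nm (0 disables)
    r_g : crowder gyration radius used for the hard-sphere ξ, nm
    a_zero, a_switch_width : optional step-like exponent a(R_H) — a is
        `a_zero` for R_H ≪ r_c_eff and the constant `a` for R_H ≫ r_c_eff,
        blended by a logistic in ln R_H of the given width (decades·ln10).
    """

    a: float
    b: float
    xi: float
    r_c_eff: float
    r_min: float = 0.0
    r_g: float | None = None
    interpolant: str = "quadrature"
    a_zero: float | None = None
    a_switch_width: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b < 0 or self.xi <= 0 or self.r_c_eff <= 0 or self.r_min < 0:
            raise ValueError("require a > 0, b >= 0, xi > 0, r_c_eff > 0, r_min >= 0")

    @property
    def psi_rcp(self) -> float:
        return psi_rcp()

    def exponent_at(self, r_h) -> np.ndarray:
        """Effective exponent a(R_H) (constant unless a_zero is set)."""
        r_h = np.asarray(r_h, dtype=float)
        if self.a_zero is None:
            return np.full_like(r_h, self.a)
        with np.errstate(divide="ignore"):
            s = 1.0 / (1.0 + np.exp(-np.log(np.maximum(r_h, 1e-300) / self.r_c_eff)
                                    / self.a_switch_width))
        return self.a_zero + (self.a - self.a_zero) * s


def d_ratio_nanovisc(r_h, params: NanoviscParams):
    """Relative diffusivity D/D0 = exp[−b·(R_eff/ξ)^a] at tracer radius r_h (nm)."""
    r_h = np.asarray(r_h, dtype=float)
    r_eff = r_eff_modified(r_h, params.r_c_eff, params.r_min, params.interpolant)
    a_eff = params.exponent_at(r_h)
    out = np.exp(-params.b * (np.asarray(r_eff) / params.xi) ** a_eff)
    return float(out) if out.ndim == 0 else out


class NanoviscosityModel:
    """Nonlinear least-squares fit of the nanoviscosity law to a
    (R_H, D/D0) curve at a known occupied volume fraction.

    The intercrowder gap is tied to the fitted effective crowder radius
    through the hard-sphere relation (R_g = r_c_eff), so the free
    parameters are (a, b, r_c_eff) — or (b, r_c_eff, r_min) when the
    exponent is held fixed, the mode used when no macroscopic-tracer data
    pin the large-R_H plateau.
    """

    N_STARTS = 8

    def __init__(self, r_h, d_ratio, sigma=None, phi_occ: float = 0.426,
                 interpolant: str = "quadrature"):
        self.r_h = np.asarray(r_h, dtype=float)
        self.d_ratio = np.asarray(d_ratio, dtype=float)
        self.sigma = None if sigma is None else np.asarray(sigma, dtype=float)
        self.phi_occ = float(phi_occ)
        self.interpolant = interpolant
        if len(self.r_h) < 4:
            raise ValueError("need at least 4 (R_H, D/D0) points")
        if np.any(self.d_ratio <= 0):
            raise ValueError("d_ratio values must be positive")
        if not 0.0 < self.phi_occ < 1.0:
            raise ValueError("phi_occ must lie in (0, 1)")

    @classmethod
    def from_dataframe(cls, df, r_col: str = "r_h_nm", d_col: str = "d_ratio",
                       sigma_col: str = "sigma", **kw) -> "NanoviscosityModel":
        sigma = df[sigma_col].to_numpy() if sigma_col in df.columns else None
        return cls(df[r_col].to_numpy(), df[d_col].to_numpy(), sigma, **kw)

    def _params_from(self, theta, fix_a) -> NanoviscParams:
        if fix_a is None:
            a, b, r_c = theta
            r_min = 0.0
        else:
            a = fix_a
            b, r_c, r_min = theta
        return NanoviscParams(
            a=a, b=b, xi=xi_hard_sphere(r_c, self.phi_occ), r_c_eff=r_c,
            r_min=r_min, r_g=r_c, interpolant=self.interpolant,
        )

    def _residuals(self, theta, fix_a):
        pred = d_ratio_nanovisc(self.r_h, self._params_from(theta, fix_a))
        res = pred - self.d_ratio
        if self.sigma is not None:
            res = res / np.where(self.sigma > 0, self.sigma, np.inf)
            res = np.where(np.isfinite(res), res, 0.0)
        return res

    def fit(self, fix_a: float | None = None) -> "NanoviscosityResults":
        """Multi-start trust-region least squares.

        Starts span log-spaced b and r_c_eff (local minima are a known
        hazard of this model); the best converged start wins.
        """
        r_span = max(self.r_h.max(), 1.0)
        b_starts = np.geomspace(0.3, 10.0, self.N_STARTS)
        rc_starts = np.geomspace(0.3 * r_span, 3.0 * r_span, self.N_STARTS)
        if fix_a is None:
            lower = [0.05, 0.0, 1e-3]
            upper = [5.0, 1e3, 1e4]
            thetas = [[0.7, b, rc] for b, rc in zip(b_starts, rc_starts)]
            thetas.append([0.7, 0.0, r_span])  # degenerate flat-curve start
            b_index = 1
        else:
            lower = [0.0, 1e-3, 0.0]
            upper = [1e3, 1e4, 1e2]
            thetas = [[b, rc, 0.1] for b, rc in zip(b_starts, rc_starts)]
            thetas.append([0.0, r_span, 0.0])
            b_index = 0
        best = None
        for theta0 in thetas:
            try:
                sol = optimize.least_squares(
                    self._residuals, theta0, args=(fix_a,), bounds=(lower, upper),
                    xtol=1e-12, ftol=1e-12,
                )
            except Exception:
                continue
            if not sol.success:
                continue
            if best is None or sol.cost < best.cost * (1.0 - 1e-9) - 1e-30:
                best = sol
            elif sol.cost <= best.cost * (1.0 + 1e-9) + 1e-30 and (
                sol.x[b_index] < best.x[b_index]
            ):
                # cost tie (flat/degenerate data): prefer the smaller prefactor
                best = sol
        if best is None:
            raise RuntimeError("nanoviscosity fit failed to converge from any start")
        theta = best.x
        n, p = len(self.r_h), len(theta)
        dof = max(n - p, 1)
        s2 = 2.0 * best.cost / dof
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        params = self._params_from(theta, fix_a)
        if fix_a is None:
            se_map = {"a": se[0], "b": se[1], "r_c_eff": se[2]}
        else:
            se_map = {"a": 0.0, "b": se[0], "r_c_eff": se[1], "r_min": se[2]}
        return NanoviscosityResults(
            model=self, params=params, bse=se_map,
            residual_norm=float(np.sqrt(2.0 * best.cost)),
            cost=float(best.cost), fixed_a=fix_a, n_obs=n,
        )


@dataclass
class NanoviscosityResults:
    """Fitted nanoviscosity parameters, their standard errors, diagnostics."""

    model: NanoviscosityModel
    params: NanoviscParams
    bse: dict
    residual_norm: float
    cost: float
    fixed_a: float | None
    n_obs: int

    def predict(self, r_h) -> np.ndarray:
        return d_ratio_nanovisc(r_h, self.params)

    def conf_int(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        from scipy import stats

        z = stats.norm.ppf(1.0 - alpha / 2.0)
        val = getattr(self.params, name)
        return val - z * self.bse[name], val + z * self.bse[name]

    def to_dict(self) -> dict:
        return {
            "a": self.params.a, "b": self.params.b, "r_c_eff": self.params.r_c_eff,
            "r_min": self.params.r_min, "xi": self.params.xi,
            "bse": {k: float(v) for k, v in self.bse.items()},
            "residual_norm": self.residual_norm, "fixed_a": self.fixed_a,
        }

    def summary(self) -> str:
        lines = [
            "Nanoviscosity fit:  D/D0 = exp[-b (R_eff/xi)^a]",
            "-" * 58,
            f"n points:       {self.n_obs:>6d}    phi_occ: {self.model.phi_occ:.3f}",
            f"a:              {self.params.a:>10.4f}"
            + ("  (fixed)" if self.fixed_a is not None else f" +/- {self.bse['a']:.4f}"),
            f"b:              {self.params.b:>10.4f} +/- {self.bse['b']:.4f}",
            f"r_c_eff [nm]:   {self.params.r_c_eff:>10.4f} +/- {self.bse['r_c_eff']:.4f}",
        ]
        if self.fixed_a is not None:
            lines.append(f"r_min [nm]:     {self.params.r_min:>10.4f} +/- {self.bse['r_min']:.4f}")
        lines += [
            f"xi [nm]:        {self.params.xi:>10.4f}  (hard-sphere gap at phi_occ)",
            f"residual norm:  {self.residual_norm:>10.4g}",
        ]
        return "\n".join(lines)


def fit_nanovisc(curve, fix_a: float | None = None, phi_occ: float = 0.426,
                 interpolant: str = "quadrature") -> NanoviscosityResults:
    """Fit the nanoviscosity law to a SlowdownCurve over R_H."""
    return NanoviscosityModel(
        curve.abscissa, curve.d_ratio, curve.sigma, phi_occ=phi_occ,
        interpolant=interpolant,
    ).fit(fix_a=fix_a)
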