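"""Nanoviscosity law: ξ, R_eff interpolants, model limits, fit recovery."""

import numpy as np
import pytest

from crowdiff.analysis import SlowdownCurve
from crowdiff.nanovisc import (
    NanoviscosityModel,
    NanoviscParams,
    d_ratio_nanovisc,
    fit_nanovisc,
    psi_rcp,
    r_eff_modified,
    r_eff_standard,
    xi_hard_sphere,
)
from crowdiff.pgste import generate_slowdown_table


def _params(a=0.67, b=3.7, r_c=12.1, phi=0.426, r_min=0.0, **kw):
    return NanoviscParams(a=a, b=b, xi=xi_hard_sphere(r_c, phi), r_c_eff=r_c,
                          r_min=r_min, r_g=r_c, **kw)


class TestPsiAndXi:
    def test_psi_rcp_value(self):
        assert round(psi_rcp(), 2) == 1.76

    def test_psi_is_phi_over_one_minus_phi_at_rcp(self):
        assert psi_rcp() == pytest.approx(0.638 / (1 - 0.638), rel=1e-15)

    def test_phi_map_sanity_at_half(self):
        phi = 0.5
        assert phi / (1 - phi) == pytest.approx(1.0)

    def test_xi_equals_rg_at_random_close_packing(self):
        assert xi_hard_sphere(5.1, 0.638) == pytest.approx(5.1, rel=1e-12)

    def test_xi_hand_value_at_cytoplasm_phi(self):
        assert xi_hard_sphere(5.1, 0.426) == pytest.approx(12.11, abs=0.02)

    def test_xi_decreasing_in_phi(self):
        phis = np.linspace(0.05, 0.95, 30)
        vals = [xi_hard_sphere(5.1, p) for p in phis]
        assert np.all(np.diff(vals) < 0)

    def test_xi_domain(self):
        with pytest.raises(ValueError):
            xi_hard_sphere(5.1, 1.0)


class TestEffectiveRadius:
    def test_large_tracer_limit_is_crowder_radius(self):
        assert r_eff_standard(510.0, 5.1) == pytest.approx(5.1, rel=1e-4)

    def test_small_tracer_limit_is_tracer_radius(self):
        r_h = 0.01 * 5.1
        assert r_eff_standard(r_h, 5.1) == pytest.approx(r_h, rel=1e-4)

    def test_self_size_value(self):
        assert r_eff_standard(5.1, 5.1) == pytest.approx(5.1 / np.sqrt(2), rel=1e-12)

    def test_harmonic_interpolant_shares_limits(self):
        assert r_eff_standard(510.0, 5.1, "harmonic") == pytest.approx(5.1, rel=1e-2)
        assert r_eff_standard(0.051, 5.1, "harmonic") == pytest.approx(0.051, rel=1e-2)

    def test_modified_reduces_to_standard_at_zero_rmin(self):
        rr = np.linspace(0.1, 20, 25)
        assert r_eff_modified(rr, 5.1, 0.0) == pytest.approx(r_eff_standard(rr, 5.1))

    def test_modified_nonvanishing_at_zero_radius(self):
        assert r_eff_modified(0.0, 5.1, 0.4) == pytest.approx(r_eff_standard(0.4, 5.1))
        assert r_eff_modified(0.0, 5.1, 0.4) > 0

    def test_modified_derivative_finite_positive_at_origin(self):
        h = 1e-6
        slope = (r_eff_modified(h, 5.1, 0.4) - r_eff_modified(0.0, 5.1, 0.4)) / h
        assert 0 < slope < 2.0


class TestDRatioModel:
    def test_zero_b_gives_unity(self):
        p = _params(b=0.0)
        assert d_ratio_nanovisc(3.0, p) == 1.0

    def test_point_tracer_limit_is_unity(self):
        p = _params(r_min=0.0)
        assert d_ratio_nanovisc(1e-9, p) == pytest.approx(1.0, abs=1e-6)

    def test_small_argument_matches_linear_expansion(self):
        # at b(R_eff/ξ)^a = 1e-2 the Taylor remainder is below 1e-4
        p = _params(a=1.0, b=1.0)
        r_h = 1e-2 * p.xi * 1.0001  # R_eff ≈ R_H here
        x = p.b * (r_eff_modified(r_h, p.r_c_eff, 0.0) / p.xi) ** p.a
        assert abs(d_ratio_nanovisc(r_h, p) - (1 - x)) < 1e-4

    def test_strictly_decreasing_in_radius_and_phi(self):
        rr = np.linspace(0.1, 30, 40)
        vals = d_ratio_nanovisc(rr, _params())
        assert np.all(np.diff(vals) < 0)
        phis = np.linspace(0.05, 0.6, 20)
        at_fixed_r = [d_ratio_nanovisc(3.0, _params(phi=p)) for p in phis]
        assert np.all(np.diff(at_fixed_r) < 0)

    def test_rmin_extension_linearizes_to_kappa_linear_in_rh(self):
        """With r_min > 0 and a = 1: κ(R_H) = −∂(D/D0)/∂φ|₀ is linear in R_H."""
        r_min, r_c = 0.4, 5.1
        dphi = 1e-5

        def kappa(r_h):
            lo = d_ratio_nanovisc(r_h, _params(a=1.0, b=1.0, r_c=r_c, phi=dphi, r_min=r_min))
            return (1.0 - lo) / dphi

        rr = np.array([1e-4, 0.05, 0.1, 0.15, 0.2])
        ks = np.array([kappa(r) for r in rr])
        assert ks[0] > 0  # point tracer still slowed (the stated purpose of r_min)
        slopes = np.diff(ks) / np.diff(rr)
        assert np.all(slopes > 0)
        assert np.ptp(slopes) / slopes.mean() < 0.05  # linear to 5% over small R_H


class TestFit:
    def test_noiseless_recovery_within_one_percent(self):
        rr = np.geomspace(0.5, 13.0, 10)
        d = d_ratio_nanovisc(rr, _params(a=0.67, b=3.7, r_c=12.1))
        res = NanoviscosityModel(rr, d, phi_occ=0.426).fit()
        assert res.params.a == pytest.approx(0.67, rel=0.01)
        assert res.params.b == pytest.approx(3.7, rel=0.01)
        assert res.params.r_c_eff == pytest.approx(12.1, rel=0.01)

    def test_noisy_recovery_calibrated(self):
        """Mean b̂ over 100 noisy replicates within 2 SE of truth; CI coverage sane."""
        truth = dict(a=0.67, b=3.7, r_c_eff=12.1, xi=xi_hard_sphere(12.1, 0.426))
        hats, ses, cover = [], [], []
        for seed in range(100):
            curve = generate_slowdown_table(
                "nanovisc_rh", dict(truth, r_h_min=0.5, r_h_max=13.0),
                n_points=10, noise_sd=0.01, seed=seed,
            )
            res = NanoviscosityModel(curve.abscissa, curve.d_ratio, curve.sigma,
                                     phi_occ=0.426).fit()
            hats.append(res.params.b)
            ses.append(res.bse["b"])
            lo, hi = res.conf_int("b")
            cover.append(lo <= 3.7 <= hi)
        hats = np.asarray(hats)
        assert abs(hats.mean() - 3.7) < 2 * hats.std(ddof=1) / np.sqrt(len(hats))
        assert 0.90 <= np.mean(cover) <= 0.99

    def test_flat_curve_drives_b_to_zero(self):
        rr = np.geomspace(0.5, 13.0, 8)
        res = NanoviscosityModel(rr, np.ones_like(rr), phi_occ=0.426).fit()
        assert res.params.b == pytest.approx(0.0, abs=1e-6)

    def test_fixed_a_mode_fits_rmin(self):
        truth = _params(a=1.0, b=2.0, r_c=8.0, r_min=0.5)
        rr = np.geomspace(0.2, 20.0, 12)
        d = d_ratio_nanovisc(rr, truth)
        res = fit_nanovisc(SlowdownCurve(rr, d, abscissa_name="r_h_nm"),
                           fix_a=1.0, phi_occ=0.426)
        assert res.params.a == 1.0
        assert res.params.b == pytest.approx(2.0, rel=0.05)
        assert res.params.r_min == pytest.approx(0.5, abs=0.1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            NanoviscosityModel([1, 2, 3], [0.9, 0.8, 0.7])

    def test_summary_reports_parameters(self):
        rr = np.geomspace(0.5, 13.0, 8)
        d = d_ratio_nanovisc(rr, _params())
        text = NanoviscosityModel(rr, d, phi_occ=0.426).fit().summary()
        assert "b:" in text and "r_c_eff" in text
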