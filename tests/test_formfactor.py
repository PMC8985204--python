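"""Core-shell sphere forward model: kernel, limits, polydispersity, S(q)."""

import numpy as np
import pytest
from scipy.stats import truncnorm

import sascontrast as sc
from sascontrast.formfactor import (
    CoreShellParams,
    core_shell_intensity,
    guinier_fit,
    hs_structure_factor,
    polydisperse_intensity,
    sphere_kernel,
    sphere_volume,
)

Q = np.logspace(np.log10(0.003), np.log10(0.2), 80)

BASE = CoreShellParams(
    core_radius=200.0, shell_thickness=15.0, sld_core=0.15, sld_shell=3.24,
    sld_solvent=6.35, volume_fraction=0.009, polydispersity=0.0,
    background=0.0,
)


class TestSphereKernel:
    def test_forward_limit_and_series_continuity(self):
        assert sphere_kernel(0.0) == 1.0
        # series/closed-form join is smooth at the switch point
        assert sphere_kernel(0.02 - 1e-9) == pytest.approx(
            sphere_kernel(0.02 + 1e-9), rel=1e-10
        )

    def test_first_root(self):
        # first root of tan x = x
        assert abs(sphere_kernel(4.4934)) < 1e-4

    def test_value_at_pi(self):
        assert sphere_kernel(np.pi) == pytest.approx(3.0 / np.pi**2, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sphere_kernel(-0.1)


class TestCoreShellIntensity:
    def test_equal_sld_collapses_to_sphere_of_total_radius(self):
        p = BASE.with_(sld_shell=BASE.sld_core)
        sphere = CoreShellParams(
            core_radius=BASE.total_radius, shell_thickness=0.0,
            sld_core=BASE.sld_core, sld_shell=BASE.sld_core,
            sld_solvent=BASE.sld_solvent, volume_fraction=BASE.volume_fraction,
        )
        np.testing.assert_allclose(
            core_shell_intensity(Q, p), core_shell_intensity(Q, sphere),
            rtol=1e-13,
        )

    def test_zero_shell_collapses_to_core_sphere(self):
        p = BASE.with_(shell_thickness=0.0)
        sphere = p.with_(sld_shell=p.sld_core)
        np.testing.assert_allclose(
            core_shell_intensity(Q, p), core_shell_intensity(Q, sphere),
            rtol=1e-13,
        )

    def test_forward_limit_closed_form(self):
        q0 = np.array([1e-8])
        v_t = sphere_volume(BASE.total_radius)
        v_c = sphere_volume(BASE.core_radius)
        f0 = v_t * (BASE.sld_shell - BASE.sld_solvent) + v_c * (
            BASE.sld_core - BASE.sld_shell
        )
        expected = 1e-4 * BASE.volume_fraction / v_t * f0**2
        assert core_shell_intensity(q0, BASE)[0] == pytest.approx(
            expected, rel=1e-9
        )

    def test_scale_linearity_in_volume_fraction(self):
        i1 = core_shell_intensity(Q, BASE.with_(background=0.1))
        i2 = core_shell_intensity(
            Q, BASE.with_(volume_fraction=2 * BASE.volume_fraction,
                          background=0.1)
        )
        np.testing.assert_allclose(i2 - 0.1, 2 * (i1 - 0.1), rtol=1e-12)

    def test_contrast_square_law(self):
        c = 3.0
        scaled = BASE.with_(
            sld_core=c * (BASE.sld_core - BASE.sld_solvent),
            sld_shell=c * (BASE.sld_shell - BASE.sld_solvent),
            sld_solvent=0.0,
        )
        np.testing.assert_allclose(
            core_shell_intensity(Q, scaled),
            c**2 * core_shell_intensity(Q, BASE),
            rtol=1e-12,
        )

    def test_zero_contrast_gives_background_exactly(self):
        p = BASE.with_(sld_core=2.0, sld_shell=2.0, sld_solvent=2.0,
                       background=0.37)
        np.testing.assert_array_equal(core_shell_intensity(Q, p),
                                      np.full_like(Q, 0.37))

    def test_nonnegative_and_q_validation(self):
        assert np.all(core_shell_intensity(Q, BASE) >= 0)
        with pytest.raises(ValueError):
            core_shell_intensity(np.array([-0.01, 0.01]), BASE)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            BASE.with_(core_radius=-1.0)
        with pytest.raises(ValueError):
            BASE.with_(volume_fraction=0.9)
        with pytest.raises(ValueError):
            BASE.with_(polydispersity=1.2)


class TestPolydispersity:
    def test_zero_pd_matches_monodisperse(self):
        np.testing.assert_allclose(
            polydisperse_intensity(Q, BASE, 35),
            core_shell_intensity(Q, BASE), rtol=1e-12,
        )

    def test_quadrature_matches_stratified_monte_carlo(self):
        """35-node Gauss average vs a 1e5-sample MC over the same truncated
        Gaussian radius distribution: agreement within 0.5% at q <= 0.2."""
        p = BASE.with_(polydispersity=0.2)
        n = 100_000
        rng = np.random.default_rng(2024)
        u = (np.arange(n) + rng.uniform(size=n)) / n  # stratified uniforms
        a, b = -3.0, 3.0  # +-3 sigma truncation, mean - 3 sigma > 0 here
        r = truncnorm.ppf(u, a, b, loc=p.core_radius,
                          scale=p.polydispersity * p.core_radius)
        from sascontrast.formfactor import core_shell_amplitude

        f = core_shell_amplitude(
            Q[:, None], r[None, :], p.shell_thickness, p.sld_core,
            p.sld_shell, p.sld_solvent,
        )
        i_mc = (
            1e-4 * p.volume_fraction * (f**2).mean(axis=1)
            / sphere_volume(r + p.shell_thickness).mean()
        )
        i_quad = polydisperse_intensity(Q, p, 35)
        assert np.abs(i_quad / i_mc - 1).max() < 0.005

    def test_polydispersity_fills_first_minimum(self):
        """Increasing pd fills the first form-factor minimum: the ratio of
        the first local-minimum intensity to the following local-maximum
        intensity increases strictly with pd."""
        qs = np.linspace(0.005, 0.06, 2000)
        ratios = []
        for pd in (0.02, 0.05, 0.1, 0.15):
            i = polydisperse_intensity(qs, BASE.with_(polydispersity=pd), 51)
            interior = (i[1:-1] < i[:-2]) & (i[1:-1] < i[2:])
            i_min = 1 + np.flatnonzero(interior)[0]
            maxima = (i[1:-1] > i[:-2]) & (i[1:-1] > i[2:])
            i_max = 1 + np.flatnonzero(maxima[i_min:])[0] + i_min
            ratios.append(i[i_min] / i[i_max])
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_node_count_contract(self):
        with pytest.raises(ValueError):
            polydisperse_intensity(Q, BASE.with_(polydispersity=0.2), 10)


class TestHardSphereStructureFactor:
    def test_zero_fraction_is_unity(self):
        np.testing.assert_array_equal(hs_structure_factor(Q, 215.0, 0.0),
                                      np.ones_like(Q))

    def test_compressibility_limit(self):
        phi = 0.092
        expected = (1 - phi) ** 4 / (1 + 2 * phi) ** 2
        s0 = hs_structure_factor(np.array([1e-10]), 215.0, phi)[0]
        assert s0 == pytest.approx(expected, abs=1e-10)

    def test_dilute_limit_justifies_unity(self):
        # at the dilute volume fraction S deviates from 1 by < 6% at the
        # lowest measured q and < 1% over the bulk of the window,
        # justifying the default S = 1 treatment
        q = np.logspace(np.log10(0.003), np.log10(0.7), 500)
        s = hs_structure_factor(q, 215.0, 0.009)
        assert np.abs(s - 1).max() < 0.06
        assert np.abs(s[q >= 0.01] - 1).max() < 0.01

    def test_series_branch_continuity(self):
        r_eff = 215.0
        q_lo = 0.1 / (2 * r_eff) * 0.999
        q_hi = 0.1 / (2 * r_eff) * 1.001
        s = hs_structure_factor(np.array([q_lo, q_hi]), r_eff, 0.2)
        assert s[0] == pytest.approx(s[1], rel=1e-4)

    def test_overpacked_rejected(self):
        with pytest.raises(ValueError):
            hs_structure_factor(Q, 215.0, 0.55)


class TestGuinier:
    def test_sphere_rg_within_1pct(self, sphere_curve):
        radius, q, i, sigma = sphere_curve
        rg, i0 = guinier_fit(q, i, sigma)
        assert rg == pytest.approx(np.sqrt(3 / 5) * radius, rel=0.01)
        p = sc.CoreShellParams(
            core_radius=radius, shell_thickness=0.0, sld_core=1.0,
            sld_shell=1.0, sld_solvent=0.0, volume_fraction=0.01,
        )
        i_zero = core_shell_intensity(np.array([1e-8]), p)[0]
        assert i0 == pytest.approx(i_zero, rel=0.01)

    def test_core_shell_rg_matches_contrast_weighted_moment(self):
        """Rg^2 = int dr r^4 drho(r) / int dr r^2 drho(r) for the radial
        contrast profile, evaluated by quadrature as an independent oracle."""
        p = BASE
        r = np.linspace(0, p.total_radius, 20001)
        drho = np.where(
            r <= p.core_radius, p.sld_core - p.sld_solvent,
            p.sld_shell - p.sld_solvent,
        )
        rg_true = np.sqrt(
            np.trapezoid(drho * r**4, r) / np.trapezoid(drho * r**2, r)
        )
        q = np.logspace(np.log10(2e-4), np.log10(0.02), 200)
        i = core_shell_intensity(q, p)
        rg, _ = guinier_fit(q, i)
        assert rg == pytest.approx(rg_true, rel=0.01)

    def test_flat_curve_rejected(self):
        q = np.linspace(1e-3, 1e-2, 50)
        with pytest.raises(ValueError):
            guinier_fit(q, np.ones_like(q))

    def test_too_few_points_rejected(self):
        q = np.array([0.001, 0.002, 0.003, 0.004])
        with pytest.raises(ValueError):
            guinier_fit(q, np.exp(-(q**2) * 100**2 / 3))
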