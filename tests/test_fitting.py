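"""Simultaneous multi-contrast fitting: SLD resolution, recovery, batteries."""

import numpy as np
import pytest

import sascontrast as sc
from sascontrast import composition
from sascontrast.fitting import (
    _ModelCache,
    _residuals,
    _unpack,
    build_problem,
    resolve_contrast,
)
from sascontrast.synthetic import StructuralTruth

TRUTH = {
    "core_radius": 200.0,
    "shell_thickness": 15.0,
    "polydispersity": 0.20,
    "hydration": 0.50,
    "volume_fraction": 0.009,
}


class TestBuildProblem:
    def test_four_contrast_fixed_slds(self, unloaded_scenario):
        problem = build_problem(sc.simulate_scenario(unloaded_scenario))
        cores = sorted({ds.sld_core for ds in problem.datasets})
        solvents = sorted({ds.sld_solvent for ds in problem.datasets})
        # computed values track the conventional table values
        assert cores[0] == pytest.approx(0.15, rel=0.05)
        assert cores[1] == pytest.approx(0.45, rel=0.05)
        assert solvents[0] == pytest.approx(-0.56, rel=0.02)
        assert solvents[1] == pytest.approx(6.35, rel=0.02)
        assert problem.dry_shell_sld == 0.13

    def test_single_dataset_is_valid(self, unloaded_scenario):
        ds = sc.simulate_dataset(unloaded_scenario, 0)
        problem = build_problem([ds])
        assert len(problem.datasets) == 1

    def test_unknown_contrast_rejected(self, unloaded_scenario):
        ds = sc.simulate_dataset(unloaded_scenario, 0)
        bare = ds.replace(sld_core=0.0, sld_solvent=0.0,
                          contrast_label="xLNC/D2O")
        with pytest.raises(ValueError, match="core kind"):
            build_problem([bare])
        with pytest.raises(ValueError, match="label"):
            build_problem([ds.replace(sld_core=0.0, sld_solvent=0.0,
                                      contrast_label="")])

    def test_resolve_contrast_labels(self):
        core, solv = resolve_contrast("hLNC/H2O")
        assert core == pytest.approx(composition.sld(composition.LABRAFAC))
        assert solv == pytest.approx(composition.sld(composition.WATER))
        _, mixed = resolve_contrast("dLNC/f=0.5")
        assert mixed == pytest.approx(composition.solvent_sld(0.5))

    def test_every_shared_param_must_be_free_or_fixed(self, unloaded_scenario):
        ds = sc.simulate_dataset(unloaded_scenario, 0)
        with pytest.raises(ValueError, match="neither free nor fixed"):
            build_problem([ds], shared_free=("core_radius",))


class TestModelFastPath:
    def test_matches_reference_route(self, unloaded_scenario):
        """The shared-kernel evaluation used inside fit() reproduces the
        explicit form-factor -> smear pipeline to machine precision."""
        problem = build_problem(sc.simulate_scenario(unloaded_scenario))
        x = np.array([210.0, 18.0, 0.22, 0.4, 0.011, 0.8, 0.04, 1.1, 0.06])
        ref = _residuals(problem, x)
        fast = _residuals(problem, x, _ModelCache(problem))
        np.testing.assert_allclose(fast, ref, rtol=1e-10, atol=1e-12)


class TestFit:
    def test_noise_free_self_consistency(self, unloaded_scenario):
        scen = unloaded_scenario.with_(noise_pct=0.0)
        problem = build_problem(sc.simulate_scenario(scen))
        result = sc.fit(problem, seed=1, n_starts=2)
        assert result.chi2_reduced < 1e-6
        for name, true in TRUTH.items():
            assert result.estimates[name] == pytest.approx(true, rel=1e-3)

    def test_noisy_estimates_inside_confidence_intervals(self, unloaded_fit):
        result, _ = unloaded_fit
        assert result.success
        assert 0.5 < result.chi2_reduced < 2.0
        for name, true in TRUTH.items():
            err = abs(result.estimates[name] - true)
            assert err < 2.0 * result.uncertainties[name], name
        # the well-conditioned parameters are recovered tightly
        for name in ("core_radius", "polydispersity", "volume_fraction"):
            assert result.estimates[name] == pytest.approx(TRUTH[name], rel=0.05)

    def test_matched_core_inflates_core_radius_ci(self, unloaded_fit,
                                                  unloaded_scenario):
        """With the core contrast-matched, the remaining signal barely
        constrains the core radius: its CI blows up versus the 4-contrast
        joint fit."""
        result4, _ = unloaded_fit
        scen = sc.reference_scenarios(seed=1)["matched_core"]
        problem = build_problem(sc.simulate_scenario(scen))
        result1 = sc.fit(problem, seed=1, max_nfev=150)
        ratio = result1.uncertainties["core_radius"] / \
            result4.uncertainties["core_radius"]
        assert ratio > 3.0

    def test_adding_zero_contrast_dataset_changes_nothing(self,
                                                          unloaded_scenario):
        scen = unloaded_scenario.with_(noise_pct=0.0)
        ds = sc.simulate_dataset(scen, 1)  # hLNC/D2O, noise-free
        null = ds.replace(
            sld_core=0.13, sld_solvent=0.13,
            i=np.full(len(ds), 0.05), sigma_i=np.full(len(ds), 0.01),
            contrast_label="null",
        )
        free = ("core_radius", "volume_fraction")
        fixed = {k: v for k, v in TRUTH.items() if k not in free}
        a = sc.fit(build_problem([ds], shared_free=free, fixed=fixed),
                   seed=3, n_starts=2)
        b = sc.fit(build_problem([ds, null], shared_free=free, fixed=fixed),
                   seed=3, n_starts=2)
        for name in free:
            assert b.estimates[name] == pytest.approx(
                a.estimates[name], rel=1e-4
            )


class TestDerivedQuantities:
    def test_total_radius_is_exact_sum_with_propagated_error(self,
                                                             unloaded_fit):
        result, problem = unloaded_fit
        d = result.derived
        assert d["total_radius"] == result.estimates["core_radius"] + \
            result.estimates["shell_thickness"]
        i = result.param_names.index("core_radius")
        j = result.param_names.index("shell_thickness")
        expected = np.sqrt(
            result.covariance[i, i] + result.covariance[j, j]
            + 2 * result.covariance[i, j]
        )
        assert d["total_radius_err"] == pytest.approx(expected)
        # correlated parameters: the propagated error differs from the
        # independent-error quadrature sum
        independent = np.hypot(result.uncertainties["core_radius"],
                               result.uncertainties["shell_thickness"])
        assert d["total_radius_err"] != pytest.approx(independent, rel=1e-3)

    def test_shell_sld_lies_between_dry_and_solvent(self, unloaded_fit):
        result, problem = unloaded_fit
        for label, value in result.derived["shell_sld_per_contrast"].items():
            if "D2O" in label:
                assert problem.dry_shell_sld < value < 6.4

    def test_theoretical_volume_fraction_from_concentration(self,
                                                            unloaded_scenario):
        ds = sc.simulate_dataset(unloaded_scenario, 1)
        ds = ds.replace(concentration_mg_ml=62.0)
        problem = build_problem([ds])
        # derived from concentration alone; no fit needed
        from sascontrast.fitting import derived_quantities, FitResult

        fake = FitResult(
            estimates={n: TRUTH[n] for n in TRUTH},
            uncertainties={n: 0.0 for n in TRUTH},
            covariance=np.zeros((5, 5)),
            param_names=list(TRUTH),
            chi2_reduced=1.0, per_dataset_chi2=[1.0], n_points=len(ds),
        )
        d = derived_quantities(fake, problem, particle_density=1.0)
        assert d["theoretical_volume_fraction"] == pytest.approx(0.062)


class TestScenarioBattery:
    def _problem(self, truth, seed, label_seed):
        scen = sc.Scenario(
            "t", truth, (("h", 1.0),), sc.make_q_grid("sans"),
            noise_pct=3.0, concentration_mg_ml=6.2, seed=label_seed,
        )
        free = ("core_radius", "polydispersity", "volume_fraction")
        fixed = {"shell_thickness": truth.shell_thickness,
                 "hydration": truth.hydration}
        return build_problem(sc.simulate_scenario(scen), shared_free=free,
                             fixed=fixed)

    def test_duplicated_problem_is_deterministic(self):
        truth = StructuralTruth(200.0, 15.0, 0.2, 0.5, 0.009)
        p = self._problem(truth, 0, 11)
        report = sc.scenario_battery([p, p], seed=5, n_starts=2)
        a, b = report.results
        assert a.estimates == b.estimates
        assert report.all_consistent

    def test_shifted_truth_is_flagged(self):
        base = StructuralTruth(200.0, 15.0, 0.2, 0.5, 0.009)
        shifted = StructuralTruth(240.0, 15.0, 0.2, 0.5, 0.009)
        report = sc.scenario_battery(
            [self._problem(base, 0, 11), self._problem(shifted, 0, 12)],
            seed=5, n_starts=2,
        )
        assert not report.param_consistent["core_radius"]
        assert not report.all_consistent

    def test_incompatible_free_sets_rejected(self, unloaded_scenario):
        ds = sc.simulate_dataset(unloaded_scenario, 1)
        p1 = build_problem([ds])
        p2 = build_problem([ds], shared_free=("core_radius",),
                           fixed={k: v for k, v in TRUTH.items()
                                  if k != "core_radius"})
        with pytest.raises(ValueError, match="incompatible"):
            sc.scenario_battery([p1, p2], seed=0)

    def test_needs_two_problems(self, unloaded_scenario):
        p = build_problem([sc.simulate_dataset(unloaded_scenario, 1)])
        with pytest.raises(ValueError):
            sc.scenario_battery([p], seed=0)
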