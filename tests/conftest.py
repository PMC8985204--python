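import numpy as np
import pytest

import sascontrast as sc


@pytest.fixture(scope="session")
def sphere_curve():
    """Noise-free homogeneous sphere curve, R = 243 Å, absolute scale."""
    radius = 243.0
    q = np.logspace(np.log10(0.002), np.log10(0.15), 180)
    p = sc.CoreShellParams(
        core_radius=radius, shell_thickness=0.0, sld_core=1.0, sld_shell=1.0,
        sld_solvent=0.0, volume_fraction=0.01,
    )
    i = sc.core_shell_intensity(q, p)
    sigma = 0.01 * np.abs(i) + 1e-4 * i[0]
    return radius, q, i, sigma


@pytest.fixture(scope="session")
def sphere_dataset(sphere_curve):
    radius, q, i, sigma = sphere_curve
    return radius, sc.SASDataset(q=q, i=i, sigma_i=sigma)


@pytest.fixture(scope="session")
def unloaded_scenario():
    return sc.reference_scenarios(seed=1)["unloaded"]


@pytest.fixture(scope="session")
def unloaded_fit(unloaded_scenario):
    """One joint 4-contrast fit of the unloaded scenario at 3% noise."""
    problem = sc.build_problem(sc.simulate_scenario(unloaded_scenario))
    return sc.fit(problem, seed=1), problem
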