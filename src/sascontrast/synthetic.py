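"""Synthetic contrast-series scattering data.

Emulates the measurement design the analysis targets: lipid nanocapsules
(triglyceride oil core, hydrated PEG-surfactant shell) measured by SAXS at
high concentration and by SANS in four core/solvent contrasts (protiated or
partly deuterated oil in H2O or D2O), with TOF-SANS fractional Q-resolution
and counting-statistics-like noise.  Every dataset is generated from an
explicit structural truth through the same forward model the fits use, so
parameter-recovery tests exercise the full pipeline.

Noise is multiplicative Gaussian: sigma(Q) = (noise_pct/100) I(Q) plus a
small floor (1e-4 of the lowest-Q intensity) so the sigma column never
vanishes; the recorded sigma column is the true noise scale.  Incoherent
background is emulated as a flat term interpolating between typical H2O
(1.0 cm^-1) and D2O (0.05 cm^-1) levels for SANS, 0.01 cm^-1 for SAXS.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from . import composition
from .dataset import SASDataset
from .formfactor import CoreShellParams, Instrument, polydisperse_intensity
from .resolution import ResolutionKernel, smear

__all__ = [
    "StructuralTruth",
    "Scenario",
    "make_q_grid",
    "simulate_dataset",
    "simulate_scenario",
    "reference_scenarios",
]

SANS_BACKGROUND_H2O = 1.0   # cm^-1, typical incoherent level of light water
SANS_BACKGROUND_D2O = 0.05  # cm^-1
SAXS_BACKGROUND = 0.01      # cm^-1
SIGMA_FLOOR_FRACTION = 1e-4


@dataclass(frozen=True)
class StructuralTruth:
    """Ground-truth structure of a scenario (lengths in Å)."""

    core_radius: float
    shell_thickness: float
    polydispersity: float
    hydration: float
    volume_fraction: float


@dataclass(frozen=True)
class Scenario:
    """One simulated measurement campaign: a truth plus its contrasts."""

    name: str
    truth: StructuralTruth
    contrasts: tuple[tuple[str, float], ...]  # (core_kind 'h'|'d', f_d2o)
    instrument: Instrument
    noise_pct: float = 3.0
    concentration_mg_ml: float = 6.2
    temperature_c: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_pct < 0:
            raise ValueError("noise_pct must be >= 0")
        if not self.contrasts:
            raise ValueError("scenario needs at least one contrast")

    def with_(self, **kwargs) -> "Scenario":
        return replace(self, **kwargs)


def make_q_grid(kind: Literal["saxs", "sans"]) -> Instrument:
    """Standard instrument configurations.

    SAXS: 200 log-spaced points, 0.0076-3 Å^-1, point collimation (no
    smearing).  SANS: 120 log-spaced points, 0.003-0.7 Å^-1 with constant
    fractional resolution dQ/Q = 0.08 (TOF pinhole geometry).
    """
    if kind == "saxs":
        q = np.logspace(np.log10(0.0076), np.log10(3.0), 200)
        return Instrument("xray", 1.541, q, np.zeros_like(q))
    if kind == "sans":
        q = np.logspace(np.log10(0.003), np.log10(0.7), 120)
        return Instrument("neutron", 6.0, q, 0.08 * q)
    raise ValueError(f"unknown instrument kind {kind!r}")


def _contrast_slds(core_kind: str, f_d2o: float, radiation: str
                   ) -> tuple[float, float, float, str]:
    """(sld_core, sld_solvent, dry_shell_sld, label) for one contrast."""
    if radiation == "xray":
        return (
            composition.sld(composition.LABRAFAC, "xray"),
            composition.sld(composition.WATER, "xray"),
            composition.sld(composition.KOLLIPHOR_HS15, "xray"),
            f"{core_kind}LNC/H2O",
        )
    if core_kind == "h":
        core = composition.sld(composition.LABRAFAC)
    elif core_kind == "d":
        core = composition.labrafac_d_blend().sld()
    else:
        raise ValueError(f"core_kind must be 'h' or 'd', got {core_kind!r}")
    solvent = composition.solvent_sld(f_d2o)
    if f_d2o == 0.0:
        solvent_name = "H2O"
    elif f_d2o == 1.0:
        solvent_name = "D2O"
    else:
        solvent_name = f"f={f_d2o:.3f}"
    return core, solvent, 0.13, f"{core_kind}LNC/{solvent_name}"


def _true_curve(scenario: Scenario, contrast_index: int
                ) -> tuple[np.ndarray, float, float, float, str]:
    core_kind, f_d2o = scenario.contrasts[contrast_index]
    inst = scenario.instrument
    core, solvent, dry_shell, label = _contrast_slds(
        core_kind, f_d2o, inst.radiation
    )
    t = scenario.truth
    shell = composition.mix_sld(
        [(dry_shell, 1.0 - t.hydration), (solvent, t.hydration)]
    )
    if inst.radiation == "xray":
        background = SAXS_BACKGROUND
    else:
        background = SANS_BACKGROUND_H2O * (1 - f_d2o) + SANS_BACKGROUND_D2O * f_d2o
    p = CoreShellParams(
        core_radius=t.core_radius,
        shell_thickness=t.shell_thickness,
        sld_core=core,
        sld_shell=shell,
        sld_solvent=solvent,
        volume_fraction=t.volume_fraction,
        polydispersity=t.polydispersity,
        background=0.0,
    )
    kernel = (
        ResolutionKernel("gaussian_pointwise", inst.dq)
        if np.any(inst.dq > 0)
        else ResolutionKernel("none")
    )
    i_true = smear(inst.q_grid, lambda qq: polydisperse_intensity(qq, p), kernel)
    return i_true + background, core, solvent, f_d2o, label


def simulate_dataset(scenario: Scenario, contrast_index: int) -> SASDataset:
    """Simulate one contrast of a scenario; deterministic given the seed."""
    inst = scenario.instrument
    i_true, core, solvent, f_d2o, label = _true_curve(scenario, contrast_index)
    sigma = (
        scenario.noise_pct / 100.0 * np.abs(i_true)
        + SIGMA_FLOOR_FRACTION * i_true[0]
    )
    if scenario.noise_pct == 0.0:
        i_noisy = i_true.copy()  # noiseless data still carries a sigma column
    else:
        rng = np.random.default_rng([scenario.seed, contrast_index])
        i_noisy = i_true + rng.normal(size=i_true.shape) * sigma
    kernel = (
        ResolutionKernel("gaussian_pointwise", inst.dq)
        if np.any(inst.dq > 0)
        else ResolutionKernel("none")
    )
    return SASDataset(
        q=inst.q_grid.copy(),
        i=i_noisy,
        sigma_i=sigma,
        resolution=kernel,
        contrast_label=label,
        sld_solvent=solvent,
        sld_core=core,
        temperature_c=scenario.temperature_c,
        concentration_mg_ml=scenario.concentration_mg_ml,
    )


def simulate_scenario(scenario: Scenario) -> list[SASDataset]:
    return [simulate_dataset(scenario, j) for j in range(len(scenario.contrasts))]


FOUR_CONTRASTS: tuple[tuple[str, float], ...] = (
    ("h", 0.0), ("h", 1.0), ("d", 0.0), ("d", 1.0),
)


def reference_scenarios(seed: int = 0) -> dict[str, Scenario]:
    """Bundled study scenarios.

    Structural truths follow the fitted point estimates of the study design
    this generator emulates: SANS four-contrast series for unloaded
    (core 200 Å, shell 15 Å, pd 0.20, hydration 0.50, phi 0.009) and
    drug-loaded (202 Å, 20 Å, 0.25, 0.70, 0.009) nanocapsules at 6.2 mg/mL;
    single-contrast SAXS sets at 62 mg/mL; a core-matched solvent scenario;
    and a dilution triple (1.24/3.1/6.2 mg/mL) sharing the unloaded truth
    with the volume fraction scaled by concentration.
    """
    sans = make_q_grid("sans")
    saxs = make_q_grid("saxs")
    unloaded_truth = StructuralTruth(200.0, 15.0, 0.20, 0.50, 0.009)
    loaded_truth = StructuralTruth(202.0, 20.0, 0.25, 0.70, 0.009)
    h_core_sld = composition.sld(composition.LABRAFAC)
    scenarios = {
        "unloaded": Scenario(
            "unloaded", unloaded_truth, FOUR_CONTRASTS, sans, seed=seed,
        ),
        "loaded": Scenario(
            "loaded", loaded_truth, FOUR_CONTRASTS, sans, seed=seed,
        ),
        "saxs_unloaded": Scenario(
            "saxs_unloaded",
            StructuralTruth(217.0, 26.0, 0.20, 0.50, 0.092),
            (("h", 0.0),), saxs, noise_pct=1.0, concentration_mg_ml=62.0,
            seed=seed,
        ),
        "saxs_loaded": Scenario(
            "saxs_loaded",
            StructuralTruth(185.0, 36.0, 0.35, 0.50, 0.092),
            (("h", 0.0),), saxs, noise_pct=1.0, concentration_mg_ml=62.0,
            seed=seed,
        ),
        "matched_core": Scenario(
            "matched_core", unloaded_truth,
            (("h", composition.match_point(h_core_sld)),), sans, seed=seed,
        ),
    }
    for j, conc in enumerate((1.24, 3.1, 6.2)):
        truth = replace(
            unloaded_truth,
            volume_fraction=unloaded_truth.volume_fraction * conc / 6.2,
        )
        # distinct seeds so dilution replicates carry independent noise
        scenarios[f"dilution_{conc}"] = Scenario(
            f"dilution_{conc}", truth, (("h", 1.0),), sans,
            concentration_mg_ml=conc, seed=seed + 1 + j,
        )
    return scenarios
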