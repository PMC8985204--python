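"""Chemical composition -> scattering length density (SLD).

The contrast in a small-angle scattering experiment is set by the SLD
difference between a structural region and the solvent.  This module turns
chemical formulas plus mass densities into neutron and X-ray SLDs, builds
H2O/D2O solvent series, finds contrast-match points, and inverts a fitted
shell SLD into a solvent (hydration) volume fraction.

All SLDs are handled on the conventional 10^-6 Å^-2 scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .elements import AVOGADRO_SCALE, ELEMENTS, R_ELECTRON

__all__ = [
    "Formula",
    "Component",
    "Mixture",
    "parse_formula",
    "sld",
    "sld_pair",
    "mix_sld",
    "solvent_sld",
    "match_point",
    "hydration_from_sld",
    "WATER",
    "HEAVY_WATER",
    "LABRAFAC",
    "KOLLIPHOR_HS15",
    "D_OCTANOIC",
    "D_DECANOIC",
    "labrafac_d_blend",
]

Radiation = Literal["neutron", "xray"]

_TOKEN = re.compile(r"([A-Z][a-z]?|d)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Element/isotope counts of one molecule (or repeat unit).

    'D' counts deuterium, distinct from 'H'.
    """

    element_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.element_counts:
            raise ValueError("formula must contain at least one element")
        for sym, n in self.element_counts.items():
            if sym not in ELEMENTS:
                raise ValueError(f"unknown element symbol: {sym!r}")
            if n < 1:
                raise ValueError(f"element count must be >= 1, got {sym}:{n}")

    @property
    def molar_mass(self) -> float:
        """g/mol."""
        return sum(ELEMENTS[s].mass * n for s, n in self.element_counts.items())

    @property
    def total_b_coh(self) -> float:
        """Sum of bound coherent scattering lengths, fm."""
        return sum(ELEMENTS[s].b_coh_fm * n for s, n in self.element_counts.items())

    @property
    def total_electrons(self) -> int:
        return sum(ELEMENTS[s].z * n for s, n in self.element_counts.items())


@dataclass(frozen=True)
class Component:
    """A named chemical species with a bulk mass density."""

    name: str
    formula: Formula
    mass_density: float  # g/cm^3

    def __post_init__(self) -> None:
        if not self.mass_density > 0:
            raise ValueError(f"mass density must be > 0, got {self.mass_density}")

    @property
    def molecular_volume(self) -> float:
        """Molecular volume, Å³, from molar mass and bulk density."""
        return self.formula.molar_mass / (AVOGADRO_SCALE * self.mass_density)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula, optionally '+'-joined ("C8H16O2 + C10H20O2").

    Counts are summed across '+' terms.  Underscore-style subscripts
    ("C_8_H_16_O_2_") are accepted and stripped.  'd' is normalised to the
    deuterium symbol 'D'.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    counts: dict[str, int] = {}
    for term in text.split("+"):
        term = term.replace("_", "").replace(" ", "")
        if not term:
            raise ValueError(f"empty term in formula: {text!r}")
        pos = 0
        while pos < len(term):
            m = _TOKEN.match(term, pos)
            if m is None or not m.group(1):
                raise ValueError(f"cannot parse formula near {term[pos:]!r}")
            sym = m.group(1)
            if sym == "d":
                sym = "D"
            if sym not in ELEMENTS:
                raise ValueError(f"unknown element symbol: {sym!r}")
            n = int(m.group(2)) if m.group(2) else 1
            counts[sym] = counts.get(sym, 0) + n
            pos = m.end()
    return Formula(counts)


def sld(component: Component, radiation: Radiation = "neutron") -> float:
    """Scattering length density of a pure component, 10^-6 Å^-2.

    Neutron: sum of bound coherent scattering lengths over the molecular
    volume.  X-ray: electron count times the classical electron radius over
    the molecular volume (far-from-edge Thomson scattering).
    """
    v = component.molecular_volume  # Å^3
    if radiation == "neutron":
        total_b = component.formula.total_b_coh * 1e-5  # fm -> Å
    elif radiation == "xray":
        total_b = component.formula.total_electrons * R_ELECTRON
    else:
        raise ValueError(f"radiation must be 'neutron' or 'xray', got {radiation!r}")
    return total_b / v * 1e6


def sld_pair(component: Component) -> tuple[float, float]:
    """(neutron, xray) SLD of a component, 10^-6 Å^-2."""
    return sld(component, "neutron"), sld(component, "xray")


@dataclass(frozen=True)
class Mixture:
    """Mass-fraction mixture of components; SLD by volume-fraction weighting."""

    parts: tuple[tuple[Component, float], ...]  # (component, mass fraction)

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.parts)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions must sum to 1, got {total}")

    def volume_fractions(self) -> list[float]:
        specific_volumes = [w / c.mass_density for c, w in self.parts]
        total = sum(specific_volumes)
        return [v / total for v in specific_volumes]

    def sld(self, radiation: Radiation = "neutron") -> float:
        phis = self.volume_fractions()
        return mix_sld(
            [(sld(c, radiation), phi) for (c, _), phi in zip(self.parts, phis)]
        )


def mix_sld(parts: Iterable[tuple[float, float]]) -> float:
    """Volume-fraction-weighted mean SLD.

    ``parts`` is a sequence of (sld, volume_fraction); fractions must be
    non-negative and sum to 1 within 1e-9.
    """
    parts = list(parts)
    total = sum(f for _, f in parts)
    if any(f < 0 for _, f in parts):
        raise ValueError("volume fractions must be >= 0")
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"volume fractions must sum to 1, got {total}")
    return sum(s * f for s, f in parts)


# Reference components.  Densities are configurable defaults: water values are
# the 25 C standard ones; Labrafac (caprylic/capric triglyceride oil) is the
# vendor-range midpoint; Kolliphor HS 15 is represented by its C20H40O4
# repeat unit (one ethylene glycol moiety per hydroxystearate), a PEG-rich
# solid for which 1.05 g/cm3 is adopted.
WATER = Component("light water", parse_formula("H2O"), 0.997)
HEAVY_WATER = Component("heavy water", parse_formula("D2O"), 1.107)
LABRAFAC = Component("Labrafac", parse_formula("C8H16O2 + C10H20O2"), 0.94)
KOLLIPHOR_HS15 = Component("Kolliphor HS 15", parse_formula("C20H40O4"), 1.05)
D_OCTANOIC = Component("octanoic-d15 acid", parse_formula("C8D15O2H"), 1.00)
D_DECANOIC = Component("decanoic-d19 acid", parse_formula("C10D19O2H"), 0.99)


def labrafac_d_blend(
    mass_fractions: Sequence[float] = (0.95, 0.0274, 0.0226),
) -> Mixture:
    """95:5 w/w blend of Labrafac with deuterated C8/C10 fatty acids.

    The deuterated 5% splits between octanoic-d15 and decanoic-d19 in the
    54.0:45.2 caprylic:capric proportion of the parent oil.
    """
    w = list(mass_fractions)
    w[-1] = 1.0 - sum(w[:-1])  # absorb rounding
    return Mixture(tuple(zip((LABRAFAC, D_OCTANOIC, D_DECANOIC), w)))


def solvent_sld(f_d2o: float) -> float:
    """Neutron SLD of an H2O/D2O mixture at D2O volume fraction ``f_d2o``."""
    if not 0.0 <= f_d2o <= 1.0:
        raise ValueError(f"f_d2o must be in [0, 1], got {f_d2o}")
    return mix_sld([(sld(WATER), 1.0 - f_d2o), (sld(HEAVY_WATER), f_d2o)])


def match_point(target_sld: float) -> float:
    """D2O fraction at which the solvent SLD equals ``target_sld``.

    Inverse of :func:`solvent_sld`; raises if the target lies outside the
    H2O..D2O range.
    """
    lo, hi = sld(WATER), sld(HEAVY_WATER)
    if not (min(lo, hi) <= target_sld <= max(lo, hi)):
        raise ValueError(
            f"target SLD {target_sld} not reachable by H2O/D2O mixing "
            f"(achievable range [{lo:.3f}, {hi:.3f}] x 1e-6 A^-2)"
        )
    return (target_sld - lo) / (hi - lo)


def hydration_from_sld(
    fitted_shell: float, dry_shell: float, solvent: float, tol: float = 0.05
) -> float:
    """Solvent volume fraction in the shell from its fitted SLD.

    Inverts the two-component linear mixing rule
    ``fitted = (1 - h) * dry + h * solvent``.  Values within ``tol`` outside
    [0, 1] are clipped; anything further out flags inconsistent SLDs.
    """
    if solvent == dry_shell:
        raise ValueError("solvent and dry-shell SLDs coincide; hydration undefined")
    h = (fitted_shell - dry_shell) / (solvent - dry_shell)
    if h < -tol or h > 1.0 + tol:
        raise ValueError(
            f"implied hydration {h:.3f} outside [0, 1]: inconsistent SLDs "
            f"(fitted={fitted_shell}, dry={dry_shell}, solvent={solvent})"
        )
    return min(max(h, 0.0), 1.0)
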