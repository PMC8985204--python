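"""Static nuclear/atomic data for SLD computation.

Bound coherent neutron scattering lengths are the Sears compilation values
(Neutron News 3 (1992) 26), in fm; bundling them as a frozen table keeps
computed SLDs independent of external database revisions.  Deuterium is a
first-class symbol ('D') distinct from natural-abundance hydrogen.
"""

from __future__ import annotations

from typing import NamedTuple

#: classical electron radius, Å
R_ELECTRON = 2.818e-5

#: Avogadro's number scaled so that V[Å³] = mass[g/mol] / (AVOGADRO_SCALE * density[g/cm³])
AVOGADRO_SCALE = 0.6022141


class ElementData(NamedTuple):
    b_coh_fm: float   # bound coherent scattering length, fm
    mass: float       # atomic mass, g/mol
    z: int            # atomic number (electron count for neutral atom)


ELEMENTS: dict[str, ElementData] = {
    "H":  ElementData(-3.7390, 1.00794, 1),
    "D":  ElementData(6.671, 2.01410, 1),
    "C":  ElementData(6.6460, 12.011, 6),
    "N":  ElementData(9.36, 14.007, 7),
    "O":  ElementData(5.803, 15.999, 8),
    "F":  ElementData(5.654, 18.9984, 9),
    "Na": ElementData(3.63, 22.9898, 11),
    "Mg": ElementData(5.375, 24.305, 12),
    "Si": ElementData(4.1491, 28.0855, 14),
    "P":  ElementData(5.13, 30.9738, 15),
    "S":  ElementData(2.847, 32.06, 16),
    "Cl": ElementData(9.5770, 35.453, 17),
    "K":  ElementData(3.67, 39.0983, 19),
    "Ca": ElementData(4.70, 40.078, 20),
    "Br": ElementData(6.795, 79.904, 35),
    "I":  ElementData(5.28, 126.904, 53),
}
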