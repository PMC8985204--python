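"""Recover the pair-distance distribution p(r) from a scattering curve.

Generates a noise-free sphere curve (R = 24.3 nm), inverts it by the
regularised indirect Fourier transform, and scans candidate maximum
dimensions to locate the particle's true support (Dmax = 2R).
"""

import numpy as np

import sascontrast as sc

radius = 243.0  # A
q = np.logspace(np.log10(0.002), np.log10(0.15), 180)
sphere = sc.CoreShellParams(
    core_radius=radius, shell_thickness=0.0, sld_core=1.0, sld_shell=1.0,
    sld_solvent=0.0, volume_fraction=0.01,
)
i = sc.core_shell_intensity(q, sphere)
sigma = 0.01 * np.abs(i) + 1e-4 * i[0]
dataset = sc.SASDataset(q=q, i=i, sigma_i=sigma)

result = sc.scan_dmax(dataset, np.arange(380, 721, 20), alpha=1e-2)
print(result.scan.head(8).to_string(index=False))
print(f"\nselected Dmax = {result.dmax:.0f} A (true 2R = {2 * radius:.0f} A)")
print(f"Rg from p(r) moments = {result.rg:.1f} A "
      f"(analytic sqrt(3/5) R = {np.sqrt(3 / 5) * radius:.1f} A)")
print(f"chi2_red of the selected inversion = {result.chi2_reduced:.3f}")
print("the p(r) of a homogeneous sphere peaks near 1.05 R and vanishes at "
      "2R; a shoulder or tail beyond that would signal aggregation or "
      "non-spherical shape")
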