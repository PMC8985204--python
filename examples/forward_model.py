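"""Evaluate the polydisperse core-shell sphere model on an absolute scale.

Computes I(Q) for a 20 nm-core, 1.5 nm-shell nanocapsule in D2O, shows the
effect of polydispersity and instrument resolution on the form-factor
minima, and a Guinier estimate of the radius of gyration.
"""

import numpy as np

import sascontrast as sc

params = sc.CoreShellParams(
    core_radius=200.0,        # A
    shell_thickness=15.0,     # A
    sld_core=0.15,            # 1e-6/A^2, protiated triglyceride
    sld_shell=3.24,           # 50%-hydrated PEG shell in D2O
    sld_solvent=6.35,         # D2O
    volume_fraction=0.009,
    polydispersity=0.20,
    background=0.05,          # cm^-1, D2O incoherent level
)
q = np.logspace(np.log10(0.003), np.log10(0.3), 120)

i_mono = sc.core_shell_intensity(q, params.with_(polydispersity=0.0))
i_poly = sc.polydisperse_intensity(q, params)
kernel = sc.ResolutionKernel("gaussian_fractional", 0.08)
i_smeared = sc.smear(q, lambda qq: sc.polydisperse_intensity(qq, params),
                     kernel)

def first_local_min(curve):
    interior = (curve[1:-1] < curve[:-2]) & (curve[1:-1] < curve[2:])
    return 1 + np.flatnonzero(interior)[0]


print(f"I(q_min) = {i_poly[0]:8.1f} cm^-1 (forward scattering, phi=0.9%)")
j = first_local_min(i_mono)
print(f"first form-factor minimum near q = {q[j]:.4f} 1/A "
      f"(~ 4.49/R_total = {4.493 / params.total_radius:.4f})")
print(f"depth there: monodisperse {i_mono[j]:.3f}, "
      f"pd=0.2 {i_poly[j]:.3f}, +smearing {i_smeared[j]:.3f} cm^-1")
print("polydispersity and Q-resolution both fill the minima - exactly what "
      "the fit must disentangle")

rg, i0 = sc.guinier_fit(q, i_poly - params.background)
print(f"\nGuinier: Rg = {rg / 10:.1f} nm, I(0) = {i0:.1f} cm^-1 "
      "(contrast- and size-weighted average over the distribution)")
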