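"""Compute scattering length densities and shell-hydration arithmetic.

Builds the lipid-nanocapsule component set (triglyceride oil core, PEG
surfactant shell, light/heavy water) and shows the contrast arithmetic that
drives a contrast-variation experiment: solvent series, core match point,
and inverting a fitted shell SLD into a hydration fraction.
"""

from sascontrast import composition as comp

for component in (comp.WATER, comp.HEAVY_WATER, comp.LABRAFAC,
                  comp.KOLLIPHOR_HS15):
    n, x = comp.sld_pair(component)
    print(f"{component.name:18s} neutron {n:6.2f}   xray {x:6.2f}  (1e-6/A^2)")

blend = comp.labrafac_d_blend()
print(f"\n5% deuterated-oil core blend: neutron SLD {blend.sld():.2f}")
f = comp.match_point(blend.sld())
print(f"matched out by {100 * f:.1f}% D2O in the solvent "
      f"(solvent SLD {comp.solvent_sld(f):.2f})")

# the fitted shell SLD in D2O (3.3) against the dry surfactant value (0.13)
h = comp.hydration_from_sld(3.3, 0.13, 6.35)
print(f"\nfitted shell SLD 3.3 in D2O -> shell hydration {100 * h:.0f}%")
print("i.e. half the shell volume is solvent: a diffuse, water-swollen "
      "PEG corona rather than a compact film")
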