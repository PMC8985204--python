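"""Simultaneous fit of a four-contrast SANS series.

Simulates the full contrast-variation design -- protiated and partly
deuterated oil cores, each in H2O and D2O -- from one structural truth,
then fits all four curves jointly with shared structure and per-dataset
backgrounds, and reports the derived quantities (total radius, per-contrast
shell SLD, hydration percentage).
"""

import sascontrast as sc

scenario = sc.reference_scenarios(seed=1)["unloaded"]
datasets = sc.simulate_scenario(scenario)
print("simulated contrasts:",
      ", ".join(ds.contrast_label for ds in datasets))
print(f"truth: core {scenario.truth.core_radius / 10:.1f} nm, shell "
      f"{scenario.truth.shell_thickness / 10:.1f} nm, pd "
      f"{scenario.truth.polydispersity}, hydration "
      f"{scenario.truth.hydration:.0%}, phi {scenario.truth.volume_fraction}")

problem = sc.build_problem(datasets)
result = sc.fit(problem, seed=1)

print(f"\njoint fit: chi2_red = {result.chi2_reduced:.2f} over "
      f"{result.n_points} points")
for name in ("core_radius", "shell_thickness", "polydispersity",
             "hydration", "volume_fraction"):
    print(f"  {name:16s} {result.estimates[name]:9.4f} "
          f"+- {result.uncertainties[name]:.4f}")

derived = result.derived
print(f"\ntotal radius = {derived['total_radius'] / 10:.1f} "
      f"+- {derived['total_radius_err'] / 10:.1f} nm")
print(f"shell hydration = {derived['hydration_pct']:.0f}%")
print("shell SLD per contrast (hydration x solvent mixing):")
for label, value in derived["shell_sld_per_contrast"].items():
    print(f"  {label:10s} {value:6.2f}")
print("\nnote the wide shell/hydration intervals: a ~1.5 nm hydrated shell "
      "is near the information limit of smeared SANS data, which is why "
      "four contrasts are fitted at once")
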