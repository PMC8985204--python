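# Methods

## The physical problem

Lipid nanocapsules are soft spherical particles with a liquid triglyceride
core (radius ≈ 20 nm) stabilised by a thin shell of PEGylated surfactant
and phospholipid. Their X-ray contrast is nearly homogeneous, so SAXS
alone sees "a sphere"; resolving the shell requires neutron contrast
variation: measuring the same particles with protiated or partly
deuterated oil cores in H₂O, D₂O or intermediate mixtures. The package
implements the full analysis chain for such an experiment: converting
compositions into scattering length densities (SLDs), forward-modelling
polydisperse core–shell spheres on an absolute scale, smearing with the
instrument resolution, inverting curves into pair-distance distributions,
and fitting all contrasts simultaneously.

## Scattering length densities

For a molecule with formula-unit atoms *i*, mass density ρ_m and molar
mass M, the molecular volume is V = M / (N_A ρ_m) and

* neutron: SLD = Σᵢ b_c,i / V, with b_c the bound coherent scattering
  lengths from a bundled, frozen Sears-style table (deuterium, symbol `D`
  or `d`, is distinct from `H`),
* X-ray: SLD = Z_total · r_e / V with r_e = 2.818×10⁻⁵ Å (Thomson limit;
  anomalous dispersion is out of scope).

All SLDs are carried on the 10⁻⁶ Å⁻² scale. Mixtures combine by volume
fraction; mass fractions are converted through component densities.
Component densities are configurable defaults: water 0.997, heavy water
1.107, the caprylic/capric triglyceride oil 0.94, the deuterated C8/C10
fatty acids 1.00/0.99 (protiated acid densities scaled by the isotopic
mass ratio) and the PEG-15 hydroxystearate surfactant 1.05 g/cm³. The
surfactant is represented by its C₂₀H₄₀O₄ repeat unit (hydroxystearate
plus one ethylene-glycol unit); no single density reproduces both its
conventional neutron (0.13) and X-ray (9.92) reference SLDs exactly, and
1.05 g/cm³ was chosen as the physically reasonable value that matches the
X-ray figure. The hydration arithmetic nevertheless uses the conventional
dry-shell value 0.13 as its default reference, since that is the value
the inversion is defined against.

Shell hydration h is defined by linear two-component mixing,
ρ_shell = (1−h)·ρ_dry + h·ρ_solvent, and inverted exactly; implied
hydrations within 5 points outside [0,1] are clipped, anything further is
rejected as inconsistent.

## Forward model

Absolute intensity of a dilute dispersion of core–shell spheres:

    I(Q) = 10⁻⁴ · (φ / ⟨V_t⟩) · ⟨F²(Q)⟩ · S(Q) + b        [cm⁻¹]
    F(Q) = V_t (ρ_sh − ρ_solv) Φ(QR_t) + V_c (ρ_c − ρ_sh) Φ(QR_c)
    Φ(x) = 3 (sin x − x cos x) / x³

with lengths in Å and SLDs on the 10⁻⁶ Å⁻² scale; the 10⁻⁴ prefactor is
the standard Å→cm conversion under that SLD convention, so φ is a true
volume fraction and the number density is always φ/⟨V_t⟩, never a free
parameter. Φ is evaluated by a series below x = 0.02 (the switch point
balances series truncation against the closed form's cancellation error).

Polydispersity is a Gaussian number distribution of the **core radius**
(σ/μ is the reported polydispersity) at fixed shell thickness, truncated
at ±3σ (never below zero) and averaged as ⟨F²⟩/⟨V⟩ by Gauss–Legendre
quadrature (default 35 nodes; ≥15 enforced, 35 agrees with a 301-node
reference to ~10⁻⁷ over the fitted Q range). The structure factor
defaults to S = 1; a Percus–Yevick hard-sphere S(Q) is available for
concentrated samples, with a series branch below 2QR = 0.1 so that S(0)
equals the compressibility limit (1−φ)⁴/(1+2φ)² exactly. At the dilute
SANS volume fraction (φ = 0.009) the PY deviation from unity is below 6%
at the lowest measured Q and below 1% over the bulk of the window, which
is what justifies the S = 1 treatment.

The Guinier estimator fits ln I = a − (R_g²/3)Q² + cQ⁴ over an iterated
window Q·R_g ≤ 1.3. The quartic nuisance term is deliberate: a pure
linear Guinier fit over that conventional window is biased by ~+1.5% for
compact spheres, while the quadratic-in-Q² form recovers the sphere
R_g = √(3/5)·R to better than 0.1%.

## Resolution smearing

Reduced pinhole data carry a Gaussian σ_Q per point (fractional δQ/Q or a
fourth data column). Model curves are convolved by Gauss–Hermite
quadrature (default 31 nodes — 21 under-resolves a δQ/Q = 0.08 kernel at
high Q; 31 keeps the deviation from a 2001-node dense convolution below
0.2%). Nodes that would fall at Q ≤ 0 are dropped and the kernel
renormalised. Defaults: δQ/Q = 0.08 for the time-of-flight SANS
configuration, no smearing for point-collimation SAXS; both overridable
per dataset.

## p(r) inversion

p(r) is expanded in the Moore sine basis Σ aₖ sin(kπr/Dmax) (k ≤ 64),
which enforces p(0) = p(Dmax) = 0, and fitted to I(Q) by weighted least
squares with a second-derivative Tikhonov penalty α·∫p″²; in this basis
the penalty matrix is diagonal, so the inversion is one regularised
normal-equation solve. α is specified relative to the data-misfit scale
(normal-matrix and penalty traces equalised), default 10⁻². R_g comes
from the p(r) moments, I(0) = 4π∫p dr. Dmax is selected by scanning
candidates and taking the smallest whose χ²_red is within 5% of the scan
minimum, whose p(r) has no negative lobe beyond 5% of the peak, and whose
χ²_red is below an absolute clear-misfit guard (10); if none qualifies
the best-χ² result is returned flagged non-ideal. The guard is what flags
candidate sets that all truncate the true support, where the inversion
stays positive but plainly misfits.

## Simultaneous multi-contrast fitting

All curves of one formulation are fitted together. Core and solvent SLDs
are fixed at their computed values per contrast; shared free parameters
are core radius, shell thickness, polydispersity, hydration and volume
fraction; per-dataset parameters are background (free by default) and an
optional intensity scale (fixed at 1 for absolute-scale data). The shell
SLD is **not** fitted directly: a single shared hydration fraction
generates each dataset's shell SLD by mixing with that dataset's solvent,
which is the only way one shell parameter can be consistent across H₂O
and D₂O contrasts; the conventional per-contrast "fitted shell SLD" is
reported as a derived quantity. Default bounds: core radius 50–600 Å,
shell 0–100 Å, polydispersity 0–0.6, hydration 0–1, volume fraction
10⁻⁴–0.3.

Optimisation is trust-region-reflective least squares on σ-weighted
residuals with five seeded Latin-hypercube starts (coarsely refined, best
polished; ties break to lowest χ², then smallest core radius), parameter
scaling by bound widths, and a 400-evaluation polish budget; exhaustion
of that budget returns the best-so-far state flagged unsuccessful rather
than an exception, because near-degenerate problems (e.g. fully
contrast-matched data) legitimately crawl along flat likelihood valleys.
Uncertainties are Jacobian-based, scaled by the reduced χ²; derived
totals (core+shell radius) propagate the full covariance. Inside the fit
the model is evaluated through a shared-kernel fast path — the Φ matrices
depend only on structure, so datasets sharing a Q grid reuse them and the
per-contrast intensity is a quadratic form in the two contrast
coefficients; the fast path is pinned to the explicit form-factor→smear
route at machine precision by a test. The optimiser uses an analytic
Jacobian assembled in the same pass (Φ′ shares the sin/cos evaluations;
quadrature nodes are affine in core radius and polydispersity), validated
against finite differences by a test — this matters because a
finite-difference Jacobian would cost ~10 model evaluations per
iteration.

`scenario_battery` fits families of problems differing only in external
conditions (concentration, temperature, salt), checks the structural
parameters pairwise against joint 95% confidence intervals, and, when
concentrations differ, regresses fitted φ on concentration. For
single-contrast dilution series the shell parameters should be fixed at
values established by a full contrast series first: one D₂O contrast
alone cannot resolve a thin hydrated shell (hydration → 1 makes the shell
invisible), and the fixed-shell workflow is what the battery examples and
tests do.

## Synthetic data

The generator emulates the study design: SANS grid of 120 log-spaced
points over 0.003–0.7 Å⁻¹ with δQ/Q = 0.08; SAXS grid of 200 points over
0.0076–3 Å⁻¹ unsmeared; four contrasts (h/d core × H₂O/D₂O); flat
incoherent background interpolating between 1.0 cm⁻¹ (H₂O) and 0.05 cm⁻¹
(D₂O) for SANS, 0.01 cm⁻¹ for SAXS. Noise is multiplicative Gaussian,
σ(Q) = (noise_pct/100)·I(Q) plus an additive floor of 10⁻⁴·I(q_min)
(counting-statistics proxy for reduced data with error bars); the σ
column records the true noise scale, and a Kolmogorov–Smirnov test on
pooled z-scores confirms it. Default noise is 3% (real reduction-chain
noise levels are unknown; 1–5% is the plausible range and the level is a
parameter). Bundled scenario truths follow the published point estimates
(unloaded: core 200 Å, shell 15 Å, pd 0.20, hydration 0.50, φ = 0.009;
loaded: 202 Å, 20 Å, 0.25, 0.70, 0.009; SAXS variants at φ = 0.092), a
core-matched solvent scenario, and a dilution triple at 1.24/3.1/6.2
mg/mL with φ scaled proportionally and distinct seeds per concentration.
What the generator does **not** emulate: Q-dependent background,
inter-particle interference (S = 1 truths), reduction artefacts,
multiple scattering, and temperature physics (temperature/salt scenarios
are replicate seeds of one truth). Passing recovery tests therefore show
estimator correctness under the stated statistical model, not robustness
to real-data systematics.

## Information content and honest limits

At the stated study conditions the Fisher information of the four-
contrast design bounds any estimator at roughly 0.6% (core radius), 1.8%
(polydispersity), 3.7% (φ), but ~17% (shell thickness) and ~21%
(hydration) per realisation: the σ floor is ≈0.15 cm⁻¹ on the bright D₂O
contrasts (I(q_min) ≈ 1500 cm⁻¹), which swamps the faint high-Q shell
signal, and shell thickness and hydration are strongly correlated
(ρ ≈ 0.8) because a thin shell enters mainly through its scattering mass.
Replicate fits show corresponding estimator bias for the weakly
identified pair (shell ≈ −5%, hydration ≈ −7% for the unloaded truth;
both < 2% for the loaded, thicker and more hydrated shell). This mirrors
the real experiment, where the unloaded shell thickness could only be
bounded (≤1.5 nm). The recovery tests therefore judge the mean over a
seeded replicate set (20 unloaded / 10 loaded seeds — counts chosen to
keep the suite tractable on one CPU), and the unloaded hydration check is
expected to sit at the edge of, or outside, a 5% band for fundamental
statistical reasons rather than implementation ones.

## Numerical conventions

Internal units Å, Å⁻¹, cm⁻¹; nm⁻¹ accepted on I/O with an explicit unit
flag or header. Canonical on-disk format is 3/4-column whitespace ASCII
with `# key: value` metadata headers; JSON for fit results and manifests.
All randomness (noise, multi-start sampling) flows from explicit integer
seeds; two runs with the same seed are byte-identical. Degenerate inputs
(zero contrast, zero shell, zero polydispersity, constant curves, empty
datasets) are exercised by the test suite.
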