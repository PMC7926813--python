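# Methods

## Sign convention

Everything in the package uses the electrical-engineering convention
ε = ε′ − jε″ with ε″ ≥ 0 and time factor e^{+jωt}. Stored complex
permittivities therefore have non-positive imaginary parts; effective
conductivity is σ_eff = 2πf·ε₀·ε″. The transfer-matrix module uses the
same convention, so k = (ω/c)√ε has Im k ≤ 0 and e^{−jkz} decays.

## Component models and fixtures

**Tissues.** Each of the ten vendored tissues (blood, cortical bone,
grey matter, white matter, CSF, muscle, nerve, fat, dry skin, and the
blended brain) carries 4-pole Cole–Cole parameters from the Gabriel
parametric compilation, stored as one JSON file per tissue with a
provenance note. These are body-temperature literature values used
as-is; temperature enters the package only through the saline model.
At 1 GHz the fixtures reproduce the standard reference values
(e.g. CSF 68.4 / 2.46 S/m, cortical bone 12.4 / 0.16 S/m).

**Brain blend.** The reference brain target is the per-frequency
volume-weighted average of 75% white and 25% grey matter. Linear
averaging of the complex permittivity is the simplest rule consistent
with the published blended value at 1 GHz (ε′ ≈ 42). Its conductivity
comes out at 0.71 S/m; note that no linear 75/25 combination of the
standard white/grey parameter sets can reach 1.0 S/m at 1 GHz (grey
matter alone is 0.99), so published blended-brain conductivities near
1.0 should be read as generously rounded. This is why the fitted brain
NaCl concentration lands nearer 5.7 g/L than 6.8 g/L.

**Triton X-100.** A single-pole Debye fixture: ε_s = 7.4, ε_∞ = 2.4,
τ = 0.212 ns, σ = 0 (and mass density 1.07 g/mL). The static value
follows low-frequency literature measurements of the pure surfactant;
the relaxation time was fixed once so the curve shows the ≈4 relative
permittivity and ≈0.1 S/m loss reported for TX-100 near 1 GHz in the
phantom literature. The file is deliberately editable: replacing it
with probe measurements of a specific TX-100 batch is the intended
workflow, and all recipe-level tolerances in the tests (±2 εr units,
±0.2 S/m, ±2 TX vol%, ±1 g/L NaCl) exist to absorb exactly this
component-level uncertainty.

**Saline.** A Debye model parametric in NaCl concentration S (g/L,
user-facing) and temperature T (°C): static permittivity ε_s(T)·a(N),
relaxation time τ(T)·b(N, T) and ionic conductivity σ(25, N) times a
temperature factor, all Stogryn-form polynomial fits in the normality
N = S/58.44 (58.44 g/mol is the NaCl molar mass; the conversion is the
only internal unit change). Declared validity window: 0–50 °C,
0–120 g/L; out-of-window inputs raise an error quoting the window.
∂ε₂/∂S is implemented analytically by differentiating the polynomials
and is held to a 1e-6 relative agreement with central finite
differences (tested).

## Mixing laws

Kraszewski (√ε_m affine in V₂ — an exact algebraic property asserted to
1e-12), Böttcher and Bruggeman (quadratic effective-medium forms solved
in closed form, selecting the root continuous with ε_m → ε₁ as V₂ → 0;
for passive right-half-plane components that root is the one with
positive real part, and a non-passive result raises an error),
Lichtenecker (logarithmic) and Looyenga (1/3-power). All complex roots,
logs and powers use the principal branch, which is unambiguous because
every permittivity of interest lies in the right half-plane. Only
Kraszewski and Böttcher track measured TX-100/saline mixtures well;
the other three are retained for comparison and are not used by the
recipe pipeline. Analytic ∂ε_m/∂V₂ and ∂ε_m/∂ε₂ are provided for all
five laws (implicit differentiation for the quadratic ones) and checked
against finite differences.

With the reconstructed TX-100 fixture, Kraszewski and Böttcher recipes
agree within 5 vol% TX / 1.5 g/L NaCl for the water-rich head tissues.
For cortical bone — the one mixture dominated by the TX-100 component —
the two laws spread to ≈9 vol% (77.6 vs 68.3, Kraszewski higher, the
same ordering as the published 80 vs 75); the spread is a direct image
of the component-fixture uncertainty and shrinks only with measured
TX-100 data.

## Optimizer

Gauss–Newton on J(x) = Σ_f ω_f |ε_m(x) − ε_t|², ω_f = 1/|ε_t|², over a
26-point linear grid on 0.5–3 GHz (both configurable). Safeguards on
the plain update x ← x − H⁻¹g:

* box projection V₂ ∈ [0, 1], S ∈ [0, 100] g/L;
* active-set reduction — a coordinate on its bound with the gradient
  pointing outward is frozen so clipping cannot distort the step (bone
  and fat converge onto the S = 0 edge);
* step halving (≤40 times) whenever J would increase, so the accepted
  cost trace is non-increasing;
* singular-Hessian fallback to the pseudo-inverse, flagged in the
  result.

Convergence is declared when the box-projected gradient norm
‖x − P(x − g)‖ < 1e-10 or the accepted step is below 1e-12 — both far
below the reporting precision (TX rounded to integer vol%, NaCl to
0.1 g/L). Default start (V₂, S) = (0.5, 5); random starts use a seeded
generator. All ten vendored tissues converge in ≤ 11 iterations with a
start-independence spread below 1e-8, matching the benign-convergence
behavior the method is known for. Non-convergence returns a flagged
result, never an exception. A 200×200 brute-force grid oracle is kept
in the package for independent verification of any fit.

## Recipes

Masses per batch use fixture densities (TX-100 1.07 g/mL, water
0.997 g/mL at 25 °C). The saline volume is taken as the water volume —
the NaCl dissolution volume change is neglected, consistent with the
g/L-of-solution concentration definition at bench accuracy; the
composition → recipe → composition round trip is exact. The viscosity
warning fires on the closed band [40, 60] TX vol% (both endpoints
included, a documented convention); it carries the warm-mix mitigation
(components warmed separately, vigorous stirring, rest at 45 °C until
bubbles clear). Fine-tuning salt/TX against probe measurements remains
a manual bench step; the tool only flags when it is likely needed.

## 1D penetration proxy

Normal-incidence, single-polarization transfer matrices through planar
layers between two semi-infinite media. This is a qualitative desk
tool: it ranks coupling media (e.g. a low-loss εr = 23 liquid beats air
into a skull/CSF/brain stack by ≈3× in field amplitude) and shows how
an ABS wall (εr = 3, σ = 0.004 S/m at 1 GHz) shifts interface
amplitudes, but it cannot stand in for full-wave 3D simulation of an
antenna array around an anthropomorphic head — no curvature, no antenna
coupling, no 3D standing-wave structure. Energy bookkeeping uses the
impedance-weighted transmittance, which closes to 1e-12 for lossless
stacks; the implementation is cross-checked in the tests against an
independent dense boundary-condition solver.

## Synthetic data and what the tests show

The package ships no measured spectra. Test targets are either the
vendored Cole–Cole fixtures (the design conditions of the method) or
mixtures generated by the package's own forward model (for
zero-model-error recovery tests, which check the optimizer to 1e-6).
Tiny tetrahedral STL files are generated programmatically for the
manifest tests. Passing tests therefore demonstrate the numerical
machinery and its agreement with the published recipe table within the
component-fixture tolerances — they do not demonstrate agreement with
probe measurements of physical mixtures, which depend on the actual
TX-100 batch, water purity and temperature control.

## Known limitations

* TX-100 Debye constants are a literature-informed reconstruction, the
  dominant uncertainty for TX-rich (low-permittivity) recipes.
* The saline polynomials are used at 25 °C in all published-table
  comparisons; the temperature dependence is exposed but not validated
  against measurements here.
* Two published NaCl concentrations (blood 9.2, blended brain 6.8 g/L)
  are reproduced only to ≈1.1 g/L rather than 1.0; see the brain-blend
  conductivity note above and the TX-100 fixture caveat.
* The penetration module is 1D and normal-incidence only, by design.
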