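# tmmkit

Design of **tissue-mimicking liquid mixtures** for microwave imaging
phantoms: given a biological tissue's dispersive permittivity, find the
Triton X-100 (TX-100) / salted-water recipe whose complex permittivity
matches it over the 0.5–3 GHz band, then turn that composition into a
bench-ready preparation sheet.

Anthropomorphic phantoms for testing microwave imaging systems (e.g.
brain-stroke scanners) are 3D-printed cavity sets filled with liquids
whose dielectric spectra mimic brain, CSF, blood, muscle, bone and other
tissues. `tmmkit` automates the numerical half of that workflow for
engineers building such phantoms.

## The method

Tissues are described by multi-pole Cole–Cole models

```
ε_t(ω) = ε_∞ + Σ_n Δε_n / (1 + (jωτ_n)^(1−α_n)) + σ_s/(jωε_0),
```

TX-100 by a single-pole Debye model ε₁, and salted water by a parametric
Debye model ε₂(S, T) whose static permittivity, relaxation time and
ionic conductivity depend on the NaCl concentration S (g/L) and
temperature T (Stogryn-form polynomials). The mixture permittivity
follows a binary mixing law; the workhorse is Kraszewski's
square-root-linear rule

```
ε_m = [ ε₁^{1/2} + V₂ (ε₂^{1/2} − ε₁^{1/2}) ]²,       V₁ + V₂ = 1,
```

with Böttcher's effective-medium law as the cross-check (Lichtenecker,
Looyenga and Bruggeman are included for comparison only). The unknown
composition **x** = (V₂, S) is found by Gauss–Newton minimization of the
weighted complex misfit

```
J(x) = Σ_f ω_f |ε_m(x) − ε_t|_f²,    ω_f = 1/|ε_t|_f²,
```

using analytic derivatives of ε_m with respect to both V₂ and S (the
latter chained through ∂ε₂/∂S of the saline model). The iteration
x_{k+1} = x_k − H⁻¹g converges in a handful of steps, essentially
independently of the starting point.

The package also includes a 1D transfer-matrix explorer for coupling-
medium and wall-material questions (normal-incidence plane waves through
a layered skull/CSF/brain stack), and STL/manifest plumbing that binds
phantom cavity files to fitted recipes.

## Worked example

Fit the recipe for cerebrospinal fluid and print the bench sheet:

```
$ tmmkit design csf
csf: TX-100 5 vol%  NaCl 14.8 g/L  (J=3.786e-03, 5 iterations, converged=True)

$ tmmkit table
tissue          TX-100 vol%  NaCl g/L  eps_r@1GHz  sigma@1GHz
brain                    34       5.7        41.7        0.72
csf                       5      14.8        67.8        2.47
muscle                   20       6.4        54.6        0.98
bone_cortical            78       0.0        13.0        0.20
blood                    13      10.3        60.3        1.60
```

Each row is the fitted TX-100 volume percentage and NaCl concentration
of the mimicking mixture, followed by the mixture's relative
permittivity and effective conductivity at 1 GHz — e.g. a CSF mimic is
95 vol% saline at 14.8 g/L NaCl with only 5 vol% surfactant, while
cortical bone needs an almost pure TX-100 liquid. The same fits are
available in Python:

```python
from tmmkit import fit_tissue, build_recipe

res = fit_tissue("csf")
print(res.tx_vol_percent_rounded, res.nacl_rounded)   # 5 14.8
print(build_recipe(res.composition, batch_volume_L=1.0).to_text())
```

The recipe sheet lists the masses per batch (TX-100, deionized water,
NaCl), the numbered preparation protocol (45 °C water bath, magnetic
stirring, dark storage) and a prominent warning whenever the TX-100
fraction falls in the viscous 40–60 vol% band (e.g. the nerve mimic).

Explore coupling media with the 1D layered proxy:

```
$ tmmkit penetrate --stack bone_cortical:7/csf:2 --coupling eps=23,sigma=0.0
$ tmmkit penetrate --stack bone_cortical:7/csf:2 --coupling air
```

A low-loss εr = 23 coupling medium delivers about three times the field
amplitude into the brain layer compared with air.

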