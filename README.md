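# crafruk

Quantitative analytics for the interaction between the *E. coli*
transcription factor Cra (catabolite repressor activator) and the enzyme
FruK (fructose-1-kinase): equilibrium biolayer-interferometry (BLI)
binding analysis with regime-aware global fitting, AFM particle
volumetry with stoichiometry classification, luciferase-assay
fold-change normalization, and growth-curve delay metrics.  Every stage
is driven by a synthetic-data generator with known ground truth, so the
whole pipeline is testable without any external download.

## The science

Cra regulates >100 genes of central carbon metabolism; FruK binds
DNA-bound Cra with nanomolar affinity and forms higher-order
(dimer)ₙ complexes.  Measuring that affinity by BLI puts the assay in
an awkward place: the immobilized Cra–DNA concentration `D_T` is close
to the dissociation constant, so titrant depletion cannot be neglected.
The package classifies the binding regime by `D_T/K_d` (equilibrium
below 0.1, stoichiometric above 10, intermediate between) and fits
plateau signals with either the hyperbola

    Y = c + Y_max · 10^X / (K_d + 10^X),        X = log10[FruK]

or, when depletion matters, the quadratic mass-balance solution

    Y = c + Y_max · (a − √(a² − 4n·10^X/D_T)) / 2n,
    a = n + 10^X/D_T + K_d/D_T

with stoichiometry `n = 1`.  Because the depleting model carries a
per-experiment `D_T`, `K_d` is only identifiable by global fitting:
one shared `K_d`, with `c`, `Y_max`, `D_T` free per curve, plus a
parametric bootstrap for interval estimates.

AFM particle volumetry converts each measured peak (height, two widths
at half-height) to an elliptic-cylinder volume
`V = π·h·(w_long/2)·(w_orth/2)`, subtracts the adjacent-DNA volume
`(2/3)·h_DNA·w_DNA²` for DNA-bound complexes, and converts to
molecular weight via the protein specific volume `v̄ = 0.67 ml/g`
(derivable from crystal structures with the included solvent-excluded
volume estimator).  Masses are then partitioned by exact 1-D
minimal-WCSS clustering (dynamic programming; optionally with the top
class pinned to a fixed member count) and matched against a reference
ladder built from the monomer masses (Cra 37,999 Da; FruK 33,756 Da):
homodimers, (dimer)₂ = Cra+FruK, (dimer)₃ = Cra–FruK–Cra.

The enzyme module expresses FruK "reverse-reaction" activity as the
fold increase of luciferase signal over buffer-only controls with
first-order error propagation, an ATP log-log standard curve, and a
permutation test for concentration dependence.  The growth module
reports the time to half-maximal OD600 and strain-vs-strain delays.

## Worked example

Simulate ten BLI titrations (true K_d = 2.0 nM, immobilized
concentrations spanning 0.5–5 nM, 2% plateau noise) and fit them
globally, then push a simulated AFM measurement sheet through
volumetry and clustering:

```
$ crafruk simulate --kind bli --seed 7 --out demo
$ crafruk fit-bli demo/titration.csv --out demo/fit.json
shared Kd = 1.790e-09 M (+/- 9.9e-11)

$ crafruk simulate --kind afm --seed 7 --out demo
$ crafruk afm demo/afm_peaks.csv --out demo/masses.csv
wrote 60 mass estimates to demo/masses.csv
$ crafruk cluster demo/masses.csv --k 3 --out demo/clusters.json
class means (Da): [75067, 141742, 245144]
```

The fitted shared K_d (1.79 ± 0.10 nM here) sits within the simulation
noise of the 2.0 nM ground truth recorded in
`demo/titration.truth.json`.  The three mass classes land near the
ladder entries 75,998 / 143,510 / 219,508 Da and are labelled
`Cra homodimer`, `(dimer)2 Cra-FruK`, `(dimer)3 Cra-FruK-Cra` in
`demo/clusters.json` (the top class is smallest and noisiest — 8
particles here — so its mean wanders the most, exactly why the
analysis supports pinning its membership).

The same operations are available as a library; estimators follow
scikit-learn conventions (`fit`, `predict`/`transform`, trailing-
underscore attributes):

```python
from crafruk import simulate, fit_global

curves, truth = simulate.gen_titration(simulate.TitrationSimSpec(seed=7))
fit = fit_global(curves)
fit.kd_, fit.kd_se_, fit.per_curve_[["c", "ymax", "dt_M", "regime"]]
```

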