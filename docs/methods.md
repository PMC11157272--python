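# Methods

This note documents the models implemented in `crafruk`, the choices made
where the underlying experimental protocols leave the analysis open, and
what the synthetic-data generators do and do not emulate.

## Equilibrium binding analysis

A biolayer-interferometry titration reports the equilibrium plateau
signal `Y` of a fixed, immobilized component (DNA-bound Cra at total
concentration `DT`) as a function of titrant (FruK) concentration `L`,
with `X = log10(L / M)` as the working variable so that points are
weighted evenly across the decades a titration spans.

Two models are available:

* **Hyperbolic (non-depleting):** `Y = c + Ymax * 10^X / (Kd + 10^X)`.
  Valid only in the *equilibrium* regime, where binding consumes a
  negligible fraction of the titrant.
* **Quadratic (ligand depletion):** with `a = n + 10^X/DT + Kd/DT`,

      Y = c + Ymax * (a - sqrt(a^2 - 4 n 10^X / DT)) / (2 n)

  the exact solution of the mass-balance equations for `n` binding
  sites.  The discriminant is mathematically nonnegative; round-off can
  drive it slightly negative near stoichiometric equivalence, so it is
  clamped at zero.  Stoichiometry `n` is fixed at 1 by default.

**Regime classification.** An assay is classified by `r = DT / Kd`:
equilibrium for `r <= 0.1`, stoichiometric for `r >= 10`, intermediate
otherwise.  Ratios exactly at a boundary go to the outer regime; nothing
in the analysis depends on this convention, but it is fixed so results
are reproducible.

**Global fitting.** In the intermediate regime `Kd` is only identifiable
by fitting several titrations simultaneously: the fit shares a single
`Kd` (optimized as `log10 Kd` to enforce positivity) while every curve
keeps its own baseline `c`, amplitude `Ymax`, and effective `DT`
(optimized as `log10 DT`, bounded to 1e-14–1e-4 M).  Treating the
per-curve `DT` as free parameters inside one optimization replaces the
manual vary-and-refit iteration sometimes used at the bench; the
objective is the same pooled weighted residual sum of squares, and the
joint optimum can never be worse.  The optimizer is a bounded
trust-region least-squares solver with a multistart over 7 log-spaced
`Kd` values in 1e-12–1e-5 M (flat valleys in `log Kd` are the typical
failure mode of these fits).  Weights default to 1; a per-point SD
column can be supplied.  The `Kd` standard error comes from the Jacobian
at the optimum; a parametric bootstrap (per-curve residual SDs, refits
warm-started at the optimum, percentile interval) is provided for
interval estimates that do not rely on the asymptotic approximation.

Single-curve fits flag non-identifiability when the observed signal span
is less than 20% of the fitted amplitude — such curves never approach
their plateau and constrain `Kd` only weakly.

No active-fraction correction is applied to `DT` (protein preparations
are typically 70–90% active): `DT` is an *effective* concentration, and
a configurable scale factor is the user's responsibility if an absolute
value is needed.  Kinetic (on/off-rate) analysis is deliberately out of
scope: the association records in this system are multiphasic, which is
why the equilibrium-plateau implementation exists at all.

## AFM volumetry

Each measured particle is reduced to a height `h` and two widths at
half-height (`w_long`, `w_orth`).  Its volume is an elliptic cylinder,

    V = pi * h * (w_long / 2) * (w_orth / 2)   [nm^3]

(radii are half the measured widths).  Two rejected alternatives — a
spherical segment (under-estimates) and a rectangular box
(over-estimates) — are not implemented.  The DNA segment adjacent to a
DNA-bound complex is modelled as

    V_DNA = (2/3) * h_DNA * w_DNA^2

and subtracted, leaving the protein-only volume.  This formula is
implemented exactly as stated even though a parabolic cross-section
swept along an independent length would read `(2/3) h w L`; the
segment length is folded into `w^2` by construction, and the choice is
kept for fidelity with the published procedure.  Peaks whose adjacent-
DNA volume exceeds the gross volume are physically impossible
measurements; they are flagged and excluded (never clamped to zero,
which would bias the mass distribution downward).

**Volume to mass.** `m = V * 1e-21 / v̄ * N_A` with the protein partial
specific volume `v̄ = 0.67 ml/g` (derived from solvent-excluded volumes
of the Cra regulatory-domain and ribokinase crystal structures) and the
exact SI Avogadro constant.  The conversion is linear in volume and
inverse-linear in `v̄`, and `mw_to_volume` is its exact inverse.

**Specific volume from a structure.** The solvent-excluded volume of an
atomic model is estimated on a voxel grid: voxels within `r_vdW + probe`
of any atom form the solvent-accessible region, and removing everything
within `probe` of its complement performs the morphological closing of
the van der Waals union by the probe sphere.  The vdW union itself is
counted by the exact per-ball test; the Euclidean distance transform
(with a half-voxel threshold correction for its center-to-center bias)
decides only the re-entrant necks the closing adds, confining the
discretization error to those regions.  Defaults: Bondi radii, probe
1.4 Å, grid 0.5 Å; the estimate converges as the grid is refined (a
single carbon atom reproduces its analytic sphere volume to ~1% at
0.25 Å).  The mass divisor must count only resolved residues; pass
`resolved_mass_da` for structures with missing density.  A utility
recomputes monomer masses from a sequence (average isotopic masses,
unmodified chain); the built-in constants are 37,999 Da (Cra) and
33,756 Da (FruK).

**Reference ladder.** Expected complex masses are integer combinations
of the monomer masses: each homodimer, the dimer-of-dimers
(one Cra + one FruK homodimer, 143,510 Da), and the trimer-of-dimers as
Cra–FruK–Cra (219,508 Da) — the composition implied by the observation
that excess FruK shifts the population toward smaller complexes.

## Stoichiometry clustering

The mass distributions are one-dimensional, and the minimal-WCSS
partition of 1-D data into `k` classes is always contiguous in sorted
order, so "model-free clustering" is realized as an exact dynamic
program (O(k n²) with prefix sums).  Unlike Lloyd-style k-means the
result is deterministic, globally optimal, and invariant to input
order.  The constrained variant pins the top class to exactly `m`
largest observations (the three-class fit of the DNA-bound population
uses `m = 7`) and runs the DP on the remainder with `k − 1` classes.
Whether that published constraint means "member count" admits another
reading (an index); it is implemented as member count and should not be
silently changed.

`choose_k` reports a WCSS elbow table and the BIC of a hard-assignment
equal-variance Gaussian classification likelihood (`2k` parameters: `k`
means, `k − 1` proportions, one variance); it never overrides an
explicitly requested `k`, because the published class counts are fixed
per panel (three classes DNA-bound, two DNA-free).

Class means map to the nearest ladder entry, ties breaking toward the
smaller complex.  All ladder entries within 10% of the class mean are
reported as alternatives and the call marked ambiguous: the Cra and
FruK homodimers differ by ~12% in mass with broadly overlapping volume
distributions, so a class sitting between them genuinely cannot be
assigned, while a class centred on one of them (≈11% from the other)
still gets a unique label.

## Enzyme assay and growth curves

Fold change is the ratio of condition mean to buffer-control mean, with
first-order propagation `fold * sqrt((sd_c/m_c)² + (sd_0/m_0)²)` using
the replicate SDs; replicate counts of 3 are too small for a bootstrap.
When independent experiments are marked, the reported fold is the mean
of per-experiment folds and the SD their spread.  Folds are
scale-invariant by construction.  A single replicate yields no SD
rather than a fabricated zero.

The ATP standard curve is fit log-log linear (the luminescence response
is a power law over the 0.03–4 mM control range); the inverse map flags
readings outside the calibrated range instead of extrapolating
silently.  Concentration dependence is assessed by Spearman rank
correlation with a seeded one-sided permutation p-value (default 10,000
permutations, `(r+1)/(n+1)` estimator), since no specific trend test is
prescribed by the protocol; the permutation null is computed vectorized
on centered ranks.

Growth curves are summarized by the first upward crossing of half the
curve's own maximum OD600, after a 3-point median filter to resist
single-point spikes, with linear interpolation between the flanking
samples.  A series that starts at or above half its maximum has no
upward crossing and is marked unreachable rather than assigned a time.
Delays are differences of half-max times between strains (negative
allowed); unreachable propagates.

## Synthetic-data generators

All generators derive substreams from one integer seed via fixed
offsets, so adding a generator never reshuffles another and fixed seeds
reproduce tables byte-identically.

* **Titrations** default to the global-fit study conditions: ten curves,
  shared true `Kd = 2.0e-9 M`, per-curve `DT` on a deterministic
  log-spaced grid over 0.5–5 nM (guaranteeing the span), baselines
  uniform in 0–0.2 and amplitudes in 0.5–1.5 signal units, and additive
  Gaussian noise of 2% of each curve's amplitude.  The plateau noise
  magnitude is not documented anywhere; 2% of `Ymax` is a configurable
  default chosen so curves of different amplitude are comparably noisy.
* **AFM peaks** draw true masses from a mixture (default: ladder masses
  at fractions 0.4/0.4/0.2, n = 60, matching the measured-population
  scale), convert them to volumes, add the adjacent-DNA volume for bound
  particles, and decompose the total into `(h, w_long, w_orth)` under a
  lognormal aspect model (height ~2 nm, CV 0.2; width ratio ~1.3, CV
  0.15) before applying lognormal per-dimension measurement noise.  The
  generative aspect model is invented — only measured values exist in
  the source data — so recovery tests make claims about the analysis
  chain, not about AFM physics (no tip convolution, no surface
  flattening artifacts).
* **Growth** is logistic with a 30-min sampling interval over 22 h,
  capacity 1 OD, rate 0.8/h, inoculum baseline 0.025 OD, Gaussian noise
  0.01 OD, clipped at zero.  Real diauxic shifts and rate differences
  between strains are not emulated; delay-recovery tests exercise pure
  lag shifts.
* **Plates** produce triplicate wells per substrate level (0.1–15 mM),
  buffer controls, and an ATP calibration series with unit log-log
  slope.  Raw luminescence scale is arbitrary (folds are
  scale-invariant).

Because the per-peak AFM measurements and raw growth series of the
original study are not deposited, the class means and delay values of
that study are *not* reproduced; those stages are validated by
property-based recovery on synthetic data instead, while the binding
constants, the specific-volume constant, and the mass ladder are
reproduced as parameter-recovery or reference-constant computations.

## Problem sizes and numerical choices

The recovery studies behind `scripts/acceptance.py` use: 10 curves × 12
concentrations per Kd condition; 601 grid points for the limit check;
60 noiseless peaks for the round trip; 100 random instances (n ≤ 15,
k ≤ 4) for the clustering oracle; 200 simulation replicates of 4-curve
sets with 80 bootstrap refits each for interval coverage (4 curves keep
the 31-parameter fits of the headline condition down to 13 parameters,
which is what makes a 16,000-fit coverage study routine on one core);
six injected lags for delay recovery; and a 301-atom synthetic globule
at 0.4 Å grid for the specific volume.  Multistart counts drop from 7
to 3 inside simulation loops, where the starting values are already
well-informed.

Known limitations: the depleting model assumes one class of independent
sites (`n` fixed); the bootstrap assumes Gaussian residuals; the SES
estimator is a voxel method, not an analytic surface triangulation, and
its necks carry the grid error; `choose_k`'s BIC uses a hard-assignment
likelihood, which is a diagnostic, not a mixture fit.
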