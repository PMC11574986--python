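# Methods

`chemocal` implements a chemometrics-assisted UV-spectrophotometric
workflow for quantifying three co-formulated drugs — montelukast (MON),
rupatadine (RUP) and desloratadine (DES) — whose zero-order spectra
overlap too severely for univariate analysis. Four model variants are
supported: PLS-1, GA-PLS, ANN and GA-ANN (PLS-1 or a linear neural
network, each with or without genetic-algorithm wavelength selection).
Because no instrument spectra ship with the package, a synthetic
spectral generator reproduces the qualitative structure of the system
and serves as the test bed for every stage.

## Calibration design

The calibration set is a five-level, three-factor cyclic design of 25
mixtures. Each analyte concentration takes coded levels in
{−2, −1, 0, +1, +2}; mixture 1 is the all-center point and, for runs
2–25, factor *j* follows a fixed base sequence of 24 coded levels
rotated left by *j* − 1 positions. This makes every factor column
perfectly balanced (each level exactly 5 times) and keeps adjacent
factors nearly uncorrelated. With center levels (11, 15, 12) µg/mL and
steps (4, 5, 4) µg/mL the realized ranges are 3–19, 5–25 and 4–20 µg/mL
for MON, RUP and DES. The base sequence is hard-coded: the package's
contract is to reproduce the published 25-mixture table cell for cell,
not to re-derive the design from first principles. The same
rotate-by-one rule generalizes to other factor counts; that extension
is ours and is untested against any external reference.

The validation set is a fixed list of 10 mixtures (ids 26–35) spanning
the calibration ranges, including two binary mixtures (one with no DES,
one with no RUP) that emulate the two-drug commercial tablets.

## Synthetic spectra

Mixture spectra follow the Beer–Lambert law on a 200–400 nm grid at
1.0 nm (201 points): absorbance is the concentration-weighted sum of
pure-component absorptivity curves, plus additive white Gaussian noise,
clipped at a detector saturation limit. Pure components are sums of
Gaussian bands (center, width, peak absorptivity per µg/mL); Gaussian
rather than Lorentzian shapes were chosen for simplicity, as solution
UV bands are broad and the downstream models are shape-agnostic.

The default phantom components encode the structure that makes this
problem interesting:

* the MON-phantom has an isolated band at 350 nm — a clean spectral
  handle — plus a band at 270 nm inside the crowded region;
* the RUP- and DES-phantoms absorb only in 230–295 nm with
  near-coincident bands; their pure spectra have cosine similarity
  ≈ 0.988 on 221–300 nm, and both are < 0.2 % of their own maxima above
  300 nm;
* all three share a strong far-UV band near 205 nm, so every
  calibration mixture saturates below 221 nm at the default 3.0 AU
  limit — reproducing the practical reason the modelling windows start
  at 221 nm — while no point at or above 221 nm saturates.

Defaults: `noise_sd = 0.002` AU (a realistic noise floor for a bench
double-beam instrument at ~1 AU signal) and `saturation_limit = 3.0`
AU. Noise streams are derived per sample from the global seed by
counter offset, so a sample's noise depends only on (seed, sample
index), never on how many rows are simulated.

What the generator does *not* emulate: stray light, wavelength drift,
baseline drift, band-shape nonlinearity at high absorbance, or
inter-day variance. Passing tests therefore demonstrate correctness of
the algorithms under ideal-instrument assumptions, not performance on
real spectra; in particular the published LV counts (2/6/6), GA
reductions (48/26/30 points) and per-mixture recoveries depend on the
real spectra and are not reproduction targets.

## Wavelength windows and preprocessing

Windows are inclusive on both ends: 221–400 nm yields 180 inputs (used
for MON) and 221–300 nm yields 80 (RUP, DES) — the only reading
consistent with the published input counts. Matching is exact on the
1.0 nm grid; no interpolation. X and y are mean-centered before PLS and
GA fitness (standard PLS practice; exposed as the `mean_center`
primitive). No smoothing or derivative preprocessing is applied.

## PLS-1

One model per analyte, via NIPALS with deflation of X only. For a
single response the NIPALS power iteration collapses to a closed form
(w ∝ Xᵀy per component), so each component is exact and deterministic;
iteration-count and tolerance guards (500, 1e−12) remain as safety
rails. The regression vector is b = W(PᵀW)⁻¹q and prediction is
ŷ = ȳ + (x − x̄)ᵀb.

The LV count is selected by leave-one-out cross-validation over
1…A_max (default 10): the count with the lowest RMSECV wins, ties going
to fewer LVs. Inside the LOO loop a single decomposition to A_max
components supplies all truncated models. Rank-deficient training data
(exact on noiseless low-rank spectra) is handled by capping at the
effective rank inside CV scans — the RMSECV curve is flat beyond the
rank — while a direct `fit_pls1` call with an unreachable LV count
raises a deflation-collapse error.

## Genetic-algorithm wavelength selection

Chromosomes are binary vectors over consecutive non-overlapping windows
of 2 grid points (a trailing shorter window absorbs any remainder).
Fitness is the random-subset cross-validated RMSE of PLS-1 restricted
to the on-windows: 4 subsets, 2 iterations per generation, with the LV
count chosen by inner argmin capped at the analyte's PLS-1 complexity
(2 for MON, 6 for RUP/DES). The two iteration curves are averaged
before the argmin. Folds are drawn from a generation-indexed seeded
stream: within a generation all chromosomes compete on identical folds,
and a run is exactly reproducible from its seed.

Selection is truncation ("survival of the fittest"): the better half
survives, the other half is refilled by single-point crossover of
randomly paired survivors, and offspring genes flip independently with
probability 0.005. Mutation is applied to offspring only; survivors
pass unchanged, which together with separate best-ever bookkeeping
makes the reported fitness trace non-increasing and a fully converged
population a fixed point at zero mutation. All-off chromosomes are
repaired at initialization (one random window switched on) and score
infinite fitness if mutation produces one later. The run stops at the
generation cap (50) or when the configured fraction of the population
(100 %) shares one chromosome. Defaults follow the reference settings:
population 50 (20 for DES), 50 % of windows on at initiation.

## Linear ANN

A single-hidden-layer feed-forward network with identity (purelin)
transfer in both layers — deliberately an affine map, matching
Beer–Lambert linearity. Inputs and targets are min–max scaled to
[−1, 1] on the calibration set (the convention of the instrument-era
toolboxes); the scaling is stored in the model so predictions accept
raw absorbance.

Training is Levenberg–Marquardt on the full-weight Jacobian of the
calibration residuals: solve (JᵀJ + µI)δ = −JᵀR; accept the step if the
SSE drops and multiply µ by 0.001, otherwise multiply µ by 100 and
retry, capping µ at 1e10. The µ parameters (0.001 / 0.001 / 100) mirror
the reference configuration; the decrease factor is aggressive relative
to common defaults and is kept configurable. A singular damped system
at some µ is treated as a rejected step (more damping is tried); only
singularity persisting to the µ cap raises a training failure, while a
cap reached with no downhill step means convergence.

Early stopping uses the 10-mixture validation set as monitor: training
halts when validation RMSE has risen for `patience` (default 6,
MATLAB-style `max_fail`) consecutive epochs while calibration RMSE
fell, and the weights from the epoch with minimal validation RMSE are
returned. **Consequence, stated prominently:** in the ANN variants the
validation set participates in training, so ANN validation statistics
are not computed on fully independent data. The PLS variants never
touch the validation set during fitting.

The hidden-neuron count is scanned over candidates (default 1, 3, 5,
8, 15); the count with the lowest validation RMSE wins, near-ties
(within numerical noise) resolving to the smallest network. For a
linear network any hidden count ≥ 1 spans the same function class, so
on noiseless data the scan ties and selects 1.

## Figures of merit

* Recovery % = 100 · predicted/actual; undefined (NA) when the true
  concentration is zero, and NA samples are excluded from means, SDs
  and RMSEP. Mean recovery and SD use the n − 1 denominator;
  RSD % = 100 · SD/mean.
* RMSEC/RMSECV/RMSEP = √(Σ(ŷ−y)²/n) with denominator n and no
  degrees-of-freedom correction. Both conventions (n − 1 SD, 1/n RMSE,
  NA exclusion) were validated by recomputing the published summary
  rows from their own per-mixture recovery columns.
* Predicted-vs-actual line by ordinary least squares with Pearson r.
* Method comparison from summary statistics: two-sided pooled-variance
  Student's t (df = n₁ + n₂ − 2) and the variance-ratio F test with the
  larger variance in the numerator, both at P = 0.05. Critical values
  come from scipy's t and F distributions.
* Assay acceptance constants: mean recovery within 100 ± 3 % and
  RSD ≤ 2 %.

## Reproduction of the reported tables

`chemocal reproduce-tables` recomputes, from the package's own
primitives, (a) all 105 design/validation concentration cells, (b) the
mean/SD/RMSEP rows under the twelve published recovery columns and
(c) the eight t and eight F statistics of the dosage-form comparison.
Tolerances reflect that the published inputs are rounded: mean/SD cells
are compared at one ulp of the printed 2 d.p. digit (0.01 — two summary
cells were visibly truncated rather than rounded), RMSEP and F cells at
0.002, t cells at 0.02. One published cell (GA-ANN DES RMSEP, 0.010) is
internally inconsistent with its own recovery column (which implies
≈ 0.1); it is flagged as a mismatch rather than reproduced.

## Problem sizes and determinism

The shipped defaults are the study conditions themselves: 25 + 10
mixtures, 180/80-point windows, GA population 50/50/20 over 50
generations, LM training to at most 1000 epochs. The planted-signal GA
benchmark uses 80 columns (40 windows, 11 carrying signal), 16 training
and 20 held-out samples, population 50 over at most 100 generations
with mutation 0.01 — sized so that signal recovery is reproducible
across seeds. End-to-end runs are deterministic given the global seed:
per-analyte seeds are derived arithmetically, GA fold draws are
generation-indexed, and simulation noise is per-sample counter-offset.

## Known limitations

* The phantoms are qualitative stand-ins; no claim is made that they
  match the real MON/RUP/DES absorptivities.
* Only the purelin-purelin transfer pair is implemented; the nonlinear
  pairs the reference workflow rejected are out of scope.
* GA uses truncation selection with single-point crossover only; no
  roulette/tournament selection, double crossover or adaptive mutation.
* The t/F comparison operates on summary statistics; raw dosage-form
  replicates are out of scope.
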