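# Methods

## Model

Each displacement **d** of a tracked cell over one analysis interval Δt
(default 40 min) is modelled as the sum of three vectors:

* **random** r — isotropic, with a population-wide mean squared modulus
  (the "random MSD", μm² per interval) and no memory between steps;
* **persistence** p·û(prev d) — fixed module p (μm per interval) along the
  unit direction of the cell's previous displacement;
* **bias** b·û(β) — one constant vector (module b μm per interval,
  direction β) shared by every cell, representing a uniform directional
  stimulus.

Assumptions worth keeping in mind: the random module is the same for all
cells and steps; the bias is constant in space and time within the
analysed window (time variation is addressed by windowing, not by the
model); persistence acts on the direction of the previous *total*
displacement, not on its random part only.  The model is 2D and assumes
regular sampling at Δt.

## Estimation procedure

1. **Raw bias.**  β is the direction of the arithmetic mean of all
   displacement vectors (all cells, all steps — including first steps,
   which carry no persistence asymmetry in expectation).  The modulus of
   that mean is the *raw bias*, the naive estimate that conflates bias
   and persistence.
2. **Projection.**  For every step with a defined predecessor direction,
   d_b = |d|·cos(θ_d − β) and α = wrap(θ_prev − β).  First steps of a
   track and steps following a zero-length displacement are excluded
   (their α is undefined).
3. **Regression.**  d_b = b + p·cos(α) is linear in (b, p) and is fitted
   by ordinary (unweighted) least squares; standard errors come from the
   OLS covariance with residual variance on n − 2 degrees of freedom.
   Neither parameter is sign-constrained: with a near-zero true value,
   sampling noise legitimately produces small negative estimates, and
   reporting them unclipped keeps the estimator unbiased.
4. **Random vectors.**  r = d − b·û(β) − p·û(prev d) per used step; the
   reconstruction d = b·û(β) + p·û(prev d) + r is exact by construction.
   The mean module r̄ of the random vectors normalises p and b when
   comparing cell lines (p/r̄, b/r̄).

β is estimated once per analysed window and the regression is run in a
single pass (no re-estimation of β after stripping persistence); per-cell
bias directions are out of scope.

## MSD analysis

The MSD curve uses every lag τ = mΔt up to the longest path duration and
all overlapping start times within each track, recording per-lag counts.
Overlapping windows maximise the counts that the weighting scheme below
relies on; the estimates at different lags are consequently correlated,
which inflates seed-to-seed scatter relative to the nominal fit errors
(see Caveats).

Two models are fitted by weighted nonlinear least squares
(`scipy.optimize.curve_fit`, weights ∝ counts, standard errors from the
residual-scaled covariance):

* **Power law** MSD = k·t^α, fitted on the original scale over *all*
  lags.  Initialisation k₀ = MSD(Δt)/Δt, α₀ = 1.
* **Fürth** MSD = 2S²P[t − P(1 − e^(−t/P))], S, P > 0 (enforced by
  bounds), initialised at P₀ = Δt, S₀ = √MSD(Δt)/Δt, with up to five
  jittered restarts on non-convergence.  By default the fit uses only
  the **first five lags** (200 min at Δt = 40).

The Fürth lag restriction is a deliberate asymmetry.  P is identified by
the curvature of the MSD at lags of order P; beyond a few persistence
times the model is a straight line.  Whenever the data contain any
ballistic component — most importantly a directional drift, whose MSD
grows as t² — the long-lag tail dominates an unrestricted weighted fit
and drives P towards the ballistic regime (on a pure-drift population the
unrestricted optimum exceeds 4000 min, with nothing in the data to pin it
down).  Restricting the fit to the short-lag region keeps P a stable,
comparable statistic across populations; it is exactly this short-lag P
that the quadratic relation below describes.  `max_lags=None` restores
the full-curve fit, which parameter-recovery tests use on data generated
from the model itself.

## Windowed analysis and the persistence relation

`windowed_analysis` slides a window (default 4 h, stepped by Δt) along
the experiment; within each window the tracks are clipped, decomposed,
and summarised as average step length, r̄, p/r̄ and b/r̄.  Windows
yielding fewer than `min_steps` regression steps (default 30 — roughly
the point where the OLS standard errors become uninformative) are omitted
with a logged warning rather than reported.

`persistence_relation` compares time-persistence with vector-persistence
across datasets: per dataset x = p/r̄ and y = P/Δt, fitted as the pure
quadratic y = a·x² (closed form a = Σx²y/Σx⁴; no intercept or linear
term, as a single-coefficient second-power law; R² is computed against
the zero baseline, the consistent choice for a no-intercept model; the
fit is unweighted across datasets).  On unbiased simulated suites a ≈ 2
with R² close to 1; biased populations sit systematically above the
curve because their Fürth P absorbs the drift while their p does not —
the quickest visual diagnostic for bias contamination of a persistence
estimate.

## Synthetic populations

The simulator generates what the analysis assumes, plus realistic
step-length dispersion:

* the random component of each step is a mini random walk of
  `n_substeps` (default 10) sub-steps, each of fixed module
  √(MSD/n_substeps) and independent uniform direction, so E|r|² equals
  the requested MSD exactly for any sub-step count while the modulus of
  the resultant is spread (asymptotically Rayleigh, mean √(π·MSD/4) —
  8.86 μm for MSD = 100 μm²; `mean_module_to_msd` converts between the
  two parameterisations).  A single fixed-module random vector per step
  would make every step length identical, which real data never are;
* persistence adds p·û(previous total displacement) from the second step
  on — a cell's first step has no predecessor and hence no persistence
  term (this affects one step per track and is visible in nothing but
  the step count);
* the bias vector is added to every step.

Default population: 30 cells × 36 steps of 40 min (a 24-h experiment at
the standard analysis interval), started on a grid (start positions are
irrelevant to every statistic computed here).  Each cell draws from an
independent RNG stream spawned from (seed, cell index), so identical
seeds give bit-identical populations and enlarging the population leaves
existing trajectories unchanged.

What the simulator does *not* emulate: growth, division, death,
cell–cell contact, spatially or temporally varying bias, per-cell random
modules, localisation noise, and track fragmentation.  Passing tests on
these populations therefore validate the estimators under the model's
own assumptions; they do not certify behaviour on data violating them
(e.g. heterogeneous populations or drifting stages).

## Numerical choices and degenerate inputs

* Coordinates are mathematical (x right, y up, angles counterclockwise,
  radians internally, degrees at the CLI); `image_y_down=True` negates y
  when reading image-convention files.
* Time is authoritative; frames are bookkeeping.  Resampling keeps every
  k-th frame from each track's first frame and *splits* tracks at gaps
  instead of interpolating — fabricated steps would bias both the MSD
  and the regression.
* Zero-length displacements make the following step's α undefined; such
  steps are excluded from the regression, like first steps.
* A zero mean displacement vector leaves β undefined; it is reported as
  degenerate with β = 0 and no δ angle.
* The δ angle (estimated vs expected migration direction) is the minimal
  absolute angular difference, in [0°, 180°].
* `%.17g` float formatting plus round-trip parsing makes track-file I/O
  bit-exact.

## Problem sizes

The validation suite and the reproduction script run populations of
10–100 cells × 36 steps with 3–10 replicate seeds per quantity —
matching the population sizes the estimators are characterised on, where
every run takes well under a second.

## Caveats

* Overlapping-lag MSD values are strongly correlated, so fitted standard
  errors for k, α, S, P understate replicate-to-replicate spread;
  compare replicate means, not single-fit CIs, across conditions.
* The Fürth P of a bias-contaminated population is reported for
  diagnosis, but it is not a persistence measurement: its value depends
  on the fitted lag range precisely because the model does not describe
  such data.  Use the decomposition's p instead.
* The decomposition estimates a single global (b, β) per window; a
  spatially varying stimulus (e.g. cells on both sides of a wound
  analysed together) must be split into regions first.
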