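# Methods

This note records the models, numerical choices, and design decisions
behind `mlpi`, in the spirit of a model-documentation page: what is
computed, under which assumptions, and what the tests do and do not show.

## The PI growth model and its solver

Tumor cell density `c(x, t)` (a fraction of carrying capacity, so
`c ∈ [0, 1]`) obeys the Proliferation-Invasion equation

    ∂c/∂t = ∇·(D(x) ∇c) + ρ c (1 − c),

with `D(x)` piecewise constant over tissue classes (white and gray
matter; `D_gray = D_white/10` by default, the conventional contrast) and
no flux across the brain/non-brain boundary.

The solver is explicit forward Euler with central-difference fluxes and
harmonic-mean interface diffusivities.  This is deliberately the simplest
scheme whose behavior is fully checkable: the stability bound
`dt ≤ h²/(2·ndim·max D)` is enforced (violations raise), the flux form
telescopes so pure diffusion conserves mass to round-off, a spatially
uniform field reduces exactly to the logistic ODE, and the 1D traveling
front approaches the Fisher-KPP speed `2√(Dρ)` from below.  The solver is
dimension-agnostic (1D strips through 3D volumes).

Numerical caveats, verified in the tests and reflected in defaults:

* The front's intrinsic width is `√(D/ρ)`.  On grids that under-resolve
  it, discrete fronts travel measurably slower than `2√(Dρ)`; the
  front-speed and calibration checks therefore run at 0.2 mm spacing
  (width ≈ 5 voxels), where the measured speed is within 5% of the
  asymptote.  The measured speed also carries the slow `O(1/ρt)` transient
  of KPP fronts, so speed is measured over the last half of a long run.
* The initial condition is a Gaussian bolus (peak 0.8, SD 1 voxel by
  default) rather than a single-voxel delta, avoiding a grid artifact.
  The bolus width is specified in voxels; grid-convergence comparisons
  must hold its physical width fixed (`bolus_sigma_voxels` scales with
  resolution).

### Patient-specific rate calibration

Clinical practice estimates `(D, ρ)` from two abnormality radii: the
T1Gd-enhancing rim (high density threshold, default 0.80) and the T2W
abnormality edge (low threshold, default 0.16).  The realization here is
the traveling-wave argument: the minimal-speed Fisher-KPP profile (solved
once as a nondimensional boundary-value problem along the unstable
manifold of the invaded state) gives the dimensionless separation of the
two threshold crossings; the physical width `r_T2 − r_T1Gd` then pins
`√(D/ρ)`, and a supplied front velocity pins `√(Dρ)` via `v = 2√(Dρ)`.
This is a faithful stand-in for radius-based calibration, not a bit-level
reproduction of any clinical pipeline (whose internals are not public);
the simulate→measure→recalibrate round trip in the tests recovers `D`
within ~8% and `ρ` within ~2%.

## Features

Every sample is the pair `(z, PI)` of 8×8 in-plane box means: one mean
intensity per image channel plus the mean PI-predicted density.  An
even-sized box "centered" on a voxel is ambiguous, so the convention is
the half-open span `[c−4, c+4)` per axis (boxes tile the grid exactly at
stride 8); all coordinates are 0-based.  Boxes that would leave the image
cause the sample to be skipped with a warning, never silently truncated.
Channels are z-scored within the brain mask per patient before modeling
(raw MR intensities are scanner-scale-arbitrary and the graph distances
need commensurate channels); this can be disabled.

Unlabeled samples are taken per slice — one representative slice per
patient, every ROI voxel at a configurable stride — matching how a
radiologist-segmented slice is used in practice.

### Synthetic biopsies

Real biopsies oversample dense tissue.  To debias the label distribution,
up to 6 training-only labeled samples per patient are planted where the
PI box mean falls below 0.2, spaced at least two box widths from each
other and from real samples.  No pathology exists at these locations, so
the assigned label is the PI box mean itself — the model's expectation
for a region chosen *because* it is expected to be low density.  This
label choice and the placement rule are reconstructions (no published
rule exists); both are logged at run time, and synthetic samples are
flagged so they can never enter any evaluation metric (asserted in
tests).

## The hybrid objective and its closed form

With `L` labeled and `U` unlabeled samples, the predictor minimizes

    (1/L) Σ_l (y_l − f(x_l))² + γ_A ‖f‖²_K + (γ_I / Σ_ij w_ij) fᵀΩf

over an RBF reproducing-kernel space, where `Ω` is the Laplacian of the
dense sample graph with product-Gaussian weights (image factor with
bandwidth `ψ_z`, PI factor with bandwidth `ψ_PI`).  Substituting the
representer expansion `f = Σ α_i K(x_i, ·)` gives the linear system

    (J K + γ_A L I + (γ_I L / Σ w_ij) Ω K) α = J y,

with `J = diag(1 labeled, 0 unlabeled)` and `K` the `(L+U)²` Gram matrix
on `x = (z, PI)`.  Unlabeled entries of `y` are zeros and are masked by
`J`.  Rather than relying on a derivation alone, the tests verify the
solution directly: on random small instances the closed form attains the
objective value of a generic numerical minimizer, and with `γ_I = 0`,
`U = 0` it coincides with scikit-learn's kernel ridge regression to
1e-8.

Numerical choices:

* `ψ_z`, `ψ_PI` default to the median heuristic (median pairwise
  distance over the training samples), overridable.
* The system is solved directly; if the solve fails or returns
  non-finite values (possible at the `γ_A = 10⁻¹⁰` grid corner), it is
  retried with a 1e-10 diagonal jitter, logged.
* Predictions are clipped to `[0, 1]` for maps and metrics (density is a
  fraction; the kernel expansion is unbounded); raw values remain
  available.

A practical property worth stating: the model is *transductive*.
Predictions are well controlled at (and near) training samples; at
feature-space locations far from any training sample the expansion can
oscillate when `α` is large (small `γ_A`, large `γ_I`).  Density maps are
therefore predicted over the same ROI voxels that serve as unlabeled
samples, which is also how the method is meant to be deployed.

## Evaluation and tuning

Both metrics tolerate a ±5% margin for pathological measurement error: a
prediction within the margin counts as exactly correct.  For MAPE this
zeroes the per-sample absolute error; for Pearson the margin semantics
are unstated in the method's description, and the minimal consistent rule
is used — snap within-margin predictions to the measured value, then
correlate (a documented choice).

Validation is leave-one-patient-out: the supervised loss term never
contains the target patient's real or synthetic biopsies; the target
patient's *unlabeled* samples do participate in the graph by default
(transductive use of unlabeled data is the method's point; configurable).
Scoring uses only real biopsies.

The tuning grid spans `γ_A, γ_I ∈ {10⁻¹⁰, …, 10⁴}`, `η ∈ {10⁻¹, …, 10²}`
at integer decades (15 × 15 × 4 points); the grid *step* is a choice —
only the endpoints are given by the method — and is configurable.
Phantom-scale studies use the every-third-decade subgrid
(`TuningGrid.coarse()`, 6 × 6 × 4 points), which keeps a full five-cohort
study under a minute while spanning the same range.  Three strategies
select parameters from per-patient prediction tensors computed once:

* **patient-specific** — independent argmin per patient on that
  patient's own real biopsies (as the method specifies; the docs flag
  this as optimistic since it requires the target patient's biopsies for
  selection);
* **uniform** — one global argmin of the pooled MAPE;
* **partially-uniform** — two parameters global, one free per patient.

By construction the pooled errors nest: patient-specific ≤ each
partially-uniform ≤ uniform.  Grid ties are broken toward the least
complex model (smallest `γ_I`, then `γ_A`, then `η`) — a choice, since no
tie rule is published.  The three-way comparison fits the ML baseline
with `γ_I = 0` and no unlabeled samples; the PI baseline needs no fit
(its prediction is the PI box mean).  Paired significance uses a
two-sided Wilcoxon signed-rank test on per-sample margined absolute
errors (the test statistic is unnamed in the method's description; this
is a documented choice).

## Relief attribution

Each feature's score is the difference of two conditional probabilities —
that the feature separates neighbor pairs with *different* model
predictions vs pairs with *similar* ones.  The estimator (unspecified in
the method's description, reconstructed RReliefF-style) takes each
sample's `r = 10` nearest neighbors by graph edge weight, splits pairs at
a prediction-difference threshold `τ = 0.05` (the margin scale), and
accumulates range-normalized absolute feature differences into the two
conditional means; scores lie in `[−1, 1]`.  Per patient, scores are
floored at zero and normalized to sum to one (reported contributions are
non-negative shares); the aggregated profile is the sum of per-patient
shares.  Relief runs on each patient's deployed (leave-one-patient-out,
patient-specifically tuned) model over that patient's own samples.

## The phantom generator

Phantoms exist so that every stage is testable without clinical data.
Each 64×64 phantom patient (2D for speed; the API is dimension-agnostic)
has: a circular brain of gray matter crossed by random white-matter
bands; a PI field grown from a seeded bolus with patient-specific
`(D, ρ)` (D_white ∈ [20, 60] mm²/yr, ρ ∈ [10, 20] /yr) until the
abnormality covers ~25% of the brain; a ground truth equal to the PI
field warped by smooth multiplicative noise (`blend_weight` sets the
PI share of the truth signal — at 1 the warp vanishes); six channels,
each a monotone response of true density (one decreasing, emulating mean
diffusivity) plus a tissue offset, spatially correlated noise, and an
arbitrary per-channel gain/offset; biopsies drawn with probability
∝ `exp(bias_strength · density)` (emulating acquisition bias toward
suspected tumor), labeled with the truth box mean plus N(0, 0.03²)
pathological noise; BAT flags where the PI box mean is below the 0.80
enhancement threshold; and an ROI covering the density abnormality.

Defaults worth justifying:

* **label noise 0.03** — the scale of pathological density-estimation
  error; configurable.
* **channel noise 0.35** (relative to the roughly unit-range density
  response) — keeps each channel's correlation with density
  weak-to-moderate (~0.6–0.8), matching how loosely any single MR
  intensity tracks cellularity.  Much cleaner channels would make every
  channel an almost noiseless density readout, which real sequences are
  not — and would make feature-attribution questions degenerate, since
  all features would carry identical information.
* **biopsies per patient 2–14**, cohort defaults mirroring an
  image-localized biopsy cohort's spread.

What the phantoms do **not** emulate: MR physics, real anatomy,
registration error, partial-volume effects, inter-scanner variation, or
non-monotone intensity-density relationships.  Passing the phantom
studies demonstrates that the machinery is correct and that the hybrid's
designed advantage materializes under its own assumptions — it is not
evidence of clinical accuracy, and the headline clinical numbers of the
original study cannot be reproduced here because that cohort is not
redistributable.

## Problem sizes in the standard studies

The acceptance studies use five 10-patient cohorts (6 biopsies per
patient, `blend_weight` 0.5, 25 unlabeled samples per patient in the
graph) for the model comparison and tuning-nesting checks, and five
8-patient cohorts at `blend_weight` 0.9 for the Relief check — sizes
chosen so a full run stays comfortably within a desktop minute while
leaving the statistical orderings stable across seeds.

## Known limitations

* Calibration assumes homogeneous-tissue traveling-wave geometry; real
  lesions in heterogeneous tissue only approximate it.
* The patient-specific tuning strategy scores on the target patient's
  own labels, as specified — an optimistic protocol, flagged above.
* The dense graph scales quadratically in `L + U`; large ROIs should use
  the `max_unlabeled` subsampling cap (uniform spatial subsampling,
  logged).
* Relief scores depend on the reconstructed estimator's `r` and `τ`;
  rankings, not magnitudes, are the supported output.
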