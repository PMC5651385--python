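# Methods

## Model

The classifier is a Bayesian model average over 19 soft-margin linear SVMs
that differ only in their cost hyperparameter C. For a training table D
(n subjects × p voxels, labels patient = 1 / control = 0), member c has
primal solution (w<sub>c</sub>, b<sub>c</sub>) of

min ½‖w‖² + c Σ<sub>i</sub> ξ<sub>i</sub>  s.t.  s<sub>i</sub>(w·x<sub>i</sub> + b) ≥ 1 − ξ<sub>i</sub>, ξ<sub>i</sub> ≥ 0,

with s<sub>i</sub> = ±1 and patients on the positive side. Scores are mapped
to probabilities with the parameter-free logistic link p = σ(w·x + b). This
keeps the training log-likelihood LL(D|C) = Σ y log p + (1−y) log(1−p) a
pure function of the SVM fit, which matters because LL(D|C) doubles as the
model evidence below. A Platt-style link (slope/offset fitted on training
scores by 1-D logistic regression) is available via `link="platt"` for
sensitivity analysis; it is not the default because a calibrated link makes
the likelihood partially a function of the calibration rather than of C.

### Cost grid

* **C_mu** — minimum cost with zero training errors. Search: doubling (or
  halving) bracket from C = 1, then bisection in log space to 1% relative
  tolerance. The search floor is 1e-4 and the cap 1e8: on symmetric
  separable data the sign-error count is zero for arbitrarily small C, so
  without a floor "minimum" is ill-defined. The zero-error set turns out not
  to be contiguous from below — isolated zero-error pockets at low cost
  occur in practice — so the result is verified at probed larger costs
  (2×, 10×, 100×) and the bracket resumes above any cost that still errs.
  This matches the definition "zero errors here and at every probed larger
  cost" rather than "first zero-error cost".
* **C_max** — minimum cost at which LL(D|C) plateaus. 40 log-spaced
  candidates over [C_mu, 1e4·C_mu]; the raw profile is smoothed with a
  length-3 median filter (endpoints pass through unchanged — the filter
  exists to remove isolated solver-noise spikes, and shrinking the window at
  the ends would let a noisy endpoint dominate); the first candidate within
  tol_flat = 1e-6·max(1, |max filtered LL|) of the filtered maximum is
  taken. When C_mu sits at the search floor the fixed relative span can end
  below the plateau, so the default scan auto-extends at the same log
  density up to the 1e8 cap before raising; an explicitly supplied candidate
  array is never extended and errors instead, so audits see exactly the
  profile they asked for.
* **Grid** — C_mu + Δ·i/9, i = −9…9, Δ = C_max − C_mu. Whenever Δ ≥ C_mu
  the lower arm goes non-positive; those values are clipped to 1e-6·C_mu
  and flagged (a warning plus a per-value `clipped` mask) rather than
  re-spacing the grid, preserving the linear formula and the center/top
  anchors.

### Bayesian weighting

The prior is a Gaussian centred at C_mu with SD Δ/2, evaluated at the
*unclipped* formula positions and normalized, which collapses to the fixed
shape w(i) ∝ exp(−2(i/9)²) — invariant to C_mu and Δ, maximal 0.0918 at the
center, 0.0274 at i = +7. Evaluating at unclipped positions means clipping
never distorts the weight pattern. Δ = 0 (all members identical) yields
uniform weights with a warning. The posterior p(C|D) ∝ exp(LL)·p(C) is
computed after shifting LL by its maximum; with ~50 training subjects
exp(LL) underflows otherwise. The shift leaves the posterior exact; the
evidence is therefore reported on the shifted scale together with the shift.
A point-mass prior reduces the ensemble exactly to one member's thresholded
prediction, which the tests use as a consistency check.

Ties at H = 0.5 predict control (strict inequality), and a score of exactly
0 in the training-error count likewise counts as a control prediction.

## Cross-validation design

Folds are stratified per class: each class is shuffled by a seeded generator
and dealt round-robin, so per-class fold sizes differ by at most one (e.g.
32/36 subjects at k = 5 give patient folds {7,7,6,6,6} and control folds
{8,7,7,7,7}). The cost grid and all 19 members are recomputed from scratch
for every training fold. Iteration metrics are computed on the pooled
out-of-fold predictions — each subject exactly once per iteration — rather
than averaging per-fold metrics; with either reading the point estimates
agree in expectation and pooling has lower variance. Iteration t uses seed
base_seed + t, so two feature tables run with the same base seed share fold
allocations exactly; `compare_measures` refuses unpaired comparisons.

β_σ uses the population denominator (divide by the number of iterations,
not N−1), matching the aggregate definition it implements. β_+/β_− count
strictly positive/negative β_I per voxel; exact zeros belong to neither.

## Synthetic cohorts

`generate_cohort` emulates what the real pipeline sees *after* masking and
extraction: control values i.i.d. Normal(μ₀, σ²) with μ₀ = 1.0 and σ = 0.1
(a plausible mean-kurtosis-like scale; the classifier is scale-equivariant
up to the cost anchors, so the choice is cosmetic), and patients shifted
down by d·σ at a designated random subset of voxels (defaults: 32/36
subjects, 500 voxels, 10% discriminative, d = 2). Patients-lower is the
default direction so recovered coefficients at true voxels are negative;
a flag flips it. Voxels are spatially independent and homoscedastic — no
spatial autocorrelation, no per-subject global offsets, no site or motion
artefacts — so passing tests demonstrate the machinery recovers planted
linear structure, not that clinical cohorts of this size will reach any
particular accuracy. `generate_volume_fixtures` plants the same features at
known grid locations with white-matter probability 0.3 and atlas label 1
exactly there, making mask-and-extract an exact round trip.

## Numerical choices

* SVM solver: libsvm (scikit-learn `SVC`) on a precomputed linear Gram
  matrix shared across all cost evaluations of one training set; the
  recovered primal coefficients are identical to a direct linear-kernel fit.
  Tolerance 1e-6, iteration cap with an explicit failure.
* Probabilities clipped to [1e-12, 1−1e-12] so LL stays finite.
* Prior/posterior normalization asserted to 1 ± 1e-12.
* Feature standardization is off by default (voxels of one measure share a
  physical unit); optional z-scoring uses training-row statistics only and
  folds the scaling back into the coefficients.

## Problem sizes in the test suite

The end-to-end recovery checks run two 50-iteration experiments at the
default cohort scale (68 subjects × 500 voxels, d = 2 and d = 0 sharing
subjects and seeds, so the null arm doubles as the paired comparison's
second "measure"); anchor-search oracle checks use 22-subject, 20-voxel
cohorts with a 200-point dense grid. These sizes make the suite complete in
about a minute while leaving every statistical margin wide (the d = 2
condition classifies essentially perfectly; chance-level behaviour at d = 0
is tested against the band [0.35, 0.65]).

## Known limitations

* The plain logistic link applies no score normalization; members with very
  different ‖w‖ are calibrated only through the cost grid itself.
* C_mu requires linear separability of every training fold; with p ≫ n this
  holds in practice, but heavily regularized regimes (n > p) may error out.
* Metrics with a missing class in the test pool are reported as NaN with a
  warning, never silently zero.
* The win-count comparison treats exact metric ties as "tie" and counts
  only strict wins.
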