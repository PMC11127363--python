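# Methods

## Model

`phrflow` models the distribution of *unaffected* participants' feature
vectors `x ∈ R^d` conditional on demographics `c = (age, gender) ∈ R²`
with an invertible map `z = f_θ(x | c)` and a diagonal-normal base
distribution `p_Z(·; ψ)`. The exact change of variables

    log p_X(x; θ, ψ) = log p_Z(f_θ(x | c); ψ) + log |det ∂f_θ/∂x|

is maximized over the unaffected training rows; at test time a row is
scored by `−exp(−‖z‖²/2)`, which decreases monotonically with the base
density at `z` and lies in [−1, 0). Disease-affected rows, never seen in
training, are expected to land away from the origin and score high.

### Layers

1. **Conditional affine** — `u = exp(a′) ⊙ x + b`, where
   `(a, b) = SPLIT(s(c))`, `a′ = α·tanh(a)`, and `s` is a
   linear–GeLU–linear network of the condition only. Its log-Jacobian is
   `Σᵢ a′ᵢ`; it is the only layer that changes volume. The tanh soft
   clamp with constant `α` (default 1.9) bounds every log-scale to
   (−α, α) so `exp` can never overflow during optimization.
2. **Volume-preserving coupling blocks** (default 8) — each block applies
   two conditional coupling layers with swapped active halves, then a
   fixed seed-derived permutation `R`, then a trainable global offset
   `t_global`. A coupling layer computes
   `u₁ = x₁ ⊙ exp(r̃) + t(x₂, c)`, `u₂ = x₂`, where
   `r̃ = tanh(s(x₂, c))` re-centred to sum to exactly zero across
   coordinates (the incompressible-flow constraint). Hence every
   coupling has `|det J| = 1` identically: an affine-coupling scale read
   off at face value would not preserve volume, and the zero-sum
   re-centring is the standard construction that does. Active/passive
   halves are `⌈d/2⌉ / ⌊d/2⌋` for any d; subnetworks are
   linear–ReLU–linear.
3. **Base distribution** — mean and log-scale vectors, frozen at (0, 1)
   unless `learnable_base` is set.

All subnetwork output layers and offsets start at zero, so a fresh flow
is an exact (permuted) identity — the standard stable initialization.
Dimension is always taken from the data, never hard-coded; the printed
split sizes in the application this package was built around (a 24/24
SPLIT of a 48-dimensional input alongside a 50-dimensional feature count)
are mutually inconsistent, so the implementation is deliberately
dimension-generic.

The implementation is pure numpy with hand-written backpropagation; the
gradients are verified against central finite differences in the test
suite, and the log-Jacobian against numerically differentiated full
Jacobians.

### Training

Adam (β = 0.9/0.999) under a closed-form cosine-annealing-with-warm-
restarts schedule: within each cycle (default 50 epochs) the rate warms
up linearly from `min_lr` (1e-5) to `max_lr` (3e-3) over 5 epochs, then
decays by a half-cosine back to `min_lr`. Gradients are clipped to a
global norm of 2.0 — flow likelihoods spike. Defaults: 400 epochs, batch
64, chosen for cohort tables of a few hundred training rows.

Training is strictly semi-supervised: if labels are passed, a non-zero
label sum raises a protocol violation. By default 15 % of the unaffected
rows are held out and the returned state is the one with the best
held-out NLL; density models of small tables overfit within a few
epochs, and best-state selection on a validation fold is what keeps
held-out latents near N(0, I) (the test suite asserts mean ‖z‖²/d in
[0.7, 1.3] on held-out unaffected rows).

An alternating-update option (`altub_enabled`) additionally refreshes the
base-distribution parameters every `altub_period` steps with a separate
optimizer. It is off by default: on small tables the alternation can
destabilize training, so it is left as an opt-in.

## Preprocessing

The chain, fitted on training rows only and applied as a pure function:
log(1+x) on configured right-skewed features (log1p keeps zero-valued
step counts finite while approximating log for large values); drops of
configured irrelevant features and of the target's own biomarker (the
label is a threshold on it — keeping it would be leakage by
construction); chained-regression (Bayesian-ridge) imputation, max 10
rounds, tol 1e-3, seeded; robust scaling (x − median)/IQR with zero-IQR
columns centred and left at scale 1 rather than dropped; PCA per
configured multicollinear group (default 1 component kept). Age and
gender are routed out of the feature matrix into the condition matrix;
age is median/IQR-scaled, gender passed through as 0/1. A state digest
over every fitted array backs the leakage-guard test: the state is
byte-identical whatever happens outside the training rows.

## Synthetic cohorts

The generator emulates the structure of an integrated PHR table:

* **Demographics** are exact per-bin counts (the default table: 706
  participants, 315 male / 391 female across five age bins), not
  sampled; ages are uniform within a bin since only bin membership is
  specified.
* **Features** come in families — gaussian, lognormal (right-skewed
  transaminases, triglycerides, daily step counts), ordinal grades
  (genetic-risk categories), and equicorrelated blocks built from a
  single shared factor (`x_j = √ρ·f + √(1−ρ)·ε_j`), the simplest
  construction that makes per-group PCA collapse meaningful. Age and
  gender shift the (latent) means per standardized decade of age and for
  male gender.
* **Labels** are thresholds on one biomarker, computed on the complete
  latent values before missingness is injected, then masked wherever the
  observed biomarker is missing. `calibrate_base_rate` sets a threshold
  to the empirical quantile that realizes a target prevalence; the
  default panel of six diseases spans base rates from 0.02 to ~0.34, the
  imbalance spectrum the package is about.
* **Missingness** is completely at random per feature. Real PHR
  missingness is surely structured, but its mechanism is not observable
  from published summaries; the rates here (1–5 %) are placeholders and
  flagged as such.

What the synthetic cohorts do *not* emulate: real feature catalogues
(hundreds of survey items), informative missingness, measurement error
correlated with disease status, or label noise. Passing tests on this
generator demonstrates that the pipeline's machinery is correct and that
the method behaves as designed under its own assumptions — not that the
same margins would be observed on any particular real cohort.

## Benchmark experiments

`make_anomaly_benchmark` draws unaffected rows from a condition-dependent
gaussian (age shifts four coordinates at 0.5 SD per decade, gender four
at 0.8 SD) and displaces affected rows by 1.4 SD on each of six
coordinates *with a random sign pattern per row* (total squared
displacement ≈ 11.8). The random signs emulate disease heterogeneity:
patients deviate from normal physiology in different directions. A
density model is indifferent to direction — its score depends only on
departure from the learned manifold — while a supervised classifier must
learn each sign pattern from scarce cases. This is the mechanism behind
the package's headline contrast: under progressive positive
undersampling the supervised baseline's AUPRC falls monotonically and
steeply, while the flow (whose training set contains no positives at
all) declines only through the shrinking base rate.

Experiment scales are chosen for a desk machine: cohorts of 3 000, flow
of 4 blocks × width 48, 50–80 epochs at batch 128, 10 repetitions per
condition; the undersampling sweep starts from a common-disease base
rate (0.30) so that 95 % undersampling still leaves enough positives to
split five ways, landing near a 0.02 realized base rate.

## Evaluation protocol

Unaffected rows are split 8:2 into a train pool and a shared test pool;
affected rows are partitioned into five near-equal subsets (sizes differ
by at most one); each test fold is the shared pool plus one subset, so
every fold's base rate stays close to the cohort's (validated at plan
time against a ±30 % relative band). Metrics are averaged over folds;
experiments are repeated with re-drawn seeds and summarized as mean ±
1.96·sd/√n (the normal-approximation 95 % CI, n defaulting to 50).
Models are compared by Welch's unequal-variance two-sided t-test on the
per-repetition values, with degenerate zero-variance inputs handled
deterministically (p = 1 for equal means, p = 0 otherwise). AUPRC is
step-wise average precision — linear PR interpolation is known-optimistic
— and AUROC is the Mann–Whitney form with ties counting one half. For
semi-supervised hyperparameter selection the plan can reserve one
affected subset as a validation fold (`reserve_validation_subset`),
which is then excluded from final evaluation; model selection for the
flow itself uses only unaffected held-out likelihood and needs no
labels.

## Baselines and resamplers

Supervised baselines (SVM, random forest, LightGBM, XGBoost) wrap the
standard library implementations with inverse-frequency class weights
and stratified five-fold CV maximizing average precision over small
documented grids; all expose one scorer surface (higher = more
positive). Risk scores are continuous (decision function where
available, positive-class probability otherwise). One-class baselines
(one-class SVM, isolation forest, Gaussian mixture scored by negative
log-likelihood; mixture size chosen by BIC on unaffected rows from
m ∈ {1, 2, 4, 8}) never see labels — a label-bearing call is a protocol
violation. SMOTE, ADASYN, and Tomek-link removal are implemented
in-package on k-NN primitives with their classical definitions, and the
tests assert the defining geometry (synthetic points on minority
segments; only majority members of mutual-NN pairs removed).

## Numerical choices and edge cases

* Zero-IQR columns: centred, scale 1, never dropped (deterministic and
  information-preserving).
* Coupling scale re-centring subtracts the mean of the tanh outputs, so
  the zero-sum constraint holds to machine precision and the coupling
  log-det is exactly 0, not approximately.
* Ties in ranking metrics: one-half convention (AUROC) and atomic tie
  groups (AUPRC staircase).
* Undersampling removes round(fraction·n_pos) positives uniformly;
  fraction 1.0 is rejected rather than silently emptying the class.
* Empty demographics give an empty cohort, not an error; an unknown
  biomarker in a disease rule is a configuration error.
* Flow inputs must be finite; non-finite training loss aborts with a
  diagnostic rather than continuing on garbage.

## Known limitations

* The conditional affine layer conditions on `c` only, so for a fixed
  condition its log-det is a constant; expressiveness for
  heavy-tailed conditionals comes from the coupling stack, which is
  volume-preserving — strongly non-gaussian tails may need more blocks
  than the default.
* Manual-gradient numpy training is single-threaded; it is sized for
  cohort tables (hundreds to thousands of rows), not for large-scale
  density estimation.
* The GMM baseline uses full covariances with a small ridge
  (reg_covar 1e-4); on near-degenerate feature sets BIC tends to pick
  m = 1, which is the intended conservative behaviour.
* CI half-widths use the normal approximation; at n = 10 repetitions
  they are indicative, not exact.
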