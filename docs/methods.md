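# Methods

## Model and objective

The package models a binary clinical outcome through a linear predictor
with main effects and all pairwise products of standardized features,

η_i = β₀ + x_iᵀ(β⁺ − β⁻) + Σ_{j<k} ((Θ_jk + Θ_kj)/2) · z_{i,(j,k)},

where z_{(j,k)} is the normalized product column for the unordered pair
(j, k). The fitted objective is the mean logistic negative log-likelihood
(or half mean squared error) plus λ(‖β⁺‖₁ + ‖β⁻‖₁) + (λ/2) Σ_j ‖Θ_j‖₁,
subject to β± ≥ 0, diag(Θ) = 0 and the per-row budgets
‖Θ_j‖₁ ≤ β⁺_j + β⁻_j. The budgets encode weak hierarchy: a pair can carry
weight only if at least one of its features carries a main-effect budget.
Θ is *not* constrained to be symmetric; only the symmetrized weight
w_jk = (Θ_jk + Θ_kj)/2 enters the predictor, each unordered pair's two row
entries receive λ/2 each (total weight λ per pair, matching the main-effect
penalty scale), and the split of w_jk across the two rows is in general not
identified — reports and invariance tests therefore work with β and w, never
with raw Θ entries.

An unpenalized intercept β₀ is included: the model is used for
classification, and without an intercept a logistic fit on an imbalanced
cohort would be forced through prevalence 1/2. This is standard practice
for penalized logistic regression and harmless for the squared loss.

## Normalization and the interaction design

Columns are z-scored to mean 0, population standard deviation 1. Unit
variance (rather than, say, unit ℓ2 norm) was chosen because the single
penalty level λ and the selection threshold τ implicitly assume
commensurate column scales; the choice is configurable in spirit — the
normalization is isolated in one function pair — but z-scoring is the
default everywhere. Product columns are built from the normalized main
columns and then z-scored again themselves, so interaction coefficients
live on the same scale as main effects. Constant columns are dropped with
a warning rather than raising, because half-size subsamples drawn during
stability selection can easily make a near-constant clinical variable
exactly constant. Training-set centers and scales are always re-applied to
test data; nothing is refit on test samples.

## Solver

Accelerated proximal gradient (FISTA) with:

- backtracking line search starting from a step estimated by a few power
  iterations on the design operator (an underestimated curvature is
  corrected by the backtracking; the estimate only sets the first trial
  step);
- a monotone safeguard: if the momentum step would increase the penalized
  objective, the step is retaken from the current iterate (plain proximal
  descent, guaranteed non-increasing), so the objective trace is
  monotone by construction;
- convergence when the relative objective change drops below `tol`
  (default 1e-7; the stability and benchmark drivers use 1e-6 with
  `max_iter` 1000, which is far below the selection threshold's scale).

The proximal step factors into p independent per-row problems: minimize a
quadratic distance plus λ(β⁺+β⁻) + (λ/2)‖Θ_j‖₁ under the row budget. Each
row is solved *exactly* through the scalar Lagrange multiplier α ≥ 0 of
its constraint: Θ_j(α) soft-thresholds at t(λ/2 + α), β±(α) =
max(0, b± − t(λ − α)), and the constraint slack is piecewise linear and
non-increasing in α, so the root is found by sorting the kink points and
interpolating on the bracketing segment (the scalar public version uses
safeguarded bisection instead; both agree to machine precision and both
are validated against an independent convex solver in the tests).

λ_max — the smallest penalty with an all-zero fit — is *not* the naive
maximum absolute correlation: the row multiplier lets a row discard
interaction correlations up to 3λ − 2|g_j| where g_j is the main-column
correlation with the intercept-only residual. The implemented closed form
max_j max(|g_j|, (M_j + 2|g_j|)/3), with M_j the largest product-column
correlation involving j, is verified in the tests against brute-force
bisection on the fitted path. The default grid is 16 geometric points from
λ_max down to λ_max/100; 16 matches the benchmark protocol's grid size,
and the floor 1/100 keeps the densest fits well-conditioned at cohort
sizes of a few hundred.

The All-Pair Lasso baseline shares the FISTA machinery with a plain
soft-threshold prox on the concatenated [mains, products] design and a
uniform ℓ1 penalty — exactly the relaxation obtained by dropping the row
budgets (with a symmetric Θ split, the per-pair penalty again totals λ).

## Selection (wHLFS)

Main effect j is selected when |β⁺_j − β⁻_j| > τ; pair (j, k) when
|Θ_jk| + |Θ_kj| > 2τ (the two row entries pool their evidence; a max-rule
alternative is available). The default τ = 1e-5 sits far below any
meaningful standardized effect and just above solver noise at the default
tolerances; sparsity along the path is controlled by λ, not by τ. Because
every fit obeys the row budgets, any selected pair has an endpoint with
positive budget — the selected set inherits the weak hierarchy without a
separate filter. The measure-zero case β⁺ = β⁻ > 0 (budget without net
effect) is permitted and logged. With a downstream classifier
(linear SVM, RBF SVM, random forest, or sparse logistic regression — all
scikit-learn, default settings, the RBF width by scikit-learn's scale
heuristic) the classifier trains on the selected normalized columns; with
no classifier the hierarchical fit itself predicts (probability > 0.5 for
the logistic loss; fitted value > 0.5 for the squared loss, since outcomes
are coded {0, 1}). An empty selection degrades to a majority-class
predictor rather than failing, so sweeping λ past λ_max stays safe.

## Stability selection

For each λ in the grid and each of B subsamples (drawn uniformly without
replacement at fraction 0.5 — the standard subsampling choice — redrawn up
to 100 times if a class is missing), the model is refit and thresholded.
S is the selection frequency and E the mean coefficient sign (0 when
unselected), both averaged over *all* (λ, b) runs; this makes |E| ≤ S an
identity rather than an approximation. The classic rule — max over λ of
the per-λ frequency — is available via `aggregate="max"` and dominates the
mean rule pointwise. Defaults: B = 100 subsamples, the solver's 16-point
grid; the recovery experiments in the test suite use B = 20 over an
8-point grid, which already separates planted from background features
cleanly at n = 400. Each (λ-index, b) run draws its RNG stream
independently from the triple (seed, λ-index, b), so results are
bit-for-bit reproducible and invariant to execution order; a failed run is
retried once with a fresh subsample, then skipped with a log record and
excluded from the denominator. Ranked reports default to the top 12 main
effects and top 34 interactions, and the signed report lists the top 10
positive and top 10 negative interactions together with their mains'
E scores, so redundancy (negative pair, positive mains) can be read
directly off one row.

## Evaluation protocol

Ten stratified outer splits (a shuffled stratified 10-fold partition, so
each sample is tested exactly once; stratification avoids class-empty test
sets at n ≈ 300 with ~45% positives), 5-fold inner CV on each training set
to pick λ by mean accuracy with ties broken toward the larger λ (the
sparser model), refit on the full training set, and accuracy /
sensitivity / specificity in percent on the held-out tenth. Sensitivity or
specificity is reported as missing (NaN) when its class is absent rather
than as 0, which would bias means. Competing feature selectors (lasso,
all-pair lasso) use the squared loss; the hierarchical selector uses the
logistic loss. The main-effects lasso is scikit-learn's coordinate
descent; the all-pair baseline is the package's own fit so that
scikit-learn can serve as an independent reference in the tests. Paired
one-sided t-tests compare the reference method's per-split accuracies
against each competitor; an all-zero difference vector reports p = 0.5 by
convention, and a constant nonzero difference reports the degenerate limit
(0 or 1) with a log record.

## Synthetic cohorts

The generator emulates the statistical shape of a conversion-prediction
cohort: two equicorrelated Gaussian blocks (default 85% "imaging-like" /
15% "clinical-like", within-block correlation ρ = 0.2 — strong enough to
make selection nontrivial, weak enough that planted features remain
identifiable), sparse main effects and hierarchy-obeying pairs specified
on the standardized scale (so they survive z-scoring), and Bernoulli
outcomes from the logistic model. Planted pairs are validated against weak
hierarchy at construction. Named scenarios fix the study conditions:

- `generic_scenario` — n = 400, p = 30, four mains (+1.0, +0.9, −0.9,
  +0.7) and two pairs (+0.9 synergistic, −0.8 redundant), for recovery
  experiments;
- `synergistic_scenario` — n = 400, p = 20, one moderate (+0.8) and one
  weak (+0.2) main with a strong positive pair (+1.0) between them;
- `redundant_scenario` — two strong mains (+1.0, +1.0) with a negative
  pair (−0.8);
- `interaction_dominant_scenario` — n = 400, p = 15, modest mains (+0.5,
  +0.5) and strong pairs (±1.3) on otherwise-silent partners. This is the
  benchmark cohort: when most of the signal sits in products of
  individually weak features, a classifier fed explicitly selected product
  columns has a real advantage over one trained on main effects alone — in
  a mains-dominated cohort a random forest recovers most of the signal
  from the raw features and the comparison is uninformative.

What the generator does *not* emulate: non-Gaussian marginals and heavy
tails of real lab values, missingness, longitudinal visits, site effects,
and the block-diagonal-plus-spikes covariance of real morphometry panels.
Passing recovery tests therefore demonstrate correctness of the machinery
under the model's own assumptions, not field performance on ADNI-like
data.

## Numerical choices and degenerate inputs

- Feasibility of every fit is structural (the prox returns feasible
  points), asserted post-fit with slack 1e-8.
- Interaction product columns that come out constant (possible for exactly
  proportional inputs) are kept with unit scale so the pair index remains
  a bijection over all p(p−1)/2 pairs.
- Outcomes {−1, +1} or any two distinct values are recoded to {0, 1} at
  load time with the mapping recorded.
- CV and ranking tie-breaks are deterministic and documented (larger λ;
  S, then |E|, then name); pair display names are canonicalized by sorted
  feature name so rankings are invariant to input column order.
- Divergent fits raise rather than returning silently; stability and
  benchmark drivers record and skip per-run failures.

## Problem sizes in the shipped experiments

The test suite and the acceptance script run recovery at n = 400, p = 30
(B = 20, 8 λ values, 20 or 5 replicates), sign recovery on the two
archetype scenarios at p = 20, and the benchmark on the
interaction-dominant cohort (10 or 3 protocol seeds, 4-point CV grid).
These sizes give stable pass/fail behavior for the planted effects while
keeping a full run in the minutes range on one CPU; larger cohorts only
sharpen the same effects.

## Known limitations

- The strong-hierarchy variant (symmetric Θ, solvable by ADMM) is not
  implemented; the weak model is the deliberate scope.
- No refitting/debiasing of selected coefficients.
- The per-pair penalty split between the two Θ rows is a convention;
  alternatives (e.g. all weight on one row) change the objective but not
  the model class, and all oracle comparisons target the declared
  objective.
- Stability scores carry no family-wise error guarantee; they are
  descriptive rankings.
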