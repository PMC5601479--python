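# Methods

## Model

A deep Cox survival network is a fully connected feed-forward network with a
proportional-hazards output layer.  Hidden layer h applies an affine map
followed by ReLU or tanh; the output layer is a pure linear form: predicted
risk R_i = X_i β where X_i are the final hidden activations of patient i and
β the Cox coefficient vector.  No exponential is applied to the output and
no intercept is fitted — the partial likelihood is invariant to adding a
constant to all scores, so an output bias would be unidentifiable (this
shift invariance is asserted to 1e−10 in the tests).

The training objective is the negative log Cox partial likelihood with the
Breslow convention for tied times: the risk set of patient i is
R_i = { j : Y_j ≥ Y_i }, ties included, and no Efron correction is applied.
The log-sum-exp over each risk set subtracts the maximum score for
stability; loss and gradient are computed in O(n log n) by sorting once and
taking suffix sums of exp(score) and prefix sums of inverse risk-set
denominators over tie groups.  An O(n²) enumeration in the test suite is
the reference implementation.

The analytic score gradient (event indicator minus accumulated softmax
weights over the risk sets containing the patient) is validated against
central finite differences at relative error < 1e−6, including tied times
and mixed censoring; its components sum to zero by construction.

## Training

Full-batch gradient descent with a backtracking line search, one parameter
update per epoch; the partial likelihood couples patients through risk
sets, so mini-batching changes the objective (a mini-batch mode exists but
is off by default and warns).  Internally the loss is averaged over events
so step sizes are insensitive to cohort size; the public loss function
returns the plain sum.

* Initialization: scaled-uniform fan-in/fan-out (limit √(6/(d_in+d_out))),
  from a seeded generator; hidden biases start at zero.
* Line search: Armijo sufficient decrease with constant 1e−4, shrink factor
  0.5, initial step 1.0.  The next epoch's search warm-starts at twice the
  previously accepted step (capped at 1e3) — full-batch steps on this loss
  vary over orders of magnitude during a fit, and restarting at 1.0 every
  epoch wastes most line-search evaluations.  The warm start is a package
  design choice (`LineSearch.adaptive`, on by default; set it off for the
  fixed-initial-step behaviour).  The Armijo guarantee is unaffected: with
  dropout off, the evaluation-mode loss is non-increasing across epochs.
* Dropout: inverted unit dropout on hidden activations (mask then scale by
  1/(1−q)), fresh masks each epoch, the same masks held fixed within an
  epoch's line search so the Armijo condition applies to a fixed objective.
  Dropout is disabled (no masking, no scaling) at evaluation and
  interpretation.  "Dropping weights" admits a second reading, DropConnect;
  that variant is available via `NetworkConfig(dropconnect=True)` and masks
  weight matrices instead of activations.
* Stopping: `max_epochs` (default 500), or relative improvement of the
  logged evaluation-mode loss below 1e−6 over 10 epochs, or a line search
  that cannot find a decrease within 50 shrinks (warn and return).
* ReLU's derivative at exactly zero input is taken as 0 — a measure-zero
  convention that matters only in tests, where finite differences are
  evaluated away from the kink.
* No weight penalty is applied; dropout is the only regularizer.

With zero hidden layers the model class is exactly linear Cox regression
trained by partial-likelihood gradient descent.  On a well-specified
simulation (n = 2000, p = 10, 30% censoring) the recovered β reaches cosine
similarity ≥ 0.95 with the generating coefficients and matches an
established Cox maximum-partial-likelihood fitter (lifelines) to 0.02 per
coefficient; held-out concordance comes within 0.02 of the true-risk
oracle.

## Synthetic cohorts

The simulator draws features i.i.d. standard normal and event times from a
proportional-hazards model: T_i is exponential with rate
`baseline_rate · exp(r_i)` (or Weibull with shape k via T = (E/rate)^{1/k},
still proportional hazards), where the log-hazard r_i is either x_iᵀβ or a
named nonlinear function.  Censoring is independent exponential; its rate
is calibrated by log-scale bisection against a 10,000-sample pilot so the
expected censored fraction hits the requested target within ±0.02 — the
pilot's censored fraction is monotone in the rate, which makes bisection
valid for arbitrary (including nonlinear) risk functions.  Everything is
deterministic per seed.

Defaults are chosen to emulate the statistical shape of molecular tumor
cohorts: hundreds to a couple thousand patients, standardized features,
heavy right-censoring (the `censoring_target` accepts up to 0.9+; cohorts
like breast carcinoma run ~90% censored).  The default linear coefficients
are sign-alternating ±0.7, a clearly prognostic but noisy signal (true-risk
c-index ≈ 0.84 at p = 10).  The nonlinear designs — `quadratic`
(x₁² − x₂²), `xor` (sign(x₁x₂)), `interaction` (1.5·x₁x₂) — are constructed
so every linear projection of the features is uninformative (population
c-index ≈ 0.5) while the true risk ranks patients well; they exercise
exactly the regime where depth pays.  On the quadratic design a
two-hidden-layer tanh network beats the linear model by ≈ 0.29 test
c-index, against a required margin of 0.10.

What the simulator does **not** emulate: correlated features,
gene-expression covariance structure, batch effects, informative censoring,
non-proportional hazards, or realistic marginal distributions.  Passing
tests demonstrate that the machinery is correct and that depth helps where
nonlinearity exists — not that it will help on any particular real cohort.

## Preprocessing

* Categorical columns expand to one binary indicator per observed level
  (`col=level`); missing originals stay missing in every indicator;
  single-level columns are dropped with a warning.
* Mean imputation (for designated binary clinical variables such as
  treatment flags) fills with the observed prevalence — the prior
  likelihood of the positive state.
* 1-nearest-neighbour imputation for sparsely missing molecular features:
  features missing in ≥ 20% of patients are discarded (the boundary is
  assigned to "drop": imputation is reserved for features strictly below
  the threshold); remaining holes are filled from the single nearest
  patient by Euclidean distance over the features observed in both, with a
  logged column-mean fallback when no usable neighbour exists.  This is
  implemented directly rather than through a library imputer because the
  threshold rule, the unscaled shared-feature distance and the fallback are
  part of the contract; a brute-force oracle checks it.
* Standardization to zero mean, unit variance with the population divisor
  n; zero-variance columns are dropped with a warning.  The returned
  mean/scale record lets validation/test data be transformed with training
  statistics.  Standardizing the pooled cohort before splitting is the
  default workflow; the record-based mode supports strict post-split
  standardization when leakage control matters more than protocol fidelity.
* Splits are 60% train / 20% validation / 20% test: round-to-nearest for
  train and validation, remainder to test, from a seeded uniform
  permutation.
* Merging cohorts (transfer learning) renames features through an alias map
  (a pathologic/clinical → "stage" unification ships as the default
  example), intersects feature names, concatenates rows, and records
  per-patient origin outside the feature matrix.  No re-normalization is
  applied at merge time.  Duplicate patient ids or an empty intersection
  are errors.

## Evaluation

Harrell's c-index with the original permissibility rule: a pair ordered by
time is permissible when the earlier patient's event was observed; pairs
tied on time count only when exactly one member is an event (the event
member treated as earlier); both-event time ties are excluded.  Risk ties
score 0.5.  The production implementation is vectorized O(n²) in numpy and
must agree exactly with the Python brute-force reference on random tied
instances; on tie-free data it also matches lifelines' implementation.
This tie convention is this package's documented choice, not a claim about
any particular prior implementation.

The repeated protocol: for each of (default) 20 repeats, re-randomize
60/20/20, run the design search on train/validation, refit the best design
on train + validation with a fresh seed, and score on test; the median
c-index over repeats is the headline number and a rank-sum helper compares
method variants.

## Design search

Gaussian-process surrogate (constant × squared-exponential kernel with
per-dimension length scales, plus a white-noise term, normalized targets)
over the four design coordinates mapped to the unit cube; integers are
relaxed and rounded, activation is a 0/1 coordinate.  The first five
designs come from a scrambled Sobol sequence; afterwards expected
improvement is maximized over 1000 seeded uniform candidates per iteration
— candidate-set maximization keeps the search deterministic for a fixed
seed.  Designs whose training raises score 0.0 and the search continues,
so one pathological configuration cannot abort a run.  Default budget: 30
evaluations.  On a deterministic toy objective the search lands within 5%
of a 50×10 grid optimum at budget 15 and matches or beats the median best
of random search over 20 seeds.

## Interpretation

`feature_risk_scores` evaluates ∂R/∂f per patient via the same chain rule
as training (β composed with the hidden-layer Jacobians at that patient's
activations), dropout off; it is validated against finite differences of
the forward risk at relative error < 1e−6 for 0–3 hidden layers and both
activations.  Scores live in the model's standardized input space; passing
the standardization record rescales them per original feature unit.

Ranking: per-feature median of the signed scores, ordered by
|median| with the sign displayed (positive = risk-increasing).  Taking the
median of |score| instead is a meaningfully different statistic when
gradients change sign across patients — both are exposed
(`method="abs-of-median"` default, `"median-of-abs"` alternative) and the
default reconciles "rank by median score" with "rank by median absolute
score" readings by ranking on the absolute value of the signed median.
Ties break by feature name.  `export_preranked` writes the two-column,
headerless, tab-separated ranked list consumed by preranked gene-set
enrichment tools; enrichment analysis itself is out of scope.

## Problem sizes in the shipped checks

The heavy checks run at desk scale on one CPU: simulations use n = 1000 or
2000 patients and p ≤ 10 features; the 20-repeat end-to-end protocol uses a
search budget of 8, widths capped at 100 and 50 training epochs per design
(full-batch training with widths up to 1000 is supported but costs minutes
per design, which an automated protocol repeated 20 times does not need to
demonstrate correctness — the median c-index criterion of 0.70 is met with
≈ 0.85 under these settings).

## Known limitations

* Full-batch training scales linearly in n × width² per epoch; very wide
  deep designs on large cohorts are slow on a single CPU.  There is no GPU
  path.
* Exponential/Weibull event times satisfy proportional hazards exactly;
  the package does not test robustness to PH violations.
* The c-index tie convention is fixed; no time-dependent AUC, Brier score
  or calibration measures.
* The GP surrogate treats the rounded integer coordinates as continuous;
  for very small widths the rounding granularity is coarse relative to the
  kernel length scale.
* No competing risks, time-varying covariates, or stratified baselines.
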