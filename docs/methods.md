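# Methods

## Scope and model

`survtab` benchmarks five right-censored risk models on mixed-type
tabular cohort data. Every model is reduced to a scalar log-risk
function h(x); ranking, partial-likelihood training and IPCW evaluation
all operate on h alone, so Cox fits and trained networks are
interchangeable behind one contract.

The shared objective is the Cox partial likelihood with the Breslow
approximation for ties: tied event times contribute the full risk set
{j : tⱼ ≥ tᵢ}. Breslow is used *everywhere* — the Newton fitter, the
penalized solver and the network loss — so that likelihood values and
scores are comparable across model families. The loss is optionally
normalized by the number of events (default on); this rescales gradient
magnitudes for the optimizer but cannot move the optimum.

## Synthetic cohort generator

The generator emulates the statistical shape of a large ageing-cohort
baseline table; it makes no attempt to reproduce the semantics of any
real variable (hearing, gait speed, …), only type, effect-size,
censoring and missingness structure.

* **Covariates.** Continuous features are equicorrelated multivariate
  normal (pairwise r = 0.2 — a typical magnitude for related clinical
  measurements); binary features are Bernoulli(0.3).
* **Outcome.** Weibull proportional hazards with closed-form inversion,
  T\* = (−log U / (λ₀ e^{xβ}))^{1/k}, shape k = 1.5 (rising hazard with
  age). Any PH generator would do; Weibull has an explicit inverse.
* **Censoring.** Administrative at 12 years plus exponential dropout at
  0.06/year. The dropout rate was chosen so the preset's median observed
  follow-up is ~10 years; the generator exposes both knobs because real
  cohorts rarely document their dropout process.
* **Calibration.** `calibrate_event_rate` bisects on λ₀ against one
  fixed 20,000-subject sample until the simulated event fraction is
  within ±1 pp of target (13% for the preset). Event fraction is
  monotone in λ₀, so bisection is exact up to Monte-Carlo noise.
* **Wave discretization.** Observed times are rounded *up* to the next
  2-year grid point, mimicking detection at the next biennial assessment
  wave; rounding never alters the event indicator and never produces
  zero times. A consequence worth knowing: with all observed times ≤ 12,
  horizon-12 time-dependent metrics have no dynamic controls (T > 12)
  and are reported as undefined. That mirrors the limits of a cohort
  whose follow-up simply ends.
* **Missingness.** MCAR masks cells independently. MAR drives each
  feature's masking through a logistic model on a designated fully
  observed feature (default: the first continuous one), the intercept
  solved by bisection so the marginal rate is exact. MAR is the preset
  default because it is the simplest mechanism under which complete-case
  analysis is biased — i.e. the setting that justifies imputation at all.
* **Preset.** 5,433 subjects, 31 continuous + 60 binary features,
  exactly 8 nonzero log hazard ratios (|β| ∈ {0.3, 0.7}), event rate
  calibrated to 13%, missingness ramping 0 → 33.5% with the first 20
  features fully observed. All randomness flows from one seed through
  named child streams (`child_seed`), so any stage replays in isolation.

What passing tests on this generator do *not* show: robustness to
non-proportional hazards, informative censoring, MNAR missingness, or
real-world measurement semantics. The generator is a correctness and
calibration harness, not a substitute cohort.

## Preprocessing

* The log transform for skewed positive predictors is implemented in its
  literal form y = log₂(x) + 1 (default), which is undefined at zero; a
  `shifted` variant y = log₂(x + 1) is provided for zero-containing
  columns. Both are exposed, neither silently substituted.
* Min-max normalization always uses training-row statistics; constant
  training columns map to 0; test values outside [0, 1] are *not*
  clipped (the map must stay affine or Cox coefficients and network
  inputs are distorted silently).
* VIF pruning removes one feature at a time — the largest VIF above 10,
  ties broken by column order — recomputing after each removal. The
  removal log replays deterministically.
* The proportional-hazards check is a score test on Schoenfeld
  residuals: for transform g(t) (default 1 − KM(t); identity and rank
  provided), the per-covariate statistic is
  [Σ(gᵢ−ḡ)sᵢ]² / (V̄ₖₖ·Σ(gᵢ−ḡ)²) with V̄ the average risk-set
  covariance, plus a global χ²_p version. Its type-I error is verified
  by simulation in the test suite (rejection rate within [0.02, 0.09]
  at α = 0.05 under exact PH).

## Imputation

Chained equations, m independent chains, initialized from observed
marginals. Continuous targets use predictive mean matching: a Bayesian
draw of the regression parameters (σ² from the scaled inverse-χ², β from
its normal posterior), predicted values matched to the 5 nearest
observed donors, one donor drawn. PMM guarantees imputed values lie in
the observed support. Binary targets use a ridge-stabilized logistic fit
with a posterior parameter draw and a Bernoulli draw. The outcome (time,
event) is forced in as a predictor of every incomplete variable but
never imputed.

Quickpred screening admits a candidate predictor when its
pairwise-complete correlation with the target *or* with the target's
missingness indicator reaches 0.1 (the canonical default), subject to a
usable-cases floor. Constant columns yield undefined correlations and
are treated as 0.

`choose_m` maps the maximum per-variable missing percentage to the
number of imputations by rounding up to the next multiple of 10 (floor
5): 33.5% → 40. The principle (more missingness, more imputations) is
standard; the exact rounding rule is this package's choice and is
configurable.

Rubin pooling reports Q̄, W, B, T = W + (1 + 1/m)B and the large-sample
df by default; the Barnard–Rubin small-sample df is available when a
complete-data df is supplied. Nested pooled models are compared with the
D1 statistic: r = (1 + 1/m)·tr(B W̄⁻¹)/k, D1 = Q̄ₑᵀW̄⁻¹Q̄ₑ/(k(1+r)),
referenced to F(k, ν₁) with the standard denominator df; r = 0 falls
back to the χ² reference.

The 5%-bias acceptability rule compares pooled imputed-cell means to
observed-cell means. Note its limits: under MAR those means *should*
differ, and near-zero-mean columns inflate the percentage; the check is
a crude screen, reported as such (absolute difference when the observed
mean is 0).

## Cox models

* `fit_cox` is a Newton–Raphson maximizer with step-halving, gradient
  tolerance 1e-8 (infinity norm), at most 100 iterations, observed-
  information covariance. Suspected monotone likelihood (|β| > 25) is
  flagged with a warning rather than an error. Risk-set sums are fully
  vectorized for small p and accumulated group-by-group for large p.
* `fit_coxnet` minimizes −(1/n)log PL + λ[α‖β‖₁ + (1−α)‖β‖₂²/2] by
  FISTA with backtracking and momentum restarts. The ℓ₁ part enters only
  through the soft-threshold prox, so zeros are exact — "selected" means
  coefficient ≠ 0 with no epsilon rounding. λ = 0 reproduces the Newton
  solution; λ → ∞ gives the zero vector in one step.
* CV deviance follows the V&VH convention: for a fold model β₋ₖ the
  contribution is −2[logPL_all(β₋ₖ) − logPL_complement(β₋ₖ)], summed
  over folds, averaged over repeats and imputed datasets. Grid ties
  prefer the largest λ (then largest α): on pure-noise data the null
  model wins.
* Stability selection runs 2× repeated event-stratified 5-fold CV inside
  each imputed dataset (10 training sets of 80%), fits the elastic net at
  one fixed (α, λ) — by default the tuning optimum of the same stack;
  per-split re-tuning is exposed but off — and keeps a feature within a
  dataset when selected in ≥ 8 of 10 splits. Consensus candidate lists
  collect features passing ≥ t of the m datasets for a ladder of t.
* `coxsf_finalize` fits each nested candidate list per imputed dataset,
  compares adjacent pairs with D1, and by default keeps the larger model
  of the *lowest-p* comparison when that p clears 0.05, falling back to
  the smallest list. This operationalizes a "keep the model whose extra
  variables matter most" rule while still rejecting pure-noise
  extensions; a conventional sequential-testing mode (`mode=
  "sequential"`) is provided. Pooled hazard ratios are exp(Q̄) with
  exp(Q̄ ± 1.96√T) intervals.

## Networks

No deep-learning framework is used: the three architectures run on a
compact numpy reverse-mode autodiff engine written for this package
(broadcast-aware elementwise ops, batched matmul, fused softmax and
layer-norm nodes, SELU, an Adam optimizer, optional float32). Gradients
are verified against central finite differences to 1e-5 in the test
suite for all three architectures.

Architecture defaults follow the documented designs: feedforward 4 × 32
SELU units with dropout 0.2 and additive Gaussian noise after each
hidden layer; dense block of 4 layers with growth rate 8 (layer ℓ input
width = p + 8(ℓ−1)); tab-transformer with per-column embeddings of the
binary features (dimension 64), 6 transformer layers of 8 heads,
continuous features bypassing the stack through a layer norm, and an
MLP head of one 32-unit SELU layer before the linear Cox node. Design
points the source designs leave open, resolved here: the Gaussian-noise
σ defaults to 0.1; no normalization inside the dense block; transformer
feed-forward expansion 2×; continuous features bypass the attention
stack (the original tabular-transformer convention).

Training minimizes the Breslow loss with Adam (default lr 1e-4, 300
epochs). Full-batch mode computes the exact partial likelihood with
global risk sets and is the default — the cohort sizes involved fit in
memory. Risk-set-batched mode shuffles subjects into mini-batches and
builds risk sets within each batch; this is a documented approximation
(within-batch risk sets are subsets of the true ones) that buys many
more optimizer steps per epoch and is used at desk scale. Batches
without events are skipped as uninformative. Both train and validation
losses are recorded every epoch in deterministic evaluation mode;
optional early stopping restores the best-validation parameters.

The loss is shift-invariant in h (only differences of log-risks enter),
so network outputs are identified only up to an additive constant —
irrelevant for ranking-based evaluation.

## Evaluation

* Harrell's C counts concordant over comparable pairs (earlier time must
  be an event; score ties count ½).
* Uno's C weights each comparable pair by Ĝ(tᵢ−)⁻², Ĝ the Kaplan–Meier
  estimator of the censoring distribution, by default estimated on the
  evaluation sample (a training-sample option exists). Truncation τ
  defaults to the 95th percentile of observed times in the pipeline.
  Pairs with Ĝ = 0 are dropped. With no censoring Uno reduces exactly
  to Harrell; the implementation agrees with an independent IPCW
  implementation to ~1e-12 on censored data.
* Time-dependent metrics use the cumulative-case / dynamic-control
  definition with the Kaplan–Meier (survivalROC-family) estimator:
  Se(c,t) = [1 − Ŝ(t | X > c)]·P(X > c)/[1 − Ŝ(t)] and the analogous
  specificity. Without censoring this reduces *exactly* to the empirical
  binary ROC of [T ≤ t]. AUC integrates trapezoidally along the
  cutoff-descending curve (re-sorting by FPR is wrong when floating
  error perturbs the terminal vertical segment). Classification cutoffs
  are chosen by Youden's J on the training split at the same horizon and
  applied to test — a declared policy, since none is standard. Balanced
  accuracy is (Se + Sp)/2 by definition, exact in every report row.
* Bootstrap CIs resample subjects with replacement (percentile 2.5/97.5,
  default B = 100); degenerate resamples are skipped and counted, > 50%
  degenerate is an error.
* Cross-model comparison: one-way ANOVA over per-(imputation × split)
  Uno's C values followed by Tukey's HSD (statsmodels). The comparison
  operates over imputed datasets, not bootstrap replicates; identical
  groups return adjusted p = 1 by convention.

## Pipeline and problem sizes

`run_experiment` executes: generate/load → chained-equations imputation
on the full predictor set (the design's stated ordering; imputing within
training folds only is the leak-free alternative and is noted as such) →
VIF pruning on the first completed dataset → event-stratified nested CV
(2 × 5-fold) → per (imputed dataset, split): train-only min-max
normalization, model fitting, test scoring → metrics with bootstrap CIs
→ Tukey comparison → JSON manifest with config hash, per-stage seeds,
library versions and wall-clock. Replaying a config reproduces every
number bit-for-bit.

The desk-scale preset (`desk_config`) is the configuration used by the
test suite and the acceptance script: n = 2000, m = 5 imputations with 5
sweeps, 2 evaluated splits, horizons {4, 8, 10} (12 is undefined under
the preset's censoring, see above), B = 50, feedforward/dense nets at
100 epochs (lr 1e-3, batched), tab-transformer scaled to embedding 8 /
1 layer / 2 heads / 16 epochs in float32. These sizes were chosen so a
full five-model run completes in a few minutes on one CPU while leaving
every qualitative conclusion intact (all informative models clear the
random baseline by ≥ 0.1 in Uno's C). The full-size architecture
defaults remain unchanged for real use.

## Known limitations

* The stability-selection λ is global per run, not re-tuned per split.
* The bias check is a mean-level screen only; no distributional
  imputation diagnostics beyond it.
* Risk-set-batched training slightly biases the loss toward small risk
  sets; use full-batch mode for final models when runtime permits.
* Calibration of predicted risks (as opposed to discrimination) is not
  measured.
* The D1 reference distribution is asymptotic; with very small m and
  strongly unbalanced missingness its p-values are approximate.
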