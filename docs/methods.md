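# Methods

## The problem and the model

The package targets prognostic modelling of a right-censored time-to-event
outcome from ultra-high-dimensional categorical predictors — the motivating
setting is germline SNP data with p in the hundreds of thousands and n of a
few hundred patients. Throughout, the association model is a proportional
hazards (PH) model with a linear predictor in the genotype dosage
(additive coding): h(t|x) = h₀(t) exp(x'β), where x ∈ {0,1,2}^p counts
minor alleles and only a small set of entries of β is nonzero.

Inference on such data proceeds in two stages: *screening* reduces p to a
manageable subset using only univariate (or offset-conditional) Cox fits,
then *selection* prunes that subset with a sparse multivariate method. The
final prediction model is always an **unpenalized** PH refit on the selected
variables; its Breslow baseline hazard supplies absolute survival
probabilities. This refit convention is a deliberate design choice: it makes
risk scores, predicted survival, calibration slopes and Brier scores all
derive from one coherent fitted model, and post-selection unpenalized refits
are the standard way to evaluate a selected model. (Prediction from the
penalized coefficients themselves is possible by using the selector's
`coefficients` directly.)

## Cox engine (coxcore)

All screening utilities rest on the Cox log partial likelihood with the risk
set R(y_i) = {j : y_j ≥ y_i} and the **Breslow** tie convention — the
likelihood exactly as written with shared risk-set denominators for tied
times. Simulated times are continuous, so ties have probability zero there;
the convention matters only for real data with coarsened times.

The marginal-utility solver is a Newton–Raphson iteration vectorized over
thousands of univariate models simultaneously (risk-set sums are suffix
cumulative sums over the time-sorted sample, so each Newton step is O(n·p)
array work; columns are processed in chunks of 20 000 to bound memory).
Safeguards:

* convergence when |score| < 1e−8, at most 50 iterations;
* step-halving enforcing a non-decreasing likelihood trajectory;
* |β̂| capped at 15 — monotone (perfectly separating) likelihoods are
  reported capped and flagged non-converged;
* constant columns are degenerate by convention: β̂ = 0, utility equal to
  the null log partial likelihood (so they rank last, never raising during a
  screen), information 0.

Conditional utilities (for iterative screening) use the **offset form**: the
conditioning set is fit once by unpenalized Cox regression on the full
sample, its linear predictor is frozen as an offset, and each candidate gets
a one-dimensional maximization on top. This preserves the vectorized solver;
a joint-refit mode exists behind a flag and agrees with the offset form on
candidate ranking in tests.

A small dense multivariate Newton solver (with the same tie and
step-halving conventions) handles conditioning-set fits, adaptive-LASSO
initial estimates, and final refits. Both solvers agree with lifelines'
`CoxPHFitter` to 1e−6 in the test suite.

## Screening

* **Aggressive SIS.** The sample is split by seeded permutation into halves
  of size ⌈n/2⌉ and ⌊n/2⌋; within each half all p marginal utilities are
  computed and the top s = ⌊n / log n⌋ (natural log) are kept; the result is
  the intersection I₁ ∩ I₂. Utility ties at the s-th rank break toward the
  lower column index, making the screen fully deterministic given the seed.
  If a half-sample has no events the split is retried with fresh
  permutations (up to 20), then errors instructing a reseed.
* **ISIS.** Iteration 1 is aggressive SIS followed by the selector → O₁.
  Iteration j ≥ 2 re-splits the sample (fresh seeded split per iteration),
  screens the p − |O_{j−1}| remaining columns by conditional utility given
  O_{j−1}, and applies the selector to (new intersection) ∪ O_{j−1}. The
  loop stops at a fixed point or after `max_iter` (default 5) iterations. An
  empty selection at iteration 1 is returned as a valid null outcome (small-
  sample weak-signal scenarios genuinely produce sub-1 average model sizes).
* **PSIS.** All p marginal MPLEs are fit on the full sample (no splitting);
  a variable passes when √I_k(β̂_k) · |β̂_k| ≥ Φ⁻¹(1 − q_m/2). The default
  q_m = 0.001 gives the cutoff 3.2905 and, under a global null, an expected
  p·q_m selected variables — the false-positive calibration the rule is
  designed for, verified by simulation in the suite.

A note on what screening can and cannot do: marginal utilities are
attenuated by omitted informative covariates (omitted-variable dilution in
PH models), so even "strong" variables occasionally miss a half-sample's
top s. This is inherent to split-sample SIS, not a solver artifact; the
conditional iteration of ISIS is precisely what recovers such variables,
and the simulations show ISIS retaining essentially all informative
variables where one-pass SIS does not.

## Selection

* **LASSO / adaptive LASSO.** L1-penalized Cox paths are computed by
  scikit-survival's Coxnet (coordinate descent with the 2/n-scaled partial
  likelihood, columns standardized internally, coefficients returned on the
  original scale, 100-point penalty path with glmnet's alpha_min_ratio
  convention). The penalty is chosen to minimize the 10-fold
  cross-validated partial-likelihood deviance in the Verweij–Van Houwelingen
  form: the fold-k contribution at penalty λ is
  −2·[ℓ_full(β̂_{−k}(λ)) − ℓ_{−k}(β̂_{−k}(λ))]. Folds are stratified by
  event status and seeded; ties in the CV curve resolve to the larger
  penalty. Variables with nonzero coefficients at the chosen λ are
  selected; an empty active set is a valid result.
  ALASSO uses penalty weights 1/|β̃_k| (capped at 1e8): β̃ is the joint
  unpenalized MPLE when p_sub < n/2, otherwise marginal MPLEs — the
  standard initializer that keeps the method defined at any p; the regime
  is recorded in the result metadata.
* **RSF minimal depth.** A purpose-built random survival forest: 100
  bootstrap trees, log-rank splitting with at most 10 random split points
  per candidate variable, mtry = ⌈√p_sub⌉, node minimum 15 (splitting stops
  below 30 cases or without events). The grower exposes full topology, from
  which two quantities come: each variable's forest-averaged minimal depth
  (a variable absent from a tree contributes that tree's depth D(S), the
  support boundary of the null law), and the mean of the noise-variable
  null distribution P(D_v = d | l₀,…) = (1−1/p)^{L_d}(1−(1−1/p)^{l_d}) for
  d < D(S), remaining mass at D(S) — a telescoping form whose normalization
  the suite asserts per tree. Variables at or below the forest-averaged
  null mean are selected.

## The synthetic-data generator

The generator emulates the study design the pipelines are compared on:

* genotypes i.i.d. per variable, codes (0,1,2) with Hardy–Weinberg
  probabilities ((1−q)², 2q(1−q), q²), default MAF q = 0.15;
* six informative variables with coefficients (−1)^u(a + |z|), u ~
  Bernoulli(½), z ~ N(0,1); a = 1 ("weak") or a = 2 ("strong"); the two
  fixed reference vectors used throughout the benchmarks are stored as
  named fixtures;
* Weibull failure times from the hazard h(t|x) = τ t^{τ−1} exp(τ x'β),
  τ = 1.5, drawn by inversion T = (−log U)^{1/τ} exp(−x'β). Note the
  PH-scale log-hazard ratios are τ·β, which is what a Cox fit recovers —
  the parameter-recovery suite tests against τβ;
* censoring C ~ Uniform(0, θ_c) independent of T, with θ_c calibrated so
  the marginal censoring probability P(T > C) equals the target rate
  (default 20%). The censoring probability is computed in closed form —
  (1/θ)∫₀^θ exp(−ρ_g t^τ)dt reduces to a regularized lower incomplete
  gamma — summed over the 3^6 informative-genotype combinations, and the
  monotone-decreasing achieved rate is bracketed and solved by Brent's
  method to 1e−10; a Monte-Carlo mode (fixed internal seed) exists as a
  cross-check. Calibration is per scenario (one θ_c per coefficient
  vector), and the empirical censoring rate verifies within ±0.01 at
  n = 20 000 for both fixtures.

Genotypes, coefficients, failure times and censoring times come from
independent sub-streams spawned from the scenario seed, and test sets are
fresh draws from the same joint distribution with the same θ_c.

What the generator does **not** emulate: linkage-disequilibrium correlation
between variables (all columns i.i.d.), variable-specific allele
frequencies, non-additive genotype effects, covariate-dependent censoring,
and competing risks. Passing benchmarks therefore demonstrate behavior
under independence and a correctly specified PH signal; on real SNP data,
correlated blocks will inflate screening's false positives in ways these
simulations cannot show.

## Evaluation

* **Harrell's c** — pinned conventions: a pair is comparable when the
  smaller observed time is an event and the times differ; predictor ties
  count ½. The implementation matches exhaustive pair enumeration exactly.
* **Brier R²** at horizon t* (default 2 years): R² = 1 − BS_model/BS_null.
  BS is the IPCW Brier score with weights from the reverse Kaplan–Meier of
  the censoring distribution estimated on the evaluation sample — events
  before t* weighted 1/G(t⁻), survivors 1/G(t*), subjects censored before
  t* contributing through the weights only. The null model predicts the
  marginal KM survival at t* for everyone, making R² exactly 0 for null
  predictions. Predicted survival comes from the training fit's Breslow
  baseline: S(t*|x) = exp(−H₀(t*) e^{lp}).
* **Calibration slope** — PH regression of new outcomes on the prognostic
  index as a single covariate (the standard survival-model calibration
  construction); 1 is ideal, below 1 indicates overfitting. The quartile
  table bins subjects into rank-based equal-sized quarters of predicted
  survival (robust to heavily tied predictions) and pairs mean predicted
  with KM-observed survival at t*.
* **Bootstrap optimism** — Harrell's procedure: refit the whole pipeline on
  each of B resamples, optimism = mean(c_resample − c_original), corrected
  c = apparent c − optimism. Failed resamples are dropped and counted;
  more than 20% failures is an error, not a silent average.

## Benchmark orchestration

`run_benchmark` replicates each scenario, shares each replicate's dataset
across all methods (the paired design of the comparison tables), and derives
every seed deterministically from (master seed, scenario index, replicate
index) so per-replicate records are bit-identical regardless of the worker
count (joblib process parallelism). Summaries are plain mean/SD/count
aggregations of the tidy per-replicate table and are exactly recomputable
from it. Empty selections are scored as the null model (c = 0.5, R² = 0);
component failures become status codes in the record, never dropped rows.

## Problem sizes and defaults

Desk-scale defaults reproduce the study's n = 300 cells with p reduced to
5 000 and 25 replicates (the informative-variable signal dominates these
cells, so their means are robust to reducing p; at full scale the original study
design uses p = 100 000 and 300 replicates, which the same configs express).
One caveat quantified during development: the expected number of *noise*
columns in SIS's two-partition top-s intersection grows as (s−p*)²/p as p
shrinks (≈0.02 at p = 10⁵ but ≈0.4 at p = 5 000 per iteration), so
ISIS-LASSO's mean final model size is biased upward by roughly one variable
at desk scale relative to full scale, while informative-variable counts,
c-indices, calibration slopes and Brier R² are unaffected. Adaptive-LASSO
variants are insensitive to this (their weights eliminate pool noise).

## Known limitations

* Breslow ties only (no Efron option).
* PSIS information uses the observed univariate information at the MPLE;
  for monotone likelihoods the capped estimate is conservative.
* The RSF grower is single-threaded and aims at screened-set sizes
  (tens of variables), not raw p.
* QC's Hardy–Weinberg test is the 1-df chi-square on genotype counts, not
  an exact test; with very rare alleles its p-values are approximate.
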