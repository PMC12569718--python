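# Methods

## Estimand and time structure

Time is discretised into T = 5 annual intervals (exposure and the
area-level covariates it is confounded with are annual quantities, and the
quantity of interest is a 5-year risk). Within interval t the ordering is:
time-varying covariates L_t are realised, then the annual-mean exposure
A_t, then censoring C_t, then the competing event/death pair — with the
within-interval priority **event > death > censoring**, because follow-up
ends at the earliest of outcome, death and loss to follow-up, examined in
that order. A subject censored mid-interval contributes no event
information for that interval (the partial interval is dropped).

The estimand is the cause-specific cumulative incidence
ψ = P(Y_T^{d} = 1) under a threshold policy d(a) = a(1−ρ) if a > δ, else
a (ρ = 0.05; δ ∈ {12, 10, 9} µg/m³), applied once per interval to the
*natural* draw of that year's exposure, with the intervened value feeding
forward into next year's covariates and exposure. Censoring is removed in
the counterfactual world (it is a nuisance); death is retained as a
competing event: a subject who dies without the event has the outcome
fixed at 0 thereafter, not censored. "Surpass" is read as strict
inequality a > δ; for a continuous exposure the boundary has probability
zero, so the reading cannot affect estimates. Only follow-up-year
exposures are intervened on; the pre-baseline exposure level enters the
baseline covariates (`pm25_hist`).

## Estimation

The LTMLE implementation follows the sequential-regression form for
modified treatment policies with competing risks:

- **Density ratios.** For each t, among subjects at risk and uncensored
  through t−1, a classifier is fitted to the stacked sample
  {(H_t, A_t): label 0} ∪ {(H_t, d(A_t)): label 1}; the held-out odds
  p̂/(1−p̂) at the natural data estimate r_t. Classifier probabilities
  are clipped to (10⁻⁵, 1−10⁻⁵) with a positivity warning when clipping
  occurs; ratios are truncated at an absolute cap (default 100). The
  identity policy short-circuits to r_t ≡ 1 without fitting.
- **Censoring.** ĝ^C_t = P(C_t = 1 | at risk, H_t, A_t) fitted with the
  same learner contract and entering weights as 1/ĝ^C_t; skipped exactly
  (ĝ ≡ 1) when the cohort contains no censoring. Cumulative weights
  Π_{s≤t} r̂_s/ĝ^C_s are truncated per interval at their 99.9th
  percentile (configurable).
- **Iterated regressions.** Backward over t = T..1: the response is the
  next step's targeted pseudo-outcome — 1 for subjects with the event by
  interval t, 0 for subjects dead without it, and Q*_{t+1}(d(A_{t+1}))
  for survivors — regressed on (W, L_1..L_t, A_1..A_{t−1}, A_t) among
  at-risk subjects uncensored through t, with held-out predictions at A_t
  and d(A_t).
- **Targeting.** A one-parameter intercept fluctuation on the logit scale
  with offset logit Q_t and the cumulative weights. The fluctuation
  parameter is obtained directly as the exact root of the weighted score
  equation (Brent's method, xtol 10⁻¹⁴) rather than by iterative GLM
  fitting — the two coincide at the optimum, and the root-finder cannot
  fail to converge on this monotone one-dimensional problem. After each
  step the weighted mean residual is ≲ 10⁻¹⁵, and the empirical EIF mean
  after the full pass is at machine precision (the advertised contract is
  ≤ 10⁻⁶).
- **Inference.** SE = SD(EIF)/√n with Wald 95% CIs (symmetric by
  construction); risk differences use the paired per-subject EIF
  difference on the identical cohort/folds/seed; subgroup contrasts use a
  two-sample z on independent EIF-based SEs. Inference is refused below
  n = 50.

**Cross-fitting** is subject-level with K = 5 folds by default, assigned
by a seeded permutation keyed to sorted subject ids (hence invariant to
input row order); all nuisances are fitted out-of-fold, and a single
pooled targeting/EIF step follows. `folds=1` disables cross-fitting and
exists for exact finite-sample checks (saturated learners then reproduce
enumeration identities to 10⁻⁶, which out-of-fold tabulations cannot).

**Numerical choices.** Interior regression predictions are clipped to
[10⁻⁴, 1−10⁻⁴] before the logit; predictions exactly 0 or 1 (a saturated
cell whose pseudo-outcomes are degenerate) pass through targeting
unchanged via logit = ∓∞, preserving exactness in deterministic strata.
Ties in within-interval transitions resolve by the event > death >
censoring priority. Learners are deterministic given their seed; the
logistic learner standardises features internally for solver
conditioning, uses a binomial GLM for fractional responses, and falls
back to a tiny-ridge weighted logistic under perfect separation.

## Learner contract

All nuisances go through `fit(X, y, sample_weight)` / `predict(X) ∈ [0,1]`.
Provided: a main-terms logistic model, gradient-boosted trees (LightGBM,
single-threaded, seeded), an exact tabulation ("saturated") learner for
discrete problems, and an intercept-only learner used as a deliberately
misspecified nuisance in robustness studies. The AutoML system used in
large-data applications sits naturally behind the same contract but is
not bundled.

## Synthetic cohort generator

`DGPParams`/`generate_cohort` emulate the structure the estimator
assumes, with defaults chosen to resemble the published cohort
description of the motivating study population:

- baseline covariates: female 54.5%; age truncated-normal(68, 4.6) on
  [60, 80] (eligibility requires ≥ 60); college degree 29%; a 7-category
  income draw mapped to an ordinal score; smoking never/former/current
  ≈ 52/39/8.6%; family history 62%; BMI normal(27.5, 4.2);
- exposure: AR(1) around a subject-level mean, marginal mean 10.4 µg/m³
  and SD ≈ 1.46 (IQR ≈ 9.4–11.4), confounded by the current covariates
  (health index, area income);
- treatment-confounder feedback: a latent health index
  h_t = 0.7·h_{t−1} + 0.12·(A_{t−1} − 10.4) + noise that both responds to
  past exposure and predicts future exposure and the hazards;
- annual logistic hazards for event, death and censoring, giving a
  ≈ 1.5% 5-year event risk (the motivating cohorts span ≈ 0.6–1.9%),
  ≈ 1.5%/year mortality and ≈ 1%/year loss to follow-up.

The Monte-Carlo oracle re-simulates the process with censoring removed
and d applied to each year's natural draw. What the generator does *not*
emulate: spatial correlation of exposure, real covariate joint
distributions beyond these marginals, within-year event timing, or
measurement error in addresses/diagnoses — so passing tests demonstrate
estimator correctness under the assumed structure, not robustness to
those real-data features.

`BinaryConfounderDGP` is the discrete companion: two-level exposure
(9.5/10.0 µg/m³), binary confounder with feedback, optional constant
censoring, and an exact path-enumeration oracle. It exists because
saturated learners (and hence exact enumeration identities and the
double-robustness study, which needs an exactly-correct density-ratio
learner) require discrete exposure support; a threshold δ = 9.9 with
ρ = 0.05 maps the high level exactly onto the low one.

## Exposure linkage

Monthly concentrations are point values at the nodes of a regular grid;
the value at a residence is the bilinear interpolation of the nearest
four nodes, and annual exposure is the arithmetic mean of 12 monthly
values. A residence move takes effect on the first day of its recorded
month. Points outside the grid raise an error; a missing node among the
four neighbours (e.g. coastal edges) yields a missing-exposure flag
rather than extrapolation, which later triggers the complete-exposure
eligibility exclusion.

## Validation suite — problem sizes

Replicate-based checks run at sizes chosen to keep the full suite fast on
a single CPU while retaining statistical power: parameter
recovery/coverage uses 150 replicates of n = 5000, T = 5 under the δ = 10
policy against a 10⁶-draw oracle; double robustness uses 150 replicates
of the discrete DGP (n = 2000, T = 2, 5% censoring) per misspecification
arm against the exact enumeration oracle; threshold-ordering uses 30
replicates. Coverage is required to fall in [90%, 98%] and replicate-mean
bias within 2 Monte-Carlo SEs.

## Known limitations

- Density-ratio estimation deteriorates where the shifted exposure has
  little support in the natural conditional distribution (low thresholds);
  clipping and weight truncation bound but do not remove the resulting
  variance — visible as wide CIs for δ = 10 and 9, as in the motivating
  application.
- Cross-fitted estimates are not exactly invariant to K when density
  ratios are reweighted (fold-resampled odds add O(10⁻³) noise at
  n = 10⁴); only the identity-policy estimate is exactly K-invariant.
- Wald CIs can be anti-conservative for very rare outcomes (few events at
  n ≲ 2000).
- Subgroup z tests assume disjoint subgroups; overlapping-group
  comparisons are refused rather than approximated.
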