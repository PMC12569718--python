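# airshift

Counterfactual cardiovascular risk under threshold-based air-pollution
interventions, estimated by cross-fitted longitudinal targeted maximum
likelihood estimation (LTMLE) with death as a competing event.

## The problem

Regulators set annual-mean PM2.5 standards (e.g. 12, 10 or 9 µg/m³). A
natural causal question for an ageing cohort is: *what would the 5-year
risk of a first cardiovascular hospitalization have been if, in every
follow-up year, each person's annual exposure had been reduced by 5%
whenever it exceeded a threshold δ?* This is a **modified treatment
policy** (MTP): the intervention d(a) = a·(1−ρ)·1{a > δ} + a·1{a ≤ δ}
acts on each year's *natural* exposure value rather than setting exposure
to a fixed level, so it respects the exposure distribution actually seen
in the population.

Estimating its effect from observational follow-up data is complicated by

- **treatment-confounder feedback** — time-varying covariates are affected
  by earlier exposure and confound later exposure, so conventional
  time-dependent regression is biased and g-methods are required;
- **competing risks** — death without a prior hospitalization precludes the
  event; the estimand is the cause-specific cumulative incidence, not a
  censoring-based quantity;
- **loss to follow-up** — handled by inverse-probability-of-censoring
  weights.

The package is aimed at environmental epidemiologists and biostatisticians
who want a tested, reproducible implementation of this estimator together
with a synthetic longitudinal cohort generator whose counterfactual risks
are known exactly (by enumeration) or to Monte-Carlo precision, so the
whole pipeline can be validated end to end.

## The estimator

For discrete annual intervals t = 1..T with baseline covariates W,
time-varying covariates L_t, exposure A_t, censoring indicator C_t, event
Y_t and competing death D_t, the target is ψ = P(Y_T^{d} = 1): the
cumulative incidence at T under the policy d, with censoring removed and
death retained. The estimator combines, with subject-level K-fold
cross-fitting (K = 5 by default):

1. **density ratios** r_t = g^d_t(A_t|H_t)/g_t(A_t|H_t), via the
   classification trick — a classifier fitted to a two-copy stacked sample
   (natural vs policy-shifted exposure) whose held-out odds at the natural
   data estimate the ratio;
2. **censoring probabilities** ĝ^C_t entering weights as 1/ĝ^C_t;
3. **iterated outcome regressions** Q_t (backward recursion on targeted
   pseudo-outcomes, with prior-event subjects contributing 1 and subjects
   dead without the event contributing 0), evaluated at the natural and
   shifted exposure;
4. a **targeting step** per backward interval — a one-parameter logistic
   fluctuation with offset logit Q_t and weights Π_{s≤t} r̂_s/ĝ^C_s,
   solved exactly by root finding so the efficient-influence-function
   score equation holds to machine precision;
5. **EIF-based inference** — SE from the sample SD of the per-subject
   influence function, Wald 95% CIs, paired EIF differences for risk
   differences vs the natural course, and two-sample z tests for disjoint
   subgroups.

The estimator is doubly robust: it remains consistent if either the
outcome regressions or the exposure/censoring mechanisms are estimated
consistently.

## Worked example

```python
import airshift as a

params = a.DGPParams(n_subjects=5000, seed=1)   # synthetic ageing cohort
cohort = a.generate_cohort(params)

policy = a.threshold_policy(12)          # reduce by 5% where above 12 µg/m³
natural = a.LongitudinalTMLE(cohort, a.NATURAL, folds=5).fit(seed=1)
intervened = a.LongitudinalTMLE(cohort, policy, folds=5).fit(seed=1)

print(intervened.summary())
contrast = intervened.risk_difference(natural)
print(contrast)
oracle = a.oracle_counterfactual_risk(params, policy, n_mc=1_000_000, seed=9002)
print(f"simulator ground truth: {1000 * oracle:.2f} per mille")
```

Output:

```
Longitudinal TMLE counterfactual risk
==============================================
Policy:            threshold_12
Horizon (years):   5
N subjects:        5000
Risk:              0.016612
SE (EIF):          0.001841
95% CI:            [0.013004, 0.020219]
Risk per mille:    16.61  [13.00, 20.22]
EIF mean:          2.40e-18
Max |score resid|: 1.75e-18
<Contrast threshold_12: RD=-1.09 per mille (-2.02 to -0.17), p=0.021>
simulator ground truth: 16.20 per mille
```

The 5-year counterfactual risk under the δ = 12 policy is 16.61 per mille
(95% CI 13.00–20.22); the risk difference vs the natural course is −1.09
per mille (p = 0.021), i.e. about one avoided hospitalization per
thousand people over five years in this simulated cohort. The simulator's
own million-draw counterfactual risk (16.20 per mille) lies inside the
CI, and the near-zero EIF mean and score residuals confirm the targeting
step solved its estimating equation.

A command-line pipeline is also available:

```bash
airshift simulate --seed 3 --n 5000 --out cohort.csv
airshift estimate --cohort cohort.csv --config run.yaml --seed 3 --out table.csv
```

where `run.yaml` declares covariate roles, policies, learner and folds
(see `airshift.cli`). `airshift link` performs bilinear grid/residence
exposure linkage and `airshift prepare` applies eligibility rules and
absorbing-state encoding to raw occurrence flags.

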