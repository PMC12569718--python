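import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import airshift as a
from airshift.tmle import LongitudinalTMLE, PositivityWarning, crossfit_estimate

SAT = dict(outcome_learner="saturated", ratio_learner="saturated",
           censor_learner="saturated")


def sat_model(coh, policy, folds=1, **kw):
    return LongitudinalTMLE(coh, policy, folds=folds, **SAT, **kw)


# --------------------------------------------------------------------------- #
# density ratios
# --------------------------------------------------------------------------- #
def test_identity_policy_ratios_are_one(discrete_cohort):
    _, coh = discrete_cohort
    res = sat_model(coh, a.NATURAL).fit(seed=0)
    assert np.array_equal(res.diagnostics["nuisance"].ratios, np.ones_like(coh.A))


def test_density_ratio_matches_pmf_enumeration(discrete_cohort, shift_policy):
    """Saturated classifier odds equal the exact shifted/natural empirical
    pmf ratio at t = 1, computed by direct enumeration."""
    _, coh = discrete_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PositivityWarning)
        res = sat_model(coh, shift_policy).fit(seed=0)
    r = res.diagnostics["nuisance"].ratios[:, 0]
    df = coh.df[coh.df["year"] == 1].copy().reset_index(drop=True)
    df["a_shift"] = a.apply_policy(df["pm25"].to_numpy(), shift_policy)
    for (w, l), g in df.groupby(["w", "l"]):
        for a_val in np.unique(g["pm25"]):
            n_nat = (g["pm25"] == a_val).sum()
            n_shift = (g["a_shift"] == a_val).sum()
            expected = min(n_shift / n_nat, 100.0)  # ratio truncation cap
            rows = (df["w"] == w) & (df["l"] == l) & (df["pm25"] == a_val)
            got = np.unique(np.round(r[rows.to_numpy()], 9))
            if n_shift == 0:
                assert (got < 1e-4).all()  # clipped near zero, flagged
            else:
                assert got.size == 1 and got[0] == pytest.approx(expected, rel=1e-6)


def test_ratios_bounded_by_cap(discrete_cohort, shift_policy):
    _, coh = discrete_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PositivityWarning)
        res = sat_model(coh, shift_policy, ratio_cap=3.0).fit(seed=0)
    r = res.diagnostics["nuisance"].ratios
    assert (r >= 0).all() and (r <= 3.0).all()


# --------------------------------------------------------------------------- #
# sequential regressions / targeting identities
# --------------------------------------------------------------------------- #
def test_all_zero_outcomes_give_zero_risk_and_se(discrete_cohort):
    _, coh = discrete_cohort
    df = coh.df.copy()
    df["event"] = 0
    coh0 = a.CohortTable(df, coh.baseline_cols, coh.tv_cols, coh.exposure_col)
    res = sat_model(coh0, a.NATURAL).fit(seed=0)
    assert res.risk == pytest.approx(0.0, abs=1e-10)
    assert res.se == pytest.approx(0.0, abs=1e-10)
    lo, hi = res.conf_int()
    assert lo == pytest.approx(0.0, abs=1e-10) and hi == pytest.approx(0.0, abs=1e-10)


def test_identity_policy_recovers_empirical_incidence(discrete_cohort):
    """No censoring here (discrete fixture has censor_prob = 0): the
    identity-policy saturated plug-in collapses to the empirical mean."""
    _, coh = discrete_cohort
    res = sat_model(coh, a.NATURAL).fit(seed=0)
    assert res.risk == pytest.approx(coh.Y[:, -1].mean(), abs=1e-8)


def test_single_timepoint_gformula_enumeration(shift_policy):
    """T = 1, binary exposure, binary covariate, saturated learners: ψ̂
    equals the brute-force g-formula sum Σ p̂(w,l,a)·Ê[Y|w,l,d(a)]."""
    dgp = a.BinaryConfounderDGP(n_subjects=3000, n_years=1, seed=21)
    coh = dgp.generate()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PositivityWarning)
        res = sat_model(coh, shift_policy).fit(seed=0)
    df = coh.df.copy()
    df["a_shift"] = a.apply_policy(df["pm25"].to_numpy(), shift_policy)
    q = df.groupby(["w", "l", "pm25"])["event"].mean()
    gf = np.mean([q.loc[(r.w, r.l, r.a_shift)] for r in df.itertuples()])
    assert res.risk == pytest.approx(gf, abs=1e-6)


def test_aalen_johansen_agreement(discrete_cohort):
    """Identity policy, competing events, no censoring: ψ̂ equals the
    nonparametric cause-specific cumulative incidence (Aalen-Johansen)."""
    lifelines = pytest.importorskip("lifelines")
    _, coh = discrete_cohort
    res = sat_model(coh, a.NATURAL).fit(seed=0)
    Y, D = coh.Y, coh.D
    T = coh.n_years
    first_y = np.where(Y.any(1), Y.argmax(1) + 1, T + 1)
    first_d = np.where(D.any(1), D.argmax(1) + 1, T + 1)
    time = np.minimum(np.minimum(first_y, first_d), T)
    status = np.where(first_y <= T, 1, np.where(first_d <= T, 2, 0))
    ajf = lifelines.AalenJohansenFitter(calculate_variance=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ajf.fit(time, status, event_of_interest=1)
    aj = float(ajf.cumulative_density_.iloc[-1, 0])
    assert res.risk == pytest.approx(aj, abs=1e-6)


def test_score_equation_and_eif_mean_solved(discrete_cohort, shift_policy):
    _, coh = discrete_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PositivityWarning)
        res = sat_model(coh, shift_policy).fit(seed=0)
    assert max(res.diagnostics["score_residuals"]) <= 1e-6
    assert abs(res.diagnostics["eif_mean"]) <= 1e-6


def test_risk_nondecreasing_in_horizon(shift_policy):
    dgp = a.BinaryConfounderDGP(n_subjects=3000, n_years=3, seed=33)
    coh = dgp.generate()
    risks = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PositivityWarning)
        for h in (1, 2, 3):
            risks.append(sat_model(coh, shift_policy).fit(seed=0, horizon=h).risk)
    assert risks[0] <= risks[1] + 1e-10 and risks[1] <= risks[2] + 1e-10


def test_censoring_weights_keep_estimate_near_truth(shift_policy):
    """With moderate random censoring, IPCW keeps the saturated estimate
    near the exact enumeration truth."""
    dgp = a.BinaryConfounderDGP(n_subjects=20_000, n_years=2, censor_prob=0.15, seed=44)
    coh = dgp.generate()
    assert coh.C.min() == 0  # censoring actually occurs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PositivityWarning)
        res = sat_model(coh, shift_policy).fit(seed=0)
    truth = dgp.exact_risk(shift_policy)
    assert abs(res.risk - truth) < 4 * res.se


# --------------------------------------------------------------------------- #
# cross-fitting mechanics
# --------------------------------------------------------------------------- #
def test_crossfit_K_invariance_saturated(shift_policy):
    """Saturated fits are fold-insensitive: exactly so under the identity
    policy (no ratio reweighting), and up to the fold-resampling noise of
    the density-ratio odds under a point-mass shift."""
    dgp = a.BinaryConfounderDGP(n_subjects=10_000, n_years=2, seed=55)
    coh = dgp.generate()
    n2 = crossfit_estimate(coh, a.NATURAL, learner="saturated", folds=2, seed=0)
    n5 = crossfit_estimate(coh, a.NATURAL, learner="saturated", folds=5, seed=0)
    assert n2.risk == pytest.approx(n5.risk, abs=1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PositivityWarning)
        r2 = crossfit_estimate(coh, shift_policy, learner="saturated", folds=2, seed=0)
        r5 = crossfit_estimate(coh, shift_policy, learner="saturated", folds=5, seed=0)
    assert r2.risk == pytest.approx(r5.risk, abs=1e-2)


def test_subject_order_permutation_invariance(discrete_cohort, shift_policy):
    _, coh = discrete_cohort
    perm_df = coh.df.sample(frac=1.0, random_state=9)
    coh_perm = a.CohortTable(perm_df, coh.baseline_cols, coh.tv_cols, coh.exposure_col)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PositivityWarning)
        r1 = LongitudinalTMLE(coh, shift_policy, folds=5, **SAT).fit(seed=3)
        r2 = LongitudinalTMLE(coh_perm, shift_policy, folds=5, **SAT).fit(seed=3)
    assert r1.risk == r2.risk


def test_repeated_runs_identical(discrete_cohort, shift_policy):
    _, coh = discrete_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PositivityWarning)
        r1 = crossfit_estimate(coh, shift_policy, learner="saturated", folds=5, seed=11)
        r2 = crossfit_estimate(coh, shift_policy, learner="saturated", folds=5, seed=11)
    assert r1.risk == r2.risk and r1.se == r2.se
    assert np.array_equal(r1.influence, r2.influence)


def test_configuration_errors(discrete_cohort, shift_policy):
    _, coh = discrete_cohort
    with pytest.raises(ValueError):
        crossfit_estimate(coh, shift_policy, folds=1)
    with pytest.raises(ValueError):
        LongitudinalTMLE(coh, shift_policy, folds=0)
    small = a.BinaryConfounderDGP(n_subjects=40, n_years=1, seed=1).generate()
    with pytest.raises(ValueError):
        LongitudinalTMLE(small, shift_policy, folds=5)  # n < K*50
    with pytest.raises(ValueError):
        sat_model(small, a.NATURAL).fit(seed=0)  # n < 50 inference refusal


def test_positivity_warning_emitted(discrete_cohort, shift_policy):
    _, coh = discrete_cohort
    with pytest.warns(PositivityWarning):
        sat_model(coh, shift_policy).fit(seed=0)


# --------------------------------------------------------------------------- #
# recovery on the continuous default DGP (single replicate sanity)
# --------------------------------------------------------------------------- #
def test_continuous_pipeline_recovers_oracle_within_ci():
    params = a.DGPParams(n_subjects=5000, seed=77)
    coh = a.generate_cohort(params)
    pol = a.threshold_policy(10)
    res = LongitudinalTMLE(coh, pol, folds=5).fit(seed=0)
    oracle = a.oracle_counterfactual_risk(params, pol, n_mc=300_000, seed=1_000_000)
    lo, hi = res.conf_int()
    assert lo - 0.002 <= oracle <= hi + 0.002  # generous single-replicate band
    assert max(res.diagnostics["score_residuals"]) <= 1e-6
    assert abs(res.diagnostics["eif_mean"]) <= 1e-6
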