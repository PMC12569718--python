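"""Cross-fitted longitudinal TMLE for modified treatment policies.

Estimates the counterfactual cumulative incidence ψ = P(Y_T^{d} = 1) of an
event by horizon T under an exposure intervention d(·), with death as a
competing event and censoring handled by inverse-probability weighting.

The estimator combines three nuisance components, each fitted through the
:mod:`~airshift.learners` contract with subject-level K-fold cross-fitting:

1. **Density ratios** r_t = g^d_t(A_t | H_t) / g_t(A_t | H_t), estimated by
   the classification trick: a two-copy stacked sample (natural exposure
   vs d(natural exposure), labelled by copy) is fitted by a classifier and
   the held-out odds p̂/(1−p̂) at the natural data estimate the ratio.
   The identity policy short-circuits to r_t ≡ 1 with no fit.
2. **Censoring probabilities** ĝ^C_t = P(C_t = 1 | at risk, H_t, A_t),
   entering the weights as 1/ĝ^C_t (skipped when no censoring occurs).
3. **Iterated outcome regressions** Q_t: a backward recursion over
   t = T..1 regressing the next step's targeted pseudo-outcome on
   (history, A_t) among at-risk uncensored subjects — subjects with the
   event contribute pseudo-outcome 1, subjects dead without the event
   contribute 0 (cause-specific cumulative incidence convention) — with
   held-out predictions at the natural and the policy-shifted exposure.

At each backward step the regression is *targeted*: a one-parameter
logistic fluctuation with offset logit(Q_t) and weights
Π_{s≤t} r̂_s / ĝ^C_s is solved exactly by root finding, so that the
weighted score (the relevant component of the efficient influence
function) is zero. The estimate ψ̂ is the mean of the final targeted
prediction at the shifted exposure; its standard error comes from the
sample variance of the per-subject efficient influence function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .data import CohortTable
from .learners import Learner, get_learner
from .policy import Policy, apply_policy

__all__ = ["LongitudinalTMLE", "TMLEResults", "NuisanceFit", "PositivityWarning"]


class PositivityWarning(UserWarning):
    """Emitted when nuisance probabilities are clipped at their bounds."""


@dataclass
class NuisanceFit:
    """Cross-fitted nuisance quantities, one column per interval."""

    ratios: np.ndarray            # r̂_t, (n, T); 1 where unused
    censor_probs: np.ndarray      # ĝ^C_t, (n, T)
    cum_weights: np.ndarray       # truncated Π_{s≤t} r̂_s / ĝ^C_s, (n, T)
    fold_id: np.ndarray           # (n,)
    q_natural: np.ndarray = None  # targeted Q*_t at A_t, (n, T)
    q_shifted: np.ndarray = None  # targeted Q*_t at d(A_t), (n, T)


class TMLEResults:
    """Counterfactual-risk estimate with EIF-based inference."""

    def __init__(self, risk, influence, policy, subject_ids, fold_id,
                 diagnostics, horizon):
        self.risk = float(risk)
        self.influence = influence
        self.policy = policy
        self.subject_ids = subject_ids
        self.fold_id = fold_id
        self.diagnostics = diagnostics
        self.horizon = horizon
        self.nobs = influence.size
        self.se = float(np.std(influence, ddof=1) / np.sqrt(self.nobs))

    def conf_int(self, alpha: float = 0.05):
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return (self.risk - z * self.se, self.risk + z * self.se)

    @property
    def risk_per_mille(self) -> float:
        return 1000.0 * self.risk

    def risk_difference(self, reference: "TMLEResults"):
        from .contrasts import risk_difference

        return risk_difference(self, reference)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Longitudinal TMLE counterfactual risk",
            "=" * 46,
            f"Policy:            {self.policy.label}",
            f"Horizon (years):   {self.horizon}",
            f"N subjects:        {self.nobs}",
            f"Risk:              {self.risk:.6f}",
            f"SE (EIF):          {self.se:.6f}",
            f"95% CI:            [{lo:.6f}, {hi:.6f}]",
            f"Risk per mille:    {self.risk_per_mille:.2f}"
            f"  [{1000 * lo:.2f}, {1000 * hi:.2f}]",
            f"EIF mean:          {self.diagnostics['eif_mean']:.2e}",
            f"Max |score resid|: {max(self.diagnostics['score_residuals'], default=0.0):.2e}",
        ]
        return "\n".join(lines)

    def __repr__(self):
        lo, hi = self.conf_int()
        return (f"<TMLEResults {self.policy.label}: risk={self.risk:.5f} "
                f"(95% CI {lo:.5f}-{hi:.5f}), n={self.nobs}>")


class LongitudinalTMLE:
    """Model object: cohort + policy + learner configuration.

    Parameters
    ----------
    data : CohortTable
        Validated long-format cohort.
    policy : Policy
        The intervention whose counterfactual risk is estimated.
    outcome_learner, ratio_learner, censor_learner : str or Learner
        Learner names ("logistic", "gbt", "saturated", "marginal") or
        instances, used for the iterated regressions, the density-ratio
        classifier, and the censoring model respectively.
    folds : int
        Number of cross-fitting folds (default 5; subject-level,
        seed-assigned). ``folds=1`` disables cross-fitting — used for
        exact small-sample checks where out-of-fold predictions would
        perturb finite-sample identities.
    ratio_cap : float
        Absolute truncation cap for the per-interval density ratios.
    weight_quantile : float or None
        Per-interval quantile at which cumulative weights are truncated
        (default 0.999); ``None`` disables.
    """

    def __init__(self, data: CohortTable, policy: Policy,
                 outcome_learner="logistic", ratio_learner="logistic",
                 censor_learner="logistic", folds: int = 5,
                 ratio_cap: float = 100.0, weight_quantile: float | None = 0.999,
                 q_clip: float = 1e-4, p_clip: float = 1e-5):
        if folds < 1:
            raise ValueError("folds must be >= 1 (>= 2 for cross-fitting)")
        if folds >= 2 and data.n_subjects < folds * 50:
            raise ValueError(
                f"cross-fitting with K={folds} needs at least {folds * 50} subjects"
            )
        self.data = data
        self.policy = policy
        self.outcome_learner = outcome_learner
        self.ratio_learner = ratio_learner
        self.censor_learner = censor_learner
        self.folds = folds
        self.ratio_cap = float(ratio_cap)
        self.weight_quantile = weight_quantile
        self.q_clip = float(q_clip)
        self.p_clip = float(p_clip)

    # ------------------------------------------------------------------ #
    def _fold_map(self, seed: int) -> np.ndarray:
        """Seeded subject-level folds, invariant to input row order."""
        n = self.data.n_subjects
        order = np.argsort(self.data.subject_ids, kind="stable")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        fold_of_rank = np.arange(n) % self.folds
        fold_id = np.empty(n, dtype=int)
        fold_id[order[perm]] = fold_of_rank
        return fold_id

    def _design(self, t: int, a_col: np.ndarray, arrays) -> np.ndarray:
        """Features at interval t (0-based): (W, L_1..L_t, A_1..A_{t-1}, a)."""
        W, A, L = arrays["W"], arrays["A"], arrays["L"]
        n = W.shape[0]
        parts = [W, L[:, : t + 1, :].reshape(n, -1), A[:, :t], a_col[:, None]]
        return np.column_stack(parts)

    def _crossfit(self, learner_spec, X_fit, y, w, fit_mask, predict_jobs,
                  fold_id, seed):
        """Fit on training folds, predict held-out. predict_jobs is a list of
        (X_pred, mask) pairs; returns one (n,) array per job (filled where mask)."""
        n = fold_id.size
        outs = [np.full(n, np.nan) for _ in predict_jobs]
        folds = np.unique(fold_id) if self.folds > 1 else [None]
        for k in folds:
            if k is None:
                tr = fit_mask
                te = np.ones(n, dtype=bool)
            else:
                tr = fit_mask & (fold_id != k)
                te = fold_id == k
                if not tr.any():
                    tr = fit_mask
            learner = get_learner(learner_spec, seed=seed)
            learner.fit(X_fit[tr], y[tr], None if w is None else w[tr])
            for out, (X_pred, mask) in zip(outs, predict_jobs):
                sel = te & mask
                if sel.any():
                    out[sel] = learner.predict(X_pred[sel])
        return outs

    def _crossfit_stacked(self, learner_spec, X_nat, X_shift, fit_mask,
                          fold_id, seed):
        """Density-ratio classifier on the two-copy stacked sample; returns
        held-out P(label = shifted | features) at the *natural* data."""
        n = fold_id.size
        out = np.full(n, np.nan)
        folds = np.unique(fold_id) if self.folds > 1 else [None]
        for k in folds:
            if k is None:
                tr = fit_mask
                te = fit_mask
            else:
                tr = fit_mask & (fold_id != k)
                te = fit_mask & (fold_id == k)
                if not tr.any():
                    tr = fit_mask
            Xs = np.vstack([X_nat[tr], X_shift[tr]])
            ys = np.concatenate([np.zeros(tr.sum()), np.ones(tr.sum())])
            learner = get_learner(learner_spec, seed=seed)
            learner.fit(Xs, ys, None)
            if te.any():
                out[te] = learner.predict(X_nat[te])
        return out

    # ------------------------------------------------------------------ #
    def fit(self, seed: int = 0, horizon: int | None = None) -> TMLEResults:
        """Run the full cross-fitted targeted estimation. Deterministic in ``seed``."""
        d = self.data
        T_full = d.n_years
        T = T_full if horizon is None else int(horizon)
        if not 1 <= T <= T_full:
            raise ValueError(f"horizon must be in 1..{T_full}")
        n = d.n_subjects
        W, A, L = d.W, d.A[:, :T], d.L[:, :T, :]
        C, Y, D = d.C[:, :T], d.Y[:, :T], d.D[:, :T]
        A_shift = np.asarray(apply_policy(np.where(np.isnan(A), np.nan, A), self.policy)) \
            if not self.policy.is_natural else A
        arrays = {"W": W, "A": A, "L": L}

        Cprev = np.column_stack([np.ones(n, dtype=int), C[:, :-1]])
        Yprev = np.column_stack([np.zeros(n, dtype=int), Y[:, :-1]])
        Dprev = np.column_stack([np.zeros(n, dtype=int), D[:, :-1]])
        at_risk = (Yprev == 0) & (Dprev == 0)
        obs = at_risk & (Cprev == 1)
        contrib = at_risk & (C == 1)

        fold_id = self._fold_map(seed)
        n_clipped = 0

        # ---- forward pass: density ratios and censoring probabilities ---- #
        ratios = np.ones((n, T))
        gC = np.ones((n, T))
        has_cens = C.min() < 1
        for t in range(T):
            m = obs[:, t]
            if not self.policy.is_natural:
                X_nat = self._design(t, A[:, t], arrays)
                X_sh = self._design(t, A_shift[:, t], arrays)
                p = self._crossfit_stacked(
                    self.ratio_learner, X_nat, X_sh, m, fold_id,
                    seed=seed + 1000 + t,
                )
                raw = p[m]
                clipped = np.clip(raw, self.p_clip, 1 - self.p_clip)
                n_clipped += int(np.sum(raw != clipped))
                ratios[m, t] = np.minimum(clipped / (1 - clipped), self.ratio_cap)
            if has_cens:
                X_nat = self._design(t, A[:, t], arrays)
                (g,) = self._crossfit(
                    self.censor_learner, X_nat, C[:, t].astype(float), None,
                    m, [(X_nat, m)], fold_id, seed=seed + 2000 + t,
                )
                gC[m, t] = np.clip(g[m], self.p_clip, 1.0)

        cw_raw = np.ones(n)
        cum_weights = np.ones((n, T))
        for t in range(T):
            m = obs[:, t]
            cw_raw = np.where(m, cw_raw * ratios[:, t] / gC[:, t], cw_raw)
            cw_t = cw_raw.copy()
            if self.weight_quantile is not None and contrib[:, t].any():
                cap = np.quantile(cw_t[contrib[:, t]], self.weight_quantile)
                cw_t = np.minimum(cw_t, cap)
            cum_weights[:, t] = cw_t

        if n_clipped:
            warnings.warn(
                f"{n_clipped} density-ratio classifier probabilities clipped to "
                f"({self.p_clip}, {1 - self.p_clip}); possible positivity violation",
                PositivityWarning, stacklevel=2,
            )

        # ---- backward pass: iterated regressions + targeting ------------- #
        q_nat_star = np.full((n, T), np.nan)
        q_shift_star = np.full((n, T), np.nan)
        score_residuals = []
        eif_terms = np.zeros(n)
        Z = np.zeros(n)  # carried pseudo-outcome (targeted, at shifted exposure)
        for t in range(T - 1, -1, -1):
            m_obs = obs[:, t]
            m_fit = contrib[:, t]
            z_next = np.where(Y[:, t] == 1, 1.0, np.where(D[:, t] == 1, 0.0, Z))
            X_nat = self._design(t, A[:, t], arrays)
            jobs = [(X_nat, m_obs)]
            if not self.policy.is_natural:
                jobs.append((self._design(t, A_shift[:, t], arrays), m_obs))
            preds = self._crossfit(
                self.outcome_learner, X_nat, z_next, None, m_fit, jobs,
                fold_id, seed=seed + 3000 + t,
            )
            q_nat = preds[0]
            q_shift = preds[0] if self.policy.is_natural else preds[1]

            w = cum_weights[:, t]
            off_nat = logit(np.clip(q_nat[m_obs], self.q_clip, 1 - self.q_clip))
            off_shift = logit(np.clip(q_shift[m_obs], self.q_clip, 1 - self.q_clip))
            eps = _solve_fluctuation(
                off_nat[m_fit[m_obs]], z_next[m_fit], w[m_fit]
            )
            qn = np.full(n, np.nan)
            qs = np.full(n, np.nan)
            qn[m_obs] = expit(off_nat + eps)
            qs[m_obs] = expit(off_shift + eps)
            q_nat_star[:, t] = qn
            q_shift_star[:, t] = qs

            resid = np.zeros(n)
            resid[m_fit] = w[m_fit] * (z_next[m_fit] - qn[m_fit])
            eif_terms += resid
            score_residuals.append(abs(resid.sum()) / n)

            Z = np.where(m_obs, qs, z_next)

        psi = float(Z.mean())
        influence = eif_terms + Z - psi
        if n < 50:
            raise ValueError("EIF-based inference refused for n < 50")
        diagnostics = {
            "score_residuals": score_residuals[::-1],  # in time order t=1..T
            "eif_mean": float(influence.mean()),
            "max_cum_weight": float(cum_weights.max()),
            "n_prob_clipped": n_clipped,
            "nuisance": NuisanceFit(
                ratios=ratios, censor_probs=gC, cum_weights=cum_weights,
                fold_id=fold_id, q_natural=q_nat_star, q_shifted=q_shift_star,
            ),
        }
        return TMLEResults(psi, influence, self.policy, d.subject_ids.copy(),
                           fold_id, diagnostics, horizon=T)


def _solve_fluctuation(offset, z, w) -> float:
    """Exact intercept fluctuation: solve Σ w (z − expit(offset + ε)) = 0."""
    if offset.size == 0 or np.sum(w) == 0:
        return 0.0

    def score(eps):
        return float(np.sum(w * (z - expit(offset + eps))))

    lo, hi = -20.0, 20.0
    s_lo, s_hi = score(lo), score(hi)
    if s_lo == 0.0:
        return lo
    if s_hi == 0.0:
        return hi
    if s_lo < 0 <= s_hi or s_hi < 0 <= s_lo:
        return brentq(score, lo, hi, xtol=1e-14, maxiter=200)
    # score has the same sign across the bracket: all z at one boundary;
    # take the end minimising |score|
    return lo if abs(s_lo) < abs(s_hi) else hi


# --------------------------------------------------------------------------- #
# functional surface mirroring the estimation steps (thin wrappers)
# --------------------------------------------------------------------------- #
def estimate_density_ratios(data: CohortTable, policy: Policy, learner="logistic",
                            folds: int = 5, seed: int = 0,
                            ratio_cap: float = 100.0) -> np.ndarray:
    """Per-interval cross-fitted density ratios r̂_t, shape (n, T)."""
    model = LongitudinalTMLE(data, policy, ratio_learner=learner, folds=folds,
                             ratio_cap=ratio_cap)
    res = model.fit(seed=seed)
    return res.diagnostics["nuisance"].ratios


def crossfit_estimate(data: CohortTable, policy: Policy, learner="logistic",
                      folds: int = 5, seed: int = 0, **kwargs) -> TMLEResults:
    """Cross-fitted LTMLE estimate with one learner for all nuisances."""
    if folds < 2:
        raise ValueError("crossfit_estimate requires K >= 2 folds")
    model = LongitudinalTMLE(data, policy, outcome_learner=learner,
                             ratio_learner=learner, censor_learner=learner,
                             folds=folds, **kwargs)
    return model.fit(seed=seed)
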