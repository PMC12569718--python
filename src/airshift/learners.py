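"""Nuisance-model learner contract.

Every nuisance quantity in the estimator — density-ratio classifiers,
censoring probabilities, iterated outcome regressions — is fitted through
the same small contract: ``fit(X, y, sample_weight)`` with a response in
[0, 1] (binary labels or fractional pseudo-outcomes) and ``predict(X)``
returning probabilities in [0, 1]. Learners must be deterministic given
their seed, so cross-fitted estimates are reproducible bit-for-bit.

Provided implementations:

``LogisticLearner``
    Main-terms logistic regression via a binomial GLM (fractional
    responses enter through variance weights); falls back to a
    ridge-stabilised solver under perfect separation.
``GradientBoostedLearner``
    LightGBM trees (single-threaded, deterministic).
``SaturatedLearner``
    Exact tabulation over unique covariate rows — the weighted mean of the
    response per cell, with unseen cells mapped to the overall weighted
    mean. Used where discrete test problems admit exact answers.
``MarginalMeanLearner``
    Intercept-only (ignores covariates); useful as a deliberately
    misspecified nuisance in robustness studies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "Learner",
    "LogisticLearner",
    "GradientBoostedLearner",
    "SaturatedLearner",
    "MarginalMeanLearner",
    "get_learner",
]


class Learner:
    """Abstract nuisance learner: probabilities in [0, 1], seeded."""

    seed: int = 0

    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight=None) -> "Learner":
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def fresh(self) -> "Learner":
        """A new unfitted copy with the same configuration."""
        import copy

        return copy.deepcopy(self)


def _ridge_logistic(X, y, w, l2=1e-6):
    """Weighted logistic MLE with a tiny L2 penalty (separation-proof)."""
    Xd = np.column_stack([np.ones(len(X)), X])
    w = np.ones(len(y)) if w is None else np.asarray(w, float)

    def nll(beta):
        eta = Xd @ beta
        # log(1 + exp(eta)) - y*eta, numerically stable
        ll = w * (np.logaddexp(0.0, eta) - y * eta)
        return ll.sum() + 0.5 * l2 * beta[1:] @ beta[1:]

    def grad(beta):
        p = expit(Xd @ beta)
        g = Xd.T @ (w * (p - y))
        g[1:] += l2 * beta[1:]
        return g

    res = minimize(nll, np.zeros(Xd.shape[1]), jac=grad, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    return res.x


class LogisticLearner(Learner):
    """Main-terms logistic model (binomial GLM; fractional y allowed)."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._beta = None
        self._const = None

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if y.min() == y.max():
            self._const = float(y[0])
            self._beta = None
            return self
        self._const = None
        # standardise for solver conditioning; coefficients mapped back below
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        if np.isin(y, (0.0, 1.0)).all():
            # binary labels: fast near-unpenalised solver
            from sklearn.linear_model import LogisticRegression

            try:
                clf = LogisticRegression(C=1e4, max_iter=1000, tol=1e-8)
                clf.fit(Xs, y, sample_weight=sample_weight)
                b0 = clf.intercept_[0]
                b = clf.coef_.ravel() / sd
                beta = np.concatenate([[b0 - mu @ b], b])
            except Exception:
                beta = _ridge_logistic(X, y, sample_weight)
        else:
            # fractional pseudo-outcomes: binomial GLM with variance weights
            import statsmodels.api as sm

            Xd = sm.add_constant(X, has_constant="add")
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = sm.GLM(y, Xd, family=sm.families.Binomial(),
                                   var_weights=sample_weight)
                    res = model.fit(maxiter=100, tol=1e-10)
                beta = np.asarray(res.params, float)
                if not np.all(np.isfinite(beta)):
                    raise ValueError("non-finite GLM coefficients")
            except Exception:
                beta = _ridge_logistic(X, y, sample_weight)
        self._beta = beta
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        if self._const is not None:
            return np.full(len(X), self._const)
        Xd = np.column_stack([np.ones(len(X)), X])
        return expit(Xd @ self._beta)


class GradientBoostedLearner(Learner):
    """Gradient-boosted trees (LightGBM), deterministic given the seed."""

    def __init__(self, seed: int = 0, n_estimators: int = 100,
                 learning_rate: float = 0.1, max_depth: int = 3,
                 min_child_samples: int = 20):
        self.seed = seed
        self.params = dict(
            n_estimators=n_estimators, learning_rate=learning_rate,
            max_depth=max_depth, min_child_samples=min_child_samples,
        )
        self._model = None
        self._const = None

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if y.min() == y.max():
            self._const = float(y[0])
            self._model = None
            return self
        self._const = None
        import lightgbm as lgb

        binary = np.isin(y, (0.0, 1.0)).all()
        cls = lgb.LGBMClassifier if binary else lgb.LGBMRegressor
        self._binary = binary
        self._model = cls(
            random_state=self.seed, n_jobs=1, deterministic=True,
            verbosity=-1, **self.params,
        )
        self._model.fit(X, y, sample_weight=sample_weight)
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        if self._const is not None:
            return np.full(len(X), self._const)
        if self._binary:
            return self._model.predict_proba(X)[:, 1]
        return np.clip(self._model.predict(X), 0.0, 1.0)


class SaturatedLearner(Learner):
    """Exact tabulation over unique covariate rows (weighted cell means)."""

    def __init__(self, seed: int = 0, decimals: int = 10):
        self.seed = seed
        self.decimals = decimals  # rounding to merge float keys robustly
        self._table = None
        self._default = None

    def _rows(self, X) -> np.ndarray:
        X = np.round(np.asarray(X, float), self.decimals) + 0.0  # -0.0 -> 0.0
        return np.ascontiguousarray(X)

    def fit(self, X, y, sample_weight=None):
        y = np.asarray(y, float)
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
        rows = self._rows(X)
        uniq, inverse = np.unique(rows, axis=0, return_inverse=True)
        wy = np.bincount(inverse, weights=w * y, minlength=len(uniq))
        ww = np.bincount(inverse, weights=w, minlength=len(uniq))
        means = wy / ww
        self._table = {u.tobytes(): m for u, m in zip(uniq, means)}
        self._default = float(np.sum(w * y) / np.sum(w))
        return self

    def predict(self, X):
        rows = self._rows(X)
        return np.array([self._table.get(r.tobytes(), self._default) for r in rows])


class MarginalMeanLearner(Learner):
    """Intercept-only learner: predicts the weighted mean response."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._mean = 0.5

    def fit(self, X, y, sample_weight=None):
        y = np.asarray(y, float)
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
        self._mean = float(np.sum(w * y) / np.sum(w))
        return self

    def predict(self, X):
        return np.full(len(np.asarray(X)), self._mean)


_REGISTRY = {
    "logistic": LogisticLearner,
    "gbt": GradientBoostedLearner,
    "saturated": SaturatedLearner,
    "marginal": MarginalMeanLearner,
}


def get_learner(spec, seed: int = 0) -> Learner:
    """Resolve a learner name or instance into a fresh seeded learner."""
    if isinstance(spec, Learner):
        out = spec.fresh()
        out.seed = seed
        return out
    if spec in _REGISTRY:
        return _REGISTRY[spec](seed=seed)
    raise KeyError(f"unknown learner {spec!r}; choose from {sorted(_REGISTRY)}")
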