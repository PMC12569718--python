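"""Long-format longitudinal cohort container.

One row per subject-year, ``T`` rows per subject (annual discrete time).
Required structural columns:

========  ====================================================================
column    meaning
========  ====================================================================
subject_id  subject identifier (any hashable)
year        interval index t = 1..T
<exposure>  annual-mean exposure A_t (µg/m³); default column name ``pm25``
uncensored  C_t ∈ {0,1}: 1 while the subject remains uncensored through t
event       Y_t ∈ {0,1}: event (hospitalization) by the end of interval t
death       D_t ∈ {0,1}: death *without prior event* by the end of interval t
========  ====================================================================

Baseline covariates W repeat on every row of a subject; time-varying
covariates L_t vary by row. Event and death are absorbing (monotone
nondecreasing), censoring is monotone (C nonincreasing), and the
competing-event convention holds: once the event occurs D is frozen, and
death without a prior event fixes Y at 0 thereafter. Exposure and
time-varying covariates must be present for every interval with
C_{t-1} = 1 (complete-exposure eligibility).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CohortTable", "SchemaError"]

STRUCT_COLS = ("subject_id", "year", "uncensored", "event", "death")


class SchemaError(ValueError):
    """Raised when a cohort table violates the longitudinal schema."""


class CohortTable:
    """Validated long-format cohort with declared covariate roles."""

    def __init__(
        self,
        df: pd.DataFrame,
        baseline_cols: Sequence[str],
        tv_cols: Sequence[str],
        exposure_col: str = "pm25",
        validate: bool = True,
    ):
        self.baseline_cols = list(baseline_cols)
        self.tv_cols = list(tv_cols)
        self.exposure_col = exposure_col
        needed = set(STRUCT_COLS) | set(self.baseline_cols) | set(self.tv_cols) | {exposure_col}
        missing = needed - set(df.columns)
        if missing:
            raise SchemaError(f"missing columns: {sorted(missing)}")
        df = df.sort_values(["subject_id", "year"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self.subject_ids = df["subject_id"].to_numpy()[:: self._infer_T(df)]
        if validate:
            self.validate()

    @staticmethod
    def _infer_T(df: pd.DataFrame) -> int:
        return int(df["year"].max())

    # ------------------------------------------------------------------ #
    @property
    def n_subjects(self) -> int:
        return self.subject_ids.size

    @property
    def n_years(self) -> int:
        return self._infer_T(self.df)

    def _wide(self, col: str) -> np.ndarray:
        """(n_subjects, T) array of a per-year column, subjects in id order."""
        return self.df[col].to_numpy(dtype=float).reshape(self.n_subjects, self.n_years)

    @property
    def W(self) -> np.ndarray:
        """(n, p) baseline covariate matrix."""
        first = self.df.iloc[:: self.n_years]
        return first[self.baseline_cols].to_numpy(dtype=float)

    @property
    def A(self) -> np.ndarray:
        return self._wide(self.exposure_col)

    @property
    def L(self) -> np.ndarray:
        """(n, T, q) time-varying covariates."""
        n, T = self.n_subjects, self.n_years
        if not self.tv_cols:
            return np.empty((n, T, 0))
        return np.stack([self._wide(c) for c in self.tv_cols], axis=2)

    @property
    def C(self) -> np.ndarray:
        return self._wide("uncensored").astype(int)

    @property
    def Y(self) -> np.ndarray:
        return self._wide("event").astype(int)

    @property
    def D(self) -> np.ndarray:
        return self._wide("death").astype(int)

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        df = self.df
        counts = df.groupby("subject_id", sort=False)["year"].agg(["count", "min", "max"])
        T = self.n_years
        if not ((counts["count"] == T).all() and (counts["min"] == 1).all()
                and (counts["max"] == T).all()):
            raise SchemaError("each subject must have exactly one row per year 1..T")
        C, Y, D = self.C, self.Y, self.D
        for name, arr in (("uncensored", C), ("event", Y), ("death", D)):
            if not np.isin(arr, (0, 1)).all():
                raise SchemaError(f"{name} must be binary")
        if np.any(np.diff(Y, axis=1) < 0) or np.any(np.diff(D, axis=1) < 0):
            raise SchemaError("event/death indicators must be absorbing (nondecreasing)")
        if np.any(np.diff(C, axis=1) > 0):
            raise SchemaError("censoring must be monotone (uncensored nonincreasing)")
        # competing-event convention: death without prior event freezes Y at 0;
        # event freezes D at its value at the event time
        n = self.n_subjects
        first_y = np.where(Y.any(axis=1), Y.argmax(axis=1), T)
        first_d = np.where(D.any(axis=1), D.argmax(axis=1), T)
        both = (first_y < T) & (first_d < T)
        if np.any(both & (first_d < first_y)):
            raise SchemaError("event after death violates the competing-event convention")
        if np.any(both & (first_d > first_y) & (first_y < T)):
            # death newly recorded after the event: D must have been frozen
            raise SchemaError("death indicator must be frozen after the event")
        # exposure / time-varying covariates present while uncensored
        Cprev = np.column_stack([np.ones(n, dtype=int), C[:, :-1]])
        obs = Cprev == 1
        if np.any(np.isnan(self.A[obs])):
            raise SchemaError("exposure missing for an uncensored interval")
        L = self.L
        if L.shape[2] and np.any(np.isnan(L[obs])):
            raise SchemaError("time-varying covariate missing for an uncensored interval")

    # ------------------------------------------------------------------ #
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, baseline_cols, tv_cols, exposure_col="pm25") -> "CohortTable":
        return cls(pd.read_csv(path), baseline_cols, tv_cols, exposure_col)
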