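"""Eligibility filtering and longitudinal process encoding.

Eligibility is evaluated at the baseline year: subjects must be at least 60
years old, have no prior hospitalization for the analysed disease subtype,
and have complete exposure data over follow-up. Exclusions are counted
per criterion, flowchart-style.

:func:`encode_processes` turns raw per-interval occurrence flags (event,
death, loss to follow-up) into the absorbing encodings the estimator
requires: the event indicator is carried forward once the event occurs;
death without a prior event fixes the event indicator at 0 thereafter (the
competing-event convention — such subjects are *not* censored); censoring
is monotone. Within an interval the priority is event > death > censoring,
because follow-up ends at the earliest of outcome, death and loss to
follow-up, examined in that order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CohortTable

__all__ = ["EligibilitySpec", "DataIntegrityError", "filter_eligible", "encode_processes"]


class DataIntegrityError(ValueError):
    """Raised when raw indicators are inconsistent (e.g. non-monotone)."""


@dataclass(frozen=True)
class EligibilitySpec:
    min_age_at_baseline: float = 60.0
    require_no_prior_event: bool = True
    require_complete_exposure: bool = True


def filter_eligible(
    raw: pd.DataFrame,
    spec: EligibilitySpec = EligibilitySpec(),
    age_col: str = "age",
    prior_event_col: str = "prior_event",
    exposure_col: str = "pm25",
) -> tuple[pd.DataFrame, dict]:
    """Apply eligibility criteria sequentially; return (kept rows, exclusion log).

    ``raw`` is a long subject-year table; ``age_col`` is age at the baseline
    year and ``prior_event_col`` flags a pre-baseline hospitalization for
    the analysed subtype (one value per subject; the same subject may be
    eligible for a different subtype). The log counts *subjects* excluded
    at each step, in order: age, prior event, incomplete exposure.
    """
    df = raw.sort_values(["subject_id", "year"], kind="mergesort")
    per_subject = df.groupby("subject_id", sort=True)
    age = per_subject[age_col].first()
    keep = pd.Series(True, index=age.index)
    log: dict[str, int] = {"total": int(keep.size)}

    below_age = age < spec.min_age_at_baseline
    log["age_below_minimum"] = int((keep & below_age).sum())
    keep &= ~below_age

    if spec.require_no_prior_event:
        if prior_event_col not in df.columns:
            raise KeyError(f"column {prior_event_col!r} required for prior-event rule")
        prior = per_subject[prior_event_col].first().astype(bool)
        log["prior_event"] = int((keep & prior).sum())
        keep &= ~prior
    if spec.require_complete_exposure:
        # exposure must be non-missing for every uncensored interval
        cens_ok = per_subject.apply(_complete_exposure, exposure_col, include_groups=False)
        log["incomplete_exposure"] = int((keep & ~cens_ok).sum())
        keep &= cens_ok

    log["eligible"] = int(keep.sum())
    kept_ids = keep.index[keep]
    out = df[df["subject_id"].isin(kept_ids)].reset_index(drop=True)
    if out.empty:
        import warnings

        warnings.warn("no subjects remain after eligibility filtering", stacklevel=2)
    return out, log


def _complete_exposure(g: pd.DataFrame, exposure_col: str) -> bool:
    g = g.sort_values("year")
    if "uncensored" in g.columns:
        cens_prev = np.concatenate([[1], g["uncensored"].to_numpy()[:-1]])
        required = cens_prev == 1
    else:
        required = np.ones(len(g), dtype=bool)
    return bool(~np.any(np.isnan(g[exposure_col].to_numpy(dtype=float)[required])))


def encode_processes(
    raw: pd.DataFrame,
    event_col: str = "event_occurred",
    death_col: str = "death_occurred",
    censor_col: str = "censor_occurred",
) -> pd.DataFrame:
    """Absorbing encodings from per-interval occurrence flags.

    Input: long table with binary flags marking the interval in which the
    event / death / loss to follow-up occurred. Output adds ``event``
    (Y_t, carried forward), ``death`` (D_t: death without prior event),
    and ``uncensored`` (C_t, monotone). Flags recorded after a subject has
    already been absorbed by another terminal state raise
    :class:`DataIntegrityError`.
    """
    df = raw.sort_values(["subject_id", "year"], kind="mergesort").reset_index(drop=True)
    for col in (event_col, death_col, censor_col):
        if col not in df.columns:
            raise KeyError(f"missing occurrence column {col!r}")
        if not df[col].isin((0, 1)).all():
            raise DataIntegrityError(f"{col} must be binary occurrence flags")
    n_per = df.groupby("subject_id", sort=False)["year"].transform("size")
    T = int(df["year"].max())
    if not (n_per == T).all():
        raise DataIntegrityError("each subject needs one row per interval 1..T")
    ev = df[event_col].to_numpy(int).reshape(-1, T)
    de = df[death_col].to_numpy(int).reshape(-1, T)
    ce = df[censor_col].to_numpy(int).reshape(-1, T)

    Y = np.zeros_like(ev)
    D = np.zeros_like(ev)
    C = np.ones_like(ev)
    state = np.zeros(ev.shape[0], dtype=int)  # 0 at risk, 1 event, 2 dead, 3 censored
    for t in range(T):
        flags = ev[:, t] + de[:, t] + ce[:, t]
        if np.any((state != 0) & (flags > 0)):
            raise DataIntegrityError(
                "occurrence flag after a terminal transition (non-monotone raw data)"
            )
        # within-interval priority: event > death > censoring
        new_event = (state == 0) & (ev[:, t] == 1)
        new_death = (state == 0) & ~new_event & (de[:, t] == 1)
        new_cens = (state == 0) & ~new_event & ~new_death & (ce[:, t] == 1)
        state = np.select([new_event, new_death, new_cens], [1, 2, 3], default=state)
        Y[:, t] = (state == 1).astype(int)
        D[:, t] = (state == 2).astype(int)
        C[:, t] = (state != 3).astype(int)
    out = df.copy()
    out["event"] = Y.reshape(-1)
    out["death"] = D.reshape(-1)
    out["uncensored"] = C.reshape(-1)
    return out


def as_cohort(df: pd.DataFrame, baseline_cols, tv_cols, exposure_col="pm25") -> CohortTable:
    """Wrap an encoded long table as a validated :class:`CohortTable`."""
    return CohortTable(df, baseline_cols, tv_cols, exposure_col)
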