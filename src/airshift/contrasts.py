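"""Risk-difference contrasts and subgroup comparisons.

The risk difference RD = ψ̂_policy − ψ̂_natural is estimated on the same
cohort, folds and seed; its standard error comes from the *paired*
per-subject difference of the two efficient influence functions, and its
confidence interval is Wald. Subgroup differences (disjoint subgroups,
hence independent estimates) are compared with a two-sample z test.
Risks and differences are reported per mille (×1000) where requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .tmle import TMLEResults

__all__ = ["Contrast", "risk_difference", "subgroup_compare"]


@dataclass
class Contrast:
    """Risk difference vs the natural course, with EIF-based inference."""

    rd: float
    se: float
    risk_policy: float
    risk_natural: float
    policy_label: str
    nobs: int
    subject_ids: np.ndarray = None

    @property
    def rd_per_mille(self) -> float:
        return 1000.0 * self.rd

    def conf_int(self, alpha: float = 0.05):
        z = norm.ppf(1 - alpha / 2)
        return (self.rd - z * self.se, self.rd + z * self.se)

    @property
    def p_value(self) -> float:
        if self.se == 0.0:
            return 1.0 if self.rd == 0.0 else 0.0
        z = self.rd / self.se
        return float(2.0 * norm.sf(abs(z)))

    def __repr__(self):
        lo, hi = self.conf_int()
        return (f"<Contrast {self.policy_label}: RD={self.rd_per_mille:.2f} per mille "
                f"({1000 * lo:.2f} to {1000 * hi:.2f}), p={self.p_value:.3g}>")


def risk_difference(est_policy: TMLEResults, est_natural: TMLEResults) -> Contrast:
    """Paired risk-difference contrast between two estimates on one cohort.

    Both estimates must come from the identical cohort, fold assignment and
    horizon, so the per-subject EIF difference is well defined.
    """
    if est_policy.nobs != est_natural.nobs or not np.array_equal(
        est_policy.subject_ids, est_natural.subject_ids
    ):
        raise ValueError("estimates were not computed on the identical cohort")
    if not np.array_equal(est_policy.fold_id, est_natural.fold_id):
        raise ValueError("estimates use different fold assignments")
    if est_policy.horizon != est_natural.horizon:
        raise ValueError("estimates use different horizons")
    rd = est_policy.risk - est_natural.risk
    delta = est_policy.influence - est_natural.influence
    n = est_policy.nobs
    se = float(np.std(delta, ddof=1) / np.sqrt(n))
    return Contrast(
        rd=float(rd), se=se, risk_policy=est_policy.risk,
        risk_natural=est_natural.risk, policy_label=est_policy.policy.label,
        nobs=n, subject_ids=est_policy.subject_ids,
    )


def subgroup_compare(contrast_a: Contrast, contrast_b: Contrast) -> float:
    """Two-sided p for RD_a = RD_b across disjoint subgroups.

    z = (RD_a − RD_b) / sqrt(SE_a² + SE_b²); the subgroups must not share
    subjects (independence of the two estimates).
    """
    if (contrast_a.subject_ids is not None and contrast_b.subject_ids is not None
            and np.intersect1d(contrast_a.subject_ids, contrast_b.subject_ids).size):
        raise ValueError("subgroups overlap; the z test assumes disjoint subgroups")
    denom = float(np.hypot(contrast_a.se, contrast_b.se))
    diff = contrast_a.rd - contrast_b.rd
    if denom == 0.0:
        return 1.0 if diff == 0.0 else 0.0
    z = diff / denom
    return float(2.0 * norm.sf(abs(z)))
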