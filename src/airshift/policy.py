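"""Hypothetical exposure interventions (modified treatment policies).

A threshold policy reduces each year's annual-mean PM2.5 exposure by a
fraction ``reduction`` whenever the natural value strictly exceeds the
threshold ``threshold`` (in µg/m³); otherwise the exposure is untouched.
The natural course (``kind="natural"``) is the identity map and serves as
the reference arm for all contrasts.

The map acts on the *natural* draw of each year's exposure — this is what
makes it a modified treatment policy, amenable to density-ratio estimation —
and the pipeline applies it exactly once per interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Policy", "NATURAL", "apply_policy", "threshold_policy"]


@dataclass(frozen=True)
class Policy:
    """An intervention d(a) on annual-mean exposure.

    Parameters
    ----------
    kind : {"natural", "threshold"}
        ``"natural"`` is the identity (no intervention); ``"threshold"``
        multiplies exposures strictly above ``threshold`` by
        ``1 - reduction``.
    threshold : float
        Threshold δ in µg/m³ (ignored for the natural course). The
        regulatory values of interest are 12, 10 and 9 µg/m³.
    reduction : float
        Fractional reduction ρ applied above the threshold (default 0.05,
        i.e. a 5% reduction).
    """

    kind: str = "threshold"
    threshold: float = 12.0
    reduction: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("natural", "threshold"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "threshold":
            if not self.threshold > 0:
                raise ValueError("threshold must be positive")
            if not 0 <= self.reduction < 1:
                raise ValueError("reduction must lie in [0, 1)")

    @property
    def is_natural(self) -> bool:
        return self.kind == "natural"

    @property
    def label(self) -> str:
        if self.is_natural:
            return "natural"
        return f"threshold_{self.threshold:g}"

    def apply(self, a):
        return apply_policy(a, self)


#: The natural course (identity policy).
NATURAL = Policy(kind="natural")


def threshold_policy(threshold: float, reduction: float = 0.05) -> Policy:
    """Convenience constructor for a threshold policy."""
    return Policy(kind="threshold", threshold=threshold, reduction=reduction)


def apply_policy(a, policy: Policy):
    """Apply the intervention map d(·) to exposure value(s) ``a``.

    ``a`` may be a scalar or array of non-negative exposures in µg/m³.
    Values strictly above the threshold ("surpass" read as strict
    inequality; the boundary has measure zero for continuous exposure) are
    multiplied by ``1 - reduction``. The output never exceeds the input.
    """
    arr = np.asarray(a, dtype=float)
    if np.any(arr < 0):
        raise ValueError("exposure must be non-negative")
    if policy.is_natural:
        out = arr.copy()
    else:
        out = np.where(arr > policy.threshold, arr * (1.0 - policy.reduction), arr)
    if np.isscalar(a) or np.ndim(a) == 0:
        return float(out)
    return out
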