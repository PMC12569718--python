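"""Paper-shaped CSV reports of risks and risk differences.

One block per outcome: a natural-course reference row (risk per mille, RD
column "[Reference]") followed by one row per threshold policy with the
counterfactual risk and the risk difference vs the natural course, both
per mille with 95% CIs, rounded to 2 decimals. Subgroup / robustness
panels reuse the same layout with a ``panel`` column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contrasts import Contrast
from .tmle import TMLEResults

__all__ = ["render_tables", "parse_rendered"]

_COLS = [
    "outcome", "panel", "intervention", "risk_per_mille", "risk_ci_low",
    "risk_ci_high", "rd_per_mille", "rd_ci_low", "rd_ci_high", "p_value",
]


def _round2(x: float) -> float:
    return float(np.round(x, 2))


def render_tables(results: dict, path=None) -> pd.DataFrame:
    """Build the risk / risk-difference table.

    ``results`` maps outcome name → ``{"natural": TMLEResults,
    "<policy label>": (TMLEResults, Contrast), ..., "panel": str?}``.
    If ``path`` is given the table is also written as CSV.
    """
    rows = []
    for outcome, block in results.items():
        panel = block.get("panel", "main")
        natural = block.get("natural")
        if natural is not None:
            lo, hi = natural.conf_int()
            rows.append({
                "outcome": outcome, "panel": panel, "intervention": "No intervention",
                "risk_per_mille": _round2(natural.risk_per_mille),
                "risk_ci_low": _round2(1000 * lo), "risk_ci_high": _round2(1000 * hi),
                "rd_per_mille": "[Reference]", "rd_ci_low": "", "rd_ci_high": "",
                "p_value": "",
            })
        for label, entry in block.items():
            if label in ("natural", "panel"):
                continue
            est, contrast = entry
            lo, hi = est.conf_int()
            rlo, rhi = contrast.conf_int()
            rows.append({
                "outcome": outcome, "panel": panel, "intervention": label,
                "risk_per_mille": _round2(est.risk_per_mille),
                "risk_ci_low": _round2(1000 * lo), "risk_ci_high": _round2(1000 * hi),
                "rd_per_mille": _round2(contrast.rd_per_mille),
                "rd_ci_low": _round2(1000 * rlo), "rd_ci_high": _round2(1000 * rhi),
                "p_value": float(np.format_float_positional(
                    contrast.p_value, precision=3, fractional=False)),
            })
    table = pd.DataFrame(rows, columns=_COLS)
    if path is not None:
        table.to_csv(path, index=False)
    return table


def parse_rendered(path) -> pd.DataFrame:
    """Read back a rendered CSV, recovering numeric columns at printed precision."""
    df = pd.read_csv(path, dtype={"rd_per_mille": str})
    for col in ("risk_per_mille", "risk_ci_low", "risk_ci_high"):
        df[col] = df[col].astype(float)
    return df
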