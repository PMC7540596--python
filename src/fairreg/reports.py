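"""Presentation-layer reports: coefficient changes and table formatting.

Currency values are rounded to whole dollars, ratios to three decimals and
R-squared to one decimal only here, at presentation time; all computation
upstream is full precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimators import FittedModel

__all__ = ["coefficient_change_report", "format_metric_table"]


def coefficient_change_report(
    reference: FittedModel, other: FittedModel, top: int = 5
) -> pd.DataFrame:
    """Largest coefficient movements between two fits on the same design.

    Returns the ``top`` largest increases and ``top`` largest decreases in
    dollars from ``reference`` (typically OLS) to ``other``, annotated with
    the relative percent change. Ranking is by absolute dollar change.
    """
    if reference.columns != other.columns:
        raise ValueError("models were fit on different design columns")
    delta = other.theta - reference.theta
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(
            reference.theta != 0, 100.0 * delta / np.abs(reference.theta), np.nan
        )
    df = pd.DataFrame(
        {
            "column": reference.columns,
            "theta_ref": reference.theta,
            "theta_new": other.theta,
            "change": delta,
            "relative_pct": rel,
        }
    )
    inc = df[df["change"] > 0].nlargest(top, "change")
    dec = df[df["change"] < 0].nsmallest(top, "change")
    out = pd.concat([inc, dec]).reset_index(drop=True)
    return out.reindex(out["change"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


def format_metric_table(table: pd.DataFrame) -> pd.DataFrame:
    """Round a metric table for display: whole dollars, 3-decimal ratios,
    1-decimal R-squared."""
    out = table.copy()
    for col in ("NC_g", "NC_gc", "MRD", "FairCov"):
        if col in out:
            out[col] = out[col].round(0).astype("Int64")
    for col in ("PR_g", "PR_gc"):
        if col in out:
            out[col] = out[col].round(3)
    if "ScaledFairCov" in out:
        out["ScaledFairCov"] = out["ScaledFairCov"].astype(float).round(3)
    if "R2" in out:
        out["R2"] = out["R2"].round(1)
    return out
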