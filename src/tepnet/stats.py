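"""Univariate group comparisons with Holm step-down correction.

The correction family is all hotspot cells within one measure panel
(8 tests by default), mirroring per-panel significance marking; the family
is configurable.  The t-test is the equal-variance pooled form.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import MEASURES

__all__ = ["two_sample_t", "holm_correct", "significance_stars",
           "compare_groups"]


def two_sample_t(group_a, group_b):
    """Two-sided pooled-variance t-test; ``(nan, nan)`` if degenerate."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    sa2 = a.var(ddof=1)
    sb2 = b.var(ddof=1)
    if sa2 == 0.0 and sb2 == 0.0:
        return float("nan"), float("nan")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def holm_correct(pvals, alpha: float = 0.05):
    """Holm step-down adjusted p-values and rejection flags.

    ``adjusted[(i)] = max_{j<=i} min(1, (m-j+1) * p_(j))`` over the
    ascending order; a hypothesis is rejected iff its adjusted p <= alpha
    (equivalent to the sequential stopping rule).
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= alpha


def significance_stars(p: float) -> str:
    """Conventional asterisk coding on a corrected p-value."""
    if np.isnan(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(feature_table: pd.DataFrame, labels: pd.Series,
                   measures=MEASURES, alpha: float = 0.05,
                   family: str = "per_measure") -> pd.DataFrame:
    """Healthy-vs-injured comparison per (measure, hotspot) cell.

    Returns a table with group means +- SE, t, raw p, Holm-adjusted p and
    stars.  ``family`` controls the correction family: ``per_measure``
    (default, all hotspots within one measure) or ``global`` (every cell).
    """
    df = feature_table.merge(labels.rename("group"), left_on="subject_id",
                             right_index=True)
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ga, gb = groups
    hotspots = list(dict.fromkeys(df["hotspot"]))
    rows = []
    for measure in measures:
        for hotspot in hotspots:
            cell = df[df["hotspot"] == hotspot]
            va = cell.loc[cell["group"] == ga, measure].dropna().to_numpy()
            vb = cell.loc[cell["group"] == gb, measure].dropna().to_numpy()
            t, p = two_sample_t(va, vb)
            rows.append({
                "measure": measure, "hotspot": hotspot,
                f"mean_{ga}": va.mean(), f"se_{ga}": sps.sem(va),
                f"mean_{gb}": vb.mean(), f"se_{gb}": sps.sem(vb),
                "t": t, "p_raw": p,
            })
    out = pd.DataFrame(rows)

    out["p_holm"] = np.nan
    if family == "per_measure":
        for measure in measures:
            idx = out.index[out["measure"] == measure]
            valid = idx[out.loc[idx, "p_raw"].notna()]
            if len(valid):
                adj, _ = holm_correct(out.loc[valid, "p_raw"].to_numpy(), alpha)
                out.loc[valid, "p_holm"] = adj
    elif family == "global":
        valid = out.index[out["p_raw"].notna()]
        if len(valid):
            adj, _ = holm_correct(out.loc[valid, "p_raw"].to_numpy(), alpha)
            out.loc[valid, "p_holm"] = adj
    else:
        raise ValueError(f"unknown correction family {family!r}")
    out["stars"] = out["p_holm"].map(significance_stars)
    return out
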