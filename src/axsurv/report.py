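"""Small reporting helpers: unit conversions and cohort summary tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "percent_share", "months_to_years", "hr_percent_reduction",
    "summarize_cohort",
]


def percent_share(count: float, total: float, decimals: int = 1) -> float:
    """Share of ``count`` in ``total`` as a rounded percentage."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def months_to_years(months: float, decimals: int = 2) -> float:
    """Convert a duration in months to years (12 months per year)."""
    return round(months / 12.0, decimals)


def hr_percent_reduction(hr: float, decimals: int = 1) -> float:
    """Relative hazard reduction implied by a hazard ratio, in percent."""
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return round((1.0 - hr) * 100.0, decimals)


_CATEGORICAL = ["age_group", "t_category", "n_category", "histology", "grade",
                "er", "pr", "her2", "bcs", "systemic", "radiotherapy"]
_CONTINUOUS = ["year_dx", "months_dx_to_tx", "nodes_removed", "nodes_positive"]


def summarize_cohort(df: pd.DataFrame, by: str = "final_label") -> pd.DataFrame:
    """Characteristics table: counts/percentages and mean (SD) by group."""
    groups = {"Total": df}
    if by in df.columns:
        for level, sub in df.groupby(by):
            groups[str(level)] = sub
    rows = []
    for var in _CATEGORICAL:
        if var not in df.columns:
            continue
        for level in sorted(df[var].dropna().unique(), key=str):
            row = {"variable": var, "level": str(level), "kind": "count"}
            for gname, sub in groups.items():
                cnt = int((sub[var] == level).sum())
                row[gname] = cnt
                row[f"{gname}_pct"] = percent_share(cnt, len(sub)) if len(sub) else np.nan
            rows.append(row)
    for var in _CONTINUOUS:
        if var not in df.columns:
            continue
        row = {"variable": var, "level": "mean_sd", "kind": "continuous"}
        for gname, sub in groups.items():
            row[gname] = float(sub[var].mean())
            row[f"{gname}_pct"] = float(sub[var].std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)
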