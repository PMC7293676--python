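"""Assembly of the 18-predictor lag design and the pooled correlation table.

Each retained (area, year) outcome record gets the area's own exposure in
the outcome year and the previous ``max_lag`` years (``loc_lag_0..k``) plus
the contiguity-neighborhood mean for the same years (``reg_lag_0..k``).
Correlations pool all rows of the unbalanced panel, unweighted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

RESPONSES = ("mortality_rate", "morbidity_rate")


def lag_columns(max_lag: int = 8) -> list[str]:
    """Fixed predictor column order: all local lags, then all regional lags."""
    return [f"loc_lag_{k}" for k in range(max_lag + 1)] + [
        f"reg_lag_{k}" for k in range(max_lag + 1)
    ]


def build_lag_design(
    exposure: pd.DataFrame,
    regional: pd.DataFrame,
    outcomes: pd.DataFrame,
    max_lag: int = 8,
) -> pd.DataFrame:
    """One design row per outcome record; rows missing any lag are dropped.

    ``exposure`` needs columns (area_id, year, mean_pm25); ``regional``
    needs (area_id, year, reg_mean) — typically the contiguity-neighborhood
    mean of the same surface; ``outcomes`` is an outcome panel.
    """
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    loc = exposure.pivot(index="area_id", columns="year", values="mean_pm25")
    reg = regional.pivot(index="area_id", columns="year", values="reg_mean")

    rows = []
    dropped = 0
    for rec in outcomes.itertuples(index=False):
        lag_years = [rec.year - k for k in range(max_lag + 1)]
        try:
            loc_vals = loc.loc[rec.area_id, lag_years].to_numpy(dtype=float)
            reg_vals = reg.loc[rec.area_id, lag_years].to_numpy(dtype=float)
        except KeyError:
            dropped += 1
            continue
        if np.isnan(loc_vals).any() or np.isnan(reg_vals).any():
            dropped += 1
            continue
        rows.append(
            (rec.area_id, rec.year, *loc_vals, *reg_vals,
             rec.mortality_rate, rec.morbidity_rate)
        )
    if dropped:
        log.info("build_lag_design: dropped %d rows lacking lag history", dropped)
    if not rows:
        raise ValueError(
            "no design rows survive: every outcome record lacks lag history"
        )
    cols = ["area_id", "year", *lag_columns(max_lag), *RESPONSES]
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["dropped_rows"] = dropped
    return df


def pearson_table(design: pd.DataFrame, max_lag: int = 8) -> pd.DataFrame:
    """Pearson r and two-sided p per (response, predictor), tidy format.

    Constant columns yield NaN (reported missing, never 0).
    """
    if len(design) < 3:
        raise ValueError("need at least 3 design rows for correlations")
    out = []
    for response in ("mortality", "morbidity"):
        y = design[f"{response}_rate"].to_numpy(dtype=float)
        for col in lag_columns(max_lag):
            x = design[col].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            scale, k = col.rsplit("_", 1)
            out.append(
                {
                    "response": response,
                    "predictor": col,
                    "scale": "local" if scale == "loc_lag" else "regional",
                    "lag": int(k),
                    "r": r,
                    "p": p,
                }
            )
    return pd.DataFrame(out)


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Wide layout: one row per response x scale, one column per lag."""
    wide = table.pivot_table(
        index=["response", "scale"], columns="lag", values="r", sort=True
    )
    wide.columns = [f"lag_{k}" for k in wide.columns]
    return wide


def write_lag_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, index=False, float_format="%.10g")


def read_lag_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
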