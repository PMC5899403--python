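"""Descriptive accessibility statistics over OD travel-time tables.

The headline outputs: per (typology, service type, mode) quartile
summaries of nearest-facility travel times, public-vs-private mode gaps
and ratios of medians, gaps relative to a baseline typology, and the
20-minute-city compliance share.  Unreachable cells (+inf) are excluded
from statistics and reported as a separate count — never imputed and
never silently dropped.  Quantiles use linear interpolation between order
statistics.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .types import OD_COLUMNS, SUMMARY_COLUMNS

logger = logging.getLogger(__name__)

_GROUP = ["typology", "service_type", "mode"]


def _check_od(od: pd.DataFrame) -> pd.DataFrame:
    for col in OD_COLUMNS:
        if col not in od.columns:
            raise ConfigError(f"OD table missing column {col!r}")
    if len(od) == 0:
        raise ConfigError("OD table is empty")
    if (od["minutes"] < 0).any():
        raise ConfigError("OD minutes must be non-negative")
    return od


def summarize(od: pd.DataFrame) -> pd.DataFrame:
    """Quartile summary of travel times per (typology, service type, mode).

    Returns one row per observed group with columns
    (n, median, q1, q3, min, max, n_unreachable); groups whose cells are
    all unreachable get n=0 and NaN statistics.
    """
    _check_od(od)

    def _stats(minutes: pd.Series) -> pd.Series:
        v = minutes.to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        n_unreachable = int(len(v) - len(finite))
        if len(finite) == 0:
            vals = dict.fromkeys(("median", "q1", "q3", "min", "max"), np.nan)
        else:
            q1, med, q3 = np.percentile(finite, [25, 50, 75])  # linear interpolation
            vals = {
                "median": med, "q1": q1, "q3": q3,
                "min": float(finite.min()), "max": float(finite.max()),
            }
        return pd.Series({"n": len(finite), **vals, "n_unreachable": n_unreachable})

    out = (
        od.groupby(_GROUP, sort=True, observed=True)["minutes"]
        .apply(_stats)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    out["n_unreachable"] = out["n_unreachable"].astype(int)
    return out[list(SUMMARY_COLUMNS)]


def mode_gap(summary: pd.DataFrame) -> pd.DataFrame:
    """Public-minus-private median difference and public/private median ratio
    per (typology, service type).

    Rows with a missing mode are skipped with a warning; the ratio is NaN
    (and logged) when the private median is zero.
    """
    wide = summary.pivot_table(
        index=["typology", "service_type"], columns="mode", values="median",
        aggfunc="first",
    )
    missing = wide.index[wide.reindex(columns=["private", "public"]).isna().any(axis=1)]
    for idx in missing:
        logger.warning("mode_gap: skipping %s - missing a mode or its median", idx)
    wide = wide.drop(index=missing)
    out = wide.reset_index()
    out["median_diff_min"] = out["public"] - out["private"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(out["private"] > 0, out["public"] / out["private"], np.nan)
    if np.isnan(ratio).any():
        logger.warning("mode_gap: ratio undefined where private median is 0")
    out["median_ratio"] = ratio
    out = out.rename(columns={"private": "median_private", "public": "median_public"})
    return out[
        ["typology", "service_type", "median_private", "median_public",
         "median_diff_min", "median_ratio"]
    ]


def baseline_gap(summary: pd.DataFrame, baseline_typology: str = "inner") -> pd.DataFrame:
    """Median travel time minus the baseline typology's median, per
    (typology, service type, mode); the baseline maps to zero."""
    base = summary[summary["typology"] == baseline_typology]
    if len(base) == 0:
        raise ConfigError(f"no rows for baseline typology {baseline_typology!r}")
    base_map = base.set_index(["service_type", "mode"])["median"]
    out = summary[["typology", "service_type", "mode", "median"]].copy()
    keys = list(zip(out["service_type"], out["mode"]))
    out["baseline_median"] = [base_map.get(k, np.nan) for k in keys]
    out["median_gap_min"] = out["median"] - out["baseline_median"]
    return out


def twenty_minute_share(
    od: pd.DataFrame, threshold_min: float = 20.0
) -> pd.DataFrame:
    """Share of reachable addresses within the travel-time threshold
    (inclusive), per (typology, service type, mode).

    The default 20-minute threshold is the 20-minute-city planning target.
    Groups with no reachable cells get a NaN share.
    """
    if threshold_min <= 0:
        raise ConfigError("threshold_min must be > 0")
    _check_od(od)

    def _share(minutes: pd.Series) -> float:
        v = minutes.to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if len(finite) == 0:
            return np.nan
        return float((finite <= threshold_min).mean())

    out = (
        od.groupby(_GROUP, sort=True, observed=True)["minutes"]
        .apply(_share)
        .rename("share_within_threshold")
        .reset_index()
    )
    out["threshold_min"] = threshold_min
    return out
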