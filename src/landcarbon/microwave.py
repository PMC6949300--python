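"""Coarse-grid L-band microwave processing: quality filtering, VOD
smoothing and outlier removal, orbit combination, VOD -> carbon-density
calibration and per-cell trend / significance analysis.

Record tables are tidy DataFrames with columns cell, date, orbit, vod,
sm, soil_temp, tb_rmse and flag_* booleans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

ALGORITHM_VERSION = "ic-style-filtering/0.1"

FROZEN_SOIL_TEMP_K = 273.5
TB_RMSE_MAX_K = 10.0


def quality_filter(
    records: pd.DataFrame,
    tb_rmse_max: float = TB_RMSE_MAX_K,
    frozen_temp: float = FROZEN_SOIL_TEMP_K,
):
    """Drop flagged, frozen-soil and high TB-RMSE observations.

    Removes records with any set flag_* column, soil_temp below the
    freezing cutoff, or tb_rmse above ``tb_rmse_max``.  Returns
    ``(retained, removal_counts)`` with per-criterion counts (a record
    failing several criteria is counted under each).
    """
    flag_cols = [c for c in records.columns if c.startswith("flag_")]
    flagged = (
        records[flag_cols].any(axis=1)
        if flag_cols
        else pd.Series(False, index=records.index)
    )
    frozen = records["soil_temp"] < frozen_temp
    rfi = records["tb_rmse"] > tb_rmse_max
    removed = flagged | frozen | rfi
    counts = {
        "flagged": int(flagged.sum()),
        "frozen_soil": int(frozen.sum()),
        "tb_rmse": int(rfi.sum()),
        "total_removed": int(removed.sum()),
        "retained": int((~removed).sum()),
    }
    return records.loc[~removed].copy(), counts


def _moving_average(dates: np.ndarray, values: np.ndarray, window_days: float):
    """Centered calendar-window moving average; edges use the truncated
    window."""
    t = dates.astype("datetime64[D]").astype(float)
    half = window_days / 2.0
    out = np.empty(len(values))
    for i in range(len(values)):
        sel = np.abs(t - t[i]) <= half
        out[i] = values[sel].mean()
    return out


def smooth_and_deoutlier_vod(
    records: pd.DataFrame,
    window_days: float = 30.0,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
):
    """Smooth one cell+orbit VOD series and drop residual outliers.

    A 30-day moving average gives residues (raw - smoothed);
    observations strictly below the 10th or strictly above the 90th
    residue percentile are excluded and the smoothed series recomputed
    on the survivors (added as column ``vod_smoothed``).  A degenerate
    all-equal-residue series loses nothing.
    """
    if len(records) < 5:
        raise ValueError(f"need >= 5 observations, got {len(records)}")
    df = records.sort_values("date").reset_index(drop=True)
    dates = df["date"].to_numpy()
    vod = df["vod"].to_numpy(dtype=float)
    smoothed = _moving_average(dates, vod, window_days)
    residues = vod - smoothed
    qlo = np.percentile(residues, lower_pct)
    qhi = np.percentile(residues, upper_pct)
    keep = (residues >= qlo) & (residues <= qhi)
    out = df.loc[keep].reset_index(drop=True)
    out["vod_smoothed"] = _moving_average(
        out["date"].to_numpy(), out["vod"].to_numpy(dtype=float), window_days
    )
    return out


def combine_orbits(
    asc: pd.DataFrame, desc: pd.DataFrame, keep_per_year: int = 30
) -> pd.DataFrame:
    """Merge ascending/descending VOD streams into one series.

    Per calendar year only the ``keep_per_year`` observations with the
    lowest TB-RMSE are kept (all of them when fewer exist); ties at the
    cutoff resolve by date order, earliest first.
    """
    both = pd.concat([asc, desc], ignore_index=True)
    if both.empty:
        return both
    both["year"] = pd.DatetimeIndex(both["date"]).year
    both = both.sort_values(["year", "tb_rmse", "date"], kind="mergesort")
    out = both.groupby("year", group_keys=False).head(keep_per_year)
    return out.sort_values("date").reset_index(drop=True)


def process_cell(
    records: pd.DataFrame,
    window_days: float = 30.0,
    keep_per_year: int = 30,
    tb_rmse_max: float = TB_RMSE_MAX_K,
):
    """Full single-cell chain: quality filter, per-orbit smoothing and
    outlier removal, orbit combination."""
    filtered, _ = quality_filter(records, tb_rmse_max=tb_rmse_max)
    parts = {}
    for orbit in ("ascending", "descending"):
        sub = filtered[filtered["orbit"] == orbit]
        if len(sub) >= 5:
            parts[orbit] = smooth_and_deoutlier_vod(sub, window_days=window_days)
        else:
            parts[orbit] = sub.copy()
    return combine_orbits(
        parts["ascending"], parts["descending"], keep_per_year=keep_per_year
    )


def _logistic(vod, lo, hi, steep, mid):
    return lo + (hi - lo) / (1.0 + np.exp(-steep * (vod - mid)))


def fit_vod_calibration(vod_ref, density):
    """Fit the four-parameter logistic density = f(VOD) calibration.

    ``vod_ref`` are per-cell reference-period mean VOD values and
    ``density`` the benchmark carbon densities aggregated to the same
    cells.  The steepness is bounded positive so the curve is monotone
    non-decreasing.
    """
    vod_ref = np.asarray(vod_ref, dtype=float)
    density = np.asarray(density, dtype=float)
    valid = np.isfinite(vod_ref) & np.isfinite(density)
    vod_ref, density = vod_ref[valid], density[valid]
    if len(vod_ref) < 4:
        raise ValueError("need >= 4 paired cells to calibrate")
    if np.ptp(vod_ref) == 0:
        raise ValueError("degenerate (constant) VOD; cannot calibrate")
    p0 = (
        float(density.min()),
        float(density.max()),
        4.0 / max(np.ptp(vod_ref), 1e-6),
        float(np.median(vod_ref)),
    )
    bounds = (
        [0.0, 0.0, 1e-6, vod_ref.min() - 5 * np.ptp(vod_ref)],
        [np.inf, np.inf, np.inf, vod_ref.max() + 5 * np.ptp(vod_ref)],
    )
    params, _ = optimize.curve_fit(
        _logistic, vod_ref, density, p0=p0, bounds=bounds, maxfev=20000
    )
    if params[1] < params[0]:  # enforce non-decreasing orientation
        raise RuntimeError("calibration fit is decreasing; check inputs")
    return tuple(float(v) for v in params)


def vod_to_cdensity(vod_values, calibrations):
    """Apply one or more fitted calibrations and average the results."""
    vod_values = np.asarray(vod_values, dtype=float)
    if not calibrations:
        raise ValueError("no calibrations supplied")
    series = [np.asarray(_logistic(vod_values, *p), dtype=float) for p in calibrations]
    return np.mean(series, axis=0)


def calibrate_vod_to_cdensity(vod_ref, benchmarks):
    """Fit one calibration per benchmark map; returns the parameter list."""
    return [fit_vod_calibration(vod_ref, np.asarray(b, dtype=float)) for b in benchmarks]


@dataclass(frozen=True)
class CellTrend:
    cell: int
    variable: str
    slope: float
    p_value: float
    n_years: int
    significant_decline: bool


def annualize(records: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Mean of surviving observations per cell and calendar year."""
    df = records.copy()
    df["year"] = pd.DatetimeIndex(df["date"]).year
    return df.groupby(["cell", "year"], as_index=False)[value_col].mean()


def cell_trends(
    annual: pd.DataFrame,
    variable: str,
    alpha: float = 0.05,
    min_years: int = 4,
    method: str = "ols",
) -> pd.DataFrame:
    """Per-cell trend with significance on annual means.

    ``annual`` has columns cell, year and the value column named by
    ``variable``.  'ols' uses least squares with a two-sided t-test;
    'theilsen' uses a Sen slope with a Mann-Kendall (Kendall tau) test.
    ``significant_decline`` marks slope < 0 with p < alpha.  Cells with
    fewer than ``min_years`` years are masked (dropped).
    """
    rows = []
    for cell, grp in annual.groupby("cell"):
        y = grp[variable].to_numpy(dtype=float)
        x = grp["year"].to_numpy(dtype=float)
        ok = np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(y) < min_years:
            continue
        if method == "ols":
            if np.ptp(y) == 0:
                slope, p = 0.0, 1.0
            else:
                fit = stats.linregress(x, y)
                slope, p = float(fit.slope), float(fit.pvalue)
        elif method == "theilsen":
            slope = float(stats.theilslopes(y, x).slope)
            tau = stats.kendalltau(x, y)
            p = float(tau.pvalue) if np.isfinite(tau.pvalue) else 1.0
        else:
            raise ValueError(f"unknown trend method {method!r}")
        rows.append(
            {
                "cell": cell,
                "variable": variable,
                "slope": slope,
                "p_value": p,
                "n_years": len(y),
                "significant_decline": bool(slope < 0 and p < alpha),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell",
            "variable",
            "slope",
            "p_value",
            "n_years",
            "significant_decline",
        ],
    )


def trend_summary(trends: pd.DataFrame) -> dict:
    """Fraction of valid cells with a significant decline, plus counts."""
    n = len(trends)
    n_sig = int(trends["significant_decline"].sum()) if n else 0
    return {
        "n_cells": n,
        "n_significant_decline": n_sig,
        "significant_decline_fraction": (n_sig / n if n else np.nan),
    }
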