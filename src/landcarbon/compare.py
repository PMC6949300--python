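"""Cross-product comparison (aggregation, correlation, RMSE as a
temporal-uncertainty proxy) and summary-table generation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from landcarbon.carbon import CarbonAccount, format_percent


def block_aggregate(fine: np.ndarray, factor: int) -> np.ndarray:
    """Mean-pool a 2-D raster into factor x factor blocks.

    Remainder rows/columns that do not fill a block are dropped; NaNs
    are ignored within a block (all-NaN blocks stay NaN).
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    fine = np.asarray(fine, dtype=float)
    nr, nc = fine.shape
    nr_c, nc_c = nr // factor, nc // factor
    if nr_c == 0 or nc_c == 0:
        raise ValueError("raster smaller than one block")
    trimmed = fine[: nr_c * factor, : nc_c * factor]
    blocks = trimmed.reshape(nr_c, factor, nc_c, factor).swapaxes(1, 2)
    with np.errstate(all="ignore"):
        return np.nanmean(blocks, axis=(2, 3))


def _paired(a, b):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("inputs must have matching shapes")
    ok = np.isfinite(a) & np.isfinite(b)
    return a[ok], b[ok]


def pearson_r(a, b) -> float:
    a, b = _paired(a, b)
    if len(a) < 3:
        raise ValueError(f"need >= 3 valid pairs, got {len(a)}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b)[0])


def spearman_r(a, b) -> float:
    a, b = _paired(a, b)
    if len(a) < 3:
        raise ValueError(f"need >= 3 valid pairs, got {len(a)}")
    return float(stats.spearmanr(a, b)[0])


def rmse(a, b) -> float:
    a, b = _paired(a, b)
    if len(a) == 0:
        raise ValueError("no valid pairs")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class ComparisonReport:
    spatial_r: float
    temporal_r: float
    rmse_temporal: float
    n_spatial_pairs: int
    n_years: int
    per_type_rmse: dict | None = None


def compare_products(
    fine_stack,
    coarse_stack,
    factor: int = 1,
    correlation: str = "pearson",
) -> ComparisonReport:
    """Compare two annual density products.

    The fine product is block-aggregated by ``factor`` to the coarse
    grid; spatial correlation uses the over-years mean map, temporal
    correlation and RMSE use the annual regional means.
    """
    corr = pearson_r if correlation == "pearson" else spearman_r
    fine = np.asarray(fine_stack, dtype=float)
    coarse = np.asarray(coarse_stack, dtype=float)
    if fine.ndim == 1 and coarse.ndim == 1:
        r_t = corr(fine, coarse)
        return ComparisonReport(
            spatial_r=np.nan,
            temporal_r=r_t,
            rmse_temporal=rmse(fine, coarse),
            n_spatial_pairs=0,
            n_years=len(fine),
        )
    if fine.ndim != 3 or coarse.ndim != 3:
        raise ValueError("expected (year, row, col) stacks or 1-D series")
    agg = np.stack([block_aggregate(fine[i], factor) for i in range(fine.shape[0])])
    if agg.shape != coarse.shape:
        raise ValueError("aggregated fine product misaligned with coarse product")
    mean_a = np.nanmean(agg, axis=0)
    mean_b = np.nanmean(coarse, axis=0)
    spatial = corr(mean_a, mean_b)
    a_t = np.nanmean(agg, axis=(1, 2))
    b_t = np.nanmean(coarse, axis=(1, 2))
    return ComparisonReport(
        spatial_r=spatial,
        temporal_r=corr(a_t, b_t),
        rmse_temporal=rmse(a_t, b_t),
        n_spatial_pairs=int(np.sum(np.isfinite(mean_a) & np.isfinite(mean_b))),
        n_years=fine.shape[0],
    )


def per_type_rmse(density_map, benchmark_map, labels, codes_to_names) -> dict:
    """Spatial RMSE against the benchmark, per land-use type."""
    out = {}
    for code, name in codes_to_names.items():
        mask = np.asarray(labels) == code
        if mask.sum() == 0:
            continue
        out[name] = rmse(
            np.asarray(density_map, dtype=float)[mask],
            np.asarray(benchmark_map, dtype=float)[mask],
        )
    return out


def disturbance_timing(diagnostics, window=(2009, 2011), seg_mag_tol: float = 0.02):
    """Fraction of detected disturbance segments whose end year falls in
    ``window``; input is a list of per-pixel SegmentationResult objects
    (or the classify_scene diagnostics when segmentation is attached)."""
    total = 0
    in_window = 0
    for res in diagnostics:
        if res is None:
            continue
        for seg in res.segments:
            if abs(seg.magnitude) > seg_mag_tol:
                total += 1
                if window[0] <= seg.end_year <= window[1]:
                    in_window += 1
    return {
        "n_disturbances": total,
        "n_in_window": in_window,
        "fraction_in_window": (in_window / total if total else np.nan),
    }


def summary_tables(
    account: CarbonAccount,
    landuse_summary: dict | None = None,
    trends_summary: dict | None = None,
    timber_series: pd.Series | None = None,
    type_rmse: dict | None = None,
) -> dict:
    """Bundle the report tables.

    Returns a dict of DataFrames: 'type_table' (per-type area fraction,
    mean density, net sink, rounded contribution), 'flux_decomposition'
    (start stock, gross gain/loss, net change), and optionally
    'timber' and 'trends'.  Pure: same inputs give identical frames.
    """
    t = account.table.copy()
    type_rows = t.index != "region"
    table = pd.DataFrame(index=t.index)
    table["n_pixels"] = t["n_pixels"]
    if landuse_summary is not None:
        fracs = landuse_summary.get("fractions", {})
        table.loc[type_rows, "area_pct"] = [
            100.0 * fracs.get(name, np.nan) for name in t.index[type_rows]
        ]
    table["mean_density"] = t["mean_density"]
    if type_rmse:
        table.loc[type_rows, "spatial_rmse"] = [
            type_rmse.get(name, np.nan) for name in t.index[type_rows]
        ]
    table["net_sink"] = t["net_sink"]
    if "contribution" in t:
        table["contribution_pct"] = t["contribution"]
        table["contribution_printed"] = [
            format_percent(v) if np.isfinite(v) else np.nan for v in t["contribution"]
        ]
    if "offset_fraction" in t:
        table["offset_pct"] = t["offset_fraction"]
    flux = pd.DataFrame(
        {
            "stock_start": t["stock_start"],
            "gross_gain": t["gross_gain"],
            "gross_loss": t["gross_loss"],
            "net_change": t["stock_end"] - t["stock_start"],
        }
    )
    out = {"type_table": table, "flux_decomposition": flux}
    if timber_series is not None:
        out["timber"] = timber_series.to_frame()
    if trends_summary is not None:
        out["trends"] = pd.DataFrame([trends_summary])
    return out
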