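"""Carbon-density modelling and per-type stock / sink accounting.

Units: density in Mg C ha^-1, stocks in Pg C (1 Pg = 1e9 Mg), sinks in
Pg C yr^-1.  Pixel area defaults to 25 ha (500 m x 500 m grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import HistGradientBoostingRegressor

from landcarbon.trajectory import LANDUSE_CODES

CO2_TO_C_DIVISOR = 3.67
MG_TO_PG = 1e-9
BIOMASS_CARBON_FRACTION = 0.5


def co2_to_c(value):
    """Convert a CO2 mass to a carbon mass (divide by 3.67)."""
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("negative CO2 mass")
    out = value / CO2_TO_C_DIVISOR
    return float(out) if out.ndim == 0 else out


def timber_carbon(volume_m3, wood_basic_density=0.5):
    """Timber volume (m^3) -> carbon (Pg C).

    biomass = volume x wood basic density (Mg m^-3); carbon = biomass x
    0.5; result scaled from Mg to Pg.
    """
    volume_m3 = np.asarray(volume_m3, dtype=float)
    density = np.asarray(wood_basic_density, dtype=float)
    if np.any(volume_m3 < 0) or np.any(density < 0):
        raise ValueError("negative volume or wood density")
    out = volume_m3 * density * BIOMASS_CARBON_FRACTION * MG_TO_PG
    return float(out) if out.ndim == 0 else out


def stock(density_map, mask=None, pixel_area_ha: float = 25.0) -> float:
    """Total carbon stock (Pg C) of masked pixels.

    ``sum(density) * pixel_area_ha * 1e-9`` over pixels where the mask
    is true; NaN pixels are treated as outside the mask.
    """
    density = np.asarray(density_map, dtype=float)
    if mask is None:
        mask = np.ones(density.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != density.shape:
            raise ValueError("mask misaligned with density map")
    mask = mask & np.isfinite(density)
    if np.any(density[mask] < 0):
        raise ValueError("negative carbon densities")
    return float(np.sum(density[mask]) * pixel_area_ha * MG_TO_PG)


def train_cdensity_model(
    benchmark,
    predictors,
    split: float = 0.5,
    seed: int = 0,
    max_iter: int = 300,
):
    """Calibrate a boosted-tree density model against a benchmark raster.

    ``benchmark`` is (row, col) Mg C ha^-1; ``predictors`` is
    (n_predictors, row, col).  Half of the valid pixels (``split``)
    train the model, the rest validate it.  Returns ``(model, quality)``
    with held-out Pearson r, regression slope (predicted vs benchmark)
    and RMSE.
    """
    benchmark = np.asarray(benchmark, dtype=float)
    predictors = np.asarray(predictors, dtype=float)
    if predictors.ndim != 3 or predictors.shape[1:] != benchmark.shape:
        raise ValueError("predictors misaligned with benchmark raster")
    X = predictors.reshape(predictors.shape[0], -1).T
    y = benchmark.reshape(-1)
    valid = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[valid], y[valid]
    if len(y) < 100:
        raise ValueError(f"need >= 100 valid pixels, got {len(y)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_train = int(round(split * len(y)))
    train_idx, test_idx = order[:n_train], order[n_train:]
    model = HistGradientBoostingRegressor(random_state=seed, max_iter=max_iter)
    model.fit(X[train_idx], y[train_idx])
    pred = model.predict(X[test_idx])
    truth = y[test_idx]
    if np.std(pred) == 0 or np.std(truth) == 0:
        r, slope = 0.0, 0.0
    else:
        r = float(stats.pearsonr(pred, truth)[0])
        slope = float(stats.linregress(truth, pred).slope)
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    quality = {"r": r, "slope": slope, "rmse": rmse, "n_validation": len(truth)}
    return model, quality


def predict_cdensity(model, predictors_by_year):
    """Apply a fitted density model year by year.

    ``predictors_by_year`` is (year, n_predictors, row, col); returns a
    (year, row, col) density stack floored at zero, NaN where any
    predictor is missing.
    """
    arr = np.asarray(predictors_by_year, dtype=float)
    ny, npred, nr, nc = arr.shape
    out = np.full((ny, nr, nc), np.nan)
    for yi in range(ny):
        X = arr[yi].reshape(npred, -1).T
        valid = np.all(np.isfinite(X), axis=1)
        flat = np.full(nr * nc, np.nan)
        if valid.any():
            flat[valid] = np.maximum(model.predict(X[valid]), 0.0)
        out[yi] = flat.reshape(nr, nc)
    return out


def format_percent(value: float) -> float:
    """Mixed-precision rounding used in the report tables.

    Nearest integer for |v| >= 1, one decimal for 0.1 <= |v| < 1, two
    decimals below that (matching the mixed precision of the printed
    per-type table).
    """
    if abs(value) >= 1:
        return float(round(value))
    if abs(value) >= 0.1:
        return round(value, 1)
    return round(value, 2)


def contribution_percentages(sinks) -> np.ndarray:
    """Per-type contribution (%) to the summed net sink (unrounded)."""
    sinks = np.asarray(sinks, dtype=float)
    total = sinks.sum()
    if total == 0:
        raise ValueError("total net sink is zero; contributions undefined")
    return sinks / total * 100.0


@dataclass
class CarbonAccount:
    """Per-type and regional stocks, fluxes, contributions and offsets."""

    table: pd.DataFrame  # one row per land-use type plus a 'region' row
    annual_stocks: pd.DataFrame  # type x year stocks, Pg C
    sink_method: str
    emissions_window: tuple | None
    mean_annual_emissions: float | None


def _net_sink(stocks: np.ndarray, years: np.ndarray, method: str) -> float:
    if method == "endpoint":
        return float((stocks[-1] - stocks[0]) / (len(years) - 1))
    if method == "ols_slope":
        return float(stats.linregress(years, stocks).slope)
    raise ValueError(f"unknown sink method {method!r}")


def carbon_account(
    density_stack,
    years,
    landuse_labels,
    emissions: pd.Series | None = None,
    pixel_area_ha: float = 25.0,
    emissions_window: tuple = (2002, 2015),
    sink_method: str = "endpoint",
) -> CarbonAccount:
    """Per-type carbon accounting from an annual density stack.

    For every land-use type and the whole region: annual stocks, net
    sink (endpoint difference over n_years - 1 by default), gross gains
    and losses (sums of positive / negative year-to-year stock deltas),
    mean density, contribution to the regional sink and — when a
    regional emissions series (Pg C, indexed by year) is supplied — the
    fraction of mean annual fossil emissions offset.
    """
    density = np.asarray(density_stack, dtype=float)
    years = np.asarray(years, dtype=int)
    labels = np.asarray(landuse_labels)
    if density.ndim != 3 or density.shape[0] != len(years):
        raise ValueError("density stack must be (year, row, col) matching years")
    if labels.shape != density.shape[1:]:
        raise ValueError("land-use labels misaligned with density stack")
    present = [c for c in LANDUSE_CODES if np.any(labels == c)]
    if not present:
        raise ValueError("no classified pixels under the land-use map")
    mean_emis = None
    if emissions is not None:
        lo, hi = emissions_window
        window = emissions[(emissions.index >= lo) & (emissions.index <= hi)]
        if window.empty:
            raise ValueError("emissions series does not overlap the window")
        mean_emis = float(window.mean())
    stocks = {}
    for code in present:
        mask = labels == code
        stocks[LANDUSE_CODES[code]] = np.array(
            [stock(density[yi], mask, pixel_area_ha) for yi in range(len(years))]
        )
    annual = pd.DataFrame(stocks, index=years).T
    annual.loc["region"] = annual.sum(axis=0)
    rows = []
    for name in annual.index:
        s = annual.loc[name].to_numpy()
        deltas = np.diff(s)
        sink = _net_sink(s, years, sink_method)
        if name == "region":
            area_mask = np.isin(labels, present)
        else:
            area_mask = labels == _code_of(name)
        n_pix = int(area_mask.sum())
        with np.errstate(invalid="ignore"):
            mean_density = float(np.nanmean(density[:, area_mask]))
        rows.append(
            {
                "type": name,
                "n_pixels": n_pix,
                "stock_start": s[0],
                "stock_end": s[-1],
                "gross_gain": float(deltas[deltas > 0].sum()),
                "gross_loss": float(-deltas[deltas < 0].sum()),
                "net_sink": sink,
                "mean_density": mean_density,
            }
        )
    table = pd.DataFrame(rows).set_index("type")
    regional_sink = table.loc["region", "net_sink"]
    type_rows = table.index != "region"
    if regional_sink != 0:
        table.loc[type_rows, "contribution"] = (
            table.loc[type_rows, "net_sink"] / regional_sink * 100.0
        )
        table.loc["region", "contribution"] = 100.0
    else:
        table["contribution"] = np.nan
    if mean_emis is not None and mean_emis > 0:
        table["offset_fraction"] = table["net_sink"] / mean_emis * 100.0
    return CarbonAccount(
        table=table,
        annual_stocks=annual,
        sink_method=sink_method,
        emissions_window=tuple(emissions_window) if emissions is not None else None,
        mean_annual_emissions=mean_emis,
    )


# internal: name -> code lookup without importing the inverse map at top level
def _code_of(name: str) -> int:
    for code, nm in LANDUSE_CODES.items():
        if nm == name:
            return code
    raise KeyError(name)


LANDUSE_NAMES_LOCAL = {v: k for k, v in LANDUSE_CODES.items()}


def regional_emissions_series(emissions_table: pd.DataFrame) -> pd.Series:
    """Sum a province x year emissions table to a regional Pg C series.

    The table needs columns province, year, value, units; units may be
    'PgC' or 'PgCO2' (converted on ingest).
    """
    df = emissions_table.copy()
    units = df["units"].unique()
    for u in units:
        if u not in ("PgC", "PgCO2"):
            raise ValueError(f"unknown emissions units {u!r}")
    df.loc[df["units"] == "PgCO2", "value"] /= CO2_TO_C_DIVISOR
    out = df.groupby("year")["value"].sum()
    out.name = "emissions_pgc"
    return out


def timber_carbon_series(
    timber_table: pd.DataFrame, wood_basic_density: float = 0.5
) -> pd.Series:
    """Regional annual timber carbon (Pg C) from a volume table."""
    df = timber_table
    vol = df.groupby("year")["value"].sum()
    out = pd.Series(timber_carbon(vol.to_numpy(), wood_basic_density), index=vol.index)
    out.name = "timber_pgc"
    return out
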