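"""Synthetic scenes, trajectories, coarse-grid microwave series and
province tables with known ground truth.

Every downstream stage of the pipeline is testable against these
generators without any external data.  Trajectory archetypes follow the
eight-type land-use typology; all randomness flows through a single
integer seed per generator call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from landcarbon.trajectory import LANDUSE_NAMES

ARCHETYPES = (
    "dense_forest",
    "forest",
    "non_forest",
    "recovery",
    "afforestation",
    "deforestation",
    "rotation",
    "rotation_L",
)

DEFAULT_YEARS = tuple(range(2002, 2018))

#: default probability levels for the trajectory templates
LEVELS = {"non_forest": 0.2, "forest": 0.65, "dense": 0.9}

#: default archetype parameters (change onset / duration in years)
DEFAULT_PARAMS = {
    "dense_forest": {"level": 0.9},
    "forest": {"level": 0.65},
    "non_forest": {"level": 0.2},
    "recovery": {"low": 0.2, "high": 0.65, "onset": 2, "duration": 10},
    # single-year planting jump so the increase rate clears the 0.4
    # management-index threshold (see package notes)
    "afforestation": {"low": 0.2, "high": 0.9, "onset": 6, "duration": 1},
    "deforestation": {"high": 0.8, "low": 0.2, "onset": 6, "duration": 4},
    "rotation": {"low": 0.2, "high": 0.8, "cycle": 5},
    "rotation_L": {"high": 0.8, "low": 0.1, "regrow": 0.42, "onset": 5},
}

#: areal fractions reported for the study region, usable as a layout
TYPICAL_AREA_FRACTIONS = {
    "dense_forest": 0.088,
    "forest": 0.205,
    "non_forest": 0.438,
    "recovery": 0.054,
    "afforestation": 0.074,
    "deforestation": 0.016,
    "rotation": 0.106,
    "rotation_L": 0.019,
}

PIXEL_AREA_HA = 25.0  # 500 m x 500 m


@dataclass(frozen=True)
class ScenarioSpec:
    archetype: str
    years: tuple = DEFAULT_YEARS
    noise_sd: float = 0.0
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if "cycle" in self.params and self.params["cycle"] < 2:
            raise ValueError("rotation cycle length must be >= 2 years")
        years = tuple(int(y) for y in self.years)
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        if "onset" in self.params:
            if not 0 <= self.params["onset"] < len(years):
                raise ValueError("change onset must fall within the year range")
        object.__setattr__(self, "years", years)


@dataclass
class SceneStack:
    """A scene: probability (year, row, col) with a ground-truth label map."""

    probability: np.ndarray
    truth_labels: np.ndarray
    years: tuple = DEFAULT_YEARS
    pixel_area_ha: float = PIXEL_AREA_HA
    reflectance: np.ndarray | None = None
    elevation: np.ndarray | None = None

    def __post_init__(self):
        p = np.asarray(self.probability, dtype=float)
        if p.ndim != 3:
            raise ValueError("probability must be (year, row, col)")
        if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must be finite and within [0, 1]")
        if self.truth_labels.shape != p.shape[1:]:
            raise ValueError("truth_labels must match the spatial grid")
        valid_codes = set(LANDUSE_NAMES.values())
        if not set(np.unique(self.truth_labels)) <= valid_codes:
            raise ValueError("truth labels outside the 8 archetype codes")

    @property
    def shape(self):
        return self.probability.shape


@dataclass(frozen=True)
class CoarseSeriesSpec:
    """Controls for the coarse-grid (25 x 25 km^2) microwave simulator."""

    n_cells: int = 50
    start: str = "2010-01-01"
    end: str = "2017-12-31"
    step_days: int = 3
    sm_trend: float | np.ndarray = 0.0
    vod_trend: float | np.ndarray = 0.0
    sm_base: float = 0.25
    vod_base: float = 0.5
    obs_noise_sd: float = 0.0
    flag_rates: dict = field(
        default_factory=lambda: {
            "frozen": 0.0,
            "topography": 0.0,
            "urban": 0.0,
            "water": 0.0,
        }
    )
    seed: int = 0

    def __post_init__(self):
        for name, rate in self.flag_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"flag rate {name}={rate} outside [0, 1]")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if pd.Timestamp(self.end) <= pd.Timestamp(self.start):
            raise ValueError("no dates: end must come after start")


def _core_trajectory(archetype: str, n: int, params: dict) -> np.ndarray:
    """Noise-free archetype template over n annual steps."""
    p = dict(DEFAULT_PARAMS[archetype])
    p.update(params)
    t = np.arange(n, dtype=float)
    if archetype in ("dense_forest", "forest", "non_forest"):
        return np.full(n, p["level"])
    if archetype == "recovery" or archetype == "afforestation":
        onset, dur = p["onset"], p["duration"]
        out = np.full(n, p["low"])
        ramp = np.clip((t - onset) / dur, 0.0, 1.0)
        out = p["low"] + ramp * (p["high"] - p["low"])
        out[: onset + 1] = p["low"]
        return out
    if archetype == "deforestation":
        onset, dur = p["onset"], p["duration"]
        ramp = np.clip((t - onset) / dur, 0.0, 1.0)
        return p["high"] + ramp * (p["low"] - p["high"])
    if archetype == "rotation":
        cycle = int(p["cycle"])
        period = cycle + 1  # cycle growth years plus a one-year clear-cut
        phase = t % period
        grow = p["low"] + (phase / cycle) * (p["high"] - p["low"])
        out = np.where(phase <= cycle, grow, p["low"])
        return out
    if archetype == "rotation_L":
        onset = int(p["onset"])
        out = np.full(n, p["high"])
        out[onset + 1 :] = p["low"]
        # slow partial regrowth never reaching the forest threshold
        for i in range(onset + 2, n):
            out[i] = min(p["regrow"], out[i - 1] + (p["regrow"] - p["low"]) / 5.0)
        return out
    raise ValueError(f"unknown archetype {archetype!r}")


def generate_trajectory(spec: ScenarioSpec) -> np.ndarray:
    """Annual forest-probability series for one archetype.

    Additive Gaussian noise (sd = ``spec.noise_sd``) is applied to the
    noise-free template and the result clipped to [0, 1]; identical
    specs and seeds give bit-identical output.
    """
    n = len(spec.years)
    core = _core_trajectory(spec.archetype, n, spec.params)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        core = core + rng.normal(0.0, spec.noise_sd, size=n)
    return np.clip(core, 0.0, 1.0)


def _grid_shape(n: int) -> tuple[int, int]:
    """Most-square factorisation of n (falls back to 1 x n for primes)."""
    for r in range(int(np.sqrt(n)), 0, -1):
        if n % r == 0:
            return r, n // r
    return 1, n


def generate_scene(
    layout: dict,
    years=DEFAULT_YEARS,
    noise_sd: float = 0.0,
    seed: int = 0,
    params: dict | None = None,
    with_reflectance: bool = False,
    n_bands: int = 7,
) -> SceneStack:
    """Build a SceneStack whose truth labels match ``layout`` exactly.

    ``layout`` maps archetype name -> pixel count.  Per-pixel
    trajectories come from :func:`generate_trajectory` with
    pixel-specific child seeds; pixel positions are shuffled
    deterministically.
    """
    if not layout:
        raise ValueError("empty layout")
    for name in layout:
        if name not in ARCHETYPES:
            raise ValueError(f"unknown archetype {name!r}")
    total = int(sum(layout.values()))
    if total <= 0:
        raise ValueError("total pixel count must be > 0")
    years = tuple(int(y) for y in years)
    nr, nc = _grid_shape(total)
    rng = np.random.default_rng(seed)
    codes = np.concatenate(
        [np.full(count, LANDUSE_NAMES[name]) for name, count in layout.items()]
    ).astype(int)
    rng.shuffle(codes)
    labels = codes.reshape(nr, nc)
    prob = np.empty((len(years), nr, nc))
    pixel_seeds = rng.integers(0, 2**31 - 1, size=total)
    params = params or {}
    flat_labels = labels.ravel()
    for i, code in enumerate(flat_labels):
        name = {v: k for k, v in LANDUSE_NAMES.items()}[code]
        spec = ScenarioSpec(
            archetype=name,
            years=years,
            noise_sd=noise_sd,
            params=params.get(name, {}),
            seed=int(pixel_seeds[i]),
        )
        prob[:, i // nc, i % nc] = generate_trajectory(spec)
    reflectance = None
    elevation = None
    if with_reflectance:
        reflectance, elevation = _reflectance_from_probability(
            prob, n_bands=n_bands, rng=rng
        )
    return SceneStack(
        probability=prob,
        truth_labels=labels,
        years=years,
        reflectance=reflectance,
        elevation=elevation,
    )


def _reflectance_from_probability(prob: np.ndarray, n_bands: int, rng) -> tuple:
    """Invertible linear band model: each band is an affine map of the
    forest probability, plus an uninformative elevation layer."""
    ny, nr, nc = prob.shape
    slopes = np.linspace(-0.3, 0.3, n_bands)
    slopes[slopes == 0] = 0.05
    offsets = np.linspace(0.1, 0.5, n_bands)
    refl = np.empty((ny, n_bands, nr, nc))
    for b in range(n_bands):
        refl[:, b] = offsets[b] + slopes[b] * prob
    elevation = rng.uniform(50.0, 800.0, size=(nr, nc))
    return refl, elevation


def default_density_law(p) -> np.ndarray:
    """Monotone probability -> carbon density map (Mg C ha^-1).

    Piecewise-linear through anchors chosen so that the default
    archetype levels land near the regional per-type mean densities
    (non-forest ~22, forest ~75, dense forest ~105 Mg C ha^-1).
    """
    xp = np.array([0.0, 0.2, 0.65, 0.9, 1.0])
    fp = np.array([8.0, 22.0, 75.0, 105.0, 112.0])
    return np.interp(np.asarray(p, dtype=float), xp, fp)


def generate_cdensity_benchmark(
    stack: SceneStack,
    density_law=default_density_law,
    noise_sd: float = 0.0,
    seed: int = 0,
    ref_year: int | None = None,
) -> np.ndarray:
    """Single-date benchmark carbon-density raster aligned to the scene.

    The law is applied to the probability layer of ``ref_year`` (2015
    when present, else the final year), mimicking a static benchmark
    map; Gaussian noise is added and values floored at zero.
    """
    grid = np.linspace(0.0, 1.0, 101)
    vals = np.asarray(density_law(grid), dtype=float)
    if np.any(np.diff(vals) < -1e-12):
        raise ValueError("density_law must be monotone non-decreasing on [0, 1]")
    years = list(stack.years)
    if ref_year is None:
        ref_year = 2015 if 2015 in years else years[-1]
    if ref_year not in years:
        raise ValueError(f"ref_year {ref_year} not in scene years")
    p = stack.probability[years.index(ref_year)]
    density = np.asarray(density_law(p), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        density = density + rng.normal(0.0, noise_sd, size=density.shape)
    return np.maximum(density, 0.0)


def default_tbrmse_sampler(rng, size):
    """Gamma-distributed TB-RMSE (K), mean 4 with an occasional tail > 10."""
    return rng.gamma(shape=2.0, scale=2.0, size=size)


def generate_coarse_series(spec: CoarseSeriesSpec, tbrmse_sampler=None):
    """Dated coarse-grid VOD / SM observation streams plus truth trends.

    Returns ``(records, truth)``: a tidy DataFrame with one row per
    observation (both orbits) and a per-cell DataFrame of the imposed
    linear trends.
    """
    rng = np.random.default_rng(spec.seed)
    sampler = tbrmse_sampler or default_tbrmse_sampler
    dates = pd.date_range(spec.start, spec.end, freq=f"{spec.step_days}D")
    if len(dates) == 0:
        raise ValueError("no dates in the requested range")
    t_years = (dates - dates[0]).days / 365.25
    doy = dates.dayofyear.to_numpy()
    sm_trend = np.broadcast_to(np.asarray(spec.sm_trend, dtype=float), (spec.n_cells,))
    vod_trend = np.broadcast_to(
        np.asarray(spec.vod_trend, dtype=float), (spec.n_cells,)
    )
    frames = []
    for cell in range(spec.n_cells):
        for orbit in ("ascending", "descending"):
            vod = spec.vod_base + vod_trend[cell] * t_years
            sm = spec.sm_base + sm_trend[cell] * t_years
            if spec.obs_noise_sd > 0:
                vod = vod + rng.normal(0.0, spec.obs_noise_sd, size=len(dates))
                sm = sm + rng.normal(0.0, spec.obs_noise_sd, size=len(dates))
            sm = np.clip(sm, 0.0, 1.0)
            vod = np.maximum(vod, 0.0)
            soil_temp = 288.0 + 8.0 * np.sin(2 * np.pi * (doy - 120) / 365.25)
            tb_rmse = np.asarray(sampler(rng, len(dates)), dtype=float)
            frame = pd.DataFrame(
                {
                    "cell": cell,
                    "date": dates,
                    "orbit": orbit,
                    "vod": vod,
                    "sm": sm,
                    "soil_temp": soil_temp,
                    "tb_rmse": tb_rmse,
                }
            )
            for flag, rate in spec.flag_rates.items():
                frame[f"flag_{flag}"] = rng.random(len(dates)) < rate
            frames.append(frame)
    records = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        {
            "cell": np.arange(spec.n_cells),
            "sm_trend": sm_trend,
            "vod_trend": vod_trend,
        }
    )
    return records, truth


def generate_province_tables(
    n_provinces: int = 8,
    years=tuple(range(1997, 2018)),
    emissions_shape: str = "rise-then-plateau",
    timber_shape="ramp",
    seed: int = 0,
    noise_sd: float = 0.0,
    emissions_anchors=((1997, 0.21), (2012, 0.63)),
    timber_range=(4.0e6, 12.0e6),
):
    """Province x year fossil-emissions (Pg C) and timber-volume (m^3)
    tables.

    The 'rise-then-plateau' emissions shape interpolates linearly
    between the two anchors and stays flat after the second anchor year,
    so the regional (summed) series passes exactly through the anchors
    when ``noise_sd`` is zero.
    """
    years = [int(y) for y in years]
    if not years:
        raise ValueError("years must be non-empty")
    rng = np.random.default_rng(seed)
    (y0, v0), (y1, v1) = emissions_anchors
    yr = np.asarray(years, dtype=float)
    if emissions_shape == "rise-then-plateau":
        regional = np.interp(yr, [y0, y1], [v0, v1])
        regional[yr > y1] = v1
    elif emissions_shape == "constant":
        regional = np.full(len(years), v1)
    else:
        raise ValueError(f"unknown emissions_shape {emissions_shape!r}")
    shares = np.full(n_provinces, 1.0 / n_provinces)
    rows = []
    for i, year in enumerate(years):
        for p in range(n_provinces):
            value = regional[i] * shares[p]
            if noise_sd > 0:
                value = max(value * (1.0 + rng.normal(0.0, noise_sd)), 0.0)
            rows.append(
                {
                    "province": f"province_{p + 1}",
                    "year": year,
                    "value": value,
                    "units": "PgC",
                }
            )
    emissions = pd.DataFrame(rows)
    rows = []
    for i, year in enumerate(years):
        if timber_shape == "ramp":
            frac = i / max(len(years) - 1, 1)
            total = timber_range[0] + frac * (timber_range[1] - timber_range[0])
            per_province = total / n_provinces
        else:  # constant per-cell value
            per_province = float(timber_shape)
        for p in range(n_provinces):
            volume = per_province
            if noise_sd > 0:
                volume = max(volume * (1.0 + rng.normal(0.0, noise_sd)), 0.0)
            rows.append(
                {
                    "province": f"province_{p + 1}",
                    "year": year,
                    "value": volume,
                    "units": "m3",
                }
            )
    timber = pd.DataFrame(rows)
    return emissions, timber
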