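"""Pipeline configuration: a single validated mapping with per-stage
blocks that round-trips losslessly through YAML."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class ThresholdConfig:
    theta_dense: float = 0.8
    theta_forest: float = 0.5
    disturbance: float = 0.4
    high: float = 0.6
    seg_mag_tol: float = 0.02


@dataclass
class SegmentationConfig:
    max_segments: int = 6
    alpha: float = 0.05
    max_gap: int = 2


@dataclass
class CarbonConfig:
    split: float = 0.5
    sink_method: str = "endpoint"
    emissions_window: tuple = (2002, 2015)
    pixel_area_ha: float = 25.0
    wood_basic_density: float = 0.5


@dataclass
class MicrowaveConfig:
    tb_rmse_max: float = 10.0
    window_days: float = 30.0
    keep_per_year: int = 30
    lower_pct: float = 10.0
    upper_pct: float = 90.0
    trend_method: str = "ols"
    trend_alpha: float = 0.05


@dataclass
class SimulationConfig:
    n_pixels: int = 400
    noise_sd: float = 0.0
    years: tuple = tuple(range(2002, 2018))
    n_coarse_cells: int = 40
    coarse_sm_trend: float = -0.005
    coarse_vod_trend: float = 0.01
    coarse_noise_sd: float = 0.01


@dataclass
class PipelineConfig:
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    carbon: CarbonConfig = field(default_factory=CarbonConfig)
    microwave: MicrowaveConfig = field(default_factory=MicrowaveConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0

    def validate(self) -> None:
        t = self.thresholds
        for name in ("theta_dense", "theta_forest", "disturbance", "high"):
            v = getattr(t, name)
            if not 0 <= v <= 1:
                raise ValueError(f"thresholds.{name}={v} outside [0, 1]")
        if t.theta_dense < t.theta_forest:
            raise ValueError("theta_dense must be >= theta_forest")
        s = self.segmentation
        if not 0 < s.alpha <= 1:
            raise ValueError(f"segmentation.alpha={s.alpha} outside (0, 1]")
        if not 1 <= s.max_segments <= 15:
            raise ValueError(f"segmentation.max_segments={s.max_segments} out of range")
        c = self.carbon
        if not 0 < c.split < 1:
            raise ValueError(f"carbon.split={c.split} outside (0, 1)")
        if c.sink_method not in ("endpoint", "ols_slope"):
            raise ValueError(f"unknown carbon.sink_method {c.sink_method!r}")
        if c.pixel_area_ha <= 0:
            raise ValueError("carbon.pixel_area_ha must be positive")
        m = self.microwave
        if m.tb_rmse_max <= 0 or m.window_days <= 0 or m.keep_per_year < 1:
            raise ValueError("microwave filter settings out of domain")
        if not 0 <= m.lower_pct < m.upper_pct <= 100:
            raise ValueError("microwave percentiles out of order")
        if m.trend_method not in ("ols", "theilsen"):
            raise ValueError(f"unknown microwave.trend_method {m.trend_method!r}")
        if not 0 < m.trend_alpha < 1:
            raise ValueError("microwave.trend_alpha outside (0, 1)")
        if self.simulation.n_pixels < 1:
            raise ValueError("simulation.n_pixels must be >= 1")
        if self.simulation.noise_sd < 0:
            raise ValueError("simulation.noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        d = self.to_dict()
        # tuples do not survive YAML; normalise to lists for round-trip
        return yaml.safe_dump(json.loads(json.dumps(d, default=list)), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, block):
            obj = klass(**{k: v for k, v in (block or {}).items()})
            for f_name, f_val in vars(obj).items():
                if isinstance(f_val, list):
                    setattr(obj, f_name, tuple(f_val))
            return obj

        cfg = cls(
            thresholds=build(ThresholdConfig, d.get("thresholds")),
            segmentation=build(SegmentationConfig, d.get("segmentation")),
            carbon=build(CarbonConfig, d.get("carbon")),
            microwave=build(MicrowaveConfig, d.get("microwave")),
            simulation=build(SimulationConfig, d.get("simulation")),
            seed=int(d.get("seed", 0)),
        )
        return cfg

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
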