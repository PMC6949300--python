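"""End-to-end orchestration on synthetic scenes.

Stages run in dependency order (simulate -> preprocess -> trajectory ->
carbon -> microwave -> report); every artifact lands in a run directory
together with a manifest recording the config hash, seed and per-stage
runtimes.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from landcarbon import carbon, compare, microwave, preprocess, synthetic, trajectory
from landcarbon.config import PipelineConfig
from landcarbon.trajectory import LANDUSE_CODES


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def _layout_from_fractions(n_pixels: int) -> dict:
    fractions = synthetic.TYPICAL_AREA_FRACTIONS
    layout = {k: int(round(v * n_pixels)) for k, v in fractions.items()}
    # pad/trim the largest class so counts total exactly n_pixels
    diff = n_pixels - sum(layout.values())
    layout["non_forest"] += diff
    return layout


def simulate_stage(cfg: PipelineConfig, rng: np.random.Generator) -> dict:
    sim = cfg.simulation
    scene = synthetic.generate_scene(
        _layout_from_fractions(sim.n_pixels),
        years=sim.years,
        noise_sd=sim.noise_sd,
        seed=int(rng.integers(2**31)),
        with_reflectance=True,
    )
    benchmark = synthetic.generate_cdensity_benchmark(
        scene, seed=int(rng.integers(2**31))
    )
    coarse_spec = synthetic.CoarseSeriesSpec(
        n_cells=sim.n_coarse_cells,
        sm_trend=sim.coarse_sm_trend,
        vod_trend=sim.coarse_vod_trend,
        obs_noise_sd=sim.coarse_noise_sd,
        seed=int(rng.integers(2**31)),
    )
    coarse_records, coarse_truth = synthetic.generate_coarse_series(coarse_spec)
    emissions_table, timber_table = synthetic.generate_province_tables(
        seed=int(rng.integers(2**31))
    )
    return {
        "scene": scene,
        "benchmark": benchmark,
        "coarse_records": coarse_records,
        "coarse_truth": coarse_truth,
        "emissions_table": emissions_table,
        "timber_table": timber_table,
    }


def preprocess_stage(cfg: PipelineConfig, scene, rng: np.random.Generator) -> dict:
    labels = scene.truth_labels
    stable_forest = np.isin(labels, [1, 2])
    stable_non = labels == 3
    feats = preprocess.average_band_features(scene.reflectance)
    nb = feats.shape[0]

    def sample(mask, n):
        rows, cols = np.where(mask)
        if len(rows) == 0:
            raise StageError("preprocess", "no_training", "a class has no pixels")
        pick = rng.choice(len(rows), size=min(n, len(rows)), replace=False)
        return rows[pick], cols[pick]

    fr, fc = sample(stable_forest, 60)
    nr_, nc_ = sample(stable_non, 120)
    X = []
    y = []
    for rows, cols, label in ((fr, fc, 1), (nr_, nc_, 0)):
        band_vals = feats[:, rows, cols].T
        elev = scene.elevation[rows, cols][:, None]
        X.append(np.hstack([band_vals, elev]))
        y.extend([label] * len(rows))
    X = np.vstack(X)
    y = np.asarray(y)
    clf, cv_r = preprocess.train_forest_classifier(
        X, y, seed=int(rng.integers(2**31)), n_estimators=100
    )
    prob = preprocess.predict_probability(clf, scene.reflectance, scene.elevation)
    return {"classifier": clf, "cv_r": cv_r, "probability": prob}


def trajectory_stage(cfg: PipelineConfig, probability, years) -> dict:
    t = cfg.thresholds
    s = cfg.segmentation
    labels, summary = trajectory.classify_scene(
        probability,
        years=np.asarray(years),
        max_segments=s.max_segments,
        alpha=s.alpha,
        theta_dense=t.theta_dense,
        theta_forest=t.theta_forest,
        disturbance_threshold=t.disturbance,
        high_threshold=t.high,
        seg_mag_tol=t.seg_mag_tol,
        max_gap=s.max_gap,
    )
    return {"labels": labels, "summary": summary}


def carbon_stage(cfg: PipelineConfig, scene, benchmark, labels, emissions_table, rng):
    refl = scene.reflectance
    years = list(scene.years)
    ref_idx = years.index(2015) if 2015 in years else len(years) - 1
    nb = refl.shape[1]
    predictors_ref = np.concatenate(
        [refl[ref_idx], scene.elevation[None]], axis=0
    )
    model, quality = carbon.train_cdensity_model(
        benchmark,
        predictors_ref,
        split=cfg.carbon.split,
        seed=int(rng.integers(2**31)),
    )
    predictors_by_year = np.stack(
        [
            np.concatenate([refl[yi], scene.elevation[None]], axis=0)
            for yi in range(len(years))
        ]
    )
    density = carbon.predict_cdensity(model, predictors_by_year)
    emissions = carbon.regional_emissions_series(emissions_table)
    account = carbon.carbon_account(
        density,
        years,
        labels,
        emissions=emissions,
        pixel_area_ha=cfg.carbon.pixel_area_ha,
        emissions_window=cfg.carbon.emissions_window,
        sink_method=cfg.carbon.sink_method,
    )
    return {
        "model_quality": quality,
        "density": density,
        "account": account,
        "emissions": emissions,
    }


def microwave_stage(cfg: PipelineConfig, coarse_records) -> dict:
    m = cfg.microwave
    processed = []
    for cell, grp in coarse_records.groupby("cell"):
        processed.append(
            microwave.process_cell(
                grp,
                window_days=m.window_days,
                keep_per_year=m.keep_per_year,
                tb_rmse_max=m.tb_rmse_max,
            )
        )
    combined = pd.concat(processed, ignore_index=True)
    sm_annual = microwave.annualize(combined, "sm")
    vod_annual = microwave.annualize(combined, "vod")
    sm_trends = microwave.cell_trends(
        sm_annual, "sm", alpha=m.trend_alpha, method=m.trend_method
    )
    vod_trends = microwave.cell_trends(
        vod_annual, "vod", alpha=m.trend_alpha, method=m.trend_method
    )
    return {
        "combined": combined,
        "sm_trends": sm_trends,
        "vod_trends": vod_trends,
        "sm_summary": microwave.trend_summary(sm_trends),
    }


def report_stage(cfg, account, landuse_summary, sm_summary, timber_table) -> dict:
    timber = carbon.timber_carbon_series(
        timber_table, cfg.carbon.wood_basic_density
    )
    return compare.summary_tables(
        account,
        landuse_summary=landuse_summary,
        trends_summary=sm_summary,
        timber_series=timber,
    )


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage and write all artifacts plus a manifest."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    runtimes = {}
    results = {}

    def timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - wrap with stage context
            raise StageError(name, "stage_failure", str(exc)) from exc
        runtimes[name] = round(time.perf_counter() - t0, 3)
        return out

    sim = timed("simulate", simulate_stage, cfg, rng)
    results.update(sim)
    pre = timed("preprocess", preprocess_stage, cfg, sim["scene"], rng)
    results.update(pre)
    traj = timed(
        "trajectory", trajectory_stage, cfg, pre["probability"], sim["scene"].years
    )
    results.update(traj)
    carb = timed(
        "carbon",
        carbon_stage,
        cfg,
        sim["scene"],
        sim["benchmark"],
        traj["labels"],
        sim["emissions_table"],
        rng,
    )
    results.update(carb)
    micro = timed("microwave", microwave_stage, cfg, sim["coarse_records"])
    results.update(micro)
    tables = timed(
        "report",
        report_stage,
        cfg,
        carb["account"],
        traj["summary"],
        micro["sm_summary"],
        sim["timber_table"],
    )
    results["tables"] = tables

    # --- artifacts (plain-text formats) ---
    np.savetxt(outdir / "landuse_labels.csv", traj["labels"], fmt="%d", delimiter=",")
    with open(outdir / "landuse_codes.json", "w") as fh:
        json.dump(LANDUSE_CODES, fh, indent=1)
    pd.DataFrame(traj["summary"]["diagnostics"]).to_csv(
        outdir / "pixel_diagnostics.csv", index=False
    )
    carb["account"].table.to_csv(outdir / "carbon_account.csv")
    carb["account"].annual_stocks.to_csv(outdir / "annual_stocks.csv")
    micro["sm_trends"].to_csv(outdir / "sm_trends.csv", index=False)
    micro["vod_trends"].to_csv(outdir / "vod_trends.csv", index=False)
    for name, frame in tables.items():
        frame.to_csv(outdir / f"report_{name}.csv")
    manifest = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "stages": list(runtimes),
        "runtimes_s": runtimes,
        "classifier_cv_r": pre["cv_r"],
        "density_model_quality": carb["model_quality"],
        "sm_trend_summary": micro["sm_summary"],
        "algorithm_version": microwave.ALGORITHM_VERSION,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    results["manifest"] = manifest
    return results
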