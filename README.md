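# landcarbon

A tested, reusable pipeline for land-use-change typology and aboveground
carbon accounting from annual forest-probability raster time series, with
an independent L-band microwave (VOD / soil-moisture) filtering and trend
stage. Every stage runs end-to-end on synthetic scenes with known ground
truth, so nothing requires external downloads.

## Stages / modules

| module | what it does |
| --- | --- |
| `landcarbon.synthetic` | scene, trajectory, benchmark, coarse-grid microwave and province-table generators with ground truth |
| `landcarbon.preprocess` | annual median compositing, 3-year moving median, random-forest forest-probability model |
| `landcarbon.trajectory` | exact-DP piecewise-linear segmentation (max 6 segments, F-test at α = 0.05), management increase/decrease indices, 9 dynamics classes, 8 land-use types |
| `landcarbon.carbon` | boosted-tree carbon-density model calibrated against a benchmark map; per-type stocks, gross gains/losses, net sinks, contributions, emission-offset fractions; CO₂→C and timber-carbon conversions |
| `landcarbon.microwave` | flag/TB-RMSE quality filtering, 30-day smoothing with 10th/90th-percentile residual outlier removal, lowest-TB-RMSE orbit combination, logistic VOD→density calibration, per-cell OLS/Theil–Sen trends with significance |
| `landcarbon.compare` | block aggregation, cross-product correlation and RMSE, summary/report tables |
| `landcarbon.config`, `landcarbon.pipeline`, `landcarbon.cli` | validated YAML config, orchestration, CLI |

## CLI

```sh
# full synthetic pipeline into a run directory (writes CSV/JSON artifacts
# plus a manifest with config hash, seed and per-stage runtimes)
landcarbon run-all --out runs/demo --seed 1

# individual stages
landcarbon simulate --out runs/sim --seed 1
landcarbon typology --probability runs/sim/probability.csv --out runs/typ
landcarbon microwave --records my_records.csv --out runs/mw

# custom settings
landcarbon run-all --config my_config.yaml --out runs/custom
```

A config YAML can be produced from the defaults with
`python -c "from landcarbon.config import PipelineConfig; print(PipelineConfig().to_yaml())"`.

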