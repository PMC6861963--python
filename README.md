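# pm-gridsense

Hourly urban PM2.5 mapping from multi-source gridded features with a deep
belief network regressor.

## What this package is for

Cities monitor fine particulate matter (PM2.5, μg/m³) with a few dozen fixed
stations, but exposure assessment and air-quality management want continuous
concentration surfaces at fine space–time resolution.  `pm-gridsense`
estimates hourly PM2.5 on a 0.01° lon/lat grid by fusing:

* **station observations** and their spatiotemporal autocorrelation features
  (PM_s, PM_t — inverse-distance-weighted interpolations over neighbouring
  stations and preceding hours);
* **social sensing data** — check-in density (RTCI), traffic-index kernel
  density (TID), road-network density (ROAD), and POI buffer counts for
  pollution-source (PS) and clean-scenery (Scen) classes;
* **satellite products** — aerosol optical thickness (AOT, cloud-gapped,
  daytime-only) and a 16-day vegetation index (NDVI);
* **meteorology** — RH, TEM, EWS, NWS, SP, PBLH — and terrain (DEM).

Every source is matched onto a common hourly 0.01° lattice; each grid cell
and hour yields one multivariate feature vector, labeled where a station
exists.  The regressor is a deep belief network: three restricted Boltzmann
machines (12/24/36 hidden units) pre-trained by contrastive divergence

    p(h_j=1|v) = σ(Σ_i w_ij v_i + c_j),    p(v_i=1|h) = σ(Σ_j w_ij h_j + b_i)
    Δw_ij = λ( p(h_j|v)v_i − p(h_j|v′)v′_i )

then unrolled and fine-tuned by backpropagation (Levenberg–Marquardt on the
mean-squared error) with min-max-normalized inputs and labels.  Model skill
is measured by 10-fold cross-validation with R², RMSE, MPE and RPE, and by a
paired variable-ablation harness; trained models predict every grid cell to
produce hourly maps and temporal aggregates.

Because the data feeds such analyses use are proprietary, the package ships
a **synthetic-city generator** with known ground truth (autocorrelated PM
field driven nonlinearly by traffic density, boundary-layer height,
vegetation, wind stagnation and a temperature–humidity interaction) so the
entire pipeline is testable offline.  See `docs/methods.md` for the model
details and the generator's design.

## Worked example

```python
from pm_gridsense import (ScenarioConfig, generate_scenario, TrainConfig,
                          cross_validate, station_feature_table)

sc = generate_scenario(ScenarioConfig(seed=1))        # 20 stations, 720 h
samples = station_feature_table(sc)                   # 14,400 labeled rows
sub = samples.sample(2000, random_state=1).sort_index()

cfg = TrainConfig(cd_epochs=30, max_iterations=40, seed=1)
lin = cross_validate(sub, "optimal_A", cfg, k=10, seed=1, model="linear")
dbn = cross_validate(sub, "optimal_A", cfg, k=10, seed=1, model="dbn")
print(f"linear  CV R2 {lin.pooled.r2:.3f}  RMSE {lin.pooled.rmse:.2f}")
print(f"DBN     CV R2 {dbn.pooled.r2:.3f}  RMSE {dbn.pooled.rmse:.2f}")
```

prints (exactly, given the fixed seeds):

```
linear  CV R2 0.873  RMSE 9.81
DBN     CV R2 0.941  RMSE 6.66
```

The `optimal_A` combination is Time, NDVI, PM_s, PM_t, RTCI, TID and the six
meteorological variables — no AOT, so maps are continuous day and night.
The DBN's ~0.07 R² advantage over the main-effects linear fit is the
synthetic city's recoverable nonlinear structure (saturation, stagnation and
interaction terms); RMSE is in μg/m³ against held-out station observations.

A command-line interface wraps the same stages:

```bash
pm-gridsense simulate --config scenario.yaml --out city/ --seed 3
pm-gridsense extract  --scenario city/ --out samples.csv
pm-gridsense train    --samples samples.csv --combo optimal_A --out model.json
pm-gridsense cv       --samples samples.csv --combo optimal_A --k 10
pm-gridsense map      --scenario city/ --model model.json --hours 5,6 --out maps.nc
pm-gridsense run      --config pipeline.yaml   # the whole thing
```

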