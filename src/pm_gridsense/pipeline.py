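"""End-to-end orchestration: featurize a scenario, assemble samples, train,
cross-validate, and produce hourly 0.01° PM2.5 maps with temporal aggregates.

Two featurization paths share the same matching rules:

* :func:`station_feature_table` evaluates every feature at the station cells
  only — the labeled (training) samples.  The spatial PM feature of a labeled
  record is computed leave-one-station-out by default, so a training sample
  never contains information derived from its own label;
* :func:`hour_feature_rasters` builds the full per-hour feature rasters used
  for prediction, where all stations contribute.

Sample-set modes mirror the aerosol-coverage trade-off: ``without-AOT`` keeps
every station-hour and excludes the AOT column (continuous maps), ``with-AOT``
adds AOT and drops any record or cell lacking a valid retrieval.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .dbn import DBNModel, TrainConfig, train_dbn
from .evaluation import cross_validate
from .features import (IDWConfig, KDAConfig, checkin_feature,
                       line_density_basis, pm_spatial_feature,
                       pm_spatial_loo_at_stations, pm_temporal_at_stations,
                       pm_temporal_feature, poi_buffer_counts, road_density)
from .grid import RasterField, expand_combo, select_temporal_slice
from .synthetic import ScenarioConfig, SyntheticScenario, generate_scenario

logger = logging.getLogger(__name__)

MET_VARS = ("RH", "TEM", "EWS", "NWS", "SP", "PBLH")


@dataclass
class FeatureConfig:
    idw: IDWConfig = field(default_factory=IDWConfig)
    kda: KDAConfig = field(default_factory=KDAConfig)
    poi_radius_km: float = 1.1
    loo_pm_s: bool = True  # leave-one-station-out spatial PM for labeled rows
    pm_lags: tuple[int, ...] = (1, 2, 3)


class FeatureCache:
    """Static per-scenario products reused across hours."""

    def __init__(self, sc: SyntheticScenario, fcfg: FeatureConfig):
        self.sc = sc
        self.fcfg = fcfg
        self._basis = None
        self._road = None
        self._pois = None

    @property
    def traffic_basis(self) -> np.ndarray:
        if self._basis is None:
            self._basis = line_density_basis(self.sc.traffic_lines,
                                             self.sc.grid, self.fcfg.kda)
        return self._basis

    @property
    def road(self) -> RasterField:
        if self._road is None:
            self._road = road_density(self.sc.road_lines, self.sc.grid)
        return self._road

    @property
    def poi_fields(self) -> dict:
        if self._pois is None:
            self._pois = poi_buffer_counts(self.sc.pois, self.sc.grid,
                                           self.fcfg.poi_radius_km)
        return self._pois


def station_feature_table(sc: SyntheticScenario,
                          fcfg: FeatureConfig | None = None,
                          cache: FeatureCache | None = None) -> pd.DataFrame:
    """One labeled sample per station-hour with the full feature vector.

    Returns the standard sample schema: keys (row, col, hour, station_id),
    ``label`` and every canonical feature column; AOT is NaN where no valid
    retrieval covers the cell-hour.
    """
    fcfg = fcfg or FeatureConfig()
    cache = cache or FeatureCache(sc, fcfg)
    grid = sc.grid
    srow, scol = sc.station_cells()
    n_st, n_h = len(sc.stations), sc.n_hours
    obs = sc.obs_wide()  # (hour, station)

    if fcfg.loo_pm_s:
        pm_s = pm_spatial_loo_at_stations(sc.stations, obs, grid, fcfg.idw)
    else:
        # all stations contribute; a station's own observation is an exact hit
        pm_s = obs.copy()
    pm_t = pm_temporal_at_stations(sc.stations, obs, grid, fcfg.idw,
                                   lags=fcfg.pm_lags)

    rtci = np.full((n_h, n_st), np.nan)
    for h in range(n_h):
        fld = checkin_feature(sc.checkin_snapshots(h), grid, fcfg.idw, hour=h)
        vals = np.where(fld.mask, fld.values, np.nan)
        rtci[h] = vals[srow, scol]

    tid = sc.traffic_index.astype(float) @ cache.traffic_basis[:, srow, scol]
    road = np.broadcast_to(cache.road.values[srow, scol], (n_h, n_st))
    ps = np.broadcast_to(cache.poi_fields["PS"].values[srow, scol], (n_h, n_st))
    scen = np.broadcast_to(cache.poi_fields["SCEN"].values[srow, scol],
                           (n_h, n_st))
    aot = sc.covariates["AOT"][:, srow, scol]
    scene_of_hour = np.minimum(np.arange(n_h) // (16 * 24),
                               len(sc.covariates["NDVI"]) - 1)
    ndvi = np.stack([sc.covariates["NDVI"][i][srow, scol]
                     for i in scene_of_hour])
    dem = np.broadcast_to(sc.covariates["DEM"][srow, scol], (n_h, n_st))

    cols = {
        "PM_S": pm_s, "PM_T": pm_t, "RTCI": rtci, "TID": tid, "ROAD": road,
        "PS": ps, "SCEN": scen, "AOT": aot, "NDVI": ndvi, "DEM": dem,
    }
    for v in MET_VARS:
        cols[v] = sc.covariates[v][:, srow, scol]

    hours = np.repeat(np.arange(n_h), n_st)
    df = pd.DataFrame({
        "row": np.tile(srow, n_h), "col": np.tile(scol, n_h), "hour": hours,
        "station_id": np.tile(sc.stations["station_id"].to_numpy(), n_h),
        "label": obs.ravel(),
        "HOUR": hours % 24, "DAY": hours // 24,
    })
    for name, mat in cols.items():
        df[name] = np.asarray(mat).ravel()
    return df.dropna(subset=["label"]).reset_index(drop=True)


def hour_feature_rasters(sc: SyntheticScenario, hour: int,
                         fcfg: FeatureConfig | None = None,
                         cache: FeatureCache | None = None) -> dict:
    """Full feature rasters of one hour (prediction grid)."""
    fcfg = fcfg or FeatureConfig()
    cache = cache or FeatureCache(sc, fcfg)
    grid = sc.grid
    obs_h = sc.station_obs[sc.station_obs["hour"] == hour].merge(
        sc.stations, on="station_id")
    out = {}
    out["PM_S"] = pm_spatial_feature(obs_h, grid, fcfg.idw, hour=hour)
    history = {}
    for lag in fcfg.pm_lags:
        if hour - lag >= 0:
            history[lag] = sc.station_obs[
                sc.station_obs["hour"] == hour - lag].merge(sc.stations,
                                                            on="station_id")
    if history:
        out["PM_T"] = pm_temporal_feature(history, grid, fcfg.idw, hour=hour)
    else:
        z = np.zeros((grid.n_rows, grid.n_cols))
        out["PM_T"] = RasterField(grid, z, name="PM_T", hour=hour,
                                  mask=np.zeros_like(z, bool))
    out["RTCI"] = checkin_feature(sc.checkin_snapshots(hour), grid, fcfg.idw,
                                  hour=hour)
    tid_vals = np.tensordot(sc.traffic_index[hour].astype(float),
                            cache.traffic_basis, axes=(0, 0))
    out["TID"] = RasterField(grid, tid_vals, name="TID", hour=hour)
    out["ROAD"] = cache.road
    out.update(cache.poi_fields)
    out["AOT"] = RasterField(grid, np.nan_to_num(sc.covariates["AOT"][hour]),
                             name="AOT", hour=hour, mask=sc.aot_mask[hour])
    ndvi_scenes = [RasterField(grid, s, name="NDVI")
                   for s in sc.covariates["NDVI"]]
    out["NDVI"] = select_temporal_slice(ndvi_scenes, hour, 16 * 24)
    out["DEM"] = RasterField(grid, sc.covariates["DEM"], name="DEM")
    for v in MET_VARS:
        out[v] = RasterField(grid, sc.covariates[v][hour], name=v, hour=hour)
    return out


# ---------------------------------------------------------------------------
# mapping

def predict_hourly_map(model: DBNModel, rasters: dict, hour: int,
                       combo, day_length: int = 24,
                       floor_at_zero: bool = False) -> RasterField:
    """Predict one hour's PM2.5 map from feature rasters.

    Cells missing any requested feature are masked; labeled cells are
    predicted like any other (the map is a continuous surface, station
    observations are overlaid separately when reported).  Predictions are not
    clipped at zero unless ``floor_at_zero``; negative values stay observable.
    """
    features = expand_combo(combo)
    grid = next(iter(rasters.values())).grid
    n = grid.n_cells
    mat = np.empty((n, len(features)))
    valid = np.ones(n, bool)
    for j, f in enumerate(features):
        if f == "HOUR":
            mat[:, j] = hour % day_length
        elif f == "DAY":
            mat[:, j] = hour // day_length
        else:
            fld = rasters[f]
            mat[:, j] = fld.values.ravel()
            valid &= fld.mask.ravel()
    vals = np.zeros(n)
    if valid.any():
        vals[valid] = model.predict(mat[valid], feature_names=features)
    else:
        logger.warning("hour %s: no cell has all features valid", hour)
    if floor_at_zero:
        vals = np.maximum(vals, 0.0)
    return RasterField(grid, vals.reshape(grid.n_rows, grid.n_cols),
                       name="PM25_PRED", hour=hour,
                       mask=valid.reshape(grid.n_rows, grid.n_cols))


def aggregate_maps(maps: list[RasterField], reducer: str = "mean",
                   stations: pd.DataFrame | None = None,
                   station_obs: pd.DataFrame | None = None):
    """Cell-wise reduction of hourly maps over their valid hours.

    Cells with zero valid hours are masked.  When a station table (and
    observations) are supplied, also returns the per-station overlay table
    comparing mean observed and mean predicted values at the station cell
    over the aggregated hours.
    """
    if not maps:
        raise ValueError("no maps to aggregate")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid != grid:
            raise ValueError("maps are on different grids")
    stack = np.stack([np.where(m.mask, m.values, np.nan) for m in maps])
    with np.errstate(all="ignore"):
        if reducer == "mean":
            vals = np.nanmean(stack, axis=0)
        elif reducer == "max":
            vals = np.nanmax(stack, axis=0)
        else:
            raise ValueError(f"unknown reducer {reducer!r}")
    mask = np.isfinite(vals)
    agg = RasterField(grid, np.where(mask, vals, 0.0), name=f"PM25_{reducer}",
                      mask=mask)
    if stations is None:
        return agg
    hours = [m.hour for m in maps]
    rows = []
    srow, scol = grid.cell_of(stations["lon"].to_numpy(),
                              stations["lat"].to_numpy())
    for (sid, r, c) in zip(stations["station_id"], srow, scol):
        pred = agg.values[r, c] if agg.mask[r, c] else np.nan
        obs_mean = np.nan
        if station_obs is not None:
            sel = station_obs[(station_obs["station_id"] == sid)
                              & station_obs["hour"].isin(hours)]
            if len(sel):
                obs_mean = float(sel["pm25"].mean())
        rows.append({"station_id": sid, "mean_observed": obs_mean,
                     "mean_predicted": pred})
    return agg, pd.DataFrame(rows)


def map_diagnostics(fld: RasterField) -> dict:
    """Anomaly feedback for variable selection: spatial roughness and local
    outlier count (the accept/reject decision stays with the user)."""
    v = np.where(fld.mask, fld.values, np.nan)
    gy, gx = np.gradient(v)
    with np.errstate(all="ignore"):
        rough = float(np.nanmean(np.hypot(gx, gy)))
        mu, sd = np.nanmean(v), np.nanstd(v)
        outliers = int(np.nansum(np.abs(v - mu) > 3 * sd)) if sd > 0 else 0
    return {"roughness": rough, "local_outliers": outliers,
            "negative_cells": int(np.nansum(v < 0)),
            "valid_cells": int(fld.mask.sum())}


# ---------------------------------------------------------------------------
# full run

@dataclass
class PipelineConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    scenario_dir: str | None = None  # ingest instead of simulate
    sample_mode: str = "without-AOT"  # or "with-AOT"
    combo: object = "optimal_A"
    train: TrainConfig = field(default_factory=TrainConfig)
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    run_cv: bool = True
    cv_k: int = 10
    max_train_samples: int | None = None
    map_hours: tuple[int, ...] = (12,)
    reducer: str = "mean"
    floor_at_zero: bool = False
    out_dir: str = "run"
    seed: int = 0

    def effective_combo(self) -> list[str]:
        feats = expand_combo(self.combo)
        if self.sample_mode == "with-AOT" and "AOT" not in feats:
            feats = ["AOT"] + feats
        if self.sample_mode == "without-AOT" and "AOT" in feats:
            feats = [f for f in feats if f != "AOT"]
        return feats


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["map_hours"] = list(cfg.map_hours)
    d["scenario"]["rush_hours"] = list(cfg.scenario.rush_hours)
    d["train"]["hidden_sizes"] = list(cfg.train.hidden_sizes)
    d["feature"]["pm_lags"] = list(cfg.feature.pm_lags)
    return d


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute simulate-or-ingest → extract → assemble → train → cv → map →
    aggregate, writing a reproducible run directory.

    The run seed overrides the scenario and training seeds, so identical
    configs and seeds produce byte-identical samples, model file and maps.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s", name)
        return lambda **extra: stages.append(
            {"stage": name, "seconds": round(time.perf_counter() - t0, 3),
             **extra})

    try:
        done = stage("scenario")
        if cfg.scenario_dir:
            sc = pio.read_scenario(cfg.scenario_dir)
        else:
            sc = generate_scenario(replace(cfg.scenario, seed=cfg.seed))
        done(n_hours=sc.n_hours, n_stations=len(sc.stations))

        done = stage("extract")
        cache = FeatureCache(sc, cfg.feature)
        samples = station_feature_table(sc, cfg.feature, cache)
        combo = cfg.effective_combo()
        usable = samples.dropna(subset=combo)
        done(labeled=len(samples), usable=len(usable))
        train_set = usable
        if cfg.max_train_samples and len(usable) > cfg.max_train_samples:
            train_set = usable.sample(cfg.max_train_samples,
                                      random_state=cfg.seed).sort_index()
        pio.write_samples(samples, out / "samples.csv")

        report: dict = {"sample_mode": cfg.sample_mode, "combo": combo,
                        "n_labeled": int(len(samples)),
                        "n_usable": int(len(usable)),
                        "n_train": int(len(train_set))}

        if cfg.run_cv:
            done = stage("cv")
            cv = cross_validate(train_set, combo, replace(cfg.train, seed=cfg.seed),
                                k=cfg.cv_k, seed=cfg.seed)
            report["cv"] = {"pooled": cv.pooled.as_dict(),
                            "fold_mean": cv.fold_mean,
                            "fitting": cv.fitting.as_dict()}
            cv.predictions.to_csv(out / "cv_predictions.csv", index=False,
                                  float_format="%.12g")
            done(cv_r2=cv.pooled.r2)

        done = stage("train")
        x = train_set[combo].to_numpy(float)
        y = train_set["label"].to_numpy(float)
        model = train_dbn(x, y, replace(cfg.train, seed=cfg.seed),
                          feature_names=combo)
        model.save(out / "model.json")
        done(final_mse=model.finetune_log[-1])

        done = stage("map")
        maps, diagnostics = [], []
        for h in cfg.map_hours:
            rasters = hour_feature_rasters(sc, h, cfg.feature, cache)
            fld = predict_hourly_map(model, rasters, h, combo,
                                     floor_at_zero=cfg.floor_at_zero)
            maps.append(fld)
            diagnostics.append({"hour": h, **map_diagnostics(fld)})
        pio.write_maps(out / "maps.nc", sc.grid, maps)
        report["map_diagnostics"] = diagnostics
        done(n_maps=len(maps))

        done = stage("aggregate")
        agg, overlay = aggregate_maps(maps, cfg.reducer, sc.stations,
                                      sc.station_obs)
        pio.write_raster_stack(out / "aggregate.nc", sc.grid,
                               np.where(agg.mask, agg.values, np.nan),
                               agg.name)
        overlay.to_csv(out / "station_overlay.csv", index=False,
                       float_format="%.12g")
        done()
    except Exception:
        failed = stages[-1]["stage"] if stages else "scenario"
        logger.exception("pipeline aborted in stage after %s", failed)
        raise

    cfg_dict = _config_dict(cfg)
    cfg_dict.pop("out_dir")  # where a run lands is not part of what it computes
    cfg_doc = json.dumps(cfg_dict, sort_keys=True)
    provenance = {
        "config": json.loads(cfg_doc),
        "config_sha256": hashlib.sha256(cfg_doc.encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": {m.__name__: m.__version__ for m in
                     (np, pd)},
    }
    with open(out / "provenance.json", "w") as f:
        json.dump(provenance, f, indent=1, sort_keys=True)
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=1, sort_keys=True)
    with open(out / "run_log.json", "w") as f:
        json.dump(stages, f, indent=1)
    return out
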