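"""On-disk contracts: CSV tables, GeoJSON line sets, NetCDF raster stacks.

The synthetic generator writes — and the pipeline reads — the same formats a
real deployment would be prepared to (WGS84 lon/lat throughout):

* ``stations.csv`` — station_id, lon, lat
* ``observations.csv`` — station_id, timestamp_iso, pm25
* ``checkins.csv`` — lon, lat, timestamp_iso, count (5-minute snapshots)
* ``roads.geojson`` — LineString features with a ``level`` property
* ``traffic/hour_HHHH.geojson`` — LineString features with an ``index``
  property, one file per hour
* ``pois.csv`` — lon, lat, poi_class
* ``rasters/<VAR>.nc`` — NetCDF stacks (time, lat, lon) with NaN gaps;
  ``DEM.nc`` static, ``NDVI.nc`` one scene per 16-day period

NetCDF files are written through xarray's scipy backend (NETCDF3), which is
byte-deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec, RasterField
from .synthetic import (ScenarioConfig, SyntheticScenario, config_from_dict,
                        config_to_dict)

_FLOAT_FMT = "%.10g"


def hour_to_timestamp(start_time: str, hour: int, minute: int = 0) -> str:
    t = pd.Timestamp(start_time) + pd.Timedelta(hours=hour, minutes=minute)
    return t.isoformat()


def timestamp_to_hour(start_time: str, ts) -> tuple[int, int]:
    delta = pd.Timestamp(ts) - pd.Timestamp(start_time)
    minutes = int(delta.total_seconds() // 60)
    return minutes // 60, minutes % 60


# ---------------------------------------------------------------------------
# rasters

def stack_to_dataset(grid: GridSpec, values: np.ndarray, name: str,
                     time_dim: str = "time") -> xr.Dataset:
    values = np.asarray(values, float)
    coords = {"lat": grid.lat_centers(), "lon": grid.lon_centers()}
    if values.ndim == 2:
        da = xr.DataArray(values, dims=("lat", "lon"), coords=coords)
    else:
        coords[time_dim] = np.arange(values.shape[0])
        da = xr.DataArray(values, dims=(time_dim, "lat", "lon"), coords=coords)
    ds = xr.Dataset({name: da})
    ds.attrs.update(lon_min=grid.lon_min, lat_min=grid.lat_min,
                    n_cols=grid.n_cols, n_rows=grid.n_rows,
                    cell_size=grid.cell_size, crs="EPSG:4326")
    return ds


def write_raster_stack(path, grid: GridSpec, values: np.ndarray, name: str,
                       time_dim: str = "time") -> None:
    stack_to_dataset(grid, values, name, time_dim).to_netcdf(path, engine="scipy")


def read_raster_stack(path, name: str | None = None):
    """Returns (grid, values, name); NaN marks masked cells."""
    ds = xr.open_dataset(path, engine="scipy")
    if name is None:
        name = list(ds.data_vars)[0]
    grid = GridSpec(float(ds.attrs["lon_min"]), float(ds.attrs["lat_min"]),
                    int(ds.attrs["n_cols"]), int(ds.attrs["n_rows"]),
                    float(ds.attrs["cell_size"]))
    values = ds[name].values.astype(float)
    ds.close()
    return grid, values, name


def write_maps(path, grid: GridSpec, maps: list[RasterField]) -> None:
    """Hourly prediction maps as one NetCDF stack (NaN = masked)."""
    vals = np.stack([np.where(m.mask, m.values, np.nan) for m in maps])
    ds = stack_to_dataset(grid, vals, "pm25", time_dim="hour")
    ds = ds.assign_coords(hour=[m.hour if m.hour is not None else i
                                for i, m in enumerate(maps)])
    ds.to_netcdf(path, engine="scipy")


def read_maps(path) -> tuple[GridSpec, np.ndarray, np.ndarray]:
    grid, vals, _ = read_raster_stack(path, "pm25")
    return grid, vals, np.arange(vals.shape[0])


# ---------------------------------------------------------------------------
# GeoJSON lines (plain JSON — shapely geometries are simple LineStrings)

def _feature(coords: np.ndarray, props: dict) -> dict:
    return {"type": "Feature", "properties": props,
            "geometry": {"type": "LineString",
                         "coordinates": np.asarray(coords, float).tolist()}}


def write_lines_geojson(path, lines: list[np.ndarray], props: list[dict]) -> None:
    doc = {"type": "FeatureCollection",
           "features": [_feature(c, p) for c, p in zip(lines, props)]}
    with open(path, "w") as f:
        json.dump(doc, f)


def read_lines_geojson(path) -> tuple[list[np.ndarray], list[dict]]:
    with open(path) as f:
        doc = json.load(f)
    lines, props = [], []
    for feat in doc["features"]:
        lines.append(np.asarray(feat["geometry"]["coordinates"], float))
        props.append(feat["properties"])
    return lines, props


# ---------------------------------------------------------------------------
# scenario round trip

def write_scenario(sc: SyntheticScenario, outdir,
                   hours: list[int] | None = None,
                   include_truth: bool = True) -> Path:
    """Write a scenario to disk in the pipeline's input contracts."""
    out = Path(outdir)
    (out / "rasters").mkdir(parents=True, exist_ok=True)
    (out / "traffic").mkdir(exist_ok=True)
    cfg = sc.config
    hours = list(range(sc.n_hours)) if hours is None else list(hours)

    sc.stations.to_csv(out / "stations.csv", index=False,
                       float_format=_FLOAT_FMT)
    obs = sc.station_obs.copy()
    obs["timestamp_iso"] = [hour_to_timestamp(cfg.start_time, h)
                            for h in obs["hour"]]
    obs[["station_id", "timestamp_iso", "pm25"]].to_csv(
        out / "observations.csv", index=False, float_format=_FLOAT_FMT)

    rows = []
    step = 60 // sc.checkin_counts.shape[1]
    lon = sc.checkin_anchors["lon"].to_numpy()
    lat = sc.checkin_anchors["lat"].to_numpy()
    for h in hours:
        for s in range(sc.checkin_counts.shape[1]):
            cnt = sc.checkin_counts[h, s]
            nz = np.flatnonzero(cnt)
            ts = hour_to_timestamp(cfg.start_time, h, s * step)
            for i in nz:
                rows.append((lon[i], lat[i], ts, int(cnt[i])))
    pd.DataFrame(rows, columns=["lon", "lat", "timestamp_iso", "count"]).to_csv(
        out / "checkins.csv", index=False, float_format=_FLOAT_FMT)

    write_lines_geojson(out / "roads.geojson",
                        [c for c, _ in sc.road_lines],
                        [{"level": lv} for _, lv in sc.road_lines])
    for h in hours:
        write_lines_geojson(out / "traffic" / f"hour_{h:04d}.geojson",
                            sc.traffic_lines,
                            [{"index": int(ix)} for ix in sc.traffic_index[h]])
    sc.pois.to_csv(out / "pois.csv", index=False, float_format=_FLOAT_FMT)

    for name in ("RH", "TEM", "EWS", "NWS", "SP", "PBLH", "AOT"):
        write_raster_stack(out / "rasters" / f"{name}.nc", sc.grid,
                           sc.covariates[name], name)
    write_raster_stack(out / "rasters" / "NDVI.nc", sc.grid,
                       np.stack(sc.covariates["NDVI"]), "NDVI",
                       time_dim="scene")
    write_raster_stack(out / "rasters" / "DEM.nc", sc.grid,
                       sc.covariates["DEM"], "DEM")
    if include_truth:
        write_raster_stack(out / "rasters" / "TRUE_PM.nc", sc.grid,
                           sc.true_pm, "TRUE_PM")
    with open(out / "scenario_config.json", "w") as f:
        json.dump(config_to_dict(cfg), f, indent=1, sort_keys=True)
    return out


def read_scenario(indir) -> SyntheticScenario:
    """Reconstruct a scenario from the on-disk contracts."""
    src = Path(indir)
    with open(src / "scenario_config.json") as f:
        cfg = config_from_dict(json.load(f))
    grid = cfg.grid()

    stations = pd.read_csv(src / "stations.csv")
    obs = pd.read_csv(src / "observations.csv")
    obs["hour"] = [timestamp_to_hour(cfg.start_time, t)[0]
                   for t in obs["timestamp_iso"]]
    station_obs = obs[["station_id", "hour", "pm25"]]

    ci = pd.read_csv(src / "checkins.csv")
    anchors = (ci[["lon", "lat"]].drop_duplicates().sort_values(["lon", "lat"])
               .reset_index(drop=True))
    key = {(r.lon, r.lat): i for i, r in anchors.iterrows()}
    n_snap = cfg.snapshots_per_hour
    counts = np.zeros((cfg.n_hours, n_snap, len(anchors)), int)
    step = 60 // n_snap
    for lon, lat, ts, cnt in ci.itertuples(index=False):
        h, minute = timestamp_to_hour(cfg.start_time, ts)
        counts[h, minute // step, key[(lon, lat)]] = cnt

    roads_geo, roads_props = read_lines_geojson(src / "roads.geojson")
    road_lines = [(c, p["level"]) for c, p in zip(roads_geo, roads_props)]
    traffic_files = sorted((src / "traffic").glob("hour_*.geojson"))
    traffic_lines, tindex = [], []
    for f in traffic_files:
        lines, props = read_lines_geojson(f)
        if not traffic_lines:
            traffic_lines = lines
        tindex.append([p["index"] for p in props])
    traffic_index = np.asarray(tindex, int)
    pois = pd.read_csv(src / "pois.csv")

    covariates = {}
    for name in ("RH", "TEM", "EWS", "NWS", "SP", "PBLH", "AOT"):
        _, vals, _ = read_raster_stack(src / "rasters" / f"{name}.nc", name)
        covariates[name] = vals
    _, ndvi, _ = read_raster_stack(src / "rasters" / "NDVI.nc", "NDVI")
    covariates["NDVI"] = [ndvi[i] for i in range(ndvi.shape[0])]
    _, dem, _ = read_raster_stack(src / "rasters" / "DEM.nc", "DEM")
    covariates["DEM"] = dem
    aot_mask = np.isfinite(covariates["AOT"])
    covariates["AOT_MASK"] = aot_mask
    true_path = src / "rasters" / "TRUE_PM.nc"
    true_pm = (read_raster_stack(true_path, "TRUE_PM")[1]
               if true_path.exists() else None)

    return SyntheticScenario(
        grid=grid, n_hours=cfg.n_hours, true_pm=true_pm, stations=stations,
        station_obs=station_obs, checkin_anchors=anchors,
        checkin_counts=counts, traffic_lines=traffic_lines,
        traffic_index=traffic_index, road_lines=road_lines, pois=pois,
        covariates=covariates, aot_mask=aot_mask, config=cfg)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False, float_format="%.12g")


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path)
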