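"""Bespoke feature extraction for the gridded PM2.5 model.

Implements the geospatial features the model consumes:

* ``PM_S`` / ``PM_T`` — spatial and temporal autocorrelation features of
  PM2.5, built by inverse-distance weighting (IDW) over neighbouring station
  observations at the current hour and at the three preceding hours;
* ``RTCI`` — hourly averaged real-time check-in density (population-activity
  proxy), rasterized per snapshot and gap-filled by IDW;
* ``TID`` — traffic-index density: kernel density of road line features
  weighted by a 6-level congestion index (quartic kernel);
* ``ROAD`` — road-network density, km of road per km² per cell;
* ``PS`` / ``SCEN`` — counts of pollution-source and clean-scenery points of
  interest within a buffer of each cell center.

All functions here are deterministic; distances are computed on a local
equirectangular plane (km per degree fixed at the grid-center latitude),
which is adequate at city scale.  Configuration lengths expressed in degrees
are converted to km with the latitude scale (1° ≈ 110.574 km).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box

from .grid import GridSpec, RasterField


@dataclass
class IDWConfig:
    """Inverse-distance weighting parameters.

    The weight of source k at distance d_k is 1 / max(d_k, epsilon)^power;
    a target within ``epsilon`` of a source takes that source's value exactly.
    ``max_neighbors``/``search_radius`` restrict the admitted sources
    (defaults: use all — station networks here are small).
    """

    power: float = 2.0
    max_neighbors: int | None = None
    search_radius: float | None = None  # degrees
    epsilon: float = 1e-6  # degrees

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("power must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class KDAConfig:
    """Kernel density analysis parameters for line features.

    The quartic kernel K(d) = 3/(π h²) (1 − (d/h)²)² for d < h integrates to
    one, so total density mass equals total (length × index) mass.
    ``segment_step`` is the line discretization step (default one quarter of
    the bandwidth).
    """

    bandwidth: float = 0.01  # degrees
    kernel: str = "quartic"
    segment_step: float | None = None  # degrees

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.kernel != "quartic":
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.segment_step is None:
            self.segment_step = self.bandwidth / 4.0
        if self.segment_step > self.bandwidth:
            raise ValueError("segment_step must not exceed bandwidth")


# ---------------------------------------------------------------------------
# plane projection helpers

def _plane(lon, lat, grid: GridSpec):
    kx, ky = grid.km_per_degree()
    return np.asarray(lon, float) * kx, np.asarray(lat, float) * ky


def _deg_to_km(deg: float | None) -> float | None:
    return None if deg is None else deg * 110.574


# ---------------------------------------------------------------------------
# IDW core

def idw_values(src_xy: np.ndarray, src_vals: np.ndarray, tgt_xy: np.ndarray,
               cfg: IDWConfig) -> tuple[np.ndarray, np.ndarray]:
    """IDW estimate at target points from source points (km-plane coords).

    Returns (values, valid) — a target with no admissible source is invalid.
    """
    src_xy = np.asarray(src_xy, float).reshape(-1, 2)
    src_vals = np.asarray(src_vals, float).ravel()
    tgt_xy = np.asarray(tgt_xy, float).reshape(-1, 2)
    if len(src_xy) == 0:
        raise ValueError("IDW requires at least one source point")
    eps_km = _deg_to_km(cfg.epsilon)
    d = np.sqrt(((tgt_xy[:, None, :] - src_xy[None, :, :]) ** 2).sum(-1))
    admit = np.ones_like(d, bool)
    if cfg.search_radius is not None:
        admit &= d <= _deg_to_km(cfg.search_radius)
    if cfg.max_neighbors is not None and cfg.max_neighbors < d.shape[1]:
        k = cfg.max_neighbors
        kth = np.partition(d, k - 1, axis=1)[:, k - 1 : k]
        admit &= d <= kth
    w = np.where(admit, 1.0 / np.maximum(d, eps_km) ** cfg.power, 0.0)
    wsum = w.sum(axis=1)
    valid = wsum > 0
    out = np.zeros(len(tgt_xy))
    out[valid] = (w[valid] @ src_vals) / wsum[valid]
    # exact hit: nearest source within epsilon wins
    hit = (d <= eps_km) & admit
    any_hit = hit.any(axis=1)
    if any_hit.any():
        nearest = np.argmin(np.where(hit, d, np.inf), axis=1)
        out[any_hit] = src_vals[nearest[any_hit]]
    return out, valid


def idw_interpolate(points: pd.DataFrame, grid: GridSpec,
                    cfg: IDWConfig | None = None,
                    name: str = "", hour: int | None = None) -> RasterField:
    """IDW surface of point values (columns lon, lat, value) on the grid."""
    cfg = cfg or IDWConfig()
    pts = points.dropna(subset=["value"])
    if len(pts) == 0:
        raise ValueError("IDW requires at least one point with a finite value")
    sx, sy = _plane(pts["lon"].to_numpy(), pts["lat"].to_numpy(), grid)
    lon, lat = grid.center_mesh()
    tx, ty = _plane(lon.ravel(), lat.ravel(), grid)
    vals, valid = idw_values(np.column_stack([sx, sy]),
                             pts["value"].to_numpy(float),
                             np.column_stack([tx, ty]), cfg)
    shape = (grid.n_rows, grid.n_cols)
    return RasterField(grid, vals.reshape(shape), name=name, hour=hour,
                       mask=valid.reshape(shape))


# ---------------------------------------------------------------------------
# spatiotemporal PM features

def pm_spatial_feature(obs: pd.DataFrame, grid: GridSpec,
                       cfg: IDWConfig | None = None,
                       exclude_station=None, hour: int | None = None) -> RasterField:
    """Spatial PM feature: IDW surface of the current hour's observations.

    ``obs`` columns: station_id, lon, lat, pm25.  With ``exclude_station``
    set (training-sample construction) that station is removed before
    interpolating, so a labeled cell never sees its own observation.
    """
    if exclude_station is not None:
        obs = obs[obs["station_id"] != exclude_station]
    if len(obs.dropna(subset=["pm25"])) == 0:
        raise ValueError("no station observations left to interpolate")
    pts = obs.rename(columns={"pm25": "value"})[["lon", "lat", "value"]]
    return idw_interpolate(pts, grid, cfg, name="PM_S", hour=hour)


def pm_spatial_loo_at_stations(stations: pd.DataFrame, obs_wide: np.ndarray,
                               grid: GridSpec,
                               cfg: IDWConfig | None = None) -> np.ndarray:
    """Leave-one-station-out spatial PM feature at every station, all hours.

    ``obs_wide`` is (n_hours, n_stations) with NaN for missing observations;
    returns the same shape: IDW over the *other* stations' values at that
    hour.  Vectorized across hours (the station geometry is fixed).
    """
    cfg = cfg or IDWConfig()
    sx, sy = _plane(stations["lon"].to_numpy(), stations["lat"].to_numpy(), grid)
    d = np.sqrt((sx[:, None] - sx[None, :]) ** 2 + (sy[:, None] - sy[None, :]) ** 2)
    eps_km = _deg_to_km(cfg.epsilon)
    w = 1.0 / np.maximum(d, eps_km) ** cfg.power
    np.fill_diagonal(w, 0.0)
    if cfg.search_radius is not None:
        w[d > _deg_to_km(cfg.search_radius)] = 0.0
    v = np.nan_to_num(obs_wide, nan=0.0)
    m = np.isfinite(obs_wide).astype(float)
    num = v @ w.T
    den = m @ w.T
    out = np.full(obs_wide.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def pm_temporal_feature(obs_history: dict[int, pd.DataFrame], grid: GridSpec,
                        cfg: IDWConfig | None = None,
                        lag_weights: dict[int, float] | None = None,
                        hour: int | None = None) -> RasterField:
    """Temporal PM feature: lag-weighted mean of IDW surfaces of past hours.

    ``obs_history`` maps lag (1, 2, 3 hours before now) to that hour's
    observation table.  The default lag weight is 1/lag; lags with no data
    are dropped and the remaining weights renormalized.
    """
    cfg = cfg or IDWConfig()
    if lag_weights is None:
        lag_weights = {lag: 1.0 / lag for lag in obs_history}
    num = np.zeros((grid.n_rows, grid.n_cols))
    den = np.zeros_like(num)
    any_lag = False
    for lag, obs in obs_history.items():
        obs = obs.dropna(subset=["pm25"])
        if len(obs) == 0:
            continue
        surf = pm_spatial_feature(obs, grid, cfg)
        lam = lag_weights[lag]
        num += np.where(surf.mask, lam * surf.values, 0.0)
        den += lam * surf.mask
        any_lag = True
    if not any_lag:
        warnings.warn("no lag has observations; temporal PM feature all-masked")
        return RasterField(grid, num, name="PM_T", hour=hour,
                           mask=np.zeros_like(num, bool))
    mask = den > 0
    vals = np.where(mask, num / np.where(mask, den, 1.0), 0.0)
    return RasterField(grid, vals, name="PM_T", hour=hour, mask=mask)


def pm_temporal_at_stations(stations: pd.DataFrame, obs_wide: np.ndarray,
                            grid: GridSpec, cfg: IDWConfig | None = None,
                            lags: tuple[int, ...] = (1, 2, 3)) -> np.ndarray:
    """Temporal PM feature evaluated at station cells for all hours at once.

    For each hour t and station s: lag-weighted (1/lag) combination of IDW
    estimates at s from all stations' observations at t−lag (a station's own
    past observation is an exact IDW hit and therefore dominates its lag
    surface, consistently with the grid version).
    """
    cfg = cfg or IDWConfig()
    n_hours, n_st = obs_wide.shape
    sx, sy = _plane(stations["lon"].to_numpy(), stations["lat"].to_numpy(), grid)
    d = np.sqrt((sx[:, None] - sx[None, :]) ** 2 + (sy[:, None] - sy[None, :]) ** 2)
    eps_km = _deg_to_km(cfg.epsilon)
    w = 1.0 / np.maximum(d, eps_km) ** cfg.power
    v = np.nan_to_num(obs_wide, nan=0.0)
    m = np.isfinite(obs_wide).astype(float)
    idw_h = np.full(obs_wide.shape, np.nan)  # per-hour IDW at each station
    num = v @ w.T
    den = m @ w.T
    ok = den > 0
    idw_h[ok] = num[ok] / den[ok]
    out_num = np.zeros(obs_wide.shape)
    out_den = np.zeros(obs_wide.shape)
    for lag in lags:
        lam = 1.0 / lag
        shifted = np.full(obs_wide.shape, np.nan)
        if n_hours > lag:
            shifted[lag:] = idw_h[:-lag]
        good = np.isfinite(shifted)
        out_num += np.where(good, lam * shifted, 0.0)
        out_den += lam * good
    out = np.full(obs_wide.shape, np.nan)
    ok = out_den > 0
    out[ok] = out_num[ok] / out_den[ok]
    return out


# ---------------------------------------------------------------------------
# check-in rasterization

def checkin_feature(snapshots: list[pd.DataFrame], grid: GridSpec,
                    cfg: IDWConfig | None = None,
                    hour: int | None = None) -> RasterField:
    """Hourly averaged check-in density, gap-filled by IDW.

    ``snapshots`` are the sub-hourly point tables (lon, lat, count) falling
    in the hour window (up to 12 at a 5-minute cadence).  Counts are summed
    per cell per snapshot and averaged across snapshots; cells receiving no
    point in any snapshot are filled by IDW over the non-empty cell centers.
    """
    cfg = cfg or IDWConfig()
    if len(snapshots) == 0:
        warnings.warn("no check-in snapshots in hour; all-masked field")
        z = np.zeros((grid.n_rows, grid.n_cols))
        return RasterField(grid, z, name="RTCI", hour=hour,
                           mask=np.zeros_like(z, bool))
    total = np.zeros((grid.n_rows, grid.n_cols))
    touched = np.zeros_like(total, bool)
    for snap in snapshots:
        if len(snap) == 0:
            continue
        row, col = grid.cell_of(snap["lon"].to_numpy(), snap["lat"].to_numpy())
        inside = row >= 0
        np.add.at(total, (row[inside], col[inside]),
                  snap["count"].to_numpy(float)[inside])
        touched[row[inside], col[inside]] = True
    mean = total / len(snapshots)
    if not touched.any():
        warnings.warn("check-in snapshots contain no in-domain points")
        return RasterField(grid, mean, name="RTCI", hour=hour,
                           mask=np.zeros_like(mean, bool))
    if not touched.all():
        lon, lat = grid.center_mesh()
        pts = pd.DataFrame({"lon": lon[touched], "lat": lat[touched],
                            "value": mean[touched]})
        fill = idw_interpolate(pts, grid, cfg)
        mean = np.where(touched, mean, fill.values)
    return RasterField(grid, np.maximum(mean, 0.0), name="RTCI", hour=hour)


# ---------------------------------------------------------------------------
# kernel density of weighted lines (traffic index density)

def _discretize_lines(lines: list[np.ndarray], grid: GridSpec, step_km: float):
    """Split polylines into sub-segments of length <= step_km.

    Returns (midpoints (N,2) km, lengths (N,), line_index (N,)).
    """
    mids, lens, idx = [], [], []
    for li, coords in enumerate(lines):
        coords = np.asarray(coords, float)
        x, y = _plane(coords[:, 0], coords[:, 1], grid)
        for i in range(len(coords) - 1):
            p0 = np.array([x[i], y[i]])
            p1 = np.array([x[i + 1], y[i + 1]])
            seg = np.linalg.norm(p1 - p0)
            if seg == 0:
                continue
            n_sub = max(1, int(np.ceil(seg / step_km)))
            t = (np.arange(n_sub) + 0.5) / n_sub
            mids.append(p0 + t[:, None] * (p1 - p0))
            lens.append(np.full(n_sub, seg / n_sub))
            idx.append(np.full(n_sub, li, int))
    if not mids:
        return (np.zeros((0, 2)), np.zeros(0), np.zeros(0, int))
    return np.vstack(mids), np.concatenate(lens), np.concatenate(idx)


def line_density_basis(lines: list[np.ndarray], grid: GridSpec,
                       cfg: KDAConfig | None = None) -> np.ndarray:
    """Per-line unit-weight kernel density fields, shape (n_lines, rows, cols).

    The traffic geometry is static while the congestion index varies by hour,
    so the hourly density is an index-weighted sum of these basis fields —
    computed once, reused for every hour.
    """
    cfg = cfg or KDAConfig()
    h_km = _deg_to_km(cfg.bandwidth)
    step_km = _deg_to_km(cfg.segment_step)
    out = np.zeros((len(lines), grid.n_rows, grid.n_cols))
    if not lines:
        return out
    mids, lens, idx = _discretize_lines(lines, grid, step_km)
    if len(mids) == 0:
        return out
    lon, lat = grid.center_mesh()
    cx, cy = _plane(lon.ravel(), lat.ravel(), grid)
    centers = np.column_stack([cx, cy])
    # chunk over sub-segments to bound memory
    chunk = max(1, int(2e7 / max(len(centers), 1)))
    flat = out.reshape(len(lines), -1)
    for s in range(0, len(mids), chunk):
        e = min(s + chunk, len(mids))
        d = np.sqrt(((mids[s:e, None, :] - centers[None, :, :]) ** 2).sum(-1))
        k = np.where(d < h_km, (3.0 / np.pi) * (1 - (d / h_km) ** 2) ** 2 / h_km**2,
                     0.0)
        contrib = lens[s:e, None] * k
        np.add.at(flat, idx[s:e], contrib)
    return out


def traffic_kernel_density(lines: list[tuple[np.ndarray, float]], grid: GridSpec,
                           cfg: KDAConfig | None = None,
                           hour: int | None = None) -> RasterField:
    """Traffic-index density (TID): kernel density of index-weighted lines.

    ``lines`` is a list of (polyline lon/lat coords, traffic index at this
    hour).  Each line contributes (length × index) of mass spread by the
    quartic kernel; the field is evaluated at cell centers, in index·km/km².
    An empty line set yields a valid all-zero field.
    """
    geoms = [c for c, _ in lines]
    weights = np.array([w for _, w in lines], float)
    basis = line_density_basis(geoms, grid, cfg)
    vals = np.tensordot(weights, basis, axes=(0, 0)) if len(lines) else (
        np.zeros((grid.n_rows, grid.n_cols)))
    return RasterField(grid, vals, name="TID", hour=hour)


# ---------------------------------------------------------------------------
# road network density

ROAD_LEVELS = ("highway", "main", "secondary", "branch")


def road_density(roads: list[tuple[np.ndarray, str]], grid: GridSpec,
                 levels: tuple[str, ...] | None = None) -> RasterField:
    """Road density (ROAD): clipped in-cell road length / cell area, km/km².

    ``roads`` is a list of (polyline lon/lat coords, level); ``levels``
    selects which of the four road levels contribute (default all).  Static
    over the study period.
    """
    levels = tuple(levels) if levels is not None else ROAD_LEVELS
    kx, ky = grid.km_per_degree()
    area = grid.cell_area_km2()
    length = np.zeros((grid.n_rows, grid.n_cols))
    s = grid.cell_size
    for coords, level in roads:
        if level not in levels:
            continue
        coords = np.asarray(coords, float)
        x, y = _plane(coords[:, 0], coords[:, 1], grid)
        line = LineString(np.column_stack([x, y]))
        # candidate cells from the line's bounding box
        lo_r, lo_c = grid.cell_of(coords[:, 0].min(), coords[:, 1].min())
        hi_r, hi_c = grid.cell_of(coords[:, 0].max(), coords[:, 1].max())
        lo_r = int(lo_r) if lo_r >= 0 else 0
        lo_c = int(lo_c) if lo_c >= 0 else 0
        hi_r = int(hi_r) if hi_r >= 0 else grid.n_rows - 1
        hi_c = int(hi_c) if hi_c >= 0 else grid.n_cols - 1
        for r in range(lo_r, hi_r + 1):
            for c in range(lo_c, hi_c + 1):
                cell = box((grid.lon_min + c * s) * kx,
                           (grid.lat_min + r * s) * ky,
                           (grid.lon_min + (c + 1) * s) * kx,
                           (grid.lat_min + (r + 1) * s) * ky)
                inter = line.intersection(cell)
                if not inter.is_empty:
                    length[r, c] += inter.length
    return RasterField(grid, length / area, name="ROAD")


# ---------------------------------------------------------------------------
# POI buffer counts

POI_CLASSES = ("PS", "Scen", "other")


def poi_buffer_counts(pois: pd.DataFrame, grid: GridSpec, radius_km: float = 1.1,
                      classes: tuple[str, ...] = ("PS", "Scen")) -> dict[str, RasterField]:
    """Counts of POIs of each class within ``radius_km`` of each cell center.

    ``pois`` columns: lon, lat, poi_class with values among PS (potential
    pollution source), Scen (clean scenery) and other.  Returns one integer
    field per requested class, keyed by the canonical feature name.
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    unknown = set(pois["poi_class"]) - set(POI_CLASSES)
    if unknown:
        raise ValueError(f"unknown POI class label(s): {sorted(unknown)}")
    lon, lat = grid.center_mesh()
    cx, cy = _plane(lon.ravel(), lat.ravel(), grid)
    out = {}
    for cls in classes:
        sub = pois[pois["poi_class"] == cls]
        counts = np.zeros(grid.n_cells)
        if len(sub):
            px, py = _plane(sub["lon"].to_numpy(), sub["lat"].to_numpy(), grid)
            d2 = (cx[:, None] - px[None, :]) ** 2 + (cy[:, None] - py[None, :]) ** 2
            counts = (d2 <= radius_km**2).sum(axis=1).astype(float)
        name = "SCEN" if cls == "Scen" else cls.upper()
        out[name] = RasterField(grid, counts.reshape(grid.n_rows, grid.n_cols),
                                name=name)
    return out
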