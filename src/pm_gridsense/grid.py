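"""Common lon/lat lattice and the grid-matching step that turns heterogeneous
sources into model samples.

All data sources — station observations, social-sensing features, satellite and
meteorological rasters — are matched onto one regular geographic grid (default
cell size 0.01 degree) at an hourly cadence.  Each grid cell at each hour then
carries one multivariate feature vector; cells containing a monitoring station
additionally carry a PM2.5 label.

Conventions (fixed across the package):

* coordinates are WGS84 longitude/latitude in decimal degrees;
* cells are half-open boxes ``[edge, edge + s)`` in both axes, so every point
  strictly inside the domain belongs to exactly one cell;
* row 0 is the southernmost row; cell centers sit at ``edge + s/2``;
* timestamps are hour indices from the study start, interpreted in local time
  (UTC+8 in the examples shipped with the package).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical feature names; "Time" expands to HOUR + DAY (see time encoding note)
FEATURE_NAMES = (
    "HOUR", "DAY", "PM_S", "PM_T", "RTCI", "TID", "ROAD", "PS", "SCEN",
    "AOT", "NDVI", "DEM", "RH", "TEM", "EWS", "NWS", "SP", "PBLH",
)

#: named variable groups used by variable-combination configs
VARIABLE_GROUPS = {
    "Time": ["HOUR", "DAY"],
    "Wea": ["RH", "TEM", "EWS", "NWS", "SP", "PBLH"],
    "PM_st": ["PM_S", "PM_T"],
    "Dynamic": ["RTCI", "TID"],
    "POIs": ["PS", "SCEN"],
}

#: variable combinations mirroring the study's experimental design
VARIABLE_COMBOS = {
    "optimal_A": ["Time", "NDVI", "PM_S", "PM_T", "RTCI", "TID", "Wea"],
    "optimal_B": ["AOT", "Time", "NDVI", "PM_S", "PM_T", "RTCI", "TID", "Wea"],
    "A_without_dynamic": ["Time", "NDVI", "PM_S", "PM_T", "Wea"],
    "A_without_pm": ["Time", "NDVI", "RTCI", "TID", "Wea"],
    "A_without_wea": ["Time", "NDVI", "PM_S", "PM_T", "RTCI", "TID"],
    "A_without_ndvi": ["Time", "PM_S", "PM_T", "RTCI", "TID", "Wea"],
    "A_without_time": ["NDVI", "PM_S", "PM_T", "RTCI", "TID", "Wea"],
    "A_plus_road": ["Time", "NDVI", "PM_S", "PM_T", "RTCI", "TID", "Wea", "ROAD"],
    "A_plus_pois": ["Time", "NDVI", "PM_S", "PM_T", "RTCI", "TID", "Wea", "POIs"],
}


def expand_combo(combo: str | list[str]) -> list[str]:
    """Resolve a combo name or mixed list of group/feature names to feature names."""
    if isinstance(combo, str):
        if combo not in VARIABLE_COMBOS:
            raise ValueError(f"unknown variable combination {combo!r}")
        combo = VARIABLE_COMBOS[combo]
    out: list[str] = []
    for name in combo:
        cols = VARIABLE_GROUPS.get(name, [name])
        for c in cols:
            if c not in FEATURE_NAMES:
                raise ValueError(f"unknown feature {c!r}")
            if c not in out:
                out.append(c)
    return out


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat lattice of square (in degrees) half-open cells."""

    lon_min: float
    lat_min: float
    n_cols: int
    n_rows: int
    cell_size: float = 0.01

    def __post_init__(self) -> None:
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_rows * self.cell_size

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols) of cell centers."""
        lon, lat = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon, lat

    def cell_of(self, lon, lat):
        """Map lon/lat arrays to (row, col); half-open rule, so a point on a
        shared edge belongs to the higher-index cell.  Points outside the
        domain get index -1."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cell_size).astype(int)
        row = np.floor((lat - self.lat_min) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def contains(self, lon, lat):
        row, _ = self.cell_of(lon, lat)
        return np.asarray(row) >= 0

    # local metric scale, used by distance-based feature extraction
    def km_per_degree(self) -> tuple[float, float]:
        """(km/deg lon, km/deg lat) at the domain-center latitude
        (equirectangular approximation, adequate at city scale)."""
        lat0 = math.radians(self.lat_min + 0.5 * self.n_rows * self.cell_size)
        return 111.320 * math.cos(lat0), 110.574

    def cell_area_km2(self) -> float:
        kx, ky = self.km_per_degree()
        return (self.cell_size * kx) * (self.cell_size * ky)


@dataclass
class RasterField:
    """One variable on a GridSpec, optionally tied to an hour index.

    ``values`` has shape (n_rows, n_cols); ``mask`` is True where the value is
    valid.  Values must be finite wherever the mask is valid.
    """

    grid: GridSpec
    values: np.ndarray
    name: str = ""
    hour: int | None = None  # None == static variable
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_rows}, {self.grid.n_cols})"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError(f"non-finite values under valid mask in {self.name!r}")

    def sample(self, lon, lat):
        """Values at point locations (cell lookup); NaN outside/masked."""
        row, col = self.grid.cell_of(lon, lat)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        out = np.full(row.shape, np.nan)
        ok = row >= 0
        rr, cc = row[ok], col[ok]
        vals = self.values[rr, cc]
        vals[~self.mask[rr, cc]] = np.nan
        out[ok] = vals
        return out


def make_grid(lon_min: float, lat_min: float, lon_max: float, lat_max: float,
              cell_size: float = 0.01) -> GridSpec:
    """Smallest grid of cells of exactly ``cell_size`` covering the box."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ValueError("degenerate or inverted bounds")
    # tolerate float representation error when the box is an exact multiple
    eps = 1e-9
    n_cols = math.ceil((lon_max - lon_min) / cell_size - eps)
    n_rows = math.ceil((lat_max - lat_min) / cell_size - eps)
    return GridSpec(lon_min, lat_min, n_cols, n_rows, cell_size)


def resample_raster(src: RasterField, dst: GridSpec,
                    method: str = "nearest") -> RasterField:
    """Resample a raster on its own grid onto ``dst`` (same geographic datum).

    The destination value is the source field evaluated at the destination
    cell center, by nearest-neighbour lookup or bilinear interpolation between
    source cell centers.  Masks propagate: a destination cell whose every
    contributing source cell is masked comes out masked; bilinear averages
    over the valid neighbours only.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown method {method!r}")
    sg = src.grid
    lon, lat = dst.center_mesh()
    # fractional index of dst centers in src cell-center coordinates
    fx = (lon - (sg.lon_min + 0.5 * sg.cell_size)) / sg.cell_size
    fy = (lat - (sg.lat_min + 0.5 * sg.cell_size)) / sg.cell_size
    inside = ((lon >= sg.lon_min) & (lon < sg.lon_max)
              & (lat >= sg.lat_min) & (lat < sg.lat_max))
    if not inside.any():
        warnings.warn("source and destination extents are disjoint; "
                      "returning an all-masked field")
        return RasterField(dst, np.zeros((dst.n_rows, dst.n_cols)),
                           name=src.name, hour=src.hour,
                           mask=np.zeros((dst.n_rows, dst.n_cols), bool))

    if method == "nearest":
        col = np.clip(np.round(fx).astype(int), 0, sg.n_cols - 1)
        row = np.clip(np.round(fy).astype(int), 0, sg.n_rows - 1)
        vals = src.values[row, col]
        mask = src.mask[row, col] & inside
    else:
        c0 = np.clip(np.floor(fx).astype(int), 0, sg.n_cols - 1)
        r0 = np.clip(np.floor(fy).astype(int), 0, sg.n_rows - 1)
        c1 = np.minimum(c0 + 1, sg.n_cols - 1)
        r1 = np.minimum(r0 + 1, sg.n_rows - 1)
        wx = np.clip(fx - c0, 0.0, 1.0)
        wy = np.clip(fy - r0, 0.0, 1.0)
        corners = [(r0, c0, (1 - wx) * (1 - wy)), (r0, c1, wx * (1 - wy)),
                   (r1, c0, (1 - wx) * wy), (r1, c1, wx * wy)]
        num = np.zeros_like(fx)
        den = np.zeros_like(fx)
        for r, c, w in corners:
            m = src.mask[r, c]
            v = np.where(m, src.values[r, c], 0.0)
            num += w * v * m
            den += w * m
        mask = (den > 0) & inside
        vals = np.where(mask, num / np.where(den > 0, den, 1.0), 0.0)

    vals = np.where(mask, vals, 0.0)
    return RasterField(dst, vals, name=src.name, hour=src.hour, mask=mask)


def select_temporal_slice(stack, hour: int, period_hours: int | None = None):
    """Pick the scene of a periodic raster series that covers ``hour``.

    ``stack`` is either a single static RasterField (returned unchanged for
    any hour — the DEM case) or a list of RasterFields covering consecutive
    half-open periods of ``period_hours`` each, starting at hour 0 (the
    16-day vegetation-index case, period_hours = 16 * 24).  An hour exactly
    on a boundary belongs to the later period.
    """
    if isinstance(stack, RasterField):
        return stack
    if period_hours is None or period_hours <= 0:
        raise ValueError("period_hours required for a scene series")
    if hour < 0:
        raise ValueError("hour before study start")
    idx = hour // period_hours
    if idx >= len(stack):
        raise ValueError(f"hour {hour} outside all {len(stack)} periods")
    return stack[idx]


def assemble_samples(grid: GridSpec,
                     hours: list[int],
                     feature_values: dict,
                     variable_combo,
                     stations: pd.DataFrame | None = None,
                     station_obs: pd.DataFrame | None = None,
                     labeled_overrides: pd.DataFrame | None = None,
                     include_unlabeled: bool = False,
                     day_length: int = 24) -> pd.DataFrame:
    """Match per-hour feature rasters and station observations into samples.

    Parameters
    ----------
    feature_values
        Mapping feature name -> either a static RasterField or a mapping
        hour -> RasterField.  The time features HOUR (hour of day) and DAY
        (day index from study start) are derived, not looked up.
    variable_combo
        Combo name or list of feature/group names; a record is kept only if
        every requested feature is valid at its cell-hour.
    stations, station_obs
        Station table (station_id, lon, lat) and observations
        (station_id, hour, pm25).  Stations outside the grid are skipped with
        a logged warning.
    labeled_overrides
        Optional long table (station_id, hour, feature, value) replacing raster
        values for labeled records — used for the leave-one-station-out spatial
        PM feature so a training sample never sees its own label.
    include_unlabeled
        Also emit one record per non-station cell-hour with all features valid
        (the prediction grid).

    Returns a DataFrame with one row per record: keys (row, col, hour,
    station_id), the requested feature columns, and ``label`` (NaN when
    unlabeled).
    """
    features = expand_combo(variable_combo)
    raster_feats = [f for f in features if f not in ("HOUR", "DAY")]

    def value_at(f: str, hour: int):
        src = feature_values.get(f)
        if src is None:
            raise ValueError(f"no raster provided for feature {f!r}")
        fld = src if isinstance(src, RasterField) else src[hour]
        vals = np.where(fld.mask, fld.values, np.nan)
        return vals

    frames = []
    st = None
    if stations is not None:
        st = stations.copy()
        row, col = grid.cell_of(st["lon"].to_numpy(), st["lat"].to_numpy())
        outside = row < 0
        for sid in st.loc[outside, "station_id"]:
            logger.warning("station %s outside grid; skipped", sid)
        st["row"], st["col"] = row, col
        st = st[~outside].reset_index(drop=True)

    ov = None
    if labeled_overrides is not None and len(labeled_overrides):
        ov = labeled_overrides.set_index(["station_id", "hour", "feature"])["value"]

    for hour in hours:
        rasters = {f: value_at(f, hour) for f in raster_feats}
        if st is not None and station_obs is not None:
            obs_h = station_obs[station_obs["hour"] == hour]
            merged = st.merge(obs_h[["station_id", "pm25"]], on="station_id",
                              how="inner")
            if len(merged):
                rec = {
                    "row": merged["row"].to_numpy(),
                    "col": merged["col"].to_numpy(),
                    "hour": hour,
                    "station_id": merged["station_id"].to_numpy(),
                    "label": merged["pm25"].to_numpy(float),
                }
                for f in raster_feats:
                    rec[f] = rasters[f][merged["row"], merged["col"]]
                df = pd.DataFrame(rec)
                if ov is not None:
                    for i, sid in enumerate(df["station_id"]):
                        for f in raster_feats:
                            key = (sid, hour, f)
                            if key in ov.index:
                                df.loc[i, f] = ov.loc[key]
                frames.append(df)
        if include_unlabeled:
            rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols),
                                 indexing="ij")
            rec = {"row": rr.ravel(), "col": cc.ravel(), "hour": hour,
                   "station_id": None, "label": np.nan}
            df = pd.DataFrame(rec)
            for f in raster_feats:
                df[f] = rasters[f].ravel()
            if st is not None:
                stcells = set(zip(st["row"], st["col"]))
                keep = [
                    (r, c) not in stcells
                    for r, c in zip(df["row"], df["col"])
                ]
                df = df[keep]
            frames.append(df)

    if not frames:
        cols = ["row", "col", "hour", "station_id", "label"] + features
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    if "HOUR" in features:
        out["HOUR"] = out["hour"] % day_length
    if "DAY" in features:
        out["DAY"] = out["hour"] // day_length
    out = out.dropna(subset=raster_feats).reset_index(drop=True)
    return out[["row", "col", "hour", "station_id", "label"] + features]
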