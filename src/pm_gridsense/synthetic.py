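"""Synthetic urban scenario generator.

Real hourly PM2.5 mapping studies of this kind rely on proprietary feeds
(regulatory station networks, location-service check-ins, commercial traffic
indices, geostationary aerosol retrievals) that cannot be redistributed.  This
module generates a synthetic city with the same *statistical* structure, so the
whole pipeline is testable end to end with known ground truth:

* a spatially and temporally autocorrelated PM2.5 field whose deterministic
  component is a documented nonlinear function of the covariates (saturating
  in traffic density, negative-exponential in boundary-layer height and
  vegetation index, a temperature × humidity interaction);
* ~20 stations observing that field with additive Gaussian noise;
* check-in points with a multi-peak diurnal cycle, traffic lines with a
  6-level congestion index peaking at rush hours, a 4-level road network and
  classed points of interest;
* a cloud-gapped aerosol optical thickness (AOT) raster available in daytime
  hours only (geostationary retrievals have no night product), plus smooth
  meteorological surfaces with diurnal cycles, a 16-day vegetation index
  series and a static elevation model.

All randomness flows from one root seed through named substreams, so the same
seed reproduces every field bit-identically and individual sources can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .features import KDAConfig, line_density_basis
from .grid import GridSpec, make_grid

# substream ids: one independent RNG per data source
_STREAMS = {
    "pm_field": 1, "stations": 2, "obs_noise": 3, "checkins": 4,
    "traffic": 5, "roads": 6, "pois": 7, "aot": 8, "met": 9,
    "ndvi": 10, "dem": 11,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


@dataclass
class LinkSpec:
    """Deterministic covariate → PM2.5 link (μg/m³ terms).

    ``sat_exp_interaction`` (the only tag) adds, on top of the autocorrelated
    residual field:

    * ``traffic_amp · T / (T + traffic_scale)`` — saturating in traffic
      density T (index·km/km²);
    * ``pblh_amp · exp(−PBLH / pblh_scale)`` — shallow boundary layers trap
      pollution;
    * ``ndvi_amp · exp(−NDVI / ndvi_scale)`` — vegetation cleans the air;
    * ``wind_amp · exp(−(EWS² + NWS²) / wind_scale²)`` — stagnant air traps
      pollution; an even function of each wind component, so it carries no
      linear main effect;
    * ``temrh_amp · z(TEM) · z(RH)`` — a temperature–humidity interaction
      with fixed standardization constants.
    """

    nonlinearity: str = "sat_exp_interaction"
    traffic_amp: float = 30.0
    traffic_scale: float = 1.0
    pblh_amp: float = 30.0
    pblh_scale: float = 500.0
    ndvi_amp: float = 12.0
    ndvi_scale: float = 0.3
    wind_amp: float = 30.0
    wind_scale: float = 2.5
    temrh_amp: float = 20.0
    tem_center: float = 288.0
    tem_sd: float = 4.0
    rh_center: float = 60.0
    rh_sd: float = 10.0


@dataclass
class ScenarioConfig:
    """All generator knobs (units in field names or docstrings)."""

    lon_min: float = 114.0
    lat_min: float = 30.3
    lon_max: float = 114.5
    lat_max: float = 30.7
    cell_size: float = 0.01
    n_hours: int = 720
    start_time: str = "2018-01-24T00:00:00+08:00"
    n_stations: int = 20
    obs_noise_sd: float = 3.0  # μg/m³
    mean_level: float = 25.0  # μg/m³, residual-field mean before link terms
    residual_sd: float = 4.0  # μg/m³
    spatial_range: float = 0.05  # degrees (kernel sd of the residual field)
    temporal_rho: float = 0.7
    link: LinkSpec = field(default_factory=LinkSpec)
    n_checkin_anchors: int = 300
    snapshots_per_hour: int = 12  # 5-minute cadence
    checkin_base_rate: float = 3.0  # mean count per anchor per snapshot
    n_traffic_lines: int = 60
    rush_hours: tuple[int, ...] = (8, 18)
    n_roads: int = 150
    n_pois: int = 300
    poi_ps_frac: float = 0.15
    poi_scen_frac: float = 0.15
    poi_buffer_km: float = 1.1
    cloud_fraction: float = 0.6
    aot_day_start: int = 7  # local hours with AOT retrievals
    aot_day_end: int = 18  # half-open
    seed: int = 0

    def validate(self) -> None:
        if self.n_stations < 2 or self.n_hours < 2:
            raise ValueError("need at least 2 stations and 2 hours")
        if not (0.0 <= self.cloud_fraction <= 1.0):
            raise ValueError("cloud_fraction must be in [0, 1]")

    def grid(self) -> GridSpec:
        return make_grid(self.lon_min, self.lat_min, self.lon_max,
                         self.lat_max, self.cell_size)


@dataclass
class SyntheticScenario:
    """A complete generated city with known ground truth."""

    grid: GridSpec
    n_hours: int
    true_pm: np.ndarray  # (hour, row, col) μg/m³
    stations: pd.DataFrame  # station_id, lon, lat
    station_obs: pd.DataFrame  # station_id, hour, pm25
    checkin_anchors: pd.DataFrame  # lon, lat
    checkin_counts: np.ndarray  # (hour, snapshot, anchor) integer counts
    traffic_lines: list[np.ndarray]  # polyline lon/lat coords
    traffic_index: np.ndarray  # (hour, line) in {1..6}
    road_lines: list[tuple[np.ndarray, str]]
    pois: pd.DataFrame  # lon, lat, poi_class
    covariates: dict  # name -> (hour,row,col) stack, static (row,col), or list of scenes
    aot_mask: np.ndarray  # (hour, row, col) True where AOT valid
    config: ScenarioConfig = None  # type: ignore[assignment]

    def checkin_snapshots(self, hour: int) -> list[pd.DataFrame]:
        """Materialize the (lon, lat, count) snapshot tables of one hour,
        dropping zero-count anchors (a point process reports presences)."""
        out = []
        lon = self.checkin_anchors["lon"].to_numpy()
        lat = self.checkin_anchors["lat"].to_numpy()
        for s in range(self.checkin_counts.shape[1]):
            cnt = self.checkin_counts[hour, s]
            nz = cnt > 0
            out.append(pd.DataFrame({"lon": lon[nz], "lat": lat[nz],
                                     "count": cnt[nz].astype(float)}))
        return out

    def traffic_at(self, hour: int) -> list[tuple[np.ndarray, float]]:
        return [(coords, float(self.traffic_index[hour, i]))
                for i, coords in enumerate(self.traffic_lines)]

    def station_cells(self) -> tuple[np.ndarray, np.ndarray]:
        return self.grid.cell_of(self.stations["lon"].to_numpy(),
                                 self.stations["lat"].to_numpy())

    def obs_wide(self) -> np.ndarray:
        """(n_hours, n_stations) observation matrix, NaN where missing."""
        n_st = len(self.stations)
        out = np.full((self.n_hours, n_st), np.nan)
        sid_pos = {sid: i for i, sid in enumerate(self.stations["station_id"])}
        idx = self.station_obs["station_id"].map(sid_pos).to_numpy()
        out[self.station_obs["hour"].to_numpy(), idx] = (
            self.station_obs["pm25"].to_numpy())
        return out


# ---------------------------------------------------------------------------
# random fields

def _smooth_noise(rng, shape, sigma_px: float) -> np.ndarray:
    """Gaussian-kernel-smoothed unit-variance white noise (one field)."""
    z = rng.standard_normal(shape)
    if sigma_px > 1e-6:
        z = gaussian_filter(z, sigma_px, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = z / sd
    return z


def generate_pm_field(grid: GridSpec, n_hours: int, spatial_range: float = 0.05,
                      temporal_rho: float = 0.8, mean_level: float = 35.0,
                      sd: float = 8.0, seed: int = 0,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Spatially and temporally autocorrelated PM2.5 residual field.

    Hour t equals ``temporal_rho`` times hour t−1 plus an innovation; the
    innovations are Gaussian-kernel-smoothed white noise with kernel sd
    ``spatial_range`` degrees, renormalized to unit variance and scaled so
    the stationary marginal sd is ``sd``.  The marginal mean is
    ``mean_level`` and values are floored at zero.
    """
    if spatial_range <= 0 and spatial_range != 0:
        raise ValueError("spatial_range must be non-negative")
    if not (0.0 <= temporal_rho < 1.0):
        raise ValueError("temporal_rho must be in [0, 1)")
    if n_hours < 1:
        raise ValueError("n_hours must be positive")
    rng = rng or _rng(seed, "pm_field")
    sigma_px = spatial_range / grid.cell_size
    shape = (grid.n_rows, grid.n_cols)
    innov_sd = sd * np.sqrt(1.0 - temporal_rho**2)
    f = np.empty((n_hours,) + shape)
    f[0] = sd * _smooth_noise(rng, shape, sigma_px)  # stationary start
    for t in range(1, n_hours):
        f[t] = temporal_rho * f[t - 1] + innov_sd * _smooth_noise(rng, shape, sigma_px)
    return np.maximum(mean_level + f, 0.0)


def link_covariates(residual: np.ndarray, covariates: dict,
                    link: LinkSpec) -> np.ndarray:
    """Add the deterministic nonlinear covariate component to the residual
    field.  With all amplitudes zero the output equals the residual exactly."""
    if link.nonlinearity != "sat_exp_interaction":
        raise ValueError(f"unknown nonlinearity tag {link.nonlinearity!r}")
    pm = residual.copy()
    if link.traffic_amp != 0.0:
        t = covariates["TRAFFIC"]
        pm = pm + link.traffic_amp * t / (t + link.traffic_scale)
    if link.pblh_amp != 0.0:
        pm = pm + link.pblh_amp * np.exp(-covariates["PBLH"] / link.pblh_scale)
    if link.ndvi_amp != 0.0:
        pm = pm + link.ndvi_amp * np.exp(-covariates["NDVI"] / link.ndvi_scale)
    if link.wind_amp != 0.0:
        speed2 = covariates["EWS"] ** 2 + covariates["NWS"] ** 2
        pm = pm + link.wind_amp * np.exp(-speed2 / link.wind_scale**2)
    if link.temrh_amp != 0.0:
        zt = (covariates["TEM"] - link.tem_center) / link.tem_sd
        zr = (covariates["RH"] - link.rh_center) / link.rh_sd
        pm = pm + link.temrh_amp * zt * zr
    return np.maximum(pm, 0.0)


# ---------------------------------------------------------------------------
# individual sources

def _random_polylines(rng, cfg: ScenarioConfig, n: int,
                      n_vertices=(3, 6), step=(0.03, 0.08)) -> list[np.ndarray]:
    lines = []
    w, h = cfg.lon_max - cfg.lon_min, cfg.lat_max - cfg.lat_min
    for _ in range(n):
        nv = int(rng.integers(n_vertices[0], n_vertices[1] + 1))
        p = np.array([cfg.lon_min + rng.random() * w,
                      cfg.lat_min + rng.random() * h])
        ang = rng.random() * 2 * np.pi
        pts = [p]
        for _ in range(nv - 1):
            ang += rng.normal(0.0, 0.6)
            d = rng.uniform(*step)
            p = p + d * np.array([np.cos(ang), np.sin(ang)])
            p[0] = np.clip(p[0], cfg.lon_min, cfg.lon_max - 1e-9)
            p[1] = np.clip(p[1], cfg.lat_min, cfg.lat_max - 1e-9)
            pts.append(p)
        lines.append(np.array(pts))
    return lines


def _diurnal_traffic(rng, cfg: ScenarioConfig) -> np.ndarray:
    """(n_hours, n_lines) congestion index in {1..6} with rush-hour peaks."""
    hours = np.arange(cfg.n_hours) % 24
    boost = np.zeros(cfg.n_hours)
    for rh in cfg.rush_hours:
        boost += 2.0 * np.exp(-0.5 * ((hours - rh) / 1.2) ** 2)
    base = rng.uniform(1.0, 3.0, cfg.n_traffic_lines)
    noise = rng.normal(0.0, 1.0, (cfg.n_hours, cfg.n_traffic_lines))
    idx = np.rint(base[None, :] + boost[:, None] + noise)
    return np.clip(idx, 1, 6).astype(int)


def _diurnal_cycle(hours: np.ndarray, peaks, widths, amps, floor: float) -> np.ndarray:
    h = hours % 24
    out = np.full(len(hours), floor)
    for p, w, a in zip(peaks, widths, amps):
        out = out + a * np.exp(-0.5 * ((h - p) / w) ** 2)
    return out


def _met_fields(rng, grid: GridSpec, n_hours: int) -> dict[str, np.ndarray]:
    """Smooth low-order spatial surfaces with diurnal cycles and mild noise."""
    xn, yn = np.meshgrid(np.linspace(-1, 1, grid.n_cols),
                         np.linspace(-1, 1, grid.n_rows))
    hours = np.arange(n_hours)
    h24 = hours % 24

    def surface(scale):
        a, b, c = rng.normal(0.0, scale, 3)
        return a * xn + b * yn + c * xn * yn

    def ar1(sd, rho=0.9):
        e = rng.normal(0.0, sd * np.sqrt(1 - rho**2), n_hours)
        z = np.empty(n_hours)
        z[0] = rng.normal(0.0, sd)
        for t in range(1, n_hours):
            z[t] = rho * z[t - 1] + e[t]
        return z

    # temperature and humidity: modest anti-phase diurnal cycles on top of
    # synoptic-scale AR noise (weather passages dominate the hour-to-hour change)
    tem = (288.0 + 3.0 * np.sin(2 * np.pi * (h24 - 8) / 24)[:, None, None]
           + surface(1.5)[None] + ar1(3.0, rho=0.6)[:, None, None])
    rh = np.clip(60.0 - 8.0 * np.sin(2 * np.pi * (h24 - 8) / 24)[:, None, None]
                 + surface(5.0)[None] + ar1(8.0, rho=0.6)[:, None, None], 5.0, 100.0)
    pblh = np.clip(
        (300.0 + 900.0 * np.exp(-0.5 * ((h24 - 14) / 3.5) ** 2))[:, None, None]
        + surface(60.0)[None] + ar1(80.0)[:, None, None], 100.0, None)
    # winds are gusty (weak hour-to-hour persistence) and near-centered:
    # stagnation effects act through the speed modulus, not the mean vector
    ews = surface(0.3)[None] + ar1(2.0, rho=0.5)[:, None, None]
    nws = surface(0.3)[None] + ar1(2.0, rho=0.5)[:, None, None]
    sp = (101.0 + 0.2 * np.sin(2 * np.pi * h24 / 12)[:, None, None]
          + surface(0.15)[None] + ar1(0.1)[:, None, None])
    return {"TEM": tem, "RH": rh, "PBLH": pblh, "EWS": ews, "NWS": nws, "SP": sp}


def _cloud_mask(rng, grid: GridSpec, fraction: float) -> np.ndarray:
    """One hour's cloud mask (True = cloudy) as a union of random disks,
    trimmed to exactly round(fraction · n_cells) cells so the requested
    missingness holds while staying spatially clustered."""
    target = int(round(fraction * grid.n_cells))
    mask = np.zeros((grid.n_rows, grid.n_cols), bool)
    if target == 0:
        return mask
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols),
                         indexing="ij")
    guard = 0
    while mask.sum() < target and guard < 10_000:
        guard += 1
        r0 = rng.uniform(-2, grid.n_rows + 2)
        c0 = rng.uniform(-2, grid.n_cols + 2)
        rad = rng.uniform(2.0, 5.0)
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        newly = disk & ~mask
        excess = int(mask.sum() + newly.sum()) - target
        if excess > 0:  # trim the last blob to land exactly on target
            idx = np.flatnonzero(newly.ravel())
            drop = rng.choice(idx, size=excess, replace=False)
            newly = newly.copy().ravel()
            newly[drop] = False
            newly = newly.reshape(mask.shape)
        mask |= newly
    return mask


# ---------------------------------------------------------------------------
# full scenario

def generate_scenario(config: ScenarioConfig | None = None) -> SyntheticScenario:
    """Generate a complete synthetic city under ``config`` (validated)."""
    cfg = config or ScenarioConfig()
    cfg.validate()
    grid = cfg.grid()
    seed = cfg.seed
    n_hours = cfg.n_hours

    # static geography -----------------------------------------------------
    dem_rng = _rng(seed, "dem")
    dem = 30.0 + 60.0 * (_smooth_noise(dem_rng, (grid.n_rows, grid.n_cols), 6.0)
                         * 0.5 + 0.5)
    ndvi_rng = _rng(seed, "ndvi")
    n_scenes = max(1, int(np.ceil(n_hours / (16 * 24))))
    base_ndvi = np.clip(0.35 + 0.25 * _smooth_noise(
        ndvi_rng, (grid.n_rows, grid.n_cols), 4.0), 0.02, 0.95)
    ndvi_scenes = [np.clip(base_ndvi + ndvi_rng.normal(0.0, 0.02)
                           + 0.03 * _smooth_noise(ndvi_rng, base_ndvi.shape, 4.0),
                           0.02, 0.95) for _ in range(n_scenes)]

    # lines, POIs ----------------------------------------------------------
    tr_rng = _rng(seed, "traffic")
    traffic_lines = _random_polylines(tr_rng, cfg, cfg.n_traffic_lines)
    traffic_index = _diurnal_traffic(tr_rng, cfg)
    rd_rng = _rng(seed, "roads")
    road_geoms = _random_polylines(rd_rng, cfg, cfg.n_roads,
                                   n_vertices=(2, 5), step=(0.02, 0.06))
    levels = rd_rng.choice(["highway", "main", "secondary", "branch"],
                           size=cfg.n_roads, p=[0.1, 0.25, 0.3, 0.35])
    road_lines = list(zip(road_geoms, levels.tolist()))
    poi_rng = _rng(seed, "pois")
    vertices = np.vstack([g for g in road_geoms])
    anchors_idx = poi_rng.integers(0, len(vertices), cfg.n_pois)
    poi_xy = vertices[anchors_idx] + poi_rng.normal(0.0, 0.01, (cfg.n_pois, 2))
    poi_xy[:, 0] = np.clip(poi_xy[:, 0], cfg.lon_min, cfg.lon_max - 1e-9)
    poi_xy[:, 1] = np.clip(poi_xy[:, 1], cfg.lat_min, cfg.lat_max - 1e-9)
    cls = poi_rng.choice(["PS", "Scen", "other"], size=cfg.n_pois,
                         p=[cfg.poi_ps_frac, cfg.poi_scen_frac,
                            1 - cfg.poi_ps_frac - cfg.poi_scen_frac])
    pois = pd.DataFrame({"lon": poi_xy[:, 0], "lat": poi_xy[:, 1],
                         "poi_class": cls})

    # check-ins ------------------------------------------------------------
    ci_rng = _rng(seed, "checkins")
    # anchors: a clustered point pattern (two thirds near random centers)
    n_anchor = cfg.n_checkin_anchors
    centers = np.column_stack([
        ci_rng.uniform(cfg.lon_min, cfg.lon_max, 6),
        ci_rng.uniform(cfg.lat_min, cfg.lat_max, 6)])
    n_clustered = (2 * n_anchor) // 3
    pick = ci_rng.integers(0, len(centers), n_clustered)
    clustered = centers[pick] + ci_rng.normal(0.0, 0.04, (n_clustered, 2))
    uniform = np.column_stack([
        ci_rng.uniform(cfg.lon_min, cfg.lon_max, n_anchor - n_clustered),
        ci_rng.uniform(cfg.lat_min, cfg.lat_max, n_anchor - n_clustered)])
    axy = np.vstack([clustered, uniform])
    axy[:, 0] = np.clip(axy[:, 0], cfg.lon_min, cfg.lon_max - 1e-9)
    axy[:, 1] = np.clip(axy[:, 1], cfg.lat_min, cfg.lat_max - 1e-9)
    anchors = pd.DataFrame({"lon": axy[:, 0], "lat": axy[:, 1]})
    weights = ci_rng.lognormal(0.0, 0.6, n_anchor)
    diurnal = _diurnal_cycle(np.arange(n_hours), peaks=(9, 13, 19),
                             widths=(1.5, 2.0, 2.5), amps=(0.8, 0.6, 1.0),
                             floor=0.25)
    lam = (cfg.checkin_base_rate * weights[None, None, :]
           * diurnal[:, None, None])
    counts = ci_rng.poisson(np.broadcast_to(
        lam, (n_hours, cfg.snapshots_per_hour, n_anchor)))

    # meteorology ----------------------------------------------------------
    met = _met_fields(_rng(seed, "met"), grid, n_hours)

    # true PM field --------------------------------------------------------
    residual = generate_pm_field(grid, n_hours, cfg.spatial_range,
                                 cfg.temporal_rho, cfg.mean_level,
                                 cfg.residual_sd, rng=_rng(seed, "pm_field"))
    basis = line_density_basis(traffic_lines, grid,
                               KDAConfig(bandwidth=grid.cell_size))
    traffic_density = np.tensordot(traffic_index.astype(float), basis,
                                   axes=(1, 0))
    scene_of_hour = np.minimum(np.arange(n_hours) // (16 * 24), n_scenes - 1)
    ndvi_stack = np.stack([ndvi_scenes[i] for i in scene_of_hour])
    link_cov = {"TRAFFIC": traffic_density, "PBLH": met["PBLH"],
                "NDVI": ndvi_stack, "TEM": met["TEM"], "RH": met["RH"],
                "EWS": met["EWS"], "NWS": met["NWS"]}
    true_pm = link_covariates(residual, link_cov, cfg.link)

    # stations and observations --------------------------------------------
    st_rng = _rng(seed, "stations")
    taken: set[tuple[int, int]] = set()
    rows = []
    while len(rows) < cfg.n_stations:
        lon = st_rng.uniform(cfg.lon_min, cfg.lon_max)
        lat = st_rng.uniform(cfg.lat_min, cfg.lat_max)
        r, c = grid.cell_of(lon, lat)
        if r < 0 or (int(r), int(c)) in taken:
            continue  # one station per cell
        taken.add((int(r), int(c)))
        rows.append({"station_id": f"S{len(rows):03d}", "lon": lon, "lat": lat})
    stations = pd.DataFrame(rows)
    srow, scol = grid.cell_of(stations["lon"].to_numpy(),
                              stations["lat"].to_numpy())
    truth_at_st = true_pm[:, srow, scol]  # (hour, station)
    noise = _rng(seed, "obs_noise").normal(0.0, cfg.obs_noise_sd,
                                           truth_at_st.shape)
    obs = truth_at_st + noise
    hour_idx, st_idx = np.meshgrid(np.arange(n_hours),
                                   np.arange(cfg.n_stations), indexing="ij")
    station_obs = pd.DataFrame({
        "station_id": stations["station_id"].to_numpy()[st_idx.ravel()],
        "hour": hour_idx.ravel(),
        "pm25": obs.ravel(),
    })

    # AOT: affine in true PM + noise, daytime only, cloud-gapped ------------
    aot_rng = _rng(seed, "aot")
    aot = 0.004 * true_pm + 0.1 + aot_rng.normal(0.0, 0.02, true_pm.shape)
    aot_mask = np.zeros(true_pm.shape, bool)
    for t in range(n_hours):
        if cfg.aot_day_start <= t % 24 < cfg.aot_day_end:
            cloud = _cloud_mask(aot_rng, grid, cfg.cloud_fraction)
            aot_mask[t] = ~cloud
    aot[~aot_mask] = np.nan

    covariates = {"AOT": aot, "AOT_MASK": aot_mask, "NDVI": ndvi_scenes,
                  "DEM": dem, "TRAFFIC": traffic_density, **met}
    return SyntheticScenario(
        grid=grid, n_hours=n_hours, true_pm=true_pm, stations=stations,
        station_obs=station_obs, checkin_anchors=anchors,
        checkin_counts=counts, traffic_lines=traffic_lines,
        traffic_index=traffic_index, road_lines=road_lines, pois=pois,
        covariates=covariates, aot_mask=aot_mask, config=cfg)


def config_to_dict(cfg: ScenarioConfig) -> dict:
    d = asdict(cfg)
    d["rush_hours"] = list(cfg.rush_hours)
    return d


def config_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    if "link" in d and isinstance(d["link"], dict):
        d["link"] = LinkSpec(**d["link"])
    if "rush_hours" in d:
        d["rush_hours"] = tuple(d["rush_hours"])
    return ScenarioConfig(**d)
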