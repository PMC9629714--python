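"""Synthetic AIS world: reception field, shore, driver rasters, and vessel
fleets with planted intentional-disabling events.

The generator emulates the statistical structure of a satellite AIS stream:

* a spatially varying reception field (expected satellite-received positions
  per vessel per day) built from a background level plus Gaussian bumps
  (negative bumps carve low-reception holes, clamped at zero);
* class A / class B transponders with different nominal ping rates;
* vessel movement as a correlated random walk attracted to gear-specific
  fishing grounds, reflected at the extent boundary;
* pings as an inhomogeneous Poisson process thinned by local reception
  (expected pings per vessel-day = base_rate * min(1, reception / reference));
* intentional disabling planted per vessel-day with logistic probability in
  per-cell covariates (by default loitering and distance to shore), with
  log-normal durations; every planted interval is anchored at a real ping so
  the gap has a well-defined last-ping-before position;
* unintentional gaps arise implicitly wherever reception is poor — they are
  never planted, matching the causal story that technical gaps are a
  property of the receiving environment, not of the vessel.

Everything is deterministic given the configured seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geo import haversine_km
from .grid import GridSpec, Raster

GEAR_TYPES = ("drifting_longlines", "squid_jigger", "tuna_purse_seine",
              "trawler", "other")
DRIVER_NAMES = ("dist_shore", "dist_mpa", "loitering", "dist_piracy",
                "chl", "eke", "sst", "sst_sd")
DISTANCE_DRIVERS = frozenset({"dist_shore", "dist_mpa", "dist_piracy"})
DISTANCE_CLIP_KM = 400.0

MESSAGE_COLUMNS = ["vessel_id", "timestamp", "lon", "lat", "device_class",
                   "is_fishing", "gear", "flag"]
TRUTH_COLUMNS = ["vessel_id", "start", "end", "start_lon", "start_lat",
                 "end_lon", "end_lat", "cause"]

_EPOCH = pd.Timestamp("2018-01-01", tz="UTC")


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianBump:
    """An isotropic Gaussian bump, amplitude * exp(-d^2 / (2 sigma^2)) with d
    the planar distance in degrees from the bump center."""
    lon: float
    lat: float
    amplitude: float
    sigma_deg: float


@dataclass(frozen=True)
class DriverFieldSpec:
    """How one driver raster is generated.

    kind "smooth": mean + amplitude * unit-variance Gaussian random field
    (length_scale_deg correlation scale), optionally clipped at zero.
    kind "distance": great-circle km to n_sources random points, clipped at
    400 km. kind "bumps": sum of n_sources random positive Gaussian bumps.
    """
    kind: str = "smooth"
    mean: float = 0.0
    amplitude: float = 1.0
    length_scale_deg: float = 2.0
    n_sources: int = 3
    nonnegative: bool = True


@dataclass(frozen=True)
class WorldConfig:
    west: float = -40.0
    south: float = -30.0
    east: float = -20.0
    north: float = -10.0
    cell_size_deg: float = 0.25
    reception_background: float = 35.0
    reception_bumps: tuple[GaussianBump, ...] = (
        GaussianBump(-26.0, -24.0, -34.0, 3.5),   # low-reception hole
        GaussianBump(-33.0, -14.0, 8.0, 3.0),     # high-reception lobe
    )
    shore: str | tuple = "west_edge"  # or tuple of (lon, lat) vertices
    driver_specs: dict = field(default_factory=lambda: dict(_DEFAULT_DRIVERS))
    seed: int = 0


_DEFAULT_DRIVERS: dict[str, DriverFieldSpec] = {
    "dist_mpa": DriverFieldSpec(kind="distance", n_sources=3),
    "dist_piracy": DriverFieldSpec(kind="distance", n_sources=2),
    "loitering": DriverFieldSpec(kind="bumps", amplitude=30.0,
                                 length_scale_deg=1.5, n_sources=5),
    "chl": DriverFieldSpec(mean=0.25, amplitude=0.15, length_scale_deg=2.0),
    "eke": DriverFieldSpec(mean=0.02, amplitude=0.015, length_scale_deg=1.5),
    "sst": DriverFieldSpec(mean=18.0, amplitude=4.0, length_scale_deg=3.0,
                           nonnegative=False),
    "sst_sd": DriverFieldSpec(mean=1.0, amplitude=0.6, length_scale_deg=2.0),
}


@dataclass(frozen=True)
class MovementConfig:
    speed_mean_deg_h: float = 0.04      # ~2.4 knots at these latitudes
    speed_sigma_log: float = 0.5
    turn_sigma_rad: float = 0.5
    attraction: float = 0.12            # pull toward the fishing ground
    ground_sigma_deg: float = 2.0       # vessel start scatter around ground


@dataclass(frozen=True)
class DisablingModel:
    """Per vessel-day logistic model for starting an intentional disabling
    event; coefficients act on the driver value in the vessel's cell
    (distances in km, loitering in hours)."""
    intercept: float = -4.2
    coefs: dict = field(default_factory=lambda: {"loitering": 0.06,
                                                 "dist_shore": 0.004})
    duration_lognormal_mu: float = math.log(40.0)   # median 40 h
    duration_lognormal_sigma: float = 0.9


@dataclass(frozen=True)
class FleetConfig:
    n_vessels: int = 100
    gear_mix: dict = field(default_factory=lambda: {
        "drifting_longlines": 0.30, "squid_jigger": 0.20,
        "tuna_purse_seine": 0.20, "trawler": 0.20, "other": 0.10})
    flag_mix: dict = field(default_factory=lambda: {
        "CHN": 0.35, "TWN": 0.20, "ESP": 0.15, "USA": 0.15, "KOR": 0.15})
    device_class_mix: dict = field(default_factory=lambda: {"A": 0.7, "B": 0.3})
    base_ping_rate: dict = field(default_factory=lambda: {"A": 100.0, "B": 13.0})
    # per-vessel broadcast-rate heterogeneity (antenna quality, shadowing):
    # lognormal multiplier with unit mean
    rate_sigma_log: float = 0.5
    reference_reception: float = 30.0
    movement: MovementConfig = field(default_factory=MovementConfig)
    disabling: DisablingModel = field(default_factory=DisablingModel)
    seed: int = 0


def _check_mix(mix: dict, name: str) -> None:
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name} proportions sum to {total}, expected 1")
    if any(v < 0 for v in mix.values()):
        raise ConfigError(f"{name} has a negative proportion")


def validate_fleet_config(fleet: FleetConfig) -> None:
    if fleet.n_vessels < 1:
        raise ConfigError("n_vessels must be >= 1 (empty fleet)")
    _check_mix(fleet.gear_mix, "gear_mix")
    _check_mix(fleet.flag_mix, "flag_mix")
    _check_mix(fleet.device_class_mix, "device_class_mix")
    for cls, rate in fleet.base_ping_rate.items():
        if rate < 0:
            raise ConfigError(f"base_ping_rate[{cls}] must be >= 0")


# ---------------------------------------------------------------------------
# world construction
# ---------------------------------------------------------------------------

@dataclass
class World:
    spec: GridSpec
    reception: Raster              # truth field, positions/vessel/day
    shore_distance_km: Raster
    shore_vertices: np.ndarray     # (m, 2) lon/lat
    drivers: dict[str, Raster]
    config: WorldConfig


def _bump_field(spec: GridSpec, background: float, bumps) -> np.ndarray:
    lon, lat = spec.center_mesh()
    out = np.full(spec.shape, float(background))
    for b in bumps:
        d2 = (lon - b.lon) ** 2 + (lat - b.lat) ** 2
        out += b.amplitude * np.exp(-d2 / (2.0 * b.sigma_deg ** 2))
    return out


def _smooth_field(spec: GridSpec, fs: DriverFieldSpec, rng) -> np.ndarray:
    noise = rng.standard_normal(spec.shape)
    sigma_cells = max(fs.length_scale_deg / spec.cell_size_deg, 1e-6)
    smooth = gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    out = fs.mean + fs.amplitude * smooth
    return np.clip(out, 0.0, None) if fs.nonnegative else out


def _shore_vertices(config: WorldConfig) -> np.ndarray:
    if isinstance(config.shore, str):
        if config.shore != "west_edge":
            raise ConfigError(f"unknown shore spec {config.shore!r}")
        n = int(round((config.north - config.south) / 0.05)) + 1
        lat = np.linspace(config.south, config.north, n)
        return np.column_stack([np.full(n, config.west), lat])
    verts = np.asarray(config.shore, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 1:
        raise ConfigError("shore polyline must be a sequence of (lon, lat)")
    return verts


def _min_distance_km(spec: GridSpec, sources: np.ndarray) -> np.ndarray:
    lon, lat = spec.center_mesh()
    flat_lon, flat_lat = lon.ravel(), lat.ravel()
    best = np.full(flat_lon.shape, np.inf)
    for slon, slat in sources:
        d = haversine_km(flat_lon, flat_lat, slon, slat)
        np.minimum(best, d, out=best)
    return best.reshape(spec.shape)


def build_world(config: WorldConfig) -> World:
    """Build reception truth, shore-distance and driver rasters on the
    configured grid; deterministic for a fixed seed."""
    spec = GridSpec(config.west, config.south, config.east, config.north,
                    config.cell_size_deg)
    rng = np.random.default_rng(config.seed)

    reception_vals = np.clip(
        _bump_field(spec, config.reception_background, config.reception_bumps),
        0.0, None)
    reception = Raster(spec, reception_vals, layer="reception",
                       units="positions/vessel/day")

    shore = _shore_vertices(config)
    shore_km = _min_distance_km(spec, shore)
    shore_raster = Raster(spec, shore_km, layer="shore_distance", units="km")

    drivers: dict[str, Raster] = {
        "dist_shore": Raster(spec, np.clip(shore_km, 0, DISTANCE_CLIP_KM),
                             layer="dist_shore", units="km")}
    margin = 0.1 * min(config.east - config.west, config.north - config.south)
    for name in DRIVER_NAMES:
        if name == "dist_shore":
            continue
        fs = config.driver_specs.get(name, DriverFieldSpec())
        if fs.kind == "distance":
            pts = np.column_stack([
                rng.uniform(config.west + margin, config.east - margin, fs.n_sources),
                rng.uniform(config.south + margin, config.north - margin, fs.n_sources)])
            vals = np.clip(_min_distance_km(spec, pts), 0, DISTANCE_CLIP_KM)
            units = "km"
        elif fs.kind == "bumps":
            bumps = [GaussianBump(
                rng.uniform(config.west + margin, config.east - margin),
                rng.uniform(config.south + margin, config.north - margin),
                fs.amplitude * rng.uniform(0.3, 1.0),
                fs.length_scale_deg)
                for _ in range(fs.n_sources)]
            vals = np.clip(_bump_field(spec, 0.0, bumps), 0, None)
            units = "hours"
        elif fs.kind == "smooth":
            vals = _smooth_field(spec, fs, rng)
            units = ""
        else:
            raise ConfigError(f"unknown driver field kind {fs.kind!r}")
        drivers[name] = Raster(spec, vals, layer=name, units=units)

    return World(spec=spec, reception=reception, shore_distance_km=shore_raster,
                 shore_vertices=shore, drivers=drivers, config=config)


# ---------------------------------------------------------------------------
# fleet simulation
# ---------------------------------------------------------------------------

def _simulate_track(world: World, mv: MovementConfig, center: np.ndarray,
                    n_hours: int, rng) -> np.ndarray:
    """Hourly positions (n_hours + 1, 2) of one vessel: correlated random
    walk with attraction to its fishing-ground center, reflected at the
    extent boundary."""
    cfg = world.config
    pos = np.empty((n_hours + 1, 2))
    p = np.array([
        np.clip(rng.normal(center[0], mv.ground_sigma_deg),
                cfg.west + 1e-6, cfg.east - 1e-6),
        np.clip(rng.normal(center[1], mv.ground_sigma_deg),
                cfg.south + 1e-6, cfg.north - 1e-6)])
    pos[0] = p
    theta = rng.uniform(0, 2 * np.pi)
    turns = rng.normal(0.0, mv.turn_sigma_rad, n_hours)
    speeds = rng.lognormal(np.log(mv.speed_mean_deg_h), mv.speed_sigma_log,
                           n_hours)
    for i in range(n_hours):
        bearing = math.atan2(center[1] - p[1], center[0] - p[0])
        # wrap the angular difference into (-pi, pi] before blending
        diff = (bearing - theta + np.pi) % (2 * np.pi) - np.pi
        theta = theta + mv.attraction * diff + turns[i]
        p = p + speeds[i] * np.array([math.cos(theta), math.sin(theta)])
        # reflective boundary
        if p[0] < cfg.west:
            p[0] = 2 * cfg.west - p[0]
            theta = np.pi - theta
        elif p[0] >= cfg.east:
            p[0] = 2 * cfg.east - p[0] - 1e-9
            theta = np.pi - theta
        if p[1] < cfg.south:
            p[1] = 2 * cfg.south - p[1]
            theta = -theta
        elif p[1] >= cfg.north:
            p[1] = 2 * cfg.north - p[1] - 1e-9
            theta = -theta
        p[0] = np.clip(p[0], cfg.west + 1e-9, cfg.east - 1e-9)
        p[1] = np.clip(p[1], cfg.south + 1e-9, cfg.north - 1e-9)
        pos[i + 1] = p
    return pos


def _ping_times(track: np.ndarray, world: World, rate_per_day: float,
                reference: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Inhomogeneous Poisson ping times (hours since start) and positions,
    thinned by local reception at the hourly track node."""
    n_hours = len(track) - 1
    recep = world.reception.value_at(track[:-1, 0], track[:-1, 1])
    lam_h = rate_per_day * np.minimum(1.0, recep / reference) / 24.0
    counts = rng.poisson(lam_h)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0), np.empty((0, 2))
    hour_idx = np.repeat(np.arange(n_hours), counts)
    frac = rng.uniform(0.0, 1.0, total)
    times = hour_idx + frac
    pos = track[hour_idx] + frac[:, None] * (track[hour_idx + 1] - track[hour_idx])
    order = np.argsort(times, kind="stable")
    return times[order], pos[order]


def _disabling_probability(world: World, model: DisablingModel,
                           lon: float, lat: float) -> float:
    z = model.intercept
    for name, coef in model.coefs.items():
        z += coef * float(world.drivers[name].value_at(lon, lat))
    return 1.0 / (1.0 + math.exp(-z))


def simulate_fleet(world: World, fleet: FleetConfig, days: int
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a fleet for ``days`` days.

    Returns (messages, truth): the AIS message table (one row per ping,
    sorted by vessel then timestamp) and the ground-truth log of planted
    intentional-disabling intervals.  Pings inside planted intervals are
    removed; the truth endpoints are the last ping before and the first ping
    after the dark period.
    """
    if days < 1:
        raise ConfigError("days must be >= 1")
    validate_fleet_config(fleet)
    if not np.any(world.reception.values > 0):
        raise ConfigError("reception field is all-zero: no observable vessels")

    rng = np.random.default_rng(fleet.seed)
    cfg = world.config
    margin = 0.15 * min(cfg.east - cfg.west, cfg.north - cfg.south)
    ground = {g: np.array([rng.uniform(cfg.west + margin, cfg.east - margin),
                           rng.uniform(cfg.south + margin, cfg.north - margin)])
              for g in fleet.gear_mix}

    gears = list(fleet.gear_mix)
    flags = list(fleet.flag_mix)
    classes = list(fleet.device_class_mix)
    n_hours = days * 24

    msg_frames = []
    truth_rows = []
    for v in range(fleet.n_vessels):
        vessel_id = f"{900000000 + v}"
        gear = gears[rng.choice(len(gears), p=[fleet.gear_mix[g] for g in gears])]
        flag = flags[rng.choice(len(flags), p=[fleet.flag_mix[f] for f in flags])]
        dev = classes[rng.choice(len(classes),
                                 p=[fleet.device_class_mix[c] for c in classes])]
        track = _simulate_track(world, fleet.movement, ground[gear], n_hours, rng)
        rate_mult = rng.lognormal(-0.5 * fleet.rate_sigma_log ** 2,
                                  fleet.rate_sigma_log)
        times, pos = _ping_times(track, world,
                                 rate_mult * fleet.base_ping_rate[dev],
                                 fleet.reference_reception, rng)
        keep = np.ones(len(times), dtype=bool)

        # plant intentional disabling events day by day
        cursor = 0.0
        for day in range(days):
            day_start = float(day * 24)
            if day_start < cursor:
                continue
            node = track[day * 24]
            p_dis = _disabling_probability(world, fleet.disabling, node[0], node[1])
            if rng.uniform() >= p_dis:
                continue
            cand = np.flatnonzero(keep & (times >= max(day_start, cursor))
                                  & (times < day_start + 24))
            if cand.size == 0:
                continue
            anchor = int(rng.choice(cand))
            duration_h = float(rng.lognormal(fleet.disabling.duration_lognormal_mu,
                                             fleet.disabling.duration_lognormal_sigma))
            dark_end = times[anchor] + duration_h
            after = np.flatnonzero(keep & (times > dark_end))
            if after.size == 0:
                continue  # event would run past the simulation: not planted
            first_after = int(after[0])
            dark = keep & (times > times[anchor]) & (times < times[first_after])
            keep[dark] = False
            truth_rows.append({
                "vessel_id": vessel_id,
                "start": times[anchor], "end": times[first_after],
                "start_lon": pos[anchor, 0], "start_lat": pos[anchor, 1],
                "end_lon": pos[first_after, 0], "end_lat": pos[first_after, 1],
                "cause": "intentional"})
            cursor = times[first_after]

        times, pos = times[keep], pos[keep]
        if len(times) == 0:
            continue
        msg_frames.append(pd.DataFrame({
            "vessel_id": vessel_id,
            "timestamp": (_EPOCH + pd.to_timedelta(times, unit="h")).floor("s"),
            "lon": pos[:, 0], "lat": pos[:, 1],
            "device_class": dev,
            "is_fishing": rng.uniform(size=len(times)) < 0.7,
            "gear": gear, "flag": flag}))

    if msg_frames:
        messages = pd.concat(msg_frames, ignore_index=True)
        messages = messages.sort_values(["vessel_id", "timestamp"],
                                        kind="stable", ignore_index=True)
        # timestamps are floored to the second; drop rare exact duplicates so
        # per-vessel timestamps are strictly increasing
        messages = messages.drop_duplicates(["vessel_id", "timestamp"],
                                            ignore_index=True)
    else:
        messages = pd.DataFrame(columns=MESSAGE_COLUMNS)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    if len(truth):
        for col in ("start", "end"):
            truth[col] = (_EPOCH + pd.to_timedelta(truth[col], unit="h")).dt.floor("s")
    truth = truth.sort_values(["vessel_id", "start"], ignore_index=True) \
        if len(truth) else truth
    return messages, truth


def sample_disabling_cells(world: World, model: DisablingModel,
                           n_trials: int, seed: int) -> Raster:
    """Cell-level event sampler: per cell, Binomial(n_trials, p) planted
    event counts with p logistic in the model's driver covariates.  A fast
    stand-in for full fleet simulation when only the spatial pattern of
    disabling matters (driver-model tests)."""
    z = np.full(world.spec.shape, model.intercept)
    for name, coef in model.coefs.items():
        z += coef * world.drivers[name].values
    p = 1.0 / (1.0 + np.exp(-z))
    rng = np.random.default_rng(seed)
    counts = rng.binomial(n_trials, p)
    return Raster(world.spec, counts.astype(float), layer="disabling_events")


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

_TS_FORMAT = "%Y-%m-%dT%H:%M:%SZ"


def write_fixture(messages: pd.DataFrame, truth: pd.DataFrame,
                  path: str | Path) -> dict[str, Path]:
    """Write messages.csv and truth.csv under ``path`` (a directory);
    ISO-8601 UTC timestamps at second resolution, lossless round-trip."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = {}
    msg = messages.copy()
    if len(msg):
        msg["timestamp"] = msg["timestamp"].dt.strftime(_TS_FORMAT)
    out["messages"] = path / "messages.csv"
    msg.to_csv(out["messages"], index=False, columns=MESSAGE_COLUMNS)
    tr = truth.copy()
    if len(tr):
        for col in ("start", "end"):
            tr[col] = tr[col].dt.strftime(_TS_FORMAT)
    out["truth"] = path / "truth.csv"
    tr.to_csv(out["truth"], index=False, columns=TRUTH_COLUMNS)
    return out


def read_messages(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"vessel_id": str})
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    if "is_fishing" in df.columns:
        df["is_fishing"] = df["is_fishing"].astype(bool)
    return df


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"vessel_id": str})
    for col in ("start", "end"):
        df[col] = pd.to_datetime(df[col], utc=True)
    return df


def default_world_config(seed: int = 0) -> WorldConfig:
    return WorldConfig(seed=seed)


def default_fleet_config(seed: int = 0, **overrides) -> FleetConfig:
    return replace(FleetConfig(seed=seed), **overrides)
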