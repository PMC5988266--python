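"""Synthetic tracks, light and immersion records, and environment grids.

Every downstream stage of the pipeline (geolocation, movement posterior,
haul-out segmentation, habitat and activity models) is testable against
the exported ground truth generated here, without any external data.

The statistical structure mirrors what the analysis assumes:

* per-step speeds are log-normal on the natural km/h scale (defaults:
  arithmetic mean 1.0 km/h, SD 0.9 km/h — the movement-prior values);
* light is a monotone logistic function of solar altitude, sampled every
  60 s and aggregated as the max per 10-min window on an integer 0-64
  scale (BAS-logger-like; the true sensor scale is not documented);
* immersion counts are 3-s salt-water tests per 10-min window (0 dry,
  200 fully wet); haul-out bouts start from an hourly hazard with diel
  and seasonal sinusoids and continue with per-hour persistence;
* environment grids are analytic stand-ins for bathymetry, weekly/monthly
  SST and monthly ice concentration sharing one lon/lat grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from . import solar
from .geodesy import (destination, haversine_km, initial_bearing_deg,
                      unit_vectors, chord_to_arc_km, wrap_lon)

LIGHT_MAX = 64  # integer sensor scale; a convention, not a documented value
WINDOW = pd.Timedelta("10min")
SAMPLE = pd.Timedelta("60s")
WET_TESTS_PER_WINDOW = 200  # 10 min at one 3-s salt-water test every 3 s


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(meanlog, sdlog) of a log-normal with arithmetic mean/SD on the natural scale."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


@dataclass
class TrackParams:
    """Parameters of a migratory central-place track simulation."""

    start_lonlat: tuple[float, float] = (-38.05, -54.01)
    central_place_lonlat: tuple[float, float] = (-38.05, -54.01)
    mean_speed: float = 1.0   # km/h, arithmetic mean of step speeds
    speed_sd: float = 0.9     # km/h, arithmetic SD of step speeds
    migration_schedule: Sequence[tuple] = ()   # (date, (lon, lat)) departure legs
    residency_days: int = 30
    step_interval: float = 12.0  # hours
    n_steps: int = 200
    start_time: str | pd.Timestamp = "2013-05-01T00:00:00"
    heading_sd: float = 20.0     # degrees, heading noise while migrating
    residency_radius_km: float = 40.0
    seed: int | None = None

    def __post_init__(self):
        if self.mean_speed <= 0:
            raise ValueError("mean_speed must be > 0")
        if self.speed_sd < 0:
            raise ValueError("speed_sd must be >= 0")
        if self.step_interval <= 0:
            raise ValueError("step_interval must be > 0")


@dataclass
class HauloutSchedule:
    """Hourly haul-out hazard: diel and seasonal sinusoids plus bout persistence."""

    base_rate: float = 0.04        # bout-start probability per at-sea hour
    diel_peak_hour: float = 12.0
    diel_amplitude: float = 0.8
    seasonal_amplitude: float = 0.4
    seasonal_peak_week: float = 3.0
    persistence: float = 0.75      # per-hour bout continuation probability
    min_bout: float = 1.0          # hours

    def __post_init__(self):
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValueError("base_rate must lie in [0, 1]")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must lie in [0, 1)")

    def start_hazard(self, hour_of_day, week_of_year):
        h = (1.0 + self.diel_amplitude
             * np.cos(2 * np.pi * (np.asarray(hour_of_day) - self.diel_peak_hour) / 24.0))
        s = (1.0 + self.seasonal_amplitude
             * np.cos(2 * np.pi * (np.asarray(week_of_year) - self.seasonal_peak_week) / 52.0))
        return np.clip(self.base_rate * h * s, 0.0, 1.0)


@dataclass
class EnvFieldSpec:
    """Analytic environment fields sharing one lon/lat grid."""

    grid_extent: tuple[float, float, float, float] = (-60.0, -20.0, -75.0, -45.0)
    resolution: float = 0.25            # degrees
    depth_gradient: float = 5.0         # metres of depth per km offshore
    sst_lat_gradient: float = 0.4       # deg C per degree latitude, equatorward
    ice_edge_latitude_by_month: Sequence[float] = (
        -64.0, -65.0, -63.5, -62.0, -60.5, -59.0,
        -58.0, -57.5, -58.0, -59.5, -61.0, -63.0,
    )
    sst_base: float = 4.0               # deg C at the reference (most poleward) latitude
    sst_seasonal_amplitude: float = 1.5
    ice_ramp_width_deg: float = 5.0
    land_polygons: Sequence[Polygon] | None = None

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        lon0, lon1, lat0, lat1 = self.grid_extent
        if len(self.ice_edge_latitude_by_month) != 12:
            raise ValueError("ice_edge_latitude_by_month needs 12 entries")
        for e in self.ice_edge_latitude_by_month:
            if not lat0 <= e <= lat1:
                raise ValueError("ice edge latitudes must lie within the grid extent")
        if self.land_polygons is None:
            self.land_polygons = default_land_polygons()


def default_land_polygons() -> list[Polygon]:
    """A small island at the deployment site plus a polar coastline block."""
    island = Point(-38.05, -54.01).buffer(0.35, quad_segs=16)
    continent = Polygon([(-60.0, -75.0), (-20.0, -75.0), (-20.0, -72.0), (-60.0, -72.0)])
    return [island, continent]


@dataclass
class GroundTruth:
    """Exported truth for a synthetic dataset (tracks, bouts, twilights)."""

    true_track: pd.DataFrame | None = None
    true_bouts: pd.DataFrame | None = None
    true_twilights: pd.DataFrame | None = None
    generator_params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.generator_params, default=str, indent=2)


# ---------------------------------------------------------------------------
# tracks

def simulate_track(params: TrackParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a migratory central-place track with log-normal step speeds.

    The track follows ``migration_schedule`` legs (departure date, target);
    before the first leg, after reaching a target, and once the schedule is
    exhausted it loops inside ``residency_radius_km`` of the current anchor.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    times = pd.date_range(pd.Timestamp(params.start_time),
                          periods=params.n_steps + 1,
                          freq=pd.Timedelta(hours=params.step_interval))
    schedule = sorted(
        ((pd.Timestamp(d), tuple(t)) for d, t in params.migration_schedule),
        key=lambda e: e[0])
    for d, _ in schedule:
        if not times[0] <= d <= times[-1]:
            raise ValueError(f"migration schedule date {d} outside the simulated window "
                             f"[{times[0]}, {times[-1]}]")

    if params.speed_sd == 0:
        speeds = np.full(params.n_steps, params.mean_speed)
    else:
        mu, sig = lognormal_params(params.mean_speed, params.speed_sd)
        speeds = rng.lognormal(mu, sig, size=params.n_steps)

    lon = np.empty(params.n_steps + 1)
    lat = np.empty(params.n_steps + 1)
    lon[0], lat[0] = params.start_lonlat
    anchor = tuple(params.central_place_lonlat)
    target = None          # active migration target
    waypoint = None        # residency loop waypoint
    leg = 0
    for i in range(params.n_steps):
        now = times[i]
        if leg < len(schedule) and now >= schedule[leg][0]:
            target = schedule[leg][1]
            leg += 1
            waypoint = None
        step_km = speeds[i] * params.step_interval
        if target is not None:
            d = haversine_km(lon[i], lat[i], target[0], target[1])
            if d <= max(step_km, 2.0):
                anchor, target, waypoint = target, None, None
        if target is not None:
            brg = initial_bearing_deg(lon[i], lat[i], target[0], target[1])
            brg += rng.normal(0.0, params.heading_sd)
        else:
            if waypoint is None or haversine_km(lon[i], lat[i], *waypoint) <= step_km:
                ang = rng.uniform(0.0, 360.0)
                rad = params.residency_radius_km * np.sqrt(rng.uniform())
                waypoint = destination(anchor[0], anchor[1], ang, rad)
                waypoint = (float(waypoint[0]), float(waypoint[1]))
            brg = initial_bearing_deg(lon[i], lat[i], waypoint[0], waypoint[1])
            brg += rng.normal(0.0, params.heading_sd)
        lon[i + 1], lat[i + 1] = destination(lon[i], lat[i], float(brg), float(step_km))

    track = pd.DataFrame({"time": times, "lon": lon, "lat": lat})
    truth = GroundTruth(true_track=track.copy(), generator_params=asdict(params))
    return track, truth


def stationary_track(lonlat, start, days: float, step_hours: float = 12.0) -> pd.DataFrame:
    """A fixed-position 'track' (e.g. a calibration tag at a known site)."""
    times = pd.date_range(pd.Timestamp(start), pd.Timestamp(start) + pd.Timedelta(days=days),
                          freq=pd.Timedelta(hours=step_hours))
    return pd.DataFrame({"time": times,
                         "lon": np.full(len(times), float(lonlat[0])),
                         "lat": np.full(len(times), float(lonlat[1]))})


def _interp_positions(track: pd.DataFrame, times: pd.DatetimeIndex):
    tt = pd.DatetimeIndex(track["time"]).asi8.astype(float)
    ti = times.asi8.astype(float)
    lon = np.interp(ti, tt, np.asarray(track["lon"], dtype=float))
    lat = np.interp(ti, tt, np.asarray(track["lat"], dtype=float))
    return lon, lat


# ---------------------------------------------------------------------------
# light

def render_light(track: pd.DataFrame, zenith_deg: float = 96.0, threshold: float = 10.0,
                 noise_sd: float = 0.0, shading_bouts: Sequence[tuple] = (),
                 seed: int | None = None, transfer_width: float = 1.5) -> pd.DataFrame:
    """Render a 10-min max-light record along a track.

    Light is a logistic function of solar altitude clipped to the integer
    0-64 scale, anchored so that the value crosses ``threshold`` exactly
    when the solar zenith equals ``zenith_deg``.  Sampled every 60 s;
    the max over each 10-min window is recorded, stamped at window start.
    During ``shading_bouts`` (intervals of (start, end)) the sensor is
    attenuated toward zero, emulating an animal covering it with its body.
    """
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(track["time"].iloc[0]).floor("10min")
    t1 = pd.Timestamp(track["time"].iloc[-1])
    samples = pd.date_range(t0, t1, freq=SAMPLE)
    lon, lat = _interp_positions(track, samples)
    zen = solar.solar_position(samples, lon, lat)
    alt = 90.0 - np.asarray(zen)
    alt_cross = 90.0 - zenith_deg
    alt0 = alt_cross + transfer_width * np.log(LIGHT_MAX / threshold - 1.0)
    light = LIGHT_MAX / (1.0 + np.exp(-(alt - alt0) / transfer_width))
    if shading_bouts:
        mask = np.zeros(len(samples), dtype=bool)
        for s, e in shading_bouts:
            mask |= (samples >= pd.Timestamp(s)) & (samples < pd.Timestamp(e))
        light = np.where(mask, light * 0.02, light)
    if noise_sd > 0:
        light = light + rng.normal(0.0, noise_sd, size=len(light))
    nwin = len(samples) // 10
    win = light[: nwin * 10].reshape(nwin, 10)
    rec = np.clip(np.round(win.max(axis=1)), 0, LIGHT_MAX).astype(int)
    wtimes = samples[: nwin * 10 : 10]
    return pd.DataFrame({"time": wtimes, "light": rec})


def true_twilights(track: pd.DataFrame, zenith_deg: float = 96.0) -> pd.DataFrame:
    """Analytic twilight times along a track (one rise/set per civil day).

    Uses the position interpolated to each day's local noon; polar days
    and nights yield no entries.
    """
    t = pd.DatetimeIndex(track["time"])
    days = pd.date_range(t[0].normalize(), t[-1].normalize(), freq="1D")
    noons = days + pd.Timedelta(hours=12)
    lon, lat = _interp_positions(track, pd.DatetimeIndex(noons))
    rows = []
    for d, lo, la in zip(days, lon, lat):
        rise, sett = solar.twilight_times([d], float(lo), float(la), zenith_deg)
        if not pd.isna(rise[0]):
            rows.append({"time": rise[0], "kind": "rise", "quality": "ok"})
        if not pd.isna(sett[0]):
            rows.append({"time": sett[0], "kind": "set", "quality": "ok"})
    out = pd.DataFrame(rows, columns=["time", "kind", "quality"])
    return out.sort_values("time").reset_index(drop=True)


def perturb_twilights(twilights: pd.DataFrame, error_model, seed: int | None = None) -> pd.DataFrame:
    """Displace twilight times toward darkness with draws from an error model.

    Rises are delayed and sets advanced by eps = X - shift, X log-normal,
    matching the observation model used by the movement posterior.
    """
    rng = np.random.default_rng(seed)
    out = twilights.copy().reset_index(drop=True)
    eps = error_model.rvs(rng, len(out))
    sign = np.where(out["kind"].to_numpy() == "rise", 1.0, -1.0)
    out["time"] = pd.DatetimeIndex(out["time"]) + pd.to_timedelta(sign * eps, unit="m")
    return out.sort_values("time").reset_index(drop=True)


# ---------------------------------------------------------------------------
# immersion

def render_immersion(track: pd.DataFrame, schedule: HauloutSchedule,
                     seed: int | None = None,
                     dip_rate: float = 0.08) -> tuple[pd.DataFrame, GroundTruth]:
    """Render a 10-min immersion-count record plus true haul-out bouts.

    An hourly two-state process: at sea, a bout starts with the schedule's
    hazard; a bout lasts at least ``min_bout`` hours and then continues
    hour-by-hour with probability ``persistence``.  Records are 0 while
    hauled out, 200 at sea with occasional surfacing dips in [150, 199].
    """
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(track["time"].iloc[0]).floor("h")
    t1 = pd.Timestamp(track["time"].iloc[-1]).floor("h")
    hours = pd.date_range(t0, t1, freq="1h")
    week = hours.isocalendar().week.to_numpy().astype(float)
    hazard = schedule.start_hazard(hours.hour.to_numpy().astype(float), week)

    bouts = []
    i = 0
    n = len(hours)
    while i < n:
        if rng.uniform() < hazard[i]:
            start = hours[i]
            dur = schedule.min_bout
            while i + int(np.ceil(dur)) < n and rng.uniform() < schedule.persistence:
                dur += 1.0
            end = start + pd.Timedelta(hours=dur)
            if end > hours[-1] + pd.Timedelta(hours=1):
                end = hours[-1] + pd.Timedelta(hours=1)
            bouts.append((start, end))
            i += int(np.ceil(dur))
        i += 1
    bouts_df = pd.DataFrame(bouts, columns=["start", "end"])

    wtimes = pd.date_range(t0, t1, freq=WINDOW)
    counts = np.full(len(wtimes), WET_TESTS_PER_WINDOW, dtype=int)
    dips = rng.uniform(size=len(wtimes)) < dip_rate
    counts[dips] = rng.integers(150, 200, size=int(dips.sum()))
    for s, e in bouts:
        dry = (wtimes >= s) & (wtimes + WINDOW <= e)
        counts[dry] = 0
    rec = pd.DataFrame({"time": wtimes, "wet_count": counts})
    truth = GroundTruth(true_bouts=bouts_df,
                        generator_params={"schedule": asdict(schedule), "seed": seed})
    return rec, truth


# ---------------------------------------------------------------------------
# environment

@dataclass
class EnvGrids:
    """Analytic environment rasters on a shared lon/lat grid.

    ``depth`` is signed elevation (negative below sea level, >= 0 on land);
    SST comes in 53 weekly and 12 monthly slices, ice concentration (%) in
    12 monthly slices.
    """

    lons: np.ndarray
    lats: np.ndarray
    depth: np.ndarray                 # (nlat, nlon)
    sst_weekly: np.ndarray            # (53, nlat, nlon); slices may be NaN (missing)
    sst_monthly: np.ndarray           # (12, nlat, nlon)
    ice_monthly: np.ndarray           # (12, nlat, nlon)
    land_polygons: Sequence[Polygon]
    ice_edge_by_month: Sequence[float]

    def _index(self, lon, lat):
        # nearest-centre lookup
        i = np.clip(np.rint((np.asarray(lat, dtype=float) - self.lats[0])
                            / (self.lats[1] - self.lats[0])).astype(int), 0, len(self.lats) - 1)
        j = np.clip(np.rint((np.asarray(lon, dtype=float) - self.lons[0])
                            / (self.lons[1] - self.lons[0])).astype(int), 0, len(self.lons) - 1)
        return i, j

    def sample_depth(self, lon, lat):
        i, j = self._index(lon, lat)
        return self.depth[i, j]

    def on_land(self, lon, lat):
        return self.sample_depth(lon, lat) >= 0.0

    def sample_ice(self, month, lon, lat):
        i, j = self._index(lon, lat)
        m = np.clip(np.asarray(month, dtype=int) - 1, 0, 11)
        return self.ice_monthly[m, i, j]

    def sample_sst(self, week, month, lon, lat):
        """Weekly SST with monthly fallback where the weekly slice is missing."""
        i, j = self._index(lon, lat)
        w = np.clip(np.asarray(week, dtype=int) - 1, 0, 52)
        m = np.clip(np.asarray(month, dtype=int) - 1, 0, 11)
        weekly = self.sst_weekly[w, i, j]
        monthly = self.sst_monthly[m, i, j]
        return np.where(np.isfinite(weekly), weekly, monthly)


def simulate_environment(spec: EnvFieldSpec) -> EnvGrids:
    """Build depth, SST and ice rasters from an analytic specification.

    Depth is ``-depth_gradient`` metres per km offshore (signed positive
    inland); SST increases equatorward at ``sst_lat_gradient`` with a
    seasonal sinusoid; ice concentration ramps from 0 at the month's edge
    latitude to 100% over ``ice_ramp_width_deg`` poleward (southern-
    hemisphere convention: poleward = more negative latitude).
    """
    lon0, lon1, lat0, lat1 = spec.grid_extent
    lons = np.arange(lon0 + spec.resolution / 2, lon1, spec.resolution)
    lats = np.arange(lat0 + spec.resolution / 2, lat1, spec.resolution)
    glon, glat = np.meshgrid(lons, lats)

    # signed distance to coastline via a KD-tree on densified boundary vertices
    bpts = []
    for poly in spec.land_polygons:
        bnd = poly.exterior.segmentize(0.05)
        bpts.append(np.asarray(bnd.coords))
    bpts = np.vstack(bpts)
    tree = cKDTree(unit_vectors(bpts[:, 0], bpts[:, 1]))
    cells = unit_vectors(glon.ravel(), glat.ravel())
    chord, _ = tree.query(cells)
    dist_km = chord_to_arc_km(chord).reshape(glat.shape)
    inside = np.zeros(glat.shape, dtype=bool)
    for poly in spec.land_polygons:
        minx, miny, maxx, maxy = poly.bounds
        cand = (glon >= minx) & (glon <= maxx) & (glat >= miny) & (glat <= maxy)
        if cand.any():
            ii = np.nonzero(cand.ravel())[0]
            from shapely import points as _shp_points, contains as _shp_contains
            pts = _shp_points(glon.ravel()[ii], glat.ravel()[ii])
            hit = _shp_contains(poly, pts)
            flat = inside.ravel()
            flat[ii] |= hit
            inside = flat.reshape(glat.shape)
    depth = np.where(inside, spec.depth_gradient * dist_km, -spec.depth_gradient * dist_km)

    # SST: equatorward = decreasing |lat|
    ref = np.abs([lat0, lat1]).max()
    base = spec.sst_base + spec.sst_lat_gradient * (ref - np.abs(glat))
    weeks = np.arange(1, 54)
    months = np.arange(1, 13)
    sst_weekly = base[None] + spec.sst_seasonal_amplitude * np.cos(
        2 * np.pi * (weeks[:, None, None] - 5.0) / 52.0)
    sst_monthly = base[None] + spec.sst_seasonal_amplitude * np.cos(
        2 * np.pi * ((months[:, None, None] - 1) * 4.33 + 2 - 5.0) / 52.0)

    edges = np.asarray(spec.ice_edge_latitude_by_month, dtype=float)
    ice = np.clip((edges[:, None, None] - glat[None]) / spec.ice_ramp_width_deg,
                  0.0, 1.0) * 100.0
    return EnvGrids(lons=lons, lats=lats, depth=depth,
                    sst_weekly=sst_weekly, sst_monthly=sst_monthly,
                    ice_monthly=ice, land_polygons=list(spec.land_polygons),
                    ice_edge_by_month=list(edges))
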