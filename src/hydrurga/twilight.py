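"""Twilight detection, tag calibration and single-day threshold positioning.

The threshold method: a twilight is the moment recorded light crosses a
calibrated threshold; longitude follows from the rise/set midpoint versus
solar noon, latitude from the day length via the sunrise equation at the
calibrated twilight zenith angle.

Twilight sequences are plain DataFrames with columns ``time`` (UTC),
``kind`` ('rise'|'set') and ``quality`` ('ok'|'suspect_shading'|
'interpolated').  Dark runs shorter than ``min_dark_hours`` flanked by
bright windows are body-shading artefacts (hauled-out animals covering the
sensor) and are flagged, not emitted as twilights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import solar
from .geodesy import wrap_lon


@dataclass(frozen=True)
class CalibrationResult:
    """Zenith/threshold pair minimizing twilight-time residuals at a known site."""

    zenith_deg: float
    light_threshold: float
    residual_spread: float  # RMS of (observed - predicted) twilight times, minutes

    def __post_init__(self):
        if not 0.0 < self.zenith_deg < 108.0:
            raise ValueError("twilight zenith angle must lie in (0, 108) degrees")


class ThresholdPosition(NamedTuple):
    lon: float
    lat: float
    lat_quality: str  # 'ok' | 'equinox_degenerate' | 'no_solution'


def detect_twilights(lights: pd.DataFrame, threshold: float,
                     rise_offset: str | pd.Timedelta = "9min",
                     min_dark_hours: float = 2.0,
                     min_bright_hours: float = 0.5,
                     gap_flag: str | pd.Timedelta = "20min") -> pd.DataFrame:
    """Detect threshold crossings in a 10-min max-light record.

    The logger stamps each window with its start time but records the
    maximum of 60-s samples, so on a rising limb the recorded value was
    attained near the window's end: rise crossings are shifted forward by
    ``rise_offset`` (window length minus one sample).  Crossing times are
    linearly interpolated in light between the bracketing windows.

    Short dark runs inside the bright span (< ``min_dark_hours``) and short
    bright blips (< ``min_bright_hours``) are flagged ``suspect_shading``.
    Crossings interpolated across record gaps (> ``gap_flag``) are flagged
    ``interpolated``.
    """
    t = pd.DatetimeIndex(pd.to_datetime(lights["time"], utc=True)).tz_convert(None)
    if len(t) and not t.is_monotonic_increasing:
        raise ValueError("light records must be sorted by time")
    light = np.asarray(lights["light"], dtype=float)
    if len(t) < 2:
        return _empty_twilights()
    rise_offset = pd.Timedelta(rise_offset)
    gap_flag = pd.Timedelta(gap_flag)

    above = light > threshold
    change = np.nonzero(above[1:] != above[:-1])[0]
    rows = []
    for i in change:
        is_rise = above[i + 1]
        l0, l1 = light[i], light[i + 1]
        frac = 0.5 if l1 == l0 else (threshold - l0) / (l1 - l0)
        dt = t[i + 1] - t[i]
        tc = t[i] + frac * dt
        if is_rise:
            tc = tc + rise_offset
        rows.append({"time": tc, "kind": "rise" if is_rise else "set",
                     "quality": "interpolated" if dt > gap_flag else "ok"})
    if not rows:
        return _empty_twilights()
    tw = pd.DataFrame(rows).sort_values("time").reset_index(drop=True)

    # shading filter: short dark (set->rise) or bright (rise->set) intervals
    times = tw["time"].to_numpy()
    kinds = tw["kind"].to_numpy()
    for i in range(len(tw) - 1):
        span_h = (times[i + 1] - times[i]) / np.timedelta64(1, "s") / 3600.0
        if kinds[i] == "set" and kinds[i + 1] == "rise" and span_h < min_dark_hours:
            tw.loc[i, "quality"] = "suspect_shading"
            tw.loc[i + 1, "quality"] = "suspect_shading"
        elif kinds[i] == "rise" and kinds[i + 1] == "set" and span_h < min_bright_hours:
            tw.loc[i, "quality"] = "suspect_shading"
            tw.loc[i + 1, "quality"] = "suspect_shading"
    return tw


def _empty_twilights() -> pd.DataFrame:
    return pd.DataFrame({"time": pd.DatetimeIndex([]), "kind": pd.Series([], dtype=str),
                         "quality": pd.Series([], dtype=str)})


def filter_ok(twilights: pd.DataFrame) -> pd.DataFrame:
    """Keep only clean crossings (quality == 'ok')."""
    return twilights[twilights["quality"] == "ok"].reset_index(drop=True)


def pair_twilights(twilights: pd.DataFrame, max_span_hours: float = 24.0) -> pd.DataFrame:
    """Pair each clean rise with the following clean set within `max_span_hours`.

    Returns a DataFrame with columns ``rise`` and ``set``.
    """
    ok = filter_ok(twilights)
    pairs = []
    i = 0
    rec = ok.to_dict("records")
    while i < len(rec) - 1:
        if rec[i]["kind"] == "rise" and rec[i + 1]["kind"] == "set":
            span = (rec[i + 1]["time"] - rec[i]["time"]).total_seconds() / 3600.0
            if 0.0 < span < max_span_hours:
                pairs.append({"rise": rec[i]["time"], "set": rec[i + 1]["time"]})
                i += 2
                continue
        i += 1
    return pd.DataFrame(pairs, columns=["rise", "set"])


def calibrate(lights: pd.DataFrame, known_lonlat,
              candidate_zeniths=None, candidate_thresholds=None) -> CalibrationResult:
    """Grid-search the (zenith, threshold) pair for a tag fixed at a known site.

    For each candidate threshold the twilights are detected once; for each
    candidate zenith the rise/set times predicted at the known location are
    matched to the nearest detection and the RMS residual (minutes)
    computed.  The minimizing pair is returned.
    """
    if candidate_zeniths is None:
        candidate_zeniths = np.arange(90.0, 100.25, 0.25)
    if candidate_thresholds is None:
        candidate_thresholds = np.arange(2.0, 33.0, 1.0)
    t = pd.to_datetime(lights["time"], utc=True)
    span_days = (t.max() - t.min()).total_seconds() / 86400.0
    if span_days < 14.0:
        raise ValueError("calibration needs at least 14 days of records at the known site")
    lon, lat = float(known_lonlat[0]), float(known_lonlat[1])
    days = pd.DatetimeIndex(t.dt.tz_convert(None).dt.normalize().unique()).sort_values()

    best = None
    for thr in candidate_thresholds:
        tw = filter_ok(detect_twilights(lights, thr))
        if len(tw) < 4:
            continue
        obs_rise = tw.loc[tw["kind"] == "rise", "time"].to_numpy()
        obs_set = tw.loc[tw["kind"] == "set", "time"].to_numpy()
        for z in candidate_zeniths:
            pred_rise, pred_set = solar.twilight_times(days, lon, lat, float(z))
            res = np.concatenate([
                _nearest_residual_minutes(obs_rise, pred_rise),
                _nearest_residual_minutes(obs_set, pred_set),
            ])
            if len(res) < 4:
                continue
            spread = float(np.sqrt(np.mean(res ** 2)))
            if best is None or spread < best[0]:
                best = (spread, float(z), float(thr))
    if best is None:
        raise ValueError("no candidate (zenith, threshold) pair produced twilight crossings")
    spread, z, thr = best
    return CalibrationResult(zenith_deg=z, light_threshold=thr, residual_spread=spread)


def _nearest_residual_minutes(obs, pred, max_minutes: float = 240.0) -> np.ndarray:
    pred = pd.DatetimeIndex(pred).dropna()
    if len(pred) == 0 or len(obs) == 0:
        return np.empty(0)
    obs = pd.DatetimeIndex(obs).asi8[:, None]
    predi = pred.asi8[None, :]
    diff = (obs - predi) / 60e9
    j = np.argmin(np.abs(diff), axis=1)
    res = diff[np.arange(len(obs)), j]
    return res[np.abs(res) <= max_minutes]


def threshold_position(rise, set_, zenith_deg: float,
                       lat_hint: float | None = None) -> ThresholdPosition:
    """Longitude and latitude from one rise/set pair.

    Longitude from the rise/set midpoint versus solar noon (equation of
    time applied); latitude solves the sunrise equation for the day length
    at the midpoint declination.  Within 10 days of an equinox the latitude
    is retained but flagged ``equinox_degenerate``.
    """
    rise = pd.Timestamp(rise)
    set_ = pd.Timestamp(set_)
    if rise.tz is not None:
        rise = rise.tz_convert("UTC").tz_localize(None)
    if set_.tz is not None:
        set_ = set_.tz_convert("UTC").tz_localize(None)
    if not rise < set_ <= rise + pd.Timedelta(hours=24):
        raise ValueError("rise must precede set within 24 h")
    tmid = rise + (set_ - rise) / 2
    decl, eot = solar.solar_coordinates([tmid])
    decl, eot = float(decl[0]), float(eot[0])
    noon_min = tmid.hour * 60 + tmid.minute + tmid.second / 60.0 + tmid.microsecond / 6e7
    lon = float(wrap_lon((720.0 - eot - noon_min) / 4.0))

    day_hours = (set_ - rise).total_seconds() / 3600.0
    target = np.cos(np.radians(day_hours * 15.0 / 2.0))

    def g(phi):
        return solar.cos_hour_angle(phi, decl, zenith_deg) - target

    grid = np.linspace(-89.9, 89.9, 360)
    vals = g(grid)
    roots = []
    for i in range(len(grid) - 1):
        if np.isfinite(vals[i]) and np.isfinite(vals[i + 1]) and vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-8))
    quality = "equinox_degenerate" if bool(solar.near_equinox([tmid])[0]) else "ok"
    if not roots:
        # near the equinoxes a ~12-h day is consistent with every latitude
        # (or none, once the twilight zenith offset is applied): keep the
        # longitude, flag the latitude
        q = quality if quality == "equinox_degenerate" else "no_solution"
        return ThresholdPosition(lon=lon, lat=np.nan, lat_quality=q)
    if lat_hint is not None:
        lat = min(roots, key=lambda r: abs(r - lat_hint))
    else:
        lat = min(roots, key=abs)
    return ThresholdPosition(lon=lon, lat=float(lat), lat_quality=quality)
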