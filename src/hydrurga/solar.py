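"""Solar geometry for light-level geolocation.

Implements the NOAA low-accuracy solar position formulae (declination,
equation of time, zenith angle) and the sunrise equation.  Accuracy is a
few hundredths of a degree in zenith, far below the ~10-min cadence of the
light loggers this package analyses.

Day length is the core geolocation primitive: for a twilight defined by a
solar zenith angle ``z`` the half-day hour angle ``H`` satisfies

    cos H = (cos z - sin(lat) sin(dec)) / (cos(lat) cos(dec))

Longitude comes from the timing of local solar noon (the rise/set
midpoint), latitude from the day length given the sun's declination.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Sentinel day lengths for polar conditions.
POLAR_DAY = np.inf
POLAR_NIGHT = -np.inf


def _julian_century(times) -> np.ndarray:
    t = pd.DatetimeIndex(pd.to_datetime(times, utc=True)).tz_convert(None)
    jd = t.astype("int64") / 1e9 / 86400.0 + 2440587.5
    return np.asarray((jd - 2451545.0) / 36525.0)


def solar_coordinates(times):
    """Solar declination (degrees) and equation of time (minutes) at `times`.

    Vectorized over an array/DatetimeIndex of UTC timestamps.
    """
    jc = _julian_century(times)
    l0 = np.mod(280.46646 + jc * (36000.76983 + jc * 0.0003032), 360.0)
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mrad = np.radians(m)
    c = (np.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
         + np.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
         + np.sin(3 * mrad) * 0.000289)
    true_long = l0 + c
    omega = np.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos(omega)
    obl_rad = np.radians(obliq)
    decl = np.degrees(np.arcsin(np.sin(obl_rad) * np.sin(np.radians(app_long))))
    y = np.tan(obl_rad / 2.0) ** 2
    l0r = np.radians(l0)
    eot = 4.0 * np.degrees(
        y * np.sin(2 * l0r)
        - 2.0 * ecc * np.sin(mrad)
        + 4.0 * ecc * y * np.sin(mrad) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r)
        - 1.25 * ecc * ecc * np.sin(2 * mrad)
    )
    return decl, eot


def solar_position(times, lon, lat):
    """Solar zenith angle in degrees at UTC `times` for positions (`lon`, `lat`).

    All arguments broadcast; refraction is not applied (a calibrated
    twilight zenith angle absorbs the constant offset).
    """
    t = pd.DatetimeIndex(pd.to_datetime(times, utc=True)).tz_convert(None)
    decl, eot = solar_coordinates(t)
    minutes = (t.hour * 60 + t.minute + t.second / 60.0 + t.microsecond / 6e7).to_numpy()
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    tst = np.mod(minutes + eot + 4.0 * lon, 1440.0)
    ha = tst / 4.0 - 180.0
    latr = np.radians(lat)
    declr = np.radians(decl)
    cosz = (np.sin(latr) * np.sin(declr)
            + np.cos(latr) * np.cos(declr) * np.cos(np.radians(ha)))
    z = np.degrees(np.arccos(np.clip(cosz, -1.0, 1.0)))
    return z if z.shape else float(z)


def cos_hour_angle(lat, declination, zenith_deg):
    """cos(H) from the sunrise equation; values outside [-1, 1] signal polar conditions."""
    latr = np.radians(np.asarray(lat, dtype=float))
    dr = np.radians(np.asarray(declination, dtype=float))
    zr = np.radians(float(zenith_deg))
    denom = np.cos(latr) * np.cos(dr)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (np.cos(zr) - np.sin(latr) * np.sin(dr)) / denom


def daylength(lat, declination, zenith_deg):
    """Hours between the twilight crossings, or a polar sentinel.

    Returns hours in (0, 24) where the sun crosses the given zenith angle,
    ``POLAR_DAY`` (+inf) when it never gets that low, and ``POLAR_NIGHT``
    (-inf) when it never gets that high.  Vectorized.
    """
    ch = cos_hour_angle(lat, declination, zenith_deg)
    scalar = np.ndim(ch) == 0
    ch = np.atleast_1d(np.asarray(ch, dtype=float))
    out = np.empty_like(ch)
    ok = (ch >= -1.0) & (ch <= 1.0)
    out[ok] = 2.0 * np.degrees(np.arccos(ch[ok])) / 15.0
    out[ch < -1.0] = POLAR_DAY
    out[ch > 1.0] = POLAR_NIGHT
    return float(out[0]) if scalar else out


def twilight_times(dates, lon, lat, zenith_deg):
    """Predicted UTC rise and set times for civil `dates` at a fixed position.

    `dates` is anything convertible to normalized timestamps.  Returns two
    DatetimeIndex (rise, set) with NaT for polar days/nights.  One
    refinement pass evaluates the solar coordinates near the event itself,
    which brings errors below ~10 s.
    """
    days = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    if days.tz is not None:
        days = days.tz_convert("UTC").tz_localize(None)
    lon = float(lon)
    lat = float(lat)
    # first guess at local solar noon
    guess = days + pd.Timedelta(hours=12) - pd.to_timedelta(lon / 15.0, unit="h")
    rise, sett = _rise_set_once(days, guess, guess, lon, lat, zenith_deg)
    # refine with coordinates evaluated at the first-pass event times
    rise_t = days + pd.to_timedelta(np.where(np.isfinite(rise), rise, 720.0), unit="m")
    set_t = days + pd.to_timedelta(np.where(np.isfinite(sett), sett, 720.0), unit="m")
    rise, sett = _rise_set_once(days, rise_t, set_t, lon, lat, zenith_deg)
    rise_out = days + pd.to_timedelta(np.where(np.isfinite(rise), rise, np.nan), unit="m")
    set_out = days + pd.to_timedelta(np.where(np.isfinite(sett), sett, np.nan), unit="m")
    return rise_out, set_out


def _rise_set_once(days, rise_ref, set_ref, lon, lat, zenith_deg):
    decl_r, eot_r = solar_coordinates(rise_ref)
    decl_s, eot_s = solar_coordinates(set_ref)
    out = []
    for decl, eot, sign in ((decl_r, eot_r, -1.0), (decl_s, eot_s, +1.0)):
        ch = cos_hour_angle(lat, decl, zenith_deg)
        ha = np.where((ch >= -1.0) & (ch <= 1.0),
                      np.degrees(np.arccos(np.clip(ch, -1.0, 1.0))), np.nan)
        noon = 720.0 - 4.0 * lon - eot
        out.append(noon + sign * 4.0 * ha)
    return out[0], out[1]


_EQUINOXES = ((3, 20), (9, 22))


def near_equinox(times, window_days: int = 10) -> np.ndarray:
    """Boolean mask: within `window_days` of a (nominal) equinox date.

    Latitude from day length is degenerate near the equinoxes; callers flag
    such twilights and inflate their observation error downstream.
    """
    t = pd.DatetimeIndex(pd.to_datetime(times))
    if t.tz is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    mask = np.zeros(len(t), dtype=bool)
    for yr_off in (-1, 0, 1):
        for month, day in _EQUINOXES:
            eq = pd.to_datetime({"year": t.year + yr_off,
                                 "month": month, "day": day})
            mask |= (np.abs((t.normalize() - pd.DatetimeIndex(eq)).days) <= window_days)
    return mask
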