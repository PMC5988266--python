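"""Hourly haul-out probability models and diel/seasonal summaries.

The response is the hourly haul-out state (1 = any overlap with a dry
bout).  Covariates: hour of day (diel, cyclic period 24), week of year /
month / Julian day (seasonal, cyclic), latitude, distance to the nearest
land polygon or the monthly ice edge (haversine), and lagged states of the
preceding hours (linear binary terms capturing bout persistence).  Fits
use the complementary log-log link — haul-out hours are the rarer outcome
— with individual (tag, with trip nested) as a ridge random effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .geodesy import haversine_km
from .pam import (PenalizedAdditiveModel, PAMResults, RandomEffectSpec,
                  SmoothSpec, adapt_basis_dim, compare)

__all__ = [
    "haversine_km", "distance_to_land_or_ice", "build_design", "ActivityModelSpec",
    "fit_activity", "candidate_specs", "select_activity_model", "diel_seasonal_summary",
]


def _densified_boundary(polygons, spacing_deg: float = 0.04) -> np.ndarray:
    pts = []
    for poly in polygons:
        pts.append(np.asarray(poly.exterior.segmentize(spacing_deg).coords))
    return np.vstack(pts)


def distance_to_land_or_ice(points, land_polygons, ice_edge_by_month,
                            month, spacing_deg: float = 0.04) -> np.ndarray:
    """Great-circle km to the nearest land-polygon boundary or monthly ice edge.

    ``points`` is (lon, lat) arrays.  Points inside a land polygon or
    poleward of the month's ice-edge latitude (southern-hemisphere
    convention: latitude <= edge) are at distance 0 — pack ice is haul-out
    substrate everywhere inside the edge.  Boundaries are densified to
    ~``spacing_deg`` (< 5 km) before the nearest-vertex search.
    """
    lon = np.atleast_1d(np.asarray(points[0], dtype=float))
    lat = np.atleast_1d(np.asarray(points[1], dtype=float))
    month = np.broadcast_to(np.asarray(month, dtype=int), lon.shape)
    if not land_polygons and ice_edge_by_month is None:
        raise ValueError("need land polygons or an ice edge")
    d = np.full(lon.shape, np.inf)
    if land_polygons:
        bnd = _densified_boundary(land_polygons, spacing_deg)
        for i in range(len(lon)):
            d[i] = haversine_km(lon[i], lat[i], bnd[:, 0], bnd[:, 1]).min()
        from shapely import contains, points as shp_points
        pts = shp_points(lon, lat)
        for poly in land_polygons:
            d[contains(poly, pts)] = 0.0
    if ice_edge_by_month is not None:
        edges = np.asarray(ice_edge_by_month, dtype=float)[month - 1]
        d_ice = np.where(lat <= edges,
                         0.0,
                         haversine_km(lon, lat, lon, edges))
        d = np.minimum(d, d_ice)
    return d if np.ndim(points[0]) else float(d[0])


def build_design(states: pd.DataFrame, path: pd.DataFrame,
                 land_polygons=None, ice_edge_by_month=None,
                 tag_id: str = "tag", trip_id: str = "trip",
                 n_lags: int = 3) -> pd.DataFrame:
    """One row per deployment hour with model covariates.

    ``states`` is the hourly haul-out series (hour_start, state);
    ``path`` a time-indexed lon/lat track (typically the pinned posterior
    mean path) interpolated to each hour.  The first ``n_lags`` hours of
    the trip are dropped (undefined lags).
    """
    hours = pd.DatetimeIndex(states["hour_start"])
    pt = pd.DatetimeIndex(path["time"]).asi8.astype(float)
    qt = hours.asi8.astype(float)
    if qt[0] > pt[-1] or qt[-1] < pt[0]:
        raise ValueError("states and path do not overlap in time")
    lon = np.interp(qt, pt, np.asarray(path["lon"], dtype=float))
    lat = np.interp(qt, pt, np.asarray(path["lat"], dtype=float))
    state = np.asarray(states["state"], dtype=int)
    df = pd.DataFrame({
        "tag": tag_id, "trip": trip_id,
        "hour_start": hours, "state": state,
        "hour_of_day": hours.hour.astype(float),
        "week": np.minimum(hours.isocalendar().week.to_numpy().astype(float), 53.0),
        "month": hours.month.astype(int),
        "julian_day": hours.dayofyear.astype(float),
        "latitude": lat,
        "longitude": lon,
    })
    if land_polygons is not None or ice_edge_by_month is not None:
        df["distance_km"] = distance_to_land_or_ice(
            (lon, lat), land_polygons or [], ice_edge_by_month, df["month"].to_numpy())
    else:
        df["distance_km"] = 0.0
    for k in range(1, n_lags + 1):
        df[f"lag{k}"] = df["state"].shift(k)
    df = df.iloc[n_lags:].reset_index(drop=True)
    for k in range(1, n_lags + 1):
        df[f"lag{k}"] = df[f"lag{k}"].astype(int)
    return df


@dataclass(frozen=True)
class ActivityModelSpec:
    """Structure of one candidate haul-out model."""

    name: str
    hour_by: str | None = "month"       # by-factor for the diel smooth
    season: str = "week"                # 'week' | 'month' | 'julian_day'
    season_by: str | None = "tag"
    latitude_by: str | None = None      # None = plain smooth
    distance_by: str | None = "tag"
    lags: tuple[int, ...] = (1, 2, 3)
    random_effect: bool = True

    def smooths(self) -> list[SmoothSpec]:
        out = [SmoothSpec("hour_of_day", basis_dim=10, cyclic=True, period=24.0,
                          by_factor=self.hour_by)]
        period = {"week": 53.0, "month": 12.0, "julian_day": 366.0}[self.season]
        out.append(SmoothSpec(self.season, basis_dim=10, cyclic=True, period=period,
                              by_factor=self.season_by))
        out.append(SmoothSpec("latitude", basis_dim=8, by_factor=self.latitude_by))
        out.append(SmoothSpec("distance_km", basis_dim=8, by_factor=self.distance_by))
        return out

    def linear(self) -> list[str]:
        return [f"lag{k}" for k in self.lags]


def default_best_model() -> ActivityModelSpec:
    """The selected structure: diel by month, seasonal week, distance and
    week grouped by tag, latitude by week group, lags 1-3."""
    return ActivityModelSpec(name="hour(by month) + s(week, by tag) + s(latitude) "
                                  "+ s(distance, by tag) + lag1 + lag2 + lag3")


def fit_activity(design: pd.DataFrame, model_spec: ActivityModelSpec | None = None,
                 penalty_selection: str = "reml",
                 lambdas: Sequence[float] | None = None) -> PAMResults:
    """Cloglog penalized additive fit of the hourly haul-out series."""
    spec = model_spec or default_best_model()
    smooths = []
    for s in spec.smooths():
        by = s.by_factor
        if by == "drop":   # term removed from this candidate
            continue
        if by is not None and design[by].nunique() < 2:
            s = SmoothSpec(s.covariate, s.basis_dim, s.cyclic, s.period, None, s.shrinkage)
        s = adapt_basis_dim(design[s.covariate], s)
        if s is None:
            continue  # degenerate covariate on this design (e.g. constant distance)
        smooths.append(s)
    re = None
    if spec.random_effect and design["tag"].nunique() > 1:
        re = RandomEffectSpec(("tag", "trip"))
    m = PenalizedAdditiveModel("state", design, linear=spec.linear(), smooths=smooths,
                               random_effect=re, link="cloglog")
    if lambdas is not None:
        return m.fit(penalty_selection="fixed", lambdas=lambdas)
    return m.fit(penalty_selection=penalty_selection)


def candidate_specs() -> list[ActivityModelSpec]:
    """The comparison family: the selected model plus the eleven variants
    (lag depth, smoother grouping, and seasonal-term alternatives)."""
    base = default_best_model()
    out = [base]
    out.append(ActivityModelSpec(name="+ lag4", lags=(1, 2, 3, 4)))
    out.append(ActivityModelSpec(name="- lag3", lags=(1, 2)))
    out.append(ActivityModelSpec(name="- distance(by tag)", distance_by="drop"))
    out.append(ActivityModelSpec(name="distance ungrouped", distance_by=None))
    out.append(ActivityModelSpec(name="week ungrouped", season_by=None))
    out.append(ActivityModelSpec(name="month(by tag) replacing week(by tag)",
                                 season="month"))
    out.append(ActivityModelSpec(name="julian_day(by tag) replacing week(by tag)",
                                 season="julian_day"))
    out.append(ActivityModelSpec(name="latitude ungrouped", latitude_by=None))
    out.append(ActivityModelSpec(name="latitude(by tag)", latitude_by="tag"))
    out.append(ActivityModelSpec(name="latitude(by month)", latitude_by="month"))
    out.append(ActivityModelSpec(name="hour(by tag)", hour_by="tag"))
    return out


def select_activity_model(design: pd.DataFrame,
                          candidates: Sequence[ActivityModelSpec] | None = None,
                          penalty_selection: str = "reml") -> pd.DataFrame:
    """Fit the candidate family and rank by AIC (stable tie-break by edf)."""
    candidates = list(candidates) if candidates is not None else candidate_specs()
    if len(candidates) < 2:
        raise ValueError("need at least two candidate specifications")
    fits = []
    names = []
    for spec in candidates:
        fits.append(fit_activity(design, spec, penalty_selection=penalty_selection))
        names.append(spec.name)
    return compare(fits, criterion="aic", names=names)


def diel_seasonal_summary(states: pd.DataFrame, trip_col: str | None = None) -> dict:
    """Hour-by-month and week(-by-trip) haul-out proportion matrices.

    Returns {'hour_month': DataFrame, 'hour_month_n': ..., 'week': ...};
    proportions are NaN where no hours were recorded.
    """
    df = states.copy()
    hours = pd.DatetimeIndex(df["hour_start"])
    df["hour_of_day"] = hours.hour
    df["month"] = hours.month
    df["week"] = np.minimum(hours.isocalendar().week.to_numpy().astype(int), 53)
    hm = df.pivot_table(index="hour_of_day", columns="month", values="state",
                        aggfunc="mean")
    hm_n = df.pivot_table(index="hour_of_day", columns="month", values="state",
                          aggfunc="count")
    if trip_col and trip_col in df.columns:
        wk = df.pivot_table(index="week", columns=trip_col, values="state",
                            aggfunc="mean")
    else:
        wk = df.groupby("week")["state"].mean().to_frame("proportion")
    return {"hour_month": hm, "hour_month_n": hm_n, "week": wk}
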