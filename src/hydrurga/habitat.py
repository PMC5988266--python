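"""Use-availability habitat association against correlated-random-walk nulls.

Observed ("use") locations come from the movement posterior: 100 chain-mean
paths by default, with the environmental covariate averaged over chains at
each time step so location uncertainty propagates into the design.
Availability is represented by 10 correlated-random-walk null tracks that
preserve the source track's step-length distribution (resampled with
replacement), draw turning angles uniformly, and carry a weak drift toward
the source's mean displacement bearing.  Binomial GAMs (logit link)
contrast use vs null rows over depth, ice concentration and SST in the
standard nine-candidate ladder: each covariate linear, each as a shrinkage
smooth, and the three pairwise linear sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodesy import destination, haversine_km, initial_bearing_deg
from .pam import (PenalizedAdditiveModel, SmoothSpec, PAMResults,
                  adapt_basis_dim, compare)
from .simulate import EnvGrids

logger = logging.getLogger(__name__)

COVARIATES = ("depth", "ice_concentration", "sst")


@dataclass
class HabitatConfig:
    n_use_chains: int = 100   # MCMC chains averaged per use row
    n_null_runs: int = 10     # CRW null-track replicates
    covariates: tuple = COVARIATES
    drift_weight: float = 0.3  # pull of null headings toward the mean bearing

    def __post_init__(self):
        if self.n_use_chains < 1 or self.n_null_runs < 1:
            raise ValueError("n_use_chains and n_null_runs must be >= 1")


def simulate_crw(track: pd.DataFrame, n_runs: int = 10, seed: int | None = None,
                 drift_weight: float = 0.3) -> list[pd.DataFrame]:
    """Correlated-random-walk null tracks from an estimated track.

    Step lengths are resampled with replacement from the source; headings
    are uniform with a weak drift toward the source's net displacement
    bearing; starts, step counts and time stamps match the source exactly.
    """
    if len(track) < 11:
        raise ValueError("need at least 10 steps in the source track")
    rng = np.random.default_rng(seed)
    lon = np.asarray(track["lon"], dtype=float)
    lat = np.asarray(track["lat"], dtype=float)
    steps = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    if np.all(steps == 0):
        raise ValueError("source track has zero step lengths")
    mean_brg = float(initial_bearing_deg(lon[0], lat[0], lon[-1], lat[-1]))
    n = len(steps)
    out = []
    for _ in range(n_runs):
        d = rng.choice(steps, size=n, replace=True)
        theta = rng.uniform(0.0, 2 * np.pi, size=n)
        # heading = direction of (1-w) * uniform unit vector + w * drift unit vector
        ux = (1 - drift_weight) * np.sin(theta) + drift_weight * np.sin(np.radians(mean_brg))
        uy = (1 - drift_weight) * np.cos(theta) + drift_weight * np.cos(np.radians(mean_brg))
        brg = np.degrees(np.arctan2(ux, uy))
        nl = np.empty(n + 1)
        na = np.empty(n + 1)
        nl[0], na[0] = lon[0], lat[0]
        for i in range(n):
            nl[i + 1], na[i + 1] = destination(nl[i], na[i], brg[i], d[i])
        out.append(pd.DataFrame({"time": track["time"].to_numpy(), "lon": nl, "lat": na}))
    return out


def _week_month(times: pd.DatetimeIndex):
    week = np.minimum(times.isocalendar().week.to_numpy().astype(int), 53)
    return week, times.month.to_numpy()


def _sample_env(env: EnvGrids, times, lon, lat):
    t = pd.DatetimeIndex(times)
    week, month = _week_month(t)
    return {
        "depth": env.sample_depth(lon, lat),
        "ice_concentration": env.sample_ice(month, lon, lat),
        "sst": env.sample_sst(week, month, lon, lat),
    }


def extract_covariates(results_or_tracks, env: EnvGrids,
                       haulout_states: pd.DataFrame | None = None,
                       config: HabitatConfig | None = None,
                       null_tracks: list[pd.DataFrame] | None = None,
                       seed: int | None = None) -> pd.DataFrame:
    """Build the use-availability design table.

    For use rows each time step's covariate is the mean over the chain
    ensemble's locations at that step (weekly SST, monthly fallback).
    Time steps whose hour is hauled out on land are discarded.  Null rows
    sample the covariates at the null-track locations.  Rows with
    non-finite covariates are dropped with a logged count.
    """
    config = config or HabitatConfig()
    if hasattr(results_or_tracks, "chain_mean_paths"):
        paths = results_or_tracks.chain_mean_paths(config.n_use_chains)
    else:
        paths = list(results_or_tracks)
    times = pd.DatetimeIndex(paths[0]["time"])
    lon_stack = np.stack([np.asarray(p["lon"], dtype=float) for p in paths])
    lat_stack = np.stack([np.asarray(p["lat"], dtype=float) for p in paths])
    cov_means = {}
    for name in config.covariates:
        vals = np.stack([
            _sample_env(env, times, lon_stack[c], lat_stack[c])[name]
            for c in range(len(paths))
        ])
        cov_means[name] = vals.mean(axis=0)
    mean_lon = lon_stack.mean(axis=0)
    mean_lat = lat_stack.mean(axis=0)

    keep = np.ones(len(times), dtype=bool)
    if haulout_states is not None and len(haulout_states):
        hs = haulout_states.set_index("hour_start")["state"]
        hours = times.floor("h")
        hauled = hs.reindex(hours).fillna(0).to_numpy().astype(bool)
        on_land = env.on_land(mean_lon, mean_lat)
        keep &= ~(hauled & on_land)
    use = pd.DataFrame({"time": times[keep], "response": 1, "source_run": -1})
    for name in config.covariates:
        use[name] = cov_means[name][keep]

    if null_tracks is None:
        src = pd.DataFrame({"time": times, "lon": mean_lon, "lat": mean_lat})
        null_tracks = simulate_crw(src, n_runs=config.n_null_runs, seed=seed,
                                   drift_weight=config.drift_weight)
    null_rows = []
    for run, nt in enumerate(null_tracks):
        nt_times = pd.DatetimeIndex(nt["time"])
        vals = _sample_env(env, nt_times, np.asarray(nt["lon"], dtype=float),
                           np.asarray(nt["lat"], dtype=float))
        d = pd.DataFrame({"time": nt_times, "response": 0, "source_run": run})
        for name in config.covariates:
            d[name] = vals[name]
        null_rows.append(d)
    table = pd.concat([use] + null_rows, ignore_index=True)
    finite = np.ones(len(table), dtype=bool)
    for name in config.covariates:
        finite &= np.isfinite(table[name].to_numpy())
    if (~finite).any():
        logger.warning("extract_covariates: dropped %d non-finite rows", int((~finite).sum()))
    table = table.loc[finite].reset_index(drop=True)
    if len(table) == 0:
        raise ValueError("use-availability table is empty after filtering")
    if table["response"].nunique() < 2:
        logger.warning("extract_covariates: only one response class remains "
                       "after filtering")
    return table


def _smooth_or_linear(values, name: str, max_dim: int = 10):
    """A SmoothSpec sized to the covariate, or None when too degenerate.

    Covariates with few distinct values (e.g. ice concentration on a track
    that never reaches the pack) cannot support a spline; the ladder then
    degrades that candidate to a linear term.
    """
    return adapt_basis_dim(values, SmoothSpec(name, basis_dim=max_dim, shrinkage=True))


def candidate_ladder(covariates=COVARIATES, table: pd.DataFrame | None = None) -> list[dict]:
    """The nine-candidate model ladder: linear singles, smooth singles, pairs."""
    cands = []
    for c in covariates:
        cands.append({"name": c, "linear": [c], "smooths": []})
    for c in covariates:
        spec = (_smooth_or_linear(table[c], c) if table is not None
                else SmoothSpec(c, basis_dim=10, shrinkage=True))
        if spec is None:
            cands.append({"name": f"s({c})", "linear": [c], "smooths": []})
        else:
            cands.append({"name": f"s({c})", "linear": [], "smooths": [spec]})
    for i in range(len(covariates)):
        for j in range(i + 1, len(covariates)):
            a, b = covariates[i], covariates[j]
            cands.append({"name": f"{a} + {b}", "linear": [a, b], "smooths": []})
    return cands


def fit_ladder(table: pd.DataFrame, covariates=COVARIATES,
               penalty_selection: str = "reml"):
    """Fit the candidate ladder and rank by log-likelihood.

    Returns (summary DataFrame ranked by log-likelihood, dict of fits,
    name of the selected model).
    """
    present = [c for c in covariates if c in table.columns]
    if len(present) < 2:
        raise ValueError("need at least two covariates in the table")
    cands = candidate_ladder(tuple(present), table=table)
    fits: dict[str, PAMResults] = {}
    for cand in cands:
        m = PenalizedAdditiveModel("response", table, linear=cand["linear"],
                                   smooths=cand["smooths"], link="logit")
        fits[cand["name"]] = m.fit(penalty_selection=penalty_selection)
    names = list(fits)
    summary = compare(list(fits.values()), criterion="loglik", names=names)
    summary["df"] = [3 + (1 if n.startswith("s(") else n.count("+"))
                     for n in summary["model"]]
    selected = summary["model"].iloc[0]
    return summary, fits, selected
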