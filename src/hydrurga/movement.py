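"""Bayesian posterior over a movement path from twilight times.

The model follows the threshold-geolocation state-space approach: one
location state per twilight, a log-normal prior on the great-circle speed
between successive states (arithmetic mean/SD on the km/h scale), known-
location days fixed, and a shifted log-normal observation model on the
minutes between observed and predicted twilight (errors run toward
darkness: shading can only delay a dawn or advance a dusk).

``MovementModel.fit`` runs Metropolis-within-Gibbs over the per-state
locations, sweeping forward through time on odd passes and backward on
even passes, with per-state Gaussian proposals (in km) whose scales adapt
during burn-in toward a 0.2-0.4 acceptance rate.  The retained, thinned
samples form a :class:`MovementResults` ensemble that carries location
uncertainty into the habitat and activity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar, twilight as _twilight
from .geodesy import haversine_km, gc_interpolate, wrap_lon
from .simulate import lognormal_params

KM_PER_DEG = 111.19493  # pi * R / 180 on the package sphere
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MovementPrior:
    """Log-normal speed prior; defaults are the tracked-seal PTT values."""

    mean_speed: float = 1.0  # km/h
    speed_sd: float = 0.9    # km/h

    def __post_init__(self):
        if self.mean_speed <= 0 or self.speed_sd <= 0:
            raise ValueError("prior mean and SD must be positive")

    @property
    def log_params(self) -> tuple[float, float]:
        return lognormal_params(self.mean_speed, self.speed_sd)


@dataclass(frozen=True)
class TwilightErrorModel:
    """Shifted log-normal on twilight-minute errors toward darkness.

    eps + shift ~ LogNormal(log(scale), sdlog); equinox-flagged twilights
    use scale * equinox_inflation (latitude is poorly identified there).
    """

    scale: float = 8.0       # minutes (median of the shifted error)
    shift: float = 2.0       # minutes; allows slightly "bright" errors
    sdlog: float = 0.7
    equinox_inflation: float = 3.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def logpdf(self, eps_minutes, equinox=False):
        scale = self.scale * np.where(equinox, self.equinox_inflation, 1.0)
        x = np.asarray(eps_minutes, dtype=float) + self.shift
        with np.errstate(divide="ignore", invalid="ignore"):
            lx = np.log(x)
            ll = (-lx - np.log(self.sdlog) - _LOG_SQRT_2PI
                  - (lx - np.log(scale)) ** 2 / (2.0 * self.sdlog ** 2))
        return np.where((x > 0) & np.isfinite(eps_minutes), ll, -np.inf)

    def rvs(self, rng, n):
        return rng.lognormal(np.log(self.scale), self.sdlog, size=n) - self.shift


def speed_log_prior(loc_a, loc_b, dt_hours, prior: MovementPrior,
                    speed_floor: float = 0.01):
    """Log-density of the implied speed between two locations.

    ``loc_a``/``loc_b`` are (lon, lat) pairs (arrays broadcast); speeds
    below ``speed_floor`` km/h are floored so that exactly repeated
    locations keep a finite density.
    """
    dt_hours = np.asarray(dt_hours, dtype=float)
    if np.any(dt_hours <= 0):
        raise ValueError("dt must be positive")
    d = haversine_km(loc_a[0], loc_a[1], loc_b[0], loc_b[1])
    v = np.maximum(d / dt_hours, speed_floor)
    mu, sig = prior.log_params
    lv = np.log(v)
    return -lv - np.log(sig) - _LOG_SQRT_2PI - (lv - mu) ** 2 / (2.0 * sig ** 2)


def twilight_log_likelihood(tw_row, lonlat, zenith_deg: float,
                            err: TwilightErrorModel) -> float:
    """Log-density of one observed twilight at a candidate location.

    Returns -inf when the location has no finite predicted twilight on
    that date (polar day/night).
    """
    t = pd.Timestamp(tw_row["time"])
    if t.tz is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    decl, eot = solar.solar_coordinates([t])
    state = {
        "obs_min": np.array([(t - t.normalize()).total_seconds() / 60.0]),
        "sin_dec": np.sin(np.radians(decl)), "cos_dec": np.cos(np.radians(decl)),
        "eot": eot,
        "kind_sign": np.array([1.0 if tw_row["kind"] == "rise" else -1.0]),
        "equinox": solar.near_equinox([t]),
    }
    ll = _twilight_ll_vec(np.atleast_1d(float(lonlat[0])), np.atleast_1d(float(lonlat[1])),
                          state, 0, zenith_deg, err)
    return float(ll[0])


def _twilight_ll_vec(lon, lat, st, k, zenith_deg, err: TwilightErrorModel):
    """Vectorized twilight log-likelihood for state k at chain locations."""
    latr = np.radians(lat)
    cosz = np.cos(np.radians(zenith_deg))
    ch = (cosz - np.sin(latr) * st["sin_dec"][k]) / (np.cos(latr) * st["cos_dec"][k])
    valid = (ch >= -1.0) & (ch <= 1.0)
    ha = np.degrees(np.arccos(np.clip(ch, -1.0, 1.0)))
    noon = 720.0 - 4.0 * lon - st["eot"][k]
    pred = noon - st["kind_sign"][k] * 4.0 * ha
    eps = st["kind_sign"][k] * (st["obs_min"][k] - pred)
    eps = (eps + 720.0) % 1440.0 - 720.0
    ll = err.logpdf(eps, equinox=bool(st["equinox"][k]))
    return np.where(valid, ll, -np.inf)


# ---------------------------------------------------------------------------
# polar-day handling

@dataclass(frozen=True)
class PolarGap:
    """A maximal run of civil days with no usable twilight and no fix."""

    start: pd.Timestamp       # first day without a twilight
    end: pd.Timestamp         # first day on which twilights resume
    n_days: int               # (end - start).days, the printed convention


def handle_polar_day(twilights: pd.DataFrame, fixes: pd.DataFrame | None = None,
                     min_gap_days: int = 2) -> list[PolarGap]:
    """Locate polar-day (or data-gap) runs in a twilight sequence.

    During such a run the light record carries no positional information;
    downstream covariate extraction pins the location to the last estimate
    before the run (the animal's last known position).
    """
    ok = _twilight.filter_ok(twilights)
    if len(ok) == 0:
        return []
    days = pd.DatetimeIndex(pd.to_datetime(ok["time"])).normalize()
    have = set(days)
    if fixes is not None and len(fixes):
        have |= set(pd.DatetimeIndex(pd.to_datetime(fixes["time"])).normalize())
    all_days = pd.date_range(min(have), max(have), freq="1D")
    missing = np.array([d not in have for d in all_days])
    gaps = []
    i = 0
    while i < len(all_days):
        if missing[i]:
            j = i
            while j < len(all_days) and missing[j]:
                j += 1
            if j - i >= min_gap_days:
                start = all_days[i]
                end = all_days[j] if j < len(all_days) else all_days[-1] + pd.Timedelta(days=1)
                gaps.append(PolarGap(start=start, end=end, n_days=(end - start).days))
            i = j
        else:
            i += 1
    return gaps


def pin_positions(times, lons, lats, state_times, gap_hours: float = 48.0):
    """Piecewise path interpolation that pins long gaps to the last position.

    ``state_times`` are the posterior state times; query ``times`` falling
    inside an inter-state interval longer than ``gap_hours`` take the
    position of the interval's left state (last known position) instead of
    being interpolated across the gap.
    """
    st = pd.DatetimeIndex(state_times).asi8.astype(float)
    qt = pd.DatetimeIndex(times).asi8.astype(float)
    lon_i = np.interp(qt, st, np.asarray(lons, dtype=float))
    lat_i = np.interp(qt, st, np.asarray(lats, dtype=float))
    gap_ns = gap_hours * 3600e9
    idx = np.clip(np.searchsorted(st, qt, side="right") - 1, 0, len(st) - 2)
    long_gap = (st[idx + 1] - st[idx]) > gap_ns
    inside = (qt > st[idx]) & (qt < st[idx + 1])
    pin = long_gap & inside
    lon_i[pin] = np.asarray(lons, dtype=float)[idx[pin]]
    lat_i[pin] = np.asarray(lats, dtype=float)[idx[pin]]
    return lon_i, lat_i


# ---------------------------------------------------------------------------
# model

class MovementModel:
    """Threshold-geolocation state-space model for one deployment.

    Parameters
    ----------
    twilights : DataFrame with columns time/kind/quality (only 'ok' rows used)
    fixes : optional DataFrame with columns time, lon, lat; every state on
        the civil day of a fix is held at the fix location and never proposed
    prior : MovementPrior speed prior
    error : TwilightErrorModel observation model
    zenith_deg : calibrated twilight zenith angle
    """

    def __init__(self, twilights: pd.DataFrame, fixes: pd.DataFrame | None = None,
                 prior: MovementPrior | None = None,
                 error: TwilightErrorModel | None = None,
                 zenith_deg: float = 96.0):
        self.prior = prior or MovementPrior()
        self.error = error or TwilightErrorModel()
        self.zenith_deg = float(zenith_deg)
        self._assemble_states(_twilight.filter_ok(twilights), fixes)
        if self.n_states < 2 and not self.fixed.any():
            raise ValueError("need at least two twilights or one fix")

    def _assemble_states(self, tw: pd.DataFrame, fixes: pd.DataFrame | None):
        times = pd.DatetimeIndex(pd.to_datetime(tw["time"]))
        if times.tz is not None:
            times = times.tz_convert("UTC").tz_localize(None)
        kinds = tw["kind"].to_numpy()
        rows = [{"time": t, "kind": k, "has_obs": True}
                for t, k in zip(times, kinds)]
        fix_lookup = {}
        if fixes is not None and len(fixes):
            ft = pd.DatetimeIndex(pd.to_datetime(fixes["time"]))
            if ft.tz is not None:
                ft = ft.tz_convert("UTC").tz_localize(None)
            tw_days = set(times.normalize())
            for t, lo, la in zip(ft, fixes["lon"], fixes["lat"]):
                day = t.normalize()
                fix_lookup[day] = (float(lo), float(la))
                if day not in tw_days:
                    rows.append({"time": day + pd.Timedelta(hours=12),
                                 "kind": "fix", "has_obs": False})
        df = pd.DataFrame(rows).sort_values("time").reset_index(drop=True)
        df = df.drop_duplicates(subset="time", keep="first").reset_index(drop=True)
        self.state_times = pd.DatetimeIndex(df["time"])
        self.n_states = len(df)
        self.has_obs = df["has_obs"].to_numpy(dtype=bool)
        days = self.state_times.normalize()
        self.fixed = np.array([d in fix_lookup for d in days])
        self.fixed_lon = np.array([fix_lookup.get(d, (np.nan, np.nan))[0] for d in days])
        self.fixed_lat = np.array([fix_lookup.get(d, (np.nan, np.nan))[1] for d in days])
        self.kinds = df["kind"].to_numpy()

        decl, eot = solar.solar_coordinates(self.state_times)
        self._st = {
            "obs_min": ((self.state_times - days).total_seconds() / 60.0).to_numpy()
            if hasattr((self.state_times - days), "total_seconds")
            else (self.state_times - days).to_numpy() / np.timedelta64(1, "m"),
            "sin_dec": np.sin(np.radians(decl)),
            "cos_dec": np.cos(np.radians(decl)),
            "eot": eot,
            "kind_sign": np.where(self.kinds == "rise", 1.0, -1.0),
            "equinox": solar.near_equinox(self.state_times),
        }
        self.dt_hours = np.diff(self.state_times.asi8) / 3600e9
        if np.any(self.dt_hours <= 0):
            raise ValueError("state times must be strictly increasing")

    # -- initialisation ----------------------------------------------------

    def initial_path(self) -> pd.DataFrame:
        """A feasible starting path balancing positions and transitions.

        Per-day threshold positions where a clean rise/set pair exists,
        fixes substituted, equinox-degenerate latitudes and polar gaps
        filled by interpolation, then speed-capped smoothing toward
        neighbour midpoints.  Raises if no finite-posterior path is found.
        """
        lon = np.full(self.n_states, np.nan)
        lat = np.full(self.n_states, np.nan)
        days = self.state_times.normalize()
        for day in pd.unique(days):
            sel = np.nonzero((days == day) & self.has_obs)[0]
            k = {self.kinds[i]: i for i in sel}
            if "rise" in k and "set" in k and k["rise"] < k["set"]:
                try:
                    pos = _twilight.threshold_position(
                        self.state_times[k["rise"]], self.state_times[k["set"]],
                        self.zenith_deg)
                except ValueError:
                    continue
                lon[sel] = pos.lon
                if pos.lat_quality == "ok":
                    lat[sel] = pos.lat
        lon[self.fixed] = self.fixed_lon[self.fixed]
        lat[self.fixed] = self.fixed_lat[self.fixed]
        if not np.isfinite(lon).any():
            raise ValueError("no twilight pair or fix yields a starting position")
        t = self.state_times.asi8.astype(float)
        for arr in (lon, lat):
            good = np.isfinite(arr)
            arr[~good] = np.interp(t[~good], t[good], arr[good])
        lon, lat = self._speed_cap_smooth(lon, lat)
        lp = self.log_posterior(lon, lat)
        if not np.isfinite(lp):
            lon, lat = self._grid_repair(lon, lat)
            lp = self.log_posterior(lon, lat)
        if not np.isfinite(lp):
            raise ValueError("initial path has non-finite posterior density; "
                             "check twilights/fixes for geometric conflicts")
        return pd.DataFrame({"time": self.state_times, "lon": lon, "lat": lat})

    def _speed_cap_smooth(self, lon, lat, n_iter: int = 300):
        cap = self.prior.mean_speed + 4.0 * self.prior.speed_sd
        lon, lat = lon.copy(), lat.copy()
        for _ in range(n_iter):
            v = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:]) / self.dt_hours
            if np.all(v <= cap):
                break
            bad = np.nonzero(v > cap)[0]
            idx = np.unique(np.concatenate([bad, bad + 1]))
            idx = idx[(idx > 0) & (idx < self.n_states - 1) & ~self.fixed[idx]]
            lon[idx] = 0.5 * lon[idx] + 0.25 * (lon[idx - 1] + lon[idx + 1])
            lat[idx] = 0.5 * lat[idx] + 0.25 * (lat[idx - 1] + lat[idx + 1])
        return lon, lat

    def _grid_repair(self, lon, lat, res: float = 2.0):
        """Coarse-grid likelihood scan for states stuck at -inf."""
        glon = np.arange(np.nanmin(lon) - 10, np.nanmax(lon) + 10 + res, res)
        glat = np.clip(np.arange(np.nanmin(lat) - 10, np.nanmax(lat) + 10 + res, res),
                       -89.0, 89.0)
        gg_lon, gg_lat = np.meshgrid(glon, glat)
        flat_lon, flat_lat = gg_lon.ravel(), gg_lat.ravel()
        for i in range(self.n_states):
            if self.fixed[i] or not self.has_obs[i]:
                continue
            if np.isfinite(_twilight_ll_vec(lon[i:i + 1], lat[i:i + 1], self._st, i,
                                            self.zenith_deg, self.error))[0]:
                continue
            ll = _twilight_ll_vec(flat_lon, flat_lat, self._st, i,
                                  self.zenith_deg, self.error)
            d = haversine_km(flat_lon, flat_lat, lon[i], lat[i])
            score = np.where(np.isfinite(ll), ll - d / 500.0, -np.inf)
            j = int(np.argmax(score))
            if np.isfinite(score[j]):
                lon[i], lat[i] = flat_lon[j], flat_lat[j]
        return lon, lat

    # -- densities ---------------------------------------------------------

    def log_posterior(self, lon, lat) -> float:
        """Log target density over the free states (lon/lat measure).

        The movement term is a proper random-walk transition kernel —
        log-normal speed times uniform heading — i.e. the speed density
        minus log(distance) (polar-coordinates Jacobian), plus the
        log(cos lat) area term of the lon/lat parameterisation.  Without
        the Jacobian the implied step prior is biased toward long steps
        (the area element grows with distance) and posterior speeds are
        systematically inflated.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        mu, sig = self.prior.log_params
        total = 0.0
        for i in range(self.n_states):
            if self.has_obs[i] and not self.fixed[i]:
                total += float(_twilight_ll_vec(lon[i:i + 1], lat[i:i + 1], self._st, i,
                                                self.zenith_deg, self.error)[0])
        total += float(np.sum(self._seg_ll(lon[:-1], lat[:-1], lon[1:], lat[1:],
                                           self.dt_hours, mu, sig)))
        total += float(np.sum(np.log(np.cos(np.radians(np.clip(lat[~self.fixed],
                                                               -89.5, 89.5))))))
        return total

    # -- sampling ----------------------------------------------------------

    def fit(self, n_chains: int = 4, n_iter: int = 2000, burn_in: float = 0.5,
            thin: int | None = None, seed: int | None = None,
            step_km: float = 40.0, max_kept_per_chain: int = 200,
            start: pd.DataFrame | None = None) -> "MovementResults":
        """Sample the location posterior by Metropolis-within-Gibbs.

        Forward sweeps on odd passes, backward on even; per-state proposal
        scales adapt during burn-in.  Deterministic under a fixed seed.
        """
        rng = np.random.default_rng(seed)
        init = start if start is not None else self.initial_path()
        lon0 = np.asarray(init["lon"], dtype=float)
        lat0 = np.asarray(init["lat"], dtype=float)
        n = self.n_states
        lon = np.tile(lon0, (n_chains, 1))
        lat = np.tile(lat0, (n_chains, 1))
        free = ~self.fixed
        jitter = rng.normal(0.0, 0.15, size=(2, n_chains, n))
        lon[:, free] += jitter[0][:, free]
        lat[:, free] += jitter[1][:, free]

        mu, sig = self.prior.log_params
        err = self.error
        zen = self.zenith_deg

        # -inf log-densities are floored so a chain that starts (or is
        # jittered) into the error model's hard support boundary can still
        # climb out; the floor is far below any reachable finite value.
        LL_FLOOR = -1e8
        tll = np.zeros((n_chains, n))
        for i in range(n):
            if self.has_obs[i] and free[i]:
                tll[:, i] = np.maximum(
                    _twilight_ll_vec(lon[:, i], lat[:, i], self._st, i, zen, err),
                    LL_FLOOR)
        sll = np.maximum(self._pair_ll(lon, lat), LL_FLOOR)

        n_burn = int(round(n_iter * burn_in))
        kept_iters = n_iter - n_burn
        if thin is None:
            thin = max(1, int(np.ceil(kept_iters / max_kept_per_chain)))
        n_kept = kept_iters // thin
        out_lon = np.empty((n_chains, n_kept, n))
        out_lat = np.empty((n_chains, n_kept, n))

        # lon-step conversion frozen at the initial-path latitude so the
        # proposal is exactly symmetric (adapting only the km scale)
        coslat_ref = np.cos(np.radians(np.clip(lat0, -89.0, 89.0)))
        steps = np.full(n, step_km)
        acc = np.zeros(n)
        prop = np.zeros(n)
        bstep = step_km
        bacc = 0
        bprop = 0
        adapt_every = 50
        kept = 0
        order_f = [i for i in range(n) if free[i]]
        order_b = order_f[::-1]
        for it in range(n_iter):
            order = order_f if it % 2 == 0 else order_b
            z = rng.normal(size=(2, n_chains, n))
            u = np.log(rng.uniform(size=(n_chains, n)))
            for i in order:
                dlat = z[0, :, i] * steps[i] / KM_PER_DEG
                dlon = z[1, :, i] * steps[i] / (KM_PER_DEG * coslat_ref[i])
                nlon = wrap_lon(lon[:, i] + dlon)
                nlat = lat[:, i] + dlat
                bad_lat = np.abs(nlat) > 89.5
                ntll = (np.maximum(_twilight_ll_vec(nlon, nlat, self._st, i, zen, err),
                                   LL_FLOOR)
                        if self.has_obs[i] else np.zeros(n_chains))
                delta = ntll - tll[:, i]
                delta = delta + (np.log(np.cos(np.radians(np.clip(nlat, -89.5, 89.5))))
                                 - np.log(np.cos(np.radians(np.clip(lat[:, i], -89.5, 89.5)))))
                if i > 0:
                    l_new = np.maximum(
                        self._seg_ll(lon[:, i - 1], lat[:, i - 1], nlon, nlat,
                                     self.dt_hours[i - 1], mu, sig), LL_FLOOR)
                    delta = delta + l_new - sll[:, i - 1]
                else:
                    l_new = None
                if i < n - 1:
                    r_new = np.maximum(
                        self._seg_ll(nlon, nlat, lon[:, i + 1], lat[:, i + 1],
                                     self.dt_hours[i], mu, sig), LL_FLOOR)
                    delta = delta + r_new - sll[:, i]
                else:
                    r_new = None
                accept = (u[:, i] < delta) & ~bad_lat
                if accept.any():
                    lon[accept, i] = nlon[accept]
                    lat[accept, i] = nlat[accept]
                    tll[accept, i] = ntll[accept]
                    if i > 0:
                        sll[accept, i - 1] = l_new[accept]
                    if i < n - 1:
                        sll[accept, i] = r_new[accept]
                acc[i] += accept.sum()
                prop[i] += n_chains
            # block-translation moves: shift a contiguous run of free states
            # by a common offset; these decorrelate the slow "cluster" modes
            # that single-site moves leave behind (residency phases, polar
            # gaps) so the prescribed iteration budgets actually mix.
            for _ in range(max(1, n // 20)):
                L = int(rng.integers(2, min(60, n) + 1))
                s0 = int(rng.integers(0, n))
                s1 = min(s0 + L, n)
                while s0 < s1 and not free[s0]:
                    s0 += 1
                e = s0
                while e < s1 and free[e]:
                    e += 1
                if e - s0 < 2:
                    continue
                off = rng.normal(size=2)
                u_blk = np.log(rng.uniform(size=n_chains))
                dlat = off[0] * bstep / KM_PER_DEG
                dlon = off[1] * bstep / (KM_PER_DEG * coslat_ref[s0:e].mean())
                nlon = wrap_lon(lon[:, s0:e] + dlon)
                nlat = lat[:, s0:e] + dlat
                if np.any(np.abs(nlat) > 89.5):
                    continue
                delta = (np.log(np.cos(np.radians(np.clip(nlat, -89.5, 89.5))))
                         - np.log(np.cos(np.radians(np.clip(lat[:, s0:e], -89.5, 89.5))))
                         ).sum(axis=1)
                ntll_blk = np.zeros((n_chains, e - s0))
                for i in range(s0, e):
                    if self.has_obs[i]:
                        ntll_blk[:, i - s0] = np.maximum(
                            _twilight_ll_vec(nlon[:, i - s0], nlat[:, i - s0],
                                             self._st, i, zen, err), LL_FLOOR)
                delta = delta + ntll_blk.sum(axis=1) - tll[:, s0:e].sum(axis=1)
                lo_edge = max(s0 - 1, 0)
                nlon_ext = np.concatenate([lon[:, lo_edge:s0], nlon, lon[:, e:e + 1]], axis=1)
                nlat_ext = np.concatenate([lat[:, lo_edge:s0], nlat, lat[:, e:e + 1]], axis=1)
                nsll = np.maximum(self._seg_ll(nlon_ext[:, :-1], nlat_ext[:, :-1],
                                               nlon_ext[:, 1:], nlat_ext[:, 1:],
                                               self.dt_hours[lo_edge:lo_edge + nlon_ext.shape[1] - 1],
                                               mu, sig), LL_FLOOR)
                old_sll = sll[:, lo_edge:lo_edge + nlon_ext.shape[1] - 1]
                delta = delta + nsll.sum(axis=1) - old_sll.sum(axis=1)
                accept = u_blk < delta
                if accept.any():
                    lon[np.ix_(accept, range(s0, e))] = nlon[accept]
                    lat[np.ix_(accept, range(s0, e))] = nlat[accept]
                    tll[np.ix_(accept, range(s0, e))] = ntll_blk[accept]
                    cols = range(lo_edge, lo_edge + nsll.shape[1])
                    sll[np.ix_(accept, cols)] = nsll[accept]
                bacc += accept.sum()
                bprop += n_chains
            if it < n_burn and (it + 1) % adapt_every == 0:
                rate = np.divide(acc, np.maximum(prop, 1))
                steps[free] = np.clip(steps[free] * np.exp(1.2 * (rate[free] - 0.3)),
                                      0.5, 2000.0)
                acc[:] = 0
                prop[:] = 0
                if bprop > 0:
                    bstep = float(np.clip(bstep * np.exp(1.2 * (bacc / bprop - 0.25)),
                                          0.5, 2000.0))
                    bacc = 0
                    bprop = 0
            if it >= n_burn and (it - n_burn) % thin == 0 and kept < n_kept:
                out_lon[:, kept, :] = lon
                out_lat[:, kept, :] = lat
                kept += 1
        rate = np.divide(acc, np.maximum(prop, 1), out=np.zeros(n), where=prop > 0)
        return MovementResults(model=self, lon=out_lon[:, :kept], lat=out_lat[:, :kept],
                               acceptance=rate)

    def _pair_ll(self, lon, lat):
        mu, sig = self.prior.log_params
        return self._seg_ll(lon[:, :-1], lat[:, :-1], lon[:, 1:], lat[:, 1:],
                            self.dt_hours, mu, sig)

    @staticmethod
    def _seg_ll(lon1, lat1, lon2, lat2, dt, mu, sig, speed_floor=0.01):
        """Random-walk transition log-density: log-normal speed, uniform heading.

        Equals the speed log-density minus log(distance); the distance term
        is the Jacobian of (distance, heading) -> position on the sphere.
        """
        v = np.maximum(haversine_km(lon1, lat1, lon2, lat2) / dt, speed_floor)
        lv = np.log(v)
        return (-lv - np.log(sig) - _LOG_SQRT_2PI - (lv - mu) ** 2 / (2.0 * sig ** 2)
                - np.log(v * dt))


# ---------------------------------------------------------------------------
# results

@dataclass
class GridSpec:
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float = 0.5  # degrees


@dataclass
class TimeSpentGrid:
    """Normalized time-weighted density raster over posterior path samples."""

    density: np.ndarray            # (nlat, nlon), sums to 1
    lon_edges: np.ndarray
    lat_edges: np.ndarray
    n_simulations: int
    clipped_hours: float           # weight falling outside the grid
    quantiles: dict = field(default_factory=dict)  # q -> (nlat, nlon) across simulations


def intermediate_locations(path: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Great-circle densification of a sampled path, time-weighted.

    Emits ``k`` points per segment at fractions (j - 1/2)/k, each carrying
    ``segment_hours / k`` so weights per segment sum to the elapsed time.
    """
    times = pd.DatetimeIndex(path["time"])
    lon = np.asarray(path["lon"], dtype=float)
    lat = np.asarray(path["lat"], dtype=float)
    fr = (np.arange(k) + 0.5) / k
    rows_lon, rows_lat, rows_w = [], [], []
    dt_h = np.diff(times.asi8) / 3600e9
    for i in range(len(lon) - 1):
        plon, plat = gc_interpolate(lon[i], lat[i], lon[i + 1], lat[i + 1], fr)
        rows_lon.append(plon)
        rows_lat.append(plat)
        rows_w.append(np.full(k, dt_h[i] / k))
    return pd.DataFrame({"lon": np.concatenate(rows_lon),
                         "lat": np.concatenate(rows_lat),
                         "weight_hours": np.concatenate(rows_w)})


class MovementResults:
    """Posterior location samples: (n_chains, n_draws, n_states) arrays."""

    def __init__(self, model: MovementModel, lon: np.ndarray, lat: np.ndarray,
                 acceptance: np.ndarray):
        self.model = model
        self.lon = lon
        self.lat = lat
        self.acceptance = acceptance
        self.times = model.state_times

    @property
    def n_chains(self) -> int:
        return self.lon.shape[0]

    @property
    def n_draws(self) -> int:
        return self.lon.shape[1]

    def posterior_mean_path(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times,
                             "lon": self.lon.mean(axis=(0, 1)),
                             "lat": self.lat.mean(axis=(0, 1))})

    def envelope(self, level: float = 0.95) -> pd.DataFrame:
        a = (1.0 - level) / 2.0
        return pd.DataFrame({
            "time": self.times,
            "lon_lo": np.quantile(self.lon, a, axis=(0, 1)),
            "lon_hi": np.quantile(self.lon, 1 - a, axis=(0, 1)),
            "lat_lo": np.quantile(self.lat, a, axis=(0, 1)),
            "lat_hi": np.quantile(self.lat, 1 - a, axis=(0, 1)),
        })

    def implied_speeds(self) -> np.ndarray:
        """Per-draw per-segment great-circle speeds, km/h."""
        d = haversine_km(self.lon[..., :-1], self.lat[..., :-1],
                         self.lon[..., 1:], self.lat[..., 1:])
        return d / self.model.dt_hours

    def mean_speed(self) -> float:
        """Posterior mean of the implied step speed (km/h)."""
        return float(self.implied_speeds().mean())

    def sample_paths(self, n: int, seed: int | None = None) -> list[pd.DataFrame]:
        """Draw `n` path samples (with replacement) from the retained draws."""
        rng = np.random.default_rng(seed)
        ch = rng.integers(0, self.n_chains, size=n)
        dr = rng.integers(0, self.n_draws, size=n)
        return [pd.DataFrame({"time": self.times, "lon": self.lon[c, d],
                              "lat": self.lat[c, d]}) for c, d in zip(ch, dr)]

    def chain_mean_paths(self, n_chains: int | None = None) -> list[pd.DataFrame]:
        """Per-chain posterior mean paths (the habitat 'use' ensemble)."""
        k = self.n_chains if n_chains is None else min(n_chains, self.n_chains)
        return [pd.DataFrame({"time": self.times, "lon": self.lon[c].mean(axis=0),
                              "lat": self.lat[c].mean(axis=0)}) for c in range(k)]

    def hourly_path(self, pin_gap_hours: float = 48.0) -> pd.DataFrame:
        """Posterior mean path interpolated to clock hours.

        Inter-state gaps longer than ``pin_gap_hours`` (polar-day runs,
        outages) are pinned to the last known position rather than
        interpolated across.
        """
        mean = self.posterior_mean_path()
        hours = pd.date_range(self.times[0].ceil("h"), self.times[-1].floor("h"), freq="1h")
        lon, lat = pin_positions(hours, mean["lon"], mean["lat"], self.times,
                                 gap_hours=pin_gap_hours)
        return pd.DataFrame({"time": hours, "lon": lon, "lat": lat})

    def time_spent_grid(self, grid: GridSpec, n_simulations: int = 1000,
                        k: int = 10, seed: int | None = None,
                        quantiles: tuple = ()) -> TimeSpentGrid:
        """Time-weighted density of densified posterior paths.

        ``n_simulations`` paths are drawn with replacement, densified with
        ``k`` intermediate locations per segment, binned and summed; the
        result is normalized to unit mass.  Optional per-cell quantiles are
        computed across simulations.
        """
        rng = np.random.default_rng(seed)
        lon_edges = np.arange(grid.lon_min, grid.lon_max + grid.resolution, grid.resolution)
        lat_edges = np.arange(grid.lat_min, grid.lat_max + grid.resolution, grid.resolution)
        shape = (len(lat_edges) - 1, len(lon_edges) - 1)
        total = np.zeros(shape)
        store = np.zeros((n_simulations,) + shape) if quantiles else None
        clipped = 0.0
        ch = rng.integers(0, self.n_chains, size=n_simulations)
        dr = rng.integers(0, self.n_draws, size=n_simulations)
        fr = (np.arange(k) + 0.5) / k
        dt_h = self.model.dt_hours
        for s, (c, d) in enumerate(zip(ch, dr)):
            lon = self.lon[c, d]
            lat = self.lat[c, d]
            pl, pa, wt = [], [], []
            for i in range(len(lon) - 1):
                il, ia = gc_interpolate(lon[i], lat[i], lon[i + 1], lat[i + 1], fr)
                pl.append(il)
                pa.append(ia)
                wt.append(np.full(k, dt_h[i] / k))
            pl = np.concatenate(pl)
            pa = np.concatenate(pa)
            wt = np.concatenate(wt)
            h, _, _ = np.histogram2d(pa, pl, bins=[lat_edges, lon_edges], weights=wt)
            clipped += wt.sum() - h.sum()
            total += h
            if store is not None:
                store[s] = h
        mass = total.sum()
        if mass <= 0:
            raise ValueError("no posterior mass falls inside the requested grid")
        qs = {}
        if store is not None:
            for q in quantiles:
                qs[q] = np.quantile(store, q, axis=0)
        return TimeSpentGrid(density=total / mass, lon_edges=lon_edges,
                             lat_edges=lat_edges, n_simulations=n_simulations,
                             clipped_hours=float(clipped), quantiles=qs)

    def summary(self) -> str:
        sp = self.implied_speeds()
        lines = [
            "MovementResults",
            f"  states: {self.model.n_states} ({int(self.model.fixed.sum())} fixed)",
            f"  chains: {self.n_chains} x {self.n_draws} retained draws",
            f"  mean acceptance rate: {np.mean(self.acceptance[~self.model.fixed]):.3f}",
            f"  posterior mean step speed: {sp.mean():.3f} km/h (sd {sp.std():.3f})",
        ]
        return "\n".join(lines)
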