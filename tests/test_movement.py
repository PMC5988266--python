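"""Movement posterior: observation model, priors, MCMC correctness."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from hydrurga import movement, simulate
from hydrurga.movement import (GridSpec, MovementModel, MovementPrior,
                               TwilightErrorModel, handle_polar_day,
                               intermediate_locations, pin_positions,
                               speed_log_prior, twilight_log_likelihood)
from tests.conftest import BIRD_ISLAND


class TestErrorModel:
    def test_density_integrates_to_one(self):
        err = TwilightErrorModel()
        val, _ = quad(lambda e: np.exp(err.logpdf(e)), -err.shift, 500.0, limit=200)
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_mode_maximizes_logpdf(self):
        err = TwilightErrorModel(scale=8.0, shift=2.0, sdlog=0.7)
        mode = 8.0 * np.exp(-0.7 ** 2) - 2.0  # mode of the shifted log-normal
        r = minimize_scalar(lambda e: -err.logpdf(e), bounds=(-1.9, 60.0),
                            method="bounded")
        assert r.x == pytest.approx(mode, abs=0.01)

    def test_support_boundary(self):
        err = TwilightErrorModel(shift=2.0)
        assert err.logpdf(-2.0) == -np.inf
        assert np.isfinite(err.logpdf(-1.9))

    def test_polar_location_has_zero_likelihood(self):
        row = {"time": pd.Timestamp("2013-06-21T12:00:00"), "kind": "rise"}
        ll = twilight_log_likelihood(row, (-38.0, -80.0), 96.0, TwilightErrorModel())
        assert ll == -np.inf


class TestSpeedPrior:
    def test_mode_maximizes_over_distance(self):
        prior = MovementPrior()
        mu, sig = prior.log_params
        mode = np.exp(mu - sig ** 2)
        r = minimize_scalar(
            lambda v: -speed_log_prior((0.0, -54.0), (v * 12.0 / 111.19493 / np.cos(np.radians(-54.0)), -54.0),
                                       12.0, prior),
            bounds=(0.05, 5.0), method="bounded")
        assert r.x == pytest.approx(mode, rel=0.02)

    def test_monte_carlo_mean_matches_prior(self, rng):
        from hydrurga.simulate import lognormal_params
        mu, sig = lognormal_params(1.0, 0.9)
        v = rng.lognormal(mu, sig, 100_000)
        assert abs(v.mean() - 1.0) <= 3 * 0.9 / np.sqrt(len(v))

    def test_dt_scaling_consistency(self):
        prior = MovementPrior()
        a, b = (0.0, -54.0), (0.5, -54.5)
        l1 = speed_log_prior(a, b, 12.0, prior)
        l2 = speed_log_prior(a, b, 24.0, prior)
        from hydrurga.geodesy import haversine_km
        d = haversine_km(*a, *b)
        mu, sig = prior.log_params

        def direct(v):
            return (-np.log(v) - np.log(sig) - 0.5 * np.log(2 * np.pi)
                    - (np.log(v) - mu) ** 2 / (2 * sig ** 2))

        assert l1 == pytest.approx(direct(d / 12.0))
        assert l2 == pytest.approx(direct(d / 24.0))

    def test_zero_distance_is_finite(self):
        assert np.isfinite(speed_log_prior((0.0, -54.0), (0.0, -54.0), 12.0,
                                           MovementPrior()))


def _daily_twilights(lonlat, start, n_days, zenith=96.0):
    track = simulate.stationary_track(lonlat, start, n_days)
    return simulate.true_twilights(track, zenith)


class TestPolarDay:
    def test_b4943_style_gap_length(self):
        """A 63-day polar-day run bounded by the printed dates is handled."""
        tw1 = _daily_twilights(BIRD_ISLAND, "2012-11-01", 18)  # through 18 Nov
        tw1 = tw1[tw1["time"] < "2012-11-20"]
        tw2 = _daily_twilights(BIRD_ISLAND, "2013-01-22", 20)
        tw = pd.concat([tw1, tw2], ignore_index=True)
        gaps = handle_polar_day(tw)
        assert len(gaps) == 1
        g = gaps[0]
        assert g.start == pd.Timestamp("2012-11-20")
        assert g.end == pd.Timestamp("2013-01-22")
        assert g.n_days == 63

    def test_no_gap_in_continuous_record(self):
        tw = _daily_twilights(BIRD_ISLAND, "2013-05-01", 20)
        assert handle_polar_day(tw) == []

    def test_pinned_positions_constant_through_gap(self):
        state_times = pd.DatetimeIndex(["2013-05-01", "2013-05-02", "2013-05-12",
                                        "2013-05-13"])
        lons = [0.0, 1.0, 5.0, 6.0]
        lats = [-54.0, -55.0, -59.0, -60.0]
        q = pd.date_range("2013-05-02", "2013-05-12", freq="12h")
        lon, lat = pin_positions(q, lons, lats, state_times, gap_hours=48.0)
        inside = (q > state_times[1]) & (q < state_times[2])
        assert np.allclose(lon[inside], 1.0) and np.allclose(lat[inside], -55.0)


class TestMCMC:
    def test_all_days_fixed_reproduces_fixes(self):
        tw = _daily_twilights(BIRD_ISLAND, "2013-05-01", 3)
        days = pd.DatetimeIndex(tw["time"]).normalize().unique()
        fixes = pd.DataFrame({"time": days,
                              "lon": -38.0 - 0.25 * np.arange(len(days)),
                              "lat": -54.0 - 0.15 * np.arange(len(days))})
        m = MovementModel(tw, fixes=fixes)
        res = m.fit(n_chains=2, n_iter=40, seed=0)
        assert m.fixed.all()
        for i in range(m.n_states):
            assert np.allclose(res.lon[..., i], m.fixed_lon[i])
            assert np.allclose(res.lat[..., i], m.fixed_lat[i])

    def test_seed_determinism(self):
        tw = _daily_twilights(BIRD_ISLAND, "2013-05-01", 6)
        m = MovementModel(tw)
        r1 = m.fit(n_chains=2, n_iter=200, seed=5)
        r2 = m.fit(n_chains=2, n_iter=200, seed=5)
        assert np.array_equal(r1.lon, r2.lon) and np.array_equal(r1.lat, r2.lat)

    def test_initial_path_feasible_and_accurate(self, stationary_lights):
        from hydrurga import twilight as twi
        tw = twi.detect_twilights(stationary_lights, 10.0)
        m = MovementModel(tw)
        path = m.initial_path()
        assert np.isfinite(m.log_posterior(path["lon"], path["lat"]))
        assert np.abs(path["lon"] - BIRD_ISLAND[0]).max() <= 1.0
        assert np.abs(path["lat"] - BIRD_ISLAND[1]).max() <= 1.0

    def test_marginal_matches_grid_posterior(self):
        """Collapsible case: one free twilight state between two fixes; the
        MCMC marginal mean must match the brute-force grid posterior."""
        tw = _daily_twilights(BIRD_ISLAND, "2013-05-02", 1)
        tw = tw.iloc[:1]  # a single rise on the middle day
        fixes = pd.DataFrame({"time": ["2013-05-01", "2013-05-03"],
                              "lon": [-38.05, -39.0], "lat": [-54.01, -54.8]})
        m = MovementModel(tw, fixes=fixes)
        assert m.n_states == 3 and m.fixed.tolist() == [True, False, True]
        res = m.fit(n_chains=4, n_iter=6000, seed=2)

        lon_g = np.arange(-42.0, -35.0, 0.05)
        lat_g = np.arange(-57.0, -52.0, 0.05)
        LO, LA = np.meshgrid(lon_g, lat_g)
        lp = np.array([
            m.log_posterior([m.fixed_lon[0], lo, m.fixed_lon[2]],
                            [m.fixed_lat[0], la, m.fixed_lat[2]])
            for lo, la in zip(LO.ravel(), LA.ravel())
        ]).reshape(LO.shape)
        w = np.exp(lp - lp.max())
        w /= w.sum()
        want_lon = float((w * LO).sum())
        want_lat = float((w * LA).sum())
        got_lon = res.lon[..., 1].mean()
        got_lat = res.lat[..., 1].mean()
        assert got_lon == pytest.approx(want_lon, abs=0.1)
        assert got_lat == pytest.approx(want_lat, abs=0.1)

    def test_migratory_recovery_and_coverage(self):
        """Posterior mean path tracks the truth; envelopes cover it."""
        p = simulate.TrackParams(
            n_steps=60, seed=7, start_time="2013-05-01",
            migration_schedule=[("2013-05-02", (-45.0, -61.0))])
        track, _ = simulate.simulate_track(p)
        tw = simulate.true_twilights(track, 96.0)
        err = TwilightErrorModel()
        obs = simulate.perturb_twilights(tw, err, seed=11)
        fixes = pd.DataFrame({
            "time": [track["time"].iloc[0], track["time"].iloc[-1]],
            "lon": [track["lon"].iloc[0], track["lon"].iloc[-1]],
            "lat": [track["lat"].iloc[0], track["lat"].iloc[-1]]})
        m = MovementModel(obs, fixes=fixes)
        res = m.fit(n_chains=4, n_iter=2000, seed=3)
        tt = pd.DatetimeIndex(track["time"]).asi8.astype(float)
        st = res.times.asi8.astype(float)
        tlon = np.interp(st, tt, track["lon"])
        tlat = np.interp(st, tt, track["lat"])
        mp = res.posterior_mean_path()
        rmse = np.sqrt(np.mean((mp["lon"] - tlon) ** 2 + (mp["lat"] - tlat) ** 2))
        assert rmse <= 2.0
        env = res.envelope(0.95)
        cover = ((tlon >= env["lon_lo"]) & (tlon <= env["lon_hi"])
                 & (tlat >= env["lat_lo"]) & (tlat <= env["lat_hi"])).mean()
        assert cover >= 0.80


@pytest.fixture(scope="module")
def fitted():
    tw = _daily_twilights(BIRD_ISLAND, "2013-05-01", 10)
    m = MovementModel(tw)
    return m.fit(n_chains=2, n_iter=400, seed=4)


class TestDerived:
    def test_intermediate_midpoints_and_weights(self, fitted):
        path = fitted.sample_paths(1, seed=0)[0]
        mid = intermediate_locations(path, k=1)
        from hydrurga.geodesy import gc_interpolate
        lo, la = gc_interpolate(path["lon"][0], path["lat"][0],
                                path["lon"][1], path["lat"][1], [0.5])
        assert mid["lon"].iloc[0] == pytest.approx(lo[0])
        assert mid["lat"].iloc[0] == pytest.approx(la[0])
        dense = intermediate_locations(path, k=7)
        dt_h = np.diff(pd.DatetimeIndex(path["time"]).asi8) / 3600e9
        seg_w = dense["weight_hours"].to_numpy().reshape(len(path) - 1, 7).sum(axis=1)
        assert np.allclose(seg_w, dt_h)

    def test_densified_length_not_shorter_than_chords(self, fitted):
        """The path through vertices plus intermediates is never shorter
        than the chord path (equal on a sphere, since the intermediates sit
        on the connecting great circles)."""
        from hydrurga.geodesy import haversine_km
        path = fitted.sample_paths(1, seed=1)[0]
        lon = path["lon"].to_numpy()
        lat = path["lat"].to_numpy()
        chord = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:]).sum()
        k = 10
        dense = intermediate_locations(path, k=k)
        full_lon, full_lat = [], []
        for i in range(len(lon) - 1):
            full_lon.append([lon[i]] + dense["lon"][i * k:(i + 1) * k].tolist())
            full_lat.append([lat[i]] + dense["lat"][i * k:(i + 1) * k].tolist())
        full_lon = np.concatenate(full_lon + [[lon[-1]]])
        full_lat = np.concatenate(full_lat + [[lat[-1]]])
        dl = haversine_km(full_lon[:-1], full_lat[:-1],
                          full_lon[1:], full_lat[1:]).sum()
        assert dl >= chord - 1e-6

    def test_time_spent_grid_normalizes(self, fitted):
        grid = GridSpec(-45.0, -30.0, -60.0, -48.0, 0.5)
        tsg = fitted.time_spent_grid(grid, n_simulations=50, seed=0,
                                     quantiles=(0.5,))
        assert tsg.density.sum() == pytest.approx(1.0)
        assert (tsg.density >= 0).all()
        assert 0.5 in tsg.quantiles

    def test_modal_cell_contains_the_stationary_site(self, fitted):
        grid = GridSpec(-45.0, -30.0, -60.0, -48.0, 0.5)
        tsg = fitted.time_spent_grid(grid, n_simulations=100, seed=1)
        i, j = np.unravel_index(np.argmax(tsg.density), tsg.density.shape)
        lon_c = 0.5 * (tsg.lon_edges[j] + tsg.lon_edges[j + 1])
        lat_c = 0.5 * (tsg.lat_edges[i] + tsg.lat_edges[i + 1])
        assert abs(lon_c - BIRD_ISLAND[0]) <= 1.5
        assert abs(lat_c - BIRD_ISLAND[1]) <= 1.5

    def test_grid_not_covering_samples_clips(self, fitted):
        grid = GridSpec(-39.5, -37.5, -55.0, -53.0, 0.25)
        tsg = fitted.time_spent_grid(grid, n_simulations=20, seed=2)
        assert tsg.clipped_hours > 0
        assert tsg.density.sum() == pytest.approx(1.0)
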