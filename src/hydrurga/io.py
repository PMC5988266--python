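"""Log-file readers/writers, run configuration and the pipeline driver.

Light and immersion logs are TSV with an ISO-8601 UTC timestamp column and
one integer value column.  All timestamps are normalized to UTC;
longitudes live in [-180, 180).  Every pipeline stage writes CSV outputs
plus a JSON provenance record (inputs, parameters, seed) sufficient to
re-run it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import haulout as _haulout
from . import movement as _movement
from . import simulate as _simulate
from . import twilight as _twilight
from . import habitat as _habitat
from . import activity as _activity

logger = logging.getLogger(__name__)


def _read_log(path, value_col: str, vmin=None, vmax=None,
              collapse: str = "max") -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected timestamp and value columns")
    df = df.iloc[:, :2]
    df.columns = ["time", value_col]
    n0 = len(df)
    if n0 == 0:
        raise ValueError(f"{path}: empty file")
    t = pd.to_datetime(df["time"], errors="coerce", utc=True, format="ISO8601")
    v = pd.to_numeric(df[value_col], errors="coerce")
    bad = t.isna() | v.isna()
    if vmin is not None:
        bad |= v < vmin
    if vmax is not None:
        bad |= v > vmax
    if bad.any():
        logger.warning("%s: skipped %d unparseable/out-of-range rows", path, int(bad.sum()))
    if bad.sum() > 0.1 * n0:
        raise ValueError(f"{path}: more than 10% bad rows ({int(bad.sum())}/{n0})")
    out = pd.DataFrame({"time": t[~bad].dt.tz_convert("UTC").dt.tz_localize(None),
                        value_col: v[~bad].astype(int)})
    dup = out["time"].duplicated(keep=False)
    if dup.any():
        logger.warning("%s: collapsing %d duplicate timestamps (%s)", path,
                       int(dup.sum()), collapse)
        out = out.groupby("time", as_index=False)[value_col].agg(collapse)
    return out.sort_values("time").reset_index(drop=True)


def read_light_log(path) -> pd.DataFrame:
    """Read a 10-min max-light TSV/CSV log (columns: time, light)."""
    return _read_log(path, "light", vmin=0, collapse="max")


def read_immersion_log(path) -> pd.DataFrame:
    """Read a 10-min immersion-count log; values outside [0, 200] rejected."""
    return _read_log(path, "wet_count", vmin=0, vmax=200, collapse="max")


def write_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, date_format="%Y-%m-%dT%H:%M:%SZ")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """Materialized parameters for a full synthetic pipeline run."""

    seed: int = 0
    out_dir: str = "run_output"
    log_level: str = "INFO"
    n_steps: int = 120
    step_interval: float = 12.0
    start_time: str = "2013-05-01T00:00:00"
    zenith_deg: float = 96.0
    light_threshold: float = 10.0
    n_chains: int = 4
    n_iter: int = 1500
    n_use_chains: int = 4
    n_null_runs: int = 10
    n_time_spent_sims: int = 200
    min_dry_duration: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _provenance(out_dir: Path, stage: str, config: RunConfig, **extra) -> None:
    rec = {"stage": stage, "config": config.to_dict(), **extra}
    (out_dir / f"{stage}_provenance.json").write_text(
        json.dumps(rec, default=str, indent=2))


def run_pipeline(config: RunConfig) -> dict:
    """Synthetic end-to-end run: simulate, geolocate, haul-out, habitat, activity.

    Writes every stage's CSV outputs plus provenance JSON under
    ``config.out_dir`` and returns the in-memory artifacts.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    try:
        # simulate
        params = _simulate.TrackParams(n_steps=config.n_steps,
                                       step_interval=config.step_interval,
                                       start_time=config.start_time,
                                       seed=config.seed)
        track, truth = _simulate.simulate_track(params)
        track.to_csv(out / "true_track.csv", index=False)
        lights = _simulate.render_light(track, config.zenith_deg,
                                        config.light_threshold, seed=config.seed)
        write_log(lights, out / "light_log.tsv")
        sched = _simulate.HauloutSchedule()
        immersion, bout_truth = _simulate.render_immersion(track, sched,
                                                           seed=config.seed + 1)
        write_log(immersion, out / "immersion_log.tsv")
        _provenance(out, "simulate", config, params=dataclasses.asdict(params))

        # twilights + movement posterior
        tw = _twilight.detect_twilights(lights, config.light_threshold)
        tw.to_csv(out / "twilights.csv", index=False)
        fixes = pd.DataFrame({"time": [track["time"].iloc[0]],
                              "lon": [track["lon"].iloc[0]],
                              "lat": [track["lat"].iloc[0]]})
        model = _movement.MovementModel(tw, fixes=fixes, zenith_deg=config.zenith_deg)
        results = model.fit(n_chains=config.n_chains, n_iter=config.n_iter,
                            seed=config.seed)
        mean_path = results.posterior_mean_path()
        mean_path.to_csv(out / "mean_path.csv", index=False)
        _provenance(out, "locate", config, n_states=model.n_states)
        artifacts["results"] = results

        # haul-out
        transformed = _haulout.transform_immersion(immersion)
        bouts = _haulout.detect_bouts(transformed,
                                      _haulout.HauloutConfig(config.min_dry_duration))
        bouts.to_csv(out / "haulout_bouts.csv", index=False)
        span = (immersion["time"].iloc[0],
                immersion["time"].iloc[-1] + pd.Timedelta("10min"))
        states = _haulout.hourly_states(bouts, span)
        states.to_csv(out / "hourly_states.csv", index=False)
        summary = _haulout.summarize(bouts, states, span)
        pd.DataFrame([summary]).to_csv(out / "haulout_summary.csv", index=False)
        _provenance(out, "haulout", config, n_bouts=len(bouts))
        artifacts["bouts"] = bouts
        artifacts["states"] = states

        # habitat
        env = _simulate.simulate_environment(_simulate.EnvFieldSpec())
        cfg = _habitat.HabitatConfig(n_use_chains=config.n_use_chains,
                                     n_null_runs=config.n_null_runs)
        table = _habitat.extract_covariates(results, env, haulout_states=states,
                                            config=cfg, seed=config.seed + 2)
        table.to_csv(out / "use_availability.csv", index=False)
        ladder, fits, selected = _habitat.fit_ladder(table)
        ladder.to_csv(out / "habitat_ladder.csv", index=False)
        _provenance(out, "habitat", config, selected=selected)
        artifacts["habitat_ladder"] = ladder

        # activity
        hourly = results.hourly_path()
        design = _activity.build_design(states, hourly,
                                        land_polygons=env.land_polygons,
                                        ice_edge_by_month=env.ice_edge_by_month)
        design.to_csv(out / "activity_design.csv", index=False)
        spec = _activity.ActivityModelSpec(name="desk", hour_by=None, season_by=None,
                                           distance_by=None, random_effect=False)
        fit = _activity.fit_activity(design, spec)
        (out / "activity_fit.txt").write_text(fit.summary())
        summ = _activity.diel_seasonal_summary(states)
        summ["hour_month"].to_csv(out / "hour_month_proportions.csv")
        summ["week"].to_csv(out / "week_proportions.csv")
        _provenance(out, "activity", config, aic=fit.aic)
        artifacts["activity_fit"] = fit

        # time-spent grid
        lo = mean_path["lon"]
        la = mean_path["lat"]
        grid = _movement.GridSpec(lo.min() - 2, lo.max() + 2, la.min() - 2,
                                  la.max() + 2, 0.5)
        tsg = results.time_spent_grid(grid, n_simulations=config.n_time_spent_sims,
                                      seed=config.seed)
        np.savetxt(out / "time_spent_grid.csv", tsg.density, delimiter=",")
        artifacts["time_spent"] = tsg
    except Exception as exc:  # re-raise with the failing stage named
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    return artifacts
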