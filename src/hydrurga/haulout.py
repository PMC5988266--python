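"""Haul-out segmentation from salt-water immersion logs.

An immersion record counts positive 3-s salt-water tests per 10-min
window: 0 means the logger was completely dry, 200 completely wet.
Following the dive-analysis convention, counts are first shifted by -200
so dry periods appear as "dives" at -200.  A haul-out bout runs from the
first completely-dry window to the first subsequently wet one; only bouts
dry for at least one hour are kept.  Each clock hour of the deployment is
then labelled hauled-out if it overlaps any bout, and the per-trip summary
reproduces the standard biologging report (total days hauled out,
proportion of time, max/median bout, inter-bout intervals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

IMMERSION_OFFSET = 200  # full-wet count per 10-min window (one test per 3 s)
DRY = -IMMERSION_OFFSET


@dataclass(frozen=True)
class HauloutConfig:
    min_dry_duration: float = 1.0   # hours
    offset: int = IMMERSION_OFFSET
    max_gap: str = "30min"          # record gaps longer than this break runs

    def __post_init__(self):
        if self.min_dry_duration <= 0:
            raise ValueError("min_dry_duration must be positive")


def transform_immersion(records: pd.DataFrame, offset: int = IMMERSION_OFFSET) -> pd.DataFrame:
    """Shift wet counts by -offset so dry windows sit at -200.

    Rows outside [0, offset] are dropped with a logged count.
    """
    out = records.copy()
    vals = np.asarray(out["wet_count"], dtype=float)
    bad = (vals < 0) | (vals > offset) | ~np.isfinite(vals)
    if bad.any():
        logger.warning("transform_immersion: dropped %d out-of-range rows", int(bad.sum()))
        out = out.loc[~bad].reset_index(drop=True)
        vals = vals[~bad]
    out["immersion"] = vals - offset
    return out[["time", "immersion"]]


def detect_bouts(transformed: pd.DataFrame, config: HauloutConfig | None = None) -> pd.DataFrame:
    """Maximal completely-dry runs as haul-out bouts.

    A bout starts at the first window reading -200 and ends at the first
    following window reading > -200; runs shorter than
    ``config.min_dry_duration`` are discarded.  Runs truncated by the end
    of the record or by gaps longer than ``config.max_gap`` are flagged
    (``truncated`` column) — their durations are unreliable.
    """
    config = config or HauloutConfig()
    t = pd.DatetimeIndex(pd.to_datetime(transformed["time"]))
    if len(t) and not t.is_monotonic_increasing:
        raise ValueError("immersion records must be sorted by time")
    vals = np.asarray(transformed["immersion"], dtype=float)
    max_gap = pd.Timedelta(config.max_gap)
    bouts = []
    i = 0
    n = len(vals)
    while i < n:
        if vals[i] == DRY:
            j = i
            truncated = False
            while j + 1 < n and vals[j + 1] == DRY:
                if t[j + 1] - t[j] > max_gap:
                    truncated = True
                    break
                j += 1
            if j + 1 < n and not truncated and t[j + 1] - t[j] <= max_gap:
                end = t[j + 1]
            else:
                end = t[j] + pd.Timedelta("10min")
                truncated = True
            dur = (end - t[i]).total_seconds() / 3600.0
            if dur >= config.min_dry_duration:
                bouts.append({"start": t[i], "end": end, "duration_h": dur,
                              "truncated": truncated})
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(bouts, columns=["start", "end", "duration_h", "truncated"])


def hourly_states(bouts: pd.DataFrame, deployment_span) -> pd.DataFrame:
    """Clock-hour binary series: 1 iff the hour overlaps any bout.

    Hours are UTC clock-aligned, closed-open [h:00, h+1:00).
    """
    start = pd.Timestamp(deployment_span[0]).floor("h")
    end = pd.Timestamp(deployment_span[1])
    hours = pd.date_range(start, end - pd.Timedelta(seconds=1), freq="1h")
    state = np.zeros(len(hours), dtype=int)
    h0 = hours.asi8
    h1 = h0 + int(3600e9)
    for _, b in bouts.iterrows():
        s = pd.Timestamp(b["start"]).value
        e = pd.Timestamp(b["end"]).value
        state[(h0 < e) & (h1 > s)] = 1
    return pd.DataFrame({"hour_start": hours, "state": state})


def summarize(bouts: pd.DataFrame, states: pd.DataFrame, span) -> dict:
    """Per-trip summary: the printed biologging aggregates.

    Returns total haul-out time (days), proportion of the span hauled out,
    max and median bout duration (hours), median/min/max inter-bout
    interval (minutes) and the longest continuously-wet period (days).
    """
    start = pd.Timestamp(span[0])
    end = pd.Timestamp(span[1])
    span_h = (end - start).total_seconds() / 3600.0
    total_h = float(bouts["duration_h"].sum()) if len(bouts) else 0.0
    out = {
        "total_time_days": total_h / 24.0,
        "proportion_of_time": total_h / span_h if span_h > 0 else np.nan,
        "max_hours": float(bouts["duration_h"].max()) if len(bouts) else np.nan,
        "median_hours": float(bouts["duration_h"].median()) if len(bouts) else np.nan,
    }
    if len(bouts) >= 2:
        gaps_min = ((bouts["start"].iloc[1:].to_numpy() - bouts["end"].iloc[:-1].to_numpy())
                    / np.timedelta64(1, "m"))
        out["median_interval_min"] = float(np.median(gaps_min))
        out["min_interval_min"] = float(np.min(gaps_min))
        out["max_interval_min"] = float(np.max(gaps_min))
    else:
        out["median_interval_min"] = out["min_interval_min"] = out["max_interval_min"] = np.nan
    # longest continuously wet period: gaps between bouts plus the leading
    # and trailing wet stretches of the record
    edges = [start] + list(bouts["end"]) if len(bouts) else [start]
    ends = list(bouts["start"]) + [end] if len(bouts) else [end]
    wet_days = [(pd.Timestamp(e) - pd.Timestamp(s)).total_seconds() / 86400.0
                for s, e in zip(edges, ends)]
    out["longest_wet_days"] = float(max(wet_days)) if wet_days else np.nan
    if len(states):
        out["proportion_of_recorded_hours"] = float(states["state"].mean())
    return out
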