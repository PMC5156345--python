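"""Per-dive foraging covariates: the table every statistical model consumes.

One row per analysable dive (duration in bounds, not a drift dive):
prey-encounter count and rate at the bottom, bottom median depth and
vertical extent (Q90 - Q10 of bottom depths), percentage of bottom time in
wiggles and in steps, circular means of transit pitch, mean transit
swimming effort, circular variances of bottom pitch and heading (vertical
and horizontal sinuosity), dive efficiency (bottom/dive duration), surface
horizontal speed from bracketing GPS fixes, and a day/night label from
solar altitude at the dive start.  A companion phase-level table (descent
and ascent rows with duration, maximum depth and mean effort) supports the
transit-duration model.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .orientation import OrientationSeries, circular_mean, circular_variance
from .segmentation import Dive
from .solar import solar_altitude_deg

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_008.8


def pee_rate_bottom(count: int, bottom_duration_min: float) -> float:
    """Prey encounters per minute of bottom time."""
    if bottom_duration_min <= 0:
        raise ValueError("bottom duration must be positive")
    return count / bottom_duration_min


def bottom_vertical_extent(bottom_depths: np.ndarray) -> float:
    """Q90 - Q10 of the 1 Hz bottom-phase depths (linear-interp quantiles)."""
    d = np.asarray(bottom_depths, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 bottom samples")
    q10, q90 = np.percentile(d, [10, 90], method="linear")
    return float(q90 - q10)


def pct_bottom_in_events(bottom_start: int, bottom_end: int, events,
                         kind: str) -> float:
    """Percent of bottom seconds covered by events of the given kind."""
    dur = bottom_end - bottom_start
    if dur <= 0:
        raise ValueError("empty bottom phase")
    covered = np.zeros(dur, dtype=bool)
    for e in events:
        if e.kind != kind:
            continue
        a = max(e.start_s, bottom_start) - bottom_start
        b = min(e.end_s, bottom_end) - bottom_start
        if b > a:
            covered[a:b] = True
    return 100.0 * covered.sum() / dur


def dive_efficiency(bottom_s: float, dive_s: float) -> float:
    """Bottom duration over dive duration, strictly inside (0, 1)."""
    if not 0 < bottom_s < dive_s:
        raise ValueError(f"bottom {bottom_s}s must lie strictly inside dive {dive_s}s")
    return bottom_s / dive_s


def haversine_m(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance (m) on a sphere of mean Earth radius."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a)))


def surface_speed(fix_before: tuple[float, float, float],
                  fix_after: tuple[float, float, float]) -> float:
    """Horizontal speed (m/s) between two (epoch_s, lat, lon) surface fixes."""
    t0, la0, lo0 = fix_before
    t1, la1, lo1 = fix_after
    if t1 <= t0:
        raise ValueError("fixes must be in time order")
    return haversine_m(la0, lo0, la1, lo1) / (t1 - t0)


def classify_day_night(epoch_s: float, lat: float, lon: float,
                       altitude_threshold_deg: float = 0.0) -> str:
    """'day' when solar altitude >= threshold (boundary counts as day)."""
    alt = float(solar_altitude_deg(epoch_s, lat, lon))
    return "day" if alt >= altitude_threshold_deg else "night"


def _interp_position(gps: pd.DataFrame, t: float,
                     max_gap_s: float = 86400.0) -> tuple[float, float] | None:
    """Linear lat/lon interpolation between fixes; None if no fix within a day."""
    if gps is None or len(gps) == 0:
        return None
    tt = gps["time"].to_numpy(dtype=float)
    if np.min(np.abs(tt - t)) > max_gap_s:
        return None
    lat = float(np.interp(t, tt, gps["lat"].to_numpy(dtype=float)))
    lon = float(np.interp(t, tt, gps["lon"].to_numpy(dtype=float)))
    return lat, lon


def _bracketing_fixes(gps: pd.DataFrame, start_t: float, end_t: float,
                      max_gap_s: float = 600.0):
    """Fixes in the surface intervals just before and after a dive, or None."""
    if gps is None or len(gps) == 0:
        return None
    tt = gps["time"].to_numpy(dtype=float)
    before = np.where((tt <= start_t) & (tt >= start_t - max_gap_s))[0]
    after = np.where((tt >= end_t) & (tt <= end_t + max_gap_s))[0]
    if before.size == 0 or after.size == 0:
        return None
    i, j = before[-1], after[0]
    row = lambda k: (float(tt[k]), float(gps["lat"].iloc[k]), float(gps["lon"].iloc[k]))
    return row(i), row(j)


def build_dive_table(dives: list[Dive], pee_events, orientation: OrientationSeries,
                     effort: np.ndarray, depth: np.ndarray,
                     gps: pd.DataFrame | None = None,
                     start_time: float = 0.0,
                     individual_id: str = "ind1") -> pd.DataFrame:
    """Assemble the dive-level covariate table (one row per analysable dive).

    Excluded dives (duration bounds, drift) are absent.  ``surface_speed_m_s``
    and ``daynight`` may be missing (NaN) when GPS coverage does not allow
    them; every other column is complete.  Rows whose bottom phase is empty
    are dropped with a log entry, never silently.
    """
    rows = []
    pitch = orientation.pitch_deg
    heading = orientation.heading_deg
    eff = np.asarray(effort, dtype=float)
    for dv in dives:
        if dv.excluded is not None:
            continue
        ph = {p.kind: p for p in dv.phases}
        bot, des, asc = ph["bottom"], ph["descent"], ph["ascent"]
        if bot.end_s - bot.start_s < 2 or des.end_s <= des.start_s or asc.end_s <= asc.start_s:
            log.warning("dive %d dropped: degenerate phase partition", dv.id)
            continue
        bot_dur_min = (bot.end_s - bot.start_s) / 60.0
        n_pee = sum(1 for e in pee_events if bot.start_s <= e.mid_s < bot.end_s)
        bot_depth = np.asarray(depth[bot.start_s:bot.end_s], dtype=float)
        row = {
            "individual_id": individual_id,
            "dive_id": dv.id,
            "start_s": dv.start_s,
            "bottom_pee_count": n_pee,
            "bottom_duration_min": bot_dur_min,
            "pee_rate_bottom": pee_rate_bottom(n_pee, bot_dur_min),
            "bottom_median_depth_m": float(np.median(bot_depth)),
            "bottom_vertical_extent_m": bottom_vertical_extent(bot_depth),
            "pct_bottom_wiggle": pct_bottom_in_events(bot.start_s, bot.end_s, dv.events, "wiggle"),
            "pct_bottom_step": pct_bottom_in_events(bot.start_s, bot.end_s, dv.events, "step"),
            "mean_pitch_descent_deg": circular_mean(pitch[des.start_s:des.end_s]),
            "mean_pitch_ascent_deg": circular_mean(pitch[asc.start_s:asc.end_s]),
            "mean_effort_descent": float(np.mean(eff[des.start_s:des.end_s])),
            "mean_effort_ascent": float(np.mean(eff[asc.start_s:asc.end_s])),
            "var_pitch_bottom": circular_variance(pitch[bot.start_s:bot.end_s]),
            "var_heading_bottom": circular_variance(
                heading[bot.start_s:bot.end_s][np.isfinite(heading[bot.start_s:bot.end_s])]),
            "dive_efficiency": dive_efficiency(bot.end_s - bot.start_s, dv.duration_s),
        }
        # GPS-dependent covariates
        speed = np.nan
        br = _bracketing_fixes(gps, start_time + dv.start_s, start_time + dv.end_s)
        if br is not None:
            speed = surface_speed(br[0], br[1])
        row["surface_speed_m_s"] = speed
        pos = _interp_position(gps, start_time + dv.start_s)
        row["daynight"] = (classify_day_night(start_time + dv.start_s, *pos)
                           if pos is not None else None)
        rows.append(row)
    cols = ["individual_id", "dive_id", "start_s", "daynight", "bottom_pee_count",
            "bottom_duration_min", "pee_rate_bottom", "bottom_median_depth_m",
            "bottom_vertical_extent_m", "pct_bottom_wiggle", "pct_bottom_step",
            "mean_pitch_descent_deg", "mean_pitch_ascent_deg", "mean_effort_descent",
            "mean_effort_ascent", "var_pitch_bottom", "var_heading_bottom",
            "dive_efficiency", "surface_speed_m_s"]
    return pd.DataFrame(rows, columns=cols)


def build_phase_table(dives: list[Dive], effort: np.ndarray, depth: np.ndarray,
                      individual_id: str = "ind1") -> pd.DataFrame:
    """Transit-phase table: one descent row and one ascent row per dive."""
    eff = np.asarray(effort, dtype=float)
    d = np.asarray(depth, dtype=float)
    rows = []
    for dv in dives:
        if dv.excluded is not None:
            continue
        for p in dv.phases:
            if p.kind == "bottom" or p.end_s <= p.start_s:
                continue
            rows.append({
                "individual_id": individual_id,
                "dive_id": dv.id,
                "phase": p.kind,
                "duration_s": p.end_s - p.start_s,
                "max_depth_m": float(np.max(d[p.start_s:p.end_s])),
                "mean_effort": float(np.mean(eff[p.start_s:p.end_s])),
            })
    return pd.DataFrame(rows, columns=["individual_id", "dive_id", "phase",
                                       "duration_s", "max_depth_m", "mean_effort"])
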