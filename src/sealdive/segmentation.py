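"""Dive delimitation, bottom-phase partition and exclusion flags.

Works on the 1 Hz depth channel.  The stages are:

* **zero-offset correction** — pressure sensors drift slowly; a rolling
  baseline (10th percentile of near-surface readings per 3 h window,
  linearly interpolated) is subtracted so surface readings centre on zero;
* **dive detection** — maximal runs of corrected depth > 15 m; dives
  shorter than 500 s or longer than 1950 s are flagged (subsurface
  incursions and gap-merged records) but kept for audit;
* **wiggle/step detection** — wiggles are down-then-up depth excursions
  (concave profile); steps are sustained glides whose vertical speed stays
  strictly inside (0, 0.35) m/s, the non-swimming sink-rate bound;
* **bottom delimitation** — the bottom phase runs from the first to the
  last wiggle/step whose depth exceeds 75% of the dive's maximum depth
  (the "ledge"), so phase limits can never fall inside an event;
  when no event qualifies, the first-to-last crossing of the 75% isobath
  is used and the dive flagged;
* **drift-dive flagging** — dives containing a long passive segment
  (negligible stroking, steady slow sinking/rising) are resting/digesting
  dives and excluded from foraging analyses.

All intervals are half-open ``[start_s, end_s)`` whole seconds on the
deployment's 1 Hz timeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIVE_THRESHOLD_M = 15.0
MIN_DIVE_S = 500
MAX_DIVE_S = 1950
STEP_SPEED_MAX = 0.35      # m/s, upper bound for a step glide
MIN_STEP_S = 5             # suppress 0.5 m quantization spikes
SPEED_EPS = 0.02           # m/s deadband: below this the animal is holding depth
SPEED_SMOOTH_S = 3
LEDGE = 0.75


@dataclass
class DivePhase:
    kind: str                # descent | bottom | ascent
    start_s: int
    end_s: int


@dataclass
class BottomEvent:
    kind: str                # wiggle | step
    start_s: int
    end_s: int
    min_depth_m: float = float("nan")
    max_depth_m: float = float("nan")


@dataclass
class Dive:
    id: int
    start_s: int
    end_s: int
    max_depth_m: float
    excluded: str | None = None          # None | too_short | too_long | drift
    fallback_delimitation: bool = False
    phases: list = field(default_factory=list)
    events: list = field(default_factory=list)

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


def zero_offset_correct(depth: np.ndarray, window_s: int = 3 * 3600,
                        surface_max_m: float = 10.0,
                        quantile: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Remove slow pressure-sensor drift from a 1 Hz depth record.

    Per rolling window the baseline is the ``quantile``-th order statistic
    of samples shallower than ``surface_max_m``, anchored at that sample's
    own time (under a monotone drift the shallowest surface readings are
    the earliest, so anchoring at the window centre would lag the drift);
    anchors are linearly interpolated/extrapolated and subtracted.
    Windows without near-surface samples carry the previous baseline
    forward (warning).  Output is clipped at >= -0.5 m (the sensor's
    depth resolution).
    """
    depth = np.asarray(depth, dtype=float)
    n = depth.shape[0]
    if n == 0:
        return depth.copy(), np.zeros(0)
    centers, baselines = [], []
    carried = 0
    prev = 0.0
    for w0 in range(0, n, window_s):
        w1 = min(w0 + window_s, n)
        chunk = depth[w0:w1]
        # surface candidates are judged relative to the running baseline so
        # a drift larger than surface_max_m cannot hide every surfacing
        near = np.where(chunk < prev + surface_max_m)[0]
        if near.size == 0:
            baseline, center = prev, 0.5 * (w0 + w1)
            carried += 1
        else:
            order = near[np.argsort(chunk[near], kind="stable")]
            k = order[int(quantile / 100.0 * (near.size - 1))]
            baseline, center = float(chunk[k]), float(w0 + k)
        centers.append(center)
        baselines.append(baseline)
        prev = baseline
    if carried:
        warnings.warn(f"{carried} correction window(s) had no surface samples; "
                      "baseline carried forward")
    t = np.arange(n)
    offset = np.interp(t, centers, baselines)
    if len(centers) >= 2:
        # extrapolate linearly beyond the first/last window centres so a
        # steady drift is followed to the record edges
        s0 = (baselines[1] - baselines[0]) / (centers[1] - centers[0])
        s1 = (baselines[-1] - baselines[-2]) / (centers[-1] - centers[-2])
        head = t < centers[0]
        tail = t > centers[-1]
        offset[head] = baselines[0] + s0 * (t[head] - centers[0])
        offset[tail] = baselines[-1] + s1 * (t[tail] - centers[-1])
    corrected = np.maximum(depth - offset, -0.5)
    return corrected, offset


def detect_dives(depth: np.ndarray, threshold_m: float = DIVE_THRESHOLD_M,
                 min_s: int = MIN_DIVE_S, max_s: int = MAX_DIVE_S) -> list[Dive]:
    """Maximal runs of depth > threshold, with duration exclusion flags."""
    deep = np.asarray(depth, dtype=float) > threshold_m
    padded = np.concatenate([[False], deep, [False]])
    d = np.diff(padded.astype(int))
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    dives = []
    for i, (a, b) in enumerate(zip(starts, ends)):
        dur = b - a
        excluded = None
        if dur < min_s:
            excluded = "too_short"
        elif dur > max_s:
            excluded = "too_long"
        dives.append(Dive(id=i, start_s=int(a), end_s=int(b),
                          max_depth_m=float(np.max(depth[a:b])), excluded=excluded))
    return dives


def vertical_speed(depth_segment: np.ndarray,
                   smooth_s: int = SPEED_SMOOTH_S) -> np.ndarray:
    """Signed vertical speed (m/s) at 1 Hz; descending (depth increasing) positive.

    Central finite difference of the ``smooth_s``-sample moving average
    (edges use partial windows), which suppresses the 0.5 m/s spikes a
    0.5 m depth-resolution sensor produces.
    """
    d = np.asarray(depth_segment, dtype=float)
    if d.shape[0] < 2:
        return np.zeros_like(d)
    sm = pd.Series(d).rolling(smooth_s, center=True, min_periods=1).mean().to_numpy()
    return np.gradient(sm)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], np.asarray(mask, dtype=bool), [False]])
    d = np.diff(padded.astype(int))
    return list(zip(np.where(d == 1)[0].tolist(), np.where(d == -1)[0].tolist()))


def find_wiggles_steps(depth_segment: np.ndarray,
                       step_speed_max: float = STEP_SPEED_MAX,
                       min_step_s: int = MIN_STEP_S,
                       smooth_s: int = SPEED_SMOOTH_S,
                       speed_eps: float = SPEED_EPS) -> list[BottomEvent]:
    """Detect wiggles and steps inside one dive (indices relative to the dive).

    A wiggle is a down-then-up excursion interior to the dive: an adjacent
    pair of a descending run and an ascending run of the smoothed vertical
    speed (zero-speed samples may separate them).  The dive's own initial
    descent run and terminal ascent run never take part in a pair — they
    are the dive profile itself, so a V- or U-shaped dive has no events.
    A step is a
    maximal run of at least ``min_step_s`` seconds with vertical speed
    strictly inside (0, ``step_speed_max``) m/s; seconds already claimed by
    a wiggle are not available to steps.

    Speeds within ``speed_eps`` of zero count as holding depth: residual
    baseline slopes left by the offset correction are orders of magnitude
    below any real wiggle or step speed and must not seed sign runs.
    """
    d = np.asarray(depth_segment, dtype=float)
    n = d.shape[0]
    vs = vertical_speed(d, smooth_s)
    sgn = np.where(np.abs(vs) <= speed_eps, 0.0, np.sign(vs))
    # compress into nonzero-sign runs
    runs: list[tuple[int, int, int]] = []   # (sign, start, end)
    i = 0
    while i < n:
        s = sgn[i]
        j = i
        while j < n and sgn[j] == s:
            j += 1
        if s != 0:
            runs.append((int(s), i, j))
        i = j
    # identify the dive's own transit runs: first run if it descends from the
    # dive start, last run if it ascends to the dive end
    transit = set()
    if runs and runs[0][0] > 0 and runs[0][1] <= 1:
        transit.add(0)
    if runs and runs[-1][0] < 0 and runs[-1][2] >= n - 1:
        transit.add(len(runs) - 1)
    events: list[BottomEvent] = []
    for k in range(len(runs) - 1):
        s0, a0, b0 = runs[k]
        s1, a1, b1 = runs[k + 1]
        if s0 > 0 and s1 < 0 and k not in transit and (k + 1) not in transit:
            events.append(BottomEvent("wiggle", a0, b1,
                                      float(np.min(d[a0:b1])), float(np.max(d[a0:b1]))))
    claimed = np.zeros(n, dtype=bool)
    for ev in events:
        claimed[ev.start_s:ev.end_s] = True
    in_band = (vs > speed_eps) & (vs < step_speed_max) & ~claimed
    for a, b in _runs(in_band):
        if b - a >= min_step_s:
            events.append(BottomEvent("step", a, b,
                                      float(np.min(d[a:b])), float(np.max(d[a:b]))))
    events.sort(key=lambda e: (e.start_s, e.end_s))
    return events


def delimit_bottom(depth_segment: np.ndarray, events: list[BottomEvent],
                   ledge: float = LEDGE) -> tuple[list[DivePhase], bool]:
    """Partition one dive into descent/bottom/ascent (dive-relative indices).

    The bottom spans from the start of the first to the end of the last
    event reaching deeper than ``ledge`` x max depth.  Without a
    qualifying event the first-to-last crossing of that isobath is used
    and the fallback flag returned True.
    """
    d = np.asarray(depth_segment, dtype=float)
    n = d.shape[0]
    iso = ledge * float(np.max(d))
    qualifying = [e for e in events if e.max_depth_m > iso]
    fallback = False
    if qualifying:
        b0 = min(e.start_s for e in qualifying)
        b1 = max(e.end_s for e in qualifying)
    else:
        deep = np.where(d > iso)[0]
        b0, b1 = int(deep[0]), int(deep[-1]) + 1
        fallback = True
    phases = [DivePhase("descent", 0, b0),
              DivePhase("bottom", b0, b1),
              DivePhase("ascent", b1, n)]
    return phases, fallback


def flag_drift_dive(vs_segment: np.ndarray, effort_segment: np.ndarray,
                    effort_p10: float, min_len_s: int = 200,
                    vs_sd_max: float = 0.1,
                    vs_abs_range: tuple[float, float] = (0.05, 0.6)) -> bool:
    """True when the dive holds a passive segment >= min_len_s.

    Passive means: window-mean swimming effort below the deployment's 10th
    percentile, window SD of vertical speed < 0.1 m/s, and window-mean
    |vertical speed| inside 0.05-0.6 m/s (a steady drift, not a hang).
    """
    vs = np.asarray(vs_segment, dtype=float)
    eff = np.asarray(effort_segment, dtype=float)
    n = min(vs.shape[0], eff.shape[0])
    if n < min_len_s:
        return False
    vs, eff = vs[:n], eff[:n]
    w = min_len_s
    kern = np.ones(w) / w
    m_eff = np.convolve(eff, kern, mode="valid")
    m_vs = np.convolve(vs, kern, mode="valid")
    m_vs2 = np.convolve(vs * vs, kern, mode="valid")
    sd_vs = np.sqrt(np.maximum(m_vs2 - m_vs ** 2, 0.0))
    m_abs = np.convolve(np.abs(vs), kern, mode="valid")
    ok = (m_eff < effort_p10) & (sd_vs < vs_sd_max) \
        & (m_abs > vs_abs_range[0]) & (m_abs < vs_abs_range[1])
    return bool(ok.any())


def segment_deployment(depth: np.ndarray, effort: np.ndarray | None = None,
                       correct_offset: bool = True,
                       ledge: float = LEDGE) -> tuple[list[Dive], np.ndarray]:
    """Full segmentation of a 1 Hz depth record.

    Returns the dive list (phases/events attached, absolute seconds) and
    the offset-corrected depth.  When a 1 Hz swimming-effort series is
    supplied, drift dives are flagged as ``excluded='drift'`` (duration
    exclusions take precedence).
    """
    depth = np.asarray(depth, dtype=float)
    corrected = depth
    if correct_offset:
        corrected, _ = zero_offset_correct(depth)
    dives = detect_dives(corrected)
    p10 = float(np.percentile(effort, 10)) if effort is not None and len(effort) else 0.0
    for dv in dives:
        seg = corrected[dv.start_s:dv.end_s]
        events = find_wiggles_steps(seg)
        phases, fallback = delimit_bottom(seg, events, ledge=ledge)
        for e in events:
            e.start_s += dv.start_s
            e.end_s += dv.start_s
        for p in phases:
            p.start_s += dv.start_s
            p.end_s += dv.start_s
        dv.events, dv.phases, dv.fallback_delimitation = events, phases, fallback
        if dv.excluded is None and effort is not None:
            vs = vertical_speed(seg)
            if flag_drift_dive(vs, np.asarray(effort)[dv.start_s:dv.end_s], p10):
                dv.excluded = "drift"
    return dives, corrected


def dives_to_frame(dives: list[Dive]) -> pd.DataFrame:
    """Tabular view of a dive list (exclusion flags always written)."""
    return pd.DataFrame(
        [{"dive_id": d.id, "start_s": d.start_s, "end_s": d.end_s,
          "duration_s": d.duration_s, "max_depth_m": d.max_depth_m,
          "excluded": d.excluded or "", "fallback_delimitation": d.fallback_delimitation}
         for d in dives],
        columns=["dive_id", "start_s", "end_s", "duration_s", "max_depth_m",
                 "excluded", "fallback_delimitation"])
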