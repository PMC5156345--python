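"""Prey-encounter event (PEE) detection from tri-axial dynamic acceleration.

Rapid head movements during prey strikes show up as simultaneous broadband
transients on all three accelerometer axes.  The detector:

1. high-passes each axis at 2.64 Hz (order-3 Butterworth, 16 Hz data),
2. takes the sample standard deviation in fixed non-overlapping 1 s windows,
3. smooths with a centred 5 s moving standard deviation,
4. splits each axis' values into a "low" and a "high" state with an exact
   1-D two-means clustering over the whole deployment,
5. marks seconds where all three axes are simultaneously high, and merges
   each maximal run of such seconds into a single event.

The two-means step is solved exactly by enumerating splits of the sorted
values (no random initialisation), so detection is fully deterministic.
Events live on the 1 Hz state timeline as half-open [start_s, end_s)
intervals; sub-second timing is out of reach of the method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import filters
from .series import UniformSeries


@dataclass(frozen=True)
class PeeEvent:
    """One detected prey-encounter interval, half-open whole seconds."""

    start_s: int
    end_s: int

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s

    @property
    def mid_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


def block_sd(x: np.ndarray, fs: int = 16) -> np.ndarray:
    """Sample SD (ddof=1) over non-overlapping 1 s blocks of a 16 Hz signal.

    A trailing partial block is dropped.
    """
    x = np.asarray(x, dtype=float)
    n_blocks = x.shape[0] // fs
    if n_blocks * fs != x.shape[0]:
        warnings.warn(f"dropping trailing partial block of {x.shape[0] - n_blocks * fs} samples")
    return x[: n_blocks * fs].reshape(n_blocks, fs).std(axis=1, ddof=1)


def moving_sd(x: np.ndarray, window: int = 5, min_periods: int = 3) -> np.ndarray:
    """Centred moving sample SD; edges use the available partial window."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < min_periods:
        raise ValueError(f"need at least {min_periods} samples, got {x.shape[0]}")
    s = pd.Series(x).rolling(window, center=True, min_periods=min_periods).std(ddof=1)
    return s.to_numpy()


def two_means_1d(values: np.ndarray) -> tuple[float, np.ndarray]:
    """Exact 1-D two-cluster split minimising within-cluster sum of squares.

    Returns ``(threshold, labels)`` where labels are True for the upper
    ("high") cluster and the threshold is the midpoint between the two
    clusters' boundary values.  All-identical input yields all-low with a
    warning.  Ties in WSS are broken toward the smallest high cluster.
    """
    raw = np.asarray(values, dtype=float)
    x = np.sort(raw)
    n = x.shape[0]
    if n < 2 or x[0] == x[-1]:
        warnings.warn("two_means_1d: degenerate input, labelling everything low")
        return float("inf"), np.zeros(raw.shape[0], dtype=bool)
    # prefix sums give every candidate split's WSS in O(n); split i puts
    # x[:i+1] in the lower cluster and x[i+1:] in the upper one
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    k = np.arange(1, n)
    s1, s2 = c1[k - 1], c2[k - 1]
    wss_lo = s2 - s1 ** 2 / k
    s1h, s2h = c1[-1] - s1, c2[-1] - s2
    wss_hi = s2h - s1h ** 2 / (n - k)
    wss = wss_lo + wss_hi
    # a split between equal values is not a realisable partition boundary
    valid = x[k] > x[k - 1]
    wss[~valid] = np.inf
    i = int(np.max(np.where(wss == wss.min())[0]))
    threshold = 0.5 * (x[i] + x[i + 1])
    labels = raw > threshold
    return float(threshold), labels


def events_from_states(high3: np.ndarray) -> list[PeeEvent]:
    """Merge maximal runs of all-axes-high seconds into events."""
    allhigh = np.all(np.asarray(high3, dtype=bool), axis=0)
    padded = np.concatenate([[False], allhigh, [False]])
    d = np.diff(padded.astype(int))
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    return [PeeEvent(int(a), int(b)) for a, b in zip(starts, ends)]


def cluster_separation(values: np.ndarray, labels: np.ndarray) -> float:
    """Between-cluster mean gap in units of pooled within-cluster SD."""
    v = np.asarray(values, dtype=float)
    if not labels.any() or labels.all() or v.shape[0] < 3:
        return 0.0
    lo, hi = v[~labels], v[labels]
    wss = float(((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum())
    if wss <= 0:
        return float("inf")
    return float((hi.mean() - lo.mean()) / np.sqrt(wss / (v.shape[0] - 2)))


def detect_pee(accel3: UniformSeries, mode: str = "zero_phase",
               min_separation: float = 4.0) -> list[PeeEvent]:
    """Run the full detector on a 16 Hz tri-axial acceleration record.

    When an axis' two states are not genuinely distinct — the between-state
    gap is below ``min_separation`` pooled within-state SDs, as happens on
    a record with no transients at all — its clustering collapses to
    all-low (a unimodal noise distribution split in two is ~2.5-3 such
    units; real strike transients sit far above).
    """
    if accel3.n_channels != 3:
        raise ValueError("detect_pee expects a tri-axial series")
    if accel3.duration_s < 60:
        raise ValueError("record too short (< 60 s) for state clustering")
    dyn = filters.dynamic_acceleration(accel3, mode=mode).values
    fs = int(round(accel3.fs_hz))
    high = []
    for j in range(3):
        sd1 = block_sd(dyn[:, j], fs)
        smooth = moving_sd(sd1)
        _, labels = two_means_1d(smooth)
        if labels.any() and cluster_separation(smooth, labels) < min_separation:
            warnings.warn(f"axis {j}: high/low states indistinct; collapsed to low")
            labels = np.zeros_like(labels)
        if not labels.any():
            warnings.warn(f"axis {j}: no high state found, zero events possible")
        high.append(labels)
    return events_from_states(np.vstack(high))


def assign_events_to_phases(events, dives) -> pd.DataFrame:
    """Label each event with the dive phase containing its midpoint second.

    ``dives`` is an iterable of objects with ``start_s``/``end_s`` and a
    ``phases`` list of objects with ``kind``/``start_s``/``end_s``.
    Events outside every dive are labelled ``"surface"``.
    """
    rows = []
    for ev in events:
        mid = ev.mid_s
        label, dive_id = "surface", None
        for d in dives:
            if d.start_s <= mid < d.end_s:
                dive_id = d.id
                label = "other"
                for ph in d.phases or []:
                    if ph.start_s <= mid < ph.end_s:
                        label = ph.kind
                        break
                break
        rows.append({"start_s": ev.start_s, "end_s": ev.end_s,
                     "duration_s": ev.duration_s, "dive_id": dive_id, "phase": label})
    return pd.DataFrame(rows, columns=["start_s", "end_s", "duration_s", "dive_id", "phase"])
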