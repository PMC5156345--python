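"""Butterworth filtering primitives shared by every pipeline stage.

Tri-axial accelerometer records mix three spectral regimes:

* a quasi-static component below ~0.2 Hz carrying the gravity direction
  (posture),
* lateral-axis stroking in the 0.44-1.02 Hz band (propulsive tail beats),
* broadband transients above ~2.64 Hz from rapid head movements during
  prey strikes.

The decomposition uses order-3 digital Butterworth filters at 16 Hz:
low-pass 0.20 Hz for the static (gravity) component, high-pass 2.64 Hz
for the dynamic component, band-pass 0.44-1.02 Hz for swimming effort.
Cutoffs are physical Hz; the default filtering mode is zero-phase
(forward-backward) so filtered states stay time-aligned with the 1 Hz
depth channel and across axes, which coincidence detection depends on.
A forward-only mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .series import UniformSeries

#: Default cutoffs (Hz) at the 16 Hz accelerometer rate.
STATIC_CUTOFF_HZ = 0.20
DYNAMIC_CUTOFF_HZ = 2.64
EFFORT_BAND_HZ = (0.44, 1.02)
FILTER_ORDER = 3
ACCEL_FS_HZ = 16.0


@dataclass(frozen=True)
class FilterSpec:
    """Specification of a digital Butterworth filter.

    ``cutoff_hz`` is a scalar for lowpass/highpass and a ``(low, high)``
    pair for bandpass; all cutoffs must lie strictly inside (0, fs/2).
    """

    order: int
    kind: str  # lowpass | highpass | bandpass
    cutoff_hz: float | tuple[float, float]
    fs_hz: float

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        nyq = self.fs_hz / 2.0
        cutoffs = np.atleast_1d(np.asarray(self.cutoff_hz, dtype=float))
        if self.kind == "bandpass" and cutoffs.size != 2:
            raise ValueError("bandpass needs (low, high) cutoffs")
        if self.kind != "bandpass" and cutoffs.size != 1:
            raise ValueError(f"{self.kind} needs a single cutoff")
        for c in cutoffs:
            if not 0.0 < c < nyq:
                raise ValueError(
                    f"cutoff {c} Hz outside (0, Nyquist={nyq} Hz) at fs={self.fs_hz} Hz")
        if self.kind == "bandpass" and cutoffs[0] >= cutoffs[1]:
            raise ValueError("bandpass cutoffs must be increasing")


def design_butterworth(spec: FilterSpec) -> np.ndarray:
    """Design the filter; returns second-order sections (shape (k, 6))."""
    wn = np.atleast_1d(np.asarray(spec.cutoff_hz, dtype=float))
    return sps.butter(spec.order, wn if wn.size > 1 else wn[0],
                      btype=spec.kind, fs=spec.fs_hz, output="sos")


def frequency_response(spec: FilterSpec, freqs_hz: np.ndarray) -> np.ndarray:
    """Complex frequency response of the (single-pass) filter at freqs_hz."""
    sos = design_butterworth(spec)
    _, h = sps.sosfreqz(sos, worN=np.asarray(freqs_hz, dtype=float), fs=spec.fs_hz)
    return h


def apply_filter(series: UniformSeries, spec: FilterSpec,
                 mode: str = "zero_phase") -> UniformSeries:
    """Filter every channel of ``series``.

    ``zero_phase`` runs the filter forward and backward (no group delay,
    squared magnitude response); ``forward`` is a single causal pass.
    Edges use reflect padding of 3 x the filter length; output length and
    sampling rate equal the input's.
    """
    if spec.fs_hz != series.fs_hz:
        raise ValueError(f"filter fs {spec.fs_hz} != series fs {series.fs_hz}")
    if series.n <= 3 * spec.order:
        raise ValueError(
            f"series of {series.n} samples too short for order-{spec.order} filter")
    sos = design_butterworth(spec)
    x = series.values
    if mode == "zero_phase":
        padlen = min(series.n - 1, 3 * max(len(sos) * 6, 24))
        y = sps.sosfiltfilt(sos, x, axis=0, padlen=padlen)
    elif mode == "forward":
        y = sps.sosfilt(sos, x, axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return series.with_values(y)


def static_acceleration(accel3: UniformSeries,
                        cutoff_hz: float = STATIC_CUTOFF_HZ,
                        order: int = FILTER_ORDER,
                        mode: str = "zero_phase") -> UniformSeries:
    """Gravity direction: low-pass each axis, then scale to unit norm.

    Samples whose pre-scaling norm is below 1e-6 g carry no direction
    information; they are flagged and linearly interpolated from
    neighbouring valid samples before scaling.
    """
    if accel3.n_channels != 3:
        raise ValueError("static_acceleration expects a tri-axial series")
    spec = FilterSpec(order, "lowpass", cutoff_hz, accel3.fs_hz)
    low = apply_filter(accel3, spec, mode=mode).values
    norm = np.linalg.norm(low, axis=1)
    bad = norm < 1e-6
    if bad.any():
        good = ~bad
        if not good.any():
            raise ValueError("no sample with usable gravity norm")
        idx = np.arange(accel3.n)
        for j in range(3):
            low[bad, j] = np.interp(idx[bad], idx[good], low[good, j])
        norm = np.linalg.norm(low, axis=1)
    unit = low / norm[:, None]
    return accel3.with_values(unit, flags=bad)


def dynamic_acceleration(accel3: UniformSeries,
                         cutoff_hz: float = DYNAMIC_CUTOFF_HZ,
                         order: int = FILTER_ORDER,
                         mode: str = "zero_phase") -> UniformSeries:
    """High-frequency component from rapid head movements (per channel)."""
    spec = FilterSpec(order, "highpass", cutoff_hz, accel3.fs_hz)
    return apply_filter(accel3, spec, mode=mode)


def swimming_effort(lateral: UniformSeries,
                    band_hz: tuple[float, float] = EFFORT_BAND_HZ,
                    order: int = FILTER_ORDER,
                    mode: str = "zero_phase") -> UniformSeries:
    """Stroking proxy: band-pass, rectify, block-average to 1 Hz.

    The lateral axis is band-passed to the stroking band, rectified, and
    the absolute value averaged over non-overlapping 1 s blocks aligned
    to whole seconds of the record start. Result is a non-negative 1 Hz
    series; a trailing partial second is dropped.
    """
    if lateral.n_channels != 1:
        raise ValueError("swimming_effort expects the single lateral axis")
    spec = FilterSpec(order, "bandpass", band_hz, lateral.fs_hz)
    y = np.abs(apply_filter(lateral, spec, mode=mode).values)
    block = int(round(lateral.fs_hz))
    n_blocks = y.shape[0] // block
    eff = y[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    return UniformSeries(eff, 1.0, lateral.start_time)
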