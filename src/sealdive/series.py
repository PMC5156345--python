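"""Uniformly sampled time series container shared across the pipeline.

All sensor streams in this package are gap-free, uniformly sampled arrays
(1 Hz depth, 16 Hz acceleration/magnetometry).  :class:`UniformSeries` is a
thin wrapper around a numpy array carrying the sampling rate and start time
so per-channel operations preserve alignment metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class UniformSeries:
    """A gap-free, uniformly sampled 1- or 3-channel series.

    Parameters
    ----------
    values : ndarray
        Shape ``(n,)`` for a single channel or ``(n, k)`` for ``k`` channels.
    fs_hz : float
        Sampling rate in Hz.
    start_time : float
        Epoch seconds of the first sample (default 0).
    """

    values: np.ndarray
    fs_hz: float
    start_time: float = 0.0
    flags: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.values.ndim not in (1, 2):
            raise ValueError("values must be 1-D or 2-D (n, channels)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n / self.fs_hz

    def times(self) -> np.ndarray:
        """Sample times in epoch seconds."""
        return self.start_time + np.arange(self.n) / self.fs_hz

    def with_values(self, values: np.ndarray, fs_hz: float | None = None,
                    flags: np.ndarray | None = None) -> "UniformSeries":
        """Copy metadata onto a new value array (optionally at a new rate)."""
        return UniformSeries(values, fs_hz if fs_hz is not None else self.fs_hz,
                             self.start_time, flags)
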