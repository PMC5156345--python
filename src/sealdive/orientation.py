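"""Body posture angles from static acceleration and magnetometry.

Conventions (fixed here because downstream metrics only use magnitudes and
angular variances, which are convention-invariant):

* body axes: X forward, Y right, Z down; a stationary level logger reads
  (0, 0, +1) g;
* pitch in [-90, 90] degrees, positive nose-up;
* roll in (-180, 180] degrees, positive right-side-down;
* heading in [0, 360) degrees, clockwise from magnetic north, in the
  North-East-Down (NED) earth frame.

With a per-sample unit gravity vector ``s`` the trigonometry is
``pitch = -arcsin(s_x)`` and ``roll = atan2(s_y, s_z)``.  Heading comes
from tilt-compensating the (low-pass filtered) body-frame magnetic vector:
rotate by roll then pitch into the horizontal plane and take
``atan2(-m_y, m_x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import UniformSeries

_UNIT_TOL = 1e-6


@dataclass
class OrientationSeries:
    """Pitch/roll/heading in degrees at a common sampling rate.

    ``heading_ok`` marks samples where the horizontal magnetic component
    was large enough for heading to be defined (pitch away from +/-90 and
    field not vertical in the body-horizontal plane).
    """

    pitch_deg: np.ndarray
    roll_deg: np.ndarray
    heading_deg: np.ndarray
    fs_hz: float
    heading_ok: np.ndarray | None = None


def pitch_roll(static3: UniformSeries) -> tuple[np.ndarray, np.ndarray]:
    """Pitch and roll (degrees) from a unit-norm static-acceleration series."""
    s = static3.values
    norm = np.linalg.norm(s, axis=1)
    if np.any(np.abs(norm - 1.0) > _UNIT_TOL):
        raise ValueError(
            "static acceleration is not unit-norm; run filters.static_acceleration first")
    pitch = -np.degrees(np.arcsin(np.clip(s[:, 0], -1.0, 1.0)))
    roll = np.degrees(np.arctan2(s[:, 1], s[:, 2]))
    return pitch, roll


def tilt_compensated_heading(pitch_deg: np.ndarray, roll_deg: np.ndarray,
                             mag3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Heading (degrees, [0, 360)) from pitch/roll and filtered magnetometry.

    The body-frame magnetic vector is de-rotated by roll about X then
    pitch about Y; the horizontal components then give
    ``heading = atan2(-m_y_h, m_x_h)``.  Returns ``(heading, ok)`` where
    ``ok`` is False on samples whose horizontal magnetic component is
    below 1e-6 of the field norm (heading undefined there; value NaN).
    """
    th = np.radians(np.asarray(pitch_deg, dtype=float))
    ph = np.radians(np.asarray(roll_deg, dtype=float))
    m = np.asarray(mag3, dtype=float)
    mx, my, mz = m[..., 0], m[..., 1], m[..., 2]
    # roll de-rotation about X
    my1 = my * np.cos(ph) - mz * np.sin(ph)
    mz1 = my * np.sin(ph) + mz * np.cos(ph)
    # pitch de-rotation about Y
    mxh = mx * np.cos(th) + mz1 * np.sin(th)
    myh = my1
    horiz = np.hypot(mxh, myh)
    ok = horiz >= 1e-6 * np.maximum(np.linalg.norm(m, axis=-1), 1e-300)
    heading = np.degrees(np.arctan2(-myh, mxh)) % 360.0
    heading = np.where(ok, heading, np.nan)
    return heading, ok


def circular_mean(angles_deg) -> float:
    """Circular mean of angles in degrees (atan2 of mean sin/cos).

    Raises on empty input; returns NaN when the mean resultant length is
    below 1e-12 (mean undefined, e.g. perfectly antipodal angles).
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circular_mean of empty input")
    c, s = np.mean(np.cos(a)), np.mean(np.sin(a))
    if np.hypot(c, s) < 1e-12:
        return float("nan")
    return float(np.degrees(np.arctan2(s, c)))


def circular_variance(angles_deg) -> float:
    """Circular variance ``1 - Rbar`` in [0, 1]; 0 = no dispersion."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circular_variance of empty input")
    rbar = np.hypot(np.mean(np.cos(a)), np.mean(np.sin(a)))
    return float(min(max(1.0 - rbar, 0.0), 1.0))


def block_circular_mean(angles_deg: np.ndarray, block: int) -> np.ndarray:
    """Circular mean over non-overlapping blocks (degree input/output)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    n_blocks = a.shape[0] // block
    a = a[: n_blocks * block].reshape(n_blocks, block)
    c = np.nanmean(np.cos(a), axis=1)
    s = np.nanmean(np.sin(a), axis=1)
    return np.degrees(np.arctan2(s, c))


def orientation_from_sensors(static3: UniformSeries, mag3_filtered: UniformSeries,
                             out_fs_hz: float = 1.0) -> OrientationSeries:
    """Full posture series at ``out_fs_hz`` (block circular means of 16 Hz angles)."""
    pitch, roll = pitch_roll(static3)
    heading, ok = tilt_compensated_heading(pitch, roll, mag3_filtered.values)
    block = int(round(static3.fs_hz / out_fs_hz))
    if block > 1:
        pitch = block_circular_mean(pitch, block)
        roll = block_circular_mean(roll, block)
        heading = block_circular_mean(heading, block) % 360.0
        n = ok.shape[0] // block
        ok = ok[: n * block].reshape(n, block).all(axis=1)
    return OrientationSeries(pitch, roll, heading % 360.0, out_fs_hz, ok)
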