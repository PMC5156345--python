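"""Synthetic daily-diary deployments with ground truth.

Real deployments of depth/acceleration/magnetometer tags on deep-diving
seals are not redistributable, so every downstream stage is exercised on a
simulator that emulates the data-generating process the pipeline assumes:

* dives of 500-1950 s to a few hundred metres, separated by 2-3 min
  surface intervals; descent and ascent at steep pitch, a bottom phase
  holding near maximum depth;
* bottom wiggles (smooth down-then-up depth excursions) and steps (slow
  glides with vertical speed strictly inside (0, 0.35) m/s);
* body orientation consistent with the motion: vertical speed equals
  swim speed x sin(pitch), heading a per-phase random walk (more sinuous
  at the bottom), gravity and the local magnetic field projected into the
  body frame at 16 Hz;
* lateral-axis stroking as a sinusoid in the 0.44-1.02 Hz band;
* prey-encounter bursts as 3-8 Hz band-limited noise applied to all three
  accelerometer axes simultaneously (two-axis-only bursts available as
  negative controls);
* slow pressure-sensor drift on the 0.5 m-quantized depth channel, and
  GPS fixes at a configurable fraction of surfacings (default 0.6);
* occasional drift dives: a long passive segment of steady slow sinking
  with no stroking (resting/digesting), to exercise the exclusion path.

Sign convention: a stationary, level logger reads (0, 0, +1) g on body
axes (X forward, Y right, Z down); pitch is positive nose-up, so a
descending seal has negative pitch and vertical speed
``= -swim_speed x sin(pitch)`` (depth positive downward).

The same seed and config always reproduce the deployment bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .series import UniformSeries

EPOCH_2010_11_01 = 1288569600.0  # default deployment start (UTC)


# --------------------------------------------------------------------------
# configuration and truth containers

@dataclass(frozen=True)
class WiggleSpec:
    """One bottom wiggle: smooth down-up excursion of ``amplitude_m``.

    ``start_s`` is relative to the bottom-phase start.  The excursion depth
    follows A sin^2(pi t / w), so peak vertical speed is A pi / w and must
    stay below the swim speed.
    """
    start_s: int
    duration_s: int
    amplitude_m: float


@dataclass(frozen=True)
class StepSpec:
    """One step glide at constant ``speed_m_s`` in (0, 0.35) m/s."""
    start_s: int
    duration_s: int
    speed_m_s: float


@dataclass(frozen=True)
class SimConfig:
    """Deployment-level simulation parameters (defaults = study conditions)."""

    seed: int = 0
    n_dives: int = 20
    depth_range_m: tuple[float, float] = (200.0, 650.0)
    dive_duration_s: tuple[int, int] = (700, 1800)
    surface_duration_s: tuple[int, int] = (120, 180)
    swim_speed_m_s: float = 2.0
    pitch_descent_deg: tuple[float, float] = (55.0, 80.0)
    stroke_freq_hz: float = 0.7
    stroke_amp: float = 0.3          # g
    pee_per_bottom_min: float = 0.8  # expected bursts per bottom minute at 400 m
    pee_depth_coef: float = -0.4     # log-rate change per +200 m of bottom depth
    burst_dur_s: tuple[int, int] = (1, 3)
    burst_amp: float = 0.4           # g RMS inside the burst
    burst_axes: tuple[int, ...] = (0, 1, 2)
    noise_sd: float = 0.03           # g, white accelerometer noise
    mag_noise_sd: float = 0.005
    pressure_drift_m_per_h: float = 0.5
    gps_fix_prob: float = 0.6
    mag_field: tuple[float, float, float] = (0.35, 0.0, -0.87)  # NED, southern hemisphere
    wiggles_per_dive: tuple[int, int] = (1, 4)
    wiggle_amp_m: tuple[float, float] = (8.0, 16.0)
    wiggle_dur_s: tuple[int, int] = (25, 45)
    steps_per_dive: tuple[int, int] = (0, 2)
    step_speed_m_s: tuple[float, float] = (0.1, 0.3)
    step_dur_s: tuple[int, int] = (20, 40)
    drift_dive_every: int | None = 10   # every k-th dive is a drift dive
    drift_sink_m_s: float = 0.3
    roll_amp_deg: float = 5.0
    heading_sd_transit_deg: float = 1.0  # per-second random-walk step
    heading_sd_bottom_deg: float = 6.0
    ramp_s: int = 8                  # body-reorientation timescale
    depth_resolution_m: float = 0.5
    accel_fs_hz: int = 16
    # midday UTC start at Kerguelen longitudes: a multi-hour record straddles
    # the evening terminator, giving both day and night dives
    start_time: float = EPOCH_2010_11_01 + 43200.0
    lat0: float = -49.5
    lon0: float = 70.2

    def __post_init__(self) -> None:
        if self.n_dives < 0:
            raise ValueError("n_dives must be >= 0")
        for lo, hi in (self.dive_duration_s, self.surface_duration_s,
                       self.burst_dur_s, self.wiggle_dur_s, self.step_dur_s):
            if lo <= 0 or hi < lo:
                raise ValueError("durations must be positive with lo <= hi")
        if not 0.44 <= self.stroke_freq_hz <= 1.02:
            raise ValueError("stroke_freq_hz must lie in the 0.44-1.02 Hz stroking band")
        if not 0 < self.step_speed_m_s[0] <= self.step_speed_m_s[1] < 0.35:
            raise ValueError("step speeds must lie strictly inside (0, 0.35) m/s")
        # reject configs whose shallowest required depth cannot be reached in
        # the longest allowed dive at the steepest transit pitch
        vmax = self.swim_speed_m_s * np.sin(np.radians(self.pitch_descent_deg[1]))
        reachable = 0.4 * self.dive_duration_s[1] * vmax
        if self.depth_range_m[0] > reachable:
            raise ValueError(
                f"min depth {self.depth_range_m[0]} m unreachable: transit can cover "
                f"at most {reachable:.0f} m in {self.dive_duration_s[1]} s")


@dataclass
class DeploymentTruth:
    """Everything the generator knows that the pipeline must recover."""

    dives: list = field(default_factory=list)          # (start_s, end_s), >15 m crossings
    phases: list = field(default_factory=list)         # per dive: {kind: (start_s, end_s)} or None
    wiggles: list = field(default_factory=list)        # absolute (start_s, end_s)
    steps: list = field(default_factory=list)
    pee: list = field(default_factory=list)            # absolute (start_s, end_s)
    drift_flags: list = field(default_factory=list)    # per dive bool
    pitch_deg: np.ndarray | None = None                # 1 Hz
    roll_deg: np.ndarray | None = None
    heading_deg: np.ndarray | None = None
    depth_true_m: np.ndarray | None = None             # noiseless, unquantized
    offset_m: np.ndarray | None = None                 # injected pressure drift


@dataclass
class SensorDeployment:
    """Synchronized multi-rate streams for one animal."""

    depth: UniformSeries       # 1 Hz, drift + quantization applied
    accel: UniformSeries       # 16 Hz x 3, g
    mag: UniformSeries         # 16 Hz x 3, arbitrary units
    gps: pd.DataFrame          # columns time (epoch s), lat, lon
    start_time: float


# --------------------------------------------------------------------------
# dive profile construction

def _cos_ramp(n: int) -> np.ndarray:
    """Smooth 0 -> 1 ramp over n samples (half-cosine)."""
    return 0.5 * (1.0 - np.cos(np.pi * (np.arange(n) + 0.5) / n))


def _plateau(n: int, level: float, ramp: int) -> np.ndarray:
    """Speed segment: ramp up, hold ``level``, ramp down; length n."""
    r = min(ramp, n // 2)
    seg = np.full(n, level, dtype=float)
    if r > 0:
        seg[:r] = level * _cos_ramp(r)
        seg[n - r:] = level * _cos_ramp(r)[::-1]
    return seg


def simulate_dive_profile(duration_s: int, max_depth_m: float,
                          wiggles: tuple[WiggleSpec, ...] = (),
                          steps: tuple[StepSpec, ...] = (),
                          swim_speed_m_s: float = 2.0,
                          pitch_descent_deg: float = 70.0,
                          pitch_ascent_deg: float = 65.0,
                          ramp_s: int = 8) -> tuple[np.ndarray, dict]:
    """Build one dive's noiseless 1 Hz depth segment and its event truth.

    The profile is a smooth vertical-speed series (cosine ramps over
    ``ramp_s`` seconds, the body-reorientation timescale) integrated to
    depth: descent to ``max_depth_m`` at the descent pitch, a bottom span
    carrying the requested wiggles and steps, then ascent back to the
    surface.  Returns ``(depth, truth)`` where truth holds the exact
    half-open event and phase intervals relative to the dive start and
    the 1 Hz vertical-speed series.
    """
    t_total = int(duration_s)
    v_d = swim_speed_m_s * np.sin(np.radians(pitch_descent_deg))
    v_a = swim_speed_m_s * np.sin(np.radians(pitch_ascent_deg))
    step_gain = sum(s.speed_m_s * (s.duration_s - min(ramp_s, s.duration_s // 2))
                    for s in steps)
    t_desc = int(round(max_depth_m / v_d)) + ramp_s
    t_asc = int(round((max_depth_m + step_gain) / v_a)) + ramp_s
    t_bottom = t_total - t_desc - t_asc
    if t_bottom < 10:
        raise ValueError(
            f"dive of {duration_s}s cannot reach {max_depth_m} m and keep a bottom phase")
    for w in wiggles:
        peak = w.amplitude_m * np.pi / w.duration_s
        if peak >= swim_speed_m_s:
            raise ValueError(
                f"wiggle amplitude {w.amplitude_m} m over {w.duration_s}s needs vertical "
                f"speed {peak:.2f} m/s >= swim speed")
        if w.start_s < 0 or w.start_s + w.duration_s > t_bottom:
            raise ValueError("wiggle outside the bottom span")
    for s in steps:
        if not 0 < s.speed_m_s < 0.35:
            raise ValueError(f"step speed {s.speed_m_s} m/s outside (0, 0.35)")
        if s.start_s < 0 or s.start_s + s.duration_s > t_bottom:
            raise ValueError("step outside the bottom span")

    vs = np.zeros(t_total)
    vs[:t_desc] = _plateau(t_desc, v_d, ramp_s)
    vs[t_total - t_asc:] = _plateau(t_asc, -v_a, ramp_s)
    b0 = t_desc
    truth_w, truth_s = [], []
    for w in wiggles:
        a = b0 + w.start_s
        tt = np.arange(w.duration_s)
        vs[a:a + w.duration_s] += (w.amplitude_m * np.pi / w.duration_s
                                   * np.sin(2 * np.pi * (tt + 0.5) / w.duration_s))
        truth_w.append((a, a + w.duration_s))
    for s in steps:
        a = b0 + s.start_s
        vs[a:a + s.duration_s] += _plateau(s.duration_s, s.speed_m_s, ramp_s)
        truth_s.append((a, a + s.duration_s))

    # trim the ascent plateau so the integrated profile ends exactly at 0 m
    residual = vs.sum()
    plateau = slice(t_total - t_asc + ramp_s, t_total - ramp_s)
    n_pl = plateau.stop - plateau.start
    if n_pl > 0:
        vs[plateau] -= residual / n_pl
    depth = np.cumsum(vs)

    events = sorted(truth_w + truth_s)
    if events:
        bottom = (events[0][0], events[-1][1])
    else:
        bottom = (b0, t_total - t_asc)
    truth = {"wiggles": truth_w, "steps": truth_s, "vs": vs,
             "phases": {"descent": (0, bottom[0]), "bottom": bottom,
                        "ascent": (bottom[1], t_total)},
             "t_descent": t_desc, "t_ascent": t_asc}
    return depth, truth


def _drift_dive_profile(duration_s: int, max_depth_m: float, sink_m_s: float,
                        swim_speed_m_s: float, pitch_deg: float,
                        ramp_s: int) -> tuple[np.ndarray, dict]:
    """Descent, long passive sink at ``sink_m_s``, ascent; no bottom events."""
    v = swim_speed_m_s * np.sin(np.radians(pitch_deg))
    t_total = int(duration_s)
    t_desc = int(round(max_depth_m / v)) + ramp_s
    # passive segment sized to leave room for the (deeper) ascent plus margin
    t_drift = t_total - 2 * t_desc - 60
    gain = sink_m_s * (t_drift - ramp_s)
    t_asc = int(round((max_depth_m + gain) / v)) + ramp_s
    idle = t_total - t_desc - t_drift - t_asc
    if idle < 0:
        t_drift += idle          # shrink the passive segment to fit
        gain = sink_m_s * (t_drift - ramp_s)
        t_asc = int(round((max_depth_m + gain) / v)) + ramp_s
    if t_drift < 250 or t_total - t_desc - t_drift - t_asc < 0:
        raise ValueError("drift dive too short for a passive segment")
    vs = np.zeros(t_total)
    vs[:t_desc] = _plateau(t_desc, v, ramp_s)
    vs[t_desc:t_desc + t_drift] = _plateau(t_drift, sink_m_s, ramp_s)
    vs[t_total - t_asc:] = _plateau(t_asc, -v, ramp_s)
    residual = vs.sum()
    plateau = slice(t_total - t_asc + ramp_s, t_total - ramp_s)
    if plateau.stop > plateau.start:
        vs[plateau] -= residual / (plateau.stop - plateau.start)
    depth = np.cumsum(vs)
    truth = {"wiggles": [], "steps": [], "vs": vs, "phases": None,
             "drift_span": (t_desc, t_desc + t_drift),
             "t_descent": t_desc, "t_ascent": t_asc}
    return depth, truth


# --------------------------------------------------------------------------
# burst synthesis

def make_burst(n_samples: int, fs: int, amp_rms: float,
               rng: np.random.Generator) -> np.ndarray:
    """Band-limited (3-8 Hz) noise burst with a Tukey envelope, given RMS."""
    sos = sps.butter(4, [3.0, min(8.0, fs / 2 - 0.01)], btype="bandpass", fs=fs,
                     output="sos")
    pad = 4 * fs
    x = sps.sosfilt(sos, rng.standard_normal(n_samples + pad))[pad:]
    x *= sps.windows.tukey(n_samples, 0.25)
    rms = np.sqrt(np.mean(x ** 2))
    return x * (amp_rms / rms) if rms > 0 else x


# --------------------------------------------------------------------------
# deployment assembly

def _draw_bottom_events(rng: np.random.Generator, cfg: SimConfig,
                        t_bottom: int) -> tuple[list[WiggleSpec], list[StepSpec]]:
    """Place non-overlapping wiggles/steps (>= 6 s gaps) in the bottom span."""
    n_w = int(rng.integers(cfg.wiggles_per_dive[0], cfg.wiggles_per_dive[1] + 1))
    n_s = int(rng.integers(cfg.steps_per_dive[0], cfg.steps_per_dive[1] + 1))
    wants = (["w"] * n_w) + (["s"] * n_s)
    rng.shuffle(wants)
    cursor, gap = 6, 6
    wiggles, steps = [], []
    for kind in wants:
        if kind == "w":
            dur = int(rng.integers(cfg.wiggle_dur_s[0], cfg.wiggle_dur_s[1] + 1))
            amp = float(rng.uniform(*cfg.wiggle_amp_m))
            amp = min(amp, 0.9 * cfg.swim_speed_m_s * dur / np.pi)
        else:
            dur = int(rng.integers(cfg.step_dur_s[0], cfg.step_dur_s[1] + 1))
        slack = t_bottom - gap - cursor - dur
        if slack <= 0:
            continue
        start = cursor + int(rng.integers(0, min(slack, 60) + 1))
        if kind == "w":
            wiggles.append(WiggleSpec(start, dur, amp))
        else:
            steps.append(StepSpec(start, dur, float(rng.uniform(*cfg.step_speed_m_s))))
        cursor = start + dur + gap
    return wiggles, steps


def simulate_deployment(cfg: SimConfig) -> tuple[SensorDeployment, DeploymentTruth]:
    """Generate one full synthetic deployment with ground truth."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.accel_fs_hz
    vmax_pitch = cfg.pitch_descent_deg[1]
    vmax = cfg.swim_speed_m_s * np.sin(np.radians(vmax_pitch))

    vs_parts: list[np.ndarray] = []
    stroke_parts: list[np.ndarray] = []   # 1 = stroking, 0 = passive
    truth = DeploymentTruth()
    surf_mids: list[float] = []
    cursor = 0

    def add_surface() -> None:
        nonlocal cursor
        dur = int(rng.integers(cfg.surface_duration_s[0], cfg.surface_duration_s[1] + 1))
        vs_parts.append(np.zeros(dur))
        stroke_parts.append(np.zeros(dur))
        surf_mids.append(cursor + dur / 2.0)
        cursor += dur

    add_surface()
    for i in range(cfg.n_dives):
        dur = int(rng.integers(cfg.dive_duration_s[0], cfg.dive_duration_s[1] + 1))
        p_desc = float(rng.uniform(*cfg.pitch_descent_deg))
        p_asc = float(rng.uniform(*cfg.pitch_descent_deg))
        v_d = cfg.swim_speed_m_s * np.sin(np.radians(p_desc))
        v_a = cfg.swim_speed_m_s * np.sin(np.radians(p_asc))
        feasible = 0.4 * dur * min(v_d, v_a)
        depth_hi = min(cfg.depth_range_m[1], feasible)
        if depth_hi <= cfg.depth_range_m[0]:
            depth_tgt = min(cfg.depth_range_m[0], feasible)
        else:
            depth_tgt = float(rng.uniform(cfg.depth_range_m[0], depth_hi))
        is_drift = (cfg.drift_dive_every is not None
                    and cfg.n_dives > 1 and (i + 1) % cfg.drift_dive_every == 0)
        if is_drift:
            d_depth = min(depth_tgt, 0.22 * dur * v_d)
            seg, tr = _drift_dive_profile(dur, d_depth, cfg.drift_sink_m_s,
                                          cfg.swim_speed_m_s, p_desc, cfg.ramp_s)
            stroke = np.ones(len(seg))
            a, b = tr["drift_span"]
            stroke[a:b] = 0.0
        else:
            t_desc = int(round(depth_tgt / v_d)) + cfg.ramp_s
            t_asc = int(round(depth_tgt / v_a)) + cfg.ramp_s
            t_bottom = dur - t_desc - t_asc - 40   # margin for step-gain ascent growth
            wig, stp = (_draw_bottom_events(rng, cfg, t_bottom)
                        if t_bottom > 60 else ([], []))
            seg, tr = simulate_dive_profile(dur, depth_tgt, tuple(wig), tuple(stp),
                                            cfg.swim_speed_m_s, p_desc, p_asc, cfg.ramp_s)
            stroke = np.ones(len(seg))
        start = cursor
        truth.wiggles += [(start + a, start + b) for a, b in tr["wiggles"]]
        truth.steps += [(start + a, start + b) for a, b in tr["steps"]]
        if tr["phases"] is not None:
            truth.phases.append({k: (start + a, start + b)
                                 for k, (a, b) in tr["phases"].items()})
        else:
            truth.phases.append(None)
        truth.drift_flags.append(is_drift)
        truth.dives.append((start, start + len(seg)))   # refined to >15 m below
        vs_parts.append(tr["vs"])
        stroke_parts.append(stroke)
        cursor += len(seg)
        add_surface()

    vs = np.concatenate(vs_parts) if vs_parts else np.zeros(0)
    stroking = np.concatenate(stroke_parts) if stroke_parts else np.zeros(0)
    n1 = vs.shape[0]
    depth_true = np.cumsum(vs)

    # refine truth dive boundaries to the > 15 m crossings of the quantized
    # noiseless channel (what a depth-threshold detector can see)
    res = cfg.depth_resolution_m
    depth_q = np.round(depth_true / res) * res
    refined = []
    for a, b in truth.dives:
        inside = np.where(depth_q[a:b] > 15.0)[0]
        refined.append((a + int(inside[0]), a + int(inside[-1]) + 1) if inside.size
                       else (a, b))
    truth.dives = refined

    # --- orientation truth at 1 Hz ------------------------------------------
    pitch = -np.degrees(np.arcsin(np.clip(vs / cfg.swim_speed_m_s, -1.0, 1.0)))
    roll = cfg.roll_amp_deg * np.sin(2 * np.pi * np.arange(n1) / 600.0)
    in_bottom = np.zeros(n1, dtype=bool)
    for ph in truth.phases:
        if ph is not None:
            a, b = ph["bottom"]
            in_bottom[a:b] = True
    hstep = np.where(in_bottom, cfg.heading_sd_bottom_deg, cfg.heading_sd_transit_deg)
    heading_unwrapped = (float(rng.uniform(0, 360))
                         + np.cumsum(hstep * rng.standard_normal(n1)))
    truth.pitch_deg = pitch
    truth.roll_deg = roll
    truth.heading_deg = heading_unwrapped % 360.0
    truth.depth_true_m = depth_true

    # --- prey-encounter bursts ----------------------------------------------
    for ph, drift in zip(truth.phases, truth.drift_flags):
        if ph is None or drift:
            continue
        a, b = ph["bottom"]
        bot_depth = float(np.mean(depth_true[a:b]))
        rate = cfg.pee_per_bottom_min * np.exp(cfg.pee_depth_coef * (bot_depth - 400.0) / 200.0)
        n_bursts = rng.poisson(rate * (b - a) / 60.0)
        got = 0
        for _ in range(int(n_bursts) * 4):
            if got >= n_bursts:
                break
            d = int(rng.integers(cfg.burst_dur_s[0], cfg.burst_dur_s[1] + 1))
            s = int(rng.integers(a, max(b - d, a) + 1))
            if all(s + d + 2 <= p or q + 2 <= s for p, q in truth.pee):
                truth.pee.append((s, s + d))
                got += 1
    truth.pee.sort()

    # --- 16 Hz sensor synthesis ---------------------------------------------
    n16 = n1 * fs
    t16 = (np.arange(n16) + 0.5) / fs          # centred within each second
    t1 = np.arange(n1) + 0.5

    def upsample(x: np.ndarray) -> np.ndarray:
        # linear interpolation leaves derivative corners at every 1 Hz knot,
        # which would put spurious high-frequency power on all axes; a ~1 s
        # smoothing kernel restores the continuity of real body motion
        if n1 == 0:
            return np.zeros(0)
        y = np.interp(t16, t1, x)
        kern = sps.windows.hann(fs + 1)
        kern /= kern.sum()
        return np.convolve(np.pad(y, fs, mode="edge"), kern, mode="same")[fs:-fs]

    pitch16 = upsample(pitch)
    roll16 = upsample(roll)
    head16 = upsample(heading_unwrapped)
    th, ph_, ps = (np.radians(pitch16), np.radians(roll16), np.radians(head16))

    # gravity in body frame: (-sin(pitch), sin(roll)cos(pitch), cos(roll)cos(pitch))
    accel = np.empty((n16, 3))
    accel[:, 0] = -np.sin(th)
    accel[:, 1] = np.sin(ph_) * np.cos(th)
    accel[:, 2] = np.cos(ph_) * np.cos(th)

    # magnetometer: NED field rotated into the body frame by R = Rz Ry Rx
    mn = np.asarray(cfg.mag_field, dtype=float)
    cps, sps_ = np.cos(ps), np.sin(ps)
    cth, sth = np.cos(th), np.sin(th)
    cph, sph = np.cos(ph_), np.sin(ph_)
    # rows of R^T (body <- NED)
    mag = np.empty((n16, 3))
    mag[:, 0] = (cth * cps) * mn[0] + (cth * sps_) * mn[1] + (-sth) * mn[2]
    mag[:, 1] = ((sph * sth * cps - cph * sps_) * mn[0]
                 + (sph * sth * sps_ + cph * cps) * mn[1] + (sph * cth) * mn[2])
    mag[:, 2] = ((cph * sth * cps + sph * sps_) * mn[0]
                 + (cph * sth * sps_ - sph * cps) * mn[1] + (cph * cth) * mn[2])

    stroke16 = np.repeat(stroking, fs)
    accel[:, 1] += (cfg.stroke_amp * stroke16
                    * np.sin(2 * np.pi * cfg.stroke_freq_hz * t16))

    for a, b in truth.pee:
        nb = (b - a) * fs
        for ax in cfg.burst_axes:
            accel[a * fs:b * fs, ax] += make_burst(nb, fs, cfg.burst_amp, rng)

    if cfg.noise_sd > 0:
        accel += cfg.noise_sd * rng.standard_normal(accel.shape)
    if cfg.mag_noise_sd > 0:
        mag += cfg.mag_noise_sd * rng.standard_normal(mag.shape)

    # --- depth channel: quantize then add drift -----------------------------
    offset = cfg.pressure_drift_m_per_h * np.arange(n1) / 3600.0
    truth.offset_m = offset
    depth_obs = depth_q + offset

    # --- GPS fixes at surfacings --------------------------------------------
    gps_rows = []
    for tm in surf_mids:
        if rng.uniform() < cfg.gps_fix_prob:
            frac = tm / 86400.0
            gps_rows.append({
                "time": cfg.start_time + tm,
                "lat": cfg.lat0 + 0.05 * frac + 0.001 * rng.standard_normal(),
                "lon": cfg.lon0 + 0.08 * frac + 0.001 * rng.standard_normal(),
            })
    gps = pd.DataFrame(gps_rows, columns=["time", "lat", "lon"])

    deployment = SensorDeployment(
        depth=UniformSeries(depth_obs, 1.0, cfg.start_time),
        accel=UniformSeries(accel, float(fs), cfg.start_time),
        mag=UniformSeries(mag, float(fs), cfg.start_time),
        gps=gps, start_time=cfg.start_time)
    return deployment, truth


# --------------------------------------------------------------------------
# covariate tables for the statistical stage

def simulate_covariate_table(n_dives: int, n_individuals: int, coefs: dict,
                             family: str, seed: int) -> tuple[pd.DataFrame, dict]:
    """Dive-level covariate table with a known regression structure.

    ``coefs`` supplies the truth: ``intercept``, ``beta`` (one slope per
    generated standard-normal covariate ``x1..xk``), plus family extras —
    ``theta`` (negative-binomial dispersion; the count response uses a log
    link and a log-exposure offset ``log_bottom_min``), ``sd_individual`` /
    ``sd_residual`` for the mixed model, or ``precision_intercept`` /
    ``precision_beta`` for the variable-dispersion beta family (logit mean,
    log precision).  Beta responses landing on 0/1 are nudged inside the
    open interval by machine epsilon and counted in the returned truth.
    """
    if family not in ("nb", "lmm", "beta"):
        raise ValueError(f"unknown family {family!r}")
    rng = np.random.default_rng(seed)
    beta = np.asarray(coefs["beta"], dtype=float)
    k = beta.shape[0]
    n = n_dives
    x = rng.standard_normal((n, k))
    ind = np.repeat(np.arange(n_individuals), int(np.ceil(n / n_individuals)))[:n]
    tbl = pd.DataFrame(x, columns=[f"x{j + 1}" for j in range(k)])
    tbl["individual_id"] = [f"ind{j + 1}" for j in ind]
    eta = coefs["intercept"] + x @ beta
    true = dict(coefs)

    if family == "nb":
        exposure = rng.uniform(3.0, 12.0, n)       # bottom minutes
        theta = float(coefs["theta"])
        mu = np.exp(eta + np.log(exposure))
        if theta > 1e8:
            y = rng.poisson(mu)
        else:
            y = rng.negative_binomial(theta, theta / (theta + mu))
        tbl["bottom_duration_min"] = exposure
        tbl["y"] = y
    elif family == "lmm":
        u = coefs["sd_individual"] * rng.standard_normal(n_individuals)
        y = eta + u[ind] + coefs["sd_residual"] * rng.standard_normal(n)
        tbl["y"] = y
        true["u"] = u
    else:
        phi = np.exp(coefs["precision_intercept"]
                     + x @ np.asarray(coefs["precision_beta"], dtype=float))
        mu = 1.0 / (1.0 + np.exp(-eta))
        y = rng.beta(mu * phi, (1.0 - mu) * phi)
        eps = np.finfo(float).eps
        clamped = (y <= 0.0) | (y >= 1.0)
        if clamped.any():
            warnings.warn(f"{clamped.sum()} beta response(s) clamped off 0/1")
        y = np.clip(y, eps, 1.0 - eps)
        tbl["y"] = y
        true["n_clamped"] = int(clamped.sum())
    return tbl, true
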