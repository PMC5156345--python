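"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops, separately from the package's
vectorised implementations, so agreement is a genuine cross-check.
"""

import math

import numpy as np


def sample_sd(values):
    """Two-pass sample standard deviation (ddof = 1)."""
    values = list(values)
    n = len(values)
    m = sum(values) / n
    return math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))


def moving_sd_windows(x, window=5, min_periods=3):
    """Centred moving SD by explicit per-window recomputation."""
    n = len(x)
    half = window // 2
    out = []
    for t in range(n):
        chunk = [x[i] for i in range(max(0, t - half), min(n, t + half + 1))]
        out.append(sample_sd(chunk) if len(chunk) >= min_periods else float("nan"))
    return np.asarray(out)


def two_means_exhaustive(values):
    """Best 2-partition of sorted values by total within-cluster SS.

    Returns a frozenset of the indices in the upper cluster (ties resolved
    toward the smallest upper cluster, matching the implementation's
    documented tie-break).
    """
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="stable")
    xs = v[order]
    n = len(xs)
    candidates = []
    for k in range(1, n):           # lower cluster = xs[:k]
        if xs[k] == xs[k - 1]:
            continue
        lo, hi = xs[:k], xs[k:]
        wss = (sum((a - lo.mean()) ** 2 for a in lo)
               + sum((b - hi.mean()) ** 2 for b in hi))
        candidates.append((wss, k))
    if not candidates:
        return frozenset()
    best = min(w for w, _ in candidates)
    best_k = max(k for w, k in candidates if w <= best + 1e-9)
    return frozenset(int(i) for i in order[best_k:])


def runs_of(mask):
    out, i = [], 0
    mask = list(mask)
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def dive_boundaries(depth, threshold=15.0):
    """Maximal runs deeper than the threshold, by linear scan."""
    return runs_of([d > threshold for d in depth])


def smoothed_speed(depth, smooth=3):
    """3-sample centred moving average then central difference, by loops."""
    n = len(depth)
    half = smooth // 2
    sm = []
    for t in range(n):
        chunk = [depth[i] for i in range(max(0, t - half), min(n, t + half + 1))]
        sm.append(sum(chunk) / len(chunk))
    vs = []
    for t in range(n):
        if t == 0:
            vs.append(sm[1] - sm[0] if n > 1 else 0.0)
        elif t == n - 1:
            vs.append(sm[-1] - sm[-2])
        else:
            vs.append((sm[t + 1] - sm[t - 1]) / 2.0)
    return np.asarray(vs)


def wiggles_steps(depth, step_max=0.35, min_step=5, eps=0.02):
    """Independent re-implementation of the wiggle/step rules."""
    n = len(depth)
    vs = smoothed_speed(depth)
    sgn = [0 if abs(v) <= eps else (1 if v > 0 else -1) for v in vs]
    runs = []
    i = 0
    while i < n:
        j = i
        while j < n and sgn[j] == sgn[i]:
            j += 1
        if sgn[i] != 0:
            runs.append((sgn[i], i, j))
        i = j
    transit = set()
    if runs and runs[0][0] == 1 and runs[0][1] <= 1:
        transit.add(0)
    if runs and runs[-1][0] == -1 and runs[-1][2] >= n - 1:
        transit.add(len(runs) - 1)
    wiggles = []
    for k in range(len(runs) - 1):
        if runs[k][0] == 1 and runs[k + 1][0] == -1 \
                and k not in transit and (k + 1) not in transit:
            wiggles.append((runs[k][1], runs[k + 1][2]))
    claimed = [False] * n
    for a, b in wiggles:
        for t in range(a, b):
            claimed[t] = True
    in_band = [(vs[t] > eps and vs[t] < step_max and not claimed[t]) for t in range(n)]
    steps = [(a, b) for a, b in runs_of(in_band) if b - a >= min_step]
    return wiggles, steps


def three_phases(depth, wiggles, steps, ledge=0.75):
    """Independent bottom delimitation (qualifying events, else isobath)."""
    iso = ledge * max(depth)
    qual = [(a, b) for a, b in wiggles + steps if max(depth[a:b]) > iso]
    if qual:
        b0 = min(a for a, _ in qual)
        b1 = max(b for _, b in qual)
        fallback = False
    else:
        deep = [t for t, d in enumerate(depth) if d > iso]
        b0, b1 = deep[0], deep[-1] + 1
        fallback = True
    return (0, b0), (b0, b1), (b1, len(depth)), fallback


def circular_mean_deg(angles):
    s = sum(math.sin(math.radians(a)) for a in angles) / len(angles)
    c = sum(math.cos(math.radians(a)) for a in angles) / len(angles)
    return math.degrees(math.atan2(s, c))


def circular_variance_deg(angles):
    s = sum(math.sin(math.radians(a)) for a in angles) / len(angles)
    c = sum(math.cos(math.radians(a)) for a in angles) / len(angles)
    return 1.0 - math.hypot(s, c)


def lambert_ellipsoidal_m(lat1, lon1, lat2, lon2):
    """Andoyer-Lambert first-order ellipsoidal distance (WGS84)."""
    a = 6378137.0
    f = 1.0 / 298.257223563
    b1 = math.atan((1 - f) * math.tan(math.radians(lat1)))
    b2 = math.atan((1 - f) * math.tan(math.radians(lat2)))
    dl = math.radians(lon2 - lon1)
    cos_sigma = (math.sin(b1) * math.sin(b2)
                 + math.cos(b1) * math.cos(b2) * math.cos(dl))
    sigma = math.acos(max(-1.0, min(1.0, cos_sigma)))
    if sigma == 0:
        return 0.0
    p = (b1 + b2) / 2.0
    q = (b2 - b1) / 2.0
    x = (sigma - math.sin(sigma)) * math.sin(p) ** 2 * math.cos(q) ** 2 \
        / math.cos(sigma / 2.0) ** 2
    y = (sigma + math.sin(sigma)) * math.cos(p) ** 2 * math.sin(q) ** 2 \
        / math.sin(sigma / 2.0) ** 2
    return a * (sigma - f / 2.0 * (x + y))


def rotation_matrix(heading_deg, pitch_deg, roll_deg):
    """Full body-to-NED rotation matrix R = Rz(psi) Ry(theta) Rx(phi)."""
    ps, th, ph = (math.radians(heading_deg), math.radians(pitch_deg),
                  math.radians(roll_deg))
    rz = np.array([[math.cos(ps), -math.sin(ps), 0],
                   [math.sin(ps), math.cos(ps), 0], [0, 0, 1]])
    ry = np.array([[math.cos(th), 0, math.sin(th)], [0, 1, 0],
                   [-math.sin(th), 0, math.cos(th)]])
    rx = np.array([[1, 0, 0], [0, math.cos(ph), -math.sin(ph)],
                   [0, math.sin(ph), math.cos(ph)]])
    return rz @ ry @ rx
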