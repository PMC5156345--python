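"""Delimited-text serialisation of deployments, truth tables and events.

One CSV per stream (epoch-second time column plus value columns), one
interval table for ground truth, one covariate CSV, and a YAML manifest
recording the generating configuration and seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .series import UniformSeries
from .simulate import DeploymentTruth, SensorDeployment, SimConfig


def write_deployment(outdir: str | Path, dep: SensorDeployment,
                     truth: DeploymentTruth | None = None,
                     config: SimConfig | None = None) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t1 = dep.depth.times()
    pd.DataFrame({"time_s": t1, "depth_m": dep.depth.values}).to_csv(
        out / "depth.csv", index=False)
    t16 = dep.accel.times()
    pd.DataFrame({"time_s": t16, "ax_g": dep.accel.values[:, 0],
                  "ay_g": dep.accel.values[:, 1],
                  "az_g": dep.accel.values[:, 2]}).to_csv(out / "accel.csv", index=False)
    pd.DataFrame({"time_s": t16, "mx": dep.mag.values[:, 0],
                  "my": dep.mag.values[:, 1],
                  "mz": dep.mag.values[:, 2]}).to_csv(out / "mag.csv", index=False)
    dep.gps.to_csv(out / "gps.csv", index=False)
    if truth is not None:
        write_truth(out / "truth.csv", truth)
    if config is not None:
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump({"config": dataclasses.asdict(config),
                            "seed": config.seed}, fh)
    return out


def write_truth(path: str | Path, truth: DeploymentTruth) -> None:
    rows = []
    for a, b in truth.dives:
        rows.append(("depth", a, b, "dive"))
    for ph in truth.phases:
        if ph:
            for kind, (a, b) in ph.items():
                rows.append(("depth", a, b, kind))
    for a, b in truth.wiggles:
        rows.append(("depth", a, b, "wiggle"))
    for a, b in truth.steps:
        rows.append(("depth", a, b, "step"))
    for a, b in truth.pee:
        rows.append(("accel", a, b, "pee"))
    pd.DataFrame(rows, columns=["stream", "start_s", "end_s", "label"]).to_csv(
        path, index=False)


def read_series(path: str | Path, fs_hz: float) -> UniformSeries:
    """Read a stream CSV (time column first, 1 or 3 value columns)."""
    df = pd.read_csv(path)
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if values.shape[1] == 1:
        values = values[:, 0]
    start = float(df.iloc[0, 0]) if len(df) else 0.0
    return UniformSeries(values, fs_hz, start)


def read_deployment(indir: str | Path) -> SensorDeployment:
    ind = Path(indir)
    depth = read_series(ind / "depth.csv", 1.0)
    accel = read_series(ind / "accel.csv", 16.0)
    mag = read_series(ind / "mag.csv", 16.0)
    gps_path = ind / "gps.csv"
    gps = (pd.read_csv(gps_path) if gps_path.exists()
           else pd.DataFrame(columns=["time", "lat", "lon"]))
    return SensorDeployment(depth, accel, mag, gps, depth.start_time)


def write_events(path: str | Path, events) -> None:
    pd.DataFrame([{"start_s": e.start_s, "end_s": e.end_s,
                   "duration_s": e.duration_s} for e in events],
                 columns=["start_s", "end_s", "duration_s"]).to_csv(path, index=False)
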