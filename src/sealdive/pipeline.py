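"""End-to-end analysis: raw sensor streams -> dive table -> five models."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import filters, metrics, pee, segmentation
from .filters import FilterSpec
from .models import DiveModel
from .orientation import OrientationSeries, orientation_from_sensors
from .series import UniformSeries
from .simulate import SensorDeployment


@dataclass
class DeploymentAnalysis:
    """Everything the pipeline derives from one deployment's streams."""

    dive_table: pd.DataFrame
    phase_table: pd.DataFrame
    dives: list
    pee_events: list
    pee_by_phase: pd.DataFrame
    orientation: OrientationSeries
    effort: np.ndarray            # 1 Hz swimming effort
    depth_corrected: np.ndarray


def analyze_deployment(dep: SensorDeployment,
                       individual_id: str = "ind1") -> DeploymentAnalysis:
    """Run the full sensor pipeline on one deployment."""
    accel, mag = dep.accel, dep.mag
    lateral = UniformSeries(accel.values[:, 1], accel.fs_hz, accel.start_time)
    effort = filters.swimming_effort(lateral).values

    static = filters.static_acceleration(accel)
    mag_f = filters.apply_filter(
        mag, FilterSpec(filters.FILTER_ORDER, "lowpass",
                        filters.STATIC_CUTOFF_HZ, mag.fs_hz))
    orient = orientation_from_sensors(static, mag_f)

    events = pee.detect_pee(accel)
    dives, depth_corr = segmentation.segment_deployment(dep.depth.values, effort)
    by_phase = pee.assign_events_to_phases(events, dives)

    dive_table = metrics.build_dive_table(
        dives, events, orient, effort, depth_corr,
        gps=dep.gps, start_time=dep.start_time, individual_id=individual_id)
    phase_table = metrics.build_phase_table(dives, effort, depth_corr,
                                            individual_id=individual_id)
    return DeploymentAnalysis(dive_table, phase_table, dives, events, by_phase,
                              orient, effort, depth_corr)


def fit_five_models(dive_table: pd.DataFrame, phase_table: pd.DataFrame,
                    thin_k: int = 1, select: bool = False):
    """Fit models 1a, 1b, 2, 3 and 4 and tabulate their pseudo-R2.

    Returns ``(summary, results)``: a goodness-of-fit table with one row
    per model (columns ``D2_pct``, ``R2m``, ``R2c``, ``Pearson2``) and the
    underlying :class:`~sealdive.models.DiveModelResults` objects.  A model
    whose subset is too small or whose fit fails gets a NaN row rather
    than aborting the batch.
    """
    from .models import standardize_covariates, thin_every_k, BEHAVIOUR_COVARIATES

    tbl = thin_every_k(dive_table, thin_k) if thin_k > 1 else dive_table
    ptbl = phase_table
    tbl, _ = standardize_covariates(tbl, [c for c in BEHAVIOUR_COVARIATES
                                          if c in tbl.columns])
    ptbl, _ = standardize_covariates(ptbl, ["max_depth_m", "mean_effort"])

    builders = {
        "1a": lambda: DiveModel.pee_rate(tbl, daynight="day"),
        "1b": lambda: DiveModel.pee_rate(tbl, daynight="night"),
        "2": lambda: DiveModel.surface_speed(tbl),
        "3": lambda: DiveModel.efficiency(tbl),
        "4": lambda: DiveModel.transit_duration(ptbl),
    }
    rows, results = [], {}
    for name, build in builders.items():
        row = {"model": name, "D2_pct": np.nan, "R2m": np.nan,
               "R2c": np.nan, "Pearson2": np.nan, "n": 0}
        try:
            model = build()
            res = model.select() if select else model.fit(
                reml=(model.spec.family == "lmm"))
            results[name] = res
            row["n"] = res.nobs
            row["Pearson2"] = res.pearson2()
            if res.spec.family == "negbin":
                row["D2_pct"] = res.deviance_explained()
            if res.spec.family == "lmm":
                row["R2m"], row["R2c"] = res.nakagawa_r2()
        except Exception as exc:
            warnings.warn(f"model {name} not fitted: {exc}")
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("model")
    return summary, results
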