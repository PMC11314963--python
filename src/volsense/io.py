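"""Delimited-text interchange formats and simulation-config loading.

Trace files are long-format CSV with one row per (cycle, sensor, time point)
and columns cycle_id, class, sensor_id, doping, time_s, resistance_ohm,
phase. Peak tables are CSV with sample/replicate identifiers alongside the
peak columns. A simulation config is a single YAML document describing the
design, schedule, sensor array, response matrix and noise model.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import gcms, simulate
from .signal import MeasurementCycle, PhaseSchedule, SensorTrace, ValidationError, segment

__all__ = [
    "write_traces",
    "read_traces",
    "write_peak_table",
    "read_peak_table",
    "load_simulation_config",
]


def write_traces(cycles: Sequence[MeasurementCycle], path) -> None:
    """Write measurement cycles to a long-format CSV trace file."""
    frames = []
    for cycle in cycles:
        for trace in cycle.traces:
            ranges = segment(trace)
            phase = np.empty(len(trace), dtype=object)
            for name, (lo, hi) in (("stabilization", ranges.stabilization),
                                   ("analysis", ranges.analysis),
                                   ("recovery", ranges.recovery)):
                phase[lo:hi] = name
            frames.append(pd.DataFrame({
                "cycle_id": cycle.cycle_id,
                "class": cycle.class_label,
                "sensor_id": trace.sensor_id,
                "doping": trace.doping,
                "time_s": trace.time_s,
                "resistance_ohm": trace.resistance_ohm,
                "phase": phase,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _schedule_from_phases(time_s: np.ndarray, phase: pd.Series) -> PhaseSchedule:
    dt = float(np.median(np.diff(time_s))) if time_s.size > 1 else 1.0
    rate = 1.0 / dt
    n_stab = int((phase == "stabilization").sum())
    n_ana = int((phase == "analysis").sum())
    n_rec = int((phase == "recovery").sum())
    return PhaseSchedule(n_stab / rate, n_ana / rate, n_rec / rate, rate)


def read_traces(path) -> list[MeasurementCycle]:
    """Read a long-format trace file back into measurement cycles.

    Cycle order follows first appearance in the file; the phase schedule is
    reconstructed from the phase column and the sampling step.
    """
    df = pd.read_csv(path)
    required = {"cycle_id", "sensor_id", "time_s", "resistance_ohm", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"trace file missing columns {sorted(missing)}")
    cycles = []
    for cycle_id, cdf in df.groupby("cycle_id", sort=False):
        traces = []
        for sensor_id, sdf in cdf.groupby("sensor_id", sort=False):
            t = sdf["time_s"].to_numpy(dtype=float)
            schedule = _schedule_from_phases(t, sdf["phase"])
            doping = sdf["doping"].iloc[0] if "doping" in sdf else None
            traces.append(SensorTrace(
                sensor_id=str(sensor_id),
                time_s=t,
                resistance_ohm=sdf["resistance_ohm"].to_numpy(dtype=float),
                schedule=schedule,
                doping=None if pd.isna(doping) else str(doping),
            ))
        label = cdf["class"].iloc[0] if "class" in cdf else None
        cycles.append(MeasurementCycle(
            cycle_id=str(cycle_id),
            class_label=None if pd.isna(label) else str(label),
            traces=traces,
        ))
    return cycles


def write_peak_table(table: gcms.PeakTable, path) -> None:
    """Write one peak table (with sample/replicate ids) to CSV."""
    df = table.data.copy()
    df.insert(0, "sample_id", table.sample_id)
    df.insert(1, "replicate_id", table.replicate_id)
    df.to_csv(path, index=False)


def read_peak_table(path) -> gcms.PeakTable:
    df = pd.read_csv(path)
    sample_id = str(df["sample_id"].iloc[0]) if "sample_id" in df else ""
    replicate_id = str(df["replicate_id"].iloc[0]) if "replicate_id" in df else ""
    cols = [c for c in df.columns if c not in ("sample_id", "replicate_id")]
    return gcms.PeakTable(df[cols].reset_index(drop=True), sample_id, replicate_id)


def load_simulation_config(path) -> dict:
    """Load a YAML simulation config into constructed simulation objects.

    Recognized top-level keys (all optional; defaults are the study
    conditions): ``design``, ``schedule``, ``noise``, ``separation``,
    ``seed``. Returns a dict with keys design, schedule, array, crm, noise.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    design = simulate.ExperimentDesign(**raw.get("design", {}))
    schedule = PhaseSchedule(**raw.get("schedule", {}))
    noise_kwargs = dict(raw.get("noise", {}))
    if "seed" in raw and "seed" not in noise_kwargs:
        noise_kwargs["seed"] = raw["seed"]
    noise = simulate.NoiseModel(**noise_kwargs)
    crm = simulate.default_response_matrix(raw.get("separation", 1.0))
    return {
        "design": design,
        "schedule": schedule,
        "array": simulate.default_sensor_array(),
        "crm": crm,
        "noise": noise,
    }
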