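"""Sensor-trace containers and raw-signal preprocessing.

A measurement cycle on the six-sensor MOX array follows a fixed phase
schedule: a stabilization phase in filtered air, an analysis phase while the
sample headspace flows over the heated sensing layers, and a recovery phase
back in clean air. The resistance of each n-type SnO2-based sensor drops when
reducing volatiles adsorb, and relaxes back afterwards.

Preprocessing mirrors standard e-nose practice: each trace is normalized to
its baseline resistance R0 (here the stabilization-phase mean), the cycle is
segmented into its three phases, and the response magnitude is the relative
drop from baseline to the analysis-phase minimum, ΔR/R0 = 1 - min(R/R0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ValidationError",
    "PhaseSchedule",
    "SensorTrace",
    "NormalizedTrace",
    "MeasurementCycle",
    "PhaseRanges",
    "segment",
    "normalize",
    "delta_response",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural precondition."""


@dataclass(frozen=True)
class PhaseSchedule:
    """Timing of one measurement cycle.

    Defaults are the operative cycle: 100 s stabilization, 200 s analysis,
    500 s recovery, sampled at 1 Hz (800 samples per cycle).
    """

    stabilization_s: float = 100.0
    analysis_s: float = 200.0
    recovery_s: float = 500.0
    sample_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        for name in ("stabilization_s", "analysis_s", "recovery_s", "sample_rate_hz"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def total_s(self) -> float:
        return self.stabilization_s + self.analysis_s + self.recovery_s

    @property
    def n_points(self) -> int:
        return int(round(self.total_s * self.sample_rate_hz))

    def phase_boundaries(self) -> tuple[int, int]:
        """Sample indices ending stabilization and analysis (half-open)."""
        i1 = int(round(self.stabilization_s * self.sample_rate_hz))
        i2 = int(round((self.stabilization_s + self.analysis_s) * self.sample_rate_hz))
        return i1, i2


@dataclass
class SensorTrace:
    """One sensor's resistance time series (Ω vs s) for a single cycle."""

    sensor_id: str
    time_s: np.ndarray
    resistance_ohm: np.ndarray
    schedule: PhaseSchedule
    doping: Optional[str] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.resistance_ohm = np.asarray(self.resistance_ohm, dtype=float)
        if self.time_s.size == 0:
            raise ValidationError("empty trace")
        if self.time_s.shape != self.resistance_ohm.shape:
            raise ValidationError("time and resistance lengths differ")
        if not np.all(np.isfinite(self.resistance_ohm)):
            raise ValidationError("non-finite resistance values")
        if np.any(self.resistance_ohm <= 0):
            raise ValidationError("resistances must be positive")
        if self.time_s[0] != 0:
            raise ValidationError("time axis must start at 0")
        if self.time_s.size > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValidationError("time axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclass
class NormalizedTrace:
    """Dimensionless R/R0 trace; r0 is the stabilization-phase mean resistance."""

    sensor_id: str
    time_s: np.ndarray
    r_over_r0: np.ndarray
    r0: float
    schedule: PhaseSchedule
    doping: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise ValidationError("r0 must be positive")

    def __len__(self) -> int:
        return int(np.asarray(self.time_s).size)


@dataclass
class MeasurementCycle:
    """Six sensor traces sharing one schedule, plus sample metadata."""

    cycle_id: str
    class_label: Optional[str]
    traces: list[SensorTrace]
    metadata: dict = field(default_factory=dict)

    def sensor_ids(self) -> list[str]:
        return [t.sensor_id for t in self.traces]

    def __len__(self) -> int:
        return len(self.traces)


@dataclass(frozen=True)
class PhaseRanges:
    """Half-open index ranges partitioning a trace into its three phases."""

    stabilization: tuple[int, int]
    analysis: tuple[int, int]
    recovery: tuple[int, int]

    def as_slices(self) -> dict[str, slice]:
        return {
            "stabilization": slice(*self.stabilization),
            "analysis": slice(*self.analysis),
            "recovery": slice(*self.recovery),
        }


def segment(trace, schedule: Optional[PhaseSchedule] = None) -> PhaseRanges:
    """Partition trace indices into stabilization / analysis / recovery.

    Ranges are half-open, non-overlapping and exhaustive over the trace.
    Samples recorded beyond the scheduled span are assigned to recovery;
    traces shorter than the schedule are rejected.
    """
    if schedule is None:
        schedule = trace.schedule
    n = len(trace)
    if n < schedule.n_points:
        raise ValidationError(
            f"trace has {n} samples but schedule requires {schedule.n_points}"
        )
    i1, i2 = schedule.phase_boundaries()
    if i2 - i1 < 1:
        raise ValidationError("degenerate schedule: empty analysis phase")
    return PhaseRanges((0, i1), (i1, i2), (i2, n))


def normalize(trace: SensorTrace) -> NormalizedTrace:
    """Divide a raw trace by its baseline R0 (stabilization-phase mean).

    The stabilization mean is used rather than the literal first sample so a
    single noisy acquisition cannot skew the whole normalized trace.
    """
    ranges = segment(trace)
    lo, hi = ranges.stabilization
    if hi - lo < 1:
        # no stabilization samples: fall back to the first acquisition
        r0 = float(trace.resistance_ohm[0])
    else:
        r0 = float(np.mean(trace.resistance_ohm[lo:hi]))
    if not r0 > 0:
        raise ValidationError("non-positive baseline R0")
    return NormalizedTrace(
        sensor_id=trace.sensor_id,
        time_s=trace.time_s,
        r_over_r0=trace.resistance_ohm / r0,
        r0=r0,
        schedule=trace.schedule,
        doping=trace.doping,
    )


def delta_response(ntrace: NormalizedTrace, ranges: Optional[PhaseRanges] = None) -> float:
    """Relative response ΔR/R0 = 1 − min(R/R0) over the analysis phase.

    Non-negative for responding sensors (resistance drops on exposure to
    reducing volatiles); zero for a flat trace.
    """
    if ranges is None:
        ranges = segment(ntrace)
    lo, hi = ranges.analysis
    if hi - lo < 1:
        raise ValidationError("empty analysis range")
    return float(1.0 - np.min(ntrace.r_over_r0[lo:hi]))
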