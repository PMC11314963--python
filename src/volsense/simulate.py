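"""Seeded synthetic data emulating the chicken-meat volatilome study design.

The study compares breast meat from broilers raised on four diets — CONTROL
(conventional soybean-based), ST (soybean-free "sustainable"), LL (ST plus
live black-soldier-fly larvae) and LD (ST plus dehydrated larvae) — each
analyzed raw and cooked, giving 8 classes. Every sample is measured in
triplicate on GC-MS and ten times on the six-sensor MOX array.

No sensor recordings or peak tables are deposited with the study, so this
module generates both from explicit, seeded models:

* **Sensor traces** follow first-order adsorption/desorption kinetics: flat
  at baseline during stabilization, exponential decay toward
  ``baseline × (1 − amplitude)`` during analysis, exponential relaxation back
  during recovery. Class identity enters through the per-(sensor, class)
  amplitude matrix; a scalar ``separation`` scales the between-class
  amplitude differences (0 ⇒ indistinguishable classes). Noise is
  multiplicative log-normal (resistance is positive) plus a linear baseline
  drift.
* **Peak tables** draw per-compound areas log-normally around class-specific
  means, with hexanal the dominant aldehyde throughout, cooked classes
  enriched in aldehydes/alcohols/ketones and raw classes in carboxylic
  acids/esters/ethers, mirroring the lipid-oxidation and Maillard chemistry
  of cooked meat.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import gcms
from .signal import (
    MeasurementCycle,
    PhaseSchedule,
    SensorTrace,
    ValidationError,
)

__all__ = [
    "DIETS",
    "STATES",
    "CLASS_LABELS",
    "SensorProfile",
    "ClassResponseMatrix",
    "NoiseModel",
    "ExperimentDesign",
    "default_sensor_array",
    "default_response_matrix",
    "default_compound_library",
    "simulate_trace",
    "simulate_cycle",
    "simulate_dataset",
    "design_summary",
    "simulate_peak_table",
]

DIETS: tuple[str, ...] = ("CONTROL", "LL", "LD", "ST")
STATES: tuple[str, ...] = ("RAW", "CK")
#: The 8 diet × cooking-state classes, state-major.
CLASS_LABELS: tuple[str, ...] = tuple(f"{s}_{d}" for s in STATES for d in DIETS)

_DOPINGS = ("SnO2", "SnO2+Pd", "SnO2+Au")


@dataclass(frozen=True)
class SensorProfile:
    """Static description of one MOX sensor in the array."""

    sensor_id: str
    doping: str
    baseline_resistance: float
    response_tau_s: float
    recovery_tau_s: float

    def __post_init__(self) -> None:
        if not self.baseline_resistance > 0:
            raise ValidationError("baseline_resistance must be > 0")
        if self.response_tau_s < 0 or self.recovery_tau_s < 0:
            raise ValidationError("time constants must be >= 0")
        if self.doping not in _DOPINGS:
            raise ValidationError(f"doping must be one of {_DOPINGS}")


def default_sensor_array() -> list[SensorProfile]:
    """Six-sensor array: two SnO2, two SnO2+Pd, two SnO2+Au."""
    specs = [
        ("S1", "SnO2", 1.2e5, 18.0, 70.0),
        ("S2", "SnO2", 9.0e4, 22.0, 85.0),
        ("S3", "SnO2+Pd", 2.5e5, 15.0, 60.0),
        ("S4", "SnO2+Pd", 3.1e5, 20.0, 75.0),
        ("S5", "SnO2+Au", 6.5e4, 25.0, 90.0),
        ("S6", "SnO2+Au", 8.0e4, 17.0, 65.0),
    ]
    return [SensorProfile(*s) for s in specs]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal noise plus linear baseline drift."""

    multiplicative_sigma: float = 0.01
    drift_per_s: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_sigma < 0:
            raise ValidationError("multiplicative_sigma must be >= 0")


@dataclass(frozen=True)
class ClassResponseMatrix:
    """Fractional resistance-drop amplitude per (sensor, class).

    ``separation`` rescales each sensor's between-class amplitude deviations
    about its class-mean: 1 keeps the stored matrix, 0 collapses every class
    onto the sensor mean (classes become indistinguishable up to noise).
    """

    classes: tuple[str, ...]
    amplitudes: np.ndarray  # shape (n_sensors, n_classes)
    separation: float = 1.0

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "classes", tuple(self.classes))
        if len(self.classes) == 0:
            raise ValidationError("response matrix needs at least one class")
        if len(set(self.classes)) != len(self.classes):
            raise ValidationError("class labels must be unique")
        if amps.ndim != 2 or amps.shape[1] != len(self.classes):
            raise ValidationError("amplitudes must be (n_sensors, n_classes)")
        if np.any(amps < 0) or np.any(amps >= 1):
            raise ValidationError("amplitudes must lie in [0, 1)")

    @property
    def n_sensors(self) -> int:
        return self.amplitudes.shape[0]

    def with_separation(self, separation: float) -> "ClassResponseMatrix":
        return replace(self, separation=separation)

    def effective_amplitudes(self) -> np.ndarray:
        """Amplitude matrix after separation scaling, clipped to [0, 0.95]."""
        mean = self.amplitudes.mean(axis=1, keepdims=True)
        eff = mean + self.separation * (self.amplitudes - mean)
        return np.clip(eff, 0.0, 0.95)

    def column(self, class_label: str) -> np.ndarray:
        """Effective per-sensor amplitudes for one class."""
        try:
            j = self.classes.index(class_label)
        except ValueError:
            raise KeyError(f"unknown class {class_label!r}; known: {self.classes}")
        return self.effective_amplitudes()[:, j]


# Per-sensor base response and structured class offsets. Cooking boosts total
# volatiles on every sensor; each diet perturbs the pattern differently, with
# the larval diets (LL, LD) farther from CONTROL/ST than from each other —
# matching the separations the discriminant plots show.
_BASE_AMPLITUDE = np.array([0.45, 0.40, 0.55, 0.50, 0.35, 0.30])
_STATE_BOOST = {"RAW": np.zeros(6),
                "CK": np.array([0.08, 0.06, 0.10, 0.05, 0.09, 0.07])}
_DIET_PATTERN = {
    "CONTROL": np.zeros(6),
    "LL": np.array([0.10, 0.02, 0.08, -0.03, 0.12, 0.04]),
    "LD": np.array([0.05, 0.09, -0.04, 0.07, 0.02, 0.10]),
    "ST": np.array([-0.06, 0.04, 0.06, 0.10, -0.05, 0.02]),
}


def default_response_matrix(separation: float = 1.0) -> ClassResponseMatrix:
    """Deterministic 6 × 8 amplitude matrix for the diet × state classes."""
    cols = []
    for label in CLASS_LABELS:
        state, diet = label.split("_", 1)
        cols.append(_BASE_AMPLITUDE + _STATE_BOOST[state] + _DIET_PATTERN[diet])
    return ClassResponseMatrix(CLASS_LABELS, np.column_stack(cols), separation)


@dataclass(frozen=True)
class ExperimentDesign:
    """Sample and replicate bookkeeping of the measurement campaign.

    Defaults reproduce the study: 48 meat samples, each run 3× on GC-MS and
    10× on the e-nose; one e-nose cycle is booked as 13 min of bench time
    (the operative phase schedule sums to 800 s).
    """

    n_samples: int = 48
    gcms_replicates: int = 3
    enose_replicates: int = 10
    cycle_minutes: float = 13.0

    def __post_init__(self) -> None:
        for name in ("n_samples", "gcms_replicates", "enose_replicates"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def design_summary(design: ExperimentDesign) -> dict[str, float]:
    """Analysis totals implied by the design."""
    return {
        "total_analyses": design.n_samples
        * (design.gcms_replicates + design.enose_replicates),
        "enose_session_minutes": design.enose_replicates * design.cycle_minutes,
    }


def _clean_trace(profile: SensorProfile, amplitude: float,
                 schedule: PhaseSchedule) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free piecewise kinetic trace; returns (time_s, resistance)."""
    n = schedule.n_points
    t = np.arange(n) / schedule.sample_rate_hz
    i1, i2 = schedule.phase_boundaries()
    r = np.full(n, profile.baseline_resistance, dtype=float)
    base = profile.baseline_resistance
    # analysis: first-order decay toward base*(1 - amplitude)
    ta = t[i1:i2] - schedule.stabilization_s
    if profile.response_tau_s > 0:
        decay = 1.0 - np.exp(-ta / profile.response_tau_s)
        r[i1:i2] = base * (1.0 - amplitude * decay)
        end_level = base * (1.0 - amplitude * (1.0 - np.exp(-schedule.analysis_s / profile.response_tau_s)))
    else:  # instantaneous response
        r[i1:i2] = base * (1.0 - amplitude)
        end_level = base * (1.0 - amplitude)
    # recovery: relax back toward baseline
    tr = t[i2:] - (schedule.stabilization_s + schedule.analysis_s)
    if profile.recovery_tau_s > 0:
        r[i2:] = base - (base - end_level) * np.exp(-tr / profile.recovery_tau_s)
    else:
        r[i2:] = base
    return t, r


def simulate_trace(
    profile: SensorProfile,
    amplitude: float,
    schedule: PhaseSchedule,
    noise: NoiseModel,
    rng: Optional[np.random.Generator] = None,
) -> SensorTrace:
    """Simulate one sensor's resistance trace for one cycle.

    The clean kinetic trace is modulated by a linear baseline drift and
    multiplicative log-normal noise. With zero amplitude, noise and drift
    the trace is constant at the baseline resistance.
    """
    if not 0 <= amplitude < 1:
        raise ValidationError(f"amplitude must lie in [0, 1), got {amplitude}")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    t, r = _clean_trace(profile, amplitude, schedule)
    if noise.drift_per_s != 0:
        r = r * (1.0 + noise.drift_per_s * t)
    if noise.multiplicative_sigma > 0:
        r = r * np.exp(rng.normal(0.0, noise.multiplicative_sigma, r.size))
    if np.any(r <= 0):
        raise ValidationError("drift drove the trace non-positive; reduce |drift_per_s|")
    return SensorTrace(profile.sensor_id, t, r, schedule, doping=profile.doping)


def simulate_cycle(
    array: Sequence[SensorProfile],
    crm: ClassResponseMatrix,
    class_label: str,
    schedule: PhaseSchedule,
    noise: NoiseModel,
    rng: Optional[np.random.Generator] = None,
    cycle_id: str = "cycle0",
) -> MeasurementCycle:
    """Simulate one six-sensor measurement cycle for a given class."""
    amps = crm.column(class_label)  # KeyError for unknown class
    if len(array) != crm.n_sensors:
        raise ValidationError(
            f"array has {len(array)} sensors but response matrix expects {crm.n_sensors}"
        )
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    traces = [
        simulate_trace(profile, float(a), schedule, noise, rng)
        for profile, a in zip(array, amps)
    ]
    return MeasurementCycle(
        cycle_id=cycle_id,
        class_label=class_label,
        traces=traces,
        metadata={
            "class": class_label,
            "seed": noise.seed,
            "schedule": (schedule.stabilization_s, schedule.analysis_s,
                         schedule.recovery_s, schedule.sample_rate_hz),
            "separation": crm.separation,
        },
    )


def simulate_dataset(
    design: ExperimentDesign,
    crm: ClassResponseMatrix,
    array: Sequence[SensorProfile],
    schedule: PhaseSchedule,
    noise: NoiseModel,
) -> tuple[list[MeasurementCycle], list[str]]:
    """Simulate a class-balanced e-nose campaign.

    ``design.n_samples`` samples are spread evenly over the response matrix's
    classes and each sample is measured ``design.enose_replicates`` times,
    yielding ``n_samples × enose_replicates`` cycles. Per-cycle RNG streams
    are spawned from ``noise.seed``, so regeneration is bit-identical.
    """
    k = len(crm.classes)
    if k == 0:
        raise ValidationError("response matrix has no classes")
    if design.n_samples % k != 0:
        raise ValidationError(
            f"n_samples={design.n_samples} not divisible by {k} classes; "
            "a class-balanced design is required"
        )
    per_class = design.n_samples // k
    if per_class < 1 or design.enose_replicates < 1:
        raise ValidationError("need at least one sample and one replicate per class")
    ss = np.random.SeedSequence(noise.seed)
    n_cycles = design.n_samples * design.enose_replicates
    children = ss.spawn(n_cycles)
    cycles: list[MeasurementCycle] = []
    labels: list[str] = []
    idx = 0
    for label in crm.classes:
        for si in range(per_class):
            for ri in range(design.enose_replicates):
                rng = np.random.default_rng(children[idx])
                cycle = simulate_cycle(
                    array, crm, label, schedule, noise, rng,
                    cycle_id=f"{label}_s{si}_r{ri}",
                )
                cycles.append(cycle)
                labels.append(label)
                idx += 1
    return cycles, labels


# ---------------------------------------------------------------------------
# GC-MS peak-table simulation
# ---------------------------------------------------------------------------

# (compound, chemical class, retention time in min, base mean area)
_COMPOUNDS: tuple[tuple[str, str, float, float], ...] = (
    ("pentanal", "aldehyde", 2.10, 4000.0),
    ("hexanal", "aldehyde", 3.05, 30000.0),
    ("2-heptanone", "ketone", 3.60, 1200.0),
    ("heptanal", "aldehyde", 4.10, 6000.0),
    ("1-hexanol", "alcohol", 4.55, 2500.0),
    ("hexyl acetate", "ester", 4.90, 700.0),
    ("3-octanone", "ketone", 5.30, 1500.0),
    ("1-octen-3-ol", "alcohol", 5.75, 9000.0),
    ("octanal", "aldehyde", 6.20, 5000.0),
    ("dibutyl ether", "ether", 6.60, 450.0),
    ("2-nonanone", "ketone", 7.05, 900.0),
    ("nonanal", "aldehyde", 7.50, 8000.0),
    ("1-tridecene", "alkene", 8.10, 3000.0),
    ("hexanoic acid", "carboxylic acid", 8.65, 2000.0),
    ("heptane, 2,2,4,6,6-pentamethyl", "alkane", 9.20, 12000.0),
    ("octanoic acid", "carboxylic acid", 9.80, 2500.0),
    ("tridecane", "alkane", 10.40, 4000.0),
    ("nonanoic acid", "carboxylic acid", 11.10, 3000.0),
    ("1-tetradecanol", "alcohol", 12.00, 800.0),
    ("tetradecane", "alkane", 12.70, 3500.0),
)

# Class-level enrichment of cooked vs raw meat headspace: cooking (lipid
# oxidation, Maillard/Strecker chemistry) boosts aldehydes, alcohols and
# ketones; raw meat retains more free fatty acids (active lipolysis) plus
# esters/ethers; hydrocarbons are stable.
_STATE_FACTOR = {
    "CK": {"aldehyde": 2.0, "alcohol": 1.6, "ketone": 1.8, "ester": 0.6,
           "carboxylic acid": 0.5, "ether": 0.7, "alkane": 1.0, "alkene": 1.0,
           "other": 1.0},
    "RAW": {"aldehyde": 1.0, "alcohol": 1.0, "ketone": 1.0, "ester": 1.0,
            "carboxylic acid": 1.0, "ether": 1.0, "alkane": 1.0, "alkene": 1.0,
            "other": 1.0},
}
# Mild diet-specific scaling of the lipid-oxidation marker classes.
_DIET_FACTOR = {
    "CONTROL": {"aldehyde": 1.0, "alcohol": 1.0, "carboxylic acid": 1.0, "ketone": 1.0},
    "LL": {"aldehyde": 1.2, "alcohol": 1.1, "carboxylic acid": 1.3, "ketone": 1.0},
    "LD": {"aldehyde": 1.1, "alcohol": 0.9, "carboxylic acid": 1.5, "ketone": 0.9},
    "ST": {"aldehyde": 0.9, "alcohol": 1.0, "carboxylic acid": 1.1, "ketone": 1.6},
}

#: type alias: class label -> {compound: (chemical_class, mean_area, dispersion)}
CompoundLibrary = Mapping[str, Mapping[str, tuple[str, float, float]]]


def default_compound_library(dispersion: float = 0.2) -> dict[str, dict[str, tuple[str, float, float]]]:
    """Per-class compound library with hexanal-dominant aldehyde profiles.

    ``dispersion`` is the log-scale SD of the sampled areas (0 ⇒ areas equal
    the library means).
    """
    library: dict[str, dict[str, tuple[str, float, float]]] = {}
    for label in CLASS_LABELS:
        state, diet = label.split("_", 1)
        entry: dict[str, tuple[str, float, float]] = {}
        for name, cls, _rt, base in _COMPOUNDS:
            mean = base * _STATE_FACTOR[state][cls] * _DIET_FACTOR[diet].get(cls, 1.0)
            entry[name] = (cls, mean, dispersion)
        library[label] = entry
    return library


_RETENTION_TIMES = {name: rt for name, _cls, rt, _a in _COMPOUNDS}


def simulate_peak_table(
    class_label: str,
    compound_library: Optional[CompoundLibrary] = None,
    seed: int = 0,
    replicate_id: str = "r0",
) -> gcms.PeakTable:
    """Draw one replicate peak table for a sample class.

    Areas are sampled log-normally around the library means (median equal to
    the mean parameter); retention times are the library's fixed, strictly
    increasing elution order, with unknown compounds appended after it.
    """
    if compound_library is None:
        compound_library = default_compound_library()
    if class_label not in compound_library:
        raise KeyError(f"unknown class {class_label!r}")
    entry = compound_library[class_label]
    if not entry:
        raise ValidationError(f"empty compound library for class {class_label!r}")
    rng = np.random.default_rng(seed)
    rows = []
    fallback_rt = max(_RETENTION_TIMES.values(), default=0.0)
    for name, (cls, mean, disp) in entry.items():
        if mean < 0 or disp < 0:
            raise ValidationError("compound mean area and dispersion must be >= 0")
        area = mean * float(np.exp(rng.normal(0.0, disp))) if disp > 0 else mean
        if name in _RETENTION_TIMES:
            rt = _RETENTION_TIMES[name]
        else:
            fallback_rt += 0.5
            rt = fallback_rt
        rows.append((rt, name, cls, area))
    rows.sort(key=lambda r: r[0])
    df = pd.DataFrame(rows, columns=["retention_time_min", "compound", "chemical_class", "area"])
    return gcms.PeakTable(df, sample_id=class_label, replicate_id=replicate_id)
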