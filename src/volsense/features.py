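"""Per-sensor descriptor extraction from normalized e-nose traces.

Eleven descriptors summarize each sensor's recorded track:

* four "Sharpe" variability indices — mean/SD of the leading or trailing
  25% / 50% of the signal;
* minimum and maximum first derivative and the trapezoidal integral over a
  selected interval (by default the analysis phase, where the gas
  interaction happens);
* ΔR, the max − min excursion of the track;
* the sum of natural logarithms of the signal;
* the track minimum and maximum.

A six-sensor cycle therefore yields a 66-dimensional feature vector. All
features are computed on R/R0-normalized traces so sensors with different
baseline resistances are comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .signal import MeasurementCycle, NormalizedTrace, ValidationError, normalize, segment

__all__ = [
    "FEATURE_NAMES",
    "UndefinedFeatureError",
    "FeatureConfig",
    "sharpe",
    "derivative_extrema",
    "integral",
    "extract",
    "build_matrix",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = (
    "sharpe_fwd_25",
    "sharpe_back_25",
    "sharpe_fwd_50",
    "sharpe_back_50",
    "min_derivative",
    "max_derivative",
    "integral",
    "delta_r",
    "log_sum",
    "minimum",
    "maximum",
)


class UndefinedFeatureError(ValueError):
    """A descriptor is undefined for this input (e.g. zero-variance window)."""


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction policy.

    interval
        Where derivative extrema and the integral are computed: ``"analysis"``
        (default — the phase where the volatiles interact with the sensor) or
        ``"full"`` for the whole recorded track.
    log_sum_mode
        ``"sum_of_logs"`` (default): Σ ln(x_i); ``"log_of_sum"``: ln(Σ x_i).
    sharpe_sentinel
        Value substituted (with a warning) when a Sharpe window has zero
        standard deviation, to keep downstream matrices finite.
    """

    interval: str = "analysis"
    log_sum_mode: str = "sum_of_logs"
    sharpe_sentinel: float = 0.0

    def __post_init__(self) -> None:
        if self.interval not in ("analysis", "full"):
            raise ValidationError(f"unknown interval policy {self.interval!r}")
        if self.log_sum_mode not in ("sum_of_logs", "log_of_sum"):
            raise ValidationError(f"unknown log_sum_mode {self.log_sum_mode!r}")


def sharpe(values: Sequence[float], fraction: float, direction: str = "forward") -> float:
    """Mean / sample-SD of the leading or trailing ``fraction`` of the signal.

    The window holds the first (``forward``) or last (``back``)
    ``ceil(fraction * n)`` points and must contain at least two points with
    nonzero sample standard deviation.
    """
    v = np.asarray(values, dtype=float)
    if direction not in ("forward", "back"):
        raise ValidationError(f"direction must be 'forward' or 'back', got {direction!r}")
    m = math.ceil(fraction * v.size)
    if m < 2:
        raise UndefinedFeatureError(f"window of {m} point(s) too short for mean/SD")
    window = v[:m] if direction == "forward" else v[-m:]
    sd = float(np.std(window, ddof=1))
    if sd == 0.0:
        raise UndefinedFeatureError("zero standard deviation in window")
    return float(np.mean(window)) / sd


def derivative_extrema(values: Sequence[float], times: Sequence[float]) -> tuple[float, float]:
    """(min, max) of the first finite differences Δv/Δt."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 points for a derivative")
    d = np.diff(v) / np.diff(t)
    return float(np.min(d)), float(np.max(d))


def integral(values: Sequence[float], times: Sequence[float]) -> float:
    """Trapezoidal integral of the signal over its time axis (value·s)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 points for an integral")
    return float(np.trapezoid(v, np.asarray(times, dtype=float)))


def _sharpe_or_sentinel(values: np.ndarray, fraction: float, direction: str,
                        config: FeatureConfig, sensor_id: str) -> float:
    try:
        return sharpe(values, fraction, direction)
    except UndefinedFeatureError as exc:
        logger.warning(
            "sensor %s: sharpe(%.2f, %s) undefined (%s); substituting %.3g",
            sensor_id, fraction, direction, exc, config.sharpe_sentinel,
        )
        return config.sharpe_sentinel


def extract(ntrace: NormalizedTrace, config: FeatureConfig | None = None) -> dict[str, float]:
    """Compute the 11 descriptors for one normalized trace, in canonical order."""
    if config is None:
        config = FeatureConfig()
    v = np.asarray(ntrace.r_over_r0, dtype=float)
    t = np.asarray(ntrace.time_s, dtype=float)
    if config.interval == "analysis":
        lo, hi = segment(ntrace).analysis
        # closed time span: include the sample at the analysis/recovery
        # boundary so a 200-s window integrates a constant 1 to 200
        hi = min(hi + 1, v.size)
        sel_v, sel_t = v[lo:hi], t[lo:hi]
    else:
        sel_v, sel_t = v, t
    dmin, dmax = derivative_extrema(sel_v, sel_t)
    if config.log_sum_mode == "sum_of_logs":
        log_sum = float(np.sum(np.log(v)))
    else:
        log_sum = float(np.log(np.sum(v)))
    feats = {
        "sharpe_fwd_25": _sharpe_or_sentinel(v, 0.25, "forward", config, ntrace.sensor_id),
        "sharpe_back_25": _sharpe_or_sentinel(v, 0.25, "back", config, ntrace.sensor_id),
        "sharpe_fwd_50": _sharpe_or_sentinel(v, 0.50, "forward", config, ntrace.sensor_id),
        "sharpe_back_50": _sharpe_or_sentinel(v, 0.50, "back", config, ntrace.sensor_id),
        "min_derivative": dmin,
        "max_derivative": dmax,
        "integral": integral(sel_v, sel_t),
        "delta_r": float(np.max(v) - np.min(v)),
        "log_sum": log_sum,
        "minimum": float(np.min(v)),
        "maximum": float(np.max(v)),
    }
    return {name: feats[name] for name in FEATURE_NAMES}


def build_matrix(
    cycles: Iterable[MeasurementCycle],
    config: FeatureConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the per-cycle feature matrix (rows = cycles, 66 columns).

    Columns are ordered sensor-major, feature-minor and named
    ``<sensor_id>__<feature>``; row order follows the input cycle order.
    Returns the matrix and the class-label vector (index = cycle_id).
    """
    cycles = list(cycles)
    if not cycles:
        raise ValidationError("no cycles supplied")
    sensor_order = cycles[0].sensor_ids()
    rows: list[dict[str, float]] = []
    labels: list[str | None] = []
    ids: list[str] = []
    for cycle in cycles:
        if cycle.sensor_ids() != sensor_order:
            raise ValidationError(
                f"cycle {cycle.cycle_id!r} sensor layout {cycle.sensor_ids()} "
                f"differs from {sensor_order}"
            )
        row: dict[str, float] = {}
        for trace in cycle.traces:
            feats = extract(normalize(trace), config)
            for name, value in feats.items():
                row[f"{trace.sensor_id}__{name}"] = value
        rows.append(row)
        labels.append(cycle.class_label)
        ids.append(cycle.cycle_id)
    X = pd.DataFrame(rows, index=pd.Index(ids, name="cycle_id"))
    y = pd.Series(labels, index=X.index, name="class")
    return X, y
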