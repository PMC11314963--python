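"""SPME-GC-MS peak-table processing.

A chromatographic run is reduced to a peak table: retention time, integrated
area, compound name and chemical class. Processing follows routine headspace
VOC workflows: peaks below an area threshold are discarded (with a QC check
on how many survive), each compound is quantified as relative abundance
(% of total retained GC area), triplicate vials are aggregated to mean ± SD
profiles, and raw vs cooked profiles are compared per chemical class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .signal import ValidationError

__all__ = [
    "CHEMICAL_CLASSES",
    "PeakTable",
    "ClassProfile",
    "StateComparison",
    "filter_peaks",
    "relative_abundance",
    "aggregate_replicates",
    "compare_states",
]

logger = logging.getLogger(__name__)

#: Chemical classes observed in poultry headspace volatiles.
CHEMICAL_CLASSES: tuple[str, ...] = (
    "aldehyde",
    "alcohol",
    "ketone",
    "alkane",
    "ester",
    "alkene",
    "carboxylic acid",
    "ether",
    "other",
)

_REQUIRED_COLUMNS = ("retention_time_min", "compound", "chemical_class", "area")


@dataclass
class PeakTable:
    """Integrated peaks of one chromatographic run.

    ``data`` holds one row per peak with columns retention_time_min,
    compound, chemical_class and area (arbitrary units). Areas must be
    non-negative and retention times non-decreasing.
    """

    data: pd.DataFrame
    sample_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"peak table missing columns {missing}")
        if (self.data["area"] < 0).any():
            raise ValidationError("peak areas must be non-negative")
        rt = self.data["retention_time_min"].to_numpy()
        if rt.size > 1 and np.any(np.diff(rt) < 0):
            raise ValidationError("retention times must be non-decreasing")
        unknown = set(self.data["chemical_class"]) - set(CHEMICAL_CLASSES)
        if unknown:
            raise ValidationError(f"unknown chemical classes {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ClassProfile:
    """Mean ± SD relative-abundance profile of one sample class.

    ``compounds`` has one row per compound: compound, chemical_class,
    mean_pct, sd_pct. Compounds absent in a replicate contribute 0% there,
    so means are over all replicates.
    """

    compounds: pd.DataFrame
    n_replicates: int
    sample_id: str = ""

    @property
    def class_counts(self) -> pd.Series:
        """Number of detected compounds (mean abundance > 0) per chemical class."""
        detected = self.compounds[self.compounds["mean_pct"] > 0]
        counts = detected.groupby("chemical_class").size()
        return counts.reindex(CHEMICAL_CLASSES, fill_value=0)

    @property
    def class_abundance(self) -> pd.Series:
        """Summed mean relative abundance (%) per chemical class."""
        sums = self.compounds.groupby("chemical_class")["mean_pct"].sum()
        return sums.reindex(CHEMICAL_CLASSES, fill_value=0.0)


@dataclass
class StateComparison:
    """Per-chemical-class deltas between two profiles (cooked − raw)."""

    per_class: pd.DataFrame
    raw_exclusive: list[str] = field(default_factory=list)
    cooked_exclusive: list[str] = field(default_factory=list)


def filter_peaks(
    table: PeakTable, min_area: float = 500.0, min_peaks: int = 70
) -> tuple[PeakTable, bool]:
    """Retain peaks with area ≥ min_area; flag runs with too few survivors.

    The area threshold is inclusive (a peak of exactly ``min_area`` counts).
    The peak-count rule is a QC check, not a hard failure: the filtered table
    is returned either way, with ``qc_ok=False`` and a logged warning when
    fewer than ``min_peaks`` peaks survive.
    """
    if min_area < 0:
        raise ValidationError("min_area must be >= 0")
    kept = table.data[table.data["area"] >= min_area].reset_index(drop=True)
    qc_ok = len(kept) >= min_peaks
    if not qc_ok:
        logger.warning(
            "sample %s replicate %s: only %d peaks >= %g (QC expects >= %d)",
            table.sample_id, table.replicate_id, len(kept), min_area, min_peaks,
        )
    return PeakTable(kept, table.sample_id, table.replicate_id), qc_ok


def relative_abundance(table: PeakTable) -> pd.Series:
    """Per-compound relative abundance as % of total retained GC area.

    Returns a Series indexed by compound name that sums to 100.
    """
    total = float(table.data["area"].sum())
    if not total > 0:
        raise ValidationError("total peak area must be positive")
    pct = 100.0 * table.data["area"] / total
    return pd.Series(pct.to_numpy(), index=table.data["compound"].to_numpy(), name="pct")


def aggregate_replicates(
    tables: Sequence[PeakTable], present_only: bool = False
) -> ClassProfile:
    """Aggregate replicate runs of one sample into a mean ± SD profile.

    Compounds are matched by exact name across replicates. By default a
    compound absent from a replicate counts as 0% there; with
    ``present_only=True`` the mean/SD run over only the replicates where the
    compound was detected.
    """
    tables = list(tables)
    if not tables:
        raise ValidationError("no replicates supplied")
    per_rep = [relative_abundance(t) for t in tables]
    classes: dict[str, str] = {}
    for t in tables:
        for comp, cls in zip(t.data["compound"], t.data["chemical_class"]):
            classes.setdefault(comp, cls)
    wide = pd.DataFrame(per_rep)
    if not present_only:
        wide = wide.fillna(0.0)
    mean = wide.mean(axis=0, skipna=True)
    # sample SD; a compound seen in a single replicate has no spread estimate
    sd = wide.std(axis=0, ddof=1, skipna=True).fillna(0.0)
    out = pd.DataFrame(
        {
            "compound": mean.index,
            "chemical_class": [classes[c] for c in mean.index],
            "mean_pct": mean.to_numpy(),
            "sd_pct": sd.to_numpy(),
        }
    ).reset_index(drop=True)
    return ClassProfile(out, n_replicates=len(tables), sample_id=tables[0].sample_id)


def compare_states(profile_raw: ClassProfile, profile_cooked: ClassProfile) -> StateComparison:
    """Per-chemical-class comparison of raw vs cooked profiles.

    Reports, per class, the compound-count and mean-abundance differences
    (cooked − raw), plus the compounds detected exclusively in one state.
    """
    counts_r, counts_c = profile_raw.class_counts, profile_cooked.class_counts
    abund_r, abund_c = profile_raw.class_abundance, profile_cooked.class_abundance
    per_class = pd.DataFrame(
        {
            "count_raw": counts_r,
            "count_cooked": counts_c,
            "count_delta": counts_c - counts_r,
            "abundance_raw_pct": abund_r,
            "abundance_cooked_pct": abund_c,
            "abundance_delta_pct": abund_c - abund_r,
        }
    )
    per_class.index.name = "chemical_class"

    def _detected(profile: ClassProfile) -> set[str]:
        df = profile.compounds
        return set(df.loc[df["mean_pct"] > 0, "compound"])

    raw_set, cooked_set = _detected(profile_raw), _detected(profile_cooked)
    return StateComparison(
        per_class=per_class,
        raw_exclusive=sorted(raw_set - cooked_set),
        cooked_exclusive=sorted(cooked_set - raw_set),
    )
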