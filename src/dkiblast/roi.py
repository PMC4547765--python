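"""ROI summaries and longitudinal table preparation.

Turns parameter maps plus region masks into the subject x time x region
records the statistics consume, applying bilateral averaging (left/right
regions pooled to improve sensitivity), per-subject baseline
normalization, and a complete-case rule that keeps only subjects imaged at
every required time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dki import FLAG_DEGENERATE, FLAG_NEGATIVE_SIGNAL, ParamMaps

__all__ = [
    "ROIMask",
    "ROIValue",
    "extract_roi_mean",
    "bilateral_average",
    "normalize_to_baseline",
    "complete_case_filter",
]

# voxels carrying no estimate at all; clamped voxels still hold usable values
_FAILURE_FLAGS = (FLAG_NEGATIVE_SIGNAL, FLAG_DEGENERATE)


@dataclass(frozen=True)
class ROIMask:
    """A named region mask on the map grid."""

    region: str  # e.g. hippocampus / internal_capsule / cerebellum
    side: str  # left / right / midline
    voxels: np.ndarray  # boolean array on the map grid

    def __post_init__(self):
        v = np.asarray(self.voxels, dtype=bool)
        if not v.any():
            raise ValueError(f"ROI {self.region}/{self.side} is empty")
        object.__setattr__(self, "voxels", v)


@dataclass(frozen=True)
class ROIValue:
    """A region summary: the mean, how many voxels went in, and why not all."""

    value: float | None
    n_used: int
    n_excluded: int = 0
    reason: str | None = None

    @property
    def missing(self) -> bool:
        return self.value is None


def extract_roi_mean(maps: ParamMaps, mask: ROIMask, measure: str) -> ROIValue:
    """Arithmetic mean of one measure over an ROI, skipping failed voxels.

    ``measure`` is one of MD / FA / MK. Voxels flagged negative-signal or
    degenerate carry no estimate and are excluded; the count used is
    reported. All voxels failed -> a missing value with the reason.
    """
    if measure not in ("MD", "FA", "MK"):
        raise ValueError(f"unknown measure {measure!r}")
    grid = getattr(maps, measure)
    if mask.voxels.shape != grid.shape:
        raise ValueError(
            f"mask grid {mask.voxels.shape} does not match map grid {grid.shape}"
        )
    sel = mask.voxels
    failed = np.isin(maps.flags, _FAILURE_FLAGS)
    usable = sel & ~failed
    n_used = int(usable.sum())
    n_excluded = int(sel.sum()) - n_used
    if n_used == 0:
        return ROIValue(None, 0, n_excluded, reason="all voxels flagged")
    return ROIValue(float(grid[usable].mean()), n_used, n_excluded)


def bilateral_average(left, right):
    """Mean of the left/right region values; single-side passthrough.

    Accepts floats, ``ROIValue`` or None; returns an ``ROIValue`` whose
    ``reason`` records a unilateral fallback. Symmetric in its arguments.
    """

    def _val(x):
        if x is None:
            return None
        if isinstance(x, ROIValue):
            return x.value
        return float(x)

    lv, rv = _val(left), _val(right)
    if lv is None and rv is None:
        return ROIValue(None, 0, reason="both sides missing")
    if lv is None or rv is None:
        return ROIValue(lv if rv is None else rv, 1, reason="unilateral")
    return ROIValue((lv + rv) / 2.0, 2)


def normalize_to_baseline(
    table: pd.DataFrame, baseline_label: str = "baseline"
) -> pd.DataFrame:
    """Divide each subject x region x measure trajectory by its baseline.

    Adds a ``normalized_value`` column; baseline rows normalize to exactly 1.
    A missing or zero baseline marks that trajectory non-normalizable (NaN)
    rather than dropping it, so the caller can decide.
    """
    required = {"subject", "time", "region", "measure", "value"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"table lacks columns {sorted(missing_cols)}")
    out = table.copy()
    key = ["subject", "region", "measure"]
    base = (
        out[out["time"] == baseline_label]
        .set_index(key)["value"]
        .rename("_baseline")
    )
    if base.index.has_duplicates:
        raise ValueError("duplicate baseline records for a subject/region/measure")
    out = out.join(base, on=key)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["normalized_value"] = np.where(
            out["_baseline"].notna() & (out["_baseline"] != 0),
            out["value"] / out["_baseline"],
            np.nan,
        )
    return out.drop(columns="_baseline")


def complete_case_filter(
    table: pd.DataFrame, required_times, measures=None
) -> tuple[pd.DataFrame, list]:
    """Keep only subjects observed at every required time point.

    Applied per region x measure combination present (or the subset given in
    ``measures``): a subject must have a non-missing value at every required
    time for every requested measure to be retained. Returns the filtered
    table and the sorted list of dropped subjects. Idempotent.
    """
    required_times = set(required_times)
    if not required_times:
        raise ValueError("required_times must be non-empty")
    t = table
    if measures is not None:
        t = t[t["measure"].isin(set(measures))]
    value_col = "value"
    present = t[t[value_col].notna()]
    needed = len(required_times) * present.groupby(
        ["region", "measure"]
    ).ngroups
    counts = (
        present[present["time"].isin(required_times)]
        .drop_duplicates(["subject", "time", "region", "measure"])
        .groupby("subject")
        .size()
    )
    keep = set(counts[counts == needed].index)
    all_subjects = set(table["subject"].unique())
    dropped = sorted(all_subjects - keep)
    return table[table["subject"].isin(keep)].copy(), dropped
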