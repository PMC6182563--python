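"""Two-class size partitioning, t-based summary statistics, core measures.

Mycelial objects frequently split into two coexisting populations — small
objects (dispersed hyphae, single spores, small agglomerates) and large
ones (agglomerates, pellets) — separated by a projected-area threshold
(10⁴ μm² is the usual choice; strongly pelleting MPEC cultures may need
10⁵ μm²). Per-timepoint descriptor statistics are reported as mean, sample
standard deviation (n−1 denominator) and a Student-t confidence half-width
at significance level α (default 0.05).

Core/filament measures of pellets (core diameter, core-to-pellet diameter
ratio, mean filament length and filament-to-diameter ratio) are computed
from explicitly supplied core masks and filament lengths — either synthetic
ground truth or manual annotations — mirroring measurements that are done
by hand on selected images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import morphometry
from .morphometry import MorphoRecord

__all__ = [
    "SizeClassPartition",
    "TimepointSummary",
    "CoreMeasure",
    "DEFAULT_CLASS_THRESHOLD",
    "partition_by_area",
    "summarize",
    "summarize_table",
    "core_measures",
]

#: Default small/large projected-area threshold, μm².
DEFAULT_CLASS_THRESHOLD = 1.0e4

#: Descriptor columns summarized by default.
SUMMARY_PARAMETERS = ("A_um2", "D_um", "Dmax_um", "E", "R", "circularity", "Mo")


@dataclass(frozen=True)
class SizeClassPartition:
    """Assignment of objects to the small/large area classes.

    Objects with A < threshold are "small"; A ≥ threshold is "large"
    (an exact tie goes to "large" — documented tie-break).
    """

    threshold: float
    assignment: Mapping[int, str]

    def ids_in(self, cls: str) -> list[int]:
        return [k for k, v in self.assignment.items() if v == cls]


@dataclass(frozen=True)
class TimepointSummary:
    """Mean / SD / t confidence half-width of one descriptor in one group."""

    time_hr: float | None
    condition: str | None
    size_class: str           # "small" | "large" | "all"
    parameter: str
    n: int
    mean: float
    sd: float                 # NaN when n = 1
    ci_half_width: float      # NaN when n = 1
    undefined: bool = False   # True when n = 1 (sd/ci not estimable)


@dataclass(frozen=True)
class CoreMeasure:
    """Manually-measured style core/filament descriptors of one pellet."""

    pellet_id: int
    core_diameter: float          # μm, largest core
    pellet_diameter: float        # μm, mean diameter of the pellet
    core_ratio: float             # core_diameter / pellet_diameter
    mean_filament_length: float   # μm
    filament_ratio: float         # mean filament length / pellet diameter
    n_cores: int


def partition_by_area(records: Sequence[MorphoRecord],
                      threshold: float = DEFAULT_CLASS_THRESHOLD,
                      ) -> SizeClassPartition:
    """Split objects into small (A < threshold) and large (A ≥ threshold)."""
    if not (threshold > 0):
        raise ValueError(f"threshold must be > 0, got {threshold}")
    assignment = {r.object_id: ("small" if r.A < threshold else "large")
                  for r in records}
    return SizeClassPartition(threshold=float(threshold),
                              assignment=assignment)


def summarize(values: Sequence[float], alpha: float = 0.05, *,
              parameter: str = "", time_hr: float | None = None,
              condition: str | None = None,
              size_class: str = "all") -> TimepointSummary:
    """Mean, sample SD and Student-t confidence half-width of one group.

    ci_half_width = t_{1−α/2, n−1} · sd / √n. For n = 1 the mean is
    returned with sd/ci flagged undefined (NaN) rather than dividing by
    zero.
    """
    vals = np.asarray([float(v) for v in values], dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("cannot summarize an empty group")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    n = len(vals)
    mean = float(vals.mean())
    if n == 1:
        return TimepointSummary(time_hr, condition, size_class, parameter,
                                n, mean, math.nan, math.nan, undefined=True)
    sd = float(vals.std(ddof=1))
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 1))
    ci = t_crit * sd / math.sqrt(n)
    return TimepointSummary(time_hr, condition, size_class, parameter,
                            n, mean, sd, ci, undefined=False)


def summarize_table(table: pd.DataFrame,
                    parameters: Sequence[str] = SUMMARY_PARAMETERS,
                    threshold: float = DEFAULT_CLASS_THRESHOLD,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per time × condition × size-class × parameter summary table.

    ``table`` is a per-object table in the schema of
    :func:`mycomorph.morphometry.records_to_frame` (must contain ``A_um2``
    plus the requested parameter columns). Non-finite descriptor values
    (e.g. the elongation sentinel for perfect lines) are excluded from
    their parameter's summary.
    """
    required = {"A_um2", *parameters}
    missing = sorted(required - set(table.columns))
    if missing:
        raise ValueError(f"object table is missing columns: {missing}")
    df = table.copy()
    df["size_class"] = np.where(df["A_um2"] < threshold, "small", "large")
    for col in ("time_hr", "condition"):
        if col not in df.columns:
            df[col] = None
    rows = []
    group_cols = ["time_hr", "condition"]
    for (t, cond), grp in df.groupby(group_cols, dropna=False):
        t = None if pd.isna(t) else float(t)
        cond = None if pd.isna(cond) else cond
        buckets = [("all", grp)]
        buckets += [(cls, sub) for cls, sub in grp.groupby("size_class")]
        for cls, sub in buckets:
            for param in parameters:
                vals = sub[param].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                if len(vals) == 0:
                    continue
                s = summarize(vals, alpha=alpha, parameter=param,
                              time_hr=t, condition=cond, size_class=cls)
                rows.append({
                    "time_hr": s.time_hr, "condition": s.condition,
                    "class": s.size_class, "parameter": s.parameter,
                    "n": s.n, "mean": s.mean, "sd": s.sd,
                    "ci_half_width": s.ci_half_width,
                })
    return pd.DataFrame(rows, columns=["time_hr", "condition", "class",
                                       "parameter", "n", "mean", "sd",
                                       "ci_half_width"])


def core_measures(pellet_mask: np.ndarray,
                  core_masks: Sequence[np.ndarray],
                  filament_lengths: Sequence[float],
                  calibration: float,
                  pellet_id: int = 1) -> CoreMeasure:
    """Core and filament measures of one pellet.

    core_diameter is the mean diameter of the largest supplied core mask;
    ratios are taken against the pellet's own mean diameter. Every core
    mask must be a subset of the pellet mask.
    """
    pellet = np.asarray(pellet_mask, dtype=bool)
    for i, cm in enumerate(core_masks):
        cm = np.asarray(cm, dtype=bool)
        if cm.shape != pellet.shape:
            raise ValueError(f"core mask {i} shape differs from pellet mask")
        if (cm & ~pellet).any():
            raise ValueError(f"core mask {i} is not inside the pellet mask")
    pellet_d = morphometry.mean_diameter(pellet, calibration)
    if core_masks:
        largest = max(core_masks, key=lambda m: int(np.asarray(m, bool).sum()))
        core_d = morphometry.mean_diameter(np.asarray(largest, bool),
                                           calibration)
        core_ratio = core_d / pellet_d
    else:
        core_d = math.nan
        core_ratio = math.nan
    if filament_lengths:
        fl = float(np.mean([float(v) for v in filament_lengths]))
        f_ratio = fl / pellet_d
    else:
        fl = math.nan
        f_ratio = math.nan
    return CoreMeasure(pellet_id=pellet_id, core_diameter=core_d,
                       pellet_diameter=pellet_d, core_ratio=core_ratio,
                       mean_filament_length=fl, filament_ratio=f_ratio,
                       n_cores=len(core_masks))
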