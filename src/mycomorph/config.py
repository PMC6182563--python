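"""Run configuration: calibration map, segmentation and filter parameters.

A run is fully described by a YAML config that round-trips losslessly, so
that a logged config hash identifies the analysis exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segmentation import FilterRule

__all__ = ["RunConfig", "config_hash"]

DEFAULT_FILENAME_PATTERN = \
    r"(?P<condition>[A-Za-z]+)_(?P<time_hr>[0-9.]+)h_(?P<index>\d+)"


@dataclass
class RunConfig:
    """All tunable parameters of an analysis run."""

    # calibration: either a direct μm/px value, or a per-objective map plus
    # the objective to use (the paper-style setup lists 1.25x-100x
    # objectives with one pixel size each)
    calibration: float | None = 1.0
    objectives: dict[str, float] = field(default_factory=dict)
    objective: str | None = None

    median_radius: int = 1
    edge_threshold: str | float = "otsu"
    closing_radius: int = 2
    edge_halo_erosion: int = 1
    n_dirs: int = 180                       # mean-diameter directions

    # debris filters: list of {kind, threshold} dicts
    filters: list[dict] = field(default_factory=lambda: [
        {"kind": "border_exclusion", "threshold": 1.0}])

    class_threshold: float = 1.0e4          # small/large split, μm²
    alpha: float = 0.05                     # confidence level for t bands
    seed: int = 0
    filename_pattern: str = DEFAULT_FILENAME_PATTERN

    def __post_init__(self) -> None:
        for thr_name in ("class_threshold",):
            if not (getattr(self, thr_name) > 0):
                raise ValueError(f"{thr_name} must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        self.filter_rules()  # validate rule dicts eagerly

    def filter_rules(self) -> list[FilterRule]:
        return [FilterRule(d["kind"], float(d["threshold"]))
                for d in self.filters]

    def resolve_calibration(self, objective: str | None = None) -> float:
        """μm/px for the given (or configured) objective, else the direct value."""
        obj = objective or self.objective
        if obj is not None:
            if obj not in self.objectives:
                raise ValueError(
                    f"objective {obj!r} not in calibration map "
                    f"{sorted(self.objectives)}")
            return float(self.objectives[obj])
        if self.calibration is None:
            raise ValueError("config declares neither a calibration value "
                             "nor an objective map entry to use")
        return float(self.calibration)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**data)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the canonical YAML rendering of a config."""
    canon = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
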