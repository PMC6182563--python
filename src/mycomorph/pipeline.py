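"""End-to-end analysis: preprocess, segment, filter, measure.

This is the programmatic core behind the command-line interface: one
function that takes a calibrated micrograph through the full chain
(green plane → median smoothing → Sobel edge magnitude → edge-based
segmentation → debris filters / AOI → per-object descriptors).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import pandas as pd

from .config import RunConfig
from .imaging import (CalibratedImage, extract_green_plane, median_smooth,
                      sobel_edge_magnitude)
from .morphometry import MorphoRecord, measure_scene, records_to_frame
from .segmentation import (LabeledScene, apply_aoi, apply_filters,
                           segment_from_edges)

__all__ = ["AnalysisResult", "analyze_image"]


@dataclasses.dataclass
class AnalysisResult:
    """Outcome of analyzing one micrograph."""

    scene: LabeledScene                 # surviving objects, labels 1..n
    records: list[MorphoRecord]         # descriptors of surviving objects
    removals: dict[int, str]            # pre-filter object id -> rule kind
    n_detected: int                     # objects before filtering

    def to_frame(self, image: str = "") -> pd.DataFrame:
        img = image
        return records_to_frame(
            self.records, image=img,
            time_hr=self.scene_time, condition=self.scene_condition)

    scene_time: float | None = None
    scene_condition: str | None = None


def analyze_image(img: CalibratedImage, config: RunConfig | None = None,
                  aoi: Sequence[tuple[float, float]] | None = None,
                  ) -> AnalysisResult:
    """Run the full segmentation + morphometry chain on one image.

    Filters come from ``config.filters``; an optional AOI polygon restricts
    analysis to objects whose centroid falls inside it.
    """
    cfg = config or RunConfig()
    gray = extract_green_plane(img)
    smoothed = median_smooth(gray, radius=cfg.median_radius)
    edges = sobel_edge_magnitude(smoothed)
    scene = segment_from_edges(edges, edge_threshold=cfg.edge_threshold,
                               closing_radius=cfg.closing_radius,
                               edge_halo_erosion=cfg.edge_halo_erosion)
    if aoi is not None:
        scene = apply_aoi(scene, aoi)
    records = measure_scene(scene.labels, scene.calibration,
                            n_dirs=cfg.n_dirs)
    n_detected = scene.n_objects
    rules = cfg.filter_rules()
    if rules and records:
        scene, removals = apply_filters(scene, rules, records)
        survivors = sorted(set(r.object_id for r in records) - set(removals))
        records = [dataclasses.replace(rec, object_id=new_id)
                   for new_id, rec in enumerate(
                       (r for r in records if r.object_id in survivors),
                       start=1)]
    else:
        removals = {}
    return AnalysisResult(scene=scene, records=records, removals=removals,
                          n_detected=n_detected,
                          scene_time=img.time_hr,
                          scene_condition=img.condition)
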