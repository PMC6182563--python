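"""Edge-based segmentation of mycelial objects and rule-based debris removal.

Pixels whose Sobel gradient magnitude exceeds a threshold (Otsu by default)
form object contours; the contours are morphologically closed, interior
holes are filled, and 8-connected components become labeled objects. The
thresholded edge ridge straddles the true object boundary by about one
pixel on each side, so the filled region is eroded back by
``edge_halo_erosion`` pixels (default 1) to recenter the mask on the true
boundary.

Debris (e.g. ~10 μm angular mineral microparticles) and invalid objects are
then removed by declarative filter rules — minimum/maximum projected area,
minimum/maximum circularity, and frame-border exclusion — with a removal
report replacing interactive operator clean-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import disk

from .imaging import CalibratedImage
from .morphometry import MorphoRecord

__all__ = [
    "LabeledScene",
    "FilterRule",
    "DEFAULT_SPORE_FILTERS",
    "DEFAULT_PELLET_FILTERS",
    "segment_from_edges",
    "apply_filters",
    "apply_aoi",
]

_RULE_KINDS = ("min_area", "max_area", "min_circularity",
               "max_circularity", "border_exclusion")


@dataclass(frozen=True)
class LabeledScene:
    """Integer label grid: 0 = background, k = object k (labels 1..n)."""

    labels: np.ndarray
    calibration: float

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be a 2-D integer grid")
        if not (self.calibration > 0):
            raise ValueError("calibration must be > 0")
        object.__setattr__(self, "labels", lab.astype(np.int32))

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def mask_of(self, object_id: int) -> np.ndarray:
        return self.labels == object_id

    def centroids(self) -> dict[int, tuple[float, float]]:
        """Per-object centroid (x, y) in pixels."""
        n = self.n_objects
        if n == 0:
            return {}
        coms = ndi.center_of_mass(self.labels > 0, self.labels,
                                  index=range(1, n + 1))
        return {k + 1: (float(cx), float(cy))
                for k, (cy, cx) in enumerate(coms)}


@dataclass(frozen=True)
class FilterRule:
    """One debris/validity rule.

    ``threshold`` is μm² for area rules, a value in (0, 1] for circularity
    rules, and a margin in pixels for ``border_exclusion`` (objects with a
    pixel within that margin of the frame edge are removed).
    """

    kind: str
    threshold: float

    def __post_init__(self) -> None:
        if self.kind not in _RULE_KINDS:
            raise ValueError(
                f"unknown rule kind {self.kind!r}; valid: {_RULE_KINDS}")
        if not (self.threshold > 0):
            raise ValueError(f"rule threshold must be > 0, got {self.threshold}")
        if self.kind in ("min_circularity", "max_circularity") \
                and self.threshold > 1:
            raise ValueError("circularity thresholds must lie in (0, 1]")


#: Defaults for spore-scale images: debris is angular (low circularity).
DEFAULT_SPORE_FILTERS = (FilterRule("min_circularity", 0.7),
                         FilterRule("border_exclusion", 1))
#: Defaults for pellet-scale images: debris is small (low projected area).
DEFAULT_PELLET_FILTERS = (FilterRule("min_area", 1000.0),
                          FilterRule("border_exclusion", 1))


def segment_from_edges(edges: CalibratedImage,
                       edge_threshold: float | str = "otsu",
                       closing_radius: int = 2,
                       edge_halo_erosion: int = 1) -> LabeledScene:
    """Label mycelial objects from a gradient-magnitude image.

    Parameters
    ----------
    edges:
        Non-negative gradient image (e.g. from ``sobel_edge_magnitude``).
    edge_threshold:
        ``"otsu"`` for Otsu's method on the gradient histogram, or an
        absolute gradient value.
    closing_radius:
        Disk radius (px) of the morphological closing that bridges small
        contour gaps before hole filling.
    edge_halo_erosion:
        Pixels eroded from the filled regions to compensate for the width
        of the thresholded edge ridge; 0 disables.

    An all-zero edge image yields an empty scene (0 objects), not an error.
    """
    g = edges.pixels
    if g.ndim != 2:
        raise ValueError("edges must be a grayscale gradient image")
    if g.min() < 0:
        raise ValueError("gradient magnitude must be non-negative")
    empty = LabeledScene(np.zeros(g.shape, np.int32), edges.calibration)
    if g.max() <= 0:
        return empty
    if edge_threshold == "otsu":
        thr = float(threshold_otsu(g))
    else:
        thr = float(edge_threshold)
    binary = g > thr
    if not binary.any():
        return empty
    if closing_radius > 0:
        binary = ndi.binary_closing(binary, structure=disk(closing_radius))
    filled = ndi.binary_fill_holes(binary)
    if edge_halo_erosion > 0:
        filled = ndi.binary_erosion(
            filled, structure=np.ones((3, 3), bool),
            iterations=int(edge_halo_erosion))
    labels = sk_label(filled, connectivity=2)
    return LabeledScene(labels, edges.calibration)


def _relabel(scene: LabeledScene, keep: Iterable[int]) -> LabeledScene:
    """New scene keeping only ``keep`` labels, renumbered 1..n' in order.

    Surviving masks are preserved pixel-for-pixel.
    """
    keep = sorted(set(int(k) for k in keep))
    lut = np.zeros(scene.n_objects + 1, np.int32)
    for new, old in enumerate(keep, start=1):
        lut[old] = new
    return LabeledScene(lut[scene.labels], scene.calibration)


def _touches_border(scene: LabeledScene, margin: int) -> set[int]:
    lab = scene.labels
    m = max(int(margin), 1)
    band = np.concatenate([
        lab[:m].ravel(), lab[-m:].ravel(),
        lab[:, :m].ravel(), lab[:, -m:].ravel()])
    return set(int(v) for v in np.unique(band) if v > 0)


def apply_filters(scene: LabeledScene, rules: Sequence[FilterRule],
                  records: Sequence[MorphoRecord],
                  ) -> tuple[LabeledScene, dict[int, str]]:
    """Remove objects violating any rule; relabel survivors 1..n'.

    ``records`` must cover every object in the scene (keyed by
    ``object_id``). Returns the filtered scene and a removal report mapping
    each removed object id to the first rule kind it violated. The
    surviving set is independent of rule order.
    """
    by_id = {r.object_id: r for r in records}
    missing = [k for k in range(1, scene.n_objects + 1) if k not in by_id]
    if missing:
        raise ValueError(f"records missing for objects {missing}")
    border_cache: dict[int, set[int]] = {}
    removed: dict[int, str] = {}
    for rule in rules:
        if rule.kind == "border_exclusion":
            margin = int(rule.threshold)
            if margin not in border_cache:
                border_cache[margin] = _touches_border(scene, margin)
        for k in range(1, scene.n_objects + 1):
            if k in removed:
                continue
            rec = by_id[k]
            bad = (
                (rule.kind == "min_area" and rec.A < rule.threshold)
                or (rule.kind == "max_area" and rec.A > rule.threshold)
                or (rule.kind == "min_circularity"
                    and rec.circularity < rule.threshold)
                or (rule.kind == "max_circularity"
                    and rec.circularity > rule.threshold)
                or (rule.kind == "border_exclusion"
                    and k in border_cache[int(rule.threshold)])
            )
            if bad:
                removed[k] = rule.kind
    keep = [k for k in range(1, scene.n_objects + 1) if k not in removed]
    return _relabel(scene, keep), removed


def apply_aoi(scene: LabeledScene,
              polygon: Sequence[tuple[float, float]]) -> LabeledScene:
    """Keep only objects whose centroid lies inside the area of interest.

    The polygon is given as (x, y) pixel vertices and must be simple with
    at least 3 vertices. The test is inclusive: a centroid exactly on the
    boundary is kept. Masks of surviving objects are never truncated.
    """
    if len(polygon) < 3:
        raise ValueError("AOI polygon needs at least 3 vertices")
    poly = Polygon([(float(x), float(y)) for x, y in polygon])
    if not poly.is_valid or not poly.is_simple or poly.area <= 0:
        raise ValueError("AOI polygon must be simple and non-degenerate")
    keep = [k for k, (cx, cy) in scene.centroids().items()
            if poly.covers(Point(cx, cy))]
    return _relabel(scene, keep)
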