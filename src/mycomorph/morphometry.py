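"""Per-object size and shape descriptors for mycelial objects.

Descriptors computed on a boolean pixel mask with a μm/px calibration:

* projected area ``A`` — pixel count × calibration²  [μm²]
* mean diameter ``D`` — chord length through the centroid, averaged over
  equally spaced directions  [μm]
* maximum diameter ``Dmax`` — maximum Feret diameter, the largest distance
  between two boundary pixel centers  [μm]
* elongation ``E`` — squared ratio of the longitudinal to the transversal
  standard deviation of the pixel coordinates along the principal
  (regression) axis; 1 for a circle, large for a thin line
* roughness ``R`` (solidity ``S``) — projected area over the rasterized
  convex hull of the pixel centers; 1 for a smooth convex object, lower
  for hairy ones (pixel-center hulls make the measure idempotent: the
  hull of a hull scores exactly 1)
* circularity — 4πA/P² with P the boundary polygon perimeter
* morphology number ``Mo = 2·sqrt(A·S) / (sqrt(π)·Dmax·E)`` — a composite
  index that is 1 for an ideal disk, stays ≥ 0.6 for circular objects
  (ungerminated spores, ideal pellets) and falls below 0.5 once
  filamentous morphology evolves.

All shape descriptors (E, R, circularity, Mo) are dimensionless and
calibration-invariant; A scales with calibration², D and Dmax with
calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import find_contours
from skimage.morphology import convex_hull_image

__all__ = [
    "MorphoRecord",
    "MO_FORMULA",
    "projected_area",
    "mean_diameter",
    "max_diameter",
    "elongation",
    "roughness",
    "convex_area",
    "perimeter",
    "circularity",
    "morphology_number",
    "measure_object",
    "measure_scene",
    "records_to_frame",
]

#: Reading of the morphology-number formula used throughout this package.
MO_FORMULA = "Mo = 2*sqrt(A*S) / (sqrt(pi)*Dmax*E)"

#: Clip tolerance: rasterization may push R/circularity/Mo slightly above 1.
CLIP_TOLERANCE = 1.02


@dataclass(frozen=True)
class MorphoRecord:
    """Descriptor bundle for one labeled object."""

    object_id: int
    n_pixels: int
    A: float                 # projected area, μm²
    convex_area: float       # μm²
    D: float                 # mean diameter, μm
    Dmax: float              # maximum Feret diameter, μm
    E: float                 # elongation, ≥ 1 (math.inf for perfect lines)
    R: float                 # roughness / solidity, (0, 1]
    circularity: float       # 4πA/P², unclipped
    Mo: float                # morphology number
    centroid: tuple[float, float]  # (x, y), pixels
    flags: tuple[str, ...] = field(default_factory=tuple)


def _as_mask(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be a 2-D boolean array")
    if not m.any():
        raise ValueError("mask is empty")
    return m


def _check_calibration(calibration: float) -> float:
    if not (calibration > 0):
        raise ValueError(f"calibration must be > 0, got {calibration}")
    return float(calibration)


def projected_area(mask: np.ndarray, calibration: float) -> float:
    """Pixel count × calibration², in μm²."""
    m = _as_mask(mask)
    cal = _check_calibration(calibration)
    return float(m.sum()) * cal * cal


def centroid_xy(mask: np.ndarray) -> tuple[float, float]:
    """Center of gravity (x, y) in pixel coordinates (x rightward, y down)."""
    m = _as_mask(mask)
    cy, cx = ndi.center_of_mass(m)
    return float(cx), float(cy)


def centroid_inside(mask: np.ndarray) -> bool:
    """Whether the rounded centroid pixel belongs to the mask."""
    m = _as_mask(mask)
    cx, cy = centroid_xy(m)
    iy, ix = int(round(cy)), int(round(cx))
    return (0 <= iy < m.shape[0]) and (0 <= ix < m.shape[1]) and bool(m[iy, ix])


def chord_lengths(mask: np.ndarray, n_dirs: int = 180,
                  step: float = 0.25) -> np.ndarray:
    """Chord length through the centroid for each of ``n_dirs`` directions.

    The chord at angle θ is the extent of the mask run containing the
    centroid, sampled at ``step``-pixel increments in both directions.
    Raises if the centroid does not lie inside the mask.
    """
    m = _as_mask(mask)
    if n_dirs < 1:
        raise ValueError("n_dirs must be ≥ 1")
    if not centroid_inside(m):
        raise ValueError("centroid lies outside the mask")
    cx, cy = centroid_xy(m)
    h, w = m.shape
    t_max = math.hypot(h, w)
    t = np.arange(1, int(t_max / step) + 2) * step          # (nt,)
    theta = np.arange(n_dirs) * (math.pi / n_dirs)
    dx, dy = np.cos(theta), np.sin(theta)                   # (nd,)
    reach = np.zeros((2, n_dirs))
    for side, sign in enumerate((1.0, -1.0)):
        xs = cx + sign * np.outer(dx, t)
        ys = cy + sign * np.outer(dy, t)
        xi = np.rint(xs).astype(np.intp)
        yi = np.rint(ys).astype(np.intp)
        inb = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
        inside = np.zeros_like(inb)
        inside[inb] = m[yi[inb], xi[inb]]
        exited = ~inside
        k = np.where(exited.any(axis=1), np.argmax(exited, axis=1),
                     inside.shape[1])
        reach[side] = k * step
    return reach.sum(axis=0)


def mean_diameter(mask: np.ndarray, calibration: float,
                  n_dirs: int = 180) -> float:
    """Mean chord length through the center of gravity, in μm.

    Averages the boundary-to-boundary chord over ``n_dirs`` equally spaced
    directions in [0, π). For a disk every chord is a diameter, so the
    result is 2r. If the centroid falls outside the mask (strongly concave
    objects) callers should fall back to :func:`max_diameter`; see
    :func:`measure_object`.
    """
    cal = _check_calibration(calibration)
    return float(chord_lengths(mask, n_dirs=n_dirs).mean()) * cal


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of mask pixels with a background 4-neighbor."""
    m = _as_mask(mask)
    eroded = ndi.binary_erosion(m, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool), border_value=0)
    return np.argwhere(m & ~eroded)


def max_diameter(mask: np.ndarray, calibration: float) -> float:
    """Maximum Feret diameter: largest boundary-pixel-center distance, μm."""
    cal = _check_calibration(calibration)
    pts = _boundary_pixels(mask).astype(float)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points: brute force below
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff ** 2).sum(axis=-1)
    return float(math.sqrt(d2.max())) * cal


def elongation(mask: np.ndarray) -> float:
    """Squared ratio of principal standard deviations of pixel coordinates.

    The regression (major principal) axis of the pixel cloud defines the
    longitudinal direction; E = (σ_long / σ_trans)² = λ_max / λ_min of the
    coordinate covariance. E = 1 for a circle; ``math.inf`` is returned for
    perfectly collinear masks (zero transversal deviation).
    """
    m = _as_mask(mask)
    pts = np.argwhere(m).astype(float)
    if len(pts) == 1:
        return 1.0
    cov = np.cov(pts.T, ddof=0)
    eigvals = np.linalg.eigvalsh(cov)
    lo, hi = float(eigvals[0]), float(eigvals[1])
    if lo <= 0:
        return math.inf
    return hi / lo


def convex_area(mask: np.ndarray, calibration: float) -> float:
    """Rasterized convex-hull area of the mask, μm²."""
    m = _as_mask(mask)
    cal = _check_calibration(calibration)
    hull = convex_hull_image(m, offset_coordinates=False)
    return float(hull.sum()) * cal * cal


def roughness(mask: np.ndarray) -> float:
    """Solidity: projected area over rasterized convex-hull area."""
    m = _as_mask(mask)
    hull = convex_hull_image(m, offset_coordinates=False)
    return float(m.sum()) / float(hull.sum())


def perimeter(mask: np.ndarray, smooth_window: int = 3) -> float:
    """Boundary polygon length, in pixels.

    The marching-squares boundary polygon of a digital object
    systematically overestimates smooth boundaries (staircase effect,
    ~+5% for circles), so the polygon vertices are smoothed with a short
    circular moving average (window 3 by default) before the length is
    taken. This keeps a large disk's circularity near 1 while leaving
    polygonal shapes essentially unchanged.
    """
    m = _as_mask(mask)
    padded = np.pad(m.astype(float), 1)
    total = 0.0
    for contour in find_contours(padded, 0.5):
        closed = bool(np.allclose(contour[0], contour[-1]))
        pts = contour[:-1] if closed else contour
        n = len(pts)
        if smooth_window > 1 and n >= smooth_window:
            half = smooth_window // 2
            kernel = np.full(smooth_window, 1.0 / smooth_window)
            sm = np.empty_like(pts)
            for j in (0, 1):
                col = pts[:, j]
                ext = np.concatenate([col[-half:], col, col[:half]])
                sm[:, j] = np.convolve(ext, kernel, mode="valid")
            pts = sm
        poly = np.vstack([pts, pts[:1]]) if closed else pts
        seg = np.diff(poly, axis=0)
        total += float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return total


def circularity(mask: np.ndarray) -> float:
    """4πA/P² (unclipped); ≈ 1 for a disk, ≪ 1 for lines and stars."""
    m = _as_mask(mask)
    p = perimeter(m)
    if p <= 0:
        raise ValueError("mask has no computable perimeter")
    return 4.0 * math.pi * float(m.sum()) / (p * p)


def morphology_number(A: float, S: float, E: float, Dmax: float) -> float:
    """Morphology number Mo = 2·sqrt(A·S) / (sqrt(π)·Dmax·E).

    ``A`` in μm², ``Dmax`` in μm, ``S`` and ``E`` dimensionless; the result
    is dimensionless and lies in (0, 1] for planar objects up to
    rasterization tolerance. Mo = 1 exactly for an ideal disk
    (A = πr², S = 1, E = 1, Dmax = 2r).
    """
    if not (A > 0):
        raise ValueError(f"A must be > 0, got {A}")
    if not (0 < S <= CLIP_TOLERANCE):
        raise ValueError(f"S must be in (0, 1], got {S}")
    if not (E >= 1):
        raise ValueError(f"E must be ≥ 1, got {E}")
    if not (Dmax > 0):
        raise ValueError(f"Dmax must be > 0, got {Dmax}")
    return 2.0 * math.sqrt(A * S) / (math.sqrt(math.pi) * Dmax * E)


def measure_object(mask: np.ndarray, calibration: float,
                   object_id: int = 1, n_dirs: int = 180) -> MorphoRecord:
    """Compute the full descriptor bundle for one object mask.

    The mask is cropped to its bounding box internally so large frames with
    small objects stay cheap. Degenerate cases are flagged rather than
    raised: a centroid outside the mask falls back to ``D = Dmax``
    (``centroid_outside`` flag); perfectly collinear masks get
    ``E = inf``/``Mo = 0`` and the ``elongation_undefined`` flag.
    """
    m = _as_mask(mask)
    cal = _check_calibration(calibration)
    rows, cols = np.nonzero(m)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    local = m[r0:r1, c0:c1]

    flags: list[str] = []
    n_px = int(local.sum())
    A = n_px * cal * cal
    if n_px >= 3:
        hull_px = int(convex_hull_image(
            local, offset_coordinates=False).sum())
    else:
        hull_px = 0
    if hull_px < n_px:  # degenerate/collinear masks have no 2-D hull
        hull_px = n_px
    c_area = hull_px * cal * cal
    R = n_px / hull_px
    dmax = max_diameter(local, cal)
    if dmax == 0.0:  # single pixel
        dmax = cal
        flags.append("single_pixel")

    cx_l, cy_l = centroid_xy(local)
    if centroid_inside(local):
        D = mean_diameter(local, cal, n_dirs=n_dirs)
    else:
        D = dmax
        flags.append("centroid_outside")

    E = elongation(local)
    circ = circularity(local)
    if math.isinf(E):
        flags.append("elongation_undefined")
        Mo = 0.0
    else:
        Mo = morphology_number(A, min(R, 1.0), max(E, 1.0), dmax)

    return MorphoRecord(
        object_id=int(object_id),
        n_pixels=n_px,
        A=A,
        convex_area=c_area,
        D=D,
        Dmax=dmax,
        E=E,
        R=R,
        circularity=circ,
        Mo=Mo,
        centroid=(cx_l + c0, cy_l + r0),
        flags=tuple(flags),
    )


def measure_scene(labels: np.ndarray, calibration: float,
                  n_dirs: int = 180) -> list[MorphoRecord]:
    """Measure every labeled object (labels 1..n, 0 = background)."""
    lab = np.asarray(labels)
    records = []
    for k in range(1, int(lab.max()) + 1):
        mask = lab == k
        if mask.any():
            records.append(measure_object(mask, calibration,
                                          object_id=k, n_dirs=n_dirs))
    return records


def records_to_frame(records: Sequence[MorphoRecord], *,
                     image: str = "", time_hr: float | None = None,
                     condition: str | None = None) -> pd.DataFrame:
    """Tabulate records in the standard per-object CSV schema.

    R, circularity and Mo are reported unclipped, with clipped-to-[0, 1]
    convenience columns alongside (rasterization can exceed 1 by up to the
    tolerance 1.02).
    """
    rows = []
    for r in records:
        rows.append({
            "image": image,
            "time_hr": time_hr,
            "condition": condition,
            "object_id": r.object_id,
            "n_pixels": r.n_pixels,
            "A_um2": r.A,
            "D_um": r.D,
            "Dmax_um": r.Dmax,
            "E": r.E,
            "R": r.R,
            "circularity": r.circularity,
            "Mo": r.Mo,
            "R_clipped": min(r.R, 1.0),
            "circularity_clipped": min(r.circularity, 1.0),
            "Mo_clipped": min(r.Mo, 1.0),
            "centroid_x": r.centroid[0],
            "centroid_y": r.centroid[1],
            "flags": ";".join(r.flags),
        })
    columns = ["image", "time_hr", "condition", "object_id", "n_pixels",
               "A_um2", "D_um", "Dmax_um", "E", "R", "circularity", "Mo",
               "R_clipped", "circularity_clipped", "Mo_clipped",
               "centroid_x", "centroid_y", "flags"]
    return pd.DataFrame(rows, columns=columns)
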