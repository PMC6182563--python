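"""Rasterizers for the canonical mycelial shapes of submerged cultures.

Each function returns a local boolean mask (tight bounding grid) for one
object kind: circular or lemon-shaped spores, germinating spores with a
germ tube, spore agglomerates built by sequential attachment, hairy pellets
(disk core plus radial filaments, optionally multicore or core-shell),
branching random-walk clumps/hyphae, a deterministic sinusoidal filament,
and angular microparticle debris. All dimensions are in pixels; callers
convert from μm using the scene calibration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk as disk_footprint

__all__ = [
    "disk_mask", "ellipse_mask", "germinating_spore_mask",
    "agglomerate_mask", "hairy_pellet_mask", "clump_mask",
    "sinusoid_filament_mask", "microparticle_mask",
]


def disk_mask(radius: float) -> np.ndarray:
    """Filled disk: pixels whose center lies within ``radius`` of the center."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    r = int(math.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (xx * xx + yy * yy) <= radius * radius


def ellipse_mask(semi_major: float, semi_minor: float,
                 angle_rad: float = 0.0) -> np.ndarray:
    """Filled rotated ellipse (pixel-center test)."""
    if semi_major <= 0 or semi_minor <= 0:
        raise ValueError("semi-axes must be > 0")
    r = int(math.ceil(max(semi_major, semi_minor))) + 1
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    u = xx * c + yy * s
    v = -xx * s + yy * c
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def _thick_path(points: np.ndarray, width_px: float,
                shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polyline of (row, col) points with the given width."""
    canvas = np.zeros(shape, bool)
    pts = np.rint(points).astype(int)
    pts[:, 0] = np.clip(pts[:, 0], 0, shape[0] - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, shape[1] - 1)
    for a, b in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(a[0], a[1], b[0], b[1])
        canvas[rr, cc] = True
    if width_px > 1:
        canvas = ndi.binary_dilation(
            canvas, structure=disk_footprint(int(round((width_px - 1) / 2))))
    return canvas


def _crop(mask: np.ndarray) -> np.ndarray:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    if not rows.any():
        raise ValueError("rasterized mask is empty")
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    return mask[r0:r1 + 1, c0:c1 + 1]


def germinating_spore_mask(spore_radius: float, tube_length: float,
                           tube_width: float, angle_rad: float) -> np.ndarray:
    """Spore body with a straight germ tube emerging at ``angle_rad``."""
    pad = int(math.ceil(spore_radius + tube_length)) + 3
    side = 2 * pad + 1
    canvas = np.zeros((side, side), bool)
    body = disk_mask(spore_radius)
    br = body.shape[0] // 2
    canvas[pad - br:pad + br + 1, pad - br:pad + br + 1] |= body
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    start = np.array([pad + s * spore_radius * 0.8,
                      pad + c * spore_radius * 0.8])
    end = np.array([pad + s * (spore_radius + tube_length),
                    pad + c * (spore_radius + tube_length)])
    canvas |= _thick_path(np.vstack([start, end]), tube_width, canvas.shape)
    return _crop(canvas)


def agglomerate_mask(n_members: int, member_radius: float,
                     overlap: float, rng: np.random.Generator) -> np.ndarray:
    """Union of spores placed by sequential attachment (one 8-connected blob).

    Each new member is attached to a randomly chosen existing member at
    center distance ``2·member_radius·(1 − overlap)``, guaranteeing contact.
    """
    if n_members < 2:
        raise ValueError("an agglomerate needs ≥ 2 members")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    # worst-case extent: chain of members
    pad = int(math.ceil(member_radius * (2 + 2 * (n_members - 1) * (1 - overlap)))) + 3
    side = 2 * pad + 1
    canvas = np.zeros((side, side), bool)
    centers = [np.array([pad, pad], float)]
    member = disk_mask(member_radius)
    mr = member.shape[0] // 2

    def stamp(cy: float, cx: float) -> None:
        iy, ix = int(round(cy)), int(round(cx))
        canvas[iy - mr:iy + mr + 1, ix - mr:ix + mr + 1] |= member

    stamp(*centers[0])
    dist = 2.0 * member_radius * (1.0 - overlap)
    for _ in range(n_members - 1):
        host = centers[rng.integers(len(centers))]
        theta = rng.uniform(0, 2 * math.pi)
        new = host + dist * np.array([math.sin(theta), math.cos(theta)])
        new = np.clip(new, mr + 1, side - mr - 2)
        centers.append(new)
        stamp(*new)
    return _crop(canvas)


def hairy_pellet_mask(core_radius: float, n_filaments: int,
                      filament_length: float, filament_width: float,
                      rng: np.random.Generator, n_cores: int = 1,
                      angle_jitter: float = 0.15,
                      ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Pellet: one or more disk cores plus radially oriented filaments.

    Returns ``(mask, core_masks)`` on the same local grid; core masks are
    kept separately so core-diameter measures can be validated against
    ground truth. Multicore pellets (up to ~4 cores are seen in MPEC runs)
    place additional touching cores around the first.
    """
    if core_radius <= 0 or n_cores < 1:
        raise ValueError("core_radius must be > 0 and n_cores ≥ 1")
    pad = int(math.ceil(core_radius * (1 + 2 * (n_cores > 1))
                        + max(filament_length, 0))) + 3
    side = 2 * pad + 1
    canvas = np.zeros((side, side), bool)
    core = disk_mask(core_radius)
    cr = core.shape[0] // 2

    core_centers = [np.array([pad, pad], float)]
    for i in range(1, n_cores):
        theta = rng.uniform(0, 2 * math.pi)
        off = 1.8 * core_radius
        core_centers.append(core_centers[0] + off * np.array(
            [math.sin(theta), math.cos(theta)]))
    core_masks = []
    for cc in core_centers:
        iy, ix = int(round(cc[0])), int(round(cc[1]))
        local = np.zeros((side, side), bool)
        local[iy - cr:iy + cr + 1, ix - cr:ix + cr + 1] = core
        core_masks.append(local)
        canvas |= local

    body = canvas.copy()
    for k in range(n_filaments):
        cc = core_centers[int(rng.integers(n_cores))]
        theta = 2 * math.pi * k / max(n_filaments, 1) \
            + rng.normal(0, angle_jitter)
        length = filament_length * rng.uniform(0.7, 1.0)
        d = np.array([math.sin(theta), math.cos(theta)])
        start = cc + d * (core_radius * 0.9)
        end = cc + d * (core_radius + length)
        canvas |= _thick_path(np.vstack([start, end]), filament_width,
                              canvas.shape)

    rows = np.any(canvas, axis=1)
    cols = np.any(canvas, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    mask = canvas[r0:r1 + 1, c0:c1 + 1]
    cores = [cm[r0:r1 + 1, c0:c1 + 1] for cm in core_masks]
    return mask, cores


def clump_mask(n_steps: int, step_px: float, width_px: float,
               branch_prob: float, rng: np.random.Generator,
               turn_sd: float = 0.35) -> np.ndarray:
    """Branching persistent random walk: dispersed hyphae / clump forms.

    ``branch_prob`` is the per-step probability that a growing tip spawns a
    second tip; 0 yields a single unbranched hypha.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be ≥ 1")
    # simulate first, rasterize once: each tip is (position, heading)
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    tips = [(np.zeros(2), rng.uniform(0, 2 * math.pi))]
    for _ in range(n_steps):
        new_tips = []
        for pos, heading in tips:
            heading += rng.normal(0, turn_sd)
            nxt = pos + step_px * np.array([math.sin(heading),
                                            math.cos(heading)])
            segments.append((pos, nxt))
            new_tips.append((nxt, heading))
            if rng.uniform() < branch_prob and len(tips) + len(new_tips) < 64:
                new_tips.append((nxt.copy(),
                                 heading + rng.choice([-1, 1])
                                 * rng.uniform(0.6, 1.3)))
        tips = new_tips
    pts = np.array([p for seg in segments for p in seg])
    lo = pts.min(axis=0)
    margin = int(math.ceil(width_px)) + 2
    shape = tuple(int(v) + 2 * margin
                  for v in np.ceil(pts.max(axis=0) - lo).astype(int) + 1)
    canvas = np.zeros(shape, bool)
    for a, b in segments:
        rr, cc = draw_line(*np.rint(a - lo + margin).astype(int),
                           *np.rint(b - lo + margin).astype(int))
        canvas[rr, cc] = True
    if width_px > 1:
        canvas = ndi.binary_dilation(
            canvas, structure=disk_footprint(int(round((width_px - 1) / 2))))
    return _crop(canvas)


def sinusoid_filament_mask(arc_length: float, width_px: float,
                           amplitude: float = 20.0,
                           wavelength: float = 150.0) -> np.ndarray:
    """Deterministic smooth curved filament of a given arc length.

    A sine curve y = amplitude·sin(2πx/wavelength) is traced until the
    accumulated arc length reaches ``arc_length``, then dilated to
    ``width_px``. No randomness: the same parameters always yield the same
    mask.
    """
    if arc_length <= 0 or width_px < 1:
        raise ValueError("arc_length must be > 0 and width_px ≥ 1")
    xs = [0.0]
    ys = [0.0]
    acc = 0.0
    dx = 0.25
    x = 0.0
    while acc < arc_length:
        x_new = x + dx
        y_new = amplitude * math.sin(2 * math.pi * x_new / wavelength)
        acc += math.hypot(dx, y_new - ys[-1])
        xs.append(x_new)
        ys.append(y_new)
        x = x_new
    pts = np.column_stack([np.asarray(ys) - min(ys) + width_px + 2,
                           np.asarray(xs) + width_px + 2])
    shape = (int(pts[:, 0].max()) + int(width_px) + 3,
             int(pts[:, 1].max()) + int(width_px) + 3)
    return _crop(_thick_path(pts, width_px, shape))


def microparticle_mask(diameter_px: float, rng: np.random.Generator,
                       inner_frac: tuple[float, float] = (0.30, 0.55),
                       n_points: tuple[int, int] = (5, 8)) -> np.ndarray:
    """Angular debris grain: a star polygon with concave fracture notches.

    Emulates crushed mineral (Al₂O₃) microparticles, which are sharp-edged
    and irregular with re-entrant fracture surfaces — markedly less
    circular than spores, which is what the circularity-based debris filter
    exploits. Vertices alternate between an outer radius near the nominal
    grain radius and an inner notch radius.
    """
    if diameter_px <= 1:
        raise ValueError("diameter_px must be > 1")
    r_out = diameter_px / 2.0
    k = int(rng.integers(n_points[0], n_points[1] + 1))
    base = np.linspace(0, 2 * math.pi, 2 * k, endpoint=False)
    angles = base + rng.uniform(-0.25, 0.25, size=2 * k) * (math.pi / k)
    radii = np.empty(2 * k)
    radii[0::2] = r_out * rng.uniform(0.75, 1.0, size=k)
    radii[1::2] = r_out * rng.uniform(*inner_frac, size=k)
    radii[0] = r_out  # keep the nominal diameter reachable
    pad = int(math.ceil(r_out)) + 2
    ys = pad + radii * np.sin(angles)
    xs = pad + radii * np.cos(angles)
    canvas = np.zeros((2 * pad + 1, 2 * pad + 1), bool)
    rr, cc = draw_polygon(ys, xs, canvas.shape)
    canvas[rr, cc] = True
    if not canvas.any():  # degenerate tiny polygon: fall back to one pixel
        canvas[pad, pad] = True
    return _crop(canvas)
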