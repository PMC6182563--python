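"""Synthetic phase-contrast-like micrographs with exact ground truth.

No image data ships with studies of this kind, so every pipeline stage is
validated against generated scenes: dark mycelial objects (spores ~2–8 μm,
agglomerates, hairy pellets) on a bright background, optionally littered
with ~10 μm angular mineral-microparticle debris, rendered at a declared
μm/px calibration. The generator records, for every object, its true pixel
mask and the true descriptor values computed by the morphometry routines on
that noiseless mask — separating rendering/segmentation error from
descriptor error in tests.

Timecourse profiles emulate, qualitatively, the morphological progressions
of submerged cultures: spore swelling → germination → agglomeration →
pellet formation (spore-agglomerative species), and the hyphal-agglomerative,
perithecia-seeded and non-agglomerative variants. Profiles are editable
YAML presets; their object sizes are geometric stand-ins, not calibrated
growth kinetics.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import shapes
from .imaging import CalibratedImage
from .morphometry import MorphoRecord, measure_object

__all__ = [
    "SceneSpec", "TrueObject", "GroundTruth", "Scene", "PlacementError",
    "build_scene", "generate_spore_field", "generate_agglomerate",
    "generate_hairy_pellet", "generate_clump", "add_microparticles",
    "render", "simulate_timecourse", "list_profiles", "load_profile",
]

_PROFILE_DIR = Path(__file__).parent / "profiles"

#: Default microparticle diameter: mineral grains of mean diameter 10 μm.
MICROPARTICLE_DIAMETER_UM = 10.0

_OBJECT_KINDS = ("spore", "swollen_spore", "germinating_spore",
                 "branched_hypha", "clump", "agglomerate", "hairy_pellet",
                 "core_shell_pellet", "multicore_pellet",
                 "sinusoid_filament")


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without overlap."""


@dataclass
class SceneSpec:
    """Generative description of one synthetic scene.

    ``objects`` is a list of dicts, each with a ``kind`` (one of
    ``spore, swollen_spore, germinating_spore, branched_hypha, clump,
    agglomerate, hairy_pellet, core_shell_pellet, multicore_pellet,
    sinusoid_filament``), an optional ``count`` (default 1), an optional
    explicit ``center`` [x, y] in pixels, and kind-specific parameters
    (``*_um`` in μm, ``*_px`` in pixels). A fixed seed yields a
    byte-identical scene, truth and rendering.
    """

    width: int = 2448
    height: int = 1920
    calibration: float = 1.0          # μm per pixel
    seed: int = 0
    objects: list[dict] = field(default_factory=list)
    n_microparticles: int = 0
    microparticle_diameter_um: float = MICROPARTICLE_DIAMETER_UM
    background: float = 220.0         # 8-bit intensity of the bright field
    noise_sd: float = 3.0             # additive Gaussian noise, 8-bit units
    object_intensity: float = 60.0    # dark mycelial objects
    debris_intensity: float = 110.0   # microparticles render distinctly
    halo_width: int = 0               # optional bright halo around objects
    min_gap_px: int = 12              # spacing enforced between objects

    def replace(self, **kw: Any) -> "SceneSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class TrueObject:
    """Ground truth for one generated object."""

    kind: str
    mask: np.ndarray                 # full-frame boolean mask
    is_mycelial: bool
    truth: MorphoRecord              # descriptors on the true mask
    core_masks: list[np.ndarray] = field(default_factory=list)
    clipped: bool = False            # object clipped at the frame border

    @property
    def n_cores(self) -> int:
        return len(self.core_masks)


@dataclass
class GroundTruth:
    """Per-scene truth: object masks, true descriptors, class labels."""

    objects: list[TrueObject]
    debris: list[TrueObject]
    calibration: float

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def class_labels(self, threshold: float) -> list[str]:
        """small/large class of each mycelial object at an area threshold."""
        return ["small" if o.truth.A < threshold else "large"
                for o in self.objects]


@dataclass
class Scene:
    """A built scene: its spec plus ground truth."""

    spec: SceneSpec
    truth: GroundTruth


def _spore_params(params: dict, rng: np.random.Generator,
                  cal: float) -> np.ndarray:
    d_um = float(params.get("diameter_um", 4.0))
    spread = float(params.get("diameter_sd_um", 0.0))
    if spread > 0:
        d_um = max(0.5, rng.normal(d_um, spread))
    ratio = float(params.get("axis_ratio", 1.0))
    r_px = d_um / 2.0 / cal
    if ratio == 1.0:
        return shapes.disk_mask(r_px)
    angle = float(params.get("angle", rng.uniform(0, math.pi)))
    # axis_ratio = major/minor with the same area as the nominal disk
    semi_major = r_px * math.sqrt(ratio)
    semi_minor = r_px / math.sqrt(ratio)
    return shapes.ellipse_mask(semi_major, semi_minor, angle)


def _make_mask(kind: str, params: dict, rng: np.random.Generator,
               cal: float) -> tuple[np.ndarray, list[np.ndarray]]:
    """Local mask (and core masks, if any) for one object spec."""
    if kind == "spore":
        return _spore_params(params, rng, cal), []
    if kind == "swollen_spore":
        p = dict(params)
        p.setdefault("diameter_um", 6.0)
        return _spore_params(p, rng, cal), []
    if kind == "germinating_spore":
        d_um = float(params.get("diameter_um", 5.0))
        tube_um = float(params.get("tube_length_um", 3 * d_um))
        mask = shapes.germinating_spore_mask(
            spore_radius=d_um / 2.0 / cal,
            tube_length=tube_um / cal,
            tube_width=float(params.get("tube_width_px", 2)),
            angle_rad=float(params.get("angle", rng.uniform(0, 2 * math.pi))))
        return mask, []
    if kind in ("clump", "branched_hypha"):
        default_branch = 0.1 if kind == "clump" else 0.25
        mask = shapes.clump_mask(
            n_steps=int(params.get("n_steps", 60)),
            step_px=float(params.get("step_px", 5.0)),
            width_px=float(params.get("width_px", 3.0)),
            branch_prob=float(params.get("branch_prob", default_branch)),
            rng=rng)
        return mask, []
    if kind == "agglomerate":
        mask = shapes.agglomerate_mask(
            n_members=int(params.get("n_members", 20)),
            member_radius=float(params.get("member_diameter_um", 6.0))
            / 2.0 / cal,
            overlap=float(params.get("overlap", 0.4)),
            rng=rng)
        return mask, []
    if kind in ("hairy_pellet", "core_shell_pellet", "multicore_pellet"):
        n_cores = int(params.get("n_cores",
                                 2 if kind == "multicore_pellet" else 1))
        core_r_um = float(params.get("core_radius_um", 60.0))
        default_fil = 2.0 * core_r_um if kind == "core_shell_pellet" \
            else 0.5 * core_r_um
        mask, cores = shapes.hairy_pellet_mask(
            core_radius=core_r_um / cal,
            n_filaments=int(params.get("n_filaments", 30)),
            filament_length=float(params.get("filament_length_um",
                                             default_fil)) / cal,
            filament_width=float(params.get("filament_width_px", 2)),
            rng=rng,
            n_cores=n_cores)
        return mask, cores
    if kind == "sinusoid_filament":
        mask = shapes.sinusoid_filament_mask(
            arc_length=float(params.get("arc_length_px", 300.0)),
            width_px=float(params.get("width_px", 3.0)),
            amplitude=float(params.get("amplitude_px", 20.0)),
            wavelength=float(params.get("wavelength_px", 150.0)))
        return mask, []
    raise ValueError(f"unknown object kind {kind!r}; valid: {_OBJECT_KINDS}")


def _place(local: np.ndarray, occupancy: np.ndarray, gap: int,
           rng: np.random.Generator,
           center: tuple[float, float] | None) -> tuple[int, int]:
    """Top-left placement of a local mask keeping ≥ gap px from others."""
    H, W = occupancy.shape
    h, w = local.shape
    if h + 2 * gap >= H or w + 2 * gap >= W:
        raise PlacementError(
            f"object of size {w}×{h} px does not fit a {W}×{H} frame "
            f"with {gap} px margins")
    if center is not None:
        y0 = int(round(center[1] - h / 2))
        x0 = int(round(center[0] - w / 2))
        if y0 < 0 or x0 < 0 or y0 + h > H or x0 + w > W:
            raise PlacementError("explicit center places object off-frame")
        return y0, x0
    def free(y0: int, x0: int) -> bool:
        window = occupancy[max(y0 - gap, 0):y0 + h + gap,
                           max(x0 - gap, 0):x0 + w + gap]
        return not window.any()

    for _ in range(200):
        y0 = int(rng.integers(gap, H - h - gap))
        x0 = int(rng.integers(gap, W - w - gap))
        if free(y0, x0):
            return y0, x0
    # rejection failed: exhaustive scan over a shuffled coarse grid, so
    # placement only fails when no slot exists at all
    stride = max(gap // 2, 4)
    ys = np.arange(gap, H - h - gap + 1, stride)
    xs = np.arange(gap, W - w - gap + 1, stride)
    cand = [(int(y), int(x)) for y in ys for x in xs]
    rng.shuffle(cand)
    for y0, x0 in cand:
        if free(y0, x0):
            return y0, x0
    raise PlacementError(
        "could not place object without overlap: scene too dense")


def build_scene(spec: SceneSpec) -> Scene:
    """Rasterize every object of a :class:`SceneSpec` into ground truth.

    Placement is rejection-sampled with a minimum bounding-box gap of
    ``spec.min_gap_px`` pixels between objects (and from the frame border
    unless an explicit center is given); too-dense requests raise
    :class:`PlacementError`. True descriptors are computed on each
    noiseless mask.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = int(spec.height), int(spec.width)
    occupancy = np.zeros((H, W), bool)
    objects: list[TrueObject] = []
    next_id = 1

    for obj in spec.objects:
        obj = dict(obj)
        kind = obj.pop("kind")
        count = int(obj.pop("count", 1))
        center = obj.pop("center", None)
        for _ in range(count):
            local, cores = _make_mask(kind, obj, rng, spec.calibration)
            y0, x0 = _place(local, occupancy, spec.min_gap_px, rng,
                            tuple(center) if center is not None else None)
            full = np.zeros((H, W), bool)
            full[y0:y0 + local.shape[0], x0:x0 + local.shape[1]] = local
            occupancy |= full
            full_cores = []
            for cm in cores:
                fc = np.zeros((H, W), bool)
                fc[y0:y0 + cm.shape[0], x0:x0 + cm.shape[1]] = cm
                full_cores.append(fc)
            rec = measure_object(full, spec.calibration, object_id=next_id)
            objects.append(TrueObject(kind=kind, mask=full, is_mycelial=True,
                                      truth=rec, core_masks=full_cores))
            next_id += 1

    debris: list[TrueObject] = []
    d_px = spec.microparticle_diameter_um / spec.calibration
    for _ in range(int(spec.n_microparticles)):
        local = shapes.microparticle_mask(d_px, rng)
        y0, x0 = _place(local, occupancy, spec.min_gap_px, rng, None)
        full = np.zeros((H, W), bool)
        full[y0:y0 + local.shape[0], x0:x0 + local.shape[1]] = local
        occupancy |= full
        rec = measure_object(full, spec.calibration, object_id=next_id)
        debris.append(TrueObject(kind="microparticle", mask=full,
                                 is_mycelial=False, truth=rec))
        next_id += 1

    truth = GroundTruth(objects=objects, debris=debris,
                        calibration=spec.calibration)
    return Scene(spec=spec, truth=truth)


def add_microparticles(scene: Scene, count: int) -> Scene:
    """Scene with ``count`` additional microparticle debris grains.

    Rebuilds deterministically from the spec; ``count = 0`` returns an
    equivalent scene.
    """
    if count < 0:
        raise ValueError("count must be ≥ 0")
    if count == 0:
        return scene
    spec = scene.spec.replace(
        n_microparticles=scene.spec.n_microparticles + count)
    return build_scene(spec)


def render(scene: Scene) -> CalibratedImage:
    """Render the scene as an 8-bit RGB phase-contrast-like micrograph.

    Dark objects on a bright background; the green plane carries the full
    contrast (red/blue are washed toward the background, as in chromatic
    phase-contrast captures). Rendering never alters ground-truth masks,
    and a fixed spec yields byte-identical images.
    """
    spec = scene.spec
    gray = np.full((spec.height, spec.width), spec.background, float)
    union = np.zeros(gray.shape, bool)
    for obj in scene.truth.objects:
        gray[obj.mask] = spec.object_intensity
        union |= obj.mask
    for d in scene.truth.debris:
        gray[d.mask] = spec.debris_intensity
        union |= d.mask
    if spec.halo_width > 0:
        from scipy import ndimage as ndi
        halo = ndi.binary_dilation(union, iterations=int(spec.halo_width)) \
            & ~union
        gray[halo] = min(255.0, spec.background + 25.0)
    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF,
                                           0x6E6F6973])
        gray = gray + noise_rng.normal(0.0, spec.noise_sd, gray.shape)
    green = np.clip(gray, 0, 255)
    washed = np.clip(0.5 * gray + 0.5 * spec.background, 0, 255)
    rgb = np.stack([washed, green, washed], axis=-1).astype(np.uint8)
    return CalibratedImage(pixels=rgb, calibration=spec.calibration)


# ---------------------------------------------------------------------------
# convenience single-population generators

def _single_scene(spec_kwargs: dict, objects: list[dict],
                  ) -> tuple[Scene, GroundTruth]:
    spec = SceneSpec(objects=objects, **spec_kwargs)
    scene = build_scene(spec)
    return scene, scene.truth


def generate_spore_field(n_spores: int, *, diameter_um: float = 4.0,
                         diameter_sd_um: float = 0.5,
                         axis_ratio: float = 1.0,
                         width: int = 600, height: int = 600,
                         calibration: float = 0.1, seed: int = 0,
                         n_microparticles: int = 0, noise_sd: float = 0.0,
                         ) -> tuple[Scene, GroundTruth]:
    """Field of circular (axis_ratio 1) or lemon-shaped spores."""
    return _single_scene(
        dict(width=width, height=height, calibration=calibration, seed=seed,
             n_microparticles=n_microparticles, noise_sd=noise_sd),
        [{"kind": "spore", "count": n_spores, "diameter_um": diameter_um,
          "diameter_sd_um": diameter_sd_um, "axis_ratio": axis_ratio}])


def generate_agglomerate(n_members: int, *, member_diameter_um: float = 6.0,
                         overlap: float = 0.4, width: int = 600,
                         height: int = 600, calibration: float = 0.5,
                         seed: int = 0, noise_sd: float = 0.0,
                         ) -> tuple[Scene, GroundTruth]:
    """One spore agglomerate built by sequential attachment."""
    return _single_scene(
        dict(width=width, height=height, calibration=calibration, seed=seed,
             noise_sd=noise_sd),
        [{"kind": "agglomerate", "n_members": n_members,
          "member_diameter_um": member_diameter_um, "overlap": overlap}])


def generate_hairy_pellet(core_radius_um: float, n_filaments: int,
                          filament_length_um: float, *,
                          filament_width_px: float = 2, n_cores: int = 1,
                          width: int = 800, height: int = 800,
                          calibration: float = 1.0, seed: int = 0,
                          noise_sd: float = 0.0,
                          ) -> tuple[Scene, GroundTruth]:
    """One hairy pellet: disk core(s) plus radial filaments."""
    return _single_scene(
        dict(width=width, height=height, calibration=calibration, seed=seed,
             noise_sd=noise_sd),
        [{"kind": "hairy_pellet", "core_radius_um": core_radius_um,
          "n_filaments": n_filaments,
          "filament_length_um": filament_length_um,
          "filament_width_px": filament_width_px, "n_cores": n_cores}])


def generate_clump(n_steps: int, *, step_px: float = 5.0,
                   width_px: float = 3.0, branch_prob: float = 0.1,
                   width: int = 800, height: int = 800,
                   calibration: float = 1.0, seed: int = 0,
                   noise_sd: float = 0.0) -> tuple[Scene, GroundTruth]:
    """One branching random-walk clump / dispersed hypha."""
    return _single_scene(
        dict(width=width, height=height, calibration=calibration, seed=seed,
             noise_sd=noise_sd),
        [{"kind": "clump", "n_steps": n_steps, "step_px": step_px,
          "width_px": width_px, "branch_prob": branch_prob}])


# ---------------------------------------------------------------------------
# timecourse profiles

def list_profiles() -> list[str]:
    """Names of the shipped timecourse presets."""
    return sorted(p.stem for p in _PROFILE_DIR.glob("*.yaml"))


def load_profile(profile: str | Path | dict) -> dict:
    """Load a profile preset by name, a YAML file path, or pass a dict."""
    if isinstance(profile, dict):
        return profile
    path = Path(profile)
    if not path.suffix:  # preset name
        path = _PROFILE_DIR / f"{profile}.yaml"
        if not path.exists():
            raise ValueError(
                f"unknown profile {profile!r}; available presets: "
                f"{', '.join(list_profiles())}")
    if not path.exists():
        raise ValueError(f"profile file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark else ""
            raise ValueError(f"malformed profile file {path}{line}: "
                             f"{exc}") from exc
    if not isinstance(data, dict) or "timepoints" not in data:
        raise ValueError(f"profile {path} must define a 'timepoints' list")
    return data


def simulate_timecourse(profile: str | Path | dict, seed: int = 0,
                        ) -> list[tuple[float, Scene, GroundTruth]]:
    """Generate one scene per timepoint of a morphological-stage profile.

    Each timepoint entry provides its own frame size, calibration
    (mirroring the objective switching needed as objects grow by orders of
    magnitude) and object composition. Returns ``(time_hr, scene, truth)``
    tuples in increasing time order; per-timepoint seeds are derived from
    ``seed`` so the whole timecourse is reproducible.
    """
    data = load_profile(profile)
    tps = data["timepoints"]
    if not tps:
        raise ValueError("profile has an empty timepoint schedule")
    times = [float(tp["time_hr"]) for tp in tps]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("timepoint schedule must be strictly increasing")
    out = []
    for i, tp in enumerate(tps):
        spec = SceneSpec(
            width=int(tp.get("width", 600)),
            height=int(tp.get("height", 600)),
            calibration=float(tp.get("calibration", 1.0)),
            seed=(int(seed) * 100003 + 7919 * i) % (2 ** 31),
            objects=[dict(o) for o in tp.get("objects", [])],
            n_microparticles=int(tp.get("microparticles", 0)),
            noise_sd=float(tp.get("noise_sd", 0.0)),
        )
        scene = build_scene(spec)
        out.append((float(tp["time_hr"]), scene, scene.truth))
    return out
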