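import numpy as np
import pytest

from mycomorph import SceneSpec, build_scene, generate_spore_field, render
from mycomorph.config import RunConfig
from mycomorph.pipeline import analyze_image


def match_to_truth(record, truth_objects):
    """Ground-truth object nearest (by centroid) to a measured record."""
    return min(truth_objects,
               key=lambda o: np.hypot(record.centroid[0] - o.truth.centroid[0],
                                      record.centroid[1] - o.truth.centroid[1]))


@pytest.fixture(scope="session")
def disk200_analysis():
    """Noise-free scene with one 200 px-radius disk, run through the full
    pipeline (render -> green plane -> median -> Sobel -> segment -> measure)."""
    spec = SceneSpec(width=520, height=520, calibration=1.0, seed=0,
                     noise_sd=0.0,
                     objects=[{"kind": "spore", "diameter_um": 400.0,
                               "diameter_sd_um": 0.0, "center": [260, 260]}])
    scene = build_scene(spec)
    result = analyze_image(render(scene), RunConfig(calibration=1.0, filters=[]))
    return scene, result


@pytest.fixture(scope="session")
def filament_analysis():
    """Noise-free scene with one deterministic sinusoidal filament
    (3 px wide, 300 px arc length), fully analyzed."""
    spec = SceneSpec(width=360, height=360, calibration=1.0, seed=0,
                     noise_sd=0.0,
                     objects=[{"kind": "sinusoid_filament",
                               "arc_length_px": 300.0, "width_px": 3.0,
                               "amplitude_px": 20.0, "wavelength_px": 150.0,
                               "center": [180, 180]}])
    scene = build_scene(spec)
    result = analyze_image(render(scene), RunConfig(calibration=1.0, filters=[]))
    return scene, result


@pytest.fixture(scope="session")
def debris_scene():
    """Canonical spore-image fixture: 20 spores plus 60 angular ~10 μm
    microparticles at 0.1 μm/px, noise-free."""
    scene, truth = generate_spore_field(20, seed=3, n_microparticles=60,
                                        width=1500, height=1500)
    return scene, truth
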