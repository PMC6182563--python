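import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from mycomorph import (SceneSpec, add_microparticles, build_scene,
                       generate_agglomerate, generate_clump,
                       generate_hairy_pellet, generate_spore_field,
                       list_profiles, render, simulate_timecourse)
from mycomorph.imaging import extract_green_plane
from mycomorph.morphometry import elongation
from mycomorph.synthetic_data import PlacementError, load_profile


class TestSporeField:
    def test_requested_count_and_size(self):
        scene, truth = generate_spore_field(
            50, diameter_um=2.0, diameter_sd_um=0.0, calibration=0.1,
            width=900, height=900, seed=4)
        assert truth.n_objects == 50
        # 2 μm spores at 0.1 μm/px are ~20 px across
        for obj in truth.objects:
            assert obj.truth.Dmax / 0.1 == pytest.approx(20, abs=2)

    def test_circular_spores_have_unit_elongation(self):
        _, truth = generate_spore_field(20, diameter_sd_um=0.0, seed=1)
        for obj in truth.objects:
            assert obj.truth.E == pytest.approx(1.0, abs=0.02)

    def test_lemon_spores_match_moment_oracle(self):
        # axis ratio a/b = 2 -> E = (a/b)² = 4 for the pixel-moment ratio
        _, truth = generate_spore_field(10, diameter_um=6.0,
                                        diameter_sd_um=0.0, axis_ratio=2.0,
                                        seed=2)
        for obj in truth.objects:
            assert elongation(obj.mask) == pytest.approx(4.0, rel=0.05)
            assert obj.truth.E == pytest.approx(4.0, rel=0.05)

    def test_same_seed_reproduces_scene_exactly(self):
        s1, t1 = generate_spore_field(12, seed=9, n_microparticles=5,
                                      noise_sd=2.0)
        s2, t2 = generate_spore_field(12, seed=9, n_microparticles=5,
                                      noise_sd=2.0)
        assert render(s1).pixels.tobytes() == render(s2).pixels.tobytes()
        for a, b in zip(t1.objects, t2.objects):
            np.testing.assert_array_equal(a.mask, b.mask)

    def test_impossible_density_raises_placement_error(self):
        with pytest.raises(PlacementError):
            generate_spore_field(200, diameter_um=8.0, width=300, height=300,
                                 calibration=0.1, seed=0)


class TestAgglomerate:
    def test_union_is_one_connected_component(self):
        _, truth = generate_agglomerate(10, seed=1)
        labeled, n = ndi.label(truth.objects[0].mask,
                               structure=np.ones((3, 3)))
        assert n == 1

    def test_overlap_shrinks_union_below_member_sum(self):
        _, truth = generate_agglomerate(10, member_diameter_um=6.0,
                                        overlap=0.4, calibration=0.5, seed=1)
        member_px = np.sum(
            (np.hypot(*np.mgrid[-6:7, -6:7]) <= 6.0))  # one 6 px-radius disk
        union_px = truth.objects[0].mask.sum()
        assert union_px < 10 * member_px

    def test_true_area_equals_pixel_count_oracle(self):
        _, truth = generate_agglomerate(8, calibration=0.5, seed=3)
        obj = truth.objects[0]
        assert obj.truth.A == pytest.approx(obj.mask.sum() * 0.25)


class TestHairyPellet:
    def test_bare_core_is_solid(self):
        _, truth = generate_hairy_pellet(50.0, 0, 0.0, seed=0)
        assert truth.objects[0].truth.R >= 0.98

    def test_roughness_decreases_with_filament_count(self):
        # decreasing while filaments still open new hull directions; once
        # the hull saturates, added filaments only fill it back in
        rs = []
        for n_fil in (0, 3, 8, 15):
            _, truth = generate_hairy_pellet(50.0, n_fil, 50.0, seed=2)
            rs.append(truth.objects[0].truth.R)
        assert rs[0] > rs[1] > rs[2] > rs[3]
        _, truth = generate_hairy_pellet(50.0, 60, 50.0, seed=2)
        assert truth.objects[0].truth.R < 0.9

    def test_dmax_spans_core_plus_filaments(self):
        _, truth = generate_hairy_pellet(60.0, 40, 40.0, seed=1)
        assert truth.objects[0].truth.Dmax == pytest.approx(
            2 * (60 + 40), rel=0.15)

    def test_multicore_truth_bookkeeping(self):
        _, truth = generate_hairy_pellet(40.0, 20, 20.0, n_cores=3, seed=5)
        obj = truth.objects[0]
        assert obj.n_cores == 3
        for cm in obj.core_masks:
            assert not (cm & ~obj.mask).any()  # cores inside the pellet


class TestClump:
    def test_zero_branching_gives_single_strand(self):
        scene, truth = generate_clump(40, branch_prob=0.0, seed=3)
        mask = truth.objects[0].mask
        # an unbranched 3 px strand: area ≈ length · width, no blob
        assert truth.objects[0].truth.E > 2

    def test_thin_filament_is_elongated_and_low_mo(self):
        spec = SceneSpec(width=400, height=400, calibration=1.0, seed=0,
                         noise_sd=0.0,
                         objects=[{"kind": "sinusoid_filament",
                                   "arc_length_px": 300.0, "width_px": 3.0,
                                   "center": [200, 200]}])
        truth = build_scene(spec).truth
        rec = truth.objects[0].truth
        assert rec.E > 4
        assert rec.Mo < 0.5


class TestMicroparticles:
    def test_zero_count_is_identity(self):
        scene, _ = generate_spore_field(5, seed=1)
        assert add_microparticles(scene, 0) is scene

    def test_debris_bookkeeping_and_identity_labels(self):
        scene, _ = generate_spore_field(5, seed=1, width=1200, height=1200)
        out = add_microparticles(scene, 30)
        assert len(out.truth.debris) == 30
        assert all(not d.is_mycelial for d in out.truth.debris)
        assert all(d.kind == "microparticle" for d in out.truth.debris)

    def test_grain_size_scale(self):
        # a circular 10 μm particle would cover π·5² ≈ 78.5 μm²; angular
        # grains are bounded by that disk
        scene, _ = generate_spore_field(3, seed=2, width=1200, height=1200)
        out = add_microparticles(scene, 20)
        for d in out.truth.debris:
            assert d.truth.A <= math.pi * 5.0 ** 2 * 1.1
            assert d.truth.Dmax <= 10.0 * 1.1
            assert d.truth.Dmax >= 4.0


class TestRender:
    def test_noise_free_rendering_hits_exact_intensities(self):
        scene, truth = generate_spore_field(3, seed=1, noise_sd=0.0)
        img = render(scene)
        green = extract_green_plane(img).pixels
        mask = truth.objects[0].mask
        assert np.all(green[mask] == scene.spec.object_intensity)
        assert green[0, 0] == scene.spec.background

    def test_green_plane_carries_full_contrast(self):
        scene, truth = generate_spore_field(3, seed=1, noise_sd=0.0)
        img = render(scene)
        mask = truth.objects[0].mask
        contrast = lambda ch: (img.pixels[..., ch][~mask].mean()
                               - img.pixels[..., ch][mask].mean())
        assert contrast(1) > contrast(0)
        assert contrast(1) > contrast(2)

    def test_rendering_is_deterministic(self):
        scene, _ = generate_spore_field(4, seed=7, noise_sd=3.0)
        assert render(scene).pixels.tobytes() == render(scene).pixels.tobytes()


class TestTimecourse:
    def test_growth_profile_mean_area_non_decreasing(self):
        course = simulate_timecourse("agglomerative-spore", seed=0)
        means = [np.mean([o.truth.A for o in truth.objects])
                 for _, _, truth in course]
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_agglomerate_stage_straddles_class_threshold(self):
        course = simulate_timecourse("agglomerative-spore", seed=0)
        data = load_profile("agglomerative-spore")
        stage_by_time = {tp["time_hr"]: tp["stage"]
                         for tp in data["timepoints"]}
        for time_hr, _, truth in course:
            if stage_by_time[time_hr] == "agglomeration":
                labels = truth.class_labels(1e4)
                assert "small" in labels and "large" in labels

    def test_all_presets_build(self):
        assert set(list_profiles()) == {
            "agglomerative-spore", "agglomerative-hyphal",
            "perithecia-seeded", "non-agglomerative"}
        for name in list_profiles():
            course = simulate_timecourse(name, seed=3)
            times = [t for t, _, _ in course]
            assert times == sorted(times)
            assert all(truth.n_objects > 0 for _, _, truth in course)

    def test_unknown_profile_lists_presets(self):
        with pytest.raises(ValueError, match="agglomerative-spore"):
            simulate_timecourse("no-such-profile")

    def test_malformed_profile_reports_line(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("timepoints:\n  - time_hr: 0\n   oops: [unclosed\n")
        with pytest.raises(ValueError, match="line"):
            load_profile(bad)
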