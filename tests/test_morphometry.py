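import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from shapely.geometry import Point, Polygon

from mycomorph import morphometry as mm
from mycomorph.shapes import (clump_mask, disk_mask, ellipse_mask,
                              hairy_pellet_mask, sinusoid_filament_mask)

SQUARE_MEAN_DIAMETER = (4 / math.pi) * math.log(1 + math.sqrt(2))  # per side


def brute_force_max_diameter(mask):
    """O(n²) maximum pairwise distance over boundary pixel centers."""
    from scipy import ndimage as ndi
    er = ndi.binary_erosion(mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool), border_value=0)
    pts = np.argwhere(mask & ~er).astype(float)
    d = pts[:, None, :] - pts[None, :, :]
    return math.sqrt(((d ** 2).sum(axis=-1)).max())


def chord_scan_oracle(mask, n_dirs=180, step=0.25):
    """Naive per-direction chord scan through the centroid (slow loops)."""
    from scipy import ndimage as ndi
    cy, cx = ndi.center_of_mass(mask)
    h, w = mask.shape
    chords = []
    for i in range(n_dirs):
        theta = i * math.pi / n_dirs
        total = 0.0
        for sign in (1, -1):
            t = step
            while True:
                x = cx + sign * t * math.cos(theta)
                y = cy + sign * t * math.sin(theta)
                ix, iy = int(round(x)), int(round(y))
                if not (0 <= ix < w and 0 <= iy < h and mask[iy, ix]):
                    break
                t += step
            total += t - step
        chords.append(total)
    return float(np.mean(chords))


def rasterized_hull_area(mask):
    """Independent hull rasterization: shapely hull polygon over pixel
    centers, counting covered pixel centers."""
    pts = np.argwhere(mask)
    hull = pts[ConvexHull(pts.astype(float)).vertices]
    poly = Polygon([(float(c), float(r)) for r, c in hull])
    rows, cols = np.nonzero(np.ones(mask.shape, bool))
    count = sum(1 for r, c in zip(rows, cols) if poly.covers(Point(c, r)))
    return count


class TestProjectedArea:
    @pytest.mark.parametrize("n_px,cal,expected", [
        (100, 0.5, 25.0),
        (1, 1.0, 1.0),
    ])
    def test_pixel_count_times_squared_calibration(self, n_px, cal, expected):
        mask = np.zeros((20, 20), bool)
        mask.flat[:n_px] = True
        assert mm.projected_area(mask, cal) == pytest.approx(expected)

    def test_rasterized_disk_close_to_pi_r_squared(self):
        mask = disk_mask(50)
        assert mm.projected_area(mask, 1.0) == pytest.approx(
            math.pi * 50 ** 2, rel=0.01)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mm.projected_area(np.zeros((5, 5), bool), 1.0)


class TestMeanDiameter:
    def test_disk_gives_twice_radius(self):
        assert mm.mean_diameter(disk_mask(50), 1.0) == pytest.approx(
            100.0, rel=0.02)

    def test_square_matches_closed_form(self):
        # average chord of a square through its center:
        # (4/π)·ln(1+√2)·s ≈ 1.1222·s
        s = 80
        got = mm.mean_diameter(np.ones((s, s), bool), 1.0)
        assert got == pytest.approx(SQUARE_MEAN_DIAMETER * s, rel=0.01)

    def test_thin_line_matches_explicit_chord_scan(self):
        mask = np.ones((1, 60), bool)
        got = mm.mean_diameter(mask, 1.0, n_dirs=90)
        assert got == pytest.approx(chord_scan_oracle(mask, n_dirs=90),
                                    rel=0.01)

    def test_calibration_scales_linearly(self):
        mask = disk_mask(30)
        assert mm.mean_diameter(mask, 2.0) == pytest.approx(
            2 * mm.mean_diameter(mask, 1.0))


class TestMaxDiameter:
    def test_disk(self):
        assert mm.max_diameter(disk_mask(40), 1.0) == pytest.approx(
            80.0, abs=1.0)

    def test_rectangle_diagonal_between_pixel_centers(self):
        mask = np.ones((20, 30), bool)
        assert mm.max_diameter(mask, 1.0) == pytest.approx(
            math.hypot(29, 19))

    def test_random_blobs_match_brute_force(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            mask = clump_mask(n_steps=rng.integers(5, 25), step_px=3.0,
                              width_px=3.0, branch_prob=0.2, rng=rng)
            assert mm.max_diameter(mask, 1.0) == pytest.approx(
                brute_force_max_diameter(mask)), f"blob {trial}"


class TestElongation:
    def test_disk_is_circular(self):
        assert mm.elongation(disk_mask(50)) == pytest.approx(1.0, abs=0.02)

    def test_rectangle_matches_discrete_uniform_variances(self):
        # variances of discrete uniform coordinates: (n²−1)/12 each axis
        assert mm.elongation(np.ones((10, 20), bool)) == pytest.approx(
            399 / 99, rel=0.01)

    def test_rotation_by_90_degrees_preserves_value(self):
        mask = ellipse_mask(40, 15, angle_rad=0.3)
        assert mm.elongation(np.rot90(mask)) == pytest.approx(
            mm.elongation(mask), abs=0.02)

    def test_perfect_line_returns_infinity(self):
        assert math.isinf(mm.elongation(np.ones((1, 30), bool)))

    def test_single_pixel_defined_as_one(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        assert mm.elongation(mask) == 1.0


class TestRoughness:
    def test_disk_is_nearly_solid(self):
        assert mm.roughness(disk_mask(40)) >= 0.96

    def test_spiky_disk_matches_hull_rasterization_oracle(self):
        rng = np.random.default_rng(5)
        mask, _ = hairy_pellet_mask(core_radius=40, n_filaments=8,
                                    filament_length=40, filament_width=1,
                                    rng=rng, angle_jitter=0.0)
        got = mm.roughness(mask)
        oracle = mask.sum() / rasterized_hull_area(mask)
        assert got == pytest.approx(oracle, abs=0.02)
        assert got < 0.6

    def test_hull_of_hull_is_solid(self):
        from skimage.morphology import convex_hull_image
        rng = np.random.default_rng(2)
        mask = clump_mask(15, 4.0, 3.0, 0.2, rng)
        hull = convex_hull_image(mask)
        assert mm.roughness(hull) >= 0.99


class TestCircularity:
    def test_disk_close_to_one(self):
        assert mm.circularity(disk_mask(20)) >= 0.9

    def test_thin_line_is_very_noncircular(self):
        # A = 100 px², P ≈ 2·100 → 4π·100/200² ≈ 0.031
        got = mm.circularity(np.ones((1, 100), bool))
        assert got < 0.1
        assert got == pytest.approx(4 * math.pi * 100 / 202 ** 2, rel=0.2)

    def test_square_close_to_pi_over_four(self):
        assert mm.circularity(np.ones((50, 50), bool)) == pytest.approx(
            math.pi / 4, rel=0.03)


class TestMorphologyNumber:
    def test_unit_disk_closed_form(self):
        assert mm.morphology_number(A=math.pi, S=1.0, E=1.0,
                                    Dmax=2.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [
        dict(A=0, S=1, E=1, Dmax=2),
        dict(A=1, S=0, E=1, Dmax=2),
        dict(A=1, S=1, E=0.5, Dmax=2),
        dict(A=1, S=1, E=1, Dmax=0),
    ])
    def test_non_positive_or_out_of_range_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            mm.morphology_number(**bad)

    def test_ordering_disk_pellet_filament_at_comparable_area(self):
        """Mo ranks morphologies: solid disk > hairy pellet > thin curved
        filament, at similar projected area."""
        rng = np.random.default_rng(9)
        disk = disk_mask(28)                              # ~2460 px
        pellet, _ = hairy_pellet_mask(core_radius=20, n_filaments=40,
                                      filament_length=20, filament_width=3,
                                      rng=rng)            # ~2500 px
        filament = sinusoid_filament_mask(arc_length=800, width_px=3,
                                          amplitude=60, wavelength=300)
        mos = [mm.measure_object(m, 1.0).Mo for m in (disk, pellet, filament)]
        assert mos[0] > mos[1] > mos[2]


class TestMeasureObject:
    def test_mo_equals_closed_form_of_own_descriptors(self):
        rng = np.random.default_rng(3)
        mask, _ = hairy_pellet_mask(30, 20, 25, 2, rng)
        rec = mm.measure_object(mask, 0.7)
        expected = 2 * math.sqrt(rec.A * min(rec.R, 1.0)) / (
            math.sqrt(math.pi) * rec.Dmax * rec.E)
        assert rec.Mo == pytest.approx(expected)

    def test_scale_equivariance_of_descriptors(self):
        mask = ellipse_mask(35, 20, 0.5)
        r1 = mm.measure_object(mask, 1.0)
        r2 = mm.measure_object(mask, 2.0)
        assert r2.A == pytest.approx(4 * r1.A)
        assert r2.D == pytest.approx(2 * r1.D)
        assert r2.Dmax == pytest.approx(2 * r1.Dmax)
        for attr in ("E", "R", "circularity", "Mo"):
            assert getattr(r2, attr) == pytest.approx(getattr(r1, attr))

    def test_rotation_invariance_of_shape_descriptors(self):
        mask = ellipse_mask(40, 18, 0.0)
        r1 = mm.measure_object(mask, 1.0)
        r2 = mm.measure_object(np.rot90(mask).copy(), 1.0)
        for attr in ("E", "R", "Mo"):
            assert getattr(r2, attr) == pytest.approx(
                getattr(r1, attr), rel=0.03)

    def test_centroid_outside_falls_back_to_dmax(self):
        # a thin C-shape: centroid lies in the empty middle
        mask = np.zeros((41, 41), bool)
        mask |= disk_mask(20)
        inner = np.zeros_like(mask)
        inner[3:38, 3:41] = disk_mask(20)[0:35, 0:38]
        mask[5:36, 8:41] = False
        mask[:, 25:] = False
        rec = mm.measure_object(mask, 1.0)
        if "centroid_outside" in rec.flags:
            assert rec.D == rec.Dmax

    def test_record_invariants_on_varied_shapes(self):
        rng = np.random.default_rng(21)
        masks = [disk_mask(15), ellipse_mask(25, 10, 0.8),
                 clump_mask(20, 4, 3, 0.1, rng),
                 hairy_pellet_mask(25, 15, 20, 2, rng)[0]]
        for mask in masks:
            rec = mm.measure_object(mask, 0.5)
            assert rec.A > 0 and rec.A <= rec.convex_area + 1e-9
            assert rec.E >= 1
            assert 0 < rec.R <= mm.CLIP_TOLERANCE
            assert 0 < rec.circularity <= mm.CLIP_TOLERANCE
            assert 0 < rec.Mo <= mm.CLIP_TOLERANCE
            assert rec.D <= rec.Dmax * 1.01
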