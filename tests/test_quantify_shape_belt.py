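import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.measure import regionprops
from skimage.transform import rotate

from prewetbelt.quantify import (
    belt_length_per_cell,
    eccentricity,
    perimeter_coverage,
    skeleton_length,
)
from prewetbelt.synth import generate_shape_fixtures


class TestEccentricity:
    def test_segment_is_degenerate_ellipse(self):
        mask = np.zeros((3, 66), bool)
        mask[1, 1:65] = True
        assert eccentricity(mask) == pytest.approx(1.0, abs=1e-6)

    def test_disc_is_circle(self):
        mask = np.zeros((210, 210), bool)
        rr, cc = draw_disk((105, 105), 100)
        mask[rr, cc] = True
        assert eccentricity(mask) <= 0.02

    def test_ellipse_closed_form(self):
        (mask, expected), = generate_shape_fixtures([("ellipse", 5, 3)])
        assert expected == pytest.approx(0.8)
        assert eccentricity(mask) == pytest.approx(0.8, abs=0.02)

    def test_matches_skimage_on_binary_regions(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            mask = np.zeros((60, 60), bool)
            rr, cc = draw_disk((30, 30), 12)
            mask[rr, cc] = True
            mask[rng.integers(18, 42, 30), rng.integers(18, 42, 30)] = True
            ours = eccentricity(mask)
            ref = regionprops(mask.astype(int))[0].eccentricity
            assert ours == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("angle", [15, 45, 77])
    def test_rotation_invariance_within_rasterization(self, angle):
        (mask, _), = generate_shape_fixtures([("ellipse", 20, 8)])
        e0 = eccentricity(mask > 0.5)
        rot = rotate((mask > 0.5).astype(float), angle, resize=True, order=0) > 0.5
        assert eccentricity(rot) == pytest.approx(e0, abs=0.02)

    def test_translation_invariance_exact(self):
        mask = np.zeros((40, 40), bool)
        mask[5:12, 5:25] = True
        shifted = np.roll(mask, (11, 7), axis=(0, 1))
        assert eccentricity(shifted) == pytest.approx(eccentricity(mask), abs=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            eccentricity(np.zeros((5, 5), bool))

    def test_pixel_correction_convention(self):
        # the unit-square pixel term makes a 1-px segment slightly sub-degenerate
        mask = np.zeros((3, 66), bool)
        mask[1, 1:65] = True
        e = eccentricity(mask, pixel_correction=True)
        assert e == pytest.approx(np.sqrt(1 - 1 / 64**2), abs=1e-9)


class TestSkeletonLength:
    def test_straight_line_pixel_count(self):
        mask = np.zeros((5, 52), bool)
        mask[2, 1:51] = True
        assert skeleton_length(mask, pixel_size=0.1) == pytest.approx(5.0)

    def test_empty_mask_zero(self):
        assert skeleton_length(np.zeros((10, 10), bool)) == 0.0

    def test_l_shaped_path_equals_pixel_audit(self):
        mask = np.zeros((30, 30), bool)
        mask[5, 5:25] = True
        mask[5:25, 24] = True
        skel_pixels = int(
            __import__("skimage.morphology", fromlist=["skeletonize"])
            .skeletonize(mask)
            .sum()
        )
        assert skeleton_length(mask, pixel_size=1.0) == pytest.approx(skel_pixels)

    def test_diagonal_weighting_on_45_degree_line(self):
        mask = np.zeros((40, 40), bool)
        for i in range(30):
            mask[i + 2, i + 2] = True
        assert skeleton_length(mask, weighting="sqrt2", skeletonize=False) == (
            pytest.approx(29 * np.sqrt(2))
        )

    def test_unknown_weighting_rejected(self):
        with pytest.raises(ValueError, match="weighting"):
            skeleton_length(np.ones((3, 3), bool), weighting="nope")


class TestBeltPerCellAndCoverage:
    def test_per_cell_division(self):
        mask = np.zeros((5, 52), bool)
        mask[2, 1:51] = True  # 5 um at 0.1 um/px
        assert belt_length_per_cell(mask, 1, 0.1) == pytest.approx(5.0)
        assert belt_length_per_cell(mask, 5, 0.1) == pytest.approx(1.0)

    def test_invalid_cell_count(self):
        with pytest.raises(ValueError):
            belt_length_per_cell(np.ones((4, 4), bool), 0)

    def test_coverage_trivials(self):
        assert perimeter_coverage(10.0, 10.0) == 100.0
        assert perimeter_coverage(0.0, 10.0) == 0.0

    def test_coverage_above_100_warns(self):
        with pytest.warns(UserWarning, match="exceeds"):
            assert perimeter_coverage(12.0, 10.0) == pytest.approx(120.0)

    def test_zero_perimeter_rejected(self):
        with pytest.raises(ValueError):
            perimeter_coverage(1.0, 0.0)

    def test_half_covered_square_perimeter(self):
        # a square cell outline, half of it traced by the belt
        n = 81
        perimeter = np.zeros((n + 2, n + 2), bool)
        perimeter[1, 1 : n + 1] = True
        perimeter[n, 1 : n + 1] = True
        perimeter[1 : n + 1, 1] = True
        perimeter[1 : n + 1, n] = True
        belt = np.zeros_like(perimeter)
        belt[1, 1 : n + 1] = True  # top side
        belt[1 : n + 1, 1] = True  # left side
        per_len = skeleton_length(perimeter, 1.0, skeletonize=False)
        belt_len = skeleton_length(belt, 1.0, skeletonize=False)
        assert perimeter_coverage(belt_len, per_len) == pytest.approx(50.0, abs=2.0)
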