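"""Descriptor measurements against analytic shapes and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import ndimage

from colonymorph import _geometry, morphometry as mm
from colonymorph.image import ImageMeta, LabeledColonyImage

from conftest import make_disk, random_blob


def square_mask(side: int, pad: int = 2) -> np.ndarray:
    m = np.zeros((side + 2 * pad, side + 2 * pad), bool)
    m[pad:pad + side, pad:pad + side] = True
    return m


class TestArea:
    def test_square_pixel_count(self):
        assert mm.region_area(square_mask(10)) == 100.0

    def test_disk_converges_to_analytic(self):
        area = mm.region_area(make_disk(100))
        assert area == pytest.approx(np.pi * 100 ** 2, rel=0.01)

    def test_pixel_size_scaling_is_quadratic(self):
        assert mm.region_area(square_mask(10), pixel_size=2.5) == 625.0

    def test_empty_mask_raises(self):
        with pytest.raises(mm.EmptyRegionError):
            mm.region_area(np.zeros((5, 5), bool))


class TestPerimeter:
    def test_square_corner_polygon(self):
        assert mm.region_perimeter(square_mask(10)) == 40.0

    def test_single_pixel_unit_square(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        assert mm.region_perimeter(m) == 4.0

    def test_rectangle_exact(self):
        m = np.zeros((20, 40), bool)
        m[3:10, 5:35] = True
        assert mm.region_perimeter(m) == 74.0

    def test_disk_converges_to_circumference(self):
        p = mm.region_perimeter(make_disk(200))
        assert p == pytest.approx(2 * np.pi * 200, rel=0.02)

    def test_linear_pixel_size_scaling(self):
        m = square_mask(10)
        assert mm.region_perimeter(m, 3.0) == 3.0 * mm.region_perimeter(m)

    def test_multiple_components_rejected(self):
        m = np.zeros((10, 10), bool)
        m[1, 1] = True
        m[5:8, 5:8] = True
        with pytest.raises(mm.MultiRegionError):
            mm.region_perimeter(m)

    def test_crofton_estimator_close_on_disk(self):
        p = mm.region_perimeter(make_disk(100), method="crofton")
        assert p == pytest.approx(2 * np.pi * 100, rel=0.05)


class TestEllipseAxes:
    def test_disk_axes_equal_diameter(self):
        major, minor = mm.ellipse_axes(make_disk(100))
        assert minor == pytest.approx(200.0, rel=0.01)
        assert major == pytest.approx(200.0, rel=0.01)

    def test_axis_aligned_ellipse_matches_construction(self):
        yy, xx = np.mgrid[:120, :120]
        mask = (((yy - 60 + 0.5) / 20) ** 2 + ((xx - 60 + 0.5) / 40) ** 2) <= 1
        major, minor = mm.ellipse_axes(mask)
        assert minor == pytest.approx(40.0, rel=0.02)
        assert major == pytest.approx(80.0, rel=0.02)

    def test_area_match_convention(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            mask = random_blob(rng)
            major, minor = mm.ellipse_axes(mask)
            assert np.pi / 4 * major * minor == pytest.approx(
                mm.region_area(mask), rel=1e-6)

    def test_collinear_region_flagged_degenerate(self):
        m = np.zeros((5, 9), bool)
        m[2, 2:7] = True
        with pytest.warns(UserWarning, match="degenerate"):
            major, minor = mm.ellipse_axes(m)
        assert minor == 0.0


class TestFeret:
    def test_rectangle_corner_convention(self):
        m = np.zeros((20, 40), bool)
        m[3:10, 5:35] = True  # 7 x 30 pixel rectangle
        feret, min_feret = mm.feret_diameters(m)
        assert feret == pytest.approx(np.hypot(7, 30))
        assert min_feret == pytest.approx(7.0)

    def test_single_pixel_diagonal(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        feret, min_feret = mm.feret_diameters(m)
        assert feret == pytest.approx(np.sqrt(2))
        assert min_feret == pytest.approx(1.0)

    def test_calipers_match_exhaustive_search_on_random_blobs(self):
        """Rotating calipers equals brute-force max pairwise hull distance."""
        rng = np.random.default_rng(123)
        for _ in range(50):
            mask = random_blob(rng, shape=(30, 45))
            hull = _geometry.convex_hull_points(mask)
            brute = 0.0
            for i in range(len(hull)):
                d = np.sqrt(((hull - hull[i]) ** 2).sum(axis=1)).max()
                brute = max(brute, float(d))
            assert _geometry.max_feret(hull) == pytest.approx(brute, abs=1e-12)

    def test_min_le_max(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            feret, min_feret = mm.feret_diameters(random_blob(rng))
            assert min_feret <= feret + 1e-12


class TestShapeFactor:
    def test_ideal_circle_values(self):
        assert mm.shape_factor(np.pi, 2 * np.pi) == pytest.approx(1.0)

    def test_unit_square(self):
        assert mm.shape_factor(1.0, 4.0) == pytest.approx(np.pi / 4)

    def test_fine_disk_close_to_one(self):
        d = make_disk(200)
        sf = mm.shape_factor(mm.region_area(d), mm.region_perimeter(d))
        assert 0.97 <= sf <= 1.03

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            mm.shape_factor(0.0, 4.0)
        with pytest.raises(ValueError):
            mm.shape_factor(1.0, -1.0)


def _toy_image(gap_rows: int = 0) -> LabeledColonyImage:
    """Footprint 20x20 with two 10x(10-gap) cells stacked vertically."""
    labels = np.zeros((24, 24), np.int32)
    footprint = np.zeros((24, 24), bool)
    footprint[2:22, 2:22] = True
    labels[2:12 - gap_rows, 2:22] = 1
    labels[12:22, 2:22] = 2
    return LabeledColonyImage(labels, footprint, 1.0, ImageMeta())


class TestAIS:
    def test_definitional_subtraction(self):
        img = _toy_image(gap_rows=2)
        # footprint 400 px, cells 400 - 2*20 px
        assert mm.colony_ais(img) == 40.0

    def test_tessellated_colony_has_zero(self):
        assert mm.colony_ais(_toy_image(0)) == 0.0

    def test_footprint_holes_count_toward_ais(self):
        labels = np.zeros((10, 10), np.int32)
        footprint = np.zeros((10, 10), bool)
        footprint[1:9, 1:9] = True
        footprint[4:6, 4:6] = False  # enclosed hole
        labels[1:9, 1:9] = 1
        labels[4:6, 4:6] = 0
        img = LabeledColonyImage(labels, footprint, 1.0, ImageMeta())
        assert mm.colony_ais(img) == 4.0

    def test_cell_outside_footprint_is_inconsistent(self):
        labels = np.zeros((8, 8), np.int32)
        footprint = np.zeros((8, 8), bool)
        footprint[2:6, 2:6] = True
        labels[2:6, 2:6] = 1
        img = LabeledColonyImage(labels, footprint, 1.0, ImageMeta())
        img.cell_labels[0, 0] = 1  # corrupt after validation
        with pytest.raises(mm.ConsistencyError):
            mm.colony_ais(img)


class TestMeasureImage:
    def test_record_cardinality(self):
        img = _toy_image(2)
        df = mm.measure_image(img)
        assert (df["unit"] == "cell").sum() == 2
        assert (df["unit"] == "colony").sum() == 1

    def test_colony_area_bounds_cell_areas(self, small_colony_image):
        df = mm.measure_image(small_colony_image)
        colony = df[df["unit"] == "colony"].iloc[0]
        assert colony["area"] >= df[df["unit"] == "cell"]["area"].sum()

    def test_metadata_propagated(self):
        img = _toy_image(1)
        img.meta.line = "X1"
        img.meta.phenotype = "bad"
        df = mm.measure_image(img)
        assert (df["line"] == "X1").all()
        assert (df["phenotype"] == "bad").all()

    def test_cell_holes_filled_before_measurement(self):
        labels = np.zeros((12, 12), np.int32)
        footprint = np.zeros((12, 12), bool)
        footprint[1:11, 1:11] = True
        labels[2:10, 2:10] = 1
        labels[5:7, 5:7] = 0  # hole inside the cell
        img = LabeledColonyImage(labels, footprint, 1.0, ImageMeta())
        df = mm.measure_image(img)
        cell = df[df["unit"] == "cell"].iloc[0]
        assert cell["area"] == 64.0  # hole filled


@settings(max_examples=40, deadline=None, derandomize=True)
@given(w=hst.integers(1, 25), h=hst.integers(1, 25))
def test_rectangle_conventions_hold_for_all_sizes(w, h):
    """Any w x h pixel rectangle measures exactly by the corner conventions."""
    m = np.zeros((h + 4, w + 4), bool)
    m[2:2 + h, 2:2 + w] = True
    assert mm.region_area(m) == w * h
    assert mm.region_perimeter(m) == 2 * (w + h)
    feret, min_feret = mm.feret_diameters(m)
    assert feret == pytest.approx(np.hypot(w, h))
    assert min_feret == pytest.approx(min(w, h))


class TestInvariances:
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_rot90_descriptors_identical(self, k):
        rng = np.random.default_rng(7)
        mask = random_blob(rng)
        rot = np.rot90(mask, k)
        assert mm.region_area(mask) == mm.region_area(rot)
        assert mm.region_perimeter(mask) == mm.region_perimeter(rot)
        f0 = mm.feret_diameters(mask)
        f1 = mm.feret_diameters(rot)
        assert f0 == pytest.approx(f1, abs=1e-9)
        a0 = mm.ellipse_axes(mask)
        a1 = mm.ellipse_axes(rot)
        assert a0 == pytest.approx(a1, abs=1e-9)

    def test_arbitrary_angle_rerasterization_within_3pct(self):
        """Descriptors of a re-rasterized rotated ellipse agree within 3%."""

        def raster_ellipse(a, b, angle, size=240):
            yy, xx = np.mgrid[:size, :size]
            y = yy - size / 2 + 0.5
            x = xx - size / 2 + 0.5
            c, s = np.cos(angle), np.sin(angle)
            u = c * x + s * y
            v = -s * x + c * y
            return (u / a) ** 2 + (v / b) ** 2 <= 1

        m0 = raster_ellipse(70, 35, 0.0)
        m1 = raster_ellipse(70, 35, 0.6)
        for op in (mm.region_area, mm.region_perimeter):
            assert op(m1) == pytest.approx(op(m0), rel=0.03)
        assert mm.feret_diameters(m1) == pytest.approx(
            mm.feret_diameters(m0), rel=0.03)
        assert mm.ellipse_axes(m1) == pytest.approx(
            mm.ellipse_axes(m0), rel=0.03)

    def test_scale_equivariance_exact(self):
        rng = np.random.default_rng(3)
        mask = random_blob(rng)
        s = 1.7
        assert mm.region_area(mask, s) == mm.region_area(mask) * s ** 2
        assert mm.region_perimeter(mask, s) == mm.region_perimeter(mask) * s
        f1, f2 = mm.feret_diameters(mask)
        g1, g2 = mm.feret_diameters(mask, s)
        assert (g1, g2) == pytest.approx((f1 * s, f2 * s), rel=1e-12)
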