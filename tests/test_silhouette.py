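"""Geometric primitives: segmentation, contour extraction, concavity, axes."""

import numpy as np
import pytest
from scipy.spatial.distance import directed_hausdorff

from conftest import depression_oracle, notched_square_contour, square_contour
from sporemorph import (
    SporeContour,
    SporeShapeParams,
    extract_contour,
    generate_contour,
    measure_axes,
    measure_mask,
    rasterize,
    segment_image,
    suprahilar_depression,
)
from sporemorph.synthesize import SporeMask, _build_polygon


def _regular_polygon(n=90, r=3.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


class TestSuprahilarDepression:
    def test_convex_polygon_scores_zero(self):
        assert suprahilar_depression(SporeContour(_regular_polygon())) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_notched_square_analytic_five_percent(self):
        # hull = 10x10 square (area 100), triangular notch area 5 -> 5.0%
        c = SporeContour(notched_square_contour(notch_area=5.0))
        assert suprahilar_depression(c) == pytest.approx(5.0, abs=1e-9)
        assert depression_oracle(c.vertices) == pytest.approx(5.0, abs=1e-9)

    def test_agrees_with_pixel_count_oracle(self):
        # fill the shape and its hull at 0.005 µm/px; depression from pixel
        # counts must agree with the polygon value within 0.1 absolute %
        from scipy.spatial import ConvexHull

        c = generate_contour(SporeShapeParams("ellipsoid", 12, 5, 0.4, 0, 0.05))
        poly_val = suprahilar_depression(c)
        hv = c.vertices[ConvexHull(c.vertices).vertices]
        # resample hull boundary to meet the vertex-count invariant
        hull_dense = np.vstack(
            [
                np.linspace(hv[i], hv[(i + 1) % len(hv)], 8, endpoint=False)
                for i in range(len(hv))
            ]
        )
        shape_px = rasterize(c, 0.005).pixels.sum()
        hull_px = rasterize(SporeContour(hull_dense), 0.005).pixels.sum()
        pixel_val = 100.0 * (hull_px - shape_px) / hull_px
        assert pixel_val == pytest.approx(poly_val, abs=0.1)

    @pytest.mark.parametrize("angle,shift,scale", [
        (30.0, (3.0, -2.0), 1.0),
        (117.0, (-40.0, 8.5), 0.2),
        (261.5, (0.0, 0.0), 12.0),
    ])
    def test_similarity_invariance(self, angle, shift, scale):
        c = SporeContour(notched_square_contour(4.0))
        ref = suprahilar_depression(c)
        th = np.radians(angle)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = SporeContour(scale * (c.vertices @ rot.T) + np.asarray(shift))
        assert suprahilar_depression(moved) == pytest.approx(ref, rel=1e-9)

    def test_deepening_notch_strictly_increases_depression(self):
        p = SporeShapeParams("ellipsoid", 12, 5, 0.3, 0, 0.05)
        vals = [
            suprahilar_depression(SporeContour(_build_polygon(p, d, 512)))
            for d in (0.2, 0.6, 1.0, 1.4)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_hull_never_smaller_than_shape(self):
        from shapely.geometry import Polygon

        for t in (0.0, 0.03):
            c = generate_contour(SporeShapeParams("ellipsoid", 12, 5, 0.3, 0, t))
            poly = Polygon(c.vertices)
            assert poly.convex_hull.area >= poly.area * (1 - 1e-12)
            assert (suprahilar_depression(c) < 1e-9) == (t == 0)


class TestMeasureAxes:
    def test_rectangle_feret_length_is_its_diagonal(self):
        # regression-pinned: max caliper of a 12 x 5 rectangle = 13
        verts = square_contour(1.0) * np.array([12.0, 5.0])
        L, W, _ = measure_axes(SporeContour(verts))
        assert L == pytest.approx(13.0, abs=1e-9)
        assert W == pytest.approx(120.0 / 13.0, abs=1e-9)  # extent ⊥ diagonal
        assert W <= 12.0

    def test_ellipse_roundtrip_recovers_axes(self):
        c = generate_contour(SporeShapeParams("ellipsoid", 12, 5, 0.0, 0, 0.0))
        g = measure_mask(rasterize(c, 0.02))
        assert g.L_um == pytest.approx(12.0, rel=0.01)
        assert g.W_um == pytest.approx(5.0, rel=0.01)

    def test_circle_length_equals_width(self):
        L, W, _ = measure_axes(SporeContour(_regular_polygon(256, 5.0)))
        assert L == pytest.approx(10.0, rel=0.01)
        assert W == pytest.approx(10.0, rel=0.01)

    def test_collinear_polygon_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 70), np.linspace(0, 2, 70)])
        with pytest.raises(ValueError, match="degenerate|simple|area"):
            measure_axes(SporeContour(line))


class TestSegmentImage:
    def _mask_image(self, bright_object=True):
        c = generate_contour(SporeShapeParams("ellipsoid", 12, 5, 0.3, 0, 0.0))
        mask = rasterize(c, 0.05)
        img = mask.pixels.astype(float)
        return mask, (img if bright_object else 1.0 - img)

    def test_binary_input_passes_through(self):
        mask, img = self._mask_image()
        seg = segment_image(img, 0.05)
        np.testing.assert_array_equal(seg.pixels, mask.pixels)

    def test_polarity_autodetected_for_dark_objects(self):
        mask, img = self._mask_image(bright_object=False)
        seg = segment_image(img, 0.05)
        np.testing.assert_array_equal(seg.pixels, mask.pixels)

    def test_salt_noise_changes_area_by_under_two_percent(self, rng):
        mask, img = self._mask_image()
        noisy = img.copy()
        flip = rng.random(img.shape) < 0.10
        noisy[flip] = 1.0 - noisy[flip]
        seg = segment_image(noisy, 0.05)
        assert seg.pixels.sum() == pytest.approx(mask.pixels.sum(), rel=0.02)

    def test_blank_image_errors(self):
        with pytest.raises(ValueError, match="no foreground"):
            segment_image(np.zeros((50, 50)), 0.05)

    def test_comparable_components_warn(self):
        img = np.zeros((60, 60))
        img[10:30, 10:30] = 1.0
        img[35:54, 35:54] = 1.0
        with pytest.warns(UserWarning, match="comparable"):
            segment_image(img, 0.05)


class TestExtractContour:
    def test_degenerate_blob_rejected(self):
        px = np.zeros((30, 30), dtype=bool)
        px[5:25, 10] = True  # 1-pixel-wide line, 20 px
        with pytest.raises(ValueError, match="minimum|component"):
            extract_contour(SporeMask(px, 0.1))

    def test_square_area_within_one_percent(self):
        mask = rasterize(SporeContour(square_contour(10.0)), 0.05)
        c = extract_contour(mask)
        assert c.area_um2 == pytest.approx(100.0, rel=0.01)

    def test_roundtrip_hausdorff_below_two_pixels(self):
        # dense source sampling so vertex-set Hausdorff approximates the
        # boundary-to-boundary distance
        src = generate_contour(SporeShapeParams("ellipsoid", 12, 5, 0.4, 0, 0.04),
                               resolution=4096)
        scale = 0.02
        out = extract_contour(rasterize(src, scale))
        d = max(
            directed_hausdorff(src.vertices, out.vertices)[0],
            directed_hausdorff(out.vertices, src.vertices)[0],
        )
        assert d < 2 * scale

    def test_multi_component_mask_rejected(self):
        px = np.zeros((40, 40), dtype=bool)
        px[2:15, 2:15] = True
        px[20:38, 20:38] = True
        with pytest.raises(ValueError, match="component"):
            extract_contour(SporeMask(px, 0.1))

    def test_convex_contour_depression_small_after_rasterization(self):
        c = generate_contour(SporeShapeParams("ellipsoid", 12, 5, 0.3, 0, 0.0))
        g = measure_mask(rasterize(c, 0.02))
        assert g.depression_pct <= 0.5
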