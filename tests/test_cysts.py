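"""Cyst shape metrics, protrusions, halves and curvature."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import circ_dist
from morphflow import cysts as cy
from morphflow import synth


def make_shape(seed=0, size=(256, 256), px=1.0, **genkw):
    spec = synth.GeneratorSpec(seed=seed, image_size=size, pixel_size=px)
    mask, truth = synth.gen_cyst_mask(spec, **genkw)
    return cy.CystShape.from_mask(mask, px), truth


class TestBinarize:
    def test_bright_ellipse_high_jaccard(self):
        spec = synth.GeneratorSpec(seed=13, image_size=(256, 256))
        mask, _ = synth.gen_cyst_mask(spec, axes=(60.0, 45.0))
        img = synth.render_mask_image(mask, spec)
        shape = cy.binarize_projection(img, 1.0)
        jac = (shape.mask & mask).sum() / (shape.mask | mask).sum()
        assert jac > 0.97

    def test_all_dark_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cy.binarize_projection(np.zeros((64, 64)))

    def test_larger_blob_retained(self):
        img = np.zeros((128, 128))
        img[10:20, 10:20] = 100.0       # 100 px
        img[50:90, 50:90] = 100.0       # 1600 px
        shape = cy.binarize_projection(img, 1.0)
        assert shape.mask[60, 60] and not shape.mask[15, 15]


class TestShapeMetrics:
    def test_circle_identities(self):
        shape, _ = make_shape(seed=0, size=(160, 160), axes=(50.0, 50.0))
        m = cy.shape_metrics(shape)
        assert m.aspect_ratio == pytest.approx(1.0, abs=0.02)
        assert m.roundness == pytest.approx(1.0, abs=0.02)
        assert m.shape_factor == pytest.approx(1.0, abs=0.02)
        assert m.area == pytest.approx(np.pi * 50**2, rel=0.02)
        assert m.perimeter == pytest.approx(2 * np.pi * 50, rel=0.02)

    def test_two_to_one_ellipse(self):
        shape, _ = make_shape(seed=0, size=(280, 280), axes=(100.0, 50.0))
        m = cy.shape_metrics(shape)
        assert m.aspect_ratio == pytest.approx(2.0, rel=0.02)
        assert m.roundness == pytest.approx(0.5, rel=0.02)

    def test_vertical_major_axis_is_90(self):
        shape, _ = make_shape(seed=0, size=(280, 280), axes=(100.0, 50.0),
                              orientation=90.0)
        m = cy.shape_metrics(shape)
        assert abs(m.orientation_angle - 90.0) < 1.0

    def test_scale_equivariance(self):
        # same physical shape sampled at 1 and 0.5 um/px
        m1 = cy.shape_metrics(make_shape(seed=11, size=(256, 256), px=1.0,
                                         axes=(60.0, 40.0), orientation=25.0)[0])
        m2 = cy.shape_metrics(make_shape(seed=11, size=(512, 512), px=0.5,
                                         axes=(60.0, 40.0), orientation=25.0)[0])
        assert m2.area == pytest.approx(m1.area, rel=0.02)
        assert m2.perimeter == pytest.approx(m1.perimeter, rel=0.02)
        assert m2.aspect_ratio == pytest.approx(m1.aspect_ratio, rel=0.02)
        assert m2.shape_factor == pytest.approx(m1.shape_factor, rel=0.02)

    def test_rotation_equivariance(self):
        from scipy.ndimage import rotate

        mask, _ = synth.gen_cyst_mask(
            synth.GeneratorSpec(seed=12, image_size=(300, 300)),
            axes=(60.0, 40.0), orientation=20.0)
        rot = rotate(mask.astype(float), 30, reshape=False, order=1) > 0.5
        m0 = cy.shape_metrics(cy.CystShape.from_mask(mask, 1.0))
        m1 = cy.shape_metrics(cy.CystShape.from_mask(rot, 1.0))
        assert circ_dist(m1.orientation_angle, m0.orientation_angle + 30.0) < 2.0
        assert m1.aspect_ratio == pytest.approx(m0.aspect_ratio, rel=0.02)


class TestProtrusionAngle:
    @pytest.mark.parametrize("tip,expected", [
        ((10.0, 0.0), 0.0),
        ((0.0, 10.0), 90.0),
        ((-10.0, 10.0), 135.0),
        ((-10.0, 0.0), 180.0),
        ((0.0, -10.0), 90.0),   # folded into [0, 180]
    ])
    def test_known_angles(self, tip, expected):
        assert cy.protrusion_angle((0.0, 0.0), tip) == pytest.approx(expected)

    def test_tip_at_centroid_rejected(self):
        with pytest.raises(ValueError):
            cy.protrusion_angle((1.0, 1.0), (1.0, 1.0))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-100, 100), st.floats(-100, 100))
    def test_fold_range(self, dx, dy):
        if dx == 0 and dy == 0:
            return
        a = cy.protrusion_angle((0.0, 0.0), (dx, dy))
        assert 0.0 <= a <= 180.0


class TestDetectProtrusions:
    def test_plain_ellipse_has_none(self):
        shape, _ = make_shape(seed=3, size=(280, 280), axes=(100.0, 50.0))
        assert len(cy.detect_protrusions(shape, prominence=5.0)) == 0

    def test_two_bumps_recovered(self):
        shape, _ = make_shape(seed=2, axes=(55.0, 55.0),
                              protrusions=[(30.0, 15.0, 8.0), (120.0, 15.0, 8.0)])
        ps = cy.detect_protrusions(shape, prominence=5.0)
        assert len(ps) == 2
        assert abs(ps.angles[0] - 30.0) < 5.0
        assert abs(ps.angles[1] - 120.0) < 5.0
        assert ps.method == "radial"

    def test_manual_tips_passed_through(self):
        shape, _ = make_shape(seed=2, axes=(55.0, 55.0))
        tips = [(shape.centroid[0] + 70, shape.centroid[1]),
                (shape.centroid[0], shape.centroid[1] + 70)]
        ps = cy.detect_protrusions(shape, tips=tips)
        assert ps.method == "manual"
        assert [p.angle for p in ps] == [
            cy.protrusion_angle(shape.centroid, t) for t in tips]


class TestProtrusionHistogram:
    def test_example_bins(self):
        h = cy.protrusion_histogram([75.0, 85.0, 175.0])
        assert h.counts[7] == 1 and h.counts[8] == 1 and h.counts[17] == 1
        assert h.n == 3

    def test_empty_flagged(self):
        h = cy.protrusion_histogram([])
        assert h.zero_count and h.counts.sum() == 0
        assert h.fraction_in_range == 0.0

    def test_exact_180_in_last_bin(self):
        h = cy.protrusion_histogram([180.0])
        assert h.counts[17] == 1

    def test_uniform_fraction(self):
        rng = np.random.default_rng(9)
        h = cy.protrusion_histogram(rng.uniform(0, 180, 1000))
        assert h.fraction_in_range == pytest.approx(40 / 180, abs=0.03)


class TestPercentTop:
    def _shape(self):
        return make_shape(seed=5, axes=(50.0, 50.0))[0]

    def test_three_up_one_down(self):
        shape = self._shape()
        cx, cyy = shape.centroid
        prot = [cy.Protrusion((cx + d[0], cyy + d[1]), 0.0, 1.0)
                for d in ((10, 5), (-5, 8), (0, 9), (3, -7))]
        top, bottom = cy.percent_protrusions_top(prot, shape)
        assert top == pytest.approx(75.0) and bottom == pytest.approx(25.0)

    def test_tie_goes_top(self):
        shape = self._shape()
        cx, cyy = shape.centroid
        prot = [cy.Protrusion((cx + 10, cyy), 0.0, 1.0)]
        assert cy.percent_protrusions_top(prot, shape) == (100.0, 0.0)

    def test_no_protrusions_rejected(self):
        with pytest.raises(ValueError):
            cy.percent_protrusions_top([], self._shape())


class TestSplit:
    def test_circle_halves_equal(self):
        shape, _ = make_shape(seed=4, size=(160, 160), axes=(50.0, 50.0))
        t, b = cy.split_top_bottom(shape)
        assert t.arc_length == pytest.approx(b.arc_length, rel=0.01)

    def test_translation_invariance(self):
        spec = synth.GeneratorSpec(seed=6, image_size=(300, 300))
        mask, _ = synth.gen_cyst_mask(spec, axes=(50.0, 40.0))
        shifted = np.roll(mask, 30, axis=0)
        t0, b0 = cy.split_top_bottom(cy.CystShape.from_mask(mask, 1.0))
        t1, b1 = cy.split_top_bottom(cy.CystShape.from_mask(shifted, 1.0))
        assert t1.arc_length == pytest.approx(t0.arc_length, rel=0.01)
        assert b1.arc_length == pytest.approx(b0.arc_length, rel=0.01)

    def test_top_ruffles_lengthen_top_arc(self):
        shape, _ = make_shape(seed=7, axes=(60.0, 50.0),
                              ruffle_amplitude_top=8.0, ruffle_amplitude_bottom=0.0)
        t, b = cy.split_top_bottom(shape)
        assert t.arc_length > b.arc_length


class TestCurvature:
    def test_circle_curvature_pointwise_analytic(self):
        # exact circle samples need no smoothing: kappa = 1/r everywhere
        phi = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        pts = np.column_stack([50 * np.cos(phi), 50 * np.sin(phi)])
        prof = cy.contour_curvature(pts, smoothing=0.0, closed=True)
        assert np.all(np.abs(prof.curvature - 0.02) < 0.03 * 0.02)

    def test_circle_curvature_from_mask(self):
        # rasterized 50 um circle: overall (mean) curvature within 3%
        shape, _ = make_shape(seed=0, size=(160, 160), axes=(50.0, 50.0))
        prof = cy.contour_curvature(shape.contour, closed=True)
        assert prof.mean == pytest.approx(0.02, rel=0.03)

    def test_straight_segment_zero(self):
        seg = np.column_stack([np.linspace(0, 100, 50), np.zeros(50)])
        prof = cy.contour_curvature(seg)
        assert prof.degenerate
        assert np.all(prof.curvature == 0)

    def test_sine_perturbed_circle_matches_dense_oracle(self):
        """Mean curvature of r = R + a sin(m phi) vs direct differential
        geometry on the dense analytic curve."""
        R, a, m = 60.0, 5.0, 7
        phi = np.linspace(0, 2 * np.pi, 20000, endpoint=False)
        r = R + a * np.sin(m * phi)
        # analytic polar curvature
        r1 = a * m * np.cos(m * phi)
        r2 = -a * m**2 * np.sin(m * phi)
        kappa = np.abs(r**2 + 2 * r1**2 - r * r2) / (r**2 + r1**2) ** 1.5
        ds = np.sqrt(r**2 + r1**2)
        oracle = float(np.sum(kappa * ds) / np.sum(ds))

        # rasterize the sine-perturbed circle directly
        from skimage.draw import polygon as sk_polygon
        xs = 150 + r * np.cos(phi)
        ys = 150 + r * np.sin(phi)
        rows = (300 - 1) - ys
        mask = np.zeros((300, 300), bool)
        rr, cc = sk_polygon(rows[::20], xs[::20], shape=(300, 300))
        mask[rr, cc] = True
        shape = cy.CystShape.from_mask(mask, 1.0)
        prof = cy.contour_curvature(shape.contour, closed=True)
        assert prof.mean == pytest.approx(oracle, rel=0.05)

    def test_scale_equivariance_of_curvature(self):
        s1, _ = make_shape(seed=8, size=(160, 160), px=1.0, axes=(50.0, 50.0))
        s2, _ = make_shape(seed=8, size=(320, 320), px=0.5, axes=(50.0, 50.0))
        p1 = cy.contour_curvature(s1.contour, closed=True)
        p2 = cy.contour_curvature(s2.contour, closed=True)
        assert p2.mean == pytest.approx(p1.mean, rel=0.02)


class TestCurvatureRatio:
    def test_circle_ratio_one(self):
        shape, _ = make_shape(seed=4, size=(160, 160), axes=(50.0, 50.0))
        t, b = cy.split_top_bottom(shape)
        ratio = cy.curvature_ratio(cy.half_curvature(t), cy.half_curvature(b))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_top_ruffling_raises_ratio(self):
        shape, _ = make_shape(seed=100, axes=(60.0, 50.0),
                              ruffle_amplitude_top=8.0, ruffle_amplitude_bottom=0.0)
        t, b = cy.split_top_bottom(shape)
        assert cy.curvature_ratio(cy.half_curvature(t), cy.half_curvature(b)) > 1.3

    def test_swapping_gives_reciprocal(self):
        shape, _ = make_shape(seed=7, axes=(60.0, 50.0),
                              ruffle_amplitude_top=6.0, ruffle_amplitude_bottom=2.0)
        t, b = cy.split_top_bottom(shape)
        pt, pb = cy.half_curvature(t), cy.half_curvature(b)
        assert cy.curvature_ratio(pt, pb) * cy.curvature_ratio(pb, pt) == pytest.approx(1.0)

    def test_flat_bottom_undefined(self):
        flat = cy.CurvatureProfile(np.arange(5.0), np.zeros(5), 1.0)
        bumpy = cy.CurvatureProfile(np.arange(5.0), np.full(5, 0.1), 1.0)
        assert np.isnan(cy.curvature_ratio(bumpy, flat))
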