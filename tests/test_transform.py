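"""Geometric transforms, warping, rescaling, and Hough transforms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from microimage import (
    DegenerateGeometryError,
    ParameterError,
    SingularTransformError,
    compose,
    draw_circle_perimeter,
    estimate_transform,
    gaussian_filter,
    hough_circle,
    hough_line,
    identity_transform,
    paint,
    projective_transform,
    similarity_transform,
    translation_transform,
    warp,
    rescale,
)

finite = st.floats(-50, 50, allow_nan=False)


class TestApplyComposeInverse:
    def test_identity(self):
        pts = np.array([[1.0, 2.0], [-3.0, 4.5]])
        np.testing.assert_array_equal(identity_transform()(pts), pts)

    def test_translation(self):
        t = translation_transform(3.0, -2.0)
        np.testing.assert_allclose(t([[0.0, 0.0]]), [[3.0, -2.0]])

    def test_perspective_division(self):
        m = np.array([[1, 0, 0], [0, 1, 0], [0.001, 0, 1.0]])
        t = projective_transform(m)
        np.testing.assert_allclose(t([[100.0, 0.0]]), [[100 / 1.1, 0.0]])

    def test_point_at_infinity_raises(self):
        m = np.array([[1, 0, 0], [0, 1, 0], [-0.01, 0, 1.0]])
        with pytest.raises(SingularTransformError):
            projective_transform(m)([[100.0, 0.0]])

    @given(finite, finite, finite, finite)
    def test_translation_composition(self, a, b, c, d):
        lhs = compose(translation_transform(a, b), translation_transform(c, d))
        np.testing.assert_allclose(
            lhs.matrix, translation_transform(a + c, b + d).matrix, atol=1e-9
        )

    def test_compose_then_inverse_is_identity(self):
        t = similarity_transform(scale=1.7, rotation=0.3, translation=(4, -1))
        np.testing.assert_allclose(
            compose(t, t.inverse).matrix, np.eye(3), atol=1e-9
        )

    def test_compose_order_is_a_then_b(self):
        scale = similarity_transform(scale=2.0)
        shift = translation_transform(1.0, 0.0)
        # scale first, then shift: origin -> origin -> (1, 0)
        np.testing.assert_allclose(compose(scale, shift)([[0.0, 0.0]]), [[1.0, 0.0]])
        # (1,0): scale -> (2,0), shift -> (3,0)
        np.testing.assert_allclose(compose(scale, shift)([[1.0, 0.0]]), [[3.0, 0.0]])

    def test_kind_lattice(self):
        s = similarity_transform(rotation=0.1)
        p = projective_transform(np.eye(3))
        assert compose(s, p).kind == "projective"
        assert compose(s, s).kind == "similarity"

    def test_singular_matrix_rejected(self):
        with pytest.raises(SingularTransformError):
            projective_transform(np.zeros((3, 3)))


class TestEstimateTransform:
    def test_src_equals_dst_gives_identity(self):
        # note: the 4th point must not be collinear with any pair
        pts = np.array([[0.0, 0.0], [10, 0], [0, 10], [6, 3]])
        for kind in ("similarity", "affine", "projective"):
            est = estimate_transform(kind, pts, pts)
            np.testing.assert_allclose(est.matrix, np.eye(3), atol=1e-9)

    def test_known_projective_recovered_from_unit_square(self):
        m = np.array([[1.2, 0.1, 3.0], [-0.05, 0.9, -2.0], [2e-3, -1e-3, 1.0]])
        t = projective_transform(m)
        src = np.array([[0.0, 0.0], [1, 0], [0, 1], [1, 1]])
        est = estimate_transform("projective", src, t(src))
        np.testing.assert_allclose(est.matrix, m, atol=1e-8)

    @pytest.mark.parametrize("kind", ["similarity", "affine", "projective"])
    def test_exact_correspondences_reproduced(self, kind, rng):
        for _ in range(20):
            if kind == "similarity":
                t = similarity_transform(
                    scale=rng.uniform(0.5, 2),
                    rotation=rng.uniform(-np.pi, np.pi),
                    translation=rng.uniform(-50, 50, 2),
                )
            elif kind == "affine":
                m = np.eye(3)
                m[:2, :2] = rng.uniform(-1.5, 1.5, (2, 2)) + 2 * np.eye(2)
                m[:2, 2] = rng.uniform(-50, 50, 2)
                t = projective_transform(m)
            else:
                m = np.eye(3)
                m[:2, :2] = rng.uniform(-1, 1, (2, 2)) + 2 * np.eye(2)
                m[:2, 2] = rng.uniform(-50, 50, 2)
                m[2, :2] = rng.uniform(-1e-3, 1e-3, 2)
                t = projective_transform(m)
            src = rng.uniform(0, 200, (30, 2))
            dst = t(src)
            est = estimate_transform(kind, src, dst)
            assert np.abs(est(src) - dst).max() < 1e-8

    def test_noisy_similarity_rotation_recovered(self, rng):
        truth = similarity_transform(scale=1.2, rotation=0.7, translation=(10, -4))
        src = rng.uniform(0, 100, (50, 2))
        dst = truth(src) + rng.normal(0, 0.1, (50, 2))
        est = estimate_transform("similarity", src, dst)
        rot = np.arctan2(est.matrix[1, 0], est.matrix[0, 0])
        assert abs(rot - 0.7) < 0.01

    def test_collinear_points_degenerate(self):
        src = np.array([[0.0, 0.0], [1, 1], [2, 2], [3, 3]])
        with pytest.raises(DegenerateGeometryError):
            estimate_transform("projective", src, src * 2)
        with pytest.raises(DegenerateGeometryError):
            estimate_transform("affine", src[:3], src[:3] * 2)

    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            estimate_transform("projective", np.zeros((3, 2)), np.zeros((3, 2)))

    def test_matches_reference_estimator(self):
        from skimage.transform import ProjectiveTransform

        rng = np.random.default_rng(5)
        m = np.array([[1.1, 0.05, 20], [0.02, 0.95, -10], [1e-4, 5e-5, 1.0]])
        src = rng.uniform(0, 200, (12, 2))
        dst = projective_transform(m)(src)
        ours = estimate_transform("projective", src, dst).matrix
        if hasattr(ProjectiveTransform, "from_estimate"):
            ref = ProjectiveTransform.from_estimate(src, dst)
        else:  # older releases
            ref = ProjectiveTransform()
            ref.estimate(src, dst)
        np.testing.assert_allclose(ours, ref.params / ref.params[2, 2], atol=1e-7)


class TestWarpRescale:
    def test_identity_is_bit_exact(self, rng):
        img = rng.random((30, 40))
        np.testing.assert_array_equal(warp(img, identity_transform()), img)

    def test_integer_translation_shifts_and_fills(self, rng):
        img = rng.random((20, 20))
        # output pixel (r, c) samples input at (c - 5, r - 3) -> shift by (+5, +3)
        inv = translation_transform(-5.0, -3.0)
        out = warp(img, inv, cval=-1.0)
        np.testing.assert_array_equal(out[3:, 5:], img[:-3, :-5])
        assert (out[:3, :] == -1.0).all()
        assert (out[:, :5] == -1.0).all()

    def test_warp_then_inverse_warp_close(self, rng):
        img = gaussian_filter(rng.random((60, 60)), 2.0)
        t = similarity_transform(scale=1.1, rotation=0.15, translation=(2, -1))
        there = warp(img, t.inverse, cval=0.0)
        back = warp(there, t, cval=0.0)
        interior = np.s_[15:45, 15:45]
        assert np.abs(back[interior] - img[interior]).max() < 0.02

    def test_constant_image_conserved(self):
        img = np.full((25, 25), 0.33)
        t = similarity_transform(rotation=0.2, translation=(1.5, 0.5))
        out = warp(img, t, cval=0.33)
        np.testing.assert_allclose(out, 0.33, atol=1e-12)

    def test_rescale_factor_one_identity(self, rng):
        img = rng.random((16, 16))
        np.testing.assert_array_equal(rescale(img, 1.0), img)

    def test_rescale_quarter_shape(self):
        assert rescale(np.zeros((100, 100)), 0.25).shape == (25, 25)

    def test_rescale_constant_stays_constant(self):
        img = np.full((40, 40), 0.5)
        for factor in (0.25, 0.5, 2.0):
            np.testing.assert_allclose(rescale(img, factor), 0.5, atol=1e-9)

    def test_rescale_invalid_factor(self):
        with pytest.raises(ParameterError):
            rescale(np.zeros((10, 10)), 0.0)


class TestHoughLine:
    def test_empty_image_zero_accumulator(self):
        res = hough_line(np.zeros((20, 20), bool))
        assert res.accumulator.sum() == 0
        assert res.peaks == []

    def test_single_column_peak(self):
        img = np.zeros((100, 60), bool)
        img[:, 30] = True
        res = hough_line(img)
        count, theta, rho = res.peaks[0]
        assert count == 100
        assert abs(theta) < 1e-9
        assert rho == 30

    def test_row_and_column_give_two_peaks(self):
        img = np.zeros((50, 50), bool)
        img[10, :] = True
        img[:, 35] = True
        res = hough_line(img)
        assert len(res.peaks) == 2
        found = {(round(th, 4), rho) for _, th, rho in res.peaks}
        assert (0.0, 35.0) in found
        assert (round(-np.pi / 2, 4), -10.0) in found

    def test_votes_conserved(self, rng):
        img = rng.random((40, 40)) > 0.9
        res = hough_line(img)
        assert res.accumulator.sum() == img.sum() * len(res.thetas)


class TestHoughCircle:
    def test_drawn_circle_recovered_exactly(self):
        img = np.zeros((100, 120), bool)
        paint(img, draw_circle_perimeter(50, 60, 20), True)
        res = hough_circle(img, np.arange(15, 26))
        count, r, c, radius = res.peaks[0]
        assert (r, c, radius) == (50, 60, 20)
        rr, _ = draw_circle_perimeter(0, 0, 20)
        assert count == len(rr)  # every perimeter pixel votes for the center

    def test_empty_image_no_peaks(self):
        res = hough_circle(np.zeros((30, 30), bool), [5, 6])
        assert res.peaks == []
        assert res.accumulators.shape == (2, 30, 30)

    def test_two_disjoint_circles(self):
        img = np.zeros((90, 90), bool)
        paint(img, draw_circle_perimeter(25, 25, 10), True)
        paint(img, draw_circle_perimeter(60, 62, 14), True)
        res = hough_circle(img, np.arange(8, 17))
        top = {(r, c, radius) for _, r, c, radius in res.peaks[:2]}
        assert (25, 25, 10) in top
        assert (60, 62, 14) in top

    def test_invalid_radius(self):
        with pytest.raises(ParameterError):
            hough_circle(np.zeros((10, 10), bool), [0])
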