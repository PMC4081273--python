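"""Linear/rank filtering, edge detection, and local thresholding."""

import numpy as np
import pytest

from microimage import (
    ContractViolationError,
    ParameterError,
    ShapeError,
    canny,
    difference_of_gaussians,
    gaussian_filter,
    median_filter,
    sobel,
    threshold_adaptive,
)


class TestGaussian:
    def test_constant_preserved(self):
        img = np.full((20, 20), 0.4)
        np.testing.assert_allclose(gaussian_filter(img, 2.0), 0.4, atol=1e-12)

    def test_impulse_mass_conserved(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = gaussian_filter(img, 1.0)
        assert abs(out.sum() - 1.0) < 1e-6
        assert out.argmax() == 16 * 33 + 16

    def test_mean_conserved_by_reflect_boundary(self, rng):
        img = rng.random((40, 40))
        assert abs(gaussian_filter(img, 3.0).mean() - img.mean()) < 1e-6

    def test_sigma_zero_is_identity(self, rng):
        img = rng.random((10, 10))
        np.testing.assert_array_equal(gaussian_filter(img, 0.0), img)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ParameterError):
            gaussian_filter(np.zeros((4, 4)), -1.0)

    def test_commutes_with_transposition(self, rng):
        img = rng.random((30, 30))
        np.testing.assert_allclose(
            gaussian_filter(img.T, 1.5), gaussian_filter(img, 1.5).T, atol=1e-12
        )


class TestSobel:
    def test_constant_is_zero(self):
        assert sobel(np.full((10, 10), 0.7)).max() < 1e-12

    def test_vertical_step_localized(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 0.5
        out = sobel(img)
        # maximal response on the two columns astride the step
        assert set(np.argwhere(out == out.max())[:, 1]) == {9, 10}
        assert out[:, :8].max() == 0.0
        assert out[:, 12:].max() == 0.0

    def test_offset_invariance(self, rng):
        img = rng.random((15, 15)) * 0.5
        np.testing.assert_allclose(sobel(img), sobel(img + 0.5), atol=1e-12)

    def test_multichannel_rejected(self):
        with pytest.raises(ShapeError):
            sobel(np.zeros((5, 5, 3)))


class TestMedian:
    def test_uint8_only(self):
        with pytest.raises(ContractViolationError):
            median_filter(np.zeros((5, 5)), 1)

    def test_constant_unchanged(self):
        img = np.full((10, 10), 37, np.uint8)
        assert (median_filter(img, 2) == 37).all()

    def test_salt_pixel_removed(self):
        img = np.full((9, 9), 10, np.uint8)
        img[4, 4] = 255
        assert (median_filter(img, 1) == 10).all()

    def test_straight_structures_survive_where_gaussian_blurs(self):
        # the classic denoising contrast: the median keeps straight
        # structures sharp where a Gaussian smears them
        from scipy import ndimage as ndi

        img = np.zeros((15, 15), np.uint8)
        img[7:9, :] = 200  # straight bar, 2 px wide
        med = median_filter(img, 1)
        assert (med[7:9, 1:-1] == 200).all()  # bar intact
        assert (med[:6] == 0).all() and (med[10:] == 0).all()  # no bleeding
        gauss = ndi.gaussian_filter(img.astype(float), 1.0)
        assert gauss[7:9, 7].max() < 200  # the Gaussian dims the bar
        assert gauss[5, 7] > 0  # ... and bleeds it outward

    def test_matches_scipy_reference(self, rng):
        from scipy import ndimage as ndi

        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        ours = median_filter(img, 1)
        ref = ndi.median_filter(img, size=3, mode="reflect")
        np.testing.assert_array_equal(ours, ref)

    def test_idempotent_on_piecewise_constant(self):
        img = np.zeros((12, 12), np.uint8)
        img[:, 6:] = 100
        once = median_filter(img, 1)
        np.testing.assert_array_equal(median_filter(once, 1), once)


class TestDifferenceOfGaussians:
    def test_constant_cancels(self):
        out = difference_of_gaussians(np.full((20, 20), 0.6), 1.0, 3.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_zero_mean(self, rng):
        out = difference_of_gaussians(rng.random((40, 40)), 1.0, 4.0)
        assert abs(out.mean()) < 1e-3

    def test_center_surround_structure(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = difference_of_gaussians(img, 1.0, 3.0)
        assert out[20, 20] > 0  # excitatory center
        assert out[20, 24] < 0  # inhibitory surround near 2 * low_sigma

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ParameterError):
            difference_of_gaussians(np.zeros((5, 5)), 2.0, 1.0)


class TestCanny:
    def test_constant_has_no_edges(self):
        assert not canny(np.full((30, 30), 0.5), sigma=1.0).any()

    def test_output_is_binary(self, square_scene):
        image, _ = square_scene
        edges = canny(image, sigma=1.0, low_threshold=0.4, high_threshold=1.0)
        assert edges.dtype == bool

    def test_square_contour_localized(self, square_scene):
        image, boundary = square_scene
        edges = canny(image, sigma=1.0, low_threshold=0.4, high_threshold=1.0)
        detected = np.argwhere(edges)
        assert len(detected)
        d = np.sqrt(
            ((detected[:, None, :] - boundary[None, :, :]) ** 2).sum(-1)
        ).min(axis=1)
        assert (d <= 1.0).mean() >= 0.95

    def test_edges_thin_across_gradient(self, square_scene):
        image, _ = square_scene
        edges = canny(image, sigma=1.0, low_threshold=0.4, high_threshold=1.0)
        # along any row crossing the square's vertical edges, each crossing
        # is at most 2 px wide (1 px up to NMS tie at the step midpoint)
        row = edges[50, :40]
        assert row.sum() <= 2

    def test_hysteresis_drops_isolated_weak_contour(self):
        # strong square plus a separate low-contrast blob whose response
        # sits between the thresholds: the weak contour must vanish
        image = np.full((100, 100), 0.2)
        image[20:45, 20:45] = 0.9
        image[65:85, 65:85] = 0.34
        edges = canny(image, sigma=1.0, low_threshold=0.2, high_threshold=0.9)
        assert edges[:55, :55].any()  # strong contour present
        assert not edges[58:, 58:].any()  # weak-only contour absent

    def test_edge_set_shrinks_with_high_threshold(self, square_scene):
        image, _ = square_scene
        prev = None
        for high in (0.6, 1.0, 1.4):
            edges = canny(image, sigma=1.0, low_threshold=0.3, high_threshold=high)
            if prev is not None:
                assert edges.sum() <= prev
            prev = edges.sum()

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ParameterError):
            canny(np.zeros((10, 10)), sigma=1.0, low_threshold=0.5, high_threshold=0.1)

    def test_agrees_with_reference_detector(self, square_scene):
        from skimage import feature as sk_feature

        image, _ = square_scene
        ours = np.argwhere(
            canny(image, sigma=1.0, low_threshold=0.4, high_threshold=1.0)
        )
        ref = np.argwhere(
            sk_feature.canny(image, sigma=1.0, low_threshold=0.4, high_threshold=1.0)
        )
        d = np.sqrt(((ours[:, None] - ref[None]) ** 2).sum(-1)).min(axis=1)
        assert (d <= 1.5).mean() >= 0.9


class TestThresholdAdaptive:
    def test_constant_image_offset_sign(self):
        img = np.full((20, 20), 0.5)
        assert threshold_adaptive(img, block_size=9, offset=0.1).all()
        assert not threshold_adaptive(img, block_size=9, offset=0.0).any()
        assert not threshold_adaptive(img, block_size=9, offset=-0.1).any()

    def test_disk_on_flat_field(self):
        img = np.full((80, 80), 0.2)
        yy, xx = np.mgrid[0:80, 0:80]
        disk = np.hypot(yy - 40, xx - 40) <= 12
        img[disk] = 0.8
        # small negative offset keeps the flat background robustly False
        bw = threshold_adaptive(img, block_size=61, offset=-0.01)
        # detected set is a superset of the disk, within 2 px of its rim
        assert bw[disk].all()
        far = np.hypot(yy - 40, xx - 40) > 14
        assert not bw[far].any()
        # agrees with a global-mean oracle here (flat illumination)
        global_oracle = img > img.mean() + 0.01
        assert (bw[disk] == global_oracle[disk]).all()

    def test_adaptivity_beats_global_threshold_on_ramp(self):
        # linear illumination gradient + small bright blobs at both ends
        cols = np.linspace(0.1, 0.7, 120)
        img = np.tile(cols, (60, 1))
        img[28:32, 10:14] += 0.2
        img[28:32, 106:110] += 0.2
        img = np.clip(img, 0, 1)
        bw = threshold_adaptive(img, block_size=31, offset=0.05)
        assert bw[29:31, 11:13].all()  # dim-end blob found
        assert bw[29:31, 107:109].all()  # bright-end blob found
        global_bw = img > img.mean()
        assert not global_bw[29:31, 11:13].any()  # global threshold misses it

    def test_even_block_size_rejected(self):
        with pytest.raises(ParameterError):
            threshold_adaptive(np.zeros((10, 10)), block_size=8)
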