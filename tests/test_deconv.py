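import numpy as np
import pytest

from cliquant.csf_mc import CSFKernel
from cliquant.deconv import (
    DepthWeights,
    RadianceImage,
    convolve_kernel,
    depth_weights,
    reconvolve_roi,
    rl_deconvolve,
    weighted_deconvolution,
)
from cliquant.geometry import DepthMap


def _unit_gaussian(sigma_px=2.0, n=15, px=0.5, depth=4.0):
    c = (n - 1) / 2.0
    ii, jj = np.indices((n, n))
    g = np.exp(-((ii - c) ** 2 + (jj - c) ** 2) / (2 * sigma_px ** 2))
    return CSFKernel(g / g.sum(), px, depth, "unit-integral")


def _unit_delta(n=11, px=0.5, depth=4.0):
    g = np.zeros((n, n))
    g[n // 2, n // 2] = 1.0
    return CSFKernel(g, px, depth, "unit-integral")


def _depth_map(depths, px=0.5):
    d = np.array(depths, float)
    return DepthMap(depth_mm=d, mask=~np.isnan(d), pixel_size_mm=px)


def test_depth_weights_normalized_and_counted():
    dm = _depth_map([[2.0, 2.0, np.nan], [6.0, np.nan, np.nan]])
    csf = {2.0: _unit_delta(depth=2.0), 6.0: _unit_delta(depth=6.0)}
    w = depth_weights(dm, csf)
    assert w.weights.sum() == pytest.approx(1.0)
    # delta kernels have identical intensity factors: weights follow counts
    assert dict(zip(w.depths_mm, w.weights))[2.0] == pytest.approx(2.0 / 3.0)


def test_depth_weights_nearest_assignment():
    dm = _depth_map([[2.4, np.nan], [5.6, np.nan]])
    csf = {2.0: _unit_delta(depth=2.0), 6.0: _unit_delta(depth=6.0)}
    w = depth_weights(dm, csf)
    assert dict(zip(w.depths_mm, w.weights))[2.0] == pytest.approx(0.5)


def test_depth_weights_validation():
    with pytest.raises(ValueError):
        DepthWeights(np.array([2.0, 4.0]), np.array([0.6, 0.6]))
    with pytest.raises(ValueError):
        DepthWeights(np.array([2.0]), np.array([-1.0]))
    dm = _depth_map([[np.nan]])
    with pytest.raises(ValueError):
        depth_weights(dm, {2.0: _unit_delta()})


def test_rl_delta_kernel_identity():
    rng = np.random.default_rng(0)
    img = rng.random((20, 20)) + 0.1
    out = rl_deconvolve(img, _unit_delta(), iterations=5)
    np.testing.assert_allclose(out, img, rtol=1e-10)


def test_rl_flat_image_fixed_point():
    img = np.full((30, 30), 7.0)
    out = rl_deconvolve(img, _unit_gaussian(), iterations=10)
    np.testing.assert_allclose(out, img, rtol=1e-6)


def test_rl_nonnegative_and_sharpens():
    img = np.zeros((41, 41))
    img[20, 20] = 100.0
    blurred = convolve_kernel(img, _unit_gaussian())
    out = rl_deconvolve(blurred, _unit_gaussian(), iterations=30)
    assert np.all(out >= 0)
    # deconvolution concentrates flux back toward the center
    assert out[20, 20] > 2.0 * blurred[20, 20]
    assert out.sum() == pytest.approx(blurred.sum(), rel=1e-3)


def test_rl_mask_excludes_unobserved():
    rng = np.random.default_rng(4)
    img = rng.random((30, 30)) + 1.0
    mask = np.ones_like(img)
    mask[:, 15:] = 0.0
    corrupted = img.copy()
    corrupted[:, 15:] = 1000.0  # garbage in the unobserved half
    a = rl_deconvolve(img, _unit_gaussian(), mask, iterations=10)
    b = rl_deconvolve(corrupted, _unit_gaussian(), mask, iterations=10)
    # observed-region result is independent of unobserved values
    np.testing.assert_allclose(b[:, :15], a[:, :15], rtol=1e-12)


def test_rl_requires_unit_kernel():
    bad = CSFKernel(np.ones((5, 5)), 0.5, 2.0, "counts")
    with pytest.raises(ValueError):
        rl_deconvolve(np.ones((10, 10)), bad)


def test_convolution_mass_conservation():
    rng = np.random.default_rng(1)
    img = np.zeros((61, 61))
    img[25:35, 25:35] = rng.random((10, 10))
    out = convolve_kernel(img, _unit_gaussian())
    assert out.sum() == pytest.approx(img.sum(), rel=1e-9)


def test_weighted_deconvolution_permutation_invariant():
    rng = np.random.default_rng(2)
    img = rng.random((25, 25)) + 0.5
    csf = {2.0: _unit_gaussian(1.5, depth=2.0), 6.0: _unit_gaussian(3.0, depth=6.0)}
    w1 = DepthWeights(np.array([2.0, 6.0]), np.array([0.3, 0.7]))
    w2 = DepthWeights(np.array([6.0, 2.0]), np.array([0.7, 0.3]))
    a = weighted_deconvolution(img, csf, w1, iterations=5)
    b = weighted_deconvolution(img, csf, w2, iterations=5)
    np.testing.assert_allclose(a, b, rtol=1e-12)


def test_weighted_deconvolution_missing_kernel_errors():
    img = np.ones((10, 10))
    csf = {2.0: _unit_gaussian(depth=2.0)}
    w = DepthWeights(np.array([2.0, 6.0]), np.array([0.5, 0.5]))
    with pytest.raises(ValueError, match="6"):
        weighted_deconvolution(img, csf, w)


def test_weighted_deconvolution_mixed_pixel_size_errors():
    img = np.ones((10, 10))
    csf = {2.0: _unit_gaussian(px=0.5, depth=2.0),
           6.0: _unit_gaussian(px=0.4, depth=6.0)}
    w = DepthWeights(np.array([2.0, 6.0]), np.array([0.5, 0.5]))
    with pytest.raises(ValueError, match="pixel"):
        weighted_deconvolution(img, csf, w)


def test_reconvolve_roi_masks_then_blurs():
    img = np.zeros((31, 31))
    img[10, 10] = 4.0   # inside ROI
    img[20, 20] = 9.0   # outside ROI
    roi = np.zeros_like(img, bool)
    roi[8:13, 8:13] = True
    csf = {4.0: _unit_gaussian(depth=4.0)}
    w = DepthWeights(np.array([4.0]), np.array([1.0]))
    out = reconvolve_roi(img, roi, csf, w)
    assert out.sum() == pytest.approx(4.0, rel=1e-6)


def test_radiance_image_round_trip(tmp_path):
    img = RadianceImage(np.random.default_rng(3).random((8, 9)), 0.554,
                        exposure_s=300.0, binning=8)
    p = tmp_path / "img.tif"
    img.to_tiff(p)
    back = RadianceImage.from_tiff(p)
    np.testing.assert_allclose(back.values, img.values, rtol=1e-6)
    assert back.pixel_size_mm == pytest.approx(0.554)
    assert back.exposure_s == 300.0
    assert back.binning == 8


def test_radiance_image_validation():
    with pytest.raises(ValueError):
        RadianceImage(np.zeros((3, 3, 3)), 0.5)
    with pytest.raises(ValueError):
        RadianceImage(np.zeros((3, 3)), -1.0)
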