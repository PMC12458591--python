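"""Depth-weighted, mask-weighted Richardson-Lucy deconvolution.

The planar Cherenkov image is deconvolved independently against the spread
function of every source depth represented in the ROI; the results are
averaged with weights proportional to (number of ROI voxels at that depth)
x (kernel intensity factor).  Pixels outside the animal photograph mask are
treated as unobserved in the RL data term.  The reconvolution step masks
the deconvolved image to the ROI projection and blurs it back with the same
weighted kernel set, returning to the physical image space in which the
depth calibration was measured.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .csf_mc import CSFKernel, fwhm_integral_intensity, peak_intensity
from .geometry import DepthMap

__all__ = [
    "RadianceImage",
    "DepthWeights",
    "depth_weights",
    "rl_deconvolve",
    "weighted_deconvolution",
    "reconvolve_roi",
    "convolve_kernel",
]

_EPS = 1e-12


@dataclass
class RadianceImage:
    """Calibrated planar image in photons/s/cm^2/sr with acquisition metadata."""

    values: np.ndarray
    pixel_size_mm: float
    exposure_s: float = 300.0
    f_number: float = 1.0
    binning: int = 8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("radiance image must be 2-D")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def pixel_area_cm2(self) -> float:
        return (self.pixel_size_mm / 10.0) ** 2

    def to_tiff(self, path) -> None:
        import json

        import tifffile

        tifffile.imwrite(str(path), self.values.astype(np.float32))
        with open(str(path) + ".json", "w") as fh:
            json.dump({"pixel_size_mm": self.pixel_size_mm,
                       "exposure_s": self.exposure_s,
                       "f_number": self.f_number, "binning": self.binning,
                       "units": "photons/s/cm^2/sr"}, fh)

    @classmethod
    def from_tiff(cls, path) -> "RadianceImage":
        import json
        import os

        import tifffile

        values = tifffile.imread(str(path))
        meta = {}
        if os.path.exists(str(path) + ".json"):
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        return cls(values=values,
                   pixel_size_mm=meta.get("pixel_size_mm", 0.554),
                   exposure_s=meta.get("exposure_s", 300.0),
                   f_number=meta.get("f_number", 1.0),
                   binning=meta.get("binning", 8))


@dataclass(frozen=True)
class DepthWeights:
    """Normalized per-depth weights for the kernel-averaged deconvolution."""

    depths_mm: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_mm, float)
        w = np.asarray(self.weights, float)
        if d.shape != w.shape or d.ndim != 1:
            raise ValueError("depths and weights must be 1-D and equal length")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "depths_mm", d)
        object.__setattr__(self, "weights", w)

    def as_dict(self) -> dict[float, float]:
        return {float(d): float(w) for d, w in zip(self.depths_mm, self.weights)}


def depth_weights(
    depth_map: DepthMap,
    csf_set: dict[float, CSFKernel],
    intensity_factor: str = "fwhm_integral",
) -> DepthWeights:
    """Per-depth deconvolution weights from the ROI depth histogram.

    Each occupied depth-map pixel is assigned to the nearest kernel depth;
    the raw weight of depth n is (pixel count at n) x (intensity factor of
    kernel n), normalized to sum to one.  The intensity factor is the
    fraction of kernel counts inside the FWHM (default) or the normalized
    kernel peak, reflecting the higher surface radiance of shallow sources.
    """
    occupied = depth_map.occupied_depths()
    if occupied.size == 0:
        raise ValueError("depth map contains no ROI pixels")
    depths = np.array(sorted(csf_set), float)
    if intensity_factor == "fwhm_integral":
        factors = np.array([fwhm_integral_intensity(csf_set[d]) for d in depths])
    elif intensity_factor == "peak":
        factors = np.array([peak_intensity(csf_set[d]) for d in depths])
    else:
        raise ValueError(f"unknown intensity factor {intensity_factor!r}")
    nearest = np.argmin(np.abs(occupied[:, None] - depths[None, :]), axis=1)
    counts = np.bincount(nearest, minlength=depths.size).astype(float)
    raw = counts * factors
    if raw.sum() <= 0:
        raise ValueError("all depth weights vanished")
    return DepthWeights(depths, raw / raw.sum())


def _check_unit_kernel(kernel: CSFKernel) -> np.ndarray:
    g = np.asarray(kernel.grid, float)
    if abs(g.sum() - 1.0) > 1e-6:
        raise ValueError("deconvolution requires a unit-integral kernel")
    return g


def convolve_kernel(image: np.ndarray, kernel: CSFKernel) -> np.ndarray:
    """Same-size convolution of an image with a (centered, odd) kernel."""
    return fftconvolve(np.asarray(image, float), np.asarray(kernel.grid, float),
                       mode="same")


def rl_deconvolve(
    image: np.ndarray,
    kernel: CSFKernel,
    weight_mask: np.ndarray | None = None,
    iterations: int = 10,
) -> np.ndarray:
    """Weighted Richardson-Lucy deconvolution.

    Pixels where the weight mask is 0 are excluded from the multiplicative
    data term (treated as unobserved); the kernel mass is renormalized by
    the in-mask response so flux does not leak across the mask boundary.
    The image is padded by the kernel size with zero-weight (unobserved)
    pixels, so a flat image is an exact fixed point regardless of boundary.
    """
    g = _check_unit_kernel(kernel)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    img = np.asarray(image, float)
    if weight_mask is None:
        w = np.ones_like(img)
    else:
        w = np.asarray(weight_mask, float)
        if w.shape != img.shape:
            raise ValueError("weight mask shape must match the image")
        if not (w > 0).any():
            raise ValueError("weight mask excludes every pixel")
        # the result must not depend on unobserved pixel values: replace
        # them with the observed mean before initialization
        img = np.where(w > 0, img, img[w > 0].mean())

    # pad by the full kernel size; the pad ring carries zero weight (treated
    # as unobserved), which makes the flat image an exact fixed point and
    # keeps FFT zero-extension artifacts out of the data term
    pad = g.shape[0] - 1
    y = np.pad(np.clip(img, 0.0, None), pad, mode="edge")
    wp = np.pad(w, pad, mode="constant")
    g_flip = g[::-1, ::-1]

    def conv(a, k):
        return fftconvolve(a, k, mode="same")

    norm = conv(wp, g_flip)  # in-mask kernel mass per pixel
    # flat positive initialization: starting from y itself leaves exact
    # zeros that the multiplicative updates can never repopulate, and the
    # eps-guarded ratio then diverges at the boundary of the zero region
    obs_mean = float(y[wp > 0].mean())
    if obs_mean <= 0:
        return np.zeros_like(img)
    x = np.full_like(y, obs_mean)
    for _ in range(iterations):
        est = np.clip(conv(x, g), 0.0, None)
        ratio = np.where(wp > 0, y / np.maximum(est, _EPS), 0.0)
        corr = conv(wp * ratio, g_flip) / np.maximum(norm, _EPS)
        # FFT round-off can push corr slightly negative; RL iterates must
        # stay non-negative or the multiplicative updates diverge
        x = np.clip(np.where(norm > _EPS, x * corr, x), 0.0, None)
    out = x[pad:-pad, pad:-pad] if pad else x
    return np.clip(out, 0.0, None)


def weighted_deconvolution(
    image: np.ndarray,
    csf_set: dict[float, CSFKernel],
    weights: DepthWeights,
    weight_mask: np.ndarray | None = None,
    iterations: int = 10,
) -> np.ndarray:
    """Weight-averaged RL deconvolution against the per-depth kernel set."""
    px = {round(k.pixel_size_mm, 6) for k in csf_set.values()}
    if len(px) != 1:
        raise ValueError("all kernels must share one pixel size")
    out = np.zeros_like(np.asarray(image, float))
    for d, w in weights.as_dict().items():
        if w == 0.0:
            continue
        if d not in csf_set:
            raise ValueError(f"no kernel available for depth {d} mm")
        out += w * rl_deconvolve(image, csf_set[d], weight_mask, iterations)
    return out


def reconvolve_roi(
    deconvolved: np.ndarray,
    roi_mask: np.ndarray,
    csf_set: dict[float, CSFKernel],
    weights: DepthWeights,
) -> np.ndarray:
    """Mask the deconvolved image to the ROI and blur back with the same weights."""
    img = np.asarray(deconvolved, float) * np.asarray(roi_mask, bool)
    out = np.zeros_like(img)
    for d, w in weights.as_dict().items():
        if w == 0.0:
            continue
        out += w * convolve_kernel(img, csf_set[d])
    return out
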