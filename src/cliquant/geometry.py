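"""CT-side processing for planar Cherenkov quantification.

Body masking by HU threshold, reduction of the CT to the camera view via a
maximum intensity projection, 2-D similarity registration of the optical
image mask onto the CT mask, and per-pixel mean ROI depth maps.

Axis convention: volumes are indexed ``(lateral, depth, longitudinal)``
where the depth axis points away from the camera — "the surface directly
above" an ROI voxel is the first body voxel encountered moving toward the
camera (decreasing depth index).  Planar images are indexed
``(lateral, longitudinal)``.  All grids are 0-based; depths are measured
center-to-center in mm.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "PlanarMask",
    "SimilarityTransform2D",
    "DepthMap",
    "body_mask_from_ct",
    "coronal_mip",
    "resample_radiance",
    "register_similarity",
    "apply_transform_image",
    "supine_mask_from_prone",
    "roi_depth_map",
    "save_volume_nifti",
    "load_volume_nifti",
]

DEPTH_AXIS = 1  # camera looks along this axis


@dataclass
class PlanarMask:
    mask: np.ndarray  # 2-D boolean
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 2:
            raise ValueError("planar mask must be 2-D")


@dataclass
class SimilarityTransform2D:
    """scale/rotation/translation, with the registration metric trace attached."""

    scale: float = 1.0
    rotation_rad: float = 0.0
    translation_mm: tuple[float, float] = (0.0, 0.0)
    final_metric: float = float("nan")
    metric_history: tuple = ()
    converged: bool = True

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"scale": self.scale, "rotation_rad": self.rotation_rad,
                       "translation_mm": list(self.translation_mm)}, fh)

    @classmethod
    def from_json(cls, path) -> "SimilarityTransform2D":
        with open(path) as fh:
            d = json.load(fh)
        return cls(scale=d["scale"], rotation_rad=d["rotation_rad"],
                   translation_mm=tuple(d["translation_mm"]))


@dataclass
class DepthMap:
    """Per-pixel mean depth (mm) of ROI voxels below the body surface."""

    depth_mm: np.ndarray  # 2-D float, NaN outside the mask
    mask: np.ndarray  # 2-D boolean ROI projection
    pixel_size_mm: float
    roi_code: int = 0

    def occupied_depths(self) -> np.ndarray:
        return self.depth_mm[self.mask]


def body_mask_from_ct(volume: np.ndarray, threshold_hu: float = -700.0) -> np.ndarray:
    """Boolean body mask: voxels >= threshold, largest connected component."""
    raw = np.asarray(volume) >= threshold_hu
    if not raw.any():
        raise ValueError("empty body mask: no voxels above the HU threshold")
    labels, n = ndimage.label(raw)
    if n == 1:
        return raw
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def coronal_mip(mask: np.ndarray, axis: int = DEPTH_AXIS,
                pixel_size_mm: float = 1.0) -> PlanarMask:
    """Reduce a boolean volume to the camera view by maximum intensity projection."""
    return PlanarMask(np.asarray(mask, bool).any(axis=axis), pixel_size_mm)


def resample_radiance(image: np.ndarray, from_pixel_mm: float,
                      to_pixel_mm: float) -> np.ndarray:
    """Resample an area-normalized radiance image to a new pixel size.

    Radiance units (photons/s/cm^2/sr) are per-area, so interpolation of
    values — not of integrated counts — preserves total radiance x area.
    """
    if from_pixel_mm <= 0 or to_pixel_mm <= 0:
        raise ValueError("pixel sizes must be positive")
    zoom = from_pixel_mm / to_pixel_mm
    return ndimage.zoom(np.asarray(image, float), zoom, order=1,
                        mode="nearest", grid_mode=True)


def _mask_to_sitk(mask: PlanarMask, smooth_sigma_px: float) -> sitk.Image:
    img = sitk.GetImageFromArray(mask.mask.astype(np.float32))
    img.SetSpacing((mask.pixel_size_mm, mask.pixel_size_mm))
    if smooth_sigma_px > 0:
        img = sitk.SmoothingRecursiveGaussian(
            img, smooth_sigma_px * mask.pixel_size_mm)
    return img


def register_similarity(
    fixed: PlanarMask,
    moving: PlanarMask,
    iterations: int = 100,
    smooth_sigma_px: float = 2.0,
) -> SimilarityTransform2D:
    """2-D similarity (scale, rotation, translation) registration of binary masks.

    Gradient descent on a mean-squares metric over lightly smoothed mask
    images; deterministic for fixed inputs.  Non-convergence returns the
    best transform found with ``converged=False``.
    """
    if not fixed.mask.any() or not moving.mask.any():
        raise ValueError("registration requires nonempty masks")
    f = _mask_to_sitk(fixed, smooth_sigma_px)
    m = _mask_to_sitk(moving, smooth_sigma_px)

    tx = sitk.CenteredTransformInitializer(
        f, m, sitk.Similarity2DTransform(),
        sitk.CenteredTransformInitializerFilter.MOMENTS)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=0.2, minStep=1e-6, numberOfIterations=iterations,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-9)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(tx, inPlace=True)
    history: list[float] = []
    reg.AddCommand(sitk.sitkIterationEvent,
                   lambda: history.append(reg.GetMetricValue()))
    reg.Execute(f, m)

    sim = sitk.Similarity2DTransform(tx)
    # translation of the physical mapping, expressed with the center folded in
    params = sim.GetParameters()  # (scale, angle, tx, ty)
    c = sim.GetCenter()
    scale, angle = params[0], params[1]
    cos_a, sin_a = np.cos(angle), np.sin(angle)
    # full offset: T(x) = s R (x - c) + c + t
    off = np.array([params[2], params[3]])
    srch = np.array([[cos_a, -sin_a], [sin_a, cos_a]]) * scale
    t_total = np.asarray(c) - srch @ np.asarray(c) + off
    converged = reg.GetOptimizerStopConditionDescription().find("Maximum") < 0
    return SimilarityTransform2D(
        scale=float(scale), rotation_rad=float(angle),
        translation_mm=(float(t_total[0]), float(t_total[1])),
        final_metric=float(reg.GetMetricValue()),
        metric_history=tuple(history), converged=converged,
    )


def apply_transform_image(
    image: np.ndarray, transform: SimilarityTransform2D, pixel_size_mm: float
) -> np.ndarray:
    """Resample an image through the similarity transform (moving -> fixed grid)."""
    img = sitk.GetImageFromArray(np.asarray(image, np.float64))
    img.SetSpacing((pixel_size_mm, pixel_size_mm))
    sim = sitk.Similarity2DTransform()
    sim.SetScale(transform.scale)
    sim.SetAngle(transform.rotation_rad)
    sim.SetTranslation(tuple(transform.translation_mm))
    out = sitk.Resample(img, img, sim, sitk.sitkLinear, 0.0)
    return sitk.GetArrayFromImage(out)


def supine_mask_from_prone(volume_mask: np.ndarray, axis: int = 2) -> np.ndarray:
    """Rotate a boolean volume 180 degrees about the longitudinal axis.

    Equivalent to flipping both axes orthogonal to ``axis``; involutive and
    voxel-count preserving.
    """
    flip_axes = tuple(a for a in range(3) if a != axis)
    return np.flip(np.asarray(volume_mask, bool), axis=flip_axes)


def roi_depth_map(
    body_mask: np.ndarray,
    label_volume: np.ndarray,
    roi_code: int,
    spacing_mm: float = 0.204,
) -> DepthMap:
    """Planar map of the mean depth of ROI voxels below the body surface.

    For every planar pixel whose projection column contains ROI voxels, the
    depth of each ROI voxel is (its depth index − the surface index directly
    above it) × spacing, averaged over the column.
    """
    body = np.asarray(body_mask, bool)
    roi = np.asarray(label_volume) == roi_code
    if not roi.any():
        raise ValueError(f"label volume contains no voxels with code {roi_code}")
    if np.any(roi & ~body):
        bad = np.argwhere(roi & ~body)[0]
        raise ValueError(f"ROI voxel outside the body mask at index {tuple(bad)}")

    body_m = np.moveaxis(body, DEPTH_AXIS, -1)  # (lat, long, depth)
    roi_m = np.moveaxis(roi, DEPTH_AXIS, -1)
    nd = body_m.shape[-1]
    surface = np.argmax(body_m, axis=-1)  # first body voxel toward the camera
    has_body = body_m.any(axis=-1)

    idx = np.arange(nd)
    depths_vox = idx[None, None, :] - surface[..., None]
    if np.any(roi_m & (depths_vox < 0)):
        bad = np.argwhere(roi_m & (depths_vox < 0))[0]
        raise ValueError(f"ROI voxel with no surface above it at index {tuple(bad)}")
    with np.errstate(invalid="ignore"):
        total = (depths_vox * roi_m).sum(axis=-1)
        count = roi_m.sum(axis=-1)
        mean_depth = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    mask = count > 0
    if np.any(mask & ~has_body):
        raise ValueError("ROI projects to a column with no body surface")
    return DepthMap(
        depth_mm=np.where(mask, mean_depth * spacing_mm, np.nan),
        mask=mask,
        pixel_size_mm=spacing_mm,
        roi_code=int(roi_code),
    )


def save_volume_nifti(path, volume: np.ndarray, spacing_mm: float) -> None:
    import nibabel as nib

    aff = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume), aff), str(path))


def load_volume_nifti(path) -> tuple[np.ndarray, float]:
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(img.header.get_zooms()[0])
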