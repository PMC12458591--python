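"""Synthetic inputs for every stage of the quantification pipeline.

No public dataset accompanies this kind of planar Cherenkov study, so the
package generates its own: the 96-well calibration phantom, voxelized mouse
phantoms with liver and tumor compartments, forward-modeled Cherenkov
radiance images (depth-dependent calibration response plus depth-weighted
spread-function blur plus instrument background), and PET-like activity
volumes for the comparison arm.

The forward optical model is the exact inverse of the quantification model:
per-pixel ideal radiance = c(depth) x activity concentration, blurred with
the same depth-weighted kernel average the deconvolution later inverts.
What it deliberately omits — surface curvature, spatially varying optics,
autoluminescence structure — is documented in the methods note.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .csf_mc import CSFKernel
from .deconv import RadianceImage, convolve_kernel, depth_weights
from .dosimetry import TimeActivityCurve
from .geometry import DepthMap, roi_depth_map
from .quantify import (
    DEFAULT_BACKGROUND_RADIANCE,
    MBQ_PER_UCI,
    Y86_HALF_LIFE_H,
    CalibrationCurve,
    WellMeasurement,
    calibration_coefficient,
)

__all__ = [
    "LABEL_CODES",
    "MousePhantomSpec",
    "ForwardModelConfig",
    "SyntheticStudy",
    "reference_calibration_curve",
    "generate_wellplate",
    "generate_mouse_phantom",
    "forward_cli_image",
    "forward_pet_volume",
    "generate_study",
]

LABEL_CODES = {"body": 1, "liver": 2, "tumor": 3}

WELL_ACTIVITIES_MBQ = (0.0, 0.185, 0.370, 0.925, 1.850)
WELL_DEPTHS_MM = (1.66, 3.31, 4.97, 6.62, 8.28, 9.93)
STUDY_TIMEPOINTS_H = (3.5, 29.0, 52.0, 97.0)
INJECTED_ACTIVITY_MBQ = 9.25


def reference_calibration_curve() -> CalibrationCurve:
    """The measured depth calibration of the well-plate phantom study."""
    return CalibrationCurve(intercept=9734.2, slope=-613.8,
                            depth_range_mm=(WELL_DEPTHS_MM[0], WELL_DEPTHS_MM[-1]),
                            pearson_r=-0.976)


@dataclass(frozen=True)
class MousePhantomSpec:
    """Ellipsoidal mouse phantom sized to a ~25 g animal.

    Axes follow the package convention (lateral, depth, longitudinal); the
    camera looks along the depth axis.  The liver ellipsoid centroid sits
    ~4 mm and the tumor sphere centroid ~2-3 mm below the dorsal surface,
    with a 5 mm edge gap in the image plane, so spread-function cross-talk
    between the organs is present but separable.
    """

    body_semi_axes_mm: tuple[float, float, float] = (12.0, 12.0, 40.0)
    liver_center_mm: tuple[float, float, float] = (0.0, -8.0, -10.0)
    liver_semi_axes_mm: tuple[float, float, float] = (5.0, 3.0, 6.0)
    tumor_center_mm: tuple[float, float, float] = (0.0, -9.0, 3.5)
    tumor_radius_mm: float = 2.5
    spacing_mm: float = 0.204
    margin_mm: float = 2.0
    hu_air: float = -1000.0
    hu_body: float = 40.0
    hu_liver: float = 60.0
    hu_tumor: float = 50.0


@dataclass
class ForwardModelConfig:
    """Settings of the forward Cherenkov imaging model."""

    curve: CalibrationCurve = field(default_factory=reference_calibration_curve)
    background_level: float = DEFAULT_BACKGROUND_RADIANCE
    background_sd: float = 307.0
    noise_model: str = "gaussian"  # {"gaussian", "poisson-scaled"}
    noise_cv: float = 0.05
    intensity_factor: str = "fwhm_integral"
    seed: int = 0


def generate_wellplate(
    activities_mbq=WELL_ACTIVITIES_MBQ,
    depths_mm=WELL_DEPTHS_MM,
    replicates: int = 3,
    curve: CalibrationCurve | None = None,
    noise_cv: float = 0.05,
    background_level: float = DEFAULT_BACKGROUND_RADIANCE,
    background_sd: float = 307.0,
    seed: int = 0,
) -> list[WellMeasurement]:
    """Simulate the calibration plate: radiance = c(depth) x concentration
    x (1 + noise) + background; zero-activity wells emit background only."""
    curve = curve or reference_calibration_curve()
    rng = np.random.default_rng(seed)
    wells = []
    for d in depths_mm:
        c = float(calibration_coefficient(curve, d, extrapolate=True))
        for a in activities_mbq:
            for rep in range(replicates):
                w = WellMeasurement(depth_mm=float(d), activity_mbq=float(a),
                                    radiance=0.0, replicate=rep)
                signal = c * w.concentration_uci_cm2
                if noise_cv > 0:
                    signal *= 1.0 + noise_cv * rng.standard_normal()
                bkg = background_level
                if noise_cv > 0 and background_sd > 0:
                    bkg += background_sd * rng.standard_normal()
                wells.append(replace(w, radiance=float(max(signal + bkg, 0.0))))
    return wells


def _ellipsoid_mask(shape, center_vox, semi_axes_vox) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    acc = np.zeros(shape)
    for g, c, s in zip(grids, center_vox, semi_axes_vox):
        acc += ((g - c) / s) ** 2
    return acc <= 1.0


def generate_mouse_phantom(spec: MousePhantomSpec = MousePhantomSpec()):
    """Voxelize the phantom: returns (HU volume, label volume).

    Label codes: 0 air, 1 body, 2 liver, 3 tumor.  Raises if the liver and
    tumor overlap or protrude from the body.
    """
    sp = spec.spacing_mm
    half = np.array(spec.body_semi_axes_mm) + spec.margin_mm
    shape = tuple(int(np.ceil(2 * h / sp)) | 1 for h in half)
    center = (np.array(shape) - 1) / 2.0

    def to_vox(point_mm):
        return center + np.asarray(point_mm) / sp

    body = _ellipsoid_mask(shape, center, np.array(spec.body_semi_axes_mm) / sp)
    liver = _ellipsoid_mask(shape, to_vox(spec.liver_center_mm),
                            np.array(spec.liver_semi_axes_mm) / sp)
    tumor = _ellipsoid_mask(shape, to_vox(spec.tumor_center_mm),
                            np.full(3, spec.tumor_radius_mm) / sp)
    if (liver & tumor).any():
        raise ValueError("liver and tumor compartments overlap")
    if (liver & ~body).any() or (tumor & ~body).any():
        raise ValueError("an ROI protrudes from the body")

    hu = np.full(shape, spec.hu_air)
    hu[body] = spec.hu_body
    hu[liver] = spec.hu_liver
    hu[tumor] = spec.hu_tumor
    labels = np.zeros(shape, dtype=np.int16)
    labels[body] = LABEL_CODES["body"]
    labels[liver] = LABEL_CODES["liver"]
    labels[tumor] = LABEL_CODES["tumor"]
    return hu, labels


def _compartment_masks(labels: np.ndarray) -> dict[str, np.ndarray]:
    return {name: np.asarray(labels) == code for name, code in LABEL_CODES.items()}


def forward_cli_image(
    label_volume: np.ndarray,
    compartment_activities_mbq: dict[str, float],
    csf_set: dict[float, CSFKernel],
    config: ForwardModelConfig,
    spacing_mm: float,
    depth_maps: dict[str, DepthMap] | None = None,
) -> RadianceImage:
    """Simulate the planar radiance the optical imager would record.

    Each compartment is filled uniformly in the image plane at its planar
    activity concentration, mapped through the depth calibration c(depth)
    pixel by pixel, blurred with that compartment's depth-weighted kernel
    average, then summed; background and noise are added last.  Linear in
    activity before noise.
    """
    from .csf_mc import normalize_kernel

    csf_set = {d: (k if k.normalization == "unit-integral" else normalize_kernel(k))
               for d, k in csf_set.items()}
    labels = np.asarray(label_volume)
    body = labels > 0
    if depth_maps is None:
        depth_maps = {
            name: roi_depth_map(body, labels, code, spacing_mm)
            for name, code in LABEL_CODES.items()
            if (labels == code).any()
        }
    rng = np.random.default_rng(config.seed)
    planar_shape = next(iter(depth_maps.values())).mask.shape
    out = np.zeros(planar_shape)
    pixel_area_cm2 = (spacing_mm / 10.0) ** 2
    for name, act_mbq in compartment_activities_mbq.items():
        key = "body" if name == "remainder" else name
        if act_mbq == 0 or key not in depth_maps:
            continue
        dm = depth_maps[key]
        n_pix = int(dm.mask.sum())
        conc = act_mbq / MBQ_PER_UCI / (n_pix * pixel_area_cm2)  # uCi/cm^2
        c = calibration_coefficient(config.curve, np.where(dm.mask, dm.depth_mm, 0.0),
                                    extrapolate=True)
        ideal = np.where(dm.mask, np.clip(c, 0.0, None) * conc, 0.0)
        w = depth_weights(dm, csf_set, config.intensity_factor)
        blurred = np.zeros_like(ideal)
        for d, wn in w.as_dict().items():
            if wn > 0:
                blurred += wn * convolve_kernel(ideal, csf_set[d])
        # The depth calibration is operationally defined on blurred images of
        # extended sources: c(d) is the measured in-footprint radiance per
        # unit concentration *including* optical spread.  Rescale the blurred
        # compartment so its in-footprint mean matches c(d) x concentration.
        in_roi = blurred[dm.mask].mean()
        if in_roi > 0:
            blurred *= ideal[dm.mask].mean() / in_roi
        out += blurred
    if config.noise_cv > 0:
        if config.noise_model == "poisson-scaled":
            scale = 1.0 / max(config.noise_cv, 1e-9) ** 2
            out = rng.poisson(np.clip(out, 0, None) / max(out.max(), 1e-9)
                              * scale) * out.max() / scale
        else:
            out = out * (1.0 + config.noise_cv * rng.standard_normal(out.shape))
        bkg = config.background_level + config.background_sd * rng.standard_normal(
            out.shape)
    else:
        bkg = np.full_like(out, config.background_level)
    return RadianceImage(values=np.clip(out + bkg, 0.0, None),
                         pixel_size_mm=spacing_mm)


def forward_pet_volume(
    label_volume: np.ndarray,
    compartment_activities_mbq: dict[str, float],
    blur_fwhm_mm: float = 1.5,
    noise_cv: float = 0.0,
    seed: int = 0,
    spacing_mm: float = 0.4,
) -> np.ndarray:
    """PET-like activity volume: uniform compartment filling + Gaussian blur.

    Total activity is conserved (the body sits well inside the grid).
    """
    if blur_fwhm_mm < 0:
        raise ValueError("blur must be non-negative")
    from .dosimetry import synthesize_activity_volume

    vol = synthesize_activity_volume(label_volume, compartment_activities_mbq,
                                     LABEL_CODES)
    if blur_fwhm_mm > 0:
        sigma = blur_fwhm_mm / 2.3548 / spacing_mm
        vol = ndimage.gaussian_filter(vol, sigma, mode="constant")
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        vol = np.clip(vol * (1.0 + noise_cv * rng.standard_normal(vol.shape)),
                      0.0, None)
    return vol


@dataclass
class SyntheticStudy:
    """A complete two-arm synthetic imaging study on one mouse phantom."""

    hu: np.ndarray
    labels: np.ndarray
    spacing_mm: float
    timepoints_h: tuple
    true_liver: TimeActivityCurve
    true_tumor: TimeActivityCurve
    true_remainder: TimeActivityCurve
    cli_images: dict[float, RadianceImage]
    csf_set: dict[float, CSFKernel]
    config: ForwardModelConfig
    injected_mbq: float = INJECTED_ACTIVITY_MBQ

    @property
    def true_total(self) -> TimeActivityCurve:
        return TimeActivityCurve(
            self.true_liver.times_h,
            self.true_liver.activities_mbq + self.true_tumor.activities_mbq
            + self.true_remainder.activities_mbq,
            "Y-86", "total")


def _true_tacs(timepoints_h, injected_mbq) -> tuple[TimeActivityCurve, ...]:
    """Ground-truth compartment kinetics of the surrogate-isotope study.

    Physical decay of the imaging isotope times single-exponential
    biological washout per compartment; the remainder clears fast
    (renal excretion), the bound compartments slowly.
    """
    t = np.asarray(timepoints_h, float)
    lam = np.log(2.0) / Y86_HALF_LIFE_H
    liver = 0.40 * injected_mbq * np.exp(-(lam + 0.004) * t)
    tumor = 0.15 * injected_mbq * np.exp(-(lam + 0.002) * t)
    remainder = 0.45 * injected_mbq * np.exp(-(lam + 0.05) * t)
    return (
        TimeActivityCurve(t, liver, "Y-86", "liver"),
        TimeActivityCurve(t, tumor, "Y-86", "tumor"),
        TimeActivityCurve(t, remainder, "Y-86", "remainder"),
    )


def generate_study(
    csf_set: dict[float, CSFKernel],
    seed: int = 0,
    spacing_mm: float = 0.4,
    timepoints_h=STUDY_TIMEPOINTS_H,
    injected_mbq: float = INJECTED_ACTIVITY_MBQ,
    noise_cv: float = 0.05,
    spec: MousePhantomSpec | None = None,
) -> SyntheticStudy:
    """Generate the full serial-imaging study used by the end-to-end tests."""
    spec = spec or MousePhantomSpec(spacing_mm=spacing_mm)
    hu, labels = generate_mouse_phantom(spec)
    liver, tumor, remainder = _true_tacs(timepoints_h, injected_mbq)
    body = labels > 0
    dms = {name: roi_depth_map(body, labels, code, spacing_mm)
           for name, code in LABEL_CODES.items()}
    config = ForwardModelConfig(noise_cv=noise_cv, seed=seed)
    images = {}
    for i, t in enumerate(timepoints_h):
        cfg = replace(config, seed=(seed * 7919 + i) & 0x7FFFFFFF)
        images[float(t)] = forward_cli_image(
            labels,
            {"liver": float(liver.activities_mbq[i]),
             "tumor": float(tumor.activities_mbq[i]),
             "remainder": float(remainder.activities_mbq[i])},
            csf_set, cfg, spacing_mm, depth_maps=dms,
        )
    return SyntheticStudy(
        hu=hu, labels=labels, spacing_mm=spacing_mm,
        timepoints_h=tuple(timepoints_h),
        true_liver=liver, true_tumor=tumor, true_remainder=remainder,
        cli_images=images, csf_set=csf_set, config=config,
        injected_mbq=injected_mbq,
    )
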