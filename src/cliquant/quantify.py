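"""Phantom-based depth calibration and radiance-to-activity conversion.

The calibration phantom is a 96-well plate with known plated activities
covered by varying depths of a tissue-mimicking liquid.  A two-stage linear
fit turns the measurements into a depth-dependent calibration coefficient
c(d) (radiance per uCi/cm^2): stage 1 regresses radiance on activity
concentration at each depth; stage 2 regresses the per-depth slopes on
depth.  Reconvolved ROI radiance divided by c(depth) yields an activity
concentration; its ROI mean times the planar area gives ROI activity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DepthMap

__all__ = [
    "MBQ_PER_UCI",
    "WELL_BOTTOM_AREA_CM2",
    "Y86_HALF_LIFE_H",
    "Y90_HALF_LIFE_H",
    "DEFAULT_BACKGROUND_RADIANCE",
    "WellMeasurement",
    "CalibrationCurve",
    "ActivityEstimate",
    "subtract_background",
    "decay_correct",
    "fit_depth_calibration",
    "calibration_coefficient",
    "roi_activity",
    "wells_from_csv",
    "wells_to_csv",
]

MBQ_PER_UCI = 0.037
WELL_BOTTOM_AREA_CM2 = 0.34  # standard 96-well growth area
Y86_HALF_LIFE_H = 14.74
Y90_HALF_LIFE_H = 64.05
# open-filter instrument background, photons/s/cm^2/sr (level and spread)
DEFAULT_BACKGROUND_RADIANCE = 7902.0
DEFAULT_BACKGROUND_SPREAD = 307.0


@dataclass(frozen=True)
class WellMeasurement:
    """One well: plated activity under a known liquid depth."""

    depth_mm: float
    activity_mbq: float
    radiance: float  # photons/s/cm^2/sr
    replicate: int = 0
    dt_h: float = 0.0  # acquisition time after plating
    concentration_uci_cm2: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.activity_mbq < 0:
            raise ValueError("activity must be non-negative")
        if self.depth_mm <= 0:
            raise ValueError("depth must be positive")
        if np.isnan(self.concentration_uci_cm2):
            object.__setattr__(
                self, "concentration_uci_cm2",
                self.activity_mbq / MBQ_PER_UCI / WELL_BOTTOM_AREA_CM2)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear depth calibration c(d) = intercept + slope * d.

    Units: radiance per uCi/cm^2 (intercept), per mm additionally (slope).
    """

    intercept: float
    slope: float
    depth_range_mm: tuple[float, float]
    pearson_r: float = float("nan")
    per_depth: dict = field(default_factory=dict)  # depth -> stage-1 slope

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump({"intercept": self.intercept, "slope": self.slope,
                       "depth_range_mm": list(self.depth_range_mm),
                       "pearson_r": self.pearson_r,
                       "per_depth": {str(k): v for k, v in self.per_depth.items()},
                       }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(intercept=d["intercept"], slope=d["slope"],
                   depth_range_mm=tuple(d["depth_range_mm"]),
                   pearson_r=d.get("pearson_r", float("nan")),
                   per_depth={float(k): v for k, v in d.get("per_depth", {}).items()})


@dataclass
class ActivityEstimate:
    activity_mbq: float
    uncertainty_mbq: float
    roi_id: str = ""
    timepoint_h: float = 0.0
    below_sensitivity: bool = False


def subtract_background(values, background: float = DEFAULT_BACKGROUND_RADIANCE,
                        floor: float = 0.0):
    """Subtract the instrument background, flooring at zero.

    Returns (subtracted, below_sensitivity_flag); the flag is set when more
    than half of the input values were floored.
    """
    if background < 0:
        raise ValueError("background must be non-negative")
    v = np.asarray(values, float)
    out = np.maximum(v - background, floor)
    flagged = bool(np.mean(v - background <= floor) > 0.5)
    return out, flagged


def decay_correct(value, dt_h: float, half_life_h: float):
    """Correct a measured value back to the reference time: x * 2^(dt/T1/2)."""
    if half_life_h <= 0:
        raise ValueError("half-life must be positive")
    return np.asarray(value, float) * 2.0 ** (dt_h / half_life_h)


def fit_depth_calibration(
    wells: list[WellMeasurement],
    noise_cv: float = 0.05,
    background_spread: float = DEFAULT_BACKGROUND_SPREAD,
) -> CalibrationCurve:
    """Two-stage depth calibration fit.

    Inputs are assumed background-subtracted and decay-corrected.  Stage 1:
    at each depth, weighted least squares of radiance on activity
    concentration (free intercept, expected near zero after background
    subtraction); its slope is the per-depth calibration coefficient.  The
    weights follow the measurement error model var = (cv x radiance)^2 +
    background_spread^2 — bright shallow wells carry proportionally larger
    absolute noise, so unweighted least squares would be needlessly noisy.
    Stage 2: ordinary least squares of the per-depth coefficients on depth;
    the Pearson correlation of stage 2 is reported.
    """
    df = pd.DataFrame([{"depth": w.depth_mm, "conc": w.concentration_uci_cm2,
                        "radiance": w.radiance} for w in wells])
    depths = np.array(sorted(df["depth"].unique()))
    if depths.size < 2:
        raise ValueError("need measurements at >= 2 depths")
    coeffs = []
    missing = []
    for d in depths:
        sub = df[df["depth"] == d]
        nz = sub[sub["conc"] > 0]
        if nz["conc"].nunique() < 2:
            missing.append(float(d))
            continue
        x = sub["conc"].to_numpy(float)
        y = sub["radiance"].to_numpy(float)
        var = (noise_cv * y) ** 2 + background_spread ** 2
        w = 1.0 / var if np.all(var > 0) else np.ones_like(y)
        sw, sx, sy = w.sum(), (w * x).sum(), (w * y).sum()
        sxx, sxy = (w * x * x).sum(), (w * x * y).sum()
        slope = (sw * sxy - sx * sy) / (sw * sxx - sx * sx)
        coeffs.append((float(d), float(slope)))
    if missing or len(coeffs) < 2:
        raise ValueError(
            "insufficient calibration design; depths lacking >=2 distinct "
            f"nonzero activities: {missing or sorted(df['depth'].unique())}")
    ds = np.array([c[0] for c in coeffs])
    cs = np.array([c[1] for c in coeffs])
    slope2, intercept2 = np.polyfit(ds, cs, 1)
    r = float(np.corrcoef(ds, cs)[0, 1])
    return CalibrationCurve(
        intercept=float(intercept2), slope=float(slope2),
        depth_range_mm=(float(ds.min()), float(ds.max())),
        pearson_r=r, per_depth=dict(coeffs),
    )


def calibration_coefficient(curve: CalibrationCurve, depth_mm,
                            extrapolate: bool = False):
    """Evaluate c(d) = intercept + slope * d; out-of-range depths error unless
    extrapolation is explicitly enabled."""
    d = np.asarray(depth_mm, float)
    lo, hi = curve.depth_range_mm
    if not extrapolate and (np.any(d < lo) or np.any(d > hi)):
        raise ValueError(
            f"depth outside the calibrated range [{lo}, {hi}] mm; "
            "pass extrapolate=True to override")
    return curve.intercept + curve.slope * d


def roi_activity(
    reconvolved: np.ndarray,
    depth_map: DepthMap,
    curve: CalibrationCurve,
    pixel_area_cm2: float,
    roi_id: str = "",
    timepoint_h: float = 0.0,
    extrapolate: bool = False,
) -> ActivityEstimate:
    """ROI activity from a reconvolved radiance image and its ROI depth map.

    Per ROI pixel: concentration (uCi/cm^2) = radiance / c(depth); the ROI
    activity is the mean concentration times the ROI planar area, converted
    to MBq.  Uncertainty propagates the pixel-wise concentration spread.
    """
    img = np.asarray(reconvolved, float)
    if img.shape != depth_map.mask.shape:
        raise ValueError("image and depth map must share one grid")
    m = depth_map.mask
    if not m.any():
        raise ValueError("empty ROI")
    c = calibration_coefficient(curve, depth_map.depth_mm[m],
                                extrapolate=extrapolate)
    if np.any(c <= 0):
        raise ValueError("calibration coefficient non-positive inside the ROI")
    conc = img[m] / c
    n = conc.size
    area = n * pixel_area_cm2
    act_uci = conc.mean() * area
    sem = conc.std(ddof=1) / np.sqrt(n) * area if n > 1 else 0.0
    return ActivityEstimate(
        activity_mbq=float(act_uci * MBQ_PER_UCI),
        uncertainty_mbq=float(sem * MBQ_PER_UCI),
        roi_id=roi_id, timepoint_h=timepoint_h,
        below_sensitivity=bool(act_uci <= 0),
    )


def wells_to_csv(path, wells: list[WellMeasurement]) -> None:
    pd.DataFrame(
        [{"depth_mm": w.depth_mm, "activity_mbq": w.activity_mbq,
          "concentration_uci_cm2": w.concentration_uci_cm2,
          "radiance": w.radiance, "replicate": w.replicate, "dt_h": w.dt_h}
         for w in wells]
    ).to_csv(path, index=False)


def wells_from_csv(path) -> list[WellMeasurement]:
    df = pd.read_csv(path)
    return [
        WellMeasurement(
            depth_mm=r.depth_mm, activity_mbq=r.activity_mbq,
            radiance=r.radiance, replicate=int(getattr(r, "replicate", 0)),
            dt_h=float(getattr(r, "dt_h", 0.0)),
            concentration_uci_cm2=float(getattr(r, "concentration_uci_cm2",
                                                float("nan"))),
        )
        for r in df.itertuples()
    ]
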