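"""Compartmental dosimetry from serial activity estimates.

Builds three-compartment (liver, tumor, remainder) synthetic activity
volumes from ROI activity estimates, transforms the time-activity curve of
an imaging surrogate isotope (Y-86) to its therapeutic counterpart (Y-90)
by exchanging physical decay while preserving biological retention, and
integrates voxel dose rates over time (trapezoid plus an analytic
physical-decay tail).

The dose engine is a LOCAL-DEPOSITION approximation: every voxel's emitted
energy is absorbed in that voxel.  This ignores beta crossfire between
organs and is flagged in every output; it stands in for full Monte Carlo
radiation transport, which is outside this package's scope.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DOSE_ENGINE_FLAG",
    "TimeActivityCurve",
    "CompartmentSet",
    "nuclear_constants",
    "fit_biexponential",
    "biexponential",
    "remainder_compartment",
    "synthesize_activity_volume",
    "surrogate_decay_transform",
    "local_deposition_dose_rate",
    "integrate_absorbed_dose",
    "roi_mean_dose",
]

DOSE_ENGINE_FLAG = "local-deposition"
_J_PER_MEV = 1.602e-13


def nuclear_constants() -> dict:
    ref = resources.files("cliquant.data").joinpath("nuclear_constants.json")
    with resources.as_file(ref) as p, open(p) as fh:
        return json.load(fh)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity (MBq) of one compartment at strictly increasing timepoints (h)."""

    times_h: np.ndarray
    activities_mbq: np.ndarray
    isotope: str = "Y-86"
    compartment: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, float)
        a = np.asarray(self.activities_mbq, float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and activities must be 1-D and equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("activities must be non-negative")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "activities_mbq", a)


@dataclass
class CompartmentSet:
    """Per-timepoint liver/tumor/remainder activities plus the label volume."""

    liver: TimeActivityCurve
    tumor: TimeActivityCurve
    remainder: TimeActivityCurve
    label_volume: np.ndarray | None = None
    label_codes: dict = field(default_factory=lambda: {"body": 1, "liver": 2,
                                                       "tumor": 3})


def biexponential(t, a1, k1, a2, k2):
    return a1 * np.exp(-k1 * np.asarray(t, float)) + a2 * np.exp(-k2 * t)


def fit_biexponential(times_h, totals_mbq) -> tuple[float, float, float, float]:
    """Nonlinear least squares of A1 e^(-k1 t) + A2 e^(-k2 t), k1, k2 > 0.

    Multi-start over a fixed grid of rate initializations; reproducible.
    Raises on failure, carrying the best residual found.
    """
    t = np.asarray(times_h, float)
    y = np.asarray(totals_mbq, float)
    if t.size < 4:
        raise ValueError("need >= 4 timepoints for a bi-exponential fit")
    if np.any(y <= 0):
        raise ValueError("totals must be positive")
    span = t.max() - t.min()
    k_grid = np.array([0.1, 0.3, 1.0, 3.0, 10.0]) / max(span, 1e-9)
    best = None
    best_res = np.inf
    for k1 in k_grid:
        for k2 in k_grid:
            if k2 <= k1:
                continue
            p0 = (y[0] * 0.7, k1, y[0] * 0.3, k2)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # degenerate starts are expected
                    popt, _ = curve_fit(
                        biexponential, t, y, p0=p0,
                        bounds=([0, 1e-12, 0, 1e-12], [np.inf] * 4),
                        maxfev=10_000)
            except RuntimeError:
                continue
            res = float(np.sum((biexponential(t, *popt) - y) ** 2))
            if res < best_res:
                best_res = res
                best = tuple(float(p) for p in popt)
    if best is None:
        raise RuntimeError(f"bi-exponential fit failed; best residual {best_res}")
    a1, k1, a2, k2 = best
    if a1 < a2:  # canonical order: slow component first
        a1, k1, a2, k2 = a2, k2, a1, k1
    if k1 > k2:
        a1, k1, a2, k2 = a2, k2, a1, k1
    return a1, k1, a2, k2


def remainder_compartment(
    total: TimeActivityCurve, liver: TimeActivityCurve, tumor: TimeActivityCurve
) -> TimeActivityCurve:
    """Total minus liver and tumor, clamped at zero with a warning."""
    if not (np.array_equal(total.times_h, liver.times_h)
            and np.array_equal(total.times_h, tumor.times_h)):
        raise ValueError("time-activity curves have misaligned timepoints")
    diff = total.activities_mbq - liver.activities_mbq - tumor.activities_mbq
    if np.any(diff < 0):
        warnings.warn("liver + tumor exceed the total activity at some "
                      "timepoints; remainder clamped to zero", stacklevel=2)
        diff = np.clip(diff, 0.0, None)
    return TimeActivityCurve(total.times_h, diff, total.isotope, "remainder")


def synthesize_activity_volume(
    labels: np.ndarray,
    compartment_activities_mbq: dict[str, float],
    label_codes: dict[str, int] | None = None,
) -> np.ndarray:
    """Uniformly fill each compartment with its activity (MBq per voxel).

    The remainder is spread over body voxels not belonging to liver/tumor.
    Total volume activity equals the sum of compartment activities.
    """
    codes = label_codes or {"body": 1, "liver": 2, "tumor": 3}
    labels = np.asarray(labels)
    out = np.zeros(labels.shape, float)
    for name, act in compartment_activities_mbq.items():
        if name == "remainder":
            mask = labels == codes["body"]
        else:
            mask = labels == codes[name]
        n = int(mask.sum())
        if n == 0:
            if act != 0:
                raise ValueError(f"compartment '{name}' is empty but has "
                                 f"activity {act} MBq")
            continue
        out[mask] += act / n
    return out


def surrogate_decay_transform(
    tac: TimeActivityCurve,
    half_life_imaging_h: float | None = None,
    half_life_therapy_h: float | None = None,
) -> TimeActivityCurve:
    """Exchange the physical decay of the imaging isotope for the therapy isotope.

    Biological retention r(t) = A(t) e^{+lambda_img t} is preserved and
    re-decayed with lambda_therapy, assuming an equal administered activity
    of the therapy isotope.
    """
    nc = nuclear_constants()["half_life_h"]
    t_img = half_life_imaging_h if half_life_imaging_h is not None else nc["Y-86"]
    t_ther = half_life_therapy_h if half_life_therapy_h is not None else nc["Y-90"]
    if t_img <= 0 or t_ther <= 0:
        raise ValueError("half-lives must be positive")
    lam_img = np.log(2.0) / t_img
    lam_ther = np.log(2.0) / t_ther
    retention = tac.activities_mbq * np.exp(lam_img * tac.times_h)
    therapy = retention * np.exp(-lam_ther * tac.times_h)
    return TimeActivityCurve(tac.times_h, therapy, "Y-90", tac.compartment)


def local_deposition_dose_rate(
    activity_volume_mbq: np.ndarray,
    density_volume_g_cm3: np.ndarray,
    voxel_volume_cm3: float,
    mean_energy_mev_per_decay: float | None = None,
) -> np.ndarray:
    """Voxel dose rate (Gy/h) assuming all emitted energy deposits locally.

    rate = activity[Bq] * E_mean[MeV] * 1.602e-13 [J/MeV] / mass[kg] * 3600.
    """
    act = np.asarray(activity_volume_mbq, float)
    rho = np.asarray(density_volume_g_cm3, float)
    if act.shape != rho.shape:
        raise ValueError("activity and density grids must match")
    if np.any(rho[act > 0] <= 0):
        raise ValueError("density must be positive wherever activity is present")
    if mean_energy_mev_per_decay is None:
        mean_energy_mev_per_decay = nuclear_constants()["mean_beta_energy_mev"]["Y-90"]
    mass_kg = rho * voxel_volume_cm3 * 1e-3
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = (act * 1e6 * mean_energy_mev_per_decay * _J_PER_MEV
                / np.maximum(mass_kg, 1e-30)) * 3600.0
    return np.where(act > 0, rate, 0.0)


def integrate_absorbed_dose(
    dose_rate_maps: list[np.ndarray],
    times_h: np.ndarray,
    lambda_phys_per_h: float,
    initial: str = "constant",
) -> np.ndarray:
    """Absorbed dose (Gy): trapezoid over the timepoints plus an analytic tail.

    From t=0 to the first timepoint the rate is held constant at the first
    map (``initial="constant"``, default) or ramped linearly from zero
    (``initial="linear"``); after the last timepoint only physical decay is
    assumed, contributing last_rate / lambda.
    """
    if lambda_phys_per_h <= 0:
        raise ValueError("physical decay constant must be positive")
    t = np.asarray(times_h, float)
    if t.size < 2 or len(dose_rate_maps) != t.size:
        raise ValueError("need >= 2 timepoints with one dose-rate map each")
    maps = np.stack([np.asarray(m, float) for m in dose_rate_maps])
    dose = np.trapezoid(maps, x=t, axis=0)
    head = maps[0] * t[0] if initial == "constant" else 0.5 * maps[0] * t[0]
    tail = maps[-1] / lambda_phys_per_h
    return dose + head + tail


def roi_mean_dose(
    dose_map: np.ndarray,
    labels: np.ndarray,
    roi_code: int,
    injected_activity_mbq: float | None = None,
) -> dict:
    """Mean absorbed dose over an ROI, optionally per injected activity."""
    mask = np.asarray(labels) == roi_code
    if not mask.any():
        raise ValueError(f"empty ROI for code {roi_code}")
    gy = float(np.asarray(dose_map, float)[mask].mean())
    out = {"mean_gy": gy, "engine": DOSE_ENGINE_FLAG,
           "approximations": [DOSE_ENGINE_FLAG]}
    if injected_activity_mbq:
        out["gy_per_mbq"] = gy / injected_activity_mbq
    return out
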