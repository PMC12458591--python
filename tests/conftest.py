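"""Shared fixtures.

The expensive artifacts (Monte Carlo kernel set, synthetic study, pipeline
runs) are session-scoped so the acceptance tests and unit tests share one
computation.
"""
from __future__ import annotations

import numpy as np
import pytest

from cliquant import pipeline as pl
from cliquant import quantify as q
from cliquant import synthdata as sd
from cliquant.csf_mc import simulate_kernel_set
from cliquant.dosimetry import TimeActivityCurve
from cliquant.optics import default_skin_composition, load_bundled_spectra

STUDY_SPACING_MM = 0.4
STUDY_KERNEL_DEPTHS = (2.0, 3.0, 4.0, 5.0, 6.0)
STUDY_KERNEL_HISTORIES = 10_000
STUDY_RL_ITERATIONS = 150


@pytest.fixture(scope="session")
def spectra():
    return load_bundled_spectra()


@pytest.fixture(scope="session")
def skin():
    return default_skin_composition()


@pytest.fixture(scope="session")
def kernel_set():
    """CSF kernels at the synthetic-study pixel size, 10k histories each."""
    return simulate_kernel_set(STUDY_KERNEL_DEPTHS,
                               n_histories=STUDY_KERNEL_HISTORIES,
                               pixel_size_mm=STUDY_SPACING_MM, seed=11)


@pytest.fixture(scope="session")
def calib_curve():
    """Noiseless well plate regenerated and refit (round trip)."""
    wells = sd.generate_wellplate(noise_cv=0.0, background_sd=0.0, seed=1)
    sub = [
        q.WellMeasurement(w.depth_mm, w.activity_mbq,
                          max(w.radiance - q.DEFAULT_BACKGROUND_RADIANCE, 0.0),
                          w.replicate)
        for w in wells
    ]
    return q.fit_depth_calibration(sub)


@pytest.fixture(scope="session")
def study(kernel_set):
    return sd.generate_study(kernel_set, seed=3, spacing_mm=STUDY_SPACING_MM)


@pytest.fixture(scope="session")
def pipeline_config(kernel_set, calib_curve):
    return pl.PipelineConfig(csf_set=kernel_set, curve=calib_curve,
                             register=False,
                             rl_iterations=STUDY_RL_ITERATIONS, seed=3)


@pytest.fixture(scope="session")
def study_results(study, pipeline_config):
    """Both arms of the study: CLI quantification + dose, PET sums + dose."""
    cfg = pipeline_config
    hu, labels = study.hu, study.labels
    sp = study.spacing_mm
    t_arr = np.array(study.timepoints_h)
    liv, tum, tot = [], [], []
    per_tp = []
    for i, t in enumerate(study.timepoints_h[:3]):
        r = pl.run_quantify_pipeline(cfg, study.cli_images[float(t)], hu,
                                     labels, sp, timepoint_h=float(t))
        per_tp.append(r)
        liv.append(r["estimates"]["liver"].activity_mbq)
        tum.append(r["estimates"]["tumor"].activity_mbq)
    for t in study.timepoints_h:
        tot.append(pl.estimate_total_body_activity(
            cfg, study.cli_images[float(t)], hu, labels, sp,
            float(t)).activity_mbq)
    cli_dose = pl.run_dose_pipeline(
        cfg, labels, sp,
        TimeActivityCurve(t_arr[:3], np.array(liv), "Y-86", "liver"),
        TimeActivityCurve(t_arr[:3], np.array(tum), "Y-86", "tumor"),
        TimeActivityCurve(t_arr, np.array(tot), "Y-86", "total"))

    pliv, ptum, ptot = [], [], []
    for i, t in enumerate(study.timepoints_h):
        acts = {"liver": float(study.true_liver.activities_mbq[i]),
                "tumor": float(study.true_tumor.activities_mbq[i]),
                "remainder": float(study.true_remainder.activities_mbq[i])}
        vol = sd.forward_pet_volume(study.labels, acts, blur_fwhm_mm=1.5,
                                    noise_cv=0.05, seed=100 + i,
                                    spacing_mm=sp)
        pliv.append(pl.pet_roi_activity(vol, labels, 2, sp))
        ptum.append(pl.pet_roi_activity(vol, labels, 3, sp))
        ptot.append(float(vol[labels > 0].sum()))
    pet_dose = pl.run_dose_pipeline(
        cfg, labels, sp,
        TimeActivityCurve(t_arr, np.array(pliv), "Y-86", "liver"),
        TimeActivityCurve(t_arr, np.array(ptum), "Y-86", "tumor"),
        TimeActivityCurve(t_arr, np.array(ptot), "Y-86", "total"))
    return {
        "per_timepoint": per_tp,
        "cli_liver_mbq": np.array(liv),
        "cli_tumor_mbq": np.array(tum),
        "cli_total_mbq": np.array(tot),
        "pet_liver_mbq": np.array(pliv),
        "pet_tumor_mbq": np.array(ptum),
        "cli_dose": cli_dose,
        "pet_dose": pet_dose,
    }
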