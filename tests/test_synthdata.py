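import numpy as np
import pytest

import cliquant.synthdata as sd
from cliquant.geometry import DEPTH_AXIS, roi_depth_map


def test_wellplate_structure_and_determinism():
    wells = sd.generate_wellplate(seed=5)
    assert len(wells) == 6 * 5 * 3  # depths x activities x replicates
    again = sd.generate_wellplate(seed=5)
    assert all(a.radiance == b.radiance for a, b in zip(wells, again))
    other = sd.generate_wellplate(seed=6)
    assert any(a.radiance != b.radiance for a, b in zip(wells, other))


def test_wellplate_zero_activity_wells_are_background_only():
    wells = sd.generate_wellplate(noise_cv=0.0, background_sd=0.0, seed=0)
    for w in wells:
        if w.activity_mbq == 0.0:
            assert w.radiance == pytest.approx(sd.DEFAULT_BACKGROUND_RADIANCE)


def test_mouse_phantom_structure():
    hu, labels = sd.generate_mouse_phantom(sd.MousePhantomSpec(spacing_mm=0.4))
    assert hu.shape == labels.shape
    assert set(np.unique(labels)) == {0, 1, 2, 3}
    # organs strictly inside the body
    assert not np.any((labels == 2) & (hu < 0))
    # odd shape with the phantom centered
    assert all(s % 2 == 1 for s in labels.shape)


def test_mouse_phantom_overlap_and_protrusion_errors():
    with pytest.raises(ValueError, match="overlap"):
        sd.generate_mouse_phantom(sd.MousePhantomSpec(
            tumor_center_mm=(0.0, -8.0, -10.0), spacing_mm=0.8))
    with pytest.raises(ValueError, match="protrudes"):
        sd.generate_mouse_phantom(sd.MousePhantomSpec(
            tumor_center_mm=(0.0, -12.0, 3.5), spacing_mm=0.8))


def test_phantom_organ_depths_are_superficial():
    """Liver centroid ~4 mm, tumor centroid ~2-3 mm below the surface."""
    spec = sd.MousePhantomSpec(spacing_mm=0.4)
    hu, labels = sd.generate_mouse_phantom(spec)
    body = labels > 0
    dm_liv = roi_depth_map(body, labels, 2, 0.4)
    dm_tum = roi_depth_map(body, labels, 3, 0.4)
    assert 2.0 < np.nanmean(dm_liv.occupied_depths()) < 5.0
    assert 1.5 < np.nanmean(dm_tum.occupied_depths()) < 4.0


def test_forward_cli_image_noiseless_in_footprint_mean(kernel_set):
    """The containment-rescaled forward model makes the background-subtracted
    in-footprint mean radiance exactly c(depth-weighted) x concentration."""
    spec = sd.MousePhantomSpec(spacing_mm=0.4)
    hu, labels = sd.generate_mouse_phantom(spec)
    body = labels > 0
    dm = roi_depth_map(body, labels, 3, 0.4)
    cfg = sd.ForwardModelConfig(noise_cv=0.0)
    act = 0.8
    img = sd.forward_cli_image(labels, {"tumor": act}, kernel_set, cfg, 0.4)
    sub = img.values - cfg.background_level
    n_pix = int(dm.mask.sum())
    conc = act / sd.MBQ_PER_UCI / (n_pix * (0.04 ** 2))
    c = sd.calibration_coefficient(cfg.curve, dm.depth_mm[dm.mask],
                                   extrapolate=True)
    assert sub[dm.mask].mean() == pytest.approx((c * conc).mean(), rel=1e-9)


def test_forward_cli_image_linear_in_activity(kernel_set):
    spec = sd.MousePhantomSpec(spacing_mm=0.4)
    hu, labels = sd.generate_mouse_phantom(spec)
    cfg = sd.ForwardModelConfig(noise_cv=0.0)
    a = sd.forward_cli_image(labels, {"liver": 1.0}, kernel_set, cfg, 0.4)
    b = sd.forward_cli_image(labels, {"liver": 2.0}, kernel_set, cfg, 0.4)
    np.testing.assert_allclose(b.values - cfg.background_level,
                               2.0 * (a.values - cfg.background_level),
                               rtol=1e-9, atol=1e-6)


def test_forward_pet_volume_conserves_activity():
    labels = np.zeros((50, 50, 50), np.int16)
    labels[12:38, 12:38, 12:38] = 1
    labels[20:25, 20:25, 20:25] = 2
    acts = {"liver": 2.0, "remainder": 3.0}
    vol = sd.forward_pet_volume(labels, acts, blur_fwhm_mm=1.5, noise_cv=0.0,
                                spacing_mm=0.4)
    assert vol.sum() == pytest.approx(5.0, rel=1e-6)
    exact = sd.forward_pet_volume(labels, acts, blur_fwhm_mm=0.0, noise_cv=0.0)
    assert exact[labels == 2].sum() == pytest.approx(2.0, rel=1e-12)
    with pytest.raises(ValueError):
        sd.forward_pet_volume(labels, acts, blur_fwhm_mm=-1.0)


def test_generate_study_structure_and_determinism(kernel_set):
    s1 = sd.generate_study(kernel_set, seed=9, spacing_mm=0.8,
                           timepoints_h=(3.5, 29.0))
    s2 = sd.generate_study(kernel_set, seed=9, spacing_mm=0.8,
                           timepoints_h=(3.5, 29.0))
    assert s1.timepoints_h == (3.5, 29.0)
    for t in s1.timepoints_h:
        np.testing.assert_array_equal(s1.cli_images[t].values,
                                      s2.cli_images[t].values)
    # truth curves conserve the injected activity at t -> 0
    t0 = (s1.true_liver.activities_mbq[0] + s1.true_tumor.activities_mbq[0]
          + s1.true_remainder.activities_mbq[0])
    assert t0 < s1.injected_mbq  # decay + washout by the first timepoint
    assert s1.true_total.activities_mbq[0] == pytest.approx(t0)
    # the camera-view image grid matches the projected CT grid
    planar = tuple(np.delete(np.array(s1.labels.shape), DEPTH_AXIS))
    assert s1.cli_images[3.5].values.shape == planar


def test_study_seed_changes_noise(kernel_set):
    s1 = sd.generate_study(kernel_set, seed=1, spacing_mm=0.8,
                           timepoints_h=(3.5,))
    s2 = sd.generate_study(kernel_set, seed=2, spacing_mm=0.8,
                           timepoints_h=(3.5,))
    assert not np.array_equal(s1.cli_images[3.5].values,
                              s2.cli_images[3.5].values)
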