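import numpy as np
import pytest

import cliquant.dosimetry as dos


def test_nuclear_constants_bundled():
    nc = dos.nuclear_constants()
    assert nc["half_life_h"]["Y-86"] == pytest.approx(14.74, rel=1e-3)
    assert nc["half_life_h"]["Y-90"] == pytest.approx(64.05, rel=1e-3)
    assert nc["mean_beta_energy_mev"]["Y-90"] == pytest.approx(0.9337, rel=1e-3)


def test_tac_validation():
    with pytest.raises(ValueError):
        dos.TimeActivityCurve(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        dos.TimeActivityCurve(np.array([1.0, 2.0]), np.array([1.0, -1.0]))
    with pytest.raises(ValueError):
        dos.TimeActivityCurve(np.array([1.0, 2.0]), np.array([[1.0, 1.0]]))


def test_biexponential_fit_recovers_parameters():
    t = np.array([3.5, 29.0, 52.0, 97.0, 140.0])
    true = (6.0, 0.01, 3.0, 0.08)
    y = dos.biexponential(t, *true)
    fit = dos.fit_biexponential(t, y)
    np.testing.assert_allclose(fit, true, rtol=1e-3)


def test_biexponential_fit_guards():
    with pytest.raises(ValueError):
        dos.fit_biexponential([1.0, 2.0, 3.0], [1.0, 0.5, 0.2])
    with pytest.raises(ValueError):
        dos.fit_biexponential([1.0, 2.0, 3.0, 4.0], [1.0, 0.5, 0.0, 0.1])


def test_remainder_compartment_and_clamp():
    t = np.array([1.0, 2.0])
    total = dos.TimeActivityCurve(t, np.array([10.0, 5.0]), compartment="total")
    liver = dos.TimeActivityCurve(t, np.array([4.0, 3.0]), compartment="liver")
    tumor = dos.TimeActivityCurve(t, np.array([1.0, 3.0]), compartment="tumor")
    with pytest.warns(UserWarning, match="clamped"):
        rem = dos.remainder_compartment(total, liver, tumor)
    np.testing.assert_allclose(rem.activities_mbq, [5.0, 0.0])
    bad = dos.TimeActivityCurve(np.array([1.0, 3.0]), np.array([4.0, 3.0]))
    with pytest.raises(ValueError, match="misaligned"):
        dos.remainder_compartment(total, bad, tumor)


def test_synthesize_activity_volume_conserves_totals():
    labels = np.zeros((10, 10, 10), np.int16)
    labels[2:8, 2:8, 2:8] = 1
    labels[3:5, 3:5, 3:5] = 2
    labels[6:7, 6:7, 6:7] = 3
    acts = {"liver": 2.0, "tumor": 0.5, "remainder": 3.0}
    vol = dos.synthesize_activity_volume(labels, acts)
    assert vol.sum() == pytest.approx(5.5, rel=1e-12)
    assert vol[labels == 2].sum() == pytest.approx(2.0)
    assert vol[labels == 0].sum() == 0.0
    with pytest.raises(ValueError, match="empty"):
        dos.synthesize_activity_volume(np.zeros((3, 3, 3)), {"liver": 1.0})


def test_surrogate_decay_transform_analytic():
    """A(t) = A0 e^{-lam_img t} (pure physical decay) maps to
    A0 e^{-lam_ther t}: biological retention is constant."""
    t = np.array([0.0001, 10.0, 50.0])
    t_img, t_ther = 14.74, 64.05
    lam_img = np.log(2) / t_img
    tac = dos.TimeActivityCurve(t, 7.0 * np.exp(-lam_img * t), "Y-86", "liver")
    out = dos.surrogate_decay_transform(tac, t_img, t_ther)
    lam_ther = np.log(2) / t_ther
    np.testing.assert_allclose(out.activities_mbq, 7.0 * np.exp(-lam_ther * t),
                               rtol=1e-12)
    assert out.isotope == "Y-90"
    with pytest.raises(ValueError):
        dos.surrogate_decay_transform(tac, -1.0, t_ther)


def test_local_deposition_rate_oracle():
    """1 MBq in 1 g of tissue at 0.9337 MeV/decay -> 0.5385 Gy/h."""
    act = np.array([[[1.0]]])
    rho = np.array([[[1.0]]])
    rate = dos.local_deposition_dose_rate(act, rho, voxel_volume_cm3=1.0,
                                          mean_energy_mev_per_decay=0.9337)
    expected = 1e6 * 0.9337 * 1.602e-13 / 1e-3 * 3600.0
    assert rate[0, 0, 0] == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.5385, rel=1e-3)
    with pytest.raises(ValueError):
        dos.local_deposition_dose_rate(act, np.zeros_like(rho), 1.0)


def test_integrate_dose_monoexponential_within_one_percent():
    """Trapezoid + constant head + analytic tail vs the closed form
    R0/lambda for a purely decaying rate sampled at the study timepoints."""
    lam = np.log(2.0) / 64.05
    t = np.array([3.5, 29.0, 52.0, 97.0])
    r0 = 2.0
    maps = [np.full((2, 2), r0 * np.exp(-lam * ti)) for ti in t]
    dose = dos.integrate_absorbed_dose(maps, t, lam)
    closed = r0 / lam
    assert dose[0, 0] == pytest.approx(closed, rel=0.01)


def test_integrate_dose_zero_activity_gives_zero():
    t = np.array([1.0, 10.0])
    maps = [np.zeros((3, 3)), np.zeros((3, 3))]
    dose = dos.integrate_absorbed_dose(maps, t, 0.01)
    assert np.all(dose == 0.0)


def test_integrate_dose_guards():
    t = np.array([1.0, 10.0])
    maps = [np.zeros((2, 2))] * 2
    with pytest.raises(ValueError):
        dos.integrate_absorbed_dose(maps, t, 0.0)
    with pytest.raises(ValueError):
        dos.integrate_absorbed_dose(maps[:1], np.array([1.0]), 0.01)


def test_roi_mean_dose_flags_engine():
    labels = np.zeros((4, 4, 4), np.int16)
    labels[1:3, 1:3, 1:3] = 2
    dose = np.where(labels == 2, 3.0, 0.0)
    out = dos.roi_mean_dose(dose, labels, 2, injected_activity_mbq=9.25)
    assert out["mean_gy"] == pytest.approx(3.0)
    assert out["gy_per_mbq"] == pytest.approx(3.0 / 9.25)
    assert out["engine"] == "local-deposition"
    assert "local-deposition" in out["approximations"]
    with pytest.raises(ValueError):
        dos.roi_mean_dose(dose, labels, 7)
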