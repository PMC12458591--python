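import numpy as np
import pytest

import cliquant.quantify as q
import cliquant.synthdata as sd
from cliquant.geometry import DepthMap


def test_well_measurement_concentration_autocomputed():
    w = q.WellMeasurement(depth_mm=3.0, activity_mbq=0.37, radiance=100.0)
    assert w.concentration_uci_cm2 == pytest.approx(
        0.37 / q.MBQ_PER_UCI / q.WELL_BOTTOM_AREA_CM2)


def test_well_measurement_validation():
    with pytest.raises(ValueError):
        q.WellMeasurement(depth_mm=0.0, activity_mbq=1.0, radiance=1.0)
    with pytest.raises(ValueError):
        q.WellMeasurement(depth_mm=1.0, activity_mbq=-1.0, radiance=1.0)


def test_subtract_background_floor_and_flag():
    vals, flag = q.subtract_background([10.0, 5.0, 1.0], background=4.0)
    np.testing.assert_allclose(vals, [6.0, 1.0, 0.0])
    assert flag is False
    vals, flag = q.subtract_background([1.0, 2.0, 10.0], background=4.0)
    assert flag is True
    with pytest.raises(ValueError):
        q.subtract_background([1.0], background=-1.0)


def test_decay_correct_analytic():
    # one half-life back-corrects by exactly x2
    assert q.decay_correct(5.0, q.Y86_HALF_LIFE_H, q.Y86_HALF_LIFE_H) \
        == pytest.approx(10.0)
    assert q.decay_correct(5.0, 0.0, 10.0) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        q.decay_correct(5.0, 1.0, 0.0)


def test_fit_noiseless_round_trip_recovers_reference_curve():
    """Regenerate a noiseless plate from the reference curve and refit it."""
    ref = sd.reference_calibration_curve()
    wells = sd.generate_wellplate(noise_cv=0.0, background_sd=0.0, seed=0)
    sub = [q.WellMeasurement(w.depth_mm, w.activity_mbq,
                             max(w.radiance - q.DEFAULT_BACKGROUND_RADIANCE, 0.0),
                             w.replicate) for w in wells]
    fit = q.fit_depth_calibration(sub)
    assert fit.intercept == pytest.approx(ref.intercept, rel=1e-6)
    assert fit.slope == pytest.approx(ref.slope, rel=1e-6)
    assert fit.pearson_r == pytest.approx(-1.0, abs=1e-6)
    assert fit.depth_range_mm == pytest.approx(ref.depth_range_mm)


def test_fit_noisy_slope_within_ten_percent():
    """5% multiplicative noise, 3 replicates: the fitted slope stays within
    10% of truth for every seed tried."""
    ref = sd.reference_calibration_curve()
    for seed in range(20):
        wells = sd.generate_wellplate(noise_cv=0.05, seed=seed)
        sub = [q.WellMeasurement(w.depth_mm, w.activity_mbq,
                                 max(w.radiance - q.DEFAULT_BACKGROUND_RADIANCE,
                                     0.0), w.replicate) for w in wells]
        fit = q.fit_depth_calibration(sub)
        assert fit.slope == pytest.approx(ref.slope, rel=0.10)
        assert fit.pearson_r < -0.9


def test_fit_rejects_degenerate_designs():
    # a single depth
    wells = [q.WellMeasurement(2.0, a, 100.0 * a) for a in (0.1, 0.2, 0.4)]
    with pytest.raises(ValueError):
        q.fit_depth_calibration(wells)
    # two depths but only one nonzero activity at one of them
    wells = ([q.WellMeasurement(2.0, a, 100.0 * a) for a in (0.1, 0.2, 0.4)]
             + [q.WellMeasurement(5.0, 0.1, 50.0)])
    with pytest.raises(ValueError, match="5.0"):
        q.fit_depth_calibration(wells)


def test_calibration_coefficient_range_guard():
    c = q.CalibrationCurve(1000.0, -100.0, (2.0, 8.0))
    assert q.calibration_coefficient(c, 5.0) == pytest.approx(500.0)
    with pytest.raises(ValueError, match="extrapolate"):
        q.calibration_coefficient(c, 10.0)
    assert q.calibration_coefficient(c, 9.0, extrapolate=True) \
        == pytest.approx(100.0)


def test_calibration_curve_json_round_trip(tmp_path):
    c = q.CalibrationCurve(9734.2, -613.8, (1.66, 9.93), pearson_r=-0.976,
                           per_depth={1.66: 8700.0})
    p = tmp_path / "curve.json"
    c.to_json(p)
    back = q.CalibrationCurve.from_json(p)
    assert back.intercept == pytest.approx(c.intercept)
    assert back.slope == pytest.approx(c.slope)
    assert back.per_depth == {1.66: 8700.0}


def test_roi_activity_uniform_analytic():
    """Uniform-depth ROI imaged at exactly c(d)*conc recovers the activity."""
    curve = q.CalibrationCurve(9734.2, -613.8, (1.0, 12.0))
    depth = 3.0
    conc = 2.0  # uCi/cm^2
    mask = np.zeros((20, 20), bool)
    mask[5:15, 5:15] = True
    dm = DepthMap(np.where(mask, depth, np.nan), mask, 0.5)
    img = np.where(mask, q.calibration_coefficient(curve, depth) * conc, 0.0)
    pixel_area = 0.05 ** 2
    est = q.roi_activity(img, dm, curve, pixel_area)
    expected_mbq = conc * 100 * pixel_area * q.MBQ_PER_UCI
    assert est.activity_mbq == pytest.approx(expected_mbq, rel=1e-12)
    assert est.uncertainty_mbq == pytest.approx(0.0, abs=1e-12)
    assert not est.below_sensitivity


def test_roi_activity_zero_image_flags_sensitivity():
    curve = q.CalibrationCurve(9734.2, -613.8, (1.0, 12.0))
    mask = np.ones((5, 5), bool)
    dm = DepthMap(np.full((5, 5), 3.0), mask, 0.5)
    est = q.roi_activity(np.zeros((5, 5)), dm, curve, 0.0025)
    assert est.activity_mbq == 0.0
    assert est.below_sensitivity


def test_roi_activity_errors():
    curve = q.CalibrationCurve(9734.2, -613.8, (1.0, 30.0))
    mask = np.ones((5, 5), bool)
    dm = DepthMap(np.full((5, 5), 3.0), mask, 0.5)
    with pytest.raises(ValueError, match="grid"):
        q.roi_activity(np.zeros((4, 4)), dm, curve, 0.0025)
    empty = DepthMap(np.full((5, 5), np.nan), np.zeros((5, 5), bool), 0.5)
    with pytest.raises(ValueError, match="empty"):
        q.roi_activity(np.zeros((5, 5)), empty, curve, 0.0025)
    deep = DepthMap(np.full((5, 5), 25.0), mask, 0.5)  # c(25) < 0
    with pytest.raises(ValueError, match="non-positive"):
        q.roi_activity(np.ones((5, 5)), deep, curve, 0.0025)


def test_wells_csv_round_trip(tmp_path):
    wells = sd.generate_wellplate(seed=2)[:10]
    p = tmp_path / "wells.csv"
    q.wells_to_csv(p, wells)
    back = q.wells_from_csv(p)
    assert len(back) == len(wells)
    for a, b in zip(wells, back):
        assert b.depth_mm == pytest.approx(a.depth_mm)
        assert b.radiance == pytest.approx(a.radiance)
        assert b.concentration_uci_cm2 == pytest.approx(a.concentration_uci_cm2)
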