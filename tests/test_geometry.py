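import numpy as np
import pytest

from cliquant.geometry import (
    DEPTH_AXIS,
    PlanarMask,
    SimilarityTransform2D,
    apply_transform_image,
    body_mask_from_ct,
    coronal_mip,
    load_volume_nifti,
    register_similarity,
    resample_radiance,
    roi_depth_map,
    save_volume_nifti,
    supine_mask_from_prone,
)


def _ellipse_mask(shape, center, semi):
    ii, jj = np.indices(shape, dtype=float)
    return ((ii - center[0]) / semi[0]) ** 2 + \
        ((jj - center[1]) / semi[1]) ** 2 <= 1.0


def test_body_mask_threshold_and_largest_component():
    vol = np.full((20, 20, 20), -1000.0)
    vol[2:10, 2:10, 2:10] = 50.0   # big blob
    vol[15:17, 15:17, 15:17] = 50.0  # small satellite
    m = body_mask_from_ct(vol, -700.0)
    assert m[5, 5, 5] and not m[16, 16, 16]
    with pytest.raises(ValueError):
        body_mask_from_ct(np.full((5, 5, 5), -1000.0))


def test_coronal_mip_projects_depth_axis():
    vol = np.zeros((4, 6, 5), bool)
    vol[1, 3, 2] = True
    mip = coronal_mip(vol, pixel_size_mm=0.5)
    assert mip.mask.shape == (4, 5)
    assert mip.mask[1, 2]
    assert mip.mask.sum() == 1
    assert DEPTH_AXIS == 1


def test_resample_radiance_preserves_mean_level():
    rng = np.random.default_rng(0)
    img = np.full((40, 40), 100.0) + rng.normal(0, 1, (40, 40))
    out = resample_radiance(img, 0.5, 1.0)
    assert out.shape == (20, 20)
    # radiance is per-area: values, not totals, are preserved
    assert out.mean() == pytest.approx(img.mean(), rel=1e-3)
    back = resample_radiance(out, 1.0, 0.5)
    assert back.shape == (40, 40)


def test_depth_map_matches_brute_force():
    rng = np.random.default_rng(1)
    shape = (50, 50, 50)
    spacing = 0.4
    ii, jj, kk = np.indices(shape, dtype=float)
    body = ((ii - 25) / 20) ** 2 + ((jj - 25) / 22) ** 2 + \
        ((kk - 25) / 24) ** 2 <= 1.0
    labels = np.zeros(shape, int)
    labels[body] = 1
    roi = body & (((ii - 25) / 6) ** 2 + ((jj - 28) / 5) ** 2 +
                  ((kk - 22) / 7) ** 2 <= 1.0)
    labels[roi] = 2
    dm = roi_depth_map(body, labels, 2, spacing)

    # independent brute-force reference: depth axis is axis 1, camera at
    # index 0; surface is the first body voxel along the column
    expect = np.full((shape[0], shape[2]), np.nan)
    for a in range(shape[0]):
        for c in range(shape[2]):
            col_roi = np.nonzero(labels[a, :, c] == 2)[0]
            if col_roi.size == 0:
                continue
            col_body = np.nonzero(body[a, :, c])[0]
            surf = col_body[0]
            expect[a, c] = (col_roi - surf).mean() * spacing
    mask_expect = ~np.isnan(expect)
    np.testing.assert_array_equal(dm.mask, mask_expect)
    np.testing.assert_allclose(dm.depth_mm[dm.mask], expect[mask_expect])


def test_depth_map_roi_outside_body_errors():
    body = np.zeros((10, 10, 10), bool)
    body[2:8, 2:8, 2:8] = True
    labels = np.zeros((10, 10, 10), int)
    labels[0, 0, 0] = 2
    with pytest.raises(ValueError):
        roi_depth_map(body, labels, 2, 1.0)


def test_registration_recovers_translation():
    shape = (120, 140)
    fixed = PlanarMask(_ellipse_mask(shape, (60, 70), (30, 40)), 1.0)
    moving = PlanarMask(_ellipse_mask(shape, (68, 64), (30, 40)), 1.0)
    tr = register_similarity(fixed, moving, iterations=200)
    out = apply_transform_image(moving.mask.astype(float), tr, 1.0) > 0.5
    inter = (out & fixed.mask).sum()
    dice = 2 * inter / (out.sum() + fixed.mask.sum())
    assert dice > 0.98
    assert tr.scale == pytest.approx(1.0, abs=0.05)
    assert abs(tr.rotation_rad) < 0.1


def test_registration_recovers_scale():
    shape = (120, 140)
    fixed = PlanarMask(_ellipse_mask(shape, (60, 70), (33, 44)), 1.0)
    moving = PlanarMask(_ellipse_mask(shape, (60, 70), (30, 40)), 1.0)
    tr = register_similarity(fixed, moving, iterations=200)
    out = apply_transform_image(moving.mask.astype(float), tr, 1.0) > 0.5
    dice = 2 * (out & fixed.mask).sum() / (out.sum() + fixed.mask.sum())
    assert dice > 0.97


def test_transform_json_round_trip(tmp_path):
    tr = SimilarityTransform2D(scale=1.1, rotation_rad=0.2,
                               translation_mm=(3.0, -4.0))
    p = tmp_path / "t.json"
    tr.to_json(p)
    tr2 = SimilarityTransform2D.from_json(p)
    assert tr2.scale == tr.scale
    assert tr2.rotation_rad == tr.rotation_rad
    assert tr2.translation_mm == tr.translation_mm


def test_supine_flip_involution():
    rng = np.random.default_rng(2)
    vol = rng.random((6, 7, 8)) > 0.5
    flipped = supine_mask_from_prone(vol)
    assert flipped.shape == vol.shape
    np.testing.assert_array_equal(supine_mask_from_prone(flipped), vol)
    # longitudinal axis untouched
    assert flipped.sum(axis=(0, 1)) == pytest.approx(vol.sum(axis=(0, 1)))


def test_nifti_round_trip(tmp_path):
    vol = np.arange(24, dtype=np.float32).reshape(2, 3, 4)
    p = tmp_path / "v.nii.gz"
    save_volume_nifti(p, vol, 0.4)
    back, spacing = load_volume_nifti(p)
    np.testing.assert_array_equal(back, vol)
    assert spacing == pytest.approx(0.4)
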