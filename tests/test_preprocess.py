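"""Preprocessing chain: reading, bounding box, crop, slice filter,
normalization, resampling and patient splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from incunet import (
    BrainBBox,
    CropSpec,
    MODALITIES,
    MultiModalVolume,
    PhantomSpec,
    centered_crop_spec,
    compute_brain_bbox,
    crop_to_fixed,
    filter_tumor_slices,
    generate_phantom_volume,
    normalize_intensity,
    read_patient,
    resample_slice,
    split_patients,
    whole_tumor_mask,
    write_patient,
)


def _manual_volume(shape=(16, 16, 4), labels=None, t1=None):
    grids = {m: np.zeros(shape) for m in MODALITIES}
    if t1 is not None:
        grids["T1"] = t1
    if labels is None:
        labels = np.zeros(shape, dtype=np.int16)
    return MultiModalVolume("manual", grids, labels)


# -- reading ------------------------------------------------------------------


def test_read_missing_modality_names_it(tmp_path, phantom_volume):
    pdir = write_patient(phantom_volume, tmp_path)
    (pdir / f"{phantom_volume.patient_id}_flair.nii.gz").unlink()
    with pytest.raises(FileNotFoundError, match="FLAIR"):
        read_patient(pdir)


def test_read_rejects_illegal_label(tmp_path, phantom_volume):
    import nibabel as nib

    pdir = write_patient(phantom_volume, tmp_path)
    bad = phantom_volume.labels.copy()
    bad[0, 0, 0] = 3
    nib.save(nib.Nifti1Image(bad.astype(np.int16), np.eye(4)),
             pdir / f"{phantom_volume.patient_id}_seg.nii.gz")
    with pytest.raises(ValueError, match="labels outside"):
        read_patient(pdir)


# -- brain bbox ---------------------------------------------------------------


def _bbox_oracle(volume):
    """Brute-force per-pixel scan, independent of the implementation."""
    rmin = cmin = 10**9
    rmax = cmax = -1
    h, w, s = volume.shape
    for r in range(h):
        for c in range(w):
            for k in range(s):
                if any(volume.modalities[m][r, c, k] != 0 for m in MODALITIES):
                    rmin, rmax = min(rmin, r), max(rmax, r)
                    cmin, cmax = min(cmin, c), max(cmax, c)
    return BrainBBox(rmin, rmax, cmin, cmax)


def test_bbox_matches_brute_force_scan(phantom_volume):
    assert compute_brain_bbox(phantom_volume) == _bbox_oracle(phantom_volume)


def test_bbox_single_voxel():
    t1 = np.zeros((16, 20, 4))
    t1[10, 17, 2] = 1.0
    vol = _manual_volume((16, 20, 4), t1=t1)
    assert compute_brain_bbox(vol) == BrainBBox(10, 10, 17, 17)


def test_bbox_all_zero_errors():
    with pytest.raises(ValueError, match="no brain tissue"):
        compute_brain_bbox(_manual_volume())


# -- cropping -----------------------------------------------------------------


def test_crop_240_to_176_reduces_voxels_46_percent():
    spec = PhantomSpec(volume_shape=(240, 240, 4), brain_radius_frac=0.5,
                       tumor_radii=(8, 4, 2), tumor_center=(120, 120, 2), seed=0)
    vol = generate_phantom_volume(spec)
    crop = centered_crop_spec((240, 240), (176, 176))
    assert crop.offsets == (32, 32)
    cropped = crop_to_fixed(vol, crop)
    assert cropped.shape == (176, 176, 4)
    per_slice_before = 240 * 240
    per_slice_after = 176 * 176
    assert per_slice_before == 57600 and per_slice_after == 30976
    reduction = 1 - per_slice_after / per_slice_before
    assert reduction == pytest.approx(0.46222, abs=5e-6)


def test_crop_identity_window(phantom_volume):
    crop = CropSpec(in_size=(64, 64), out_size=(64, 64), offsets=(0, 0))
    out = crop_to_fixed(phantom_volume, crop)
    assert np.array_equal(out.labels, phantom_volume.labels)


def test_crop_refuses_to_discard_brain():
    t1 = np.zeros((64, 64, 2))
    t1[5, 30, 0] = 1.0  # brain touches row 5, window starts at row 16
    t1[30:40, 30:40, :] = 1.0
    vol = _manual_volume((64, 64, 2), t1=t1)
    crop = CropSpec(in_size=(64, 64), out_size=(32, 32), offsets=(16, 16))
    with pytest.raises(ValueError, match="outside crop window"):
        crop_to_fixed(vol, crop)


def test_crop_never_discards_brain_voxels():
    spec = PhantomSpec(volume_shape=(64, 64, 8), brain_radius_frac=0.6,
                       tumor_radii=(4, 2, 1), tumor_center=(32, 32, 4), seed=1)
    vol = generate_phantom_volume(spec)
    crop = centered_crop_spec((64, 64), (48, 48))
    cropped = crop_to_fixed(vol, crop)
    assert cropped.brain_support().sum() == vol.brain_support().sum()


def test_crop_spec_validates_window():
    with pytest.raises(ValueError):
        CropSpec(in_size=(64, 64), out_size=(48, 48), offsets=(20, 20))


# -- tumor slice filtering ----------------------------------------------------


def test_filter_count_matches_slice_scan(phantom_volume):
    samples = filter_tumor_slices(phantom_volume)
    expected = [k for k in range(phantom_volume.shape[2])
                if phantom_volume.labels[:, :, k].any()]
    assert [s.slice_index for s in samples] == expected
    for s in samples:
        assert s.image.shape == (4, 64, 64)
        assert set(np.unique(s.mask)) <= {0, 1}


def test_filter_tumor_free_volume_is_empty():
    assert filter_tumor_slices(_manual_volume()) == []


def test_filter_every_slice_tumor():
    labels = np.full((8, 8, 16), 2, dtype=np.int16)
    vol = _manual_volume((8, 8, 16), labels=labels, t1=np.ones((8, 8, 16)))
    assert len(filter_tumor_slices(vol)) == 16


def test_whole_tumor_mask_definition():
    labels = np.array([0, 1, 2, 4])
    assert whole_tumor_mask(labels).tolist() == [0, 1, 1, 1]
    assert not whole_tumor_mask(np.zeros(5, dtype=int)).any()


def test_whole_tumor_mask_count_equals_nonzero_labels(phantom_volume):
    assert whole_tumor_mask(phantom_volume.labels).sum() == (phantom_volume.labels > 0).sum()


# -- normalization ------------------------------------------------------------


def test_normalize_brain_moments(phantom_volume):
    nv = normalize_intensity(phantom_volume)
    for m in MODALITIES:
        orig = phantom_volume.modalities[m]
        mask = orig != 0
        vals = nv.modalities[m][mask]
        assert abs(vals.mean()) < 1e-6
        assert abs(vals.std() - 1.0) < 1e-6
        assert not nv.modalities[m][~mask].any()  # background stays exactly 0


def test_normalize_constant_brain_yields_zeros():
    t1 = np.zeros((8, 8, 2))
    t1[2:6, 2:6, :] = 3.7
    nv = normalize_intensity(_manual_volume((8, 8, 2), t1=t1))
    assert not nv.modalities["T1"].any()


# -- resampling ---------------------------------------------------------------


@pytest.mark.parametrize("method", ["linear", "cubic"])
def test_resample_identity_and_constant(method):
    rng = np.random.default_rng(0)
    img = rng.normal(size=(9, 7))
    np.testing.assert_allclose(resample_slice(img, (9, 7), method), img, atol=1e-9)
    const = np.full((5, 5), 2.5)
    np.testing.assert_allclose(resample_slice(const, (11, 8), method), 2.5, atol=1e-9)


def test_linear_upsample_hits_arithmetic_means():
    ramp = np.array([[0.0, 1.0], [2.0, 3.0]])
    out = resample_slice(ramp, (3, 3), "linear")
    expected = np.array([[0.0, 0.5, 1.0], [1.0, 1.5, 2.0], [2.0, 2.5, 3.0]])
    np.testing.assert_allclose(out, expected, atol=1e-12)


def test_resample_unknown_method():
    with pytest.raises(ValueError, match="method"):
        resample_slice(np.zeros((4, 4)), (8, 8), "sinc")


# -- splitting ----------------------------------------------------------------


def test_split_335_into_235_50_50():
    ids = [f"p{i:03d}" for i in range(335)]
    split = split_patients(ids, (235, 50, 50), seed=4)
    assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) == (235, 50, 50)
    union = set(split.train_ids) | set(split.val_ids) | set(split.test_ids)
    assert union == set(ids)


def test_split_deterministic():
    ids = [f"p{i}" for i in range(20)]
    assert split_patients(ids, (10, 5, 5), seed=1) == split_patients(ids, (10, 5, 5), seed=1)


def test_split_bad_sizes():
    with pytest.raises(ValueError, match="sum"):
        split_patients([f"p{i}" for i in range(335)], (300, 50, 50), seed=0)


@settings(max_examples=25, deadline=None)
@given(st.integers(5, 40), st.integers(0, 2**31 - 1), st.data())
def test_split_is_partition(n, seed, data):
    n_train = data.draw(st.integers(1, n - 2))
    n_val = data.draw(st.integers(1, n - n_train - 1))
    ids = [f"p{i}" for i in range(n)]
    split = split_patients(ids, (n_train, n_val, n - n_train - n_val), seed=seed)
    parts = [set(split.train_ids), set(split.val_ids), set(split.test_ids)]
    assert sum(len(p) for p in parts) == n
    assert set.union(*parts) == set(ids)
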