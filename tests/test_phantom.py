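"""Phantom generator: determinism, label nesting, contrast semantics, IO."""

import numpy as np
import pytest

from incunet import (
    MODALITIES,
    MultiModalVolume,
    PhantomSpec,
    PhantomSpecError,
    default_spec_sampler,
    generate_phantom_cohort,
    generate_phantom_volume,
    read_patient,
    write_patient,
)


def test_same_spec_and_seed_is_bit_identical(phantom_volume):
    spec = PhantomSpec(volume_shape=(64, 64, 16), tumor_radii=(5.0, 3.0, 1.5),
                       tumor_center=(32, 32, 8), noise_sigma=0.02, seed=7)
    again = generate_phantom_volume(spec, patient_id="fixture-000")
    assert np.array_equal(again.labels, phantom_volume.labels)
    for m in MODALITIES:
        assert np.array_equal(again.modalities[m], phantom_volume.modalities[m])


def test_zero_tumor_radii_gives_empty_labels():
    spec = PhantomSpec(volume_shape=(32, 32, 8), tumor_radii=(0, 0, 0), seed=1)
    vol = generate_phantom_volume(spec)
    assert not vol.labels.any()


def test_tumor_slice_span_matches_per_slice_scan():
    """A radius-15 tumor sphere centered at slice 75 labels slices 60..90."""
    spec = PhantomSpec(volume_shape=(64, 64, 155), tumor_radii=(15, 9, 4),
                       tumor_center=(32, 32, 75), noise_sigma=0.0, seed=0)
    vol = generate_phantom_volume(spec)
    # independent brute-force scan over slices
    with_tumor = [k for k in range(155) if vol.labels[:, :, k].any()]
    assert with_tumor == list(range(60, 91))
    assert len(with_tumor) == 31


def test_label_regions_are_nested(phantom_volume):
    labels = phantom_volume.labels
    enhancing = labels == 4
    core_region = np.isin(labels, (1, 4))
    whole = labels > 0
    assert (enhancing <= core_region).all()
    assert (core_region <= whole).all()
    assert enhancing.sum() > 0 and core_region.sum() > enhancing.sum()


def test_tumor_voxels_lie_inside_brain_support(phantom_volume):
    support = phantom_volume.brain_support()
    assert support[phantom_volume.labels > 0].all()


def test_modality_contrast_ordering():
    spec = PhantomSpec(volume_shape=(48, 48, 12), tumor_radii=(6, 4, 2),
                       tumor_center=(24, 24, 6), noise_sigma=0.001, seed=2)
    vol = generate_phantom_volume(spec)
    labels, support = vol.labels, vol.brain_support()
    edema, brain = labels == 2, support & (labels == 0)
    core, enh = labels == 1, labels == 4
    for m in ("T2", "FLAIR"):
        assert vol.modalities[m][edema].mean() > vol.modalities[m][brain].mean()
    assert vol.modalities["T1ce"][enh].mean() > vol.modalities["T1ce"][core].mean()


def test_tumor_outside_brain_is_rejected():
    spec = PhantomSpec(volume_shape=(32, 32, 8), tumor_radii=(6, 3, 1),
                       tumor_center=(2, 2, 4), seed=0)
    with pytest.raises(PhantomSpecError, match="outside the brain"):
        generate_phantom_volume(spec)


def test_non_increasing_radii_enforced():
    with pytest.raises(PhantomSpecError, match="non-increasing"):
        PhantomSpec(tumor_radii=(5, 8, 2))


def test_cohort_is_reproducible_with_distinct_ids():
    sampler = default_spec_sampler(volume_shape=(24, 24, 12), tumor_slice_frac=0.4)
    a = generate_phantom_cohort(3, sampler, seed=11)
    b = generate_phantom_cohort(3, sampler, seed=11)
    assert len({v.patient_id for v in a}) == 3
    for va, vb in zip(a, b):
        assert va.patient_id == vb.patient_id
        assert np.array_equal(va.labels, vb.labels)


def test_cohort_with_certain_tumors_has_tumor_everywhere():
    sampler = default_spec_sampler(volume_shape=(24, 24, 12), tumor_slice_frac=0.4,
                                   tumor_prob=1.0)
    for vol in generate_phantom_cohort(3, sampler, seed=5):
        assert vol.labels.any()


def test_cohort_tumor_slice_fraction_is_controllable():
    """The default sampler targets the stated fraction of tumor-bearing slices."""
    sampler = default_spec_sampler(volume_shape=(48, 48, 64), tumor_slice_frac=0.43)
    cohort = generate_phantom_cohort(6, sampler, seed=9)
    total = with_tumor = 0
    for vol in cohort:
        for k in range(vol.shape[2]):
            total += 1
            with_tumor += bool(vol.labels[:, :, k].any())
    assert with_tumor / total == pytest.approx(0.43, abs=0.06)


def test_invalid_n_patients():
    with pytest.raises(ValueError):
        generate_phantom_cohort(0, seed=0)


def test_nifti_round_trip(tmp_path, phantom_volume):
    pdir = write_patient(phantom_volume, tmp_path)
    back = read_patient(pdir)
    assert back.patient_id == phantom_volume.patient_id
    assert np.array_equal(back.labels, phantom_volume.labels)
    for m in MODALITIES:  # float32 on disk
        np.testing.assert_allclose(back.modalities[m], phantom_volume.modalities[m],
                                   atol=1e-6)


def test_volume_rejects_bad_labels():
    grids = {m: np.ones((4, 4, 2)) for m in MODALITIES}
    labels = np.zeros((4, 4, 2), dtype=np.int16)
    labels[0, 0, 0] = 3
    with pytest.raises(ValueError, match=r"labels outside"):
        MultiModalVolume("p0", grids, labels)
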