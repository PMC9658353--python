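"""Shared fixtures: small, seeded phantom data generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from incunet import (
    PhantomSpec,
    default_spec_sampler,
    generate_phantom_cohort,
    generate_phantom_volume,
    prepare_volume,
    filter_tumor_slices,
)

SMALL_SHAPE = (24, 24, 16)


@pytest.fixture(scope="session")
def phantom_volume():
    """One 64x64x16 phantom with a centered three-region tumor."""
    spec = PhantomSpec(
        volume_shape=(64, 64, 16),
        tumor_radii=(5.0, 3.0, 1.5),
        tumor_center=(32, 32, 8),
        noise_sigma=0.02,
        seed=7,
    )
    return generate_phantom_volume(spec, patient_id="fixture-000")


@pytest.fixture(scope="session")
def small_cohort():
    """Four small tumor-bearing patients for pipeline-level tests."""
    sampler = default_spec_sampler(volume_shape=SMALL_SHAPE, tumor_slice_frac=0.6,
                                   noise_sigma=0.02)
    return generate_phantom_cohort(4, sampler, seed=3)


@pytest.fixture(scope="session")
def seg_dataset(small_cohort):
    """Stacked tumor-bearing slices (X: (n,4,24,24), y: (n,24,24))."""
    X, y = [], []
    for vol in small_cohort:
        pv = prepare_volume(vol, crop_size=None)
        for s in filter_tumor_slices(pv):
            X.append(s.image)
            y.append(s.mask)
    X, y = np.stack(X), np.stack(y)
    return X[:20], y[:20]
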