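"""BraTS-layout reading and the preprocessing chain.

Stages, in the order a training run applies them: read the four modality
volumes plus segmentation, validate the brain bounding box against a fixed
crop window (the per-sample "brute force" check that no brain voxel is
discarded), crop 240x240 slices to 176x176, keep only axial slices whose
label mask is nonzero, z-score intensities over brain voxels, and split the
cohort patient-wise into train/validation/test.
"""

from __future__ import annotations

import dataclasses
import pathlib
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .phantom import MODALITIES, VALID_LABELS, MultiModalVolume, _FILE_SUFFIXES

__all__ = [
    "BrainBBox",
    "CropSpec",
    "SliceSample",
    "DatasetSplit",
    "read_patient",
    "compute_brain_bbox",
    "centered_crop_spec",
    "crop_to_fixed",
    "filter_tumor_slices",
    "whole_tumor_mask",
    "normalize_intensity",
    "resample_slice",
    "split_patients",
]


@dataclasses.dataclass(frozen=True)
class BrainBBox:
    """Inclusive min/max nonzero row and column over all slices & modalities."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int


@dataclasses.dataclass(frozen=True)
class CropSpec:
    """Fixed 2D crop window: 0-based offsets, half-open [offset, offset+size)."""

    in_size: tuple[int, int]
    out_size: tuple[int, int]
    offsets: tuple[int, int]

    def __post_init__(self):
        for o, s, i in zip(self.offsets, self.out_size, self.in_size):
            if o < 0 or s <= 0 or o + s > i:
                raise ValueError(f"crop window {self} does not fit inside input")


@dataclasses.dataclass
class SliceSample:
    """One 2D training example: stacked modality channels + binary mask."""

    image: np.ndarray  # (4, H, W), channel order T1, T2, T1ce, FLAIR
    mask: np.ndarray  # (H, W) in {0, 1}
    patient_id: str
    slice_index: int

    def __post_init__(self):
        if self.image.shape[1:] != self.mask.shape:
            raise ValueError("image and mask spatial shapes differ")
        vals = set(np.unique(self.mask).tolist())
        if not vals <= {0, 1}:
            raise ValueError(f"mask is not binary: {sorted(vals)}")


@dataclasses.dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sum(len(s) for s in sets) != len(set.union(*sets)):
            raise ValueError("split lists are not pairwise disjoint")


def read_patient(dir_path: str | pathlib.Path) -> MultiModalVolume:
    """Read one BraTS-layout patient directory into a validated volume.

    Expects ``<id>_t1 / _t2 / _t1ce / _flair / _seg`` NIfTI files (``.nii``
    or ``.nii.gz``).  Missing modalities, shape mismatches and labels outside
    {0,1,2,4} are rejected with explicit diagnostics.
    """
    dir_path = pathlib.Path(dir_path)
    patient_id = dir_path.name
    grids: dict[str, np.ndarray] = {}
    spacing = (1.0, 1.0, 1.0)
    for mod, suffix in _FILE_SUFFIXES.items():
        path = _find_nifti(dir_path, suffix)
        if path is None:
            raise FileNotFoundError(f"{patient_id}: missing {mod} file (*_{suffix}.nii[.gz])")
        img = nib.load(str(path))
        grids[mod] = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    seg_path = _find_nifti(dir_path, "seg")
    if seg_path is None:
        raise FileNotFoundError(f"{patient_id}: missing segmentation file (*_seg.nii[.gz])")
    labels = np.asarray(nib.load(str(seg_path)).dataobj)
    labels = np.rint(labels).astype(np.int16)
    # MultiModalVolume validates shapes and the {0,1,2,4} label alphabet
    return MultiModalVolume(patient_id=patient_id, modalities=grids, labels=labels,
                            voxel_spacing=spacing)


def _find_nifti(dir_path: pathlib.Path, suffix: str) -> pathlib.Path | None:
    for ext in (".nii.gz", ".nii"):
        matches = sorted(dir_path.glob(f"*_{suffix}{ext}"))
        if matches:
            return matches[0]
    return None


def compute_brain_bbox(volume: MultiModalVolume) -> BrainBBox:
    """Scan every slice and modality for the extreme nonzero rows/columns.

    This is the exhaustive check that locates the first and last pixels
    containing brain tissue in both image directions, taken over the union
    of all modalities.
    """
    support = volume.brain_support()
    flat = support.any(axis=2)  # collapse slices: (H, W)
    rows = np.flatnonzero(flat.any(axis=1))
    cols = np.flatnonzero(flat.any(axis=0))
    if rows.size == 0:
        raise ValueError(f"{volume.patient_id}: no brain tissue (all-zero volume)")
    return BrainBBox(int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1]))


def centered_crop_spec(in_size: tuple[int, int], out_size: tuple[int, int]) -> CropSpec:
    """Centered window, e.g. 240x240 -> 176x176 has offsets (32, 32)."""
    offsets = tuple((i - o) // 2 for i, o in zip(in_size, out_size))
    return CropSpec(in_size=in_size, out_size=out_size, offsets=offsets)


def crop_to_fixed(volume: MultiModalVolume, crop: CropSpec) -> MultiModalVolume:
    """Crop all modality and label grids to the fixed window.

    Refuses (rather than silently truncating) whenever the brain bounding
    box extends outside the window, so no brain voxel is ever discarded.
    """
    h, w = volume.shape[:2]
    if (h, w) != tuple(crop.in_size):
        raise ValueError(f"crop expects in-plane size {crop.in_size}, volume has {(h, w)}")
    bbox = compute_brain_bbox(volume)
    (r0, c0), (rh, cw) = crop.offsets, crop.out_size
    if bbox.row_min < r0 or bbox.row_max >= r0 + rh or bbox.col_min < c0 or bbox.col_max >= c0 + cw:
        raise ValueError(
            f"{volume.patient_id}: brain bbox {bbox} extends outside crop window "
            f"rows [{r0},{r0 + rh}) cols [{c0},{c0 + cw})"
        )
    sl = (slice(r0, r0 + rh), slice(c0, c0 + cw))
    return MultiModalVolume(
        patient_id=volume.patient_id,
        modalities={m: g[sl] for m, g in volume.modalities.items()},
        labels=volume.labels[sl],
        voxel_spacing=volume.voxel_spacing,
    )


def whole_tumor_mask(labels: np.ndarray) -> np.ndarray:
    """Binary whole-tumor mask: 1 where label is in {1, 2, 4}, else 0."""
    return np.isin(labels, (1, 2, 4)).astype(np.uint8)


def filter_tumor_slices(volume: MultiModalVolume) -> list[SliceSample]:
    """Keep exactly the axial slices whose label mask has >= 1 tumor voxel.

    Each kept slice is paired with its binary whole-tumor mask and the four
    modality channels stacked in the order T1, T2, T1ce, FLAIR.
    """
    samples: list[SliceSample] = []
    wt = whole_tumor_mask(volume.labels)
    for k in range(volume.shape[2]):
        if wt[:, :, k].any():
            image = np.stack([volume.modalities[m][:, :, k] for m in MODALITIES])
            samples.append(
                SliceSample(image=image, mask=wt[:, :, k], patient_id=volume.patient_id,
                            slice_index=k)
            )
    return samples


def normalize_intensity(volume: MultiModalVolume, eps: float = 1e-8) -> MultiModalVolume:
    """Per-volume, per-modality z-score over nonzero (brain) voxels.

    Background voxels stay exactly 0; a near-constant modality (sigma < eps)
    is zeroed rather than divided by ~0.
    """
    out: dict[str, np.ndarray] = {}
    for mod, grid in volume.modalities.items():
        mask = grid != 0
        new = np.zeros_like(grid)
        if mask.any():
            vals = grid[mask]
            sigma = vals.std()
            if sigma >= eps:
                new[mask] = (vals - vals.mean()) / sigma
        out[mod] = new
    return MultiModalVolume(
        patient_id=volume.patient_id, modalities=out, labels=volume.labels.copy(),
        voxel_spacing=volume.voxel_spacing,
    )


_INTERP_ORDER = {"linear": 1, "cubic": 3}


def resample_slice(image: np.ndarray, out_size: tuple[int, int], method: str = "linear") -> np.ndarray:
    """Resample a 2D image to ``out_size`` by linear or cubic interpolation.

    Samples on an endpoint-aligned grid (corners map to corners), so the
    identity size returns the input values unchanged and a linear upsample
    of a ramp hits exact arithmetic means at midpoints.
    """
    if method not in _INTERP_ORDER:
        raise ValueError(f"method must be one of {sorted(_INTERP_ORDER)}, got {method!r}")
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    ho, wo = out_size
    rows = np.linspace(0, h - 1, ho)
    cols = np.linspace(0, w - 1, wo)
    grid = np.stack(np.meshgrid(rows, cols, indexing="ij"))
    return ndimage.map_coordinates(image, grid, order=_INTERP_ORDER[method], mode="nearest")


def split_patients(patient_ids: Sequence[str], sizes: tuple[int, int, int], seed: int) -> DatasetSplit:
    """Seeded shuffle then partition into train/validation/test id lists."""
    ids = list(patient_ids)
    if sum(sizes) != len(ids):
        raise ValueError(f"sizes {sizes} sum to {sum(sizes)} but cohort has {len(ids)} patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_train, n_val, n_test = sizes
    return DatasetSplit(
        train_ids=tuple(shuffled[:n_train]),
        val_ids=tuple(shuffled[n_train : n_train + n_val]),
        test_ids=tuple(shuffled[n_train + n_val :]),
        seed=seed,
    )
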