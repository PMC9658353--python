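"""Synthetic multi-modal brain MRI phantoms with BraTS-style tumor labels.

A phantom is an ellipsoidal "brain" inside a 3D grid, containing up to three
concentric spherical tumor sub-regions that follow the BraTS label taxonomy:
peritumoral edema (label 2), necrotic/non-enhancing core (label 1) and
enhancing tumor (label 4), nested enhancing ⊆ core ⊆ whole tumor.  Modality
contrast follows MRI semantics: edema is brighter than normal brain on the
T2-weighted and FLAIR channels (water-sensitive sequences), and the enhancing
rim is brighter than the core on the gadolinium-contrast T1ce channel.

Everything is deterministic given ``(spec, seed)``; no real data is needed to
exercise the preprocessing, training and evaluation stages downstream.
"""

from __future__ import annotations

import dataclasses
import pathlib
from typing import Callable, Mapping, Sequence

import nibabel as nib
import numpy as np

MODALITIES = ("T1", "T2", "T1ce", "FLAIR")
REGIONS = ("background", "brain", "edema", "core", "enhancing")

#: Per-modality mean intensity (arbitrary units) for each tissue region.
#: Encodes the modality semantics asserted by the phantom invariants.
DEFAULT_CONTRAST: dict[str, dict[str, float]] = {
    "T1": {"background": 0.0, "brain": 0.50, "edema": 0.42, "core": 0.38, "enhancing": 0.45},
    "T2": {"background": 0.0, "brain": 0.40, "edema": 0.75, "core": 0.55, "enhancing": 0.50},
    "T1ce": {"background": 0.0, "brain": 0.50, "edema": 0.45, "core": 0.40, "enhancing": 0.95},
    "FLAIR": {"background": 0.0, "brain": 0.40, "edema": 0.80, "core": 0.60, "enhancing": 0.55},
}

LABEL_EDEMA = 2
LABEL_CORE = 1
LABEL_ENHANCING = 4
VALID_LABELS = frozenset({0, 1, 2, 4})


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is inconsistent."""


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic patient volume.

    ``tumor_radii`` are voxel radii of the whole-tumor, core and enhancing
    spheres (non-increasing); ``tumor_center`` is either voxel coordinates or
    ``"random"`` for a seeded draw inside the brain.
    """

    volume_shape: tuple[int, int, int] = (240, 240, 155)
    # 0.70 of the half-width keeps the whole brain inside the 176/240 = 73%
    # centered crop window with a safety margin
    brain_radius_frac: float = 0.70
    tumor_center: tuple[int, int, int] | str = "random"
    tumor_radii: tuple[float, float, float] = (30.0, 18.0, 9.0)
    contrast_table: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: DEFAULT_CONTRAST
    )
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        whole, core, enh = self.tumor_radii
        if not (whole >= core >= enh >= 0):
            raise PhantomSpecError(
                f"tumor radii must be non-increasing whole>=core>=enhancing>=0, got {self.tumor_radii}"
            )
        if not 0 < self.brain_radius_frac <= 1:
            raise PhantomSpecError("brain_radius_frac must lie in (0, 1]")
        for mod in MODALITIES:
            if mod not in self.contrast_table:
                raise PhantomSpecError(f"contrast_table missing modality {mod!r}")
        ct = self.contrast_table
        if not (ct["T2"]["edema"] > ct["T2"]["brain"] and ct["FLAIR"]["edema"] > ct["FLAIR"]["brain"]):
            raise PhantomSpecError("edema must be brighter than brain on T2 and FLAIR")
        if not ct["T1ce"]["enhancing"] > ct["T1ce"]["core"]:
            raise PhantomSpecError("enhancing rim must be brighter than core on T1ce")


@dataclasses.dataclass
class MultiModalVolume:
    """One patient: four co-registered modality grids plus a label grid."""

    patient_id: str
    modalities: dict[str, np.ndarray]
    labels: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        shapes = {m: g.shape for m, g in self.modalities.items()}
        if set(self.modalities) != set(MODALITIES):
            raise ValueError(f"expected modalities {MODALITIES}, got {tuple(self.modalities)}")
        if len(set(shapes.values())) != 1 or self.labels.shape not in set(shapes.values()):
            raise ValueError(f"modality/label shapes disagree: {shapes}, labels {self.labels.shape}")
        found = set(np.unique(self.labels).tolist())
        if not found <= VALID_LABELS:
            raise ValueError(f"labels outside {{0,1,2,4}}: {sorted(found - VALID_LABELS)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def brain_support(self) -> np.ndarray:
        """Union of nonzero voxels over all modalities."""
        support = np.zeros(self.shape, dtype=bool)
        for grid in self.modalities.values():
            support |= grid != 0
        return support


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / max(a, 1e-12)) ** 2
    return acc <= 1.0


def _brain_mask(spec: PhantomSpec) -> np.ndarray:
    h, w, s = spec.volume_shape
    center = ((h - 1) / 2, (w - 1) / 2, (s - 1) / 2)
    semi = (spec.brain_radius_frac * h / 2, spec.brain_radius_frac * w / 2, 0.95 * s / 2)
    return _ellipsoid_mask(spec.volume_shape, center, semi)


def generate_phantom_volume(spec: PhantomSpec, patient_id: str = "phantom-000") -> MultiModalVolume:
    """Generate one seeded multi-modal phantom volume.

    Raises :class:`PhantomSpecError` if the requested tumor does not fit
    inside the brain support.  Identical ``(spec, seed)`` produce
    bit-identical arrays.
    """
    rng = np.random.default_rng(spec.seed)
    brain = _brain_mask(spec)
    if not brain.any():
        raise PhantomSpecError("brain support is empty for this spec")

    whole_r, core_r, enh_r = spec.tumor_radii
    labels = np.zeros(spec.volume_shape, dtype=np.int16)
    if whole_r > 0:
        if spec.tumor_center == "random":
            center = _draw_center(rng, spec, whole_r)
        else:
            center = tuple(int(c) for c in spec.tumor_center)
        whole = _ellipsoid_mask(spec.volume_shape, center, (whole_r,) * 3)
        if (whole & ~brain).any():
            raise PhantomSpecError(
                f"tumor sphere (center {center}, radius {whole_r}) extends outside the brain support"
            )
        core = _ellipsoid_mask(spec.volume_shape, center, (core_r,) * 3) if core_r > 0 else np.zeros_like(whole)
        enh = _ellipsoid_mask(spec.volume_shape, center, (enh_r,) * 3) if enh_r > 0 else np.zeros_like(whole)
        labels[whole] = LABEL_EDEMA
        labels[core] = LABEL_CORE
        labels[enh] = LABEL_ENHANCING
    else:
        # tumor-free patient; rng still drawn for center symmetry is not needed
        pass

    region_masks = {
        "brain": brain & (labels == 0),
        "edema": labels == LABEL_EDEMA,
        "core": labels == LABEL_CORE,
        "enhancing": labels == LABEL_ENHANCING,
    }
    modalities: dict[str, np.ndarray] = {}
    for mod in MODALITIES:
        grid = np.zeros(spec.volume_shape)
        for region, mask in region_masks.items():
            grid[mask] = spec.contrast_table[mod][region]
        if spec.noise_sigma > 0:
            grid[brain] += rng.normal(0.0, spec.noise_sigma, size=int(brain.sum()))
        np.clip(grid, 0.0, None, out=grid)
        modalities[mod] = grid
    return MultiModalVolume(patient_id=patient_id, modalities=modalities, labels=labels)


def _draw_center(rng, spec: PhantomSpec, whole_r: float) -> tuple[int, int, int]:
    """Draw a tumor center such that the whole-tumor sphere fits in the brain."""
    h, w, s = spec.volume_shape
    bc = np.array([(h - 1) / 2, (w - 1) / 2, (s - 1) / 2])
    semi = np.array([spec.brain_radius_frac * h / 2, spec.brain_radius_frac * w / 2, 0.95 * s / 2])
    # a radius-r sphere at p fits inside the ellipsoid whenever the
    # ellipsoid norm of p is <= 1 - r/min(semi); keep one voxel of margin
    margin = 1.0 - (whole_r + 1.0) / semi.min()
    if margin <= 0:
        raise PhantomSpecError(
            f"whole-tumor radius {whole_r} too large for brain semi-axes {semi.tolist()}"
        )
    for _ in range(1000):
        offs = rng.uniform(-1, 1, size=3) * semi * margin
        if np.sqrt(((offs / semi) ** 2).sum()) <= margin:
            center = tuple(int(round(v)) for v in (bc + offs))
            return center
    raise PhantomSpecError("failed to place tumor center")  # pragma: no cover


def default_spec_sampler(
    volume_shape: tuple[int, int, int] = (240, 240, 155),
    tumor_slice_frac: float = 0.43,
    tumor_prob: float = 1.0,
    noise_sigma: float = 0.02,
) -> Callable[[np.random.Generator, int], PhantomSpec]:
    """Sampler of per-patient :class:`PhantomSpec` for cohort generation.

    ``tumor_slice_frac`` sets the target fraction of axial slices per volume
    whose label mask is nonzero (a tumor sphere of voxel radius r touches
    2r+1 slices); ``tumor_prob`` is the probability a patient has a tumor at
    all, so the class-imbalance path can be exercised.
    """
    n_slices = volume_shape[2]

    def sampler(rng: np.random.Generator, index: int) -> PhantomSpec:
        has_tumor = rng.random() < tumor_prob
        if has_tumor:
            r = max(1.0, (tumor_slice_frac * n_slices - 1) / 2)
            r *= rng.uniform(0.9, 1.1)  # mild patient-to-patient variation
            radii = (r, 0.6 * r, 0.3 * r)
        else:
            radii = (0.0, 0.0, 0.0)
        return PhantomSpec(
            volume_shape=volume_shape,
            tumor_radii=radii,
            tumor_center="random",
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    return sampler


def generate_phantom_cohort(
    n_patients: int,
    spec_sampler: Callable[[np.random.Generator, int], PhantomSpec] | None = None,
    seed: int = 0,
) -> list[MultiModalVolume]:
    """Generate ``n_patients`` reproducible phantom volumes with distinct ids."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if spec_sampler is None:
        spec_sampler = default_spec_sampler()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_patients):
        spec = spec_sampler(rng, i)
        cohort.append(generate_phantom_volume(spec, patient_id=f"phantom-{i:03d}"))
    return cohort


# -- NIfTI persistence (BraTS directory layout) -------------------------------

_FILE_SUFFIXES = {"T1": "t1", "T2": "t2", "T1ce": "t1ce", "FLAIR": "flair"}


def write_patient(volume: MultiModalVolume, out_dir: str | pathlib.Path) -> pathlib.Path:
    """Write one patient as BraTS-style ``<id>/<id>_<mod>.nii.gz`` files."""
    out_dir = pathlib.Path(out_dir) / volume.patient_id
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.voxel_spacing) + [1.0])
    for mod, suffix in _FILE_SUFFIXES.items():
        img = nib.Nifti1Image(volume.modalities[mod].astype(np.float32), affine)
        nib.save(img, out_dir / f"{volume.patient_id}_{suffix}.nii.gz")
    seg = nib.Nifti1Image(volume.labels.astype(np.int16), affine)
    nib.save(seg, out_dir / f"{volume.patient_id}_seg.nii.gz")
    return out_dir
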