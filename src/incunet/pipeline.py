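"""Two-stage training and inference pipeline.

Stage one is a slice-level classifier on the FLAIR and T2 channels (the
water-sensitive sequences that highlight whole-tumor areas); stage two is a
pixelwise segmentation network on all four modalities, applied only to
slices the classifier flags.  Both stages are exposed as scikit-learn style
estimators (`fit` / `predict` / `get_params`) so they compose with sklearn
model selection; the module-level ``train_*`` functions are thin wrappers
that assemble slice datasets from a cohort of volumes and fit an estimator.

The training recipe defaults follow the reference setup: Adam at learning
rate 1e-4, 200 epochs, batch size 25, dice loss for segmentation, binary
cross-entropy for the classifier, and augmentation by horizontal/vertical
flips, 10% zoom range and 0.2 shear range.
"""

from __future__ import annotations

import dataclasses
import time
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin

from . import metrics as _metrics
from .arch import InitSpec, ModelSpec, build_model, count_parameters, init_weights
from .nn import Adam, Tensor, binary_cross_entropy, soft_dice_loss
from .phantom import MODALITIES, MultiModalVolume
from .preprocess import (
    SliceSample,
    centered_crop_spec,
    crop_to_fixed,
    filter_tumor_slices,
    normalize_intensity,
    whole_tumor_mask,
)

#: Channel order fed to the slice classifier.
CLASSIFIER_MODALITIES = ("FLAIR", "T2")

__all__ = [
    "AugmentConfig",
    "TrainConfig",
    "RunRecord",
    "augment_sample",
    "TumorSegmenter",
    "TumorSliceClassifier",
    "train_classifier",
    "train_segmenter",
    "learning_rate_sweep",
    "two_stage_predict",
    "evaluate",
    "prepare_volume",
    "save_estimator",
    "load_estimator",
]


@dataclasses.dataclass(frozen=True)
class AugmentConfig:
    hflip: bool = True
    vflip: bool = True
    zoom_range: float = 0.10
    shear_range: float = 0.20


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    epochs: int = 200
    batch_size: int = 25
    augmentation: AugmentConfig | None = AugmentConfig()
    loss: str = "dice_loss"
    seed: int = 0
    checkpoint_dir: str | None = None
    lr_sweep: tuple[float, ...] | None = None
    crop_size: int = 176
    max_steps: int | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss not in ("dice_loss", "binary_cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclasses.dataclass
class RunRecord:
    """Per-epoch training log plus the config snapshot and wall time."""

    history: pd.DataFrame
    config: dict
    wall_time: float
    final_metrics: _metrics.SegMetrics | None = None


# -- augmentation -------------------------------------------------------------


def _affine_params(config: AugmentConfig, rng: np.random.Generator) -> dict:
    return {
        "hflip": bool(config.hflip and rng.random() < 0.5),
        "vflip": bool(config.vflip and rng.random() < 0.5),
        "zoom": float(rng.uniform(1 - config.zoom_range, 1 + config.zoom_range))
        if config.zoom_range > 0
        else 1.0,
        "shear": float(rng.uniform(-config.shear_range, config.shear_range))
        if config.shear_range > 0
        else 0.0,
    }


def _apply_geometric(plane: np.ndarray, params: dict, order: int) -> np.ndarray:
    out = plane
    if params["zoom"] != 1.0 or params["shear"] != 0.0:
        h, w = plane.shape
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        shear_m = np.array([[1.0, params["shear"]], [0.0, 1.0]])
        matrix = shear_m / params["zoom"]  # output -> input coordinates
        offset = center - matrix @ center
        out = ndimage.affine_transform(out, matrix, offset=offset, order=order, mode="nearest")
    if params["hflip"]:
        out = out[:, ::-1]
    if params["vflip"]:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def augment_sample(
    sample: SliceSample, config: AugmentConfig, seed: int | np.random.Generator = 0
) -> SliceSample:
    """Apply one random flip/zoom/shear draw, identically to image and mask.

    The image channels are interpolated linearly; the mask uses
    nearest-neighbor resampling and is re-binarized afterwards.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = _affine_params(config, rng)
    image = np.stack([_apply_geometric(ch, params, order=1) for ch in sample.image])
    mask = (_apply_geometric(sample.mask.astype(np.float64), params, order=0) > 0.5).astype(np.uint8)
    return SliceSample(image=image, mask=mask, patient_id=sample.patient_id,
                       slice_index=sample.slice_index)


# -- estimators ---------------------------------------------------------------


def _check_images(X, n_channels: int) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 4 or X.shape[1] != n_channels:
        raise ValueError(f"expected X of shape (n, {n_channels}, H, W), got {X.shape}")
    return X


class TumorSegmenter(BaseEstimator):
    """Pixelwise whole-tumor segmentation estimator.

    Wraps one of the five U-Net families: fit on stacked 4-channel slices
    and binary masks, predict per-pixel tumor probability maps.  Fitted
    attributes: ``model_``, ``history_``, ``n_params_``, ``epoch0_loss_``.
    """

    def __init__(self, family="ds_hybrid", depth=4, base_filters=16, in_channels=4,
                 learning_rate=1e-4, epochs=200, batch_size=25, max_steps=None,
                 loss="dice_loss", smooth=1.0, threshold=0.5, seed=0,
                 init_sigma=0.01, augment=None, encoder_residual=None,
                 full_scale_skips=False, stop_at_dice=None):
        self.family = family
        self.depth = depth
        self.base_filters = base_filters
        self.in_channels = in_channels
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.loss = loss
        self.smooth = smooth
        self.threshold = threshold
        self.seed = seed
        self.init_sigma = init_sigma
        self.augment = augment
        self.encoder_residual = encoder_residual
        self.full_scale_skips = full_scale_skips
        self.stop_at_dice = stop_at_dice

    def _model_spec(self) -> ModelSpec:
        return ModelSpec(
            family=self.family, in_channels=self.in_channels, depth=self.depth,
            base_filters=self.base_filters, encoder_residual=self.encoder_residual,
            full_scale_skips=self.full_scale_skips,
        )

    def fit(self, X, y, X_val=None, y_val=None):
        t0 = time.perf_counter()
        X = _check_images(X, self.in_channels)
        y = np.asarray(y)
        if y.shape != (X.shape[0], *X.shape[2:]):
            raise ValueError(f"mask shape {y.shape} does not match images {X.shape}")
        self.model_ = init_weights(build_model(self._model_spec()),
                                   InitSpec(0.0, self.init_sigma), seed=self.seed)
        self.n_params_ = count_parameters(self.model_)
        optimizer = Adam(self.model_.parameters(), lr=self.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1]))

        n = X.shape[0]
        steps_done = 0
        self.epoch0_loss_ = None
        rows = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses, dices = [], []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y[idx]
                if self.augment is not None:
                    xb, yb = _augment_batch(xb, yb, self.augment, rng)
                pred = self.model_(Tensor(xb)).reshape(len(idx), *xb.shape[2:])
                loss = (
                    soft_dice_loss(pred, yb, smooth=self.smooth)
                    if self.loss == "dice_loss"
                    else binary_cross_entropy(pred, yb)
                )
                if self.epoch0_loss_ is None:
                    self.epoch0_loss_ = float(loss.data)
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(float(loss.data))
                dices.append(
                    _metrics.dice_coefficient((pred.data >= self.threshold).astype(np.uint8), yb)
                )
                steps_done += 1
                if self.max_steps is not None and steps_done >= self.max_steps:
                    break
            row = dict(epoch=epoch, loss=float(np.mean(losses)), dice=float(np.mean(dices)))
            if X_val is not None:
                vp = self.predict_proba(X_val)
                row["val_dice"] = _metrics.dice_coefficient(
                    (vp >= self.threshold).astype(np.uint8), np.asarray(y_val)
                )
                row["val_loss"] = 1.0 - _metrics.dice_coefficient(vp, np.asarray(y_val), smooth=self.smooth)
                self.model_.train()
            rows.append(row)
            if self.max_steps is not None and steps_done >= self.max_steps:
                break
            if self.stop_at_dice is not None and row["dice"] >= self.stop_at_dice:
                break
        self.history_ = pd.DataFrame(rows)
        self.wall_time_ = time.perf_counter() - t0
        return self

    def predict_proba(self, X, batch_size: int = 8) -> np.ndarray:
        X = _check_images(X, self.in_channels)
        self.model_.eval()
        chunks = [
            self.model_(Tensor(X[i : i + batch_size])).data[:, 0]
            for i in range(0, X.shape[0], batch_size)
        ]
        self.model_.train()
        return np.concatenate(chunks, axis=0)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Hard Dice of the thresholded prediction against y."""
        return _metrics.dice_coefficient(self.predict(X), np.asarray(y))


def _augment_batch(xb, yb, config: AugmentConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for img, msk in zip(xb, yb):
        s = SliceSample(image=img, mask=msk.astype(np.uint8), patient_id="", slice_index=0)
        a = augment_sample(s, config, rng)
        xs.append(a.image)
        ys.append(a.mask)
    return np.stack(xs), np.stack(ys)


class TumorSliceClassifier(BaseEstimator, ClassifierMixin):
    """Slice-level tumor/no-tumor classifier on the FLAIR+T2 channels."""

    def __init__(self, base_filters=32, in_channels=2, learning_rate=1e-4, epochs=200,
                 batch_size=25, max_steps=None, threshold=0.5, seed=0, init_sigma=0.01,
                 init_scheme="glorot", augment=None):
        self.base_filters = base_filters
        self.in_channels = in_channels
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.threshold = threshold
        self.seed = seed
        self.init_sigma = init_sigma
        self.init_scheme = init_scheme
        self.augment = augment

    def fit(self, X, y):
        t0 = time.perf_counter()
        X = _check_images(X, self.in_channels)
        y = np.asarray(y).astype(np.float64).reshape(-1)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths differ")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(
                f"training set contains a single class ({classes.tolist()}); "
                "the tumor/no-tumor classifier needs both"
            )
        self.classes_ = np.array([0, 1])
        spec = ModelSpec(family="classifier", in_channels=self.in_channels,
                         base_filters=self.base_filters)
        self.model_ = init_weights(build_model(spec), InitSpec(0.0, self.init_sigma),
                                   seed=self.seed, scheme=self.init_scheme)
        self.n_params_ = count_parameters(self.model_)
        optimizer = Adam(self.model_.parameters(), lr=self.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 2]))

        n = X.shape[0]
        steps_done = 0
        self.epoch0_loss_ = None
        rows = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses, accs = [], []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y[idx]
                if self.augment is not None:
                    masks = np.zeros((len(idx), *xb.shape[2:]), dtype=np.uint8)
                    xb, _ = _augment_batch(xb, masks, self.augment, rng)
                pred = self.model_(Tensor(xb)).reshape(len(idx))
                loss = binary_cross_entropy(pred, yb)
                if self.epoch0_loss_ is None:
                    self.epoch0_loss_ = float(loss.data)
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(float(loss.data))
                accs.append(float(np.mean((pred.data >= self.threshold) == (yb >= 0.5))))
                steps_done += 1
                if self.max_steps is not None and steps_done >= self.max_steps:
                    break
            rows.append(dict(epoch=epoch, loss=float(np.mean(losses)),
                             accuracy=float(np.mean(accs))))
            if self.max_steps is not None and steps_done >= self.max_steps:
                break
        self.history_ = pd.DataFrame(rows)
        self.wall_time_ = time.perf_counter() - t0
        return self

    def predict_proba(self, X, batch_size: int = 16) -> np.ndarray:
        X = _check_images(X, self.in_channels)
        self.model_.eval()
        probs = [
            self.model_(Tensor(X[i : i + batch_size])).data.reshape(-1)
            for i in range(0, X.shape[0], batch_size)
        ]
        self.model_.train()
        p1 = np.concatenate(probs)
        return np.stack([1 - p1, p1], axis=1)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(np.uint8)


# -- cohort-level wrappers ----------------------------------------------------


def prepare_volume(volume: MultiModalVolume, crop_size: int | None = 176) -> MultiModalVolume:
    """Normalize intensities, then crop to the fixed centered window."""
    vol = normalize_intensity(volume)
    if crop_size is not None and crop_size != vol.shape[0]:
        crop = centered_crop_spec(vol.shape[:2], (crop_size, crop_size))
        vol = crop_to_fixed(vol, crop)
    return vol


def _segmentation_dataset(cohort, ids, crop_size) -> tuple[np.ndarray, np.ndarray]:
    images, masks = [], []
    for vol in cohort:
        if vol.patient_id not in ids:
            continue
        for s in filter_tumor_slices(prepare_volume(vol, crop_size)):
            images.append(s.image)
            masks.append(s.mask)
    if not images:
        raise ValueError("no tumor-bearing slices found for the requested patients")
    return np.stack(images), np.stack(masks)


def _classifier_dataset(cohort, ids, crop_size) -> tuple[np.ndarray, np.ndarray]:
    mod_idx = [MODALITIES.index(m) for m in CLASSIFIER_MODALITIES]
    images, labels = [], []
    for vol in cohort:
        if vol.patient_id not in ids:
            continue
        pv = prepare_volume(vol, crop_size)
        wt = whole_tumor_mask(pv.labels)
        stack = np.stack([pv.modalities[m] for m in MODALITIES])
        for k in range(pv.shape[2]):
            images.append(stack[mod_idx, :, :, k])
            labels.append(int(wt[:, :, k].any()))
    return np.stack(images), np.asarray(labels)


def train_segmenter(cohort, split, model_spec: ModelSpec | Mapping, config: TrainConfig):
    """Assemble tumor-bearing training slices and fit a :class:`TumorSegmenter`."""
    if isinstance(model_spec, Mapping):
        model_spec = ModelSpec.from_dict(dict(model_spec))
    X, y = _segmentation_dataset(cohort, set(split.train_ids), config.crop_size)
    est = TumorSegmenter(
        family=model_spec.family, depth=model_spec.depth, base_filters=model_spec.base_filters,
        in_channels=model_spec.in_channels, learning_rate=config.learning_rate,
        epochs=config.epochs, batch_size=config.batch_size, max_steps=config.max_steps,
        loss=config.loss if config.loss == "dice_loss" else "binary_cross_entropy",
        seed=config.seed, augment=config.augmentation,
        encoder_residual=model_spec.encoder_residual,
    )
    if split.val_ids:
        Xv, yv = _segmentation_dataset(cohort, set(split.val_ids), config.crop_size)
        est.fit(X, y, X_val=Xv, y_val=yv)
    else:
        est.fit(X, y)
    record = RunRecord(history=est.history_, config=dict(dataclasses.asdict(config),
                       model=model_spec.to_dict()), wall_time=est.wall_time_)
    return est, record


def train_classifier(cohort, split, config: TrainConfig, base_filters: int = 32):
    """Fit the slice-level classifier on all slices of the training patients."""
    X, y = _classifier_dataset(cohort, set(split.train_ids), config.crop_size)
    est = TumorSliceClassifier(
        base_filters=base_filters, learning_rate=config.learning_rate, epochs=config.epochs,
        batch_size=config.batch_size, max_steps=config.max_steps, seed=config.seed,
        augment=config.augmentation,
    )
    est.fit(X, y)
    record = RunRecord(history=est.history_, config=dataclasses.asdict(config),
                       wall_time=est.wall_time_)
    return est, record


def learning_rate_sweep(cohort, split, model_spec: ModelSpec, config: TrainConfig,
                        rates: Sequence[float] | None = None) -> dict[float, RunRecord]:
    """Train one segmenter per learning rate; returns rate -> RunRecord."""
    rates = tuple(rates if rates is not None else (config.lr_sweep or ()))
    if not rates:
        raise ValueError("no learning rates given")
    records = {}
    for lr in rates:
        cfg = dataclasses.replace(config, learning_rate=lr, lr_sweep=None)
        _, rec = train_segmenter(cohort, split, model_spec, cfg)
        records[lr] = rec
    return records


def two_stage_predict(classifier: TumorSliceClassifier | None, segmenter: TumorSegmenter,
                      volume: MultiModalVolume, gate_threshold: float = 0.5,
                      gate: bool = True) -> np.ndarray:
    """Predict a binary whole-tumor mask volume for one preprocessed volume.

    Slices the classifier scores below ``gate_threshold`` receive all-zero
    masks; the rest get the thresholded segmenter output.  With ``gate=False``
    (or no classifier) every slice is segmented.
    """
    stack = np.stack([volume.modalities[m] for m in MODALITIES])  # (4, H, W, S)
    n_slices = volume.shape[2]
    slices = np.moveaxis(stack, 3, 0)  # (S, 4, H, W)
    if gate and classifier is not None:
        mod_idx = [MODALITIES.index(m) for m in CLASSIFIER_MODALITIES]
        keep = classifier.predict_proba(slices[:, mod_idx])[:, 1] >= gate_threshold
    else:
        keep = np.ones(n_slices, dtype=bool)
    pred = np.zeros(volume.shape, dtype=np.uint8)
    if keep.any():
        seg = segmenter.predict(slices[keep])
        pred[:, :, keep] = np.moveaxis(seg, 0, 2)
    return pred


def evaluate(model_or_pair, cohort, test_ids, crop_size: int | None = 176,
             gate: bool = True, out_csv=None, model_name: str | None = None,
             reference: str = "baseline_unet") -> _metrics.SegMetrics:
    """Pooled-confusion evaluation over all slices of the test patients.

    ``model_or_pair`` is a fitted :class:`TumorSegmenter` or a
    ``(classifier, segmenter)`` pair.  When ``out_csv`` is given, a metrics
    row is appended and, once two or more models have rows, a comparison
    table against ``reference`` is rewritten next to it.
    """
    if isinstance(model_or_pair, tuple):
        classifier, segmenter = model_or_pair
    else:
        classifier, segmenter = None, model_or_pair
    test_ids = set(test_ids)
    tally = np.zeros(4, dtype=np.int64)
    for vol in cohort:
        if vol.patient_id not in test_ids:
            continue
        pv = prepare_volume(vol, crop_size)
        pred = two_stage_predict(classifier, segmenter, pv, gate=gate)
        tally += np.array(_metrics.confusion_tally(pred, whole_tumor_mask(pv.labels)))
    result = _metrics.metrics_from_tally(*tally.tolist())
    if out_csv is not None:
        _append_report(out_csv, model_name or getattr(segmenter, "family", "model"),
                       result, reference)
    return result


def save_estimator(est, path) -> None:
    """Checkpoint a fitted estimator: constructor params + weight arrays."""
    import json
    import pathlib

    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    params = est.get_params()
    arrays = {f"param_{i}": p.data for i, p in enumerate(est.model_.parameters())}
    running = {}
    for i, m in enumerate(est.model_.modules()):
        if hasattr(m, "running_mean"):
            running[f"rmean_{i}"] = m.running_mean
            running[f"rvar_{i}"] = m.running_var
    np.savez_compressed(path, **arrays, **running)
    meta = dict(cls=type(est).__name__, params=_jsonable(params))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_estimator(path):
    """Restore a checkpointed estimator saved by :func:`save_estimator`."""
    import json
    import pathlib

    path = pathlib.Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    params = meta["params"]
    if params.get("augment"):
        params["augment"] = AugmentConfig(**params["augment"])
    cls = {"TumorSegmenter": TumorSegmenter, "TumorSliceClassifier": TumorSliceClassifier}[
        meta["cls"]
    ]
    est = cls(**params)
    if isinstance(est, TumorSegmenter):
        est.model_ = init_weights(build_model(est._model_spec()), seed=0)
    else:
        spec = ModelSpec(family="classifier", in_channels=est.in_channels,
                         base_filters=est.base_filters)
        est.model_ = init_weights(build_model(spec), seed=0)
        est.classes_ = np.array([0, 1])
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    for i, p in enumerate(est.model_.parameters()):
        p.data = data[f"param_{i}"]
    for i, m in enumerate(est.model_.modules()):
        if hasattr(m, "running_mean") and f"rmean_{i}" in data:
            m.running_mean = data[f"rmean_{i}"]
            m.running_var = data[f"rvar_{i}"]
    est.n_params_ = count_parameters(est.model_)
    return est


def _jsonable(params: dict) -> dict:
    out = {}
    for k, v in params.items():
        if dataclasses.is_dataclass(v):
            out[k] = dataclasses.asdict(v)
        else:
            out[k] = v
    return out


def _append_report(out_csv, name: str, result: _metrics.SegMetrics, reference: str) -> None:
    import pathlib

    path = pathlib.Path(out_csv)
    row = pd.DataFrame([dict(model=name, **result.as_row())])
    if path.exists():
        table = pd.concat([pd.read_csv(path), row], ignore_index=True)
        table = table.drop_duplicates(subset="model", keep="last")
    else:
        table = row
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    if len(table) >= 2 and reference in set(table["model"]):
        models = {
            r["model"]: (r["dice"], r["sensitivity"], r["specificity"])
            for _, r in table.iterrows()
        }
        cmp_table = _metrics.improvement_table(models, reference)
        cmp_table.to_frame().to_csv(path.with_name(path.stem + "_vs_" + reference + ".csv"))
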