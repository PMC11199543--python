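"""Two-phase training loop, prediction, and dataset splitting.

Training runs ``total_epochs`` epochs of Adam on single-volume batches.
With auto-adaptation enabled, the first ``adapt_epoch`` epochs see the
original volumes; at the boundary the model's own predictions drive the
crop schema (:func:`oclnet.autoadapt.adapt_dataset`) and the remaining
epochs train on the lesion-centred crops with the same weights carried
over.  Held-out volumes are adapted with model predictions as well — never
with their ground truth — so evaluation sees the same input distribution
as training without label leakage.

Everything is seeded: weight initialization, shuffling, and dropout all
derive from ``TrainConfig.seed``, so identical configurations reproduce
identical histories.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .autoadapt import AdaptConfig, AdaptReport, adapt_dataset, restore_to_native
from .io import normalize_intensity, resample_volume
from .losses import (
    LossValue,
    MetricsReport,
    auc_score,
    combined_loss,
    dice_score,
    downsample_mask,
    evaluate_pair,
    iou_score,
)
from .model import NetConfig, SegmentationModel
from .nn import Adam, Context
from .volume import MaskVolume, Volume

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "TrainHistory",
    "split_dataset",
    "train",
    "predict",
    "predict_two_stage",
    "evaluate_dataset",
    "resolve_net_config",
]


@dataclass(frozen=True)
class TrainConfig:
    """Schedule hyperparameters; defaults follow the full-scale protocol."""

    total_epochs: int = 200
    adapt_epoch: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 1
    test_fraction: float = 0.2
    seed: int = 0
    use_autoadapt: bool = True
    use_multiscale: bool = True
    use_size_loss: bool = True
    val_every: int = 5

    def __post_init__(self) -> None:
        if self.use_autoadapt and not 0 < self.adapt_epoch < self.total_epochs:
            raise ValueError("adapt_epoch must lie strictly inside the schedule")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")

    @classmethod
    def test_preset(cls) -> "TrainConfig":
        """Desk-scale schedule: short, with a high rate suited to the small model."""
        return cls(total_epochs=40, adapt_epoch=20, learning_rate=3e-3)


@dataclass
class EpochRecord:
    epoch: int
    mean_loss: float
    bce: float
    size_dice: float
    phase: str  # pre-adapt | post-adapt
    val_dice: float | None = None


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)
    adapt_report: AdaptReport | None = None
    # weight snapshot taken at the adapt boundary; the phase-1 model is the
    # reliable full-volume locator for two-stage inference
    phase1_state: dict | None = None

    def write_csv(self, path: str) -> str:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "mean_loss", "bce", "size_dice", "phase", "val_dice"])
            for r in self.records:
                w.writerow(
                    [
                        r.epoch,
                        f"{r.mean_loss:.6f}",
                        f"{r.bce:.6f}",
                        f"{r.size_dice:.6f}",
                        r.phase,
                        "" if r.val_dice is None else f"{r.val_dice:.4f}",
                    ]
                )
        return path


def resolve_net_config(net: NetConfig, cfg: TrainConfig) -> NetConfig:
    """Apply the ablation switches that live on the training side."""
    if not cfg.use_multiscale and net.attention_scales != 0:
        return replace(net, attention_scales=0)
    return net


def split_dataset(dataset: list, test_fraction: float, seed: int) -> tuple[list, list]:
    """Seeded random split; test size = round(fraction * n)."""
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least two items to split")
    n_test = round(test_fraction * n)
    if n_test == 0 or n_test == n:
        raise ValueError(
            f"test fraction {test_fraction} leaves an empty side for n={n}"
        )
    order = np.random.default_rng(seed).permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [dataset[i] for i in range(n) if i not in test_idx]
    test = [dataset[i] for i in range(n) if i in test_idx]
    return train, test


def _prepare_input(image: Volume, shape: tuple[int, int, int]) -> np.ndarray:
    if image.shape != tuple(shape):
        image = resample_volume(image, shape, mode="trilinear")
    return normalize_intensity(image.data)


def predict(
    model: SegmentationModel, image: Volume, threshold: float = 0.5
) -> tuple[MaskVolume, np.ndarray]:
    """Segment one volume.

    The image is resampled to the network input shape and min–max
    normalized; the binary mask is resampled back (nearest) to the
    original grid.  Returns the mask plus the raw probability grid at
    network resolution.
    """
    if not np.isfinite(image.data).all():
        raise ValueError("non-finite values in input volume")
    x = _prepare_input(image, model.config.input_shape)
    res = model.forward(x, Context(training=False))
    prob = np.asarray(res.prob.data, dtype=np.float32)
    hard = MaskVolume((prob > threshold).astype(np.uint8))
    if hard.shape != image.shape:
        hard = resample_volume(hard, image.shape, mode="nearest")
    return MaskVolume(hard.data, image.spacing, image.origin), prob


def predict_two_stage(
    model: SegmentationModel,
    locator: SegmentationModel,
    image: Volume,
    adapt_config: AdaptConfig | None = None,
    threshold: float = 0.5,
) -> tuple[MaskVolume, np.ndarray]:
    """Locate with the phase-1 model, segment the crop, map back to native.

    The locator's thresholded prediction drives the crop schema exactly as
    during training; ``model`` (the phase-2 weights) then segments the
    lesion-centred crop, and both the binary mask and the probability grid
    are restored to the original volume's grid (probabilities outside the
    crop are zero).
    """
    shape = tuple(model.config.input_shape)
    cfg = adapt_config or AdaptConfig(
        upscale_shape=tuple(2 * n for n in shape), crop_shape=shape
    )
    dummy = MaskVolume(np.zeros(image.shape, dtype=np.uint8))
    loc_mask, _ = predict(locator, image, threshold)
    adapted, report = adapt_dataset(lambda _img: loc_mask, [(image, dummy)], cfg)
    crop_img, _ = adapted[0]
    record = report.records[0]
    x = _prepare_input(crop_img, shape)
    prob_crop = np.asarray(
        model.forward(x, Context(training=False)).prob.data, dtype=np.float32
    )
    mask_crop = MaskVolume((prob_crop > threshold).astype(np.uint8))
    mask_native = restore_to_native(mask_crop, record, cfg, image.shape)
    prob_native = restore_to_native(
        Volume(prob_crop), record, cfg, image.shape
    ).data
    return (
        MaskVolume(mask_native.data, image.spacing, image.origin),
        prob_native,
    )


def evaluate_dataset(
    model: SegmentationModel,
    pairs: list[tuple[Volume, MaskVolume]],
    threshold: float = 0.5,
    locator: SegmentationModel | None = None,
    adapt_config: AdaptConfig | None = None,
) -> list:
    """Per-volume metric reports.

    Without a locator, each image is segmented directly and scored at
    network resolution.  With a ``locator`` (the phase-1 weights of an
    auto-adapted run) every volume goes through two-stage inference and is
    scored on its native grid against the unmodified ground truth.
    """
    if locator is not None:
        reports = []
        for image, label in pairs:
            mask, prob = predict_two_stage(
                model, locator, image, adapt_config, threshold
            )
            reports.append(
                MetricsReport(
                    dice=dice_score(mask.data, label.data),
                    iou=iou_score(mask.data, label.data),
                    auc=auc_score(prob, label.data),
                )
            )
        return reports
    reports = []
    for image, label in pairs:
        x = _prepare_input(image, model.config.input_shape)
        res = model.forward(x, Context(training=False))
        prob = np.asarray(res.prob.data, dtype=np.float64)
        y = label.data
        if y.shape != prob.shape:
            y = resample_volume(label, prob.shape, mode="nearest").data
        reports.append(evaluate_pair(prob, y, threshold))
    return reports


def _mean_val_dice(model: SegmentationModel, pairs, threshold: float = 0.5) -> float:
    reports = evaluate_dataset(model, pairs, threshold)
    return float(np.mean([r.dice for r in reports]))


def train(
    model: SegmentationModel,
    dataset: list[tuple[Volume, MaskVolume]],
    train_config: TrainConfig,
    adapt_config: AdaptConfig | None = None,
    val_dataset: list[tuple[Volume, MaskVolume]] | None = None,
) -> tuple[SegmentationModel, TrainHistory, list]:
    """Run the (optionally two-phase) schedule.

    Returns the trained model, the epoch history, and the validation pairs
    actually used after the adapt boundary (the model-predicted crops when
    auto-adaptation is on, the originals otherwise).
    """
    cfg = train_config
    net_shape = tuple(model.config.input_shape)
    for image, _ in dataset:
        if image.shape != net_shape:
            raise ValueError(
                f"all training volumes must match the network input {net_shape}"
            )
    if cfg.use_autoadapt:
        adapt_config = adapt_config or AdaptConfig(
            upscale_shape=tuple(2 * n for n in net_shape), crop_shape=net_shape
        )
        if adapt_config.mode == "S" and tuple(adapt_config.crop_shape) != net_shape:
            raise ValueError("mode S requires crop_shape == network input shape")

    rng = np.random.default_rng(cfg.seed)
    ctx = Context(training=True, rng=np.random.default_rng(rng.integers(2**31)))
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()

    pairs = list(dataset)
    val_pairs = list(val_dataset) if val_dataset else []
    ks = model.config.attention_ks if model.config.deep_supervision else ()

    for epoch in range(1, cfg.total_epochs + 1):
        phase = (
            "post-adapt" if cfg.use_autoadapt and epoch > cfg.adapt_epoch else "pre-adapt"
        )
        order = rng.permutation(len(pairs))
        # store scalars, never LossValue tensors: a retained total would
        # keep the whole per-step autodiff graph alive
        losses: list[tuple[float, float, float]] = []
        for idx in order:
            image, label = pairs[idx]
            x = normalize_intensity(image.data)
            res = model.forward(x, ctx)
            y = label.data
            deep = None
            if ks:
                deep = [
                    [
                        (m.reshape(*m.shape[1:]), downsample_mask(y, 2**k))
                        for k, m in zip(ks, res.attention_maps)
                    ]
                ]
            lv = combined_loss(
                [(res.prob, y)], deep_outputs=deep, use_size_loss=cfg.use_size_loss
            )
            if not math.isfinite(lv.total.item()):
                raise RuntimeError(
                    f"loss diverged (non-finite) at epoch {epoch}"
                )
            optimizer.zero_grad()
            lv.total.backward()
            optimizer.step()
            losses.append((lv.total.item(), lv.bce_part, lv.size_dice_part))

        arr = np.asarray(losses)
        rec = EpochRecord(
            epoch=epoch,
            mean_loss=float(arr[:, 0].mean()),
            bce=float(arr[:, 1].mean()),
            size_dice=float(arr[:, 2].mean()),
            phase=phase,
        )
        if val_pairs and (epoch % cfg.val_every == 0 or epoch == cfg.total_epochs):
            rec.val_dice = _mean_val_dice(model, val_pairs)
        history.records.append(rec)

        if cfg.use_autoadapt and epoch == cfg.adapt_epoch:
            history.phase1_state = {
                k: v.copy() for k, v in model.state_arrays().items()
            }
            predictor = lambda img: predict(model, img)[0]  # noqa: E731
            pairs, report = adapt_dataset(predictor, pairs, adapt_config)
            history.adapt_report = report
            if val_pairs:
                val_pairs, _ = adapt_dataset(predictor, val_pairs, adapt_config)

    return model, history, val_pairs
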