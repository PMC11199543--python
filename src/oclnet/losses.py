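"""Training losses and evaluation metrics for lesion segmentation.

The training objective combines voxelwise binary cross-entropy with a
size-aware Dice loss

    l_sd(P, Y) = min(|ΣP − ΣY| / ΣY, 1) − 2·Σ(P·Y) / (ΣP + ΣY),

where the sizes are soft sums over the probability map P and the binary
ground truth Y.  The first term penalizes the relative size error of the
prediction (clamped to 1 so grossly oversized predictions keep a bounded
loss); the second is the soft Dice overlap.  The loss ranges over [-1, 1]
and is minimized at -1 exactly when P = Y.

Evaluation metrics are the Dice coefficient 2|A∩B|/(|A|+|B|), the
intersection-over-union |A∩B|/|A∪B|, and the voxelwise ROC AUC in its
rank (Mann–Whitney) formulation with ties counted one half.

Loss functions accept either plain numpy arrays or autodiff tensors for the
prediction, so the same code is used for training and for closed-form
checks; metrics are plain numpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .nn.tensor import Tensor

__all__ = [
    "EPS",
    "LossValue",
    "MetricsReport",
    "bce_loss",
    "size_aware_dice_loss",
    "plain_dice_loss",
    "combined_loss",
    "dice_score",
    "iou_score",
    "auc_score",
    "evaluate_pair",
    "downsample_mask",
]

EPS = 1e-7  # probability clip before logarithms


@dataclass
class LossValue:
    """Combined loss split into its two parts; total = bce + size-dice."""

    total: Tensor
    bce_part: float
    size_dice_part: float


@dataclass
class MetricsReport:
    dice: float
    iou: float
    auc: float | None  # None when the ground truth has a single class


def _as_tensor(P) -> Tensor:
    return P if isinstance(P, Tensor) else Tensor(np.asarray(P, dtype=np.float64))


def _check_shapes(P, Y) -> np.ndarray:
    Y = np.asarray(Y)
    p_shape = P.shape if isinstance(P, Tensor) else np.asarray(P).shape
    if tuple(p_shape) != tuple(Y.shape):
        raise ValueError(f"shape mismatch: prediction {p_shape} vs target {Y.shape}")
    return Y


def bce_loss(P, Y) -> Tensor:
    """Mean binary cross-entropy; probabilities clipped to [EPS, 1-EPS]."""
    Y = _check_shapes(P, Y)
    Pt = _as_tensor(P).clamp(EPS, 1.0 - EPS)
    yf = Y.astype(Pt.data.dtype)
    loss = -(Tensor(yf) * Pt.log() + Tensor(1.0 - yf) * (1.0 - Pt).log()).mean()
    return loss


def size_aware_dice_loss(P, Y) -> Tensor:
    """Clamped size-ratio term minus soft Dice overlap; range [-1, 1]."""
    Y = _check_shapes(P, Y)
    sy = float(Y.sum())
    if sy == 0:
        raise ValueError("size-aware Dice loss is undefined for empty ground truth")
    Pt = _as_tensor(P)
    yf = Y.astype(Pt.data.dtype)
    sp = Pt.sum()
    size_term = ((sp - sy).abs() / sy).minimum(1.0)
    overlap = (Pt * Tensor(yf)).sum() * 2.0 / (sp + sy)
    return size_term - overlap


def plain_dice_loss(P, Y) -> Tensor:
    """Soft Dice overlap term alone (used when the size term is disabled)."""
    Y = _check_shapes(P, Y)
    sy = float(Y.sum())
    if sy == 0:
        raise ValueError("Dice loss is undefined for empty ground truth")
    Pt = _as_tensor(P)
    yf = Y.astype(Pt.data.dtype)
    return -((Pt * Tensor(yf)).sum() * 2.0 / (Pt.sum() + sy))


def downsample_mask(Y: np.ndarray, factor: int) -> np.ndarray:
    """Block-maximum downsampling of a binary mask by an integer factor.

    A coarse cell is foreground when any of its fine voxels is — point
    sampling instead would erase lesions only a few voxels across, and the
    per-scale supervision would then actively train the attention maps
    toward zero on exactly the small-lesion cases they exist for.
    """
    if factor == 1:
        return Y
    d, h, w = Y.shape
    f = factor
    return (
        Y.reshape(d // f, f, h // f, f, w // f, f).max(axis=(1, 3, 5))
    )


def combined_loss(
    pairs,
    deep_outputs=None,
    use_size_loss: bool = True,
) -> LossValue:
    """Combined supervision over a batch of (P, Y) pairs.

    ``deep_outputs`` optionally supplies, per pair, a list of per-scale
    (probability map, downsampled ground truth) pairs; the combined
    bce + size-dice term is then averaged with equal weight over the main
    output and every supervised scale.  Outputs whose (downsampled) ground
    truth is empty — degenerate crops — contribute their cross-entropy
    term only.
    """
    if not pairs:
        raise ValueError("empty batch")
    dice_fn = size_aware_dice_loss if use_size_loss else plain_dice_loss
    totals: list[Tensor] = []
    bces: list[float] = []
    sds: list[float] = []
    for i, (P, Y) in enumerate(pairs):
        terms_b: list[Tensor] = [bce_loss(P, Y)]
        terms_d: list[Tensor | None] = [
            dice_fn(P, Y) if np.asarray(Y).sum() > 0 else None
        ]
        if deep_outputs is not None:
            for Ps, Ys in deep_outputs[i]:
                terms_b.append(bce_loss(Ps, Ys))
                terms_d.append(dice_fn(Ps, Ys) if Ys.sum() > 0 else None)
        k = len(terms_b)
        b = terms_b[0] * (1.0 / k)
        for t in terms_b[1:]:
            b = b + t * (1.0 / k)
        d: Tensor | None = None
        for t in terms_d:
            if t is None:
                continue
            t = t * (1.0 / k)
            d = t if d is None else d + t
        bces.append(b.item())
        sds.append(0.0 if d is None else d.item())
        totals.append(b if d is None else b + d)
    n = len(totals)
    total = totals[0] * (1.0 / n)
    for t in totals[1:]:
        total = total + t * (1.0 / n)
    return LossValue(
        total=total,
        bce_part=float(np.mean(bces)),
        size_dice_part=float(np.mean(sds)),
    )


# -- evaluation metrics (numpy only) ------------------------------------


def _binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return a.astype(np.int64)


def dice_score(A: np.ndarray, B: np.ndarray) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|); 1.0 when both sets are empty."""
    A, B = _binary(A, "A"), _binary(_check_shapes(A, B), "B")
    denom = A.sum() + B.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (A & B).sum() / denom)


def iou_score(A: np.ndarray, B: np.ndarray) -> float:
    """Intersection over union |A∩B|/|A∪B|; 1.0 when both sets are empty."""
    A, B = _binary(A, "A"), _binary(_check_shapes(A, B), "B")
    union = (A | B).sum()
    if union == 0:
        return 1.0
    return float((A & B).sum() / union)


def auc_score(P: np.ndarray, Y: np.ndarray) -> float | None:
    """Rank-based ROC AUC of P against binary Y; None when Y is single-class."""
    Y = _binary(_check_shapes(P, Y), "Y").ravel()
    P = np.asarray(P, dtype=np.float64).ravel()
    n_pos = int(Y.sum())
    n_neg = Y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(P, method="average")
    return float((ranks[Y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate_pair(P: np.ndarray, Y: np.ndarray, threshold: float = 0.5) -> MetricsReport:
    """Dice/IoU on the thresholded prediction, AUC on the raw probabilities."""
    Y = _check_shapes(P, Y)
    hard = (np.asarray(P) > threshold).astype(np.uint8)
    return MetricsReport(
        dice=dice_score(hard, Y),
        iou=iou_score(hard, Y),
        auc=auc_score(P, Y),
    )
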