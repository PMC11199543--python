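"""Losses and metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oclnet.losses import (
    auc_score,
    bce_loss,
    combined_loss,
    dice_score,
    downsample_mask,
    evaluate_pair,
    iou_score,
    plain_dice_loss,
    size_aware_dice_loss,
)
from oclnet.nn.tensor import Tensor

# -- independent oracles -------------------------------------------------


def bce_oracle(P, Y, eps=1e-7):
    """Per-voxel python-loop cross-entropy."""
    total = 0.0
    for p, y in zip(np.ravel(P), np.ravel(Y)):
        p = min(max(p, eps), 1 - eps)
        total += -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return total / np.size(P)


def auc_oracle(P, Y):
    """O(n^2) all-pairs comparison with half-credit ties."""
    pos = np.ravel(P)[np.ravel(Y) == 1]
    neg = np.ravel(P)[np.ravel(Y) == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def set_metric_oracle(A, B):
    a = set(map(tuple, np.argwhere(np.asarray(A))))
    b = set(map(tuple, np.argwhere(np.asarray(B))))
    inter, union = len(a & b), len(a | b)
    dice = 1.0 if not a and not b else 2 * inter / (len(a) + len(b))
    iou = 1.0 if union == 0 else inter / union
    return dice, iou


# -- BCE ------------------------------------------------------------------


def test_bce_perfect_prediction_near_zero():
    Y = np.zeros((4, 4, 4))
    Y[1:3, 1:3, 1:3] = 1
    assert bce_loss(Y.copy(), Y).item() <= 1e-6


def test_bce_half_everywhere_is_ln2():
    Y = (np.arange(64).reshape(4, 4, 4) % 2).astype(float)
    assert bce_loss(np.full((4, 4, 4), 0.5), Y).item() == pytest.approx(np.log(2), abs=1e-12)


def test_bce_matches_bruteforce(rng):
    P = rng.random((4, 4, 4))
    Y = (rng.random((4, 4, 4)) > 0.5).astype(float)
    assert bce_loss(P, Y).item() == pytest.approx(bce_oracle(P, Y), abs=1e-9)


def test_bce_shape_mismatch():
    with pytest.raises(ValueError):
        bce_loss(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


# -- size-aware Dice loss -------------------------------------------------


def test_size_loss_perfect_prediction_is_minus_one():
    Y = np.zeros((4, 4, 4))
    Y[0:2, 0:2, 0:2] = 1
    assert size_aware_dice_loss(Y.copy(), Y).item() == pytest.approx(-1.0, abs=1e-6)


def test_size_loss_empty_prediction_is_plus_one():
    Y = np.zeros((4, 4, 4))
    Y[0:2, 0:2, 0:2] = 1  # |Y| = 8
    assert size_aware_dice_loss(np.zeros((4, 4, 4)), Y).item() == pytest.approx(1.0)


def test_size_loss_hand_computed_subset():
    """4 predicted voxels inside an 8-voxel truth: 0.5 - 2*4/12 = -1/6."""
    Y = np.zeros((4, 4, 4))
    Y[0:2, 0:2, 0:2] = 1
    P = np.zeros((4, 4, 4))
    P[0, 0:2, 0:2] = 1
    assert size_aware_dice_loss(P, Y).item() == pytest.approx(0.5 - 8 / 12, abs=1e-12)


def test_size_loss_clamp_for_oversized_prediction():
    Y = np.zeros((10, 10, 10))
    Y[0, 0, :5] = 1  # |Y| = 5
    P = np.full((10, 10, 10), 0.5)  # soft size 500 = 100 * |Y|
    val = size_aware_dice_loss(P, Y).item()
    assert -1.0 <= val <= 1.0


def test_size_loss_empty_truth_raises():
    with pytest.raises(ValueError):
        size_aware_dice_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_size_loss_bounded_on_random_pairs(seed):
    rng = np.random.default_rng(seed)
    Y = np.zeros(27)
    Y[rng.choice(27, size=rng.integers(1, 27), replace=False)] = 1
    Y = Y.reshape(3, 3, 3)
    P = rng.random((3, 3, 3)) if rng.random() < 0.5 else (rng.random((3, 3, 3)) > 0.5).astype(float)
    assert -1.0 <= size_aware_dice_loss(P, Y).item() <= 1.0


def test_size_loss_gradient_flows():
    Y = np.zeros((3, 3, 3))
    Y[1, 1, 1] = 1
    P = Tensor(np.full((3, 3, 3), 0.3), requires_grad=True)
    size_aware_dice_loss(P, Y).backward()
    assert P.grad is not None and np.abs(P.grad).max() > 0


# -- combined loss ---------------------------------------------------------


def _perfect_pair():
    Y = np.zeros((4, 4, 4))
    Y[1:3, 1:3, 1:3] = 1
    return Y.copy(), Y


def test_combined_perfect_is_minus_one():
    P, Y = _perfect_pair()
    lv = combined_loss([(P, Y)])
    assert lv.total.item() == pytest.approx(-1.0, abs=1e-5)
    assert lv.total.item() == pytest.approx(lv.bce_part + lv.size_dice_part, abs=1e-9)


def test_combined_batch_mean_semantics():
    P, Y = _perfect_pair()
    one = combined_loss([(P, Y)]).total.item()
    two = combined_loss([(P, Y), (P, Y)]).total.item()
    assert one == pytest.approx(two, abs=1e-9)


def test_combined_deep_supervision_perfect_still_minus_one():
    P, Y = _perfect_pair()
    deep = [[(downsample_mask(Y, 2).astype(float), downsample_mask(Y, 2))]]
    lv = combined_loss([(P, Y)], deep_outputs=deep)
    assert lv.total.item() == pytest.approx(-1.0, abs=1e-5)


def test_combined_without_size_loss_uses_plain_dice():
    P, Y = _perfect_pair()
    lv = combined_loss([(P, Y)], use_size_loss=False)
    expected = bce_loss(P, Y).item() + plain_dice_loss(P, Y).item()
    assert lv.total.item() == pytest.approx(expected, abs=1e-9)


def test_combined_empty_truth_falls_back_to_bce():
    P = np.full((2, 2, 2), 0.2)
    Y = np.zeros((2, 2, 2))
    lv = combined_loss([(P, Y)])
    assert lv.total.item() == pytest.approx(bce_loss(P, Y).item(), abs=1e-9)


# -- metrics ---------------------------------------------------------------


def test_dice_iou_basic_cases():
    A = np.zeros((4, 4, 4), dtype=int)
    A[0:2, 0:2, 0:2] = 1
    assert dice_score(A, A) == 1.0
    assert iou_score(A, A) == 1.0
    B = np.zeros_like(A)
    B[2:4, 2:4, 2:4] = 1
    assert dice_score(A, B) == 0.0
    assert iou_score(A, B) == 0.0


def test_dice_iou_subset_counts():
    B = np.zeros((4, 4, 4), dtype=int)
    B[0:2, 0:2, 0:2] = 1  # 8 voxels
    A = np.zeros_like(B)
    A[0, 0:2, 0:2] = 1  # 4 voxels inside B
    assert dice_score(A, B) == pytest.approx(8 / 12)
    assert iou_score(A, B) == pytest.approx(0.5)
    # functional identity
    assert dice_score(A, B) == pytest.approx(2 * 0.5 / 1.5)


def test_both_empty_convention():
    Z = np.zeros((3, 3, 3), dtype=int)
    assert dice_score(Z, Z) == 1.0
    assert iou_score(Z, Z) == 1.0


def test_metrics_match_set_oracle(rng):
    for _ in range(20):
        A = (rng.random((4, 4, 4)) > 0.6).astype(int)
        B = (rng.random((4, 4, 4)) > 0.6).astype(int)
        d_o, i_o = set_metric_oracle(A, B)
        assert dice_score(A, B) == pytest.approx(d_o, abs=1e-12)
        assert iou_score(A, B) == pytest.approx(i_o, abs=1e-12)


def test_auc_separable_and_constant():
    Y = np.array([0, 0, 1, 1]).reshape(1, 2, 2)
    assert auc_score(np.array([0.1, 0.2, 0.8, 0.9]).reshape(1, 2, 2), Y) == 1.0
    assert auc_score(np.full((1, 2, 2), 0.5), Y) == 0.5


def test_auc_matches_pairwise_oracle(rng):
    P = rng.random(20)
    P[5] = P[7]  # inject ties
    Y = np.zeros(20, dtype=int)
    Y[rng.choice(20, 8, replace=False)] = 1
    got = auc_score(P.reshape(4, 5, 1), Y.reshape(4, 5, 1))
    assert got == pytest.approx(auc_oracle(P, Y), abs=1e-12)


def test_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    P = rng.random((6, 6, 6))
    Y = (rng.random((6, 6, 6)) > 0.8).astype(int)
    assert auc_score(P, Y) == pytest.approx(
        roc_auc_score(Y.ravel(), P.ravel()), abs=1e-12
    )


def test_auc_single_class_is_undefined():
    assert auc_score(np.random.rand(2, 2, 2), np.zeros((2, 2, 2), dtype=int)) is None


def test_auc_invariant_under_monotone_transform(rng):
    P = rng.random((5, 5, 5))
    Y = (rng.random((5, 5, 5)) > 0.7).astype(int)
    base = auc_score(P, Y)
    assert auc_score(np.exp(3 * P), Y) == pytest.approx(base, abs=1e-12)
    assert auc_score(P**3, Y) == pytest.approx(base, abs=1e-12)


def test_evaluate_pair_perfect_and_anti():
    Y = np.zeros((4, 4, 4), dtype=int)
    Y[1:3, 1:3, 1:3] = 1
    perfect = evaluate_pair(Y.astype(float), Y)
    assert (perfect.dice, perfect.iou, perfect.auc) == (1.0, 1.0, 1.0)
    anti = evaluate_pair(1.0 - Y.astype(float), Y)
    assert (anti.dice, anti.iou, anti.auc) == (0.0, 0.0, 0.0)
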