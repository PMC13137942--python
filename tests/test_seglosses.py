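"""Composite segmentation objective: closed-form values, brute-force
oracles for the geometric terms, and monotonicity in the weights."""

import numpy as np
import pytest

from cspine.seglosses import (LossWeights, boundary_loss, focal_dice,
                              onehot_encode, ordering_loss, overlap_loss,
                              seg_loss, weighted_ce)

N_CLASSES = 8


def _softmax(x, axis=0):
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def _random_probs(rng, shape=(N_CLASSES, 6, 6, 6)):
    return _softmax(rng.normal(size=shape).astype(np.float32))


def test_focal_dice_perfect_wrong_and_half_overlap(rng):
    labels = rng.integers(0, N_CLASSES, size=(5, 5, 5))
    oh = onehot_encode(labels)
    assert focal_dice(oh, oh) < 1e-4

    # all mass on the wrong class: each present class contributes ~1
    wrong = np.roll(oh, 1, axis=0)
    present = len(np.unique(labels))
    assert focal_dice(wrong, oh, gamma=1.0) == pytest.approx(present,
                                                             abs=1e-3)

    # single class, half overlap, gamma=2 -> (1/3)^2
    n = 8
    q = np.zeros((2, n, 1, 1), dtype=np.float32)
    q[1, :, 0, 0] = 1.0
    p = np.zeros_like(q)
    p[1, :n // 2, 0, 0] = 1.0
    p[0, n // 2:, 0, 0] = 1.0
    term = focal_dice(p, q, class_weights=[0.0, 1.0], gamma=2.0)
    assert term == pytest.approx((1.0 / 3.0) ** 2, abs=1e-4)


def test_weighted_ce_closed_forms(rng):
    labels = rng.integers(0, N_CLASSES, size=(4, 4, 4))
    oh = onehot_encode(labels)
    assert weighted_ce(np.clip(oh, 1e-7, 1), labels) < 1e-5

    uniform = np.full((N_CLASSES, 4, 4, 4), 1.0 / N_CLASSES)
    assert weighted_ce(uniform, labels) == pytest.approx(np.log(8), rel=1e-5)

    # doubling one class weight doubles its contribution
    w = np.ones(N_CLASSES)
    base = weighted_ce(uniform, labels, w)
    w2 = w.copy()
    w2[3] = 2.0
    frac3 = np.mean(labels == 3)
    assert weighted_ce(uniform, labels, w2) == pytest.approx(
        base + frac3 * np.log(8), rel=1e-5)

    with pytest.raises(ValueError):
        weighted_ce(uniform, np.full((4, 4, 4), 9))


def test_boundary_loss_degenerate_and_localization(small_sample):
    from cspine.preprocess import build_prior_stack
    probs = np.zeros((N_CLASSES, 8, 8, 8), dtype=np.float32)
    probs[0] = 0.3
    probs[1] = 0.7
    mask = np.ones((8, 8, 8), bool)
    assert boundary_loss(probs, np.zeros((8, 8, 8)), mask) == \
        pytest.approx(0.0)

    e = np.random.default_rng(0).random((8, 8, 8)).astype(np.float32)
    assert boundary_loss(probs, e, mask) == pytest.approx(float(
        np.mean(e ** 2)), rel=1e-5)

    with pytest.raises(ValueError):
        boundary_loss(probs, e, np.zeros((8, 8, 8), bool))

    # a step aligned with the true cortical boundary beats a displaced one
    stack = build_prior_stack(small_sample.ct)
    fg = small_sample.labels.labels > 0
    aligned = np.zeros((N_CLASSES,) + fg.shape, dtype=np.float32)
    aligned[1] = fg
    aligned[0] = 1.0 - fg
    shifted_fg = np.roll(fg, 3, axis=0)
    shifted = np.zeros_like(aligned)
    shifted[1] = shifted_fg
    shifted[0] = 1.0 - shifted_fg
    l_aligned = boundary_loss(aligned, stack.edge_map, stack.body_mask)
    l_shifted = boundary_loss(shifted, stack.edge_map, stack.body_mask)
    assert l_aligned < l_shifted


def test_ordering_loss_hinge_and_oracle(rng, small_sample):
    # ordered one-hot labels: zero loss
    oh = onehot_encode(small_sample.labels.labels)
    assert ordering_loss(oh, small_sample.ct.spacing) == pytest.approx(0.0)

    # two adjacent classes swapped by 10 mm with margin 1 -> 11/6
    nz = 30
    probs = np.zeros((N_CLASSES, 1, 1, nz), dtype=np.float32)
    probs[3, 0, 0, 20] = 1.0  # z = 20 mm
    probs[4, 0, 0, 10] = 1.0  # z = 10 mm
    loss = ordering_loss(probs, (1, 1, 1.0), margin_mm=1.0)
    assert loss == pytest.approx(11.0 / 6.0, rel=1e-5)

    # soft centroids equal brute-force weighted means
    p = _random_probs(rng, (N_CLASSES, 8, 8, 8))
    spacing = (1.0, 1.0, 2.0)
    z_mm = np.arange(8) * spacing[2]
    cents = {k: float((p[k] * z_mm[None, None, :]).sum() / p[k].sum())
             for k in range(1, 8)}
    expected = sum(max(0.0, cents[k] - cents[k + 1] + 1.0)
                   for k in range(1, 7)) / 6.0
    assert ordering_loss(p, spacing) == pytest.approx(expected, abs=1e-5)


def test_overlap_loss_values_and_oracle(rng):
    labels = rng.integers(0, N_CLASSES, size=(5, 5, 5))
    assert overlap_loss(onehot_encode(labels)) == 0.0

    p = np.zeros((N_CLASSES, 4, 4, 4), dtype=np.float32)
    p[2] = 0.5
    p[3] = 0.5
    assert overlap_loss(p) == pytest.approx(0.25)

    q = _random_probs(rng, (N_CLASSES, 5, 5, 5))
    brute = np.mean(sum(q[k] * q[k + 1] for k in range(1, 7)))
    assert overlap_loss(q) == pytest.approx(float(brute), abs=1e-7)


def test_seg_loss_composition(rng, small_sample):
    from cspine.preprocess import build_prior_stack
    stack = build_prior_stack(small_sample.ct)
    labels = small_sample.labels.labels
    p = _random_probs(rng, (N_CLASSES,) + labels.shape)

    only_dice = LossWeights(alpha=0, beta=0, lambda_ord=0, lambda_ovl=0)
    total, comp = seg_loss(p, labels, stack.edge_map, stack.body_mask,
                           only_dice, small_sample.ct.spacing)
    assert total == pytest.approx(comp["focal_dice"], rel=1e-6)

    w = LossWeights()
    total, comp = seg_loss(p, labels, stack.edge_map, stack.body_mask, w,
                           small_sample.ct.spacing)
    recon = comp["focal_dice"] + w.alpha * comp["weighted_ce"] \
        + w.beta * comp["boundary"] + w.lambda_ord * comp["ordering"] \
        + w.lambda_ovl * comp["overlap"]
    assert total == pytest.approx(recon, abs=1e-8)
    assert all(v >= 0 for v in comp.values())

    # monotone nondecreasing in each weight
    heavier = LossWeights(alpha=2.0, beta=1.0, lambda_ord=0.5,
                          lambda_ovl=0.5)
    total2, _ = seg_loss(p, labels, stack.edge_map, stack.body_mask,
                         heavier, small_sample.ct.spacing)
    assert total2 >= total

    # a perfect (one-hot) prediction drives the total near zero
    oh = onehot_encode(labels).astype(np.float32)
    total3, _ = seg_loss(
        oh, labels, np.zeros_like(stack.edge_map), stack.body_mask,
        LossWeights(beta=0.0), small_sample.ct.spacing)
    assert total3 < 1e-3


def test_loss_weight_validation():
    with pytest.raises(ValueError):
        LossWeights(gamma=0.5)
    with pytest.raises(ValueError):
        LossWeights(alpha=-1.0)
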