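"""Fracture classifier: chain-operator algebra, head arithmetic,
threshold calibration against exhaustive sweeps, and the effect of the
level embeddings."""

import numpy as np
import pytest

from cspine.classify import (ClassifierConfig, FractureClassifier,
                             SubjectFeatures, calibrate_threshold,
                             chain_operator, cls_loss, fracture_head,
                             message_pass, pool_roi_feature,
                             predict_subjects, train_classifier)
from cspine.networks import ViTConfig, ViTEncoder


def test_chain_operator_entries():
    op = chain_operator()
    a_hat = op.a_hat
    assert a_hat[0, 0] == pytest.approx(0.5)            # 1/sqrt(2*2)
    assert a_hat[0, 1] == pytest.approx(1 / np.sqrt(6))  # 1/sqrt(2*3)
    assert a_hat[2, 1] + a_hat[2, 2] + a_hat[2, 3] == pytest.approx(1.0)
    # brute-force D^{-1/2} (A+I) D^{-1/2}
    a = op.adjacency
    d = np.diag(1.0 / np.sqrt((a + np.eye(7)).sum(axis=1)))
    brute = d @ (a + np.eye(7)) @ d
    assert np.abs(a_hat - brute).max() < 1e-12
    assert np.abs(a_hat - a_hat.T).max() < 1e-12
    assert np.all(np.diag(a) == 0)


def test_message_pass_rowsums_and_modes(rng):
    ones = np.ones((7, 1), dtype=np.float32)
    out = message_pass(ones, weight=np.eye(1, dtype=np.float32),
                       activation="identity")
    rowsums = chain_operator().a_hat.sum(axis=1)
    assert np.allclose(out[:, 0], rowsums, atol=1e-6)
    assert out[2, 0] == pytest.approx(1.0, abs=1e-6)  # interior-flanked row

    z = rng.normal(size=(7, 5)).astype(np.float32)
    assert np.allclose(message_pass(z, weight=np.zeros((5, 5))), 0.0)
    assert np.array_equal(message_pass(z, enabled=False), z)


def test_fracture_head_arithmetic(rng):
    z = rng.normal(size=(3, 6)).astype(np.float32)
    w1 = rng.normal(size=(6, 4)).astype(np.float32)
    assert np.allclose(fracture_head(z, w1, np.zeros((4, 1)),
                                     np.zeros(1)), 0.5)
    assert np.all(fracture_head(z, w1, np.zeros((4, 1)),
                                np.full(1, 50.0)) > 0.999)
    a = fracture_head(z, w1, rng.normal(size=(4, 1)), np.zeros(1))
    b = fracture_head(z, w1, rng.normal(size=(4, 1)), np.zeros(1))
    # evaluation mode: deterministic given fixed weights
    w2 = rng.normal(size=(4, 1)).astype(np.float32)
    assert np.array_equal(fracture_head(z, w1, w2, np.zeros(1)),
                          fracture_head(z, w1, w2, np.zeros(1)))


def test_cls_loss_values_and_oracle(rng):
    y = np.array([1.0, 0.0, 1.0])
    assert cls_loss(np.array([1.0, 0.0, 1.0]), y) < 1e-5
    assert cls_loss(np.full(3, 0.5), y) == pytest.approx(np.log(2),
                                                         rel=1e-6)
    p = rng.random(20)
    yy = rng.integers(0, 2, 20)
    brute = -np.mean([yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                      for pi, yi in zip(np.clip(p, 1e-7, 1 - 1e-7), yy)])
    assert cls_loss(p, yy) == pytest.approx(brute, abs=1e-6)
    with pytest.raises(ValueError):
        cls_loss(np.array([]), np.array([]))


def test_calibrate_threshold_enumeration(rng):
    thr = calibrate_threshold([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1])
    assert 0.4 < thr < 0.6
    pred = np.array([0.1, 0.4, 0.6, 0.9]) >= thr
    assert np.array_equal(pred, [False, False, True, True])  # F1 = 1

    # exhaustive sweep oracle on 200 random instances
    p = rng.random(200)
    y = rng.integers(0, 2, 200)

    def f1_at(t):
        pr = p >= t
        tp = np.sum(pr & (y == 1))
        den = 2 * tp + np.sum(pr & (y == 0)) + np.sum(~pr & (y == 1))
        return 2 * tp / den if den else 0.0

    thr = calibrate_threshold(p, y)
    best = max(f1_at(t) for t in np.unique(p))
    assert f1_at(thr) == pytest.approx(best, abs=1e-12)

    with pytest.raises(ValueError):
        calibrate_threshold([0.2, 0.6], [1, 1])


def test_pool_roi_feature_matches_token_average(rng):
    cfg = ViTConfig(in_chans=1, patch_size=8, d=32, depth=2, heads=4,
                    ref_grid=(2, 2, 2))
    enc = ViTEncoder(cfg, np.random.default_rng(0))
    roi = rng.random((16, 16, 16)).astype(np.float32)
    z = pool_roi_feature(roi, enc)
    from cspine import autodiff as ad
    with ad.no_grad():
        tokens, grid = enc.tokenize(roi[None])
        toks = enc.forward(tokens, grid)[-1].data
    brute = sum(toks[i] for i in range(toks.shape[0])) / toks.shape[0]
    assert np.abs(z - brute).max() < 1e-6
    assert np.array_equal(z, pool_roi_feature(roi, enc))

    empty = pool_roi_feature(np.zeros((16, 16, 16)), enc)
    assert np.linalg.norm(z - empty) > 0

    with pytest.raises(ValueError):
        pool_roi_feature(rng.random((15, 16, 16)), enc)


def _toy_subjects(rng, n, d=8, effect=3.0, prevalence=0.4):
    subs = []
    for i in range(n):
        y = (rng.random(7) < prevalence).astype(int)
        feats = rng.normal(size=(7, d)).astype(np.float32)
        feats[:, 0] += effect * y
        subs.append(SubjectFeatures(study_id=f"s{i}", features=feats,
                                    available=np.ones(7, bool), labels=y))
    return subs


def test_classifier_learns_separable_features(rng):
    cfg = ClassifierConfig(feature_dim=8, hidden=8, epochs=120, dropout=0.1)
    train = _toy_subjects(rng, 30)
    val = _toy_subjects(rng, 12)
    model, info = train_classifier(train, val, cfg, seed=1)
    from cspine.metrics import roc_pr
    p, y = predict_subjects(model, val)
    assert roc_pr(p, y)["auc"] > 0.9
    assert 0.0 < info["threshold"] < 1.0


def test_level_embedding_effect_is_live(rng):
    """With embeddings, identical ROI features at different levels can
    yield different probabilities; without them they cannot."""
    feats = np.tile(rng.normal(size=(1, 8)).astype(np.float32), (7, 1))
    sub = SubjectFeatures("s", feats, np.ones(7, bool),
                          np.zeros(7, dtype=int))
    with_emb = FractureClassifier(
        ClassifierConfig(feature_dim=8, level_embeddings=True),
        np.random.default_rng(3))
    p1 = with_emb.forward(sub).data
    assert np.ptp(p1) > 1e-6

    without = FractureClassifier(
        ClassifierConfig(feature_dim=8, level_embeddings=False),
        np.random.default_rng(3))
    p2 = without.forward(sub).data
    assert np.ptp(p2) < 1e-7


def test_missing_levels_are_excluded(rng):
    subs = _toy_subjects(rng, 10)
    subs[0].available[2] = False
    model, info = train_classifier(
        subs[:8], subs[8:],
        ClassifierConfig(feature_dim=8, hidden=8, epochs=5), seed=0)
    p, y = predict_subjects(model, [subs[0]])
    assert len(p) == 6  # the unavailable level is not assessed
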