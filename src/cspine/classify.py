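"""Stage 3: vertebra-level fracture classification.

Each standardized ROI is encoded by the (frozen) Stage-1 encoder and
mean-pooled to a compact feature ``z_k``; a learnable level embedding
``e_k`` is concatenated (``z'_k = z_k || e_k``) so the classifier knows
which vertebra it is seeing. An optional single message-passing step
``Z'' = ReLU(Â Z' W)`` over the C1↔C2↔…↔C7 chain graph (Â the
degree-normalized adjacency with self-loops) diffuses cues along the
cranio-caudal axis. A two-layer MLP head with dropout produces the
per-level fracture probability ``p̂_k = σ(W2·ReLU(W1·z''_k) + b2)``;
training minimizes binary cross-entropy over balanced mini-batches, and
the operating threshold is calibrated on validation data to maximize F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Module, Parameter, Tensor, as_tensor, stack
from .ctio import N_LEVELS
from .networks import ViTEncoder

__all__ = [
    "SubjectFeatures",
    "ChainGraphOperator",
    "pool_roi_feature",
    "chain_operator",
    "message_pass",
    "fracture_head",
    "cls_loss",
    "calibrate_threshold",
    "ClassifierConfig",
    "FractureClassifier",
    "train_classifier",
    "predict_subjects",
]

_PROB_CLIP = 1e-7


@dataclass
class SubjectFeatures:
    """Pooled ROI features for one study; missing levels carry a zero
    feature row and ``available = False``."""

    study_id: str
    features: np.ndarray            # (7, d)
    available: np.ndarray           # (7,) bool
    labels: np.ndarray | None = None  # (7,) 0/1 ground truth


def pool_roi_feature(roi: np.ndarray, encoder: ViTEncoder) -> np.ndarray:
    """Mean-pool the encoder's final token features of one ROI volume
    (already bone-window normalized) into a single (d,) vector."""
    roi = np.asarray(roi, dtype=np.float32)
    if roi.ndim != 3:
        raise ValueError("ROI must be a 3-D volume")
    p = encoder.config.patch_size
    if any(s % p for s in roi.shape):
        raise ValueError(f"ROI shape {roi.shape} not divisible by patch {p}")
    with ad.no_grad():
        tokens, grid = encoder.tokenize(roi[None])
        out = encoder.forward(tokens, grid)[-1]
    return out.data.mean(axis=0)


# ---------------------------------------------------------------------------
# Chain-graph message passing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainGraphOperator:
    adjacency: np.ndarray   # (7, 7) chain, zero diagonal
    a_hat: np.ndarray       # D^{-1/2} (A + I) D^{-1/2}


def chain_operator(n_levels: int = N_LEVELS) -> ChainGraphOperator:
    """Normalized chain operator ``Â = D^{−1/2}(A+I)D^{−1/2}`` for the
    C1↔C2↔…↔C7 chain with self-loops."""
    a = np.zeros((n_levels, n_levels))
    for k in range(n_levels - 1):
        a[k, k + 1] = a[k + 1, k] = 1.0
    a_self = a + np.eye(n_levels)
    d = a_self.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return ChainGraphOperator(adjacency=a,
                              a_hat=dinv[:, None] * a_self * dinv[None, :])


def message_pass(z_prime, operator: ChainGraphOperator | None = None,
                 weight=None, activation: str = "relu",
                 enabled: bool = True):
    """One step ``Z'' = act(Â Z' W)``; missing-level rows participate as
    zeros. ``enabled=False`` returns ``Z'`` unchanged. Accepts numpy or
    Tensors."""
    numpy_in = not isinstance(z_prime, Tensor)
    z = as_tensor(z_prime)
    if not enabled:
        return z.data if numpy_in else z
    op = operator or chain_operator(z.shape[0])
    out = Tensor(op.a_hat.astype(np.float32)) @ z
    if weight is not None:
        out = out @ as_tensor(weight)
    if activation == "relu":
        out = out.relu()
    elif activation != "identity":
        raise ValueError(f"unknown activation {activation!r}")
    return out.data if numpy_in else out


def fracture_head(z, w1, w2, b2, dropout_rate: float = 0.0,
                  training: bool = False,
                  rng: np.random.Generator | None = None):
    """``p̂ = σ(W2·ReLU(W1·z) + b2)`` per row of ``z``; dropout on the
    hidden layer only in training mode."""
    numpy_in = not isinstance(z, Tensor)
    zt = as_tensor(z)
    squeeze = zt.ndim == 1
    if squeeze:
        zt = zt.reshape(1, -1)
    h = (zt @ as_tensor(w1)).relu()
    if training and dropout_rate > 0.0:
        rng = rng or np.random.default_rng()
        keep = (rng.random(h.shape) >= dropout_rate).astype(np.float32)
        h = h * Tensor(keep / max(1.0 - dropout_rate, 1e-8))
    p = ((h @ as_tensor(w2)) + as_tensor(b2)).sigmoid()
    if squeeze:
        p = p.reshape(-1)
    return p.data if numpy_in else p


def cls_loss(p_hat, y):
    """Mean binary cross-entropy over the vertebra instances in a batch;
    probabilities are clipped at 1e-7."""
    yv = np.asarray(y, dtype=np.float32).ravel()
    if yv.size == 0:
        raise ValueError("batch contains no vertebra instances")
    numpy_in = not isinstance(p_hat, Tensor)
    p = as_tensor(p_hat).reshape(-1).clip(_PROB_CLIP, 1.0 - _PROB_CLIP)
    yt = Tensor(yv)
    loss = -(yt * p.log() + (1.0 - yt) * (1.0 - p).log()).mean()
    return loss.item() if numpy_in else loss


def calibrate_threshold(probabilities, labels) -> float:
    """Threshold (from sorted unique-probability midpoints) maximizing
    validation F1; ties break toward the higher threshold (higher
    specificity). Decisions are ``p >= threshold``."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("calibration requires both classes in validation")
    uniq = np.unique(p)
    if len(uniq) == 1:
        return float(uniq[0])
    # midpoints between distinct scores, plus the lowest score itself
    # (the all-positive operating point)
    mids = np.concatenate([[uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0])
    best_thr, best_f1 = mids[0], -1.0
    for thr in mids:
        pred = p >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 >= best_f1:  # >= keeps the highest qualifying threshold
            best_f1, best_thr = f1, thr
    return float(best_thr)


# ---------------------------------------------------------------------------
# Model and training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    feature_dim: int = 64
    level_embed_dim: int = 16
    hidden: int = 32
    dropout: float = 0.2
    message_passing: bool = False
    level_embeddings: bool = True
    epochs: int = 150
    lr: float = 5e-3
    batch_subjects: int = 16


class FractureClassifier(Module):
    """Level embeddings + optional chain message passing + MLP head."""

    def __init__(self, config: ClassifierConfig, rng: np.random.Generator):
        self.config = config
        d_total = config.feature_dim + (config.level_embed_dim
                                        if config.level_embeddings else 0)
        self.embed = Parameter(rng.normal(
            0, 0.1, size=(N_LEVELS, config.level_embed_dim)
        ).astype(np.float32)) if config.level_embeddings else None
        self.operator = chain_operator()
        self.mix = Parameter(
            (np.eye(d_total) + rng.normal(0, 0.02, size=(d_total, d_total)))
            .astype(np.float32)) if config.message_passing else None
        # training-set feature standardization (set by train_classifier)
        self.feat_mean = np.zeros(config.feature_dim, dtype=np.float32)
        self.feat_std = np.ones(config.feature_dim, dtype=np.float32)
        self.w1 = Parameter(rng.normal(
            0, 1.0 / np.sqrt(d_total), size=(d_total, config.hidden)
        ).astype(np.float32))
        self.w2 = Parameter(rng.normal(
            0, 1.0 / np.sqrt(config.hidden), size=(config.hidden, 1)
        ).astype(np.float32))
        self.b2 = Parameter(np.zeros(1, dtype=np.float32))

    def forward(self, subject: SubjectFeatures, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Per-level fracture probabilities (7,); rows of unavailable
        levels are computed but ignored by the loss."""
        avail = np.asarray(subject.available, dtype=np.float32)[:, None]
        standardized = (subject.features - self.feat_mean) / self.feat_std
        feats = Tensor(standardized.astype(np.float32) * avail)
        if self.embed is not None:
            zp = ad.concat([feats, self.embed], axis=1)
        else:
            zp = feats
        zp = zp * Tensor(avail)  # missing-level rows stay zero
        z2 = message_pass(zp, self.operator, weight=self.mix,
                          enabled=self.mix is not None)
        return fracture_head(z2, self.w1, self.w2, self.b2,
                             dropout_rate=self.config.dropout,
                             training=training, rng=rng).reshape(-1)


def _balanced_instances(subjects, rng) -> list[tuple[int, int]]:
    """(subject, level) pairs with fractured instances oversampled to a
    1:1 ratio against sampled non-fractured ones."""
    pos, neg = [], []
    for si, s in enumerate(subjects):
        for k in range(N_LEVELS):
            if not s.available[k]:
                continue
            (pos if s.labels[k] else neg).append((si, k))
    if not pos or not neg:
        return pos + neg
    n = max(len(pos), 1)
    neg_sel = [neg[i] for i in rng.choice(len(neg), size=min(n, len(neg)),
                                          replace=False)]
    return pos + neg_sel


def train_classifier(train: list[SubjectFeatures],
                     val: list[SubjectFeatures],
                     config: ClassifierConfig | None = None,
                     seed: int = 0):
    """Train the fracture classifier on pooled ROI features.

    Returns ``(model, info)`` where info holds the calibrated threshold
    and validation probabilities/labels. Deterministic for fixed seed.
    """
    cfg = config or ClassifierConfig()
    rng = np.random.default_rng(seed)
    model = FractureClassifier(cfg, rng)
    rows = np.concatenate([s.features[np.asarray(s.available, bool)]
                           for s in train], axis=0)
    if len(rows):
        model.feat_mean = rows.mean(axis=0).astype(np.float32)
        model.feat_std = np.maximum(rows.std(axis=0), 1e-6).astype(np.float32)
    opt = Adam(model.parameters(), lr=cfg.lr)
    history = []
    idx = np.arange(len(train))
    for epoch in range(cfg.epochs):
        rng.shuffle(idx)
        losses = []
        for start in range(0, len(idx), cfg.batch_subjects):
            batch = [train[i] for i in idx[start:start + cfg.batch_subjects]]
            pairs = _balanced_instances(batch, rng)
            if not pairs:
                continue
            probs = stack([model.forward(s, training=True, rng=rng)
                           for s in batch], axis=0)
            sel = probs[tuple(np.array(pairs).T)]
            yb = np.array([batch[si].labels[k] for si, k in pairs],
                          dtype=np.float32)
            loss = cls_loss(sel, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)) if losses else np.nan)
    val_probs, val_labels = predict_subjects(model, val)
    threshold = calibrate_threshold(val_probs, val_labels)
    return model, {"threshold": threshold, "val_probs": val_probs,
                   "val_labels": val_labels, "loss_history": history}


def predict_subjects(model: FractureClassifier,
                     subjects: list[SubjectFeatures]):
    """Deterministic (eval-mode) probabilities and labels for all
    available vertebra instances, flattened across subjects."""
    probs, labels = [], []
    with ad.no_grad():
        for s in subjects:
            p = model.forward(s, training=False).data
            for k in range(N_LEVELS):
                if s.available[k]:
                    probs.append(float(p[k]))
                    labels.append(int(s.labels[k]) if s.labels is not None
                                  else -1)
    return np.asarray(probs), np.asarray(labels)
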