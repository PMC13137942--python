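"""Cross-validation folds, training loops, and the staged runner.

The runner ties the stages together on phantom cohorts: ``phantom``
writes a synthetic cohort; ``pretrain`` fits the masked autoencoder;
``segment`` trains the gated-attention U-Net on the labeled training
split; ``classify`` trains the vertebra-level fracture classifier with
patient-wise cross-validation and per-fold threshold calibration;
``evaluate`` aggregates unseen test predictions from all folds into a
metrics report. Every run directory records a manifest with the config
hash, the root seed, and digests of its input files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Adam, load_checkpoint, save_checkpoint
from .classify import (ClassifierConfig, SubjectFeatures, pool_roi_feature,
                       predict_subjects, train_classifier)
from .ctio import CTVolume, N_LEVELS, SegLabelVolume, load_nifti, save_nifti
from .metrics import ConfusionCounts, classification_metrics, dice_iou, roc_pr
from .networks import (SegConfig, SegNet, ViTConfig, ViTEncoder,
                       load_encoder_state, seg_forward)
from .phantom import (PhantomSpec, default_levels_for_grid,
                      generate_cohort, save_cohort)
from .postprocess import (DEFAULT_ROI_SHAPE, DEFAULT_ROI_SPACING,
                          clean_labels, extract_roi, vertebra_geometry)
from .preprocess import build_prior_stack
from .pretrain import MAETrainConfig, pretrain_loop
from .seglosses import LossWeights, seg_loss

__all__ = [
    "FoldAssignment",
    "make_folds",
    "SegTrainConfig",
    "train_segmentation",
    "predict_volume",
    "subject_features_from_sample",
    "run_stage",
]


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    assignments: dict[str, int]
    k: int
    table: pd.DataFrame

    def fold_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f != fold]

    def level_counts(self) -> np.ndarray:
        """(k, 7) fractured-vertebra counts per fold and level."""
        counts = np.zeros((self.k, N_LEVELS), dtype=int)
        cols = [f"C{i}" for i in range(1, N_LEVELS + 1)]
        for _, row in self.table.iterrows():
            counts[self.assignments[row["study_id"]]] += \
                row[cols].to_numpy(dtype=int)
        return counts


def make_folds(table: pd.DataFrame, k: int = 5,
               seed: int = 0) -> FoldAssignment:
    """Patient-wise stratified k-fold assignment.

    ``table`` has columns study_id, C1..C7 (binary). Studies are
    assigned greedily (most-fractured first, seeded tie-breaking) to the
    eligible fold that best balances per-level fracture counts; fold
    sizes differ by at most one.
    """
    n = len(table)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} studies")
    cols = [f"C{i}" for i in range(1, N_LEVELS + 1)]
    rng = np.random.default_rng(seed)
    rows = list(table[["study_id"] + cols].itertuples(index=False))
    order = sorted(range(n),
                   key=lambda i: (-sum(rows[i][1:]), rng.random()))
    base, extra = divmod(n, k)
    sizes = np.zeros(k, dtype=int)
    counts = np.zeros((k, N_LEVELS), dtype=float)
    assignments: dict[str, int] = {}
    for i in order:
        sid, *y = rows[i]
        y = np.asarray(y, dtype=float)
        at_cap = int(np.sum(sizes > base))
        eligible = [f for f in range(k)
                    if sizes[f] < base or (sizes[f] == base
                                           and at_cap < extra)]
        # fold currently least loaded on this study's fractured levels,
        # then least loaded overall, then smallest
        fold = min(eligible,
                   key=lambda f: (float(counts[f] @ y),
                                  float(counts[f].sum()), sizes[f], f))
        assignments[sid] = fold
        sizes[fold] += 1
        counts[fold] += y
    return FoldAssignment(assignments=assignments, k=k, table=table.copy())


# ---------------------------------------------------------------------------
# Segmentation training / inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegTrainConfig:
    seg: SegConfig = field(default_factory=lambda: SegConfig(
        encoder=ViTConfig(in_chans=3, patch_size=8, d=64, depth=4, heads=4,
                          ref_grid=(8, 8, 8))))
    crop: int = 64
    epochs: int = 10
    steps_per_epoch: int = 8
    lr: float = 3e-3
    weights: LossWeights = field(default_factory=LossWeights)
    freeze_fraction: float = 0.2  # of epochs with lowest blocks frozen


def _labeled_crop(labels: np.ndarray, crop: int,
                  rng: np.random.Generator) -> tuple[int, int, int]:
    """Crop origin whose window is centered near a random labeled voxel."""
    fg = np.argwhere(labels > 0)
    center = fg[rng.integers(len(fg))] if len(fg) else \
        np.array(labels.shape) // 2
    origin = []
    for c, s in zip(center, labels.shape):
        o = int(np.clip(c - crop // 2, 0, s - crop))
        origin.append(o)
    return tuple(origin)


def train_segmentation(samples, config: SegTrainConfig | None = None,
                       encoder_state: dict | None = None,
                       sample_weights=None, seed: int = 0,
                       net: SegNet | None = None):
    """Train the Stage-2 network on (ct, labels) samples.

    ``samples`` is a list of objects with ``.ct`` and ``.labels``;
    ``sample_weights`` biases case sampling (confidence-based mixing of
    pseudo-labeled cases). With ``encoder_state`` the encoder starts from
    Stage-1 weights and the lowest ⌈L/3⌉ blocks stay frozen for the
    first ``freeze_fraction`` of epochs before being unfrozen.
    Returns ``(net, trace)`` with the per-epoch mean composite loss.
    """
    cfg = config or SegTrainConfig()
    rng = np.random.default_rng(seed)
    if net is None:
        net = SegNet(cfg.seg, rng)
    if encoder_state is not None:
        load_encoder_state(net.encoder, encoder_state)
    depth = cfg.seg.encoder.depth
    n_freeze = int(np.ceil(depth / 3))
    frozen: list = []
    for blk in net.encoder.blocks[:n_freeze]:
        frozen.extend(blk.parameters())
    freeze_epochs = int(np.ceil(cfg.freeze_fraction * cfg.epochs)) \
        if encoder_state is not None else 0
    opt = Adam(net.parameters(), lr=cfg.lr)
    weights = None
    if sample_weights is not None:
        weights = np.asarray(sample_weights, dtype=float)
        weights = weights / weights.sum()
    trace = []
    stacks = [build_prior_stack(s.ct) for s in samples]
    for epoch in range(cfg.epochs):
        losses = []
        for _ in range(cfg.steps_per_epoch):
            i = int(rng.choice(len(samples), p=weights))
            sample, stack = samples[i], stacks[i]
            c = cfg.crop
            ox, oy, oz = _labeled_crop(sample.labels.labels, c, rng)
            sl = (slice(ox, ox + c), slice(oy, oy + c), slice(oz, oz + c))
            chans = stack.channels()[(slice(None),) + sl]
            probs = seg_forward(chans, net).softmax(axis=0)
            loss, _ = seg_loss(probs, sample.labels.labels[sl],
                               stack.edge_map[sl], stack.body_mask[sl],
                               cfg.weights, spacing=sample.ct.spacing)
            opt.zero_grad()
            loss.backward()
            if epoch < freeze_epochs:
                for p in frozen:
                    p.grad = None
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)))
    return net, trace


def predict_volume(net: SegNet, ct: CTVolume, tile: int = 64):
    """Tile-wise inference over a full volume.

    Returns ``(probs, labels)``: the (8, X, Y, Z) softmax output and the
    argmax label volume. Volume axes must be divisible by the encoder
    patch size.
    """
    stack = build_prior_stack(ct)
    chans = stack.channels()
    shape = chans.shape[1:]
    p = net.config.encoder.patch_size
    if any(s % p for s in shape):
        raise ValueError(f"volume shape {shape} not divisible by patch {p}")
    probs = np.zeros((net.config.n_classes,) + shape, dtype=np.float32)
    steps = [range(0, s, min(tile, s)) for s in shape]
    with ad.no_grad():
        for ox in steps[0]:
            for oy in steps[1]:
                for oz in steps[2]:
                    sl = (slice(ox, min(ox + tile, shape[0])),
                          slice(oy, min(oy + tile, shape[1])),
                          slice(oz, min(oz + tile, shape[2])))
                    block = chans[(slice(None),) + sl]
                    probs[(slice(None),) + sl] = \
                        seg_forward(block, net).softmax(axis=0).data
    labels = SegLabelVolume(np.argmax(probs, axis=0).astype(np.int16),
                            ct.spacing, ct.origin)
    return probs, labels


# ---------------------------------------------------------------------------
# Stage-3 plumbing
# ---------------------------------------------------------------------------

def subject_features_from_sample(ct: CTVolume, labels: SegLabelVolume,
                                 encoder: ViTEncoder, study_id: str,
                                 fracture_labels=None,
                                 probs: np.ndarray | None = None,
                                 roi_shape=DEFAULT_ROI_SHAPE,
                                 roi_spacing=DEFAULT_ROI_SPACING
                                 ) -> SubjectFeatures:
    """Clean the label volume, derive per-level OBB geometry, extract
    standardized ROIs, and pool encoder features for one study. Missing
    levels get zero features and ``available = False``."""
    cleaned = clean_labels(labels)
    d = encoder.config.d
    feats = np.zeros((N_LEVELS, d), dtype=np.float32)
    avail = np.zeros(N_LEVELS, dtype=bool)
    for level in range(1, N_LEVELS + 1):
        geom = vertebra_geometry(cleaned, probs, level)
        if geom is None:
            continue
        roi = extract_roi(ct, geom, roi_shape, roi_spacing)
        feats[level - 1] = pool_roi_feature(roi, encoder)
        avail[level - 1] = True
    y = None if fracture_labels is None else \
        np.asarray(fracture_labels, dtype=int)
    return SubjectFeatures(study_id=study_id, features=feats,
                           available=avail, labels=y)


# ---------------------------------------------------------------------------
# Stage runner
# ---------------------------------------------------------------------------

STAGES = ("phantom", "pretrain", "segment", "classify", "evaluate")


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True,
                                     default=str).encode()).hexdigest()[:16]


def _file_digest(paths) -> str:
    h = hashlib.sha256()
    for p in sorted(str(p) for p in paths):
        st = Path(p).stat()
        h.update(f"{Path(p).name}:{st.st_size}".encode())
    return h.hexdigest()[:16]


def _write_manifest(run_dir: Path, stage: str, config: dict, seed: int,
                    inputs) -> None:
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "config_hash": _digest(config),
        "input_digest": _file_digest(inputs) if inputs else None,
        "config": config,
    }
    with open(run_dir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _load_cohort(data_dir: Path):
    df = pd.read_csv(data_dir / "fracture_labels.csv")
    subjects = []
    for sid in df["study_id"]:
        ct = load_nifti(data_dir / f"{sid}_ct.nii.gz")
        labels = load_nifti(data_dir / f"{sid}_labels.nii.gz", labels=True)
        subjects.append((sid, ct, labels))
    return df, subjects


class _Sample:
    def __init__(self, ct, labels):
        self.ct = ct
        self.labels = labels


def run_stage(stage: str, config: dict, workdir) -> dict:
    """Execute one pipeline stage under ``workdir``; returns a summary
    dict of the artifacts written. Raises ``FileNotFoundError`` naming
    any missing prerequisite artifact."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    workdir = Path(workdir)
    seed = int(config.get("seed", 0))
    data_dir = workdir / "data"
    ckpt_dir = workdir / "checkpoints"
    out: dict = {"stage": stage}

    if stage == "phantom":
        ph = config.get("phantom", {})
        shape = tuple(ph.get("shape", (128, 128, 160)))
        spacing = tuple(ph.get("spacing", (1.0, 1.0, 2.0)))
        spec = PhantomSpec(
            shape=shape, spacing=spacing,
            levels=default_levels_for_grid(shape, spacing),
            body_radius_mm=0.38 * min(shape[0] * spacing[0],
                                      shape[1] * spacing[1]))
        samples = generate_cohort(int(ph.get("n_subjects", 12)),
                                  base_spec=spec,
                                  prevalence=float(ph.get("prevalence", 0.14)),
                                  variability=float(ph.get("variability",
                                                           0.08)),
                                  seed=seed)
        ids = save_cohort(samples, data_dir)
        _write_manifest(workdir, stage, config, seed, [])
        out.update(n_subjects=len(ids), data_dir=str(data_dir))
        return out

    if not (data_dir / "fracture_labels.csv").exists():
        raise FileNotFoundError(f"missing prerequisite "
                                f"{data_dir / 'fracture_labels.csv'}; run the "
                                "'phantom' stage first")
    df, subjects = _load_cohort(data_dir)
    inputs = sorted(data_dir.glob("*"))

    if stage == "pretrain":
        pc = config.get("pretrain", {})
        vit = ViTConfig(in_chans=1,
                        patch_size=int(pc.get("patch_size", 8)),
                        d=int(pc.get("d", 64)),
                        depth=int(pc.get("depth", 4)),
                        heads=int(pc.get("heads", 4)),
                        ref_grid=tuple(pc.get("ref_grid", (4, 4, 4))))
        cfg = MAETrainConfig(epochs=int(pc.get("epochs", 5)),
                             crop=int(pc.get("crop", 32)),
                             crops_per_volume=int(pc.get("crops_per_volume",
                                                         2)),
                             vit=vit,
                             mask_ratio=float(pc.get("mask_ratio", 0.7)),
                             bias_eta=float(pc.get("bias_eta", 0.5)),
                             lr=float(pc.get("lr", 1e-3)))
        model, trace = pretrain_loop([ct for _, ct, _ in subjects], cfg,
                                     seed=seed)
        save_checkpoint(ckpt_dir / "encoder.npz",
                        model.encoder.state_dict(),
                        {"vit": cfg.vit.__dict__})
        pd.DataFrame({"epoch": range(len(trace)), "mae_loss": trace}) \
            .to_csv(workdir / "pretrain_loss.csv", index=False)
        _write_manifest(workdir, stage, config, seed, inputs)
        out.update(checkpoint=str(ckpt_dir / "encoder.npz"),
                   final_loss=trace[-1])
        return out

    folds = make_folds(df, k=int(config.get("k_folds", 5)), seed=seed)

    if stage == "segment":
        sc = config.get("segment", {})
        enc_path = ckpt_dir / "encoder.npz"
        if sc.get("random_init", False):
            enc_state = None
        elif enc_path.exists():
            enc_state, _ = load_checkpoint(enc_path)
        else:
            raise FileNotFoundError(f"missing prerequisite {enc_path}; run "
                                    "'pretrain' or set segment.random_init")
        fold = int(sc.get("fold", 0))
        train_ids = set(folds.train_ids(fold))
        train_samples = [_Sample(ct, lab) for sid, ct, lab in subjects
                         if sid in train_ids]
        cfg = SegTrainConfig(epochs=int(sc.get("epochs", 2)),
                             steps_per_epoch=int(sc.get("steps_per_epoch", 4)),
                             crop=int(sc.get("crop", 64)))
        net, trace = train_segmentation(train_samples, cfg,
                                        encoder_state=enc_state, seed=seed)
        save_checkpoint(ckpt_dir / "segnet.npz", net.state_dict(),
                        {"fold": fold})
        pred_dir = workdir / "predictions"
        dice_rows = []
        for sid, ct, lab in subjects:
            if sid in train_ids:
                continue
            probs, pred = predict_volume(net, ct)
            save_nifti(clean_labels(pred), pred_dir / f"{sid}_pred.nii.gz")
            d = dice_iou(clean_labels(pred).labels, lab.labels)
            dice_rows.append({"study_id": sid, "macro_dice": d["macro_dice"]})
        pd.DataFrame(dice_rows).to_csv(workdir / "segment_dice.csv",
                                       index=False)
        _write_manifest(workdir, stage, config, seed, inputs)
        out.update(checkpoint=str(ckpt_dir / "segnet.npz"),
                   loss_trace=trace)
        return out

    if stage == "classify":
        cc = config.get("classify", {})
        enc_path = ckpt_dir / "encoder.npz"
        if not enc_path.exists():
            raise FileNotFoundError(f"missing prerequisite {enc_path}; run "
                                    "'pretrain' first")
        enc_state, enc_cfg = load_checkpoint(enc_path)
        rng = np.random.default_rng(seed)
        encoder = ViTEncoder(ViTConfig(**{**enc_cfg["vit"],
                                          "ref_grid": tuple(
                                              enc_cfg["vit"]["ref_grid"])}),
                             rng)
        load_encoder_state(encoder, enc_state)
        cols = [f"C{i}" for i in range(1, N_LEVELS + 1)]
        feats = {}
        for sid, ct, lab in subjects:
            y = df.loc[df.study_id == sid, cols].to_numpy()[0]
            feats[sid] = subject_features_from_sample(ct, lab, encoder, sid,
                                                      fracture_labels=y)
        cls_cfg = ClassifierConfig(
            epochs=int(cc.get("epochs", 60)),
            message_passing=bool(cc.get("message_passing", False)),
            feature_dim=encoder.config.d)
        rows = []
        calib = {}
        for fold in range(folds.k):
            train_ids = folds.train_ids(fold)
            test_ids = folds.fold_ids(fold)
            n_val = max(1, len(train_ids) // 5)
            val_ids = train_ids[-n_val:]
            fit_ids = train_ids[:-n_val] or val_ids
            model, info = train_classifier(
                [feats[s] for s in fit_ids], [feats[s] for s in val_ids],
                cls_cfg, seed=seed + fold)
            calib[fold] = info["threshold"]
            for sid in test_ids:
                p, y = predict_subjects(model, [feats[sid]])
                levels = [k + 1 for k in range(N_LEVELS)
                          if feats[sid].available[k]]
                for lv, pi, yi in zip(levels, p, y):
                    rows.append({"study_id": sid, "level": f"C{lv}",
                                 "probability": pi, "label": yi,
                                 "fold": fold,
                                 "decision": int(pi >= info["threshold"]),
                                 "threshold": info["threshold"]})
        pd.DataFrame(rows).to_csv(workdir / "predictions.csv", index=False)
        with open(workdir / "calibration.json", "w") as fh:
            json.dump(calib, fh, indent=2)
        _write_manifest(workdir, stage, config, seed, inputs)
        out.update(predictions=str(workdir / "predictions.csv"),
                   n_rows=len(rows))
        return out

    # evaluate
    pred_path = workdir / "predictions.csv"
    if not pred_path.exists():
        raise FileNotFoundError(f"missing prerequisite {pred_path}; run "
                                "'classify' first")
    preds = pd.read_csv(pred_path)
    curves = roc_pr(preds["probability"].to_numpy(),
                    preds["label"].to_numpy())
    cm = ConfusionCounts(
        tp=int(((preds.decision == 1) & (preds.label == 1)).sum()),
        fp=int(((preds.decision == 1) & (preds.label == 0)).sum()),
        fn=int(((preds.decision == 0) & (preds.label == 1)).sum()),
        tn=int(((preds.decision == 0) & (preds.label == 0)).sum()))
    report = {
        "n_vertebrae": int(len(preds)),
        "auc": curves["auc"],
        "prevalence": curves["prevalence"],
        "confusion": cm.__dict__,
        "metrics": classification_metrics(cm),
    }
    pd.DataFrame({"fpr": curves["fpr"], "tpr": curves["tpr"]}) \
        .to_csv(workdir / "roc_points.csv", index=False)
    pd.DataFrame({"precision": curves["precision"],
                  "recall": curves["recall"]}) \
        .to_csv(workdir / "pr_points.csv", index=False)
    with open(workdir / "metrics_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _write_manifest(workdir, stage, config, seed, inputs)
    out.update(report=report)
    return out
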