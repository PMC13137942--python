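"""Morphology-consistent pseudo-labeling for semi-supervised segmentation.

A trained seed model predicts masks on unlabeled studies; per level,
the (cleaned) component is accepted only if its volume reaches a
vertebra-specific minimum AND its mean softmax probability reaches a
confidence threshold. Accepted pseudo-labeled studies are mixed with
the labeled set using confidence-based sampling weights, and the model
is retrained for one or two rounds. Pseudo-labels are only ever
generated on the training split; a provenance log records every
decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ctio import N_LEVELS, SegLabelVolume
from .postprocess import clean_labels

__all__ = [
    "PseudoMaskRecord",
    "DEFAULT_MIN_VOLUMES",
    "DEFAULT_PROB_THRESHOLD",
    "filter_pseudo_mask",
    "mix_training_set",
    "self_train_round",
]

# phantom-scaled defaults: C1 is the smallest (ring) vertebra
DEFAULT_MIN_VOLUMES = (500.0,) + (700.0,) * (N_LEVELS - 1)  # mm^3
DEFAULT_PROB_THRESHOLD = 0.8


@dataclass
class PseudoMaskRecord:
    study_id: str
    accepted: np.ndarray        # (7,) bool
    mean_prob: np.ndarray       # (7,) mean softmax prob (nan if absent)
    volume_mm3: np.ndarray      # (7,) component volume
    sampling_weight: float = 0.0

    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))


def filter_pseudo_mask(probs: np.ndarray, cleaned: SegLabelVolume,
                       min_volumes=DEFAULT_MIN_VOLUMES,
                       prob_threshold: float = DEFAULT_PROB_THRESHOLD,
                       study_id: str = "") :
    """Apply the conjunctive volume/confidence rule per level.

    Returns ``(record, filtered_labels)``; rejected levels are reset to
    background. ``probs`` is the (8, X, Y, Z) softmax output aligned to
    ``cleaned`` (output of :func:`cspine.postprocess.clean_labels`).
    """
    probs = np.asarray(probs)
    voxel_mm3 = float(np.prod(cleaned.spacing))
    accepted = np.zeros(N_LEVELS, dtype=bool)
    mean_prob = np.full(N_LEVELS, np.nan)
    volume = np.zeros(N_LEVELS)
    out = cleaned.labels.copy()
    for k in range(1, N_LEVELS + 1):
        mask = cleaned.labels == k
        n = int(mask.sum())
        if n == 0:
            continue
        volume[k - 1] = n * voxel_mm3
        mean_prob[k - 1] = float(probs[k][mask].mean())
        ok = volume[k - 1] >= min_volumes[k - 1] \
            and mean_prob[k - 1] >= prob_threshold
        accepted[k - 1] = ok
        if not ok:
            out[mask] = 0
    record = PseudoMaskRecord(study_id=study_id, accepted=accepted,
                              mean_prob=mean_prob, volume_mm3=volume)
    return record, SegLabelVolume(out, cleaned.spacing, cleaned.origin)


def mix_training_set(n_labeled: int, records: list[PseudoMaskRecord],
                     temperature: float = 1.0) -> np.ndarray:
    """Sampling weights over labeled + pseudo-labeled cases.

    Labeled cases weigh 1 each; pseudo case i weighs
    ``(mean accepted-level prob)_i ** temperature``, renormalized so the
    total pseudo mass never exceeds the labeled mass (a 50% cap on the
    effective sample). The returned vector sums to 1, labeled first.
    """
    if n_labeled < 1:
        raise ValueError("need at least one labeled case")
    labeled = np.ones(n_labeled)
    if not records:
        return labeled / labeled.sum()
    conf = []
    for r in records:
        if r.accepted.any():
            conf.append(float(np.nanmean(r.mean_prob[r.accepted])))
        else:
            conf.append(0.0)
    pseudo = np.asarray(conf) ** temperature
    pseudo[np.asarray(conf) <= 0.0] = 0.0
    if pseudo.sum() > n_labeled:
        pseudo = pseudo * (n_labeled / pseudo.sum())
    for r, w in zip(records, pseudo):
        r.sampling_weight = float(w)
    weights = np.concatenate([labeled, pseudo])
    return weights / weights.sum()


def self_train_round(predict_fn, retrain_fn,
                     labeled_ids: list[str],
                     unlabeled_ids: list[str],
                     rounds: int = 1,
                     min_volumes=DEFAULT_MIN_VOLUMES,
                     prob_threshold: float = DEFAULT_PROB_THRESHOLD,
                     temperature: float = 1.0,
                     log_path=None):
    """Run ``rounds`` (1..2) of pseudo-labeling and retraining.

    ``predict_fn(study_id) -> (probs, SegLabelVolume)`` produces the
    model's softmax output and predicted labels for an unlabeled
    training-split study; ``retrain_fn(weights, pseudo)`` retrains given
    the mixed sampling weights and the accepted pseudo-label volumes and
    returns the updated model. Returns ``(model, provenance)`` where
    provenance lists one record dict per study and round.
    """
    if not 1 <= rounds <= 2:
        raise ValueError("rounds must be 1 or 2")
    provenance = []
    model = None
    for rnd in range(rounds):
        records, pseudo_volumes = [], {}
        for sid in unlabeled_ids:
            probs, pred = predict_fn(sid)
            rec, filtered = filter_pseudo_mask(
                probs, clean_labels(pred), min_volumes, prob_threshold,
                study_id=sid)
            records.append(rec)
            if rec.accepted.any():
                pseudo_volumes[sid] = filtered
            provenance.append({
                "round": rnd,
                "study_id": sid,
                "accepted": [bool(a) for a in rec.accepted],
                "mean_prob": [None if np.isnan(v) else float(v)
                              for v in rec.mean_prob],
                "volume_mm3": [float(v) for v in rec.volume_mm3],
                "prob_threshold": prob_threshold,
                "min_volumes": list(min_volumes),
                "accepted_levels": int(rec.accepted.sum()),
                "total_levels": N_LEVELS,
            })
        weights = mix_training_set(len(labeled_ids),
                                   [r for r in records if r.accepted.any()],
                                   temperature)
        model = retrain_fn(weights, pseudo_volumes)
    if log_path is not None:
        log_path = Path(log_path)
        log_path.parent.mkdir(parents=True, exist_ok=True)
        with open(log_path, "w") as fh:
            for entry in provenance:
                fh.write(json.dumps(entry) + "\n")
    return model, provenance
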