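"""ROC/AUC metrics and patient-aware cross-validation designs.

The fitness metric throughout is the area under the ROC curve with ACP as the
positive class, computed by a threshold sweep with tied scores grouped into a
single step and trapezoidal integration (equivalent to the tie-corrected
Mann-Whitney pairwise probability).

Three five-fold cross-validation designs are provided for studying how
augmented images interact with fold boundaries:

* scenario 1 — originals and augmented images pooled, folds split at the
  *image* level.  Augmented descendants of a validation image can land in a
  training fold, so this design deliberately leaks and inflates performance.
* scenario 2 — folds split at the *patient* level over originals; augmented
  images join only training folds, and only as descendants of training-fold
  originals.
* scenario 3 — patient-level folds over originals only (no augmentation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classifier import (
    ClassifierConfig,
    POSITIVE_CLASS,
    predict_classes,
    predict_scores,
    train_classifier,
)
from .embeddings import EmbeddingMatrix
from .imaging import DatasetManifest

__all__ = [
    "ROCCurve",
    "SplitPlan",
    "CVResult",
    "roc_auc",
    "accuracy",
    "make_cv_plan",
    "run_cv",
    "find_parent_leakage",
]


@dataclass
class ROCCurve:
    """Threshold-swept ROC curve with trapezoidal area."""

    thresholds: np.ndarray  # descending; leading +inf sentinel
    fpr: np.ndarray
    tpr: np.ndarray
    area: float

    def to_table(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds.tolist(), self.fpr.tolist(), self.tpr.tolist()))


def _positives(labels: Sequence) -> np.ndarray:
    out = np.empty(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        if isinstance(lab, str):
            out[i] = lab == POSITIVE_CLASS
        else:
            out[i] = bool(lab)
    return out


def roc_auc(labels: Sequence, scores: Sequence[float]) -> ROCCurve:
    """ROC curve and AUC with ACP (or 1/True) as the positive class.

    Equal scores are grouped into a single threshold step, which makes the
    trapezoidal area equal to the tie-corrected probability that a random
    positive outranks a random negative (ties count half).
    """
    y = _positives(labels)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("labels and scores lengths differ")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to sweep a ROC curve")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # indices where the score changes: close one threshold group
    distinct = np.where(np.diff(s_sorted))[0]
    cut = np.r_[distinct, len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[cut]
    fps = (cut + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[cut]]
    area = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, area=area)


def accuracy(labels: Sequence, predicted: Sequence) -> float:
    """Fraction of matching class decisions."""
    if len(labels) != len(predicted):
        raise ValueError("labels and predictions lengths differ")
    y = _positives(labels)
    p = _positives(predicted)
    return float(np.mean(y == p))


# ---------------------------------------------------------------------------
# Cross-validation plans
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    scenario: int
    k: int
    fold_of_unit: Mapping[str, int]  # image_id (scenario 1) or patient_id (2-3)
    train_ids: tuple[tuple[str, ...], ...]  # per-fold training image_ids
    val_ids: tuple[tuple[str, ...], ...]  # per-fold validation image_ids


def _deal_stratified(
    units_by_class: Mapping[str, list[str]], k: int, rng: np.random.Generator
) -> dict[str, int]:
    """Shuffle units within class and deal round-robin so fold class ratios
    stay within one unit of the global ratio."""
    fold_of: dict[str, int] = {}
    fold_cursor = 0
    for cls in sorted(units_by_class):
        units = sorted(units_by_class[cls])
        rng.shuffle(units)
        for u in units:
            fold_of[u] = fold_cursor % k
            fold_cursor += 1
    return fold_of


def make_cv_plan(
    manifest: DatasetManifest,
    k: int = 5,
    scenario: int = 2,
    rng: np.random.Generator | None = None,
) -> SplitPlan:
    """Assign the manifest's images to k folds per the chosen scenario.

    The manifest should contain the images to cross-validate (typically a
    training split), with augmented records carrying ``parent_image_id``.
    """
    if scenario not in (1, 2, 3):
        raise ValueError("scenario must be 1, 2 or 3")
    rng = np.random.default_rng() if rng is None else rng
    records = manifest.records
    originals = [r for r in records if r.parent_image_id is None]
    augmented = [r for r in records if r.parent_image_id is not None]
    rec_of = {r.image_id: r for r in records}

    if scenario == 1:
        by_class: dict[str, list[str]] = {}
        for r in records:
            by_class.setdefault(r.class_label, []).append(r.image_id)
        fold_of = _deal_stratified(by_class, k, rng)
        train, val = [], []
        for f in range(k):
            val_f = tuple(r.image_id for r in records if fold_of[r.image_id] == f)
            train_f = tuple(r.image_id for r in records if fold_of[r.image_id] != f)
            val.append(val_f)
            train.append(train_f)
        return SplitPlan(scenario, k, fold_of, tuple(train), tuple(val))

    patients = sorted({r.patient_id for r in originals})
    if k > len(patients):
        raise ValueError(f"k={k} exceeds the {len(patients)} patients available")
    cls_of_patient: dict[str, str] = {}
    for r in originals:
        cls_of_patient[r.patient_id] = r.class_label
    by_class = {}
    for p in patients:
        by_class.setdefault(cls_of_patient[p], []).append(p)
    fold_of = _deal_stratified(by_class, k, rng)

    train, val = [], []
    for f in range(k):
        val_f = tuple(
            r.image_id for r in originals if fold_of[r.patient_id] == f
        )
        train_orig = [r.image_id for r in originals if fold_of[r.patient_id] != f]
        if scenario == 2:
            train_aug = [
                r.image_id
                for r in augmented
                if fold_of[rec_of[r.parent_image_id].patient_id] != f
            ]
        else:
            train_aug = []
        train.append(tuple(train_orig + train_aug))
        val.append(val_f)
    return SplitPlan(scenario, k, fold_of, tuple(train), tuple(val))


def find_parent_leakage(
    plan: SplitPlan, manifest: DatasetManifest
) -> list[tuple[int, str, str]]:
    """Scan for fold leakage: (fold, train_image, val_relative) triples where a
    training image shares an origin (itself, parent or sibling) with a
    validation image of the same fold.  Empty for sound patient-level plans.
    """
    rec_of = {r.image_id: r.parent_image_id for r in manifest.records}

    def root(iid: str) -> str:
        parent = rec_of.get(iid)
        return parent if parent else iid

    leaks = []
    for f in range(plan.k):
        val_roots = {root(v) for v in plan.val_ids[f]}
        for t in plan.train_ids[f]:
            if root(t) in val_roots:
                leaks.append((f, t, root(t)))
    return leaks


@dataclass
class CVResult:
    per_fold_auc: tuple[float, ...]
    per_fold_accuracy: tuple[float, ...]
    mean_auc: float
    mean_accuracy: float
    pooled_auc: float
    pooled_accuracy: float
    invalid_folds: tuple[int, ...]


def run_cv(
    plan: SplitPlan,
    embeddings: EmbeddingMatrix,
    manifest: DatasetManifest,
    config: ClassifierConfig,
) -> CVResult:
    """Train one classifier per fold and score its validation images.

    Reports per-fold AUC/accuracy, their means, and pooled-prediction metrics
    (all validation scores concatenated before a single sweep).  A fold whose
    validation or training portion lacks a class is recorded as invalid and
    excluded from the per-fold means.
    """
    label_of = {r.image_id: r.class_label for r in manifest.records}
    aucs, accs, invalid = [], [], []
    pooled_scores: list[float] = []
    pooled_labels: list[str] = []
    pooled_preds: list[str] = []
    for f in range(plan.k):
        tr, va = plan.train_ids[f], plan.val_ids[f]
        ytr = [label_of[i] for i in tr]
        yva = [label_of[i] for i in va]
        if len(set(ytr)) < 2 or len(set(yva)) < 2:
            invalid.append(f)
            aucs.append(np.nan)
            accs.append(np.nan)
            continue
        clf = train_classifier(embeddings.subset(tr).values, ytr, config)
        xva = embeddings.subset(va).values
        scores = predict_scores(clf, xva)
        preds = predict_classes(clf, xva)
        aucs.append(roc_auc(yva, scores).area)
        accs.append(accuracy(yva, preds))
        pooled_scores.extend(scores.tolist())
        pooled_labels.extend(yva)
        pooled_preds.extend(preds)

    valid_aucs = [a for a in aucs if np.isfinite(a)]
    valid_accs = [a for a in accs if np.isfinite(a)]
    return CVResult(
        per_fold_auc=tuple(aucs),
        per_fold_accuracy=tuple(accs),
        mean_auc=float(np.mean(valid_aucs)) if valid_aucs else np.nan,
        mean_accuracy=float(np.mean(valid_accs)) if valid_accs else np.nan,
        pooled_auc=roc_auc(pooled_labels, pooled_scores).area
        if len(set(pooled_labels)) == 2
        else np.nan,
        pooled_accuracy=accuracy(pooled_labels, pooled_preds)
        if pooled_labels
        else np.nan,
        invalid_folds=tuple(invalid),
    )
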