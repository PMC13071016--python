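"""Classification metrics, confusion matrices, centralized baselines and
comparison reports.

Precision, recall, F1 and one-vs-rest ROC-AUC are support-weighted across
classes; support-weighted recall then coincides with accuracy, which is
the identity used to sanity-check reported tables.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .client import TrainingConfig, local_train, PrototypeSet
from .data import LabeledDataset
from .models import build_model, layer_inventory, make_skip_plan, state_from_model, TinyCNN
from .nn import softmax

__all__ = [
    "MetricsRow",
    "classification_metrics",
    "confusion_matrix",
    "evaluate_model",
    "nearest_prototype_predict",
    "run_centralized_baseline",
    "compare_report",
    "privacy_utility_table",
    "rows_to_frame",
]

METRIC_COLUMNS = ["label", "accuracy", "precision", "recall", "f1", "roc_auc", "training_time_s"]


@dataclass
class MetricsRow:
    """One evaluated model or configuration."""

    label: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_auc: float
    training_time_s: float = 0.0

    def as_dict(self) -> dict:
        return asdict(self)


def classification_metrics(
    y_true: np.ndarray, y_score: np.ndarray, label: str = "", training_time_s: float = 0.0
) -> MetricsRow:
    """Support-weighted multi-class metrics from per-class probabilities.

    Predictions are the argmax of ``y_score``. If some classes are absent
    from ``y_true``, ROC-AUC is computed over the present classes only
    (with a warning).
    """
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=np.float64)
    if y_true.shape[0] != y_score.shape[0]:
        raise ValueError("y_true and y_score lengths differ")
    if not np.allclose(y_score.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("score rows must sum to 1")
    y_pred = y_score.argmax(axis=1)
    acc = accuracy_score(y_true, y_pred)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0
        )
    def _auc(y, scores):
        if scores.shape[1] == 2:
            return roc_auc_score(y, scores[:, 1])
        return roc_auc_score(y, scores, multi_class="ovr", average="weighted")

    present = np.unique(y_true)
    if present.size < 2:
        auc = float("nan")
        warnings.warn("ROC-AUC undefined with a single present class")
    elif present.size < y_score.shape[1]:
        warnings.warn(
            f"classes {sorted(set(range(y_score.shape[1])) - set(present))} absent "
            "from y_true; ROC-AUC restricted to present classes"
        )
        sub = y_score[:, present]
        sub = sub / sub.sum(axis=1, keepdims=True)
        remap = {c: i for i, c in enumerate(present)}
        auc = _auc(np.array([remap[c] for c in y_true]), sub)
    else:
        auc = _auc(y_true, y_score)
    return MetricsRow(label, float(acc), float(prec), float(rec), float(f1), float(auc), training_time_s)


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Counts with entry (i, j) = true class i predicted as class j."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    for arr in (y_true, y_pred):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError("label outside [0, n_classes)")
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


def evaluate_model(
    model: TinyCNN,
    test_set: LabeledDataset,
    label: str = "",
    prototypes: PrototypeSet | None = None,
    batch_size: int = 256,
) -> MetricsRow:
    """Evaluate softmax predictions (or nearest-prototype predictions when
    ``prototypes`` is given) on a held-out test set."""
    x = test_set.pixel_array()
    y = test_set.labels
    if prototypes is not None:
        scores = nearest_prototype_predict(model, x, prototypes, test_set.n_classes)
    else:
        parts = [
            softmax(model.forward(x[i : i + batch_size]))
            for i in range(0, len(x), batch_size)
        ]
        scores = np.vstack(parts)
    return classification_metrics(y, scores, label=label)


def nearest_prototype_predict(
    model: TinyCNN, x: np.ndarray, prototypes: PrototypeSet, n_classes: int
) -> np.ndarray:
    """Soft nearest-centroid scores: softmax of negative feature distances
    to the global class prototypes (classes without a prototype score 0)."""
    feats = model.features(x)
    d = np.full((feats.shape[0], n_classes), np.inf)
    for c, p in prototypes.prototypes.items():
        d[:, c] = np.linalg.norm(feats - p[None, :], axis=1)
    return softmax(-d)


def run_centralized_baseline(
    arch_names: list[str],
    train_set: LabeledDataset,
    test_set: LabeledDataset,
    cfg: TrainingConfig,
    input_stats: tuple[float, float] = (0.5, 0.25),
) -> list[MetricsRow]:
    """Train each registry architecture centrally and evaluate it.

    Emits one MetricsRow per architecture; the best-F1 row (ties broken by
    first occurrence) is the recommended federated backbone.
    """
    rows: list[MetricsRow] = []
    for arch in arch_names:
        model, state = build_model(arch, train_set.n_classes, seed=cfg.seed, input_stats=input_stats)
        plan = make_skip_plan(layer_inventory(arch, train_set.n_classes), 0.0)
        t0 = time.perf_counter()
        update = local_train(state, plan, train_set, cfg, input_stats=input_stats)
        elapsed = time.perf_counter() - t0
        from .models import load_state_into_model

        load_state_into_model(model, update.model_state)
        row = evaluate_model(model, test_set, label=arch)
        row.training_time_s = elapsed
        rows.append(row)
    return rows


def best_f1_row(rows: list[MetricsRow]) -> MetricsRow:
    best = rows[0]
    for r in rows[1:]:
        if r.f1 > best.f1:
            best = r
    return best


def rows_to_frame(rows: list[MetricsRow]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in rows], columns=METRIC_COLUMNS)


def compare_report(
    centralized: list[MetricsRow], federated: list[MetricsRow]
) -> pd.DataFrame:
    """Accuracy drop of each federated configuration against the best-F1
    centralized baseline (drop = centralized accuracy - federated accuracy)."""
    if not centralized or not federated:
        raise ValueError("both row lists must be non-empty")
    base = best_f1_row(centralized)
    rows = [
        {
            "configuration": f.label,
            "centralized_baseline": base.label,
            "centralized_accuracy": base.accuracy,
            "federated_accuracy": f.accuracy,
            "accuracy_drop": base.accuracy - f.accuracy,
            "federated_f1": f.f1,
        }
        for f in federated
    ]
    return pd.DataFrame(rows)


def privacy_utility_table(federated: list[MetricsRow], leakage: dict[str, float]) -> pd.DataFrame:
    """Configuration / leakage score / accuracy / F1 table."""
    rows = [
        {
            "configuration": f.label,
            "leakage_score": leakage.get(f.label, float("nan")),
            "accuracy": f.accuracy,
            "f1": f.f1,
        }
        for f in federated
    ]
    return pd.DataFrame(rows)
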