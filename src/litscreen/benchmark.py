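"""Published benchmark results for the neck-pain screening task.

Metric rows (percent) reported for the attention-based screening model
and its competitors on the original 3,350-article neck-pain benchmark,
kept here as reference data so that metric arithmetic — harmonic-mean
consistency of F1 with its own precision/recall, and per-metric deltas
against the strongest baseline — can be recomputed offline.

``MAIN_RESULTS`` covers the model-comparison experiment; ``ABLATION``
covers the feature-ablation experiment (T = title, A = abstract,
J = journal features).
"""

from __future__ import annotations

from .train_eval import compare_models

__all__ = [
    "MAIN_RESULTS",
    "ABLATION",
    "FULL_MODEL",
    "f1_from_precision_recall",
    "best_baseline",
    "deltas_vs_best_baseline",
    "ablation_precision_drop",
]

FULL_MODEL = "intersample-attention-full"

#: metric -> percent; rows of the model-comparison experiment.
MAIN_RESULTS: dict[str, dict[str, float]] = {
    "random-forest": dict(precision=59.11, recall=79.10, specificity=76.54, accuracy=77.31, f1=67.66, auc=85.28),
    "l1-logistic": dict(precision=75.00, recall=52.24, specificity=92.54, accuracy=80.45, f1=61.58, auc=85.64),
    "bilstm": dict(precision=64.86, recall=59.70, specificity=86.14, accuracy=78.21, f1=62.18, auc=82.21),
    "bilstm-attention": dict(precision=66.67, recall=68.66, specificity=85.29, accuracy=80.30, f1=67.65, auc=83.63),
    "textcnn": dict(precision=66.67, recall=61.69, specificity=86.78, accuracy=79.25, f1=64.08, auc=85.22),
    "textrcnn": dict(precision=61.54, recall=79.60, specificity=78.68, accuracy=78.96, f1=69.41, auc=86.15),
    "biomedical-transformer": dict(precision=71.69, recall=78.11, specificity=86.78, accuracy=84.18, f1=74.76, auc=89.59),
    FULL_MODEL: dict(precision=71.55, recall=82.59, specificity=85.92, accuracy=84.93, f1=76.67, auc=91.84),
}

#: Feature-ablation rows; "full" uses title + abstract + journal.
ABLATION: dict[str, dict[str, float]] = {
    "T": dict(precision=69.19, recall=72.64, specificity=86.14, f1=70.87, accuracy=82.09, auc=86.71),
    "A": dict(precision=72.22, recall=71.14, specificity=88.27, f1=71.68, accuracy=83.13, auc=89.72),
    "TJ": dict(precision=58.87, recall=77.61, specificity=76.76, f1=66.95, accuracy=77.01, auc=86.98),
    "TA": dict(precision=70.40, recall=78.11, specificity=85.93, f1=74.06, accuracy=83.58, auc=89.15),
    "AJ": dict(precision=71.95, recall=79.10, specificity=86.78, f1=75.36, accuracy=84.48, auc=89.98),
    "FULL": dict(precision=71.55, recall=82.59, specificity=85.92, f1=76.67, accuracy=84.93, auc=91.84),
}


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """F1 = 2PR / (P + R), on the percent scale."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def best_baseline(metric: str) -> tuple[str, float]:
    """The strongest non-full model on ``metric`` in the main experiment."""
    candidates = {k: v for k, v in MAIN_RESULTS.items() if k != FULL_MODEL}
    name = max(candidates, key=lambda k: candidates[k][metric])
    return name, candidates[name][metric]


def deltas_vs_best_baseline() -> dict[str, float]:
    """Full-model improvement, per metric, over the per-metric strongest
    baseline (percentage points)."""
    return {
        metric: compare_models(MAIN_RESULTS[FULL_MODEL], {metric: best_baseline(metric)[1]})[metric]
        for metric in ("precision", "recall", "specificity", "accuracy", "f1", "auc")
    }


def ablation_precision_drop(variant: str = "TJ") -> float:
    """Precision drop (percentage points) of an ablated variant vs full."""
    return ABLATION["FULL"]["precision"] - ABLATION[variant]["precision"]
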