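"""Classification metrics, threshold selection, and interpretability scores.

Standard rates (accuracy, precision, recall, F1, balanced accuracy, AUROC)
are delegated to scikit-learn; the structural interpretability score, the
adaptation-speed counter, and the run-to-run stability indicator are the
graph-specific measures defined here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from fcmdss.fcm_core import ConceptGraph, classify

#: Sentinel for metrics that are undefined in a given configuration
#: (single-class AUROC, interpretability with no active edge, adaptation
#: speed never reached).
NOT_APPLICABLE = float("nan")

#: Default validation grid for the classification threshold: 0.10 to 0.90 in
#: steps of 0.05 (17 points).
DEFAULT_TAU_GRID = tuple(round(0.10 + 0.05 * k, 2) for k in range(17))

#: Smaller alternative grid, selectable by configuration.
SMALL_TAU_GRID = (0.45, 0.50, 0.55, 0.60)

#: An edge is structurally active when its magnitude exceeds this.
ACTIVE_EDGE_THRESHOLD = 0.05


@dataclass
class MetricsReport:
    """Per-model metric values with optional mean/sd aggregation over repeats."""

    accuracy: float = NOT_APPLICABLE
    precision: float = NOT_APPLICABLE
    recall: float = NOT_APPLICABLE
    f1: float = NOT_APPLICABLE
    balanced_accuracy: float = NOT_APPLICABLE
    auroc: float = NOT_APPLICABLE
    i_struct: float = NOT_APPLICABLE
    adaptation_speed: float = NOT_APPLICABLE
    stability_indicator: float = NOT_APPLICABLE
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    _RATE_FIELDS = (
        "accuracy",
        "precision",
        "recall",
        "f1",
        "balanced_accuracy",
        "auroc",
        "i_struct",
        "adaptation_speed",
        "stability_indicator",
    )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self._RATE_FIELDS}

    @classmethod
    def aggregate(cls, reports: Sequence["MetricsReport"]) -> "MetricsReport":
        """Mean and (population) sd over repeats, skipping not-applicable
        entries per metric."""
        agg = cls()
        for name in cls._RATE_FIELDS:
            vals = [getattr(r, name) for r in reports]
            vals = [v for v in vals if not math.isnan(v)]
            if vals:
                agg.mean[name] = float(np.mean(vals))
                agg.sd[name] = float(np.std(vals))
        return agg


def confusion_metrics(y: Sequence[int], yhat: Sequence[int]) -> dict:
    """Accuracy, precision, recall, F1, and balanced accuracy.

    Zero-denominator precision or recall is reported as 0 with a warning.
    """
    y = np.asarray(list(y), dtype=int)
    yhat = np.asarray(list(yhat), dtype=int)
    if y.size == 0:
        raise ValueError("empty label vectors")
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if not (np.all(np.isin(y, (0, 1))) and np.all(np.isin(yhat, (0, 1)))):
        raise ValueError("labels and predictions must be binary")
    if yhat.sum() == 0 or y.sum() == 0:
        warnings.warn(
            "zero-denominator precision/recall reported as 0", stacklevel=2
        )
    return {
        "accuracy": float(accuracy_score(y, yhat)),
        "precision": float(precision_score(y, yhat, zero_division=0)),
        "recall": float(recall_score(y, yhat, zero_division=0)),
        "f1": float(f1_score(y, yhat, zero_division=0)),
        "balanced_accuracy": float(balanced_accuracy_score(y, yhat)),
    }


def auroc(y: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a random positive outranks a random negative (ties 1/2).

    Returns the not-applicable sentinel (NaN) when only one class is present.
    """
    y = np.asarray(list(y), dtype=int)
    s = np.asarray(list(scores), dtype=float)
    if len(np.unique(y)) < 2:
        return NOT_APPLICABLE
    return float(roc_auc_score(y, s))


def select_threshold(
    y_val: Sequence[int],
    scores_val: Sequence[float],
    grid: Sequence[float] = DEFAULT_TAU_GRID,
) -> float:
    """Grid threshold maximizing validation F1; ties go to the smallest tau
    (favoring sensitivity)."""
    if len(grid) == 0:
        raise ValueError("threshold grid must be non-empty")
    y = np.asarray(list(y_val), dtype=int)
    s = np.asarray(list(scores_val), dtype=float)
    best_tau, best_f1 = None, -1.0
    for tau in grid:
        yhat = np.array([classify(v, tau) for v in s])
        f1 = float(f1_score(y, yhat, zero_division=0))
        if f1 > best_f1:  # strict: first (smallest) tau wins ties
            best_tau, best_f1 = float(tau), f1
    return best_tau


def i_struct(
    learned: ConceptGraph,
    prior: ConceptGraph,
    active_threshold: float = ACTIVE_EDGE_THRESHOLD,
) -> float:
    """Structural interpretability: fraction of active learned edges whose
    sign matches the expert prior.

    An edge is active when ``|w| > active_threshold``.  Sign agreement is
    strict (``sign(0) = 0``), so a zero prior entry under an active learned
    edge counts as disagreement.  With no active edge the score is not
    applicable (NaN).
    """
    if learned.weights.shape != prior.weights.shape:
        raise ValueError(
            f"shape mismatch: {learned.weights.shape} vs {prior.weights.shape}"
        )
    active = np.abs(learned.weights) > active_threshold
    n_active = int(active.sum())
    if n_active == 0:
        return NOT_APPLICABLE
    agree = np.sign(learned.weights[active]) == np.sign(prior.weights[active])
    return float(agree.sum() / n_active)


def adaptation_speed(change_norms: Sequence[float], delta: float) -> float:
    """1-based index of the first outer iteration whose weight change is at
    most ``delta``; NaN if never reached."""
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    for k, v in enumerate(change_norms, start=1):
        if v <= delta:
            return float(k)
    return NOT_APPLICABLE


def stability_indicator(final_deltas: Sequence[float]) -> float:
    """Mean final-step weight-change norm over repeated runs."""
    vals = list(final_deltas)
    if not vals:
        raise ValueError("stability indicator needs at least one run")
    return float(np.mean(vals))
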