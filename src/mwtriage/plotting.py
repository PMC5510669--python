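"""Diagnostic plots: ROC curve and per-subject decision-value scatter."""

from __future__ import annotations

import numpy as np

from .classifier import PATIENT_LABEL
from .evaluate import EvaluationResult, ROCCurve
from .simulate import Cohort

__all__ = ["plot_roc", "plot_decision_values"]


def plot_roc(curve: ROCCurve, auc_value: float | None = None, ax=None):
    """ROC curve with the chance diagonal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    label = None if auc_value is None else f"AUC = {auc_value:.2f}"
    ax.plot(curve.fpr, curve.tpr, drawstyle="steps-post", label=label)
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
    ax.set_xlabel("1 - specificity (false-positive rate)")
    ax.set_ylabel("sensitivity (true-positive rate)")
    if label:
        ax.legend(loc="lower right")
    return ax


def plot_decision_values(
    result: EvaluationResult, cohort: Cohort | None = None, threshold: float | None = None, ax=None
):
    """Scatter of per-subject decision values.

    Patients are plotted left of controls; when the cohort (with its volume
    metadata) is given, patients are ordered by increasing total hematoma
    volume.  An optional threshold line marks the operating point.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = np.asarray(result.labels)
    scores = np.asarray(result.scores)
    pos = labels == PATIENT_LABEL
    pos_idx = np.flatnonzero(pos)
    if cohort is not None:
        volumes = np.array([s.total_volume for s in cohort.subjects])
        pos_idx = pos_idx[np.argsort(volumes[pos_idx], kind="stable")]
    neg_idx = np.flatnonzero(~pos)
    order = np.concatenate([pos_idx, neg_idx])
    x = np.arange(len(order))
    colors = np.where(pos[order], "tab:red", "tab:blue")
    ax.scatter(x, scores[order], c=colors)
    if threshold is not None:
        ax.axhline(threshold, linestyle="--", color="black")
    ax.set_xlabel("subjects (patients by increasing hematoma volume, then controls)")
    ax.set_ylabel("decision value")
    return ax
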