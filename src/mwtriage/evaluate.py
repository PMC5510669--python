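"""Leave-one-out evaluation, ROC/AUC, and model selection.

Diagnostic accuracy is assessed by leave-one-out (LOO) cross-validation:
each subject is scored by a classifier trained on all other subjects, so the
scored measurement never enters its own training set.  The resulting decision
values, one per subject, yield

* the ROC curve, traced by sweeping the decision threshold over all observed
  score values (hematoma patients are the positive class);
* the AUC (trapezoidal area, identical to the Mann-Whitney statistic);
* the specificity at 100% sensitivity: the fraction of controls correctly
  rejected at the most permissive threshold that still detects every patient.

Model selection sweeps every frequency interval on the 50 MHz grid with at
least the minimum width (400 MHz by default), crossed with candidate subspace
ranks.  The rank with the highest AUC *averaged over all intervals* is chosen
first; among intervals at that rank, the one with the highest specificity at
full sensitivity wins.  Tie-breaks are deterministic: lower rank, then wider
interval, then lower band start.  The selection is run once on the full
cohort (not nested inside the LOO), so the selected setting's LOO figures
carry the usual selection optimism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import (
    CONTROL_LABEL,
    PATIENT_LABEL,
    ClassifierConfig,
    decision_value,
    fit,
)
from .features import cohort_features
from .simulate import Cohort

__all__ = [
    "ROCCurve",
    "EvaluationResult",
    "SweepResult",
    "roc_curve",
    "auc",
    "specificity_at_full_sensitivity",
    "loo_cross_validate",
    "enumerate_intervals",
    "sweep_model_selection",
]


@dataclass
class ROCCurve:
    """ROC points (FPR, TPR) with the generating thresholds.

    The point at threshold t counts subjects with score >= t as positive —
    equivalently, it is the operating point of ``classify`` at a threshold
    just below t, consistent with the "score > threshold => positive" rule.
    The first point (0, 0) corresponds to a sentinel threshold above the
    maximum score.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = labels == PATIENT_LABEL
    neg = labels == CONTROL_LABEL
    if not np.all(pos | neg):
        bad = labels[~(pos | neg)][0]
        raise ValueError(f"unknown label {bad!r}")
    if not pos.any() or not neg.any():
        raise ValueError("need at least one subject of each class")
    return scores, pos


def roc_curve(scores, labels) -> ROCCurve:
    """ROC by sweeping the decision threshold over all observed scores."""
    scores, pos = _check_scores_labels(scores, labels)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    fpr = np.empty(len(thresholds))
    tpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        flagged = scores >= t
        tpr[i] = flagged[pos].sum() / n_pos
        fpr[i] = flagged[~pos].sum() / n_neg
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def auc(scores, labels) -> float:
    """Trapezoidal area under the ROC curve (equals Mann-Whitney U / (n1*n2))."""
    curve = roc_curve(scores, labels)
    return float(np.trapezoid(curve.tpr, curve.fpr))


def specificity_at_full_sensitivity(scores, labels) -> float:
    """Specificity at the most permissive threshold detecting every patient.

    With the "score > threshold" positivity rule, the threshold sits just
    below the minimum patient score; a control tied with that minimum counts
    as a false positive.  Returns the fraction of controls strictly below
    the minimum patient score.
    """
    scores, pos = _check_scores_labels(scores, labels)
    min_pos = scores[pos].min()
    neg = scores[~pos]
    return float((neg < min_pos).sum() / len(neg))


@dataclass
class EvaluationResult:
    """Per-subject LOO decision values with summary accuracy figures."""

    subject_ids: list[str]
    labels: np.ndarray
    scores: np.ndarray
    auc: float
    spec_at_full_sens: float
    config: ClassifierConfig

    def roc(self) -> ROCCurve:
        return roc_curve(self.scores, self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_ids, "label": self.labels, "score": self.scores}
        )


def _loo_scores(X: np.ndarray, labels: np.ndarray, config: ClassifierConfig) -> np.ndarray:
    """LOO decision values from a precomputed feature matrix."""
    pos = labels == PATIENT_LABEL
    n = len(labels)
    for name, m in ((PATIENT_LABEL, pos.sum()), (CONTROL_LABEL, (~pos).sum())):
        if m < config.rank + 1:
            raise ValueError(
                f"class {name!r} has {m} subjects; leave-one-out at rank "
                f"{config.rank} needs at least {config.rank + 1}"
            )
    scores = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        model = fit(X[keep & pos], X[keep & ~pos], config)
        scores[i] = decision_value(model, X[i])
    return scores


def loo_cross_validate(
    cohort: Cohort, config: ClassifierConfig | None = None
) -> EvaluationResult:
    """Leave-one-out cross-validation of the subspace classifier on a cohort."""
    config = config or ClassifierConfig()
    X, labels, ids = cohort_features(cohort, config.mask, config.f_lo, config.f_hi)
    scores = _loo_scores(X, labels, config)
    return EvaluationResult(
        subject_ids=ids,
        labels=labels,
        scores=scores,
        auc=auc(scores, labels),
        spec_at_full_sens=specificity_at_full_sensitivity(scores, labels),
        config=config,
    )


def enumerate_intervals(
    f_start: float, f_stop: float, step: float, min_width: float
) -> list[tuple[float, float]]:
    """All (f_lo, f_hi) with endpoints on the step grid and width >= min_width.

    The default sweep (0.1-1.95 GHz, 50 MHz step, 400 MHz minimum width)
    yields 465 candidate intervals on the 38-point grid.
    """
    if min_width < step:
        raise ValueError("min_width must be at least one grid step")
    n = round((f_stop - f_start) / step) + 1
    if n < 2:
        raise ValueError("grid must contain at least two points")
    min_steps = round(min_width / step)
    grid = f_start + step * np.arange(n)
    intervals = [
        (float(grid[i]), float(grid[j]))
        for i in range(n)
        for j in range(i + min_steps, n)
    ]
    if not intervals:
        raise ValueError("no candidate interval satisfies the minimum width")
    return intervals


@dataclass
class SweepResult:
    """Model-selection sweep over (frequency interval, subspace rank)."""

    table: pd.DataFrame  # columns f_lo, f_hi, rank, auc, spec_at_full_sens
    selected_rank: int
    selected_interval: tuple[float, float]

    @property
    def selected_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            rank=self.selected_rank,
            f_lo=self.selected_interval[0],
            f_hi=self.selected_interval[1],
        )


def sweep_model_selection(
    cohort: Cohort,
    f_start: float = 0.10,
    f_stop: float = 1.95,
    step: float = 0.05,
    min_width: float = 0.40,
    ranks: list[int] = (1, 2, 3),
    mask=None,
) -> SweepResult:
    """Grid search over frequency intervals and subspace ranks.

    Runs a full LOO per (interval, rank).  The rank maximizing the mean AUC
    across all intervals is selected; among that rank's intervals the one
    maximizing specificity at full sensitivity wins, with deterministic
    tie-breaks (lower rank, wider interval, lower f_lo).
    """
    from .channels import default_exclusion_mask

    mask = mask if mask is not None else default_exclusion_mask(8)
    intervals = enumerate_intervals(f_start, f_stop, step, min_width)
    rows = []
    for rank in ranks:
        for f_lo, f_hi in intervals:
            cfg = ClassifierConfig(rank=rank, f_lo=f_lo, f_hi=f_hi, mask=mask)
            X, labels, _ = cohort_features(cohort, mask, f_lo, f_hi)
            scores = _loo_scores(X, labels, cfg)
            rows.append(
                {
                    "f_lo": f_lo,
                    "f_hi": f_hi,
                    "rank": rank,
                    "auc": auc(scores, labels),
                    "spec_at_full_sens": specificity_at_full_sensitivity(scores, labels),
                }
            )
    table = pd.DataFrame(rows)

    mean_auc = table.groupby("rank")["auc"].mean()
    best = mean_auc.max()
    selected_rank = int(min(r for r in mean_auc.index if mean_auc[r] == best))

    sub = table[table["rank"] == selected_rank].copy()
    sub["width"] = sub["f_hi"] - sub["f_lo"]
    sub = sub.sort_values(
        by=["spec_at_full_sens", "width", "f_lo"], ascending=[False, False, True]
    )
    top = sub.iloc[0]
    return SweepResult(
        table=table,
        selected_rank=selected_rank,
        selected_interval=(float(top["f_lo"]), float(top["f_hi"])),
    )
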