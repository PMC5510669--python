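"""Resampling checks: robustness under subject removal, permutation null.

Two complementary analyses probe whether a cohort's LOO performance is an
artifact of the exact data configuration:

* **Robustness** — repeat the full LOO after removing k random subjects
  (k = 2 by default), 100 times; a mean AUC close to the full-cohort AUC
  with a small SD indicates the chosen settings do not hinge on particular
  subjects.
* **Random diagnosis** — repeat the LOO after reassigning every subject an
  independent fair-coin class label, 100 times; an unbiased pipeline scores
  at chance (mean AUC near 0.5) because the labels carry no information.

One master seed spawns independent per-iteration substreams, so results do
not depend on iteration scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import CONTROL_LABEL, PATIENT_LABEL, ClassifierConfig
from .evaluate import _loo_scores, auc
from .features import cohort_features
from .simulate import Cohort

__all__ = ["ResamplingResult", "robustness_remove_k", "random_diagnosis_null"]


@dataclass
class ResamplingResult:
    """Per-iteration AUCs of a resampling analysis with mean +/- SD."""

    mode: str  # "remove_k" or "random_diagnosis"
    n_iterations: int
    aucs: np.ndarray
    mean_auc: float
    sd_auc: float
    seed: int
    redraws: int = 0

    def summary(self) -> str:
        return f"{self.mode}: mean AUC {self.mean_auc:.2f} +/- {self.sd_auc:.2f} (n={self.n_iterations})"


def _result(mode: str, aucs: list[float], seed: int, redraws: int = 0) -> ResamplingResult:
    a = np.asarray(aucs)
    return ResamplingResult(
        mode=mode,
        n_iterations=len(a),
        aucs=a,
        mean_auc=float(a.mean()),
        sd_auc=float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        seed=seed,
        redraws=redraws,
    )


def robustness_remove_k(
    cohort: Cohort,
    config: ClassifierConfig | None = None,
    k: int = 2,
    n_iterations: int = 100,
    seed: int = 0,
    stratified: bool = False,
) -> ResamplingResult:
    """Mean +/- SD of the LOO AUC after removing k random subjects per iteration.

    Removal is uniform over subjects without regard to class (``stratified``
    removes proportionally from each class instead).  ``k = 0`` degenerates
    to repeating the full-cohort LOO.
    """
    config = config or ClassifierConfig()
    n = len(cohort)
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= n - 2:
        raise ValueError(f"cannot remove {k} of {n} subjects")
    X, labels, _ = cohort_features(cohort, config.mask, config.f_lo, config.f_hi)
    streams = np.random.SeedSequence(seed).spawn(n_iterations)
    idx = np.arange(n)
    aucs = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        if stratified and k > 0:
            pos = idx[labels == PATIENT_LABEL]
            neg = idx[labels == CONTROL_LABEL]
            k_pos = round(k * len(pos) / n)
            drop = np.concatenate(
                [
                    rng.choice(pos, size=k_pos, replace=False),
                    rng.choice(neg, size=k - k_pos, replace=False),
                ]
            )
        else:
            drop = rng.choice(idx, size=k, replace=False)
        keep = np.setdiff1d(idx, drop)
        scores = _loo_scores(X[keep], labels[keep], config)
        aucs.append(auc(scores, labels[keep]))
    return _result("remove_k", aucs, seed)


def random_diagnosis_null(
    cohort: Cohort,
    config: ClassifierConfig | None = None,
    n_iterations: int = 100,
    seed: int = 0,
    balanced: bool = False,
) -> ResamplingResult:
    """Null distribution of the LOO AUC under random class assignment.

    Each iteration assigns every subject an independent fair-coin label
    (``balanced`` instead permutes the true labels, preserving class sizes)
    and records the LOO AUC against the reassigned labels.  Assignments
    leaving either class with fewer than rank + 2 subjects are redrawn; the
    redraw count is reported in the result.
    """
    config = config or ClassifierConfig()
    if n_iterations < 2:
        raise ValueError("need at least 2 iterations for a standard deviation")
    X, labels, _ = cohort_features(cohort, config.mask, config.f_lo, config.f_hi)
    n = len(labels)
    min_class = config.rank + 2
    streams = np.random.SeedSequence(seed).spawn(n_iterations)
    aucs = []
    redraws = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        while True:
            if balanced:
                new = labels[rng.permutation(n)]
            else:
                new = np.where(
                    rng.random(n) < 0.5, PATIENT_LABEL, CONTROL_LABEL
                )
            n_pos = (new == PATIENT_LABEL).sum()
            if min_class <= n_pos <= n - min_class:
                break
            redraws += 1
        scores = _loo_scores(X, new, config)
        aucs.append(auc(scores, new))
    return _result("random_diagnosis", aucs, seed, redraws=redraws)
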