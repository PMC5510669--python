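"""Rank-truncated subspace classifier for complex spectral features.

Each diagnostic class (hematoma patients ``cSDH``, healthy controls ``HC``)
is summarized by the leading ``r`` left singular vectors of the matrix whose
columns are that class's training feature vectors — an orthonormal basis of
the class's dominant subspace through the origin.  A new subject's feature
vector x is scored by its relative projection residuals onto the two
subspaces,

    d_k(x) = || x - U_k U_k^H x || / ||x||,        k in {cSDH, HC},

and the scalar decision value is

    score(x) = d_HC(x) - d_cSDH(x),

so larger scores mean the vector sits closer to the patient subspace than to
the control subspace.  Classification thresholds the score: ``cSDH`` iff
score > threshold, with ties resolved to ``HC`` (a tie never triggers a
positive).

Normalizing residuals by ||x|| makes the score invariant to a global complex
rescaling of the measurement, so subjects with different overall signal
amplitude (head size, antenna contact) are comparable.  No mean-centering is
applied before the SVD: the subspaces pass through the origin, which is what
makes the scale invariance exact.  A centered variant is available for
sensitivity checks via ``ClassifierConfig.center``.

The screening analysis retains only the first subspace dimension (r = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .channels import ChannelMask, default_exclusion_mask

__all__ = [
    "ClassifierConfig",
    "SubspaceModel",
    "fit",
    "decision_value",
    "classify",
    "save_model",
    "load_model",
]

PATIENT_LABEL = "cSDH"
CONTROL_LABEL = "HC"

_DEGENERACY_RTOL = 1e-12


def _default_mask() -> ChannelMask:
    return default_exclusion_mask(8)


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier settings: subspace rank, frequency band, channel mask."""

    rank: int = 1
    f_lo: float = 0.75
    f_hi: float = 1.95
    mask: ChannelMask = field(default_factory=_default_mask)
    center: bool = False

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.f_lo >= self.f_hi:
            raise ValueError("f_lo must be below f_hi")


@dataclass
class SubspaceModel:
    """Per-class orthonormal bases of the retained subspace dimensions.

    ``basis[k]`` is a (feature_dim, rank) complex matrix with orthonormal
    columns ordered by decreasing singular value.
    """

    basis: dict[str, np.ndarray]
    n_train: dict[str, int]
    config: ClassifierConfig
    means: dict[str, np.ndarray] | None = None

    @property
    def feature_dim(self) -> int:
        return next(iter(self.basis.values())).shape[0]


def _class_basis(X: np.ndarray, rank: int, label: str) -> np.ndarray:
    """Leading ``rank`` left singular vectors of the column-stacked class matrix."""
    M = X.T  # columns = training vectors
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    if s[0] <= 0 or (rank <= len(s) and s[rank - 1] <= _DEGENERACY_RTOL * s[0]):
        raise ValueError(
            f"class {label!r}: training matrix is degenerate at rank {rank} "
            f"(singular values {s[:rank]})"
        )
    return np.ascontiguousarray(U[:, :rank])


def fit(
    train_patients: np.ndarray,
    train_controls: np.ndarray,
    config: ClassifierConfig | None = None,
) -> SubspaceModel:
    """Fit per-class subspaces from training feature vectors.

    Parameters
    ----------
    train_patients, train_controls
        Complex arrays of shape (n_class, feature_dim), one training vector
        per row.
    config
        Subspace rank and provenance; defaults to the rank-1 screening
        configuration.
    """
    config = config or ClassifierConfig()
    Xp = np.atleast_2d(np.asarray(train_patients, dtype=complex))
    Xc = np.atleast_2d(np.asarray(train_controls, dtype=complex))
    if Xp.shape[1] != Xc.shape[1]:
        raise ValueError("class training sets must share one feature dimension")
    r = config.rank
    for name, X in ((PATIENT_LABEL, Xp), (CONTROL_LABEL, Xc)):
        if X.shape[0] < max(2, r):
            raise ValueError(
                f"class {name!r} has {X.shape[0]} training vectors; need >= {max(2, r)}"
            )
    means = None
    if config.center:
        means = {PATIENT_LABEL: Xp.mean(axis=0), CONTROL_LABEL: Xc.mean(axis=0)}
        Xp = Xp - means[PATIENT_LABEL]
        Xc = Xc - means[CONTROL_LABEL]
    basis = {
        PATIENT_LABEL: _class_basis(Xp, r, PATIENT_LABEL),
        CONTROL_LABEL: _class_basis(Xc, r, CONTROL_LABEL),
    }
    return SubspaceModel(
        basis=basis,
        n_train={PATIENT_LABEL: Xp.shape[0], CONTROL_LABEL: Xc.shape[0]},
        config=config,
        means=means,
    )


def _relative_residual(U: np.ndarray, x: np.ndarray, mean: np.ndarray | None) -> float:
    y = x if mean is None else x - mean
    proj = U @ (U.conj().T @ y)
    return float(np.linalg.norm(y - proj) / np.linalg.norm(x))


def decision_value(model: SubspaceModel, x: np.ndarray) -> float:
    """Scalar decision value; larger means more hematoma-like.

    score(x) = d_HC(x) - d_cSDH(x) with d_k the relative projection
    residual onto class k's subspace.  Invariant to global complex
    rescaling of x.
    """
    x = np.asarray(x, dtype=complex).ravel()
    if x.shape[0] != model.feature_dim:
        raise ValueError(
            f"feature dimension mismatch: got {x.shape[0]}, model expects {model.feature_dim}"
        )
    if np.linalg.norm(x) == 0:
        raise ValueError("cannot score the zero vector")
    means = model.means or {}
    d_pat = _relative_residual(model.basis[PATIENT_LABEL], x, means.get(PATIENT_LABEL))
    d_ctl = _relative_residual(model.basis[CONTROL_LABEL], x, means.get(CONTROL_LABEL))
    return d_ctl - d_pat


def classify(model: SubspaceModel, x: np.ndarray, threshold: float) -> str:
    """Threshold the decision value: ``cSDH`` iff score > threshold.

    Equality goes to ``HC`` — a tie never triggers a positive finding.
    """
    return PATIENT_LABEL if decision_value(model, x) > threshold else CONTROL_LABEL


def save_model(model: SubspaceModel, path: str | Path) -> None:
    """Serialize a fitted model (bases + config echo) to an .npz container."""
    cfg = model.config
    arrays = {
        "U_patient": model.basis[PATIENT_LABEL],
        "U_control": model.basis[CONTROL_LABEL],
        "n_train": np.array([model.n_train[PATIENT_LABEL], model.n_train[CONTROL_LABEL]]),
        "config_rank": np.array([cfg.rank]),
        "config_band": np.array([cfg.f_lo, cfg.f_hi]),
        "config_center": np.array([int(cfg.center)]),
        "mask_tokens": np.array([str(c) for c in cfg.mask]),
    }
    if model.means is not None:
        arrays["mean_patient"] = model.means[PATIENT_LABEL]
        arrays["mean_control"] = model.means[CONTROL_LABEL]
    np.savez(path, **arrays)


def load_model(path: str | Path) -> SubspaceModel:
    from .channels import mask_from_config

    with np.load(path, allow_pickle=False) as z:
        mask = mask_from_config([str(t) for t in z["mask_tokens"]])
        cfg = ClassifierConfig(
            rank=int(z["config_rank"][0]),
            f_lo=float(z["config_band"][0]),
            f_hi=float(z["config_band"][1]),
            mask=mask,
            center=bool(z["config_center"][0]),
        )
        means = None
        if "mean_patient" in z:
            means = {PATIENT_LABEL: z["mean_patient"], CONTROL_LABEL: z["mean_control"]}
        return SubspaceModel(
            basis={PATIENT_LABEL: z["U_patient"], CONTROL_LABEL: z["U_control"]},
            n_train={PATIENT_LABEL: int(z["n_train"][0]), CONTROL_LABEL: int(z["n_train"][1])},
            config=cfg,
            means=means,
        )
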