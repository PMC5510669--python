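"""Feature assembly: triplicate averaging, band selection, vectorization.

The classifier consumes one complex vector per subject.  That vector is
produced in three steps, mirroring the device's analysis chain:

1. the three consecutive measurements are averaged coherently (elementwise
   complex mean), which suppresses measurement noise while preserving phase;
2. a frequency band is selected on the 50 MHz sweep grid (the screening
   analysis uses 0.75-1.95 GHz);
3. the retained channels' selected frequencies are concatenated,
   channel-major then frequency, in canonical channel order.

No other calibration or normalization of the raw data is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import Channel, ChannelMask
from .simulate import Cohort, SubjectMeasurement

__all__ = [
    "FrequencySelection",
    "FeatureVector",
    "average_repetitions",
    "select_frequencies",
    "assemble_feature_vector",
    "cohort_features",
]


@dataclass(frozen=True)
class FrequencySelection:
    """A closed frequency interval resolved to grid indices."""

    f_lo: float
    f_hi: float
    indices: tuple[int, ...]
    values: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.indices)


def select_frequencies(grid, f_lo: float, f_hi: float) -> FrequencySelection:
    """Resolve a closed interval [f_lo, f_hi] (GHz) onto a frequency grid.

    Grid points within half a grid step of the interval endpoints are kept,
    avoiding float-comparison fragility on the 50 MHz grid.  Raises on an
    inverted interval or an empty selection.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("grid must be a non-empty 1-D array")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if f_lo >= f_hi:
        raise ValueError(f"inverted interval [{f_lo}, {f_hi}]")
    step = np.median(np.diff(grid)) if len(grid) > 1 else 0.0
    tol = step / 2.0
    keep = (grid >= f_lo - tol) & (grid <= f_hi + tol)
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        raise ValueError(f"no grid points in [{f_lo}, {f_hi}]")
    return FrequencySelection(
        f_lo=f_lo,
        f_hi=f_hi,
        indices=tuple(int(i) for i in idx),
        values=tuple(float(grid[i]) for i in idx),
    )


@dataclass
class FeatureVector:
    """One subject's complex feature vector with layout provenance."""

    values: np.ndarray
    subject_id: str
    label: str
    mask: ChannelMask
    selection: FrequencySelection

    def __post_init__(self) -> None:
        expected = len(self.mask) * len(self.selection)
        if self.values.shape != (expected,):
            raise ValueError(
                f"feature vector length {self.values.shape} != "
                f"{len(self.mask)} channels x {len(self.selection)} frequencies"
            )
        if not np.all(np.isfinite(self.values.view(float))):
            raise ValueError("non-finite feature values")


def average_repetitions(m: SubjectMeasurement) -> np.ndarray:
    """Coherent (complex) mean of a subject's repeated measurements."""
    shapes = {r.shape for r in m.repetitions}
    if len(shapes) != 1:
        raise ValueError(f"repetition shape mismatch: {shapes}")
    return np.mean(np.stack(m.repetitions), axis=0)


def assemble_feature_vector(
    mean_matrix: np.ndarray,
    channels: list[Channel],
    mask: ChannelMask,
    selection: FrequencySelection,
    *,
    subject_id: str = "",
    label: str = "HC",
) -> FeatureVector:
    """Concatenate masked channels x selected frequencies into one vector.

    ``channels`` gives the row order of ``mean_matrix``.  The output is
    channel-major in the mask's canonical order, each channel contributing
    its selected frequencies in increasing order.
    """
    if len(mask) == 0:
        raise ValueError("empty channel mask")
    if len(selection) == 0:
        raise ValueError("empty frequency selection")
    index = {c: i for i, c in enumerate(channels)}
    rows = []
    for c in mask:
        if c not in index:
            raise ValueError(f"channel {c} absent from the measurement matrix")
        rows.append(index[c])
    values = mean_matrix[np.ix_(rows, list(selection.indices))].ravel()
    return FeatureVector(
        values=values, subject_id=subject_id, label=label, mask=mask, selection=selection
    )


def cohort_features(
    cohort: Cohort, mask: ChannelMask, f_lo: float, f_hi: float
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix for a whole cohort.

    Returns ``(X, labels, subject_ids)`` where ``X`` is complex with one row
    per subject in cohort order.
    """
    sel = select_frequencies(cohort.freq_grid, f_lo, f_hi)
    rows = []
    for s in cohort.subjects:
        fv = assemble_feature_vector(
            average_repetitions(s),
            cohort.channels,
            mask,
            sel,
            subject_id=s.subject_id,
            label=s.label,
        )
        rows.append(fv.values)
    X = np.stack(rows)
    return X, cohort.labels, [s.subject_id for s in cohort.subjects]
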