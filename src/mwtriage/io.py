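"""Cohort CSV serialization.

Long-format dialect, one row per (subject, repetition, channel, frequency):

    subject_id,label,repetition,antenna_a,antenna_b,freq_ghz,real,imag

UTF-8, "." decimal, mandatory header, rows in lexicographic order of
(subject_id, repetition, antenna_a, antenna_b, freq_ghz).  Floats are written
with 17 significant digits, so a write/read round trip preserves complex
values to float64 precision.

Subject metadata (age, sex, volumes) is generator provenance and is not part
of the measurement dialect; reading reconstructs measurements and labels
only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .channels import Channel
from .simulate import Cohort, SubjectMeasurement, CONTROL_LABEL, PATIENT_LABEL

__all__ = ["write_cohort", "read_cohort", "CohortParseError"]

_COLUMNS = ["subject_id", "label", "repetition", "antenna_a", "antenna_b", "freq_ghz", "real", "imag"]


class CohortParseError(ValueError):
    """Raised when a cohort CSV violates the dialect or its invariants."""


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to the long-format CSV dialect."""
    n_chan = len(cohort.channels)
    n_freq = len(cohort.freq_grid)
    frames = []
    a = np.array([c.antenna_a for c in cohort.channels])
    b = np.array([c.antenna_b for c in cohort.channels])
    for s in sorted(cohort.subjects, key=lambda s: s.subject_id):
        for r, mat in enumerate(s.repetitions, start=1):
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": s.subject_id,
                        "label": s.label,
                        "repetition": r,
                        "antenna_a": np.repeat(a, n_freq),
                        "antenna_b": np.repeat(b, n_freq),
                        "freq_ghz": np.tile(cohort.freq_grid, n_chan),
                        "real": mat.real.ravel(),
                        "imag": mat.imag.ravel(),
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV, validating shapes and uniqueness.

    Raises
    ------
    CohortParseError
        On an empty file, a malformed header, duplicate
        (subject, repetition, channel, frequency) keys, or a subject whose
        measurements do not cover the full channel x frequency grid (the
        error names the subject and channel).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CohortParseError(f"{path}: no records") from None
    if df.empty:
        raise CohortParseError(f"{path}: no records")
    if list(df.columns) != _COLUMNS:
        raise CohortParseError(
            f"{path}: malformed header {list(df.columns)}; expected {_COLUMNS}"
        )
    bad_label = ~df["label"].isin([PATIENT_LABEL, CONTROL_LABEL])
    if bad_label.any():
        row = int(np.flatnonzero(bad_label.to_numpy())[0]) + 2  # 1-based + header
        raise CohortParseError(f"{path}:{row}: unknown label {df['label'].iloc[row - 2]!r}")

    # canonical grids from the union of all rows
    freq_grid = np.sort(df["freq_ghz"].unique())
    chan_keys = sorted(
        set(zip(df["antenna_a"].astype(int), df["antenna_b"].astype(int)))
    )
    channels = [Channel(a, b) for a, b in chan_keys]
    chan_index = {(c.antenna_a, c.antenna_b): i for i, c in enumerate(channels)}
    freq_index = {f: i for i, f in enumerate(freq_grid)}

    dup = df.duplicated(subset=["subject_id", "repetition", "antenna_a", "antenna_b", "freq_ghz"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise CohortParseError(f"{path}:{row}: duplicate measurement key")

    subjects = []
    expected = len(channels) * len(freq_grid)
    for sid, sdf in df.groupby("subject_id", sort=True):
        labels = sdf["label"].unique()
        if len(labels) != 1:
            raise CohortParseError(f"{path}: subject {sid} has inconsistent labels")
        reps = []
        for rep, rdf in sdf.groupby("repetition", sort=True):
            if len(rdf) != expected:
                # find which channel is incomplete, for the error message
                counts = rdf.groupby(["antenna_a", "antenna_b"]).size()
                for (a, b), n in counts.items():
                    if n != len(freq_grid):
                        raise CohortParseError(
                            f"{path}: subject {sid} repetition {rep} channel {a}-{b}: "
                            f"expected {len(freq_grid)} frequency rows, found {n}"
                        )
                raise CohortParseError(
                    f"{path}: subject {sid} repetition {rep}: expected {expected} rows, "
                    f"found {len(rdf)}"
                )
            mat = np.zeros((len(channels), len(freq_grid)), dtype=complex)
            ci = [chan_index[(int(a), int(b))] for a, b in zip(rdf["antenna_a"], rdf["antenna_b"])]
            fi = [freq_index[f] for f in rdf["freq_ghz"]]
            mat[ci, fi] = rdf["real"].to_numpy() + 1j * rdf["imag"].to_numpy()
            reps.append(mat)
        subjects.append(
            SubjectMeasurement(subject_id=str(sid), label=str(labels[0]), repetitions=reps)
        )
    return Cohort(subjects=subjects, channels=channels, freq_grid=freq_grid)
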