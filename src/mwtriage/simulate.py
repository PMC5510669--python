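"""Synthetic cohorts of multi-antenna microwave measurements.

The clinical raw scattering data behind the hematoma-screening study were
never published, so this module generates statistical stand-ins: cohorts of
patients (chronic subdural hematoma, ``cSDH``) and healthy controls (``HC``),
each measured three consecutive times as triplicate complex channel-by-
frequency matrices over 0.1-1.95 GHz.

The generative model is an intentionally simple attenuation-plus-delay
surrogate, not an electromagnetic field solver.  It reproduces the
*statistical* structure the classifier must cope with:

* smooth complex spectra per channel, with amplitude decaying in frequency
  and path length and phase accumulating with path delay;
* inter-subject head variability as a random scale factor on all path
  lengths (head size is a dominant nuisance in practice);
* a hematoma perturbation that is local in azimuth (channels whose midpoint
  faces the lesion are affected most), scales like the linear dimension of
  the lesion (volume^(1/3)), and is phase-shifted relative to the baseline;
* triplicate measurements differing by a repositioning gain and additive
  complex noise proportional to the local signal magnitude.

All randomness flows from ``config.seed``; the generator is a pure function
of its configuration.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import yaml

from .channels import AntennaArray, Channel, enumerate_channels

__all__ = ["SyntheticConfig", "SubjectMeasurement", "Cohort", "generate_cohort"]

PATIENT_LABEL = "cSDH"
CONTROL_LABEL = "HC"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic measurement generator.

    Attributes
    ----------
    n_patients, n_controls
        Cohort sizes (clinical study: 20 + 20).
    n_antennas, array_radius
        Circular array geometry; 8 antennas on a 0.09 m radius circle.
    freq_start, freq_stop, freq_step
        Frequency grid in GHz; 0.10-1.95 GHz in 50 MHz steps gives the
        38-point device grid.
    repetitions
        Consecutive measurements per subject (the device takes three).
    attenuation_coeff
        Amplitude decay alpha in nepers per (meter * GHz); the baseline
        amplitude of a channel of path length L at frequency f is
        exp(-alpha * s * L * f) for head scale s.
    slowness
        Propagation slowness tau0 in nanoseconds per meter; sets the phase
        2*pi*f*tau0*s*L accrued along the path (f in GHz, so GHz*ns = 1).
    head_scale_sd
        SD of the per-subject head scale s ~ Normal(1, sd^2), a global
        inter-subject nuisance.
    contact_sd
        SD of the per-subject, per-channel complex contact gain
        c ~ CN(1, sd^2) multiplying the channel's whole spectrum: antenna
        coupling to skin and hair differs between subjects channel by
        channel and is stable across the three consecutive repetitions.
        This is the high-dimensional component of inter-subject
        variability.
    repositioning_sd
        SD of the per-repetition multiplicative gain g_r ~ Normal(1, sd^2).
    noise_sd
        Relative complex measurement noise: epsilon ~ CN(0, sd^2 |B|^2)
        added independently per repetition, channel and frequency.
    hematoma_gain
        kappa, relative magnitude of the lesion perturbation for a 100 mL
        lesion on the channel facing it.
    hematoma_spread
        lambda in radians; the lesion weight on a channel decays as
        exp(-(angular distance / lambda)^2) from the lesion azimuth.
    volume_lognormal_mu, volume_lognormal_sigma
        Log-scale parameters of the lesion volume draw in mL; defaults
        (log 100, 0.6) mimic the large surgical-cohort volumes (mean
        ~112 mL).
    bilateral_prob
        Probability that the lesion volume is split 2:1 over two opposite
        azimuths (6/20 clinical patients had bilateral hematomas).
    volume_scaling
        ``"cbrt"`` (default) scales the perturbation like volume^(1/3), a
        linear lesion dimension; ``"linear"`` scales it like the volume.
    lesion_azimuth_arc
        (lo, hi) in radians; lesion azimuths are drawn uniformly on this
        arc.  The default is the arc covered by the lateral antennas 3-6
        (pi/2 to 5*pi/4): chronic subdural hematomas sit laterally, which
        is also what motivates the default channel mask.  Set to
        (0, 2*pi) for lesions anywhere on the circle.
    lesion_band
        Optional (f_min, f_max) in GHz restricting the perturbation to a
        frequency band; outside it the lesion leaves the signal untouched.
        Used for planted-structure recovery experiments.
    seed
        Master seed; the whole cohort is deterministic given the config.
    """

    n_patients: int = 20
    n_controls: int = 20
    n_antennas: int = 8
    array_radius: float = 0.09
    freq_start: float = 0.10
    freq_stop: float = 1.95
    freq_step: float = 0.05
    repetitions: int = 3
    attenuation_coeff: float = 25.0
    slowness: float = 20.0
    head_scale_sd: float = 0.01
    contact_sd: float = 0.05
    repositioning_sd: float = 0.01
    noise_sd: float = 0.02
    hematoma_gain: float = 0.2
    hematoma_spread: float = 1.8
    volume_lognormal_mu: float = math.log(100.0)
    volume_lognormal_sigma: float = 0.6
    bilateral_prob: float = 0.3
    volume_scaling: str = "cbrt"
    lesion_azimuth_arc: tuple[float, float] = (math.pi / 2, 5 * math.pi / 4)
    lesion_band: Optional[tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.freq_start >= self.freq_stop:
            raise ValueError("freq_start must be below freq_stop")
        if self.freq_step <= 0:
            raise ValueError("freq_step must be positive")
        n_steps = (self.freq_stop - self.freq_start) / self.freq_step
        if abs(n_steps - round(n_steps)) > 1e-6:
            raise ValueError("freq_step must divide the frequency span")
        for name in (
            "head_scale_sd",
            "contact_sd",
            "repositioning_sd",
            "noise_sd",
            "hematoma_gain",
            "hematoma_spread",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.bilateral_prob <= 1.0:
            raise ValueError("bilateral_prob must lie in [0, 1]")
        if self.repetitions < 1:
            raise ValueError("need at least one repetition")
        if self.volume_scaling not in ("cbrt", "linear"):
            raise ValueError("volume_scaling must be 'cbrt' or 'linear'")

    @property
    def freq_grid(self) -> np.ndarray:
        n = round((self.freq_stop - self.freq_start) / self.freq_step) + 1
        return self.freq_start + self.freq_step * np.arange(n)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if d["lesion_band"] is not None:
            d["lesion_band"] = list(d["lesion_band"])
        d["lesion_azimuth_arc"] = list(d["lesion_azimuth_arc"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if d.get("lesion_band") is not None:
            d["lesion_band"] = tuple(d["lesion_band"])
        if "lesion_azimuth_arc" in d:
            d["lesion_azimuth_arc"] = tuple(d["lesion_azimuth_arc"])
        return cls(**d)


@dataclass
class SubjectMeasurement:
    """Triplicate complex measurements of one subject.

    ``repetitions`` holds the consecutive measurements, each a complex
    matrix indexed [channel, frequency] in the cohort's canonical channel
    order.  ``total_volume`` is 0 for controls; ``lesion_azimuth`` is None
    for controls.
    """

    subject_id: str
    label: str
    repetitions: list[np.ndarray]
    age: float | None = None
    sex: str | None = None
    total_volume: float = 0.0
    lesion_azimuth: float | None = None

    def __post_init__(self) -> None:
        if self.label not in (PATIENT_LABEL, CONTROL_LABEL):
            raise ValueError(f"label must be {PATIENT_LABEL!r} or {CONTROL_LABEL!r}")
        if not self.repetitions:
            raise ValueError("at least one repetition required")
        shape = self.repetitions[0].shape
        for r in self.repetitions:
            if r.shape != shape:
                raise ValueError("all repetitions must share one shape")
            if not np.all(np.isfinite(r.view(float))):
                raise ValueError("non-finite measurement values")


@dataclass
class Cohort:
    """A set of subjects sharing one channel list and frequency grid."""

    subjects: list[SubjectMeasurement]
    channels: list[Channel]
    freq_grid: np.ndarray
    config: SyntheticConfig | None = None

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")
        shape = (len(self.channels), len(self.freq_grid))
        for s in self.subjects:
            if s.repetitions[0].shape != shape:
                raise ValueError(
                    f"subject {s.subject_id} measurements have shape "
                    f"{s.repetitions[0].shape}, expected {shape}"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects])

    def with_labels(self, labels: Sequence[str]) -> "Cohort":
        """A shallow copy with reassigned class labels (for permutation nulls)."""
        if len(labels) != len(self.subjects):
            raise ValueError("need one label per subject")
        subjects = [
            replace_label(s, lab) for s, lab in zip(self.subjects, labels)
        ]
        return Cohort(subjects, self.channels, self.freq_grid, self.config)

    def subset(self, indices: Sequence[int]) -> "Cohort":
        subjects = [self.subjects[i] for i in indices]
        return Cohort(subjects, self.channels, self.freq_grid, self.config)


def replace_label(s: SubjectMeasurement, label: str) -> SubjectMeasurement:
    return SubjectMeasurement(
        subject_id=s.subject_id,
        label=label,
        repetitions=s.repetitions,
        age=s.age,
        sex=s.sex,
        total_volume=s.total_volume,
        lesion_azimuth=s.lesion_azimuth,
    )


def _path_lengths(array: AntennaArray, channels: list[Channel]) -> np.ndarray:
    """Propagation path length per channel in meters.

    Transmission channels use the chord between the two antennas; reflection
    channels use a small constant 0.3 * radius, standing in for the shallow
    round trip into superficial tissue.
    """
    lengths = np.empty(len(channels))
    for i, c in enumerate(channels):
        if c.is_reflection:
            lengths[i] = 0.3 * array.radius
        else:
            dtheta = array.azimuth(c.antenna_a) - array.azimuth(c.antenna_b)
            lengths[i] = abs(2.0 * array.radius * math.sin(dtheta / 2.0))
    return lengths


def _midpoint_azimuths(array: AntennaArray, channels: list[Channel]) -> np.ndarray:
    """Channel midpoint azimuth: arithmetic mean of the antenna azimuths, wrapped."""
    mid = np.empty(len(channels))
    for i, c in enumerate(channels):
        mid[i] = (array.azimuth(c.antenna_a) + array.azimuth(c.antenna_b)) / 2.0
    return np.mod(mid, 2.0 * np.pi)


def _wrapped_distance(a: np.ndarray, b: float) -> np.ndarray:
    """Angular distance on the circle, in [0, pi]."""
    d = np.abs(np.mod(a - b + np.pi, 2.0 * np.pi) - np.pi)
    return d


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a synthetic cohort; deterministic given ``config``.

    Patients are generated first (ids ``P01..``), controls second
    (``C01..``).  See the module docstring for the generative model.
    """
    if config.n_patients < 1 or config.n_controls < 1:
        raise ValueError("both classes need at least one subject")
    freq = config.freq_grid  # GHz
    if len(freq) < 2:
        raise ValueError("frequency grid must contain at least two points")

    array = AntennaArray(n_antennas=config.n_antennas, radius=config.array_radius)
    channels = enumerate_channels(config.n_antennas)
    lengths = _path_lengths(array, channels)  # (C,)
    midpoints = _midpoint_azimuths(array, channels)  # (C,)
    rng = np.random.default_rng(config.seed)

    in_band = np.ones_like(freq, dtype=bool)
    if config.lesion_band is not None:
        lo, hi = config.lesion_band
        in_band = (freq >= lo) & (freq <= hi)

    subjects: list[SubjectMeasurement] = []
    n_total = config.n_patients + config.n_controls
    for k in range(n_total):
        is_patient = k < config.n_patients
        label = PATIENT_LABEL if is_patient else CONTROL_LABEL
        sid = (f"P{k + 1:02d}" if is_patient else f"C{k - config.n_patients + 1:02d}")

        s = 1.0 + config.head_scale_sd * rng.standard_normal()
        contact = 1.0 + config.contact_sd * (
            rng.standard_normal(len(channels)) + 1j * rng.standard_normal(len(channels))
        ) / np.sqrt(2.0)
        # baseline: attenuation in amplitude, path delay in phase
        lf = np.outer(lengths, freq)  # (C, F), meter*GHz
        baseline = np.exp(-config.attenuation_coeff * s * lf) * np.exp(
            -2j * np.pi * config.slowness * s * lf
        )

        total_volume = 0.0
        lesion_azimuth: float | None = None
        perturbation = np.zeros_like(baseline)
        if is_patient:
            v = float(rng.lognormal(config.volume_lognormal_mu, config.volume_lognormal_sigma))
            arc_lo, arc_hi = config.lesion_azimuth_arc
            phi = float(np.mod(rng.uniform(arc_lo, arc_hi), 2.0 * np.pi))
            bilateral = rng.random() < config.bilateral_prob
            total_volume = v
            lesion_azimuth = phi
            lesions = [(v, phi)]
            if bilateral:
                lesions = [(2.0 * v / 3.0, phi), (v / 3.0, phi + np.pi)]
            for v_i, phi_i in lesions:
                if config.volume_scaling == "cbrt":
                    size = (v_i / 100.0) ** (1.0 / 3.0)
                else:
                    size = v_i / 100.0
                w = np.exp(-((_wrapped_distance(midpoints, phi_i) / config.hematoma_spread) ** 2))
                perturbation += (
                    config.hematoma_gain
                    * size
                    * w[:, None]
                    * baseline
                    * np.exp(2j * np.pi * freq * 0.1)[None, :]
                    * in_band[None, :]
                )

        clean = contact[:, None] * (baseline + perturbation)
        noise_scale = config.noise_sd * np.abs(baseline)
        reps = []
        for _ in range(config.repetitions):
            g = 1.0 + config.repositioning_sd * rng.standard_normal()
            noise = (
                rng.standard_normal(clean.shape) + 1j * rng.standard_normal(clean.shape)
            ) * (noise_scale / np.sqrt(2.0))
            reps.append(g * clean + noise)

        age = float(np.clip(rng.normal(75.0, 10.0), 50.0, 92.0))
        sex = "M" if rng.random() < 0.55 else "F"
        subjects.append(
            SubjectMeasurement(
                subject_id=sid,
                label=label,
                repetitions=reps,
                age=age,
                sex=sex,
                total_volume=total_volume,
                lesion_azimuth=lesion_azimuth,
            )
        )

    return Cohort(subjects=subjects, channels=channels, freq_grid=freq, config=config)
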