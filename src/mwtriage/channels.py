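"""Antenna channel combinatorics and channel-exclusion masks.

The measurement device carries ``n_antennas`` antennas around the head (eight
in the clinical layout, numbered 1-2 at the forehead, 3-6 laterally, 7-8 at
the back of the head).  A *channel* is one unordered antenna pair: a
reflection channel when the same antenna transmits and receives, a
transmission channel otherwise.  By reciprocity one complex scattering
coefficient is kept per unordered pair, so an 8-antenna array has
8 + C(8,2) = 36 channels.

Channels dominated by long, strongly attenuated paths through the head, and
channels probing only the peripheral forehead/occiput region, carry little
information about the typically lateral hematomas; the default exclusion mask
removes them, keeping every channel that touches at least one lateral antenna
(3-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Channel",
    "AntennaArray",
    "ChannelMask",
    "enumerate_channels",
    "default_exclusion_mask",
    "mask_from_config",
    "read_mask",
    "write_mask",
]

#: Lateral antennas in the 8-antenna clinical layout (1-based).
LATERAL_ANTENNAS = frozenset({3, 4, 5, 6})


@dataclass(frozen=True, order=True)
class Channel:
    """One unordered antenna pair; ``antenna_a <= antenna_b`` always holds."""

    antenna_a: int
    antenna_b: int

    def __post_init__(self) -> None:
        a, b = self.antenna_a, self.antenna_b
        if not (isinstance(a, (int, np.integer)) and isinstance(b, (int, np.integer))):
            raise TypeError("antenna indices must be integers")
        if a < 1 or b < 1:
            raise ValueError(f"antenna indices are 1-based, got ({a}, {b})")
        if a > b:
            # canonicalize the unordered pair
            object.__setattr__(self, "antenna_a", int(b))
            object.__setattr__(self, "antenna_b", int(a))
        else:
            object.__setattr__(self, "antenna_a", int(a))
            object.__setattr__(self, "antenna_b", int(b))

    @property
    def is_reflection(self) -> bool:
        return self.antenna_a == self.antenna_b

    @property
    def is_transmission(self) -> bool:
        return not self.is_reflection

    def __str__(self) -> str:
        return f"{self.antenna_a}-{self.antenna_b}"

    @classmethod
    def parse(cls, token: str) -> "Channel":
        """Parse an ``"a-b"`` token (e.g. ``"3-5"``)."""
        parts = token.strip().split("-")
        if len(parts) != 2:
            raise ValueError(f"malformed channel token {token!r}; expected 'a-b'")
        return cls(int(parts[0]), int(parts[1]))


@dataclass(frozen=True)
class AntennaArray:
    """Circular antenna layout; azimuths are used only by the simulator.

    Parameters
    ----------
    n_antennas
        Number of antennas (device default 8).
    azimuths
        Per-antenna azimuth angle in radians, strictly increasing in
        [0, 2*pi).  Defaults to a uniform circle.
    radius
        Circle radius in meters.
    """

    n_antennas: int = 8
    radius: float = 0.09
    azimuths: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_antennas < 1:
            raise ValueError("n_antennas must be positive")
        if self.azimuths is None:
            az = tuple(2.0 * np.pi * k / self.n_antennas for k in range(self.n_antennas))
            object.__setattr__(self, "azimuths", az)
        az = np.asarray(self.azimuths, dtype=float)
        if az.shape != (self.n_antennas,):
            raise ValueError("need one azimuth per antenna")
        if np.any(az < 0) or np.any(az >= 2 * np.pi) or np.any(np.diff(az) <= 0):
            raise ValueError("azimuths must be strictly increasing in [0, 2*pi)")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def azimuth(self, antenna: int) -> float:
        """Azimuth of a 1-based antenna index."""
        return self.azimuths[antenna - 1]


def enumerate_channels(n_antennas: int) -> list[Channel]:
    """All channels of an ``n_antennas`` array in canonical order.

    Returns reflection channels plus unordered transmission pairs, sorted
    lexicographically by ``(antenna_a, antenna_b)``.  The length is
    ``n * (n + 1) / 2``.
    """
    if not isinstance(n_antennas, (int, np.integer)) or n_antennas < 1:
        raise ValueError(f"n_antennas must be a positive integer, got {n_antennas!r}")
    return [
        Channel(a, b)
        for a in range(1, n_antennas + 1)
        for b in range(a, n_antennas + 1)
    ]


@dataclass(frozen=True)
class ChannelMask:
    """An ordered subset of channels retained for analysis.

    The ordering is canonical (lexicographic by antenna pair) so that the
    feature-vector layout downstream is deterministic.
    """

    retained: tuple[Channel, ...]

    def __post_init__(self) -> None:
        chans = tuple(sorted(set(self.retained)))
        object.__setattr__(self, "retained", chans)

    def __len__(self) -> int:
        return len(self.retained)

    def __iter__(self):
        return iter(self.retained)

    def __contains__(self, channel: Channel) -> bool:
        return channel in set(self.retained)

    def serialize(self) -> str:
        """Plain-text form: one ``a-b`` token per line, canonical order."""
        return "\n".join(str(c) for c in self.retained) + "\n"


def default_exclusion_mask(n_antennas: int = 8) -> ChannelMask:
    """The clinical-layout channel mask for the 8-antenna device.

    Retains exactly the channels with at least one antenna among the lateral
    antennas 3-6; removes the reflections of antennas 1, 2, 7, 8 and every
    transmission channel internal to {1, 2, 7, 8}.  Of the 36 channels, 26
    are retained.

    Raises for any other antenna count: the mask encodes the specific device
    layout (forehead / lateral / occipital pairs) and does not generalize.
    """
    if n_antennas != 8:
        raise ValueError(
            f"the default exclusion mask is specific to the 8-antenna layout, got {n_antennas}"
        )
    retained = [
        c
        for c in enumerate_channels(8)
        if c.antenna_a in LATERAL_ANTENNAS or c.antenna_b in LATERAL_ANTENNAS
    ]
    return ChannelMask(tuple(retained))


def mask_from_config(
    spec: Iterable[Channel | str | Sequence[int]], n_antennas: int = 8
) -> ChannelMask:
    """Build a mask from channel descriptors.

    Descriptors may be :class:`Channel` objects, ``"a-b"`` strings, or
    ``(a, b)`` pairs.  Unordered duplicates (e.g. ``(5, 3)`` and ``(3, 5)``)
    collapse to a single channel.  Antenna indices outside
    ``1..n_antennas`` are rejected.
    """
    valid = set(enumerate_channels(n_antennas))
    channels: list[Channel] = []
    for item in spec:
        if isinstance(item, Channel):
            c = item
        elif isinstance(item, str):
            c = Channel.parse(item)
        else:
            a, b = item
            c = Channel(int(a), int(b))
        if c not in valid:
            raise ValueError(
                f"channel {c} is not valid for an array of {n_antennas} antennas"
            )
        channels.append(c)
    return ChannelMask(tuple(channels))


def write_mask(mask: ChannelMask, path: str | Path) -> None:
    Path(path).write_text(mask.serialize(), encoding="utf-8")


def read_mask(path: str | Path, n_antennas: int = 8) -> ChannelMask:
    """Read a mask from its plain-text serialization (one ``a-b`` per line)."""
    tokens = [
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    return mask_from_config(tokens, n_antennas=n_antennas)
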