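"""Channel montages: ordered electrode labels with optional 3-D scalp positions.

Positions live on (a cap of) the unit sphere in arbitrary units.  Only the
channel count and, for the synthetic generator's spatial smoothing, the
relative distances matter; no physical head model is implied.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["ChannelMontage", "synthetic_scalp_montage"]


@dataclass(frozen=True)
class ChannelMontage:
    """An ordered set of EEG channels.

    Parameters
    ----------
    labels
        Unique channel identifiers, in recording order.
    positions
        Optional ``(n_channels, 3)`` array of unit-sphere coordinates
        (arbitrary units), one row per label.
    """

    labels: tuple[str, ...]
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        if len(labels) != len(set(labels)):
            raise InvalidInputError("montage labels must be unique")
        object.__setattr__(self, "labels", labels)
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float)
            if pos.shape != (len(labels), 3):
                raise InvalidInputError(
                    f"positions must have shape ({len(labels)}, 3), got {pos.shape}"
                )
            pos = pos.copy()
            pos.setflags(write=False)
            object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def fingerprint(self) -> str:
        """Stable identifier derived from the ordered labels; used to detect montage mismatches."""
        h = hashlib.sha1("\x00".join(self.labels).encode()).hexdigest()
        return h[:12]


def synthetic_scalp_montage(n_channels: int = 128, cap_fraction: float = 0.6) -> ChannelMontage:
    """Deterministic sunflower layout on a spherical cap, emulating a dense electrode net.

    Channels are labelled ``E1``..``E<n>``.  ``cap_fraction`` controls how far
    below the vertex the cap extends (0.6 reaches slightly below the equator,
    roughly like a 128-channel geodesic net).
    """
    if n_channels < 1:
        raise InvalidInputError("n_channels must be positive")
    i = np.arange(n_channels) + 0.5
    z = 1.0 - (i / n_channels) * (2.0 * cap_fraction)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * np.arange(n_channels)
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    labels = tuple(f"E{k + 1}" for k in range(n_channels))
    return ChannelMontage(labels=labels, positions=pos)
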