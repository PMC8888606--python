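"""Topography-level primitives: average reference, global field power, spatial correlation.

A *topography* (map) is the vector of scalp potentials across all channels at
one time frame.  All microstate math downstream assumes average-referenced
(zero channel-mean) maps; the polarity of a map is treated as ambiguous, so
correlations are optionally compared by absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import InvalidInputError, NotReferencedError, UndefinedCorrelationError

__all__ = [
    "TopographyMap",
    "ErpEpoch",
    "apply_average_reference",
    "crop_window",
    "gfp",
    "spatial_correlation",
    "nondegenerate_frames",
]

# Relative tolerance for "channel mean is zero": |mean| <= REF_RTOL * rms(values).
REF_RTOL = 1e-8


@dataclass(frozen=True)
class TopographyMap:
    """A potential vector over channels at one instant (µV or arbitrary units)."""

    values: np.ndarray
    montage_ref: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidInputError("TopographyMap values must be 1-D")
        object.__setattr__(self, "values", v)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ErpEpoch:
    """One subject x condition ERP: channels x frames, with timing metadata.

    Parameters
    ----------
    data
        ``(n_channels, n_frames)`` potential matrix in µV.
    sfreq
        Sampling rate in Hz.
    t0
        Time of the first frame relative to stimulus onset, in ms.
    subject, condition
        Identifiers used for provenance and the metrics table.
    referenced
        Whether ``data`` is already average-referenced.
    montage_ref
        Fingerprint of the montage the rows index.
    """

    data: np.ndarray
    sfreq: float
    t0: float = 0.0
    subject: str = ""
    condition: str = ""
    referenced: bool = False
    montage_ref: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise InvalidInputError("ErpEpoch data must be channels x frames (2-D)")
        if d.shape[1] < 2:
            raise InvalidInputError("ErpEpoch needs at least 2 frames")
        if not self.sfreq > 0:
            raise InvalidInputError("sfreq must be positive")
        object.__setattr__(self, "data", d)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        """Frame times relative to stimulus onset, in ms."""
        return self.t0 + np.arange(self.n_frames) * (1000.0 / self.sfreq)


def apply_average_reference(epoch: ErpEpoch) -> ErpEpoch:
    """Re-reference every frame to the channel average (zero channel mean).

    Idempotent; preserves all inter-channel differences.  Applied defensively
    throughout the pipeline even when ``epoch.referenced`` is already true.
    """
    if epoch.n_channels < 2:
        raise InvalidInputError("average reference needs at least 2 channels")
    data = epoch.data - epoch.data.mean(axis=0, keepdims=True)
    return replace(epoch, data=data, referenced=True)


def crop_window(epoch: ErpEpoch, start_ms: float, stop_ms: float) -> ErpEpoch:
    """Restrict an epoch to the half-open analysis window ``[start_ms, stop_ms)``."""
    mask = (epoch.times_ms >= start_ms) & (epoch.times_ms < stop_ms)
    if mask.sum() < 2:
        raise InvalidInputError(
            f"analysis window [{start_ms}, {stop_ms}) ms covers fewer than 2 frames"
        )
    first = int(np.flatnonzero(mask)[0])
    return replace(epoch, data=epoch.data[:, mask], t0=float(epoch.times_ms[first]))


def _values(x) -> np.ndarray:
    if isinstance(x, TopographyMap):
        return x.values
    return np.asarray(x, dtype=float)


def _check_zero_mean(v: np.ndarray, what: str) -> None:
    scale = np.sqrt(np.mean(v**2, axis=0))
    m = np.abs(v.mean(axis=0))
    bad = m > REF_RTOL * np.maximum(scale, 1e-300)
    if np.any(bad & (scale > 0)):
        raise NotReferencedError(f"{what} must be average-referenced (zero channel mean)")


def gfp(values, *, check_reference: bool = True):
    """Global field power: the standard deviation of the potential across channels.

    For a zero-mean map ``v`` this is ``sqrt(mean(v**2))`` — a reference-free
    amplitude measure.  Accepts a single map (1-D) or a channels x frames
    matrix (2-D, returns one value per frame).
    """
    v = _values(values)
    if v.ndim == 1:
        v = v[:, None]
        squeeze = True
    elif v.ndim == 2:
        squeeze = False
    else:
        raise InvalidInputError("gfp expects a 1-D map or 2-D channels x frames matrix")
    if check_reference:
        _check_zero_mean(v, "gfp input")
    out = np.sqrt(np.mean(v**2, axis=0))
    return float(out[0]) if squeeze else out


def spatial_correlation(u, v, ignore_polarity: bool = False) -> float:
    """Pearson correlation of two zero-mean maps across channels.

    Equals the cosine similarity for average-referenced maps.  With
    ``ignore_polarity`` the absolute value is returned, treating a map and its
    sign-flipped copy as the same topography.
    """
    a, b = _values(u), _values(v)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("maps must be 1-D with identical length")
    if isinstance(u, TopographyMap) and isinstance(v, TopographyMap):
        if u.montage_ref and v.montage_ref and u.montage_ref != v.montage_ref:
            from .exceptions import MontageMismatchError

            raise MontageMismatchError("maps index different montages")
    _check_zero_mean(a[:, None], "spatial_correlation input")
    _check_zero_mean(b[:, None], "spatial_correlation input")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedCorrelationError("spatial correlation undefined for a zero-norm map")
    r = float(np.dot(a, b) / (na * nb))
    r = max(-1.0, min(1.0, r))
    return abs(r) if ignore_polarity else r


def nondegenerate_frames(data: np.ndarray, rel_tol: float = 1e-12) -> np.ndarray:
    """Boolean mask of frames whose GFP is non-negligible.

    All-zero (or numerically flat) frames carry no topography; they are
    excluded from clustering and left unassigned in backfitting rather than
    raising on the whole run.
    """
    g = np.sqrt(np.mean(np.asarray(data, float) ** 2, axis=0))
    return g > rel_tol * max(float(g.max(initial=0.0)), 1e-300)
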