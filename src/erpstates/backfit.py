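"""Backfitting global templates to ERPs and the three microstate metrics.

Each frame of an ERP is assigned to the global template with the highest
absolute spatial correlation, yielding a microstate label sequence.  From the
sequence's contiguous runs derive, per microstate class:

* mean duration (ms) — average run length;
* occurrence (Hz) — number of distinct runs per second of analysis window;
* coverage (%) — share of assigned frames carrying the class.

For a fully assigned sequence these satisfy, exactly and per sequence,
``coverage/100 = occurrence * duration / 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clustering import _normalize_rows
from .exceptions import InvalidInputError, MontageMismatchError
from .group import GlobalTemplateSet
from .topography import ErpEpoch, apply_average_reference, crop_window, nondegenerate_frames

__all__ = [
    "MicrostateSequence",
    "backfit",
    "run_lengths",
    "mean_duration",
    "occurrence",
    "coverage",
    "build_metrics_table",
    "UNASSIGNED",
]

UNASSIGNED = -1


@dataclass
class MicrostateSequence:
    """Per-frame microstate class labels for one ERP.

    ``labels`` are 0-based template indices, ``UNASSIGNED`` (-1) for frames
    excluded as flat; ``fit_r`` is each frame's winning |spatial correlation|.
    """

    labels: np.ndarray
    sfreq: float
    subject: str = ""
    condition: str = ""
    fit_r: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise InvalidInputError("labels must be a nonempty 1-D array")
        if not self.sfreq > 0:
            raise InvalidInputError("sfreq must be positive")

    @property
    def n_frames(self) -> int:
        return self.labels.size

    @property
    def window_s(self) -> float:
        """Analysis-window length in seconds (all frames, assigned or not)."""
        return self.n_frames / self.sfreq


def backfit(
    epoch: ErpEpoch,
    templates: GlobalTemplateSet | np.ndarray,
    *,
    window_ms: tuple[float, float] | None = None,
    min_duration_ms: float = 0.0,
) -> MicrostateSequence:
    """Assign every frame to the best-|r| global template.

    Ties break toward the lower template index; flat (zero-GFP) frames stay
    unassigned.  ``min_duration_ms`` optionally merges runs shorter than the
    threshold into the neighbouring template with the better mean fit
    (default off: no temporal smoothing).
    """
    t = templates.templates if isinstance(templates, GlobalTemplateSet) else np.asarray(templates, float)
    if isinstance(templates, GlobalTemplateSet) and templates.montage_ref and epoch.montage_ref:
        if templates.montage_ref != epoch.montage_ref:
            raise MontageMismatchError("epoch and templates index different montages")
    if t.shape[1] != epoch.n_channels:
        raise MontageMismatchError(
            f"templates have {t.shape[1]} channels, epoch has {epoch.n_channels}"
        )
    epoch = apply_average_reference(epoch)
    if window_ms is not None:
        epoch = crop_window(epoch, *window_ms)
    tn = _normalize_rows(t)
    keep = nondegenerate_frames(epoch.data)
    frames = epoch.data.T
    labels = np.full(epoch.n_frames, UNASSIGNED, dtype=int)
    fit = np.zeros(epoch.n_frames)
    if keep.any():
        vn = _normalize_rows(frames[keep])
        absr = np.abs(tn @ vn.T)  # (k, n_kept)
        labels[keep] = np.argmax(absr, axis=0)  # argmax takes the lowest index on ties
        fit[keep] = absr.max(axis=0)
    if min_duration_ms > 0.0:
        labels = _merge_short_runs(labels, frames, tn, min_duration_ms, epoch.sfreq)
        if keep.any():
            vn = _normalize_rows(frames[keep])
            absr = np.abs(tn @ vn.T)
            fit[keep] = np.abs(absr[labels[keep], np.arange(int(keep.sum()))])
    return MicrostateSequence(
        labels=labels,
        sfreq=epoch.sfreq,
        subject=epoch.subject,
        condition=epoch.condition,
        fit_r=fit,
    )


def _merge_short_runs(labels, frames, tn, min_ms, sfreq):
    """Relabel runs shorter than ``min_ms`` to the better-fitting neighbouring class."""
    min_frames = int(np.ceil(min_ms * sfreq / 1000.0))
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        for start, length, cls in run_lengths(labels):
            if cls == UNASSIGNED or length >= min_frames:
                continue
            candidates = []
            if start > 0 and labels[start - 1] != UNASSIGNED:
                candidates.append(labels[start - 1])
            end = start + length
            if end < labels.size and labels[end] != UNASSIGNED:
                candidates.append(labels[end])
            if not candidates:
                continue
            seg = frames[start:end]
            seg = seg / np.linalg.norm(seg, axis=1, keepdims=True)
            best = max(candidates, key=lambda c: float(np.mean(np.abs(seg @ tn[c]))))
            labels[start:end] = best
            changed = True
            break
    return labels


def run_lengths(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a label sequence: list of (start, length, label)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(s), int(e - s), int(labels[s])) for s, e in zip(starts, ends)]


def mean_duration(seq: MicrostateSequence, cls: int) -> float:
    """Mean contiguous-run length of a class, in ms; NaN when the class never occurs.

    Runs truncated by the window edges enter with their observed length.
    """
    runs = [l for _, l, c in run_lengths(seq.labels) if c == cls]
    if not runs:
        return float("nan")
    return float(np.mean(runs)) * 1000.0 / seq.sfreq


def occurrence(seq: MicrostateSequence, cls: int) -> float:
    """Number of distinct runs of a class per second of analysis window (Hz)."""
    n_runs = sum(1 for _, _, c in run_lengths(seq.labels) if c == cls)
    return n_runs / seq.window_s


def coverage(seq: MicrostateSequence, cls: int) -> float:
    """Percentage of assigned frames labelled with the class."""
    assigned = int(np.sum(seq.labels != UNASSIGNED))
    if assigned == 0:
        return float("nan")
    return 100.0 * int(np.sum(seq.labels == cls)) / assigned


def build_metrics_table(
    sequences: Iterable[MicrostateSequence],
    n_classes: int,
    class_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per subject x condition x class with the three metrics.

    Classes absent from a sequence get an explicit row with NaN duration,
    zero occurrence and zero coverage.
    """
    if class_names is None:
        class_names = [f"M{i + 1}" for i in range(n_classes)]
    if len(class_names) != n_classes:
        raise InvalidInputError("class_names length must equal n_classes")
    rows = []
    for seq in sequences:
        for cls in range(n_classes):
            rows.append(
                {
                    "subject": seq.subject,
                    "condition": seq.condition,
                    "class": class_names[cls],
                    "duration_ms": mean_duration(seq, cls),
                    "occurrence_hz": occurrence(seq, cls),
                    "coverage_pct": coverage(seq, cls),
                }
            )
    if not rows:
        raise InvalidInputError("no sequences supplied")
    return pd.DataFrame(rows)
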