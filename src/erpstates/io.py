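"""Plain-text serialisation: ERP matrices with YAML sidecars, montages, templates, sequences.

The normative on-disk form is delimited text.  An ERP is a channels x frames
TSV matrix (``<stem>.tsv``) plus a YAML sidecar (``<stem>.yaml``) carrying
sfreq, t0, subject, condition, reference state and channel labels.  Standard
EEG container formats can be converted to this form with the usual ecosystem
tools; this module deliberately stays format-agnostic beyond it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidInputError
from .group import GlobalTemplateSet
from .backfit import MicrostateSequence
from .montage import ChannelMontage
from .topography import ErpEpoch

__all__ = [
    "save_epoch",
    "load_epoch",
    "save_montage",
    "load_montage",
    "save_templates",
    "load_templates",
    "save_sequence",
    "load_sequence",
]

_FLOAT_FMT = "%.10g"


def save_epoch(stem: Path | str, epoch: ErpEpoch, labels: tuple[str, ...] | None = None) -> None:
    """Write ``<stem>.tsv`` (channels x frames) and ``<stem>.yaml`` sidecar."""
    stem = Path(stem)
    np.savetxt(stem.with_suffix(".tsv"), epoch.data, fmt=_FLOAT_FMT, delimiter="\t")
    meta = {
        "sfreq": float(epoch.sfreq),
        "t0_ms": float(epoch.t0),
        "subject": epoch.subject,
        "condition": epoch.condition,
        "referenced": bool(epoch.referenced),
        "montage_ref": epoch.montage_ref,
        "n_channels": epoch.n_channels,
        "n_frames": epoch.n_frames,
    }
    if labels is not None:
        meta["channels"] = list(labels)
    stem.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def load_epoch(stem: Path | str) -> ErpEpoch:
    stem = Path(stem)
    data = np.loadtxt(stem.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    meta = yaml.safe_load(stem.with_suffix(".yaml").read_text())
    if data.shape[0] != meta.get("n_channels", data.shape[0]):
        raise InvalidInputError(f"{stem}: matrix rows disagree with sidecar n_channels")
    return ErpEpoch(
        data=data,
        sfreq=float(meta["sfreq"]),
        t0=float(meta.get("t0_ms", 0.0)),
        subject=str(meta.get("subject", "")),
        condition=str(meta.get("condition", "")),
        referenced=bool(meta.get("referenced", False)),
        montage_ref=str(meta.get("montage_ref", "")),
    )


def save_montage(path: Path | str, montage: ChannelMontage) -> None:
    """Delimited ``label, x, y, z`` table (positions optional)."""
    if montage.positions is not None:
        df = pd.DataFrame(montage.positions, columns=["x", "y", "z"])
        df.insert(0, "label", montage.labels)
    else:
        df = pd.DataFrame({"label": montage.labels})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_montage(path: Path | str) -> ChannelMontage:
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise InvalidInputError("montage table needs a 'label' column")
    positions = None
    if {"x", "y", "z"} <= set(df.columns):
        positions = df[["x", "y", "z"]].to_numpy(dtype=float)
    return ChannelMontage(labels=tuple(df["label"].astype(str)), positions=positions)


def save_templates(stem: Path | str, templates: GlobalTemplateSet) -> None:
    """Channels x k delimited matrix plus YAML metadata."""
    stem = Path(stem)
    np.savetxt(stem.with_suffix(".tsv"), templates.templates.T, fmt=_FLOAT_FMT, delimiter="\t")
    meta = {
        "k_global": templates.k_global,
        "names": list(templates.names),
        "montage_ref": templates.montage_ref,
        "provenance_n": templates.provenance_n,
        "seed": templates.seed,
    }
    if templates.kl_curve is not None:
        meta["kl_rule"] = templates.kl_curve.rule
        meta["kl_flags"] = list(templates.kl_curve.flags)
    stem.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def load_templates(stem: Path | str) -> GlobalTemplateSet:
    stem = Path(stem)
    mat = np.loadtxt(stem.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    meta = yaml.safe_load(stem.with_suffix(".yaml").read_text())
    return GlobalTemplateSet(
        templates=mat.T,
        montage_ref=str(meta.get("montage_ref", "")),
        provenance_n=int(meta.get("provenance_n", 0)),
        names=tuple(meta.get("names", ())),
        seed=meta.get("seed"),
    )


def save_sequence(path: Path | str, seq: MicrostateSequence) -> None:
    """One row per frame: frame index, time (ms), label, winning |r|."""
    n = seq.n_frames
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_ms": np.arange(n) * 1000.0 / seq.sfreq,
            "label": seq.labels,
            "fit_r": seq.fit_r if seq.fit_r is not None else np.full(n, np.nan),
        }
    )
    header = f"# subject={seq.subject} condition={seq.condition} sfreq={seq.sfreq}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def load_sequence(path: Path | str) -> MicrostateSequence:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=", 1) for kv in header.split())
        df = pd.read_csv(fh, sep="\t")
    return MicrostateSequence(
        labels=df["label"].to_numpy(dtype=int),
        sfreq=float(meta["sfreq"]),
        subject=meta.get("subject", ""),
        condition=meta.get("condition", ""),
        fit_r=df["fit_r"].to_numpy(dtype=float),
    )
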