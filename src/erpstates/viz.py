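"""Minimal topography rendering: one scatter panel per global template.

Plots the montage positions projected to 2-D (azimuthal, vertex at the
centre), coloured by potential.  Deliberately schematic — no head-shape
interpolation; matplotlib is imported lazily and only needed here.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError
from .group import GlobalTemplateSet
from .montage import ChannelMontage

__all__ = ["plot_templates"]


def _project(positions: np.ndarray) -> np.ndarray:
    # azimuthal equidistant projection of unit-sphere points, vertex at origin
    x, y, z = positions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def plot_templates(templates: GlobalTemplateSet, montage: ChannelMontage, path=None):
    """Save (or return) a figure with one topography panel per template."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if montage.positions is None:
        raise InvalidInputError("montage has no positions; cannot plot topographies")
    if montage.n_channels != templates.templates.shape[1]:
        raise InvalidInputError("montage size does not match template channels")
    pts = _project(montage.positions)
    k = templates.k_global
    fig, axes = plt.subplots(1, k, figsize=(3 * k, 3), squeeze=False)
    vmax = float(np.abs(templates.templates).max())
    for i, ax in enumerate(axes[0]):
        ax.scatter(
            pts[:, 0], pts[:, 1], c=templates.templates[i],
            cmap="RdBu_r", vmin=-vmax, vmax=vmax, s=30,
        )
        ax.set_title(templates.names[i])
        ax.set_aspect("equal")
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
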