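"""Polarity-invariant modified k-means clustering of scalp topographies.

The modified k-means of the microstate literature differs from vanilla
k-means in one key respect: a map and its sign-flipped copy represent the
same topography.  Assignment therefore maximises the *squared* spatial
correlation, and the cluster "mean" is the dominant eigenvector of the sum of
outer products of the assigned maps — the direction that maximises the summed
squared correlation regardless of each member's sign.

Clustering operates on unit-normalised maps (topography shape only); the
global explained variance (GEV) diagnostic re-weights frames by their GFP²,
so high-amplitude frames dominate the variance accounting while the cluster
geometry stays amplitude-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .exceptions import InvalidInputError

__all__ = [
    "ClusteringResult",
    "modified_kmeans",
    "global_explained_variance",
    "within_dispersion",
]


@dataclass
class ClusteringResult:
    """Outcome of one modified k-means fit (best restart).

    Attributes
    ----------
    templates
        ``(k, n_channels)`` unit-norm, zero-mean template maps with a
        canonical sign (largest-magnitude channel positive).
    labels
        Cluster index per input map.
    polarity
        +1/-1 per input map: the sign aligning it to its template.
    gev
        Global explained variance in [0, 1].
    dispersion_w
        Within-cluster dispersion W(k) of the normalised, sign-aligned maps.
    n_iter
        Iterations of the winning restart.
    seed
        Seed that reproduces the fit.
    """

    templates: np.ndarray
    labels: np.ndarray
    polarity: np.ndarray
    gev: float
    dispersion_w: float
    n_iter: int
    seed: int | None = None
    montage_ref: str = ""
    epoch_ref: tuple[str, str] | None = None  # (subject, condition) provenance

    @property
    def k(self) -> int:
        return self.templates.shape[0]


def _as_maps(maps) -> np.ndarray:
    arr = np.asarray(maps, dtype=float)
    if arr.ndim != 2:
        raise InvalidInputError("maps must be a (n_maps, n_channels) array")
    return arr


def _normalize_rows(maps: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(maps, axis=1)
    if np.any(norms == 0):
        raise InvalidInputError("degenerate all-zero map; exclude flat frames before clustering")
    return maps / norms[:, None]


def _canonical_sign(t: np.ndarray) -> np.ndarray:
    """Flip a template so its largest-|value| channel is positive (first on ties).

    Makes template output deterministic and exactly invariant to sign flips of
    the input maps.
    """
    i = int(np.argmax(np.abs(t)))
    return -t if t[i] < 0 else t


def _dominant_pattern(members: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of sum_m v_m v_m^T for unit-norm member rows.

    The polarity-invariant cluster mean.  Computed from the small Gram matrix
    (members x members) when that is cheaper than channels x channels.
    """
    m, c = members.shape
    if m == 1:
        t = members[0].copy()
    elif m <= c:
        gram = members @ members.T
        _, vec = scipy.linalg.eigh(gram, subset_by_index=[m - 1, m - 1])
        t = members.T @ vec[:, 0]
    else:
        s = members.T @ members
        _, vec = scipy.linalg.eigh(s, subset_by_index=[c - 1, c - 1])
        t = vec[:, 0]
    n = np.linalg.norm(t)
    if n == 0.0:  # pathological exact cancellation
        t = members[0].copy()
        n = np.linalg.norm(t)
    return _canonical_sign(t / n)


def _distinct_map_indices(vn: np.ndarray, decimals: int = 10) -> np.ndarray:
    """Indices of maps distinct up to sign (used for initialisation)."""
    canon = np.array([_canonical_sign(v) for v in vn])
    _, idx = np.unique(np.round(canon, decimals), axis=0, return_index=True)
    return np.sort(idx)


def global_explained_variance(maps, weights, templates, labels) -> float:
    """GEV = sum_t GFP_t² r_t² / sum_t GFP_t², with r polarity-ignored.

    ``weights`` are the per-map GFP values (amplitude); ``r_t`` is the spatial
    correlation between map t and its assigned template.
    """
    maps = _as_maps(maps)
    templates = np.asarray(templates, dtype=float)
    labels = np.asarray(labels)
    w = np.asarray(weights, dtype=float)
    if np.all(w == 0):
        raise InvalidInputError("all map weights (GFP) are zero; GEV undefined")
    vn = _normalize_rows(maps)
    tn = _normalize_rows(templates)
    r = np.einsum("ij,ij->i", vn, tn[labels])
    w2 = w**2
    return float(np.sum(w2 * r**2) / np.sum(w2))


def within_dispersion(maps, templates, labels, polarity) -> float:
    """W(k) = sum over clusters and members of ||s_m v̂_m - template||².

    ``v̂_m`` is the unit-normalised member map and ``s_m`` its polarity sign.
    """
    vn = _normalize_rows(_as_maps(maps))
    tn = np.asarray(templates, dtype=float)
    labels = np.asarray(labels)
    s = np.asarray(polarity, dtype=float)
    resid = s[:, None] * vn - tn[labels]
    return float(np.sum(resid**2))


def modified_kmeans(
    maps,
    k: int,
    *,
    weights=None,
    n_restarts: int = 64,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = 0,
    init: np.ndarray | None = None,
    montage_ref: str = "",
    epoch_ref: tuple[str, str] | None = None,
) -> ClusteringResult:
    """Cluster topographies into k polarity-invariant classes; keep the best restart by GEV.

    Per restart: initialise templates as k distinct maps drawn uniformly at
    random; assign each map to the template with the highest squared spatial
    correlation; update each template to the dominant eigenvector of its
    members' outer-product sum; iterate until the assignment is stable or the
    GEV improvement falls below ``tol`` (relative).  An empty cluster is
    re-seeded from the currently worst-fit map.

    Parameters
    ----------
    maps
        ``(n_maps, n_channels)`` zero-mean maps (any amplitude).
    weights
        Per-map GFP used in the GEV weighting; computed from ``maps`` if None.
    init
        Optional ``(k, n_channels)`` template array run as one additional,
        deterministic restart (used to warm-start k from the k-1 solution so
        W(k) stays non-increasing across a model-selection sweep).
    """
    maps = _as_maps(maps)
    n, c = maps.shape
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if n < k:
        raise InvalidInputError(f"need at least k={k} maps, got {n}")
    vn = _normalize_rows(maps)
    if weights is None:
        w = np.sqrt(np.mean(maps**2, axis=1))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise InvalidInputError("weights must have one entry per map")
    w2 = w**2
    w2sum = float(w2.sum())
    if w2sum == 0.0:
        raise InvalidInputError("all map weights are zero")

    distinct = _distinct_map_indices(vn)
    if len(distinct) < k:
        raise InvalidInputError(
            f"k={k} exceeds the number of distinct maps ({len(distinct)})"
        )

    if k == 1:
        n_restarts = 1  # update step is initialisation-independent for k=1

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None

    inits: list[np.ndarray | None] = [None] * n_restarts
    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.shape != (k, c):
            raise InvalidInputError(f"init must have shape ({k}, {c})")
        inits = [_normalize_rows(init)] + inits

    for start in inits:
        if start is None:
            chosen = rng.choice(distinct, size=k, replace=False)
            start = vn[chosen]
        templates = np.array([_canonical_sign(v) for v in start])
        labels = np.full(n, -1, dtype=int)
        prev_gev = -np.inf
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            corr = templates @ vn.T  # (k, n)
            new_labels = np.argmax(corr**2, axis=0)
            # empty-cluster handling: re-seed from the worst-fit map
            fit = np.abs(corr[new_labels, np.arange(n)])
            for cl in range(k):
                if not np.any(new_labels == cl):
                    worst = int(np.argmin(fit))
                    new_labels[worst] = cl
                    fit[worst] = 1.0
            stable = bool(np.array_equal(new_labels, labels))
            labels = new_labels
            for cl in range(k):
                templates[cl] = _dominant_pattern(vn[labels == cl])
            r = np.einsum("ij,ij->i", vn, templates[labels])
            gev = float(np.sum(w2 * r**2) / w2sum)
            if stable:
                break
            if gev - prev_gev < tol * max(abs(gev), 1e-300) and n_iter > 1:
                break
            prev_gev = gev
        # final consistent assignment against the converged templates
        corr = templates @ vn.T
        labels = np.argmax(corr**2, axis=0)
        fit = np.abs(corr[labels, np.arange(n)])
        for cl in range(k):
            if not np.any(labels == cl):
                worst = int(np.argmin(fit))
                labels[worst] = cl
                fit[worst] = 1.0
        r = np.einsum("ij,ij->i", vn, templates[labels])
        gev = float(np.sum(w2 * r**2) / w2sum)
        if best is None or gev > best[0]:
            best = (gev, templates.copy(), labels.copy(), n_iter)

    assert best is not None
    gev, templates, labels, n_iter = best
    signed = np.einsum("ij,ij->i", vn, templates[labels])
    polarity = np.where(signed >= 0, 1, -1)  # ties (r == 0) -> +1
    w_disp = float(np.sum((polarity[:, None] * vn - templates[labels]) ** 2))
    return ClusteringResult(
        templates=templates,
        labels=labels,
        polarity=polarity,
        gev=gev,
        dispersion_w=w_disp,
        n_iter=n_iter,
        seed=seed,
        montage_ref=montage_ref,
        epoch_ref=epoch_ref,
    )
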