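"""Choosing the number of microstates with the Krzanowski-Lai (KL) criterion.

For a contiguous range of candidate cluster counts k with within-cluster
dispersions W(k) in a p-dimensional space (p = number of channels):

    DIFF(k) = (k-1)^(2/p) * W(k-1) - k^(2/p) * W(k)
    KL(k)   = | DIFF(k) / DIFF(k+1) |

KL is defined for 2 <= k <= k_max - 1.  Sharp drops in W produce peaks in
KL; candidate cluster counts are the local maxima of the curve.  The
selection rule is configurable because "the second KL maximum value" admits
two readings: here ``second_max`` ranks the local maxima by KL value and
takes the second largest (falling back, with a flag, to the only one),
``first_max`` takes the first local maximum in ascending k, and
``global_max`` takes the k with the largest KL anywhere on the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .clustering import ClusteringResult, modified_kmeans, _distinct_map_indices, _normalize_rows
from .exceptions import InvalidInputError, ModelSelectionError
from .topography import ErpEpoch, apply_average_reference, gfp, nondegenerate_frames

__all__ = ["KlCurve", "kl_criterion", "select_k_for_erp", "KL_RULES"]

KL_RULES = ("second_max", "first_max", "global_max")


@dataclass
class KlCurve:
    """The KL criterion evaluated over a k range, with the chosen k.

    ``diff`` and ``kl`` are aligned with ``k_range``; entries where the
    quantity is undefined are NaN.  ``maxima`` lists local maxima as
    ``(k, KL(k))`` ordered by descending KL value.  ``flags`` records
    selection anomalies ("no_second_max", "no_clear_structure").
    """

    k_range: tuple[int, ...]
    w: np.ndarray
    diff: np.ndarray
    kl: np.ndarray
    chosen_k: int
    maxima: list[tuple[int, float]]
    rule: str = "second_max"
    flags: list[str] = field(default_factory=list)

    def as_table(self):
        """Delimited-friendly view: one row per k."""
        import pandas as pd

        is_max = {k for k, _ in self.maxima}
        return pd.DataFrame(
            {
                "k": list(self.k_range),
                "W": self.w,
                "DIFF": self.diff,
                "KL": self.kl,
                "is_local_max": [k in is_max for k in self.k_range],
                "chosen": [k == self.chosen_k for k in self.k_range],
            }
        )


def kl_criterion(
    w: Sequence[float],
    p: int,
    k_range: Iterable[int] | None = None,
    rule: str = "second_max",
) -> KlCurve:
    """Build the KL curve from dispersions W(k) and select the cluster count.

    Parameters
    ----------
    w
        Within-cluster dispersion per k, on best-of-restarts solutions, over a
        contiguous k range starting at 1.
    p
        Dimensionality of the clustered space (number of channels).
    k_range
        The k values ``w`` corresponds to; defaults to ``1..len(w)``.
    """
    if rule not in KL_RULES:
        raise InvalidInputError(f"unknown KL rule {rule!r}; choose from {KL_RULES}")
    w = np.asarray(list(w), dtype=float)
    ks = tuple(k_range) if k_range is not None else tuple(range(1, len(w) + 1))
    if len(ks) != len(w):
        raise InvalidInputError("k_range and W lengths differ")
    if list(ks) != list(range(ks[0], ks[0] + len(ks))):
        raise InvalidInputError("k_range must be contiguous")
    if ks[0] != 1:
        raise InvalidInputError("k_range must start at 1 (W(k-1) is needed for DIFF)")
    if len(ks) < 4:
        raise ModelSelectionError(
            "need at least 4 k values to form a second KL maximum; widen k_range"
        )
    if p < 1:
        raise InvalidInputError("dimensionality p must be positive")

    kv = np.asarray(ks, dtype=float)
    diff = np.full(len(ks), np.nan)
    # DIFF(k) needs W(k-1): defined from the second entry on.
    diff[1:] = (kv[1:] - 1) ** (2.0 / p) * w[:-1] - kv[1:] ** (2.0 / p) * w[1:]
    kl = np.full(len(ks), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(diff[1:-1] / diff[2:])
    ratio[diff[2:] == 0.0] = np.nan
    # W(k) is non-increasing for exact best-of-all solutions, so DIFF > 0 in
    # theory; non-positive DIFF flags an under-optimised fit and any KL ratio
    # built on it is meaningless noise -> treat as undefined.
    ratio[(diff[1:-1] <= 0.0) | (diff[2:] <= 0.0)] = np.nan
    kl[1:-1] = ratio

    defined = np.flatnonzero(np.isfinite(kl))
    flags: list[str] = []
    maxima: list[tuple[int, float]] = []
    for i in defined:
        left = kl[i - 1] if i - 1 in defined else -np.inf
        right = kl[i + 1] if i + 1 in defined else -np.inf
        if kl[i] > left and kl[i] > right:
            maxima.append((ks[i], float(kl[i])))
    maxima.sort(key=lambda t: (-t[1], t[0]))

    if len(defined) == 0:
        # e.g. flat W: every DIFF non-positive -> no usable ratios anywhere.
        return KlCurve(
            k_range=ks, w=w, diff=diff, kl=kl, chosen_k=int(ks[1]),
            maxima=[], rule=rule, flags=["no_clear_structure"],
        )

    if rule == "global_max":
        i = defined[int(np.argmax(kl[defined]))]
        chosen = ks[i]
        if not maxima:
            flags.append("no_clear_structure")
    elif rule == "first_max":
        if maxima:
            chosen = min(k for k, _ in maxima)
        else:
            chosen = ks[defined[0]]
            flags.append("no_clear_structure")
    else:  # second_max
        if len(maxima) >= 2:
            chosen = maxima[1][0]
        elif len(maxima) == 1:
            chosen = maxima[0][0]
            flags.append("no_second_max")
        else:
            chosen = ks[defined[0]]
            flags.append("no_clear_structure")

    return KlCurve(
        k_range=ks, w=w, diff=diff, kl=kl, chosen_k=int(chosen),
        maxima=maxima, rule=rule, flags=flags,
    )


def _warm_start(prev: ClusteringResult | None, maps: np.ndarray, k: int) -> np.ndarray | None:
    """Seed k's clustering with the (k-1)-solution plus its worst-fit map.

    One extra deterministic restart per k; since it extends the previous
    best solution, the best-of-restarts dispersion W(k) stays (near-)
    monotonically non-increasing even with modest restart counts, which the
    KL differences assume.
    """
    if prev is None or prev.k + 1 != k or maps.shape[0] < k:
        return None
    vn = maps / np.linalg.norm(maps, axis=1, keepdims=True)
    absr = np.abs(prev.templates @ vn.T).max(axis=0)
    worst = int(np.argmin(absr))
    return np.vstack([prev.templates, vn[worst]])


def _degenerate_curve(ks: tuple[int, ...], w: list[float], chosen: int) -> KlCurve:
    n = len(ks)
    return KlCurve(
        k_range=ks,
        w=np.asarray(w, dtype=float),
        diff=np.full(n, np.nan),
        kl=np.full(n, np.nan),
        chosen_k=chosen,
        maxima=[],
        rule="degenerate",
        flags=["degenerate_k_range"],
    )


def kl_sweep(
    maps: np.ndarray,
    weights: np.ndarray,
    ks: tuple[int, ...],
    *,
    rule: str,
    n_restarts: int,
    max_iter: int,
    tol: float,
    seed: int | None,
    montage_ref: str = "",
    epoch_ref: tuple[str, str] | None = None,
) -> tuple[KlCurve, ClusteringResult]:
    """Run modified k-means over a k range (warm-started) and select k by KL.

    The range is capped at the number of distinct maps (up to sign): with
    near-duplicate inputs — e.g. noiseless synthetic maps — larger k is
    infeasible.  When fewer than 4 feasible k values remain, KL cannot be
    formed; the smallest k reaching (numerically) perfect fit is returned with
    a flagged degenerate curve instead.
    """
    n_distinct = len(_distinct_map_indices(_normalize_rows(maps)))
    ks_eff = tuple(k for k in ks if k <= n_distinct)
    if not ks_eff:
        raise InvalidInputError("no feasible k values for these maps")
    ss = np.random.SeedSequence(seed if seed is not None else None)
    results: dict[int, ClusteringResult] = {}
    w: list[float] = []
    prev: ClusteringResult | None = None
    for k, child in zip(ks_eff, ss.spawn(len(ks_eff))):
        res = modified_kmeans(
            maps,
            k,
            weights=weights,
            n_restarts=n_restarts,
            max_iter=max_iter,
            tol=tol,
            seed=int(child.generate_state(1)[0] % (2**31)),
            init=_warm_start(prev, maps, k),
            montage_ref=montage_ref,
            epoch_ref=epoch_ref,
        )
        results[k] = res
        w.append(res.dispersion_w)
        prev = res
    # Exactly noiseless data reaches a perfect fit at some k; beyond it W is 0,
    # the KL differences vanish and the ratio criterion is uninformative, so
    # the smallest perfectly fitting k is the answer.
    for k in ks_eff:
        if results[k].gev >= 1.0 - 1e-9:
            return _degenerate_curve(ks_eff, w, k), results[k]
    if len(ks_eff) >= 4:
        curve = kl_criterion(w, p=maps.shape[1], k_range=ks_eff, rule=rule)
        return curve, results[curve.chosen_k]
    k = ks_eff[-1]
    return _degenerate_curve(ks_eff, w, k), results[k]


def select_k_for_erp(
    epoch: ErpEpoch,
    k_range: Iterable[int] = range(1, 13),
    *,
    rule: str = "second_max",
    n_restarts: int = 64,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = 0,
) -> tuple[KlCurve, ClusteringResult]:
    """Run modified k-means over a k range on one ERP and pick k by the KL criterion.

    All time frames of the (average-referenced) epoch enter the clustering;
    flat frames are excluded.  Returns the KL curve and the clustering at the
    chosen k.  Results for every k are cached internally so the chosen
    solution is the very fit that produced its W(k).
    """
    ks = tuple(k_range)
    epoch = apply_average_reference(epoch)
    keep = nondegenerate_frames(epoch.data)
    maps = epoch.data.T[keep]
    n = maps.shape[0]
    if n < 2:
        raise InvalidInputError("epoch has fewer than 2 usable frames")
    if max(ks) > n:
        raise InvalidInputError(
            f"k_range up to {max(ks)} exceeds the {n} usable frames of this epoch"
        )
    weights = gfp(epoch.data, check_reference=False)[keep]
    return kl_sweep(
        maps,
        weights,
        ks,
        rule=rule,
        n_restarts=n_restarts,
        max_iter=max_iter,
        tol=tol,
        seed=seed,
        montage_ref=epoch.montage_ref,
        epoch_ref=(epoch.subject, epoch.condition),
    )
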