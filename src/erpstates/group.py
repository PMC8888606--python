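"""Second-level (group) clustering: pooling subject-wise templates into global microstate maps."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import scipy.optimize

from .clustering import ClusteringResult, _normalize_rows
from .exceptions import InvalidInputError, MontageMismatchError
from .model_selection import KlCurve, kl_sweep

__all__ = [
    "GlobalTemplateSet",
    "pool_subject_templates",
    "cluster_group",
    "match_templates",
    "TemplateMatch",
]


@dataclass
class GlobalTemplateSet:
    """k_global unit-norm, zero-mean global template maps (the cohort-level microstates).

    ``names`` hold the display labels (``M1``..``Mk``) after canonical
    ordering; ``provenance_n`` counts the subject-level maps pooled into the
    second-level clustering.
    """

    templates: np.ndarray
    montage_ref: str = ""
    provenance_n: int = 0
    names: tuple[str, ...] = ()
    kl_curve: KlCurve | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.templates, dtype=float)
        if t.ndim != 2 or t.shape[0] < 1:
            raise InvalidInputError("templates must be a (k, n_channels) array with k >= 1")
        self.templates = t
        if not self.names:
            self.names = tuple(f"M{i + 1}" for i in range(t.shape[0]))

    @property
    def k_global(self) -> int:
        return self.templates.shape[0]

    def reordered(self, order: Sequence[int]) -> "GlobalTemplateSet":
        """New set with templates permuted into ``order`` and names reset to M1..Mk."""
        order = list(order)
        if sorted(order) != list(range(self.k_global)):
            raise InvalidInputError("order must be a permutation of 0..k-1")
        return replace(
            self,
            templates=self.templates[order],
            names=tuple(f"M{i + 1}" for i in range(self.k_global)),
        )


def pool_subject_templates(
    results: Iterable[ClusteringResult],
) -> tuple[np.ndarray, list[tuple[str, str, int]]]:
    """Concatenate all subject-level template maps, unit-normalised, with provenance.

    Returns the pooled ``(n_pooled, n_channels)`` array and a provenance list
    of ``(subject, condition, template_index)`` triples.  All results must
    share one montage.
    """
    results = list(results)
    if not results:
        raise InvalidInputError("no subject-level clustering results to pool")
    refs = {r.montage_ref for r in results if r.montage_ref}
    if len(refs) > 1:
        raise MontageMismatchError(f"pooled results span multiple montages: {sorted(refs)}")
    blocks, provenance = [], []
    for r in results:
        blocks.append(_normalize_rows(r.templates))
        subj, cond = r.epoch_ref if r.epoch_ref else ("", "")
        provenance.extend((subj, cond, i) for i in range(r.k))
    return np.vstack(blocks), provenance


def cluster_group(
    pooled: np.ndarray,
    k_range: Iterable[int] = range(1, 13),
    *,
    rule: str = "second_max",
    n_restarts: int = 64,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = 0,
    montage_ref: str = "",
    gev_weighted: bool = False,
    gev_weights=None,
) -> GlobalTemplateSet:
    """Second k-means over the pooled subject maps; k_global chosen by the KL rule.

    Subject-level templates enter unweighted by default (one map, one vote);
    set ``gev_weighted`` with per-map weights to weight the GEV accounting
    instead.
    """
    pooled = np.asarray(pooled, dtype=float)
    if pooled.ndim != 2 or pooled.shape[0] < 1:
        raise InvalidInputError("pooled maps must be a nonempty (n, n_channels) array")
    ks = tuple(k_range)
    n = pooled.shape[0]
    if max(ks) > n:
        raise InvalidInputError(f"k_range up to {max(ks)} exceeds {n} pooled maps")
    if gev_weighted and gev_weights is not None:
        weights = np.asarray(gev_weights, dtype=float)
    else:
        weights = np.ones(n)
    curve, chosen = kl_sweep(
        pooled,
        weights,
        ks,
        rule=rule,
        n_restarts=n_restarts,
        max_iter=max_iter,
        tol=tol,
        seed=seed,
        montage_ref=montage_ref,
    )
    return GlobalTemplateSet(
        templates=chosen.templates,
        montage_ref=montage_ref,
        provenance_n=n,
        kl_curve=curve,
        seed=seed,
    )


@dataclass
class TemplateMatch:
    """Optimal one-to-one assignment between two template sets.

    ``pairs`` maps recovered index -> reference index with the matched |r|;
    ``unmatched_recovered``/``unmatched_reference`` list leftover indices when
    the two sets have different k.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_recovered: list[int] = field(default_factory=list)
    unmatched_reference: list[int] = field(default_factory=list)

    @property
    def mean_abs_r(self) -> float:
        return float(np.mean([r for _, _, r in self.pairs]))

    @property
    def min_abs_r(self) -> float:
        return float(np.min([r for _, _, r in self.pairs]))


def match_templates(
    recovered: GlobalTemplateSet | np.ndarray,
    reference: GlobalTemplateSet | np.ndarray,
) -> TemplateMatch:
    """Match recovered to reference templates maximising total |spatial correlation|.

    Polarity-blind by construction.  With unequal template counts a partial
    assignment is returned with the unmatched indices made explicit.
    """
    a = recovered.templates if isinstance(recovered, GlobalTemplateSet) else np.asarray(recovered, float)
    b = reference.templates if isinstance(reference, GlobalTemplateSet) else np.asarray(reference, float)
    if (
        isinstance(recovered, GlobalTemplateSet)
        and isinstance(reference, GlobalTemplateSet)
        and recovered.montage_ref
        and reference.montage_ref
        and recovered.montage_ref != reference.montage_ref
    ):
        raise MontageMismatchError("template sets index different montages")
    if a.shape[1] != b.shape[1]:
        raise MontageMismatchError("template sets have different channel counts")
    an, bn = _normalize_rows(a), _normalize_rows(b)
    absr = np.abs(an @ bn.T)
    rows, cols = scipy.optimize.linear_sum_assignment(-absr)
    pairs = [(int(i), int(j), float(absr[i, j])) for i, j in zip(rows, cols)]
    return TemplateMatch(
        pairs=pairs,
        unmatched_recovered=[i for i in range(a.shape[0]) if i not in set(rows)],
        unmatched_reference=[j for j in range(b.shape[0]) if j not in set(cols)],
    )
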