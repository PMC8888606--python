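"""Group-level inference on the metrics table.

Classical univariate repeated-measures ANOVA (subject as random blocking
factor, uncorrected degrees of freedom), Duncan's multiple range test for
post-hoc pairwise comparisons, and Pearson correlations between per-subject
metric means and handedness scores.  A declarative analysis battery replays
the full condition-design structure: omnibus microstate ANOVAs per metric,
per-microstate Emotion x Side and bilateral-condition ANOVAs, the two
five-level valence families, and the handedness correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .design import (
    BILATERAL,
    EMOTION_OF,
    SIDE_OF,
    UNILATERAL,
    VALENCE_FAMILIES,
)
from .exceptions import IncompleteDesignError, InvalidInputError, UndefinedCorrelationError

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "rm_anova",
    "rm_anova_matrix",
    "rm_anova_matrix_2way",
    "duncan_posthoc",
    "metric_handedness_correlation",
    "run_battery",
    "METRICS",
]

METRICS = ("duration_ms", "occurrence_hz", "coverage_pct")

ALPHA = 0.05  # significance threshold


@dataclass
class AnovaResult:
    """One effect of a repeated-measures ANOVA, in the usual reporting format."""

    effect: str
    df_effect: int
    df_error: int
    F: float
    mse: float
    p: float
    partial_eta_sq: float

    def __str__(self) -> str:
        return (
            f"{self.effect}: F({self.df_effect},{self.df_error}) = {self.F:.2f}, "
            f"MSE = {self.mse:.2f}, p = {self.p:.4g}, eta_p^2 = {self.partial_eta_sq:.2f}"
        )


@dataclass
class PosthocResult:
    """One pairwise comparison of Duncan's multiple range test."""

    pair: tuple[str, str]
    mean_difference: float
    p: float
    significant: bool


def rm_anova_matrix(y: np.ndarray) -> AnovaResult:
    """One-way within-subject ANOVA on a (n_subjects, n_levels) matrix.

    Classical decomposition: SS_total = SS_subjects + SS_treatment + SS_error,
    F = MS_treatment / MS_error with df (a-1, (a-1)(n-1)).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise InvalidInputError("need a (n_subjects >= 2, n_levels >= 2) matrix")
    if np.any(~np.isfinite(y)):
        raise IncompleteDesignError("matrix contains missing values")
    n, a = y.shape
    grand = y.mean()
    ss_subj = a * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_a = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_subj - ss_a
    df_a, df_err = a - 1, (a - 1) * (n - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f = 0.0 if ss_a <= 0 else np.inf
    else:
        f = (ss_a / df_a) / ms_err
    p = float(scipy.stats.f.sf(f, df_a, df_err)) if np.isfinite(f) else 0.0
    denom = ss_a + ss_err
    eta = float(ss_a / denom) if denom > 0 else 0.0
    return AnovaResult("condition", df_a, df_err, float(f), float(ms_err), p, eta)


def rm_anova_matrix_2way(y: np.ndarray, names: tuple[str, str] = ("A", "B")) -> list[AnovaResult]:
    """Two-way fully within-subject ANOVA on a (n_subjects, a, b) array.

    Each effect is tested against its own interaction-with-subjects error term
    (A x S, B x S, A x B x S).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise InvalidInputError("need a (n_subjects, a, b) array")
    if np.any(~np.isfinite(y)):
        raise IncompleteDesignError("array contains missing values")
    n, a, b = y.shape
    if n < 2 or a < 2 or b < 2:
        raise InvalidInputError("each dimension must have at least 2 levels")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    out = []
    for effect, ss_eff, df_eff, ss_err, df_err in [
        (names[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (names[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (f"{names[0]} x {names[1]}", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ]:
        ms_err = ss_err / df_err
        if ms_err <= 0:
            f = 0.0 if ss_eff <= 0 else np.inf
        else:
            f = (ss_eff / df_eff) / ms_err
        p = float(scipy.stats.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
        denom = ss_eff + ss_err
        eta = float(ss_eff / denom) if denom > 0 else 0.0
        out.append(AnovaResult(effect, df_eff, df_err, float(f), float(ms_err), p, eta))
    return out


def _pivot_complete(
    table: pd.DataFrame, dv: str, factors: Sequence[str], subject: str
) -> tuple[np.ndarray, list]:
    """Pivot a long table to subject x cells and verify the design is complete."""
    for col in (dv, subject, *factors):
        if col not in table.columns:
            raise InvalidInputError(f"table lacks a {col!r} column")
    grouped = table.groupby([subject, *factors], sort=True, observed=True)[dv]
    counts = grouped.size()
    if (counts > 1).any():
        raise IncompleteDesignError(
            f"more than one value per subject/cell: {counts[counts > 1].index.tolist()[:3]}"
        )
    cells = grouped.mean().unstack(list(range(1, len(factors) + 1)))
    missing = cells.isna()
    if missing.to_numpy().any():
        where = [
            (subj, col)
            for subj in cells.index
            for col in cells.columns[missing.loc[subj]]
        ]
        raise IncompleteDesignError(f"incomplete design; missing cells: {where[:5]}")
    return cells.to_numpy(), list(cells.columns)


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "subject",
) -> list[AnovaResult]:
    """Repeated-measures ANOVA on a long-format metrics table.

    ``within`` names one or two within-subject factor columns; every subject
    must contribute exactly one value per cell.
    """
    within = list(within)
    if len(within) == 1:
        y, _ = _pivot_complete(table, dv, within, subject)
        res = rm_anova_matrix(y)
        res.effect = within[0]
        return [res]
    if len(within) == 2:
        y2, cols = _pivot_complete(table, dv, within, subject)
        a_levels = sorted({c[0] for c in cols})
        b_levels = sorted({c[1] for c in cols})
        y = np.empty((y2.shape[0], len(a_levels), len(b_levels)))
        for j, (la, lb) in enumerate(cols):
            y[:, a_levels.index(la), b_levels.index(lb)] = y2[:, j]
        return rm_anova_matrix_2way(y, names=(within[0], within[1]))
    raise InvalidInputError("rm_anova supports 1 or 2 within-subject factors")


def duncan_posthoc(
    table: pd.DataFrame,
    dv: str,
    factor: str,
    subject: str = "subject",
    alpha: float = ALPHA,
) -> list[PosthocResult]:
    """Duncan's multiple range test over the levels of one within-subject factor.

    Means are ranked; a pair spanning r ranked means is compared against the
    studentized-range critical value at the protection level
    ``1 - (1 - alpha)**(r - 1)`` with the one-way ANOVA error term.  The
    step-down rule applies: a span declared non-significant blocks all spans
    nested inside it.
    """
    y, levels = _pivot_complete(table, dv, [factor], subject)
    n, a = y.shape
    if a < 2:
        raise InvalidInputError("factor needs at least 2 levels")
    omnibus = rm_anova_matrix(y)
    ms_err, df_err = omnibus.mse, omnibus.df_error
    means = y.mean(axis=0)
    order = np.argsort(means)
    se = np.sqrt(ms_err / n)

    blocked = np.zeros((a, a), dtype=bool)
    results: dict[tuple[int, int], PosthocResult] = {}
    for span in range(a, 1, -1):
        for i0 in range(0, a - span + 1):
            j0 = i0 + span - 1
            li, lj = order[i0], order[j0]
            diff = float(means[lj] - means[li])
            if se > 0:
                q_obs = abs(diff) / se
                p_range = float(scipy.stats.studentized_range.sf(q_obs, span, df_err))
                p_adj = float(1.0 - (1.0 - p_range) ** (1.0 / (span - 1)))
            else:
                p_adj = 1.0 if diff == 0 else 0.0
            sig = (p_adj <= alpha) and not blocked[i0, j0]
            if not sig:
                # block all nested spans
                for ii in range(i0, j0 + 1):
                    for jj in range(ii, j0 + 1):
                        blocked[ii, jj] = True
            pair = (str(levels[li]), str(levels[lj]))
            results[(i0, j0)] = PosthocResult(pair, diff, p_adj, sig)
    # report in level order
    out = []
    for i in range(a):
        for j in range(i + 1, a):
            # locate span positions of levels i, j in the ranked order
            pi, pj = sorted((int(np.where(order == i)[0][0]), int(np.where(order == j)[0][0])))
            res = results[(pi, pj)]
            out.append(
                PosthocResult((str(levels[i]), str(levels[j])), float(means[j] - means[i]), res.p, res.significant)
            )
    return out


def metric_handedness_correlation(
    table: pd.DataFrame,
    scores: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Pearson r between per-subject mean metrics and handedness scores.

    ``scores`` maps subject id to an Edinburgh-style laterality score in
    [-100, 100].  Returns one row per (class, metric) with r and two-sided p.
    """
    scores = pd.Series(scores)
    rows = []
    for cls, sub in table.groupby("class", sort=True):
        per_subject = sub.groupby("subject")[list(METRICS)].mean()
        common = per_subject.index.intersection(scores.index)
        if len(common) < 3:
            raise InvalidInputError("need scores for at least 3 subjects")
        s = scores.loc[common].to_numpy(dtype=float)
        for metric in METRICS:
            m = per_subject.loc[common, metric].to_numpy(dtype=float)
            if np.any(~np.isfinite(m)):
                rows.append({"class": cls, "metric": metric, "r": np.nan, "p": np.nan})
                continue
            if np.std(s) == 0 or np.std(m) == 0:
                raise UndefinedCorrelationError(
                    f"zero variance in {'scores' if np.std(s) == 0 else metric}; correlation undefined"
                )
            r, p = scipy.stats.pearsonr(s, m)
            rows.append({"class": cls, "metric": metric, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def _anova_rows(results: list[AnovaResult], **extra) -> list[dict]:
    return [
        {
            **extra,
            "effect": r.effect,
            "df_effect": r.df_effect,
            "df_error": r.df_error,
            "F": r.F,
            "MSE": r.mse,
            "p": r.p,
            "partial_eta_sq": r.partial_eta_sq,
        }
        for r in results
    ]


def run_battery(
    table: pd.DataFrame,
    handedness: Mapping[str, float] | pd.Series | None = None,
    alpha: float = ALPHA,
) -> dict[str, pd.DataFrame]:
    """Replay the full condition-design analysis battery on a metrics table.

    Returns a dict of result tables:

    * ``omnibus`` — per metric, one-way Microstate ANOVA plus Duncan pairs;
    * ``unilateral`` — per microstate and metric, Emotion x Side ANOVA;
    * ``bilateral`` — per microstate and metric, 4-level Condition ANOVA;
    * ``valence`` — per microstate, metric and family, 5-level ANOVA;
    * ``posthoc`` — Duncan comparisons for the omnibus microstate effects;
    * ``correlations`` — handedness correlations (when scores given);
    * ``skipped`` — analyses skipped for incomplete cells.

    Analyses whose cells are incomplete (a class absent for some subject and
    condition, e.g. NaN durations) are skipped and listed rather than failing
    the whole battery.
    """
    anova_rows: list[dict] = []
    posthoc_rows: list[dict] = []
    skipped: list[dict] = []

    def try_run(tag: str, fn):
        try:
            fn()
        except IncompleteDesignError as exc:
            skipped.append({"analysis": tag, "reason": str(exc)})

    # 1. Omnibus per metric: Microstate (4 levels) within factor, collapsing conditions.
    per_subject_class = (
        table.groupby(["subject", "class"], observed=True)[list(METRICS)].mean().reset_index()
    )
    for metric in METRICS:
        def _omni(metric=metric):
            res = rm_anova(per_subject_class, metric, within=["class"])
            anova_rows.extend(_anova_rows(res, analysis="omnibus", metric=metric, **{"class": "all"}))
            for ph in duncan_posthoc(per_subject_class, metric, "class", alpha=alpha):
                posthoc_rows.append(
                    {
                        "analysis": "omnibus",
                        "metric": metric,
                        "pair": " vs ".join(ph.pair),
                        "mean_difference": ph.mean_difference,
                        "p": ph.p,
                        "significant": ph.significant,
                    }
                )
        try_run(f"omnibus/{metric}", _omni)

    # 2. Per microstate: unilateral Emotion x Side ANOVA and bilateral Condition ANOVA.
    for cls, sub in table.groupby("class", sort=True, observed=True):
        uni = sub[sub["condition"].isin(UNILATERAL)].copy()
        uni["emotion"] = uni["condition"].map(EMOTION_OF)
        uni["side"] = uni["condition"].map(SIDE_OF)
        bil = sub[sub["condition"].isin(BILATERAL)]
        for metric in METRICS:
            def _uni(cls=cls, uni=uni, metric=metric):
                res = rm_anova(uni, metric, within=["emotion", "side"])
                anova_rows.extend(_anova_rows(res, analysis="unilateral", metric=metric, **{"class": cls}))
            def _bil(cls=cls, bil=bil, metric=metric):
                res = rm_anova(bil, metric, within=["condition"])
                anova_rows.extend(_anova_rows(res, analysis="bilateral", metric=metric, **{"class": cls}))
            try_run(f"unilateral/{cls}/{metric}", _uni)
            try_run(f"bilateral/{cls}/{metric}", _bil)

        # 3. Valence families: 5-level one-way ANOVAs, each family independently.
        for family, conds in VALENCE_FAMILIES.items():
            fam = sub[sub["condition"].isin(conds)]
            for metric in METRICS:
                def _val(cls=cls, fam=fam, metric=metric, family=family):
                    res = rm_anova(fam, metric, within=["condition"])
                    anova_rows.extend(
                        _anova_rows(res, analysis=f"valence_{family}", metric=metric, **{"class": cls})
                    )
                try_run(f"valence_{family}/{cls}/{metric}", _val)

    out = {
        "anovas": pd.DataFrame(anova_rows),
        "posthoc": pd.DataFrame(posthoc_rows),
        "skipped": pd.DataFrame(skipped),
    }
    if handedness is not None:
        out["correlations"] = metric_handedness_correlation(table, handedness)
    return out
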