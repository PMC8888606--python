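"""Repeated-measures ANOVA, Duncan post-hocs, handedness correlations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from erpstates import (
    duncan_posthoc,
    metric_handedness_correlation,
    rm_anova,
    run_battery,
)
from erpstates.simulate import simulate_condition_matrix
from erpstates.stats import rm_anova_matrix, rm_anova_matrix_2way
from erpstates.exceptions import (
    IncompleteDesignError,
    InvalidInputError,
    UndefinedCorrelationError,
)

# Fixed 4-subject x 3-condition toy table; expected values frozen from an
# independent sums-of-squares computation (cross-checked against statsmodels
# AnovaRM and pingouin rm_anova).
TOY = np.array(
    [[10.0, 12.0, 15.0], [11.0, 14.0, 16.0], [9.0, 11.0, 13.0], [12.0, 13.0, 18.0]]
)
TOY_F = 45.6
TOY_MSE = 0.5555555555555536
TOY_P = 0.00023520955289486268
TOY_ETA = 0.9382716049382718


def long_table(y, subject_prefix="s", factor="condition", dv="duration_ms"):
    n, a = y.shape
    rows = [
        {"subject": f"{subject_prefix}{i}", factor: f"c{j}", dv: y[i, j]}
        for i in range(n)
        for j in range(a)
    ]
    return pd.DataFrame(rows)


class TestRmAnovaOneWay:
    def test_matches_frozen_ss_oracle(self):
        res = rm_anova_matrix(TOY)
        assert res.F == pytest.approx(TOY_F, rel=1e-10)
        assert res.mse == pytest.approx(TOY_MSE, rel=1e-9)
        assert res.p == pytest.approx(TOY_P, rel=1e-9)
        assert res.partial_eta_sq == pytest.approx(TOY_ETA, rel=1e-10)
        assert (res.df_effect, res.df_error) == (2, 6)

    def test_no_effect_when_cells_identical_within_subject(self):
        y = np.tile([[5.0], [7.0], [6.0]], (1, 4))
        res = rm_anova_matrix(y)
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert res.p == pytest.approx(1.0)

    def test_long_format_wrapper_and_order_invariance(self, rng):
        y = rng.normal(10, 2, size=(6, 4))
        table = long_table(y)
        base = rm_anova(table, "duration_ms", within=["condition"])[0]
        shuffled = table.sample(frac=1, random_state=0)
        again = rm_anova(shuffled, "duration_ms", within=["condition"])[0]
        assert again.F == pytest.approx(base.F, rel=1e-12)
        assert again.p == pytest.approx(base.p, rel=1e-12)

    def test_missing_cell_names_offender(self):
        table = long_table(TOY).drop(index=5)
        with pytest.raises(IncompleteDesignError):
            rm_anova(table, "duration_ms", within=["condition"])

    def test_agrees_with_statsmodels_on_random_tables(self, rng):
        from statsmodels.stats.anova import AnovaRM

        for _ in range(3):
            y = rng.normal(0, 1, size=(7, 5)) + rng.normal(0, 1, size=5)
            table = long_table(y)
            ours = rm_anova_matrix(y)
            ref = AnovaRM(table, "duration_ms", "subject", within=["condition"]).fit()
            assert ours.F == pytest.approx(float(ref.anova_table["F Value"].iloc[0]), rel=1e-9)
            assert ours.p == pytest.approx(float(ref.anova_table["Pr > F"].iloc[0]), abs=1e-12)


class TestRmAnovaTwoWay:
    def test_matches_statsmodels_frozen_values(self):
        # 5 x 2 x 3 design, rng seed 42; F/p frozen from statsmodels AnovaRM
        rng = np.random.default_rng(42)
        y = rng.normal(0, 1, (5, 2, 3)) + np.array([[0.0, 1.0, 2.0], [1.0, 3.0, 0.0]])[None]
        res = {r.effect: r for r in rm_anova_matrix_2way(y, names=("a", "b"))}
        assert res["a"].F == pytest.approx(0.154887, abs=1e-5)
        assert res["a"].p == pytest.approx(0.713985, abs=1e-5)
        assert (res["a"].df_effect, res["a"].df_error) == (1, 4)
        assert res["b"].F == pytest.approx(6.444149, abs=1e-5)
        assert res["b"].p == pytest.approx(0.021515, abs=1e-5)
        assert res["a x b"].F == pytest.approx(27.120260, abs=1e-4)
        assert res["a x b"].p == pytest.approx(0.000273, abs=1e-5)

    def test_planted_side_effect_power(self):
        # 5 ms LVF-vs-RVF shift, sigma_within 3 ms, n = 16: detected nearly always
        hits = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            y = simulate_condition_matrix(
                16, effects=[5.0, 0.0], sigma_within=3.0, sigma_subject=5.0, rng=rng
            )
            hits += rm_anova_matrix(y).p < 0.05
        assert hits / n_sims >= 0.9

    def test_null_calibration_quick(self):
        rejections = 0
        n_sims = 400
        for seed in range(n_sims):
            rng = np.random.default_rng(10_000 + seed)
            y = simulate_condition_matrix(
                16, effects=[0.0] * 4, sigma_within=3.0, sigma_subject=5.0, rng=rng
            )
            rejections += rm_anova_matrix(y).p < 0.05
        assert 0.02 <= rejections / n_sims <= 0.08


class TestDuncan:
    def test_two_levels_reduce_to_rank2_studentized_range(self, rng):
        y = rng.normal(0, 1, size=(8, 2)) + np.array([0.0, 1.0])
        table = long_table(y)
        res = duncan_posthoc(table, "duration_ms", "condition")
        assert len(res) == 1
        omnibus = rm_anova_matrix(y)
        q_obs = abs(y.mean(0)[1] - y.mean(0)[0]) / np.sqrt(omnibus.mse / 8)
        p_expected = float(scipy.stats.studentized_range.sf(q_obs, 2, omnibus.df_error))
        assert res[0].p == pytest.approx(p_expected, rel=1e-9)
        assert res[0].significant == (p_expected <= 0.05)

    def test_identical_means_nothing_significant(self):
        y = np.tile(np.arange(6, dtype=float)[:, None], (1, 4))
        res = duncan_posthoc(long_table(y), "duration_ms", "condition")
        assert not any(r.significant for r in res)

    def test_well_separated_means_all_significant(self, rng):
        y = rng.normal(0, 0.05, size=(10, 4)) + np.array([0.0, 5.0, 10.0, 15.0])
        res = duncan_posthoc(long_table(y), "duration_ms", "condition")
        assert len(res) == 6
        assert all(r.significant for r in res)

    def test_level_permutation_invariance(self, rng):
        y = rng.normal(0, 1, size=(8, 3)) + np.array([0.0, 1.5, 3.0])
        table = long_table(y)
        res_a = {frozenset(r.pair): (r.p, r.significant) for r in duncan_posthoc(table, "duration_ms", "condition")}
        relabel = {"c0": "c2", "c1": "c0", "c2": "c1"}
        table_b = table.assign(condition=table["condition"].map(relabel))
        res_b = {
            frozenset(r.pair): (r.p, r.significant)
            for r in duncan_posthoc(table_b, "duration_ms", "condition")
        }
        for key, (p, sig) in res_a.items():
            key_b = frozenset(relabel[p_] for p_ in key)
            assert res_b[key_b][0] == pytest.approx(p, rel=1e-9)
            assert res_b[key_b][1] == sig

    def test_single_level_rejected(self):
        y = np.ones((4, 1))
        with pytest.raises(InvalidInputError):
            duncan_posthoc(long_table(y), "duration_ms", "condition")


class TestHandednessCorrelation:
    def metrics_table(self, values_by_subject, cls="M1"):
        rows = []
        for subj, v in values_by_subject.items():
            rows.append(
                {
                    "subject": subj,
                    "condition": "AN-LVF",
                    "class": cls,
                    "duration_ms": v,
                    "occurrence_hz": 2.0 + 0.01 * v,
                    "coverage_pct": 25.0 + 0.05 * v,
                }
            )
        return pd.DataFrame(rows)

    def test_perfect_linear_relation(self):
        scores = {f"S{i}": float(10 * i) for i in range(8)}
        table = self.metrics_table({s: 50.0 + 0.3 * v for s, v in scores.items()})
        res = metric_handedness_correlation(table, scores)
        r_dur = res[(res["class"] == "M1") & (res.metric == "duration_ms")]["r"].item()
        assert r_dur == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        scores = {f"S{i}": 50.0 for i in range(6)}
        table = self.metrics_table({s: float(i) for i, s in enumerate(scores)})
        with pytest.raises(UndefinedCorrelationError):
            metric_handedness_correlation(table, scores)

    def test_unrelated_scores_give_small_r(self, rng):
        n = 100
        scores = {f"S{i}": float(rng.normal()) for i in range(n)}
        table = self.metrics_table({s: float(rng.normal()) for s in scores})
        res = metric_handedness_correlation(table, scores)
        assert abs(res[res.metric == "duration_ms"]["r"].item()) < 0.25


class TestBattery:
    def test_full_battery_structure(self, rng):
        from erpstates.design import CONDITIONS

        rows = []
        for s in range(6):
            for cond in CONDITIONS:
                for cls in ("M1", "M2", "M3", "M4"):
                    rows.append(
                        {
                            "subject": f"S{s:02d}",
                            "condition": cond,
                            "class": cls,
                            "duration_ms": rng.normal(100, 10),
                            "occurrence_hz": rng.normal(2.5, 0.3),
                            "coverage_pct": rng.normal(25, 3),
                        }
                    )
        table = pd.DataFrame(rows)
        scores = {f"S{s:02d}": float(rng.normal(78, 9)) for s in range(6)}
        out = run_battery(table, scores)
        anovas = out["anovas"]
        assert {"omnibus", "unilateral", "bilateral", "valence_negative", "valence_positive"} <= set(
            anovas["analysis"].unique()
        )
        # unilateral analyses decompose into emotion, side, interaction per class x metric
        uni = anovas[anovas.analysis == "unilateral"]
        assert len(uni) == 4 * 3 * 3
        assert len(out["correlations"]) == 4 * 3
        assert out["skipped"].empty
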