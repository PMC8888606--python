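"""Synthetic cohort generator: determinism, planted structure, SNR control."""

import numpy as np
import pytest

from erpstates import (
    SyntheticSpec,
    backfit,
    lateralized_effects_spec,
    make_cohort,
    make_sequence,
    make_templates,
    render_epoch,
    synthetic_scalp_montage,
)
from erpstates.backfit import run_lengths
from erpstates.design import LVF_CONDITIONS, RVF_CONDITIONS
from erpstates.exceptions import InvalidInputError
from erpstates.topography import gfp

SMALL = dict(n_channels=32, n_subjects=2, conditions=("AN-LVF", "AN-RVF"))


class TestTemplates:
    def test_zero_corr_bound_gives_orthogonal_pair(self):
        spec = SyntheticSpec(n_channels=16, k_true=2, template_corr_bound=0.0, seed=0)
        t = make_templates(spec)
        assert abs(float(t[0] @ t[1])) < 1e-10
        assert np.allclose(np.linalg.norm(t, axis=1), 1.0)
        assert np.allclose(t.mean(axis=1), 0.0, atol=1e-12)

    def test_default_bound_respected_at_scale(self):
        spec = SyntheticSpec(seed=1)
        t = make_templates(spec)
        corr = np.abs(t @ t.T)
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= spec.template_corr_bound + 1e-12

    def test_rank_limit_rejected(self):
        with pytest.raises(InvalidInputError):
            make_templates(SyntheticSpec(n_channels=4, k_true=4, seed=0))


class TestSequences:
    def test_single_class_occupancy(self):
        spec = SyntheticSpec(
            n_channels=16, k_true=4, seed=0,
            inclusion_overrides={"AN-LVF": {1: 0.0, 2: 0.0, 3: 0.0}},
        )
        rng = np.random.default_rng(0)
        seq = make_sequence(spec, "AN-LVF", rng)
        assert set(seq.tolist()) == {0}

    def test_mean_run_length_near_planted(self):
        spec = SyntheticSpec(n_channels=16, seed=0)
        rng = np.random.default_rng(1)
        runs = []
        for _ in range(300):
            seq = make_sequence(spec, "AN-AN", rng)
            # drop the edge-truncated final run
            rl = run_lengths(seq)
            runs.extend(l for _, l, _ in rl[:-1])
        mean_ms = np.mean(runs) * 1000.0 / spec.sfreq
        assert abs(mean_ms - spec.duration_mean_ms) / spec.duration_mean_ms < 0.1

    def test_all_planted_classes_visited(self):
        spec = SyntheticSpec(n_channels=16, seed=0)
        rng = np.random.default_rng(2)
        for _ in range(20):
            seq = make_sequence(spec, "HA-HA", rng)
            assert set(seq.tolist()) == {0, 1, 2, 3}

    def test_no_immediate_self_transition(self):
        spec = SyntheticSpec(n_channels=16, seed=0)
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = make_sequence(spec, "AN-HA", rng)
            runs = run_lengths(seq)
            for (_, _, a), (_, _, b) in zip(runs, runs[1:]):
                assert a != b


class TestRenderEpoch:
    def test_noise_off_backfit_recovers_planted_sequence(self):
        spec = SyntheticSpec(n_channels=24, snr_db=None, seed=4)
        montage = synthetic_scalp_montage(24)
        t = make_templates(spec, montage=montage)
        rng = np.random.default_rng(5)
        seq = make_sequence(spec, "AN-LVF", rng)
        epoch = render_epoch(t, seq, spec, rng, montage=montage)
        recovered = backfit(epoch, t)
        assert np.array_equal(recovered.labels, seq)

    def test_realized_snr_matches_request(self):
        spec = SyntheticSpec(n_channels=64, snr_db=5.0, seed=6)
        montage = synthetic_scalp_montage(64)
        t = make_templates(spec, montage=montage)
        rng = np.random.default_rng(7)
        seq = make_sequence(spec, "HA-LVF", rng)
        noiseless = render_epoch(t, seq, SyntheticSpec(**{**spec.__dict__, "snr_db": None}), np.random.default_rng(7), montage=montage)
        noisy = render_epoch(t, seq, spec, np.random.default_rng(7), montage=montage)
        p_sig = float(np.mean(gfp(noiseless.data, check_reference=False) ** 2))
        p_noise = float(np.mean(gfp(noisy.data - noiseless.data, check_reference=False) ** 2))
        realized_db = 10 * np.log10(p_sig / p_noise)
        assert abs(realized_db - 5.0) <= 0.5

    def test_epoch_is_average_referenced(self):
        spec = SyntheticSpec(n_channels=32, seed=8)
        cohort = make_cohort(SyntheticSpec(**{**SMALL, "seed": 8}))
        for e in cohort.epochs[:3]:
            assert np.all(np.abs(e.data.mean(axis=0)) < 1e-10)


class TestCohort:
    def test_default_shape(self):
        cohort = make_cohort(SyntheticSpec(**SMALL, seed=0))
        assert len(cohort.epochs) == 2 * 2
        assert cohort.epochs[0].data.shape == (32, 100)
        assert len(cohort.ground_truth.sequences) == 4
        assert set(cohort.ground_truth.handedness) == {"S01", "S02"}

    def test_byte_identical_under_same_seed(self):
        a = make_cohort(SyntheticSpec(**SMALL, seed=42))
        b = make_cohort(SyntheticSpec(**SMALL, seed=42))
        for ea, eb in zip(a.epochs, b.epochs):
            assert np.array_equal(ea.data, eb.data)
        assert a.ground_truth.handedness == b.ground_truth.handedness

    def test_different_seed_differs(self):
        a = make_cohort(SyntheticSpec(**SMALL, seed=1))
        b = make_cohort(SyntheticSpec(**SMALL, seed=2))
        assert not np.array_equal(a.epochs[0].data, b.epochs[0].data)

    def test_planted_duration_effect_recovered_in_sequences(self):
        # +25 ms on class 3 in LVF vs -5 in RVF per the effects preset: the
        # planted sequences themselves must carry the ordering.
        diffs = []
        for seed in range(10):
            spec = lateralized_effects_spec(
                n_channels=16, n_subjects=4, seed=seed, snr_db=None
            )
            cohort = make_cohort(spec)
            lvf_runs, rvf_runs = [], []
            for (subj, cond), seq in cohort.ground_truth.sequences.items():
                runs = [l for _, l, c in run_lengths(seq) if c == 3]
                if cond in LVF_CONDITIONS:
                    lvf_runs.extend(runs)
                elif cond in RVF_CONDITIONS:
                    rvf_runs.extend(runs)
            diffs.append(
                (np.mean(lvf_runs) - np.mean(rvf_runs)) * 1000.0 / spec.sfreq
            )
        assert np.mean(diffs) > 10.0  # planted 30 ms gap, attenuated by edge truncation

    def test_handedness_beta_plants_correlation(self):
        spec = SyntheticSpec(
            n_channels=16, n_subjects=12, conditions=("AN-LVF",),
            handedness_beta=2.0, handedness_sd=15.0, snr_db=None, seed=3,
        )
        cohort = make_cohort(spec)
        durs, scores = [], []
        for (subj, cond), seq in cohort.ground_truth.sequences.items():
            runs = [l for _, l, c in run_lengths(seq) if c == 0]
            durs.append(np.mean(runs))
            scores.append(cohort.ground_truth.handedness[subj])
        r = np.corrcoef(scores, durs)[0, 1]
        assert r > 0.3
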