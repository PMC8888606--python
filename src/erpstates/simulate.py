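"""Synthetic ERP cohorts with planted microstate ground truth.

The generator emulates the structure of a divided-visual-field ERP study:
k planted template topographies on a dense electrode montage, piecewise-
constant microstate sequences with condition-dependent durations and
occurrences, an ERP-like amplitude envelope, random per-run polarity, and
additive spatially correlated noise at a controlled SNR.  Every epoch comes
with its planted label sequence so each pipeline stage has a recoverable
target.

Sequences are built from weighted-order *cycles*: each cycle visits every
planted class once, in an order drawn by weighted sampling without
replacement (no immediate self-transition across cycle boundaries), with run
lengths drawn from a truncated normal around the condition's class duration
mean.  This mirrors ERP microstate segmentations, where every template
occupies a contiguous stretch of the short analysis window.  Per-class
*cycle-inclusion probabilities* below 1 let a condition skip a class in some
cycles, which lowers that class's occurrence and coverage — the knob used to
plant occurrence effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .design import BILATERAL, CONDITIONS, LVF_CONDITIONS, RVF_CONDITIONS
from .exceptions import InvalidInputError
from .montage import ChannelMontage, synthetic_scalp_montage
from .topography import ErpEpoch

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "Cohort",
    "make_templates",
    "make_sequence",
    "render_epoch",
    "make_cohort",
    "lateralized_effects_spec",
    "simulate_condition_matrix",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study geometry: 128 channels, 250 Hz, a 400 ms
    post-stimulus window, 4 planted templates, 16 subjects and the 8
    divided-visual-field conditions.  Per-condition duration means and class
    weights are overridable via nested mappings ``{condition: {class: value}}``.
    """

    n_channels: int = 128
    sfreq: float = 250.0
    window_ms: float = 400.0
    k_true: int = 4
    n_subjects: int = 16
    conditions: tuple[str, ...] = CONDITIONS
    duration_mean_ms: float = 100.0
    duration_sd_ms: float = 20.0
    #: {condition: {class_index: duration mean in ms}} overrides.
    duration_overrides: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    #: {condition: {class_index: weight}} cycle-ordering weights (default equal).
    occupancy_overrides: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    #: {condition: {class_index: probability}} cycle-inclusion probabilities (default 1).
    inclusion_overrides: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    snr_db: float | None = 5.0
    template_corr_bound: float = 0.5
    subject_duration_jitter_sd_ms: float = 5.0
    subject_template_jitter: float = 0.08
    noise_spatial_scale: float = 0.3
    noise_spatial_mix: float = 0.25
    envelope_bumps: tuple[tuple[float, float, float], ...] = ((100.0, 1.0, 80.0), (200.0, 0.8, 120.0))
    envelope_floor: float = 0.5
    amplitude_uv: float = 5.0
    handedness_mean: float = 78.85
    handedness_sd: float = 8.64
    handedness_beta: float = 0.0
    handedness_link_class: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_channels, self.k_true, self.n_subjects) < 1:
            raise InvalidInputError("all counts must be positive")
        if not (self.sfreq > 0 and self.window_ms > 0):
            raise InvalidInputError("sfreq and window_ms must be positive")
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            object.__setattr__(self, "snr_db", None)

    @property
    def n_frames(self) -> int:
        return int(round(self.window_ms / 1000.0 * self.sfreq))

    def duration_mean(self, condition: str, cls: int) -> float:
        return float(self.duration_overrides.get(condition, {}).get(cls, self.duration_mean_ms))

    def occupancy(self, condition: str) -> np.ndarray:
        w = np.array(
            [self.occupancy_overrides.get(condition, {}).get(c, 1.0) for c in range(self.k_true)],
            dtype=float,
        )
        if np.any(w <= 0):
            raise InvalidInputError("occupancy weights must be positive")
        return w / w.sum()

    def inclusion(self, condition: str, cls: int) -> float:
        return float(self.inclusion_overrides.get(condition, {}).get(cls, 1.0))


@dataclass
class GroundTruth:
    """Planted structure behind a cohort: templates, per-epoch sequences, scores."""

    templates: np.ndarray
    sequences: dict[tuple[str, str], np.ndarray]
    handedness: dict[str, float]
    spec: SyntheticSpec


@dataclass
class Cohort:
    epochs: list[ErpEpoch]
    ground_truth: GroundTruth
    montage: ChannelMontage

    def epoch(self, subject: str, condition: str) -> ErpEpoch:
        for e in self.epochs:
            if e.subject == subject and e.condition == condition:
                return e
        raise KeyError((subject, condition))


def _smoothing_kernel(positions: np.ndarray, length_scale: float) -> np.ndarray:
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    k = np.exp(-d2 / (2.0 * length_scale**2))
    return k / k.sum(axis=1, keepdims=True)


def _smooth_random_maps(montage: ChannelMontage, n: int, rng, length_scale: float = 0.6) -> np.ndarray:
    """(n, C) zero-mean spatially smooth random maps."""
    k = _smoothing_kernel(montage.positions, length_scale)
    raw = (k @ rng.standard_normal((montage.n_channels, n))).T
    return raw - raw.mean(axis=1, keepdims=True)


def make_templates(spec: SyntheticSpec, rng=None, montage: ChannelMontage | None = None) -> np.ndarray:
    """k_true zero-mean, unit-norm smooth templates with pairwise |r| below the bound.

    Smooth random maps are orthonormalised and then gently re-mixed so the
    templates are correlated-but-distinct; the mixing strength is backed off
    until every pairwise |r| respects ``template_corr_bound``.
    """
    if spec.k_true > spec.n_channels - 1:
        raise InvalidInputError(
            f"cannot plant {spec.k_true} zero-mean templates on {spec.n_channels} channels"
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if montage is None:
        montage = synthetic_scalp_montage(spec.n_channels)
    smooth = _smooth_random_maps(montage, spec.k_true, rng)
    # Gram-Schmidt on zero-mean maps keeps columns zero-mean.
    q, _ = np.linalg.qr(smooth.T)
    q = q[:, : spec.k_true]
    gamma = 0.4 * spec.template_corr_bound
    mix = rng.standard_normal((spec.k_true, spec.k_true))
    np.fill_diagonal(mix, 0.0)
    for _ in range(30):
        m = np.eye(spec.k_true) + gamma * mix
        t = q @ m
        t /= np.linalg.norm(t, axis=0, keepdims=True)
        corr = np.abs(t.T @ t)
        np.fill_diagonal(corr, 0.0)
        if corr.max() <= spec.template_corr_bound:
            return np.ascontiguousarray(t.T)
        gamma *= 0.5
    return np.ascontiguousarray(q.T)  # gamma -> 0: exactly orthogonal


def _weighted_order(included: np.ndarray, weights: np.ndarray, rng) -> np.ndarray:
    """Weighted sampling without replacement via Gumbel keys (descending)."""
    keys = np.log(weights[included]) + rng.gumbel(size=included.size)
    return included[np.argsort(-keys)]


def _draw_run_frames(mean_ms: float, sd_ms: float, sfreq: float, rng) -> int:
    """Truncated-normal run length (>= 2 frames)."""
    min_frames = 2
    for _ in range(100):
        ms = rng.normal(mean_ms, sd_ms)
        frames = int(round(ms / 1000.0 * sfreq))
        if frames >= min_frames:
            return frames
    return min_frames


def make_sequence(
    spec: SyntheticSpec,
    condition: str,
    rng,
    duration_offsets: Mapping[int, float] | None = None,
) -> np.ndarray:
    """Planted label sequence for one epoch (values 0..k_true-1).

    Cycles visit the included classes in weighted random order; run lengths
    follow a truncated normal around the condition- (and subject-) specific
    duration mean.  ``duration_offsets`` add per-class subject effects in ms.
    """
    n_frames = spec.n_frames
    weights = spec.occupancy(condition) * spec.k_true  # relative weights
    offsets = duration_offsets or {}
    labels: list[int] = []
    prev = -1
    while len(labels) < n_frames:
        included = np.array(
            [c for c in range(spec.k_true) if rng.random() < spec.inclusion(condition, c)],
            dtype=int,
        )
        if included.size == 0:
            continue
        order = _weighted_order(included, weights, rng)
        if order.size > 1 and order[0] == prev:
            order[0], order[1] = order[1], order[0]
        for c in order:
            mean = spec.duration_mean(condition, int(c)) + float(offsets.get(int(c), 0.0))
            frames = _draw_run_frames(mean, spec.duration_sd_ms, spec.sfreq, rng)
            labels.extend([int(c)] * frames)
            prev = int(c)
            if len(labels) >= n_frames:
                break
    return np.asarray(labels[:n_frames], dtype=int)


def _envelope(spec: SyntheticSpec, n_frames: int) -> np.ndarray:
    """ERP-like amplitude profile: raised-cosine bumps over a positive floor."""
    t = np.arange(n_frames) * 1000.0 / spec.sfreq
    env = np.full(n_frames, spec.envelope_floor)
    for center, amp, width in spec.envelope_bumps:
        in_b = np.abs(t - center) <= width
        env[in_b] += amp * 0.5 * (1.0 + np.cos(np.pi * (t[in_b] - center) / width))
    return env * spec.amplitude_uv


def render_epoch(
    templates: np.ndarray,
    sequence: np.ndarray,
    spec: SyntheticSpec,
    rng,
    *,
    montage: ChannelMontage | None = None,
    subject: str = "",
    condition: str = "",
) -> ErpEpoch:
    """Render an ERP from a planted sequence: envelope x signed template + scaled noise.

    The per-run sign is random (polarity ambiguity); spatially correlated
    Gaussian noise is scaled so the mean GFP²(signal)/GFP²(noise) ratio over
    the epoch matches ``snr_db`` exactly.  The result is average-referenced.
    """
    templates = np.asarray(templates, dtype=float)
    sequence = np.asarray(sequence, dtype=int)
    n_frames = sequence.size
    if montage is None:
        montage = synthetic_scalp_montage(spec.n_channels)
    env = _envelope(spec, n_frames)
    # one sign per contiguous run
    signs = np.empty(n_frames)
    start = 0
    for i in range(1, n_frames + 1):
        if i == n_frames or sequence[i] != sequence[start]:
            signs[start:i] = rng.choice([-1.0, 1.0])
            start = i
    signal = (env * signs) * templates[sequence].T  # (C, T)

    data = signal
    if spec.snr_db is not None:
        c = montage.n_channels
        white = rng.standard_normal((c, n_frames))
        k = _smoothing_kernel(montage.positions, spec.noise_spatial_scale)
        smooth = k @ white
        smooth /= np.std(smooth)
        noise = (1.0 - spec.noise_spatial_mix) * white + spec.noise_spatial_mix * smooth
        noise -= noise.mean(axis=0, keepdims=True)
        p_sig = float(np.mean(signal**2))
        p_noise = float(np.mean(noise**2))
        target = p_sig / (10.0 ** (spec.snr_db / 10.0))
        noise *= np.sqrt(target / p_noise)
        data = signal + noise
    return ErpEpoch(
        data=data,
        sfreq=spec.sfreq,
        t0=0.0,
        subject=subject,
        condition=condition,
        referenced=True,
        montage_ref=montage.fingerprint,
    )


def make_cohort(spec: SyntheticSpec) -> Cohort:
    """Generate epochs for all subjects x conditions with ground truth.

    Subject-level random effects: a small jitter on class duration means and
    on the template topographies, so between-subject variance exists.
    Handedness scores are drawn from a clipped normal; with
    ``handedness_beta`` nonzero, the linked class's duration mean shifts by
    ``beta * (score - mean)`` to plant a recoverable correlation.
    Deterministic given ``spec.seed``: identical spec + seed reproduce the
    cohort exactly.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_templates, ss_subjects, ss_hand = root.spawn(3)
    montage = synthetic_scalp_montage(spec.n_channels)
    templates = make_templates(spec, np.random.default_rng(ss_templates), montage)

    rng_hand = np.random.default_rng(ss_hand)
    subjects = [f"S{i + 1:02d}" for i in range(spec.n_subjects)]
    handedness = {
        s: float(np.clip(rng_hand.normal(spec.handedness_mean, spec.handedness_sd), -100, 100))
        for s in subjects
    }

    epochs: list[ErpEpoch] = []
    sequences: dict[tuple[str, str], np.ndarray] = {}
    for subject, ss_subj in zip(subjects, ss_subjects.spawn(spec.n_subjects)):
        rng_subj = np.random.default_rng(ss_subj)
        offsets = {
            c: float(rng_subj.normal(0.0, spec.subject_duration_jitter_sd_ms))
            for c in range(spec.k_true)
        }
        if spec.handedness_beta != 0.0:
            offsets[spec.handedness_link_class] = offsets.get(spec.handedness_link_class, 0.0) + (
                spec.handedness_beta * (handedness[subject] - spec.handedness_mean)
            )
        subj_templates = templates
        if spec.subject_template_jitter > 0:
            jitter = _smooth_random_maps(montage, spec.k_true, rng_subj)
            jitter /= np.linalg.norm(jitter, axis=1, keepdims=True)
            subj_templates = templates + spec.subject_template_jitter * jitter
            subj_templates -= subj_templates.mean(axis=1, keepdims=True)
            subj_templates /= np.linalg.norm(subj_templates, axis=1, keepdims=True)
        for condition in spec.conditions:
            seq = make_sequence(spec, condition, rng_subj, offsets)
            epoch = render_epoch(
                subj_templates, seq, spec, rng_subj,
                montage=montage, subject=subject, condition=condition,
            )
            epochs.append(epoch)
            sequences[(subject, condition)] = seq
    gt = GroundTruth(templates=templates, sequences=sequences, handedness=handedness, spec=spec)
    return Cohort(epochs=epochs, ground_truth=gt, montage=montage)


def lateralized_effects_spec(**overrides) -> SyntheticSpec:
    """Cohort spec planting the qualitative lateralisation pattern.

    * class 3 (the 4th planted template): longer duration — hence higher
      coverage — in LVF than in RVF unilateral conditions (125 vs 95 ms);
    * class 1 (the 2nd): included in only ~45 % of cycles in bilateral
      conditions, so unilateral presentations show higher occurrence and
      coverage for it.
    """
    duration = {c: {3: 125.0} for c in LVF_CONDITIONS}
    duration.update({c: {3: 95.0} for c in RVF_CONDITIONS})
    inclusion = {c: {1: 0.45} for c in BILATERAL}
    kwargs = dict(duration_overrides=duration, inclusion_overrides=inclusion)
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def simulate_condition_matrix(
    n_subjects: int,
    effects: Sequence[float],
    sigma_within: float,
    sigma_subject: float,
    rng,
    baseline: float = 100.0,
) -> np.ndarray:
    """Direct (n_subjects, n_conditions) metric draws for statistics calibration.

    ``effects`` holds the per-condition shifts added to ``baseline``;
    subject random intercepts have sd ``sigma_subject`` and cell noise sd
    ``sigma_within``.  Used to study the ANOVA's type-I error and power
    without the cost of rendering EEG.
    """
    effects = np.asarray(effects, dtype=float)
    subj = rng.normal(0.0, sigma_subject, size=(n_subjects, 1))
    noise = rng.normal(0.0, sigma_within, size=(n_subjects, effects.size))
    return baseline + effects[None, :] + subj + noise
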