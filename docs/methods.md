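# Methods

This note records the model, the algorithmic and numerical choices, what the
synthetic generator does and does not emulate, and the known limitations.

## The microstate model for task ERPs

The package treats a subject × condition ERP as a channels × frames matrix
sampled over a 0–400 ms post-stimulus analysis window.  The working model is
that the average-referenced topography at each frame is, up to amplitude,
polarity and noise, one of a small number of fixed template maps, and that
the template identity is piecewise constant in time (runs of roughly
40–120 ms).  Amplitude is carried by the global field power (GFP, the
across-channel standard deviation); topography shape is the unit-normalised
map.  Polarity is treated as meaningless throughout: a map and its negation
are the same microstate.  This is the standard ERP microstate abstraction;
everything downstream (clustering, model selection, backfitting, metrics)
is a consequence of it.

## Polarity-invariant modified k-means

* Input: all non-flat frames of one ERP (no GFP-peak subsampling), unit
  normalised.  Flat (zero-GFP) frames are excluded from clustering and left
  unassigned in backfitting rather than failing the run.
* Assignment maximises squared spatial correlation; the update sets each
  template to the dominant eigenvector of the members' outer-product sum,
  computed from the smaller of the member-Gram or channel-covariance matrix.
  Templates are sign-canonicalised (largest-|value| channel positive), which
  makes the whole algorithm exactly invariant to sign flips of any input
  subset and makes outputs deterministic under a fixed seed.
* Restarts: initial templates are k distinct observed maps drawn uniformly;
  the best restart by GEV is kept.  Empty clusters are re-seeded from the
  currently worst-fit map.  Convergence: assignment stable, or relative GEV
  improvement < 1e-7 (configurable), max 300 iterations.
* GEV weights frames by GFP²; the cluster geometry itself is
  amplitude-free.  This decouples "which topography" from "how strong",
  consistent with the microstate model.
* In a model-selection sweep each k is additionally warm-started from the
  best (k−1) solution plus its worst-fit map.  This costs one extra restart
  and keeps the best-of-restarts dispersion W(k) effectively non-increasing,
  which the Krzanowski–Lai differences assume; without it, occasional
  under-optimised fits at large k produce spurious KL spikes.

## Krzanowski–Lai model selection

`DIFF(k) = (k−1)^{2/p} W(k−1) − k^{2/p} W(k)`, `KL(k) = |DIFF(k)/DIFF(k+1)|`
with p = channel count and W the within-cluster dispersion of sign-aligned
unit maps.  KL is defined for 2 ≤ k ≤ k_max−1 over a contiguous range
starting at 1 (W(1) uses the single dominant eigenvector).  Numerical
choices:

* Non-positive DIFF values (possible only through incomplete optimisation,
  since exact best-of-all-partitions W is non-increasing) make the adjacent
  KL ratios undefined rather than feeding huge spurious ratios.
* "Second KL maximum value" is ambiguous; the default rule ranks local
  maxima by KL value and takes the second largest (flagged fallback to the
  only one).  `first_max` (ascending k) and `global_max` (arg-max of the
  curve) are alternatives; on synthetic data with well-separated planted
  templates, `global_max` is by far the most reliable at recovering the
  planted k, and the pipeline runs used for the acceptance checks configure
  it explicitly.  The rule is always recorded in output metadata.
* If some k values are infeasible because the data contain fewer distinct
  maps (noiseless synthetic input), the range is truncated; and if any k
  reaches a numerically perfect fit (GEV ≥ 1−1e-9), the smallest such k is
  chosen directly — beyond it W is exactly 0 and the ratio criterion carries
  no information.  Both paths flag the curve as degenerate.
* Flat/structureless W yields no defined maxima; the smallest candidate k is
  returned flagged `no_clear_structure` instead of raising.

## Two-level (group) clustering

All subject × condition template sets are pooled unit-normalised, one map
one vote (GEV weighting is available behind a flag but off by default), and
re-clustered over the same k range with the same machinery.  Global
templates are canonically ordered by descending total cohort coverage after
backfitting and labelled M1..Mk, so labels are stable across reruns with a
fixed seed.  Recovered-vs-reference template matching solves the optimal
one-to-one assignment on |r| with the Hungarian algorithm (exact for the
total-|r| objective).

## Backfitting and metrics

Each frame takes the global template with the highest |spatial correlation|
(ties toward the lower index; flat frames unassigned).  No temporal
smoothing or minimum-duration rejection is applied by default; a
`min_duration_ms` hook exists but is off, since the analysis this package
replays used none.  Runs truncated by the window edges count as full runs
for occurrence and enter duration at their observed length — this biases
edge-run durations short (see Limitations).

Per sequence and class: duration = mean run length in ms; occurrence =
number of runs divided by the window length in seconds; coverage = 100 ×
class frames / assigned frames.  On fully assigned sequences
`coverage/100 = occurrence × duration / 1000` holds exactly and is asserted
in the test suite on every synthetic run.  Absent classes are reported with
NaN duration and zero occurrence/coverage, never silently dropped.

## Statistics

Classical univariate repeated-measures ANOVA with subject as the random
blocking factor; in two-way designs each effect is tested against its own
interaction-with-subjects error term.  Degrees of freedom are uncorrected
(no sphericity correction by default, matching the reporting convention the
battery replays); partial η² = SS_effect/(SS_effect+SS_error).  Duncan's
multiple range test uses the studentized-range distribution at protection
level 1−(1−α)^{r−1} for a pair spanning r ranked means, with the omnibus
error term and the usual step-down blocking of nested ranges; α = 0.05.
Handedness correlations are Pearson r between per-subject mean metrics and
scores on the −100..100 laterality scale.  The full battery (omnibus
microstate ANOVAs per metric; per-microstate Emotion × Side and bilateral
ANOVAs; the two five-level valence families analysed independently;
correlations) is data-driven from the condition codes; analyses whose cells
are incomplete (e.g. NaN duration for an absent class) are skipped and
listed, not fatal.

## Synthetic cohorts

The generator emulates the study geometry: 128-channel montage (deterministic
sunflower layout on a spherical cap), 250 Hz, 400 ms window, 4 planted
templates, 16 subjects, the 8 divided-visual-field condition codes.
Defaults and rationale:

* **Templates**: spatially smooth (Gaussian-kernel mixing over montage
  positions), zero-mean, unit-norm, pairwise |r| ≤ 0.5 via orthonormalisation
  plus gentle re-mixing.  Smoothness mimics volume conduction.
* **Sequences**: built from cycles that visit every planted class once in
  weighted random order (no immediate self-transition), run lengths from a
  truncated normal (mean 100 ms per the 80–120 ms stability range, sd 20 ms,
  ≥ 2 frames).  The cycle construction guarantees each planted class appears
  within the short window, as ERP microstate segmentations show; i.i.d.
  class draws would leave a large fraction of 400 ms windows missing one of
  four classes, making the planted k unrecoverable in principle.  Occupancy
  weights shape the ordering; per-class cycle-inclusion probabilities < 1
  thin a class out of some cycles and are the handle for planting occurrence
  and coverage effects.
* **Rendering**: frame = envelope × run-sign × template + noise.  The
  envelope is two raised-cosine bumps (peaks near 100 and 200 ms) over a
  floor of 0.5 of the bump scale — ERP GFP varies within roughly a factor of
  three across a window, and a near-zero floor would make trough frames pure
  noise regardless of the nominal SNR.  Noise is Gaussian with mild spatial
  correlation (25 % smoothed component; stronger smoothing makes the noise
  low-rank and lets it form spurious topography clusters), scaled so the
  epoch-mean GFP² signal-to-noise ratio matches `snr_db` exactly (default
  5 dB).
* **Between-subject variance**: per-subject jitter on class duration means
  (sd 5 ms) and on template topographies (8 % admixture, re-normalised).
  Handedness scores are drawn from a clipped normal (mean 78.85, sd 8.64,
  the published sample statistics of the scale); an optional slope β links a
  class's duration to the score for correlation-recovery tests.
* **Planted lateralisation preset** (`lateralized_effects_spec`): class 3
  duration 125 ms in LVF vs 95 ms in RVF unilateral conditions (coverage
  follows), and class 1 included in only 45 % of cycles in bilateral
  conditions (occurrence and coverage drop there).  The occurrence effect is
  strong (roughly a halving) and a 16-subject within-design detects it
  essentially always.  The duration effect is intrinsically noisier: each
  subject-condition epoch contributes only ~1 run of the boosted class, and
  window truncation attenuates long runs, so the realised cohort-level gap
  fluctuates around ~10–25 ms across cohort seeds and its ANOVA p-value can
  cross 0.05 for unlucky seeds even though the ordering of condition means
  is preserved.

Everything is deterministic given the spec seed (seed-sequence spawning per
subject and epoch); identical spec + seed reproduces cohorts bit for bit.

What the generator does **not** emulate: biophysical sources and volume
conduction (no lead field), ocular/muscle artifacts, autocorrelated or
1/f-spectrum noise, latency jitter between subjects, gradual topography
transitions.  Passing recovery tests therefore show the pipeline is correct
and well-calibrated under the stated model — piecewise-stable topographies
plus spatially correlated Gaussian noise — not that real recordings satisfy
that model.

## Problem sizes used in the automated checks

The acceptance checks run the full two-level pipeline on 16 × 8 cohorts
(128 channels, 100 frames per epoch) with 8 restarts at the subject level
and 24 at the group level — planted separations are large, and spot checks
against higher restart counts select the same k and templates; per-ERP KL
selection over 50 seeded ERPs with 12 restarts; ANOVA calibration on 1000
and power on 300 direct metric-table simulations; clustering-oracle
comparisons on instances up to 12 maps × 6 channels × k = 3 (exhaustive
partition enumeration).

## Known limitations

* Edge-truncated runs bias duration downward and occurrence upward near
  window boundaries; with ~4 runs per 400 ms window the realised mean
  duration sits ~10 % below the planted generative mean.
* The KL curve's tail (large k) is intrinsically noisy — ratios of small
  dispersion drops; the `second_max` reading of the selection rule is
  sensitive to this, which is why the rule is configurable and logged.
* The repeated-measures ANOVA assumes sphericity (uncorrected df by
  design); a Greenhouse–Geisser option is deliberately not applied by
  default to match the replayed reporting convention.
* Duncan's test controls error only at the protection levels of the range
  test; it is liberal by modern standards and provided for fidelity, not as
  a recommendation.
* The statistics layer requires complete subject × cell designs; incomplete
  cells are skipped per analysis rather than imputed.
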