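# Methods

## Scope and model

`cfcalcium` analyses climbing-fiber (CF) triggered calcium events in
Purkinje-cell (PC) dendrites imaged with two-photon microscopy, and ships a
generator that simulates such recordings forward from known parameters. The
generator and the analysis are two independent views of the same model, so
every estimator can be validated as a recovery problem: inject calibrated
physiology, run the full pipeline, compare.

The signal model for one dendrite is additive:

    ΔF/F(t) = Σ_events g_k · K(t − t_k) + Σ_trials N_c(t − s_j) + ε(t)

- `K` is the CF transient kernel
  `K(t) ∝ (1 − exp(−t/τ_r)) · exp(−t·ln2 / t_half)` with the rise constant
  `τ_r` solved numerically so the peak falls exactly at the time-to-peak
  (10 ms default) and `t_half = 74 ms`. Note that the *post-peak half-decay*
  of this kernel is ≈76.7 ms, not 74 ms: the saturating rise term
  contributes a small correction. The analysis template and all recovery
  tests use the same functional form, so the convention is self-consistent.
- `g_k` is a per-event amplitude gain: 1 for spontaneous events (times a
  log-normal variability factor, CV 0.1, mean 1), `event_gain[condition]`
  for evoked events. Defaults are 1.0 for d1–d3 and 1.15 for d4, placing
  d1–d3 in the additive regime and making d4 supralinear.
- `N_c` is the slow non-CF component added on every stimulated trial: an
  alpha-like shape `(t/tp)^a e^{a(1−t/tp)}` (shape a = 2) with time-to-peak
  `noncf_rise[c]` (73/114/130/148 ms for d1–d4) and amplitude scaled so its
  own post-peak 100 ms integral equals `noncf_integral[c]` (defaults
  0.10/0.20/0.30/0.40) in units of the mean spontaneous-event integral.
- `ε` is white Gaussian noise per output sample, SD 0.03 ΔF/F. No noise or
  SNR value is reported for the original recordings; this default makes
  detection near-perfect, matching an analysis that treats detected events
  as ground truth.

Raw fluorescence is emitted as `F = F0·(1 + ΔF/F)` with an arbitrary
baseline `F0 = 100` (ΔF/F is scale-free; the analysis must be invariant to
F0, and a property test asserts this).

## Stimulus protocol and event statistics

Trials occur every 4 s, 35 per condition, in randomized order, with
conditions either airpuff durations d1–d4 (8/15/30/45 ms at 30 psi) or
pressures p1–p2 (10/50 psi at 30 ms).

**Spontaneous events** are Poisson per dendrite at 0.7 Hz with a 200 ms
refractory period. The refractory thinning acts as a non-paralyzable dead
time (kept rate `λ/(1+λτ)`), so the generator inflates the driving rate to
`λ0 = r/(1 − rτ)` to make the *realized* rate equal the configured one.
Distance-dependent co-activation comes from a population source process:
sources at uniform mediolateral positions recruit each dendrite with
probability `0.3·exp(−d/50 µm)`; independent events top each dendrite up to
the target marginal rate.

**Evoked events** (at most one per trial per dendrite) are governed by a
per-trial shared facilitation state `S ~ Bernoulli(q_c)`: a dendrite with
marginal probability p fires with `β·p` when S is on and
`p(1 − q·β)/(1 − q)` otherwise, leaving the marginal exactly p while a
dendrite pair gains extra synchrony `q/(1−q)·(β−1)²·p_i·p_j` — a closed
form the tests check. Defaults: β = 1.25, q increasing 0.15→0.45 over
d1→d4, yielding ~0.1–3% extra synchrony rising with stimulus strength. The
marginal probabilities default to a graded profile 0.35/0.50/0.65/0.80
(d1–d4); 58% of dendrites carry that profile, the rest are threshold-like —
a step at a random duration, low response (0.05) below and the strongest
condition's probability above.

**Spontaneous events whose peak would fall inside an evoked window** are
thinned by the generator (configurable, on by default). At 0.7 Hz roughly
10% of trials would otherwise contain a coincidental spontaneous event in
the 150 ms evoked window, contaminating the injected evoked probability,
latency and size statistics that the recovery targets are calibrated to.
This is also consistent with CF refractoriness on responsive trials. Real
recordings do contain such coincidences; analyses of real data should
expect a chance-level inflation of evoked statistics that the spontaneous
('sp') reference window is designed to quantify.

## Evoked latencies

Latency targets are the printed medians (67.1/71.8/78.8/80.9 ms, d1–d4)
and MADs (23.3/21.1/19.3/18.0 ms). Because classification accepts only
events peaking in [50, 200) ms after the stimulus, latencies are confined
to [40, 190) ms given the 10 ms rise. Within that support, a hard
constraint links median and MAD: a distribution with median m can have MAD
at most `min(m − 40, 190 − m)`, and for any distribution the mass inside
`[m − MAD, m + MAD]` must be exactly one half. For d1 (median 67.1, MAD
23.3) these constraints force substantial probability mass into the few
milliseconds just above the 40 ms floor — ~17% below 44 ms for the family
used here. A plain truncated log-normal cannot reach the d1 MAD at all
(its supremum is ≈20.3 ms); the generator therefore uses a
*support-shifted* truncated log-normal, moving the distribution's origin
toward the lower bound by the smallest amount (on a 5 ms grid) that makes
the target MAD achievable with a 2% margin, then solving (µ, σ) so the
truncated distribution's median and MAD match the targets exactly. Only d1
requires a shift; d2–d4 and p1–p2 solve as ordinary truncated log-normals.

Consequence worth knowing: per-dendrite *sample* MADs over ~12 events
(35 trials × p≈0.35) under-read the population MAD by ~6% for the
edge-heavy d1 shape, and per-dendrite sample medians carry a similar-scale
small-sample wobble. This is a property of the estimators at the study's
trial counts, not of the detection pipeline (whose per-event latency error
is ≈0.2 ± 0.3 ms in dense mode); the recovery tests therefore compare
against the targets at 2 SEM of the measured across-dendrite spread, and
the d1 jitter sits near the edge of that band by construction.

## Rendering and analysis resolutions

Traces are always rendered at the dense resolution (1 ms default) and
either kept dense or bin-averaged to the 64 ms frame period; noise is
added at the output resolution. Dense mode separates estimator accuracy
from frame quantization: latency statistics and kinetics are validated in
dense mode, while the frame mode exercises the realistic imaging regime.
Movies paint each dendrite as a 2-pixel vertical stripe (PC dendrites
appear as parasagittally aligned, tube-like structures) into a 32×128
field with per-pixel noise, plus a labeled mask image.

## Estimator definitions and numerical choices

- **ΔF/F baseline**: 8th percentile (linear-interpolation definition) in a
  centered window of ~1 s, truncated at the trace edges. The window half
  is rounded to whole frames (±8 frames at 64 ms). On dense traces the
  baseline is evaluated on a subgrid (one point per frame period) and
  linearly interpolated — it varies on second timescales, so this is
  accuracy-neutral. The low-percentile baseline sits ~1.4 noise SD below
  the true floor, giving every ΔF/F trace a small positive offset; all
  stimulus-aligned composite averages are therefore baseline-corrected by
  their pre-stimulus (or, for the mean spontaneous event, pre-onset) mean.
- **Detection**: normalized cross-correlation against the CF template,
  local maxima with score ≥ 0.8, then an amplitude threshold. The template
  spans a 30 ms pre-onset baseline plus two decay half-lives — long enough
  to encode baseline-rise-decay (a monotone template would match any
  decaying stretch), short enough that a neighbour at the ~200 ms
  refractory distance does not corrupt the window. On frame-rate data the
  binned transient's shape depends on the event's phase within its onset
  frame, so two phase variants (0 and ½ frame) are matched and the better
  score taken. The amplitude threshold defaults to
  `max(3·σ_noise, 0.45·(Q99.5 − median))` of the trace: CF events are
  all-or-none and large, so a fixed fraction of the large-transient
  amplitude rejects the smaller non-CF bumps, whose *shape* alone scores
  0.78–0.97 against the template. σ_noise is estimated robustly from the
  MAD of first differences. Refractory deduplication keeps the
  larger-amplitude candidate, with one frame of slack for quantization of
  near-refractory spacings.
- **Peak times**: frames are 0-based and start-time indexed; the *event
  peak estimate* is the centre of the peak frame — unbiased under uniform
  phase, whereas the start-time convention reads peaks systematically half
  a frame early, which at 64 ms pushes a third of early-latency evoked
  events out of the 50 ms window edge and couples dendrites through the
  shared trial phase (spuriously inflating extra synchrony by ~2% in an
  independent-by-construction simulation).
- **Classification**: evoked iff the peak lies in [onset+50, onset+200) ms
  (half-open, as are all windows); the 'sp' chance reference uses matched
  150 ms pre-stimulus windows.
- **Onset latency**: last crossing of 10% of peak amplitude before the
  peak, linearly interpolated, referenced to a local baseline (median over
  [peak−45, peak−15) ms) so the slowly rising non-CF component does not
  drag the crossing early; undefined (NaN, flagged) when no crossing
  exists or the latency falls outside (0, 200) ms. Latency summaries
  require ≥5 events per dendrite-condition: a median over one or two
  events is not a latency estimate, and near-unresponsive dendrites would
  otherwise dominate the across-dendrite spread with values biased toward
  the skewed distribution mean.
- **Sizes**: trapezoidal ΔF/F-integrals over [peak, peak+100 ms] on the
  spontaneous-peak-normalized trace, evoked values divided by the
  dendrite's mean spontaneous integral (so the spontaneous mean is exactly
  1). Trials with ≥2 evoked-window events <100 ms apart are excluded from
  size analyses and the exclusion fraction logged. Condition-mean trace
  integrals anchor at the trace peak, located on a 15 ms-smoothed copy
  (the raw argmax of a noisy mean rides its largest noise excursion,
  biasing noisier traces upward).
- **Non-CF extraction**: trials without an evoked event *and* without any
  detected transient peaking in or decaying into the aligned segment — at
  0.7 Hz about a quarter of no-response trials contain an incidental
  spontaneous event that would otherwise contaminate the slow average.
  Rise time is stimulus onset to the (smoothed) peak of the condition-mean
  trace, matching the generator's time-to-peak parameterization; per-trial
  integrals use one uniformly drawn anchor in [50, 200) ms per
  dendrite-trial, seeded.
- **Linearity**: enhancement (evoked mean minus the jitter-matched
  spontaneous reference) and non-CF sizes are computed per dendrite as
  peak-anchored integrals in units of that dendrite's spontaneous
  integral, then compared across dendrites as paired differences; the
  supralinearity flag fires when the mean paired difference exceeds twice
  its SEM. The jitter-matched reference places each dendrite's
  (floor-corrected) mean spontaneous event at every evoked event's
  latency, so the reference carries the evoked averages' temporal jitter
  exactly — which is why all composite peaks sit well below 1.
- **Responsiveness / laterality**: a dendrite is responsive when its
  best-condition response count beats the spontaneous pre-window chance in
  a one-sided binomial test at α = 0.05 (Bonferroni over dendrites for the
  laterality labels). Population coactivation requires ≥6 responsive
  dendrites; smaller fields are excluded with a logged reason.
- **Statistics**: two-way ANOVA with factors condition + experiment
  (dendrites, trials or pairs as observations) and Tukey HSD on condition;
  two-sample KS on early/late latency-interval counts between the weakest
  and strongest condition; two-sample t between measured and independent
  joint probabilities. All two-tailed; p-values reported exactly.
- **Dendrite categories**: category 1 (graded) requires the
  spontaneous-corrected probabilities to share the duration rank order
  within one binomial SE per comparison, a positive overall span, and a
  2-parameter line to fit no worse than the best 2-level step; otherwise
  the best-fitting step position (least squares over the four candidates)
  gives categories 2–5. The model-comparison clause is needed because a
  pure rank-order test with SE tolerance accepts most step profiles (their
  flat segments pass a tolerance test by chance), which would destroy the
  graded-fraction recovery.

## Determinism and problem sizes

Everything is driven by `numpy.random.Generator` seeded from the
configuration; identical config + seed reproduce byte-identical report
tables. The recovery studies use 50 dendrites × 600 s for the spontaneous
rate, 12 experiments × 8 dendrites × 140 trials (dense) for latency, and
3 experiments × 12 dendrites with a low-response configuration for the
non-CF rise time — sizes chosen to match the original study's scale while
keeping a full run in minutes on one core.

## What the generator does not emulate

Motion artifacts, slow fluorescence drift and photobleaching, dye-kinetics
nonlinearity, locomotion-related modulation, overlapping dendrites and
neuropil contamination, ICA-based segmentation (masks are ground truth),
and biophysical CF-burst structure (the spike count enters only as an
amplitude gain). Passing recovery tests therefore demonstrate estimator
correctness under the stated statistical model, not robustness to these
real-data nuisances; the mask-based extraction path and the percentile
baseline are the only components that would absorb them in practice.
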