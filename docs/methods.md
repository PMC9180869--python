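# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `evacpanic`, and what the synthetic cohorts do and do not
establish about real recordings.

## Session model

A session is: a roaming baseline (default 120 s), then three
stimulus–evacuation rounds (default 20 s each) separated by 80 s
onset-to-onset, each followed by a 60 s buffer; total 360 s. The three
scenario labels (Alarm, Smoke, Flame) are assigned to presentation slots
in one of three counterbalanced orders; a default cohort of 56 splits
26/15/15 across the orders, rescaled by largest remainder for other
cohort sizes. Time is seconds from session start, sample indices are
0-based, analysis windows are half-open, and onsets snap to the nearest
sample of each device's grid (60 Hz eye, 10 Hz fNIRS). The round length
is treated as an exact configuration value even though evacuations in
practice take "approximately" that long: reproducibility requires a fixed
window. Whether the 80 s spacing is exact or approximate in a real
protocol is likewise resolved as exact here.

## Pupil pipeline

Blink gaps are filled by linear interpolation (interior gaps) or constant
extension (edge gaps) per eye before averaging the eyes; if one eye is
entirely absent in a window the other is used with a warning. The
magnification baseline is the mean of the **first 10 samples** of the
round window at the eye rate (~0.167 s); that literal reading is adopted
because the alternative (10 s, or 10 fNIRS-rate points) is not supported
by the device context. The dilation amplitude is the plain maximum of
M_t over the round. White pupil noise inflates this maximum slightly
(extreme-value bias, about +0.04 at the default 1.5% noise); the noiseless
recovery tests isolate the pipeline from that generator property.

## Fixation/saccade ratios

The denominator N counts **all** window samples including blinks, so
r_fix + r_sac < 1 by roughly the blink fraction — consistent with
published ratio pairs that sum to ~0.9. Eyes are averaged at the ratio
level (not sample level). Both conventions are configurable reading
points but fixed here; the alternative orderings differ only at the third
decimal for realistic blink rates.

## Binned gaze entropy

Gaze samples are assigned to 10×10-pixel bins by floor division
(lower-edge inclusive); the view plane defaults to 1920×1080 px and
off-plane samples are clamped into the boundary bin and logged. N counts
only valid (non-blink) samples, since missing coordinates cannot be
binned. The entropy uses the natural log — reported values of ~3.5–4.5
nats over thousands of occupied 10-px bins are only consistent with
natural log. The implementation uses the log N − (1/N)Σ n_i log n_i
form; tests assert agreement with the −Σ p log p form and with an
independent Counter-based histogram to 1e-9.

## fNIRS activation model

The canonical HRF is a difference of gamma densities (shapes 6 and 16,
unit scale, undershoot ratio 1/6), normalized to unit peak so that β̂
carries ΔHbO units. On a dense grid the peak sits at 5.00 s, the
undershoot minimum at 15.75 s, and |h| stays within 2% of peak from 23 s
on; the constructor enforces these timing constraints (±1 s) on any
user-supplied parameterization. The regressor is the Kronecker impulse at
the onset sample convolved with the sampled HRF.

Each channel and each regressor pass through the **same** zero-phase
band-pass (order-3 Butterworth, 0.01–0.1 Hz, forward–backward via
`sosfiltfilt`, reflective padding of one longest passband period). 
Filtering the regressor as well as the data is essential: the raw
HRF bump has most of its energy below 0.01 Hz, and projecting filtered
data onto an unfiltered regressor is biased even without noise.

Filtering also smears each regressor's support beyond its 30 s span,
which breaks the exactness of a per-stimulus windowed scalar projection
(a ~4% bias at zero noise was measured). The default fit therefore solves
the three coefficients per channel **jointly** over the whole filtered
session. For disjoint raw supports this is algebraically the same as
three scalar projections (a tested invariant), and it remains exact under
filtering; `mode="separate"` retains the windowed scalar-projection
variant (window: onset + 35 s) for comparison.

## Questionnaire shifts

Shifts are exact integer differences of 9-point scores against the
roaming baseline, in −8..8. Missing entries are excluded listwise per
term per participant and logged.

## Contrast statistics

All participants experience all scenarios, so the default test is the
paired t-test on within-participant differences, two-sided, p from the t
distribution with n−1 df; an independent-samples pooled-variance variant
sits behind a switch for sensitivity analysis. Degenerate zero-variance
differences return p = 1 (zero mean) or the p → 0 limit with a warning.
Summaries report arithmetic means and sample SDs (n−1). No
multiple-testing correction is applied by default, matching per-contrast
α = 0.05 reporting conventions; a Holm step-down option exists. Roaming
enters the contrast set only for indicators measured during roaming
(ratios, entropy) — shifts, dilation amplitude and β have no roaming
value by construction.

## Synthetic cohorts

The generator's defaults are the cohort-level truths the analysis is
meant to recover:

* pupil amplitude means 1.46/1.31/1.32 (SD 0.24/0.14/0.18) for
  Alarm/Smoke/Flame;
* fixation/saccade ratio targets 0.863/0.052 (Roaming), 0.835/0.063
  (Alarm), 0.887/0.040 (Smoke), 0.903/0.027 (Flame), realized through a
  two-state renewal process with mean saccade dwell 0.05 s and fixation
  dwell set by the target odds;
* per-channel activation-coefficient means/SDs per scenario (range
  ≈ 2.1–5.7, SD ≈ 1.0–2.9);
* emotion shift means/SDs per term and scenario, with roaming baselines
  centred at calm-exploration values (negative emotions ≈ 2, happiness
  and valence ≈ 6, arousal ≈ 3, dominance ≈ 6, SD 1).

Pupil bumps are raised-cosine (rise 0.5–3.5 s after onset, plateau to
10 s, decayed by 18 s): any smooth unimodal bump satisfies the
peak-amplitude contract; raised cosine gives a closed-form peak exactly
equal to the configured amplitude, so the noiseless pipeline recovers it
to interpolation error. Blinks arrive as a Poisson process (10/min) with
gamma-distributed durations (mean 0.25 s); during a blink the pupil and
gaze are missing and both flags are false. Gaze alternates dwell points
drawn from a mixture of wide uniform scanning (weight per scenario:
0.70/0.65/0.25/0.30 for Roaming/Alarm/Smoke/Flame, chosen to reproduce
the reported entropy ranking) and clustered dwelling around a few
segment-level cluster centres; entropy responds monotonically to the
scanning weight. Both eyes share behavioural state (flags, blinks, gaze)
— real trackers report them near-perfectly coupled — while pupil noise is
drawn per eye.

ΔHbO channels are the clean regressor combination plus a sub-0.01 Hz
sinusoidal drift (amplitude 2) with a linear trend, respiratory (0.3 Hz,
amplitude 0.5) and cardiac (1 Hz, amplitude 0.3) sinusoids with random
phases per channel, and white noise (SD 0.4), all in β units.

Emotion scores are sampled as baseline + normal shift, rounded and
clamped into 1..9; the *realized* shift after clamping is the recovery
truth, since the bounded scale is a hard constraint on real respondents
too.

Each participant draws an independent child stream of the master seed
(`SeedSequence(seed, spawn_key=(i,))`), so cohorts are bit-reproducible
and participants statistically independent.

**What passing tests show, and what they do not.** The generator matches
the analysis's assumptions by construction: HRF-shaped responses, smooth
unimodal pupil bumps, stationary renewal fixation behaviour, independent
participants. Recovery and calibration results therefore validate the
*estimators*, not the assumptions themselves. Real recordings add motion
artifacts, luminance-driven pupil changes, foreshortening, drifting
calibration, non-HRF haemodynamic shapes and serial correlation, none of
which are emulated.

## Problem sizes and numerical tolerances

Test and acceptance workloads use full-length 360 s sessions; statistical
checks use 200 synthetic fNIRS sessions for β recovery, 80 null cohorts
of 56 participants (2160 contrasts) for type-I calibration, and an
8-participant cohort for byte-level end-to-end determinism — sizes at
which every check completes in seconds while estimates remain stable.
Oracle agreements (entropy, least squares, separability) are asserted at
1e-9 absolute; exact generative identities (noiseless recovery) at 1e-6
relative or tighter; filter contracts at the 5%/20 dB/1% levels standard
for an order-3 zero-phase Butterworth band.

## Known limitations

* The HRF parameterization is fixed to the canonical timing; subject- or
  region-specific haemodynamics are out of scope.
* Single-regressor-per-stimulus GLM only: no nuisance regressors, no
  motion correction, no deoxy-haemoglobin channel.
* Fixation/saccade booleans are consumed as device output; event
  detection from raw gaze is not implemented.
* The generator's gaze model is a dwell-point mixture, not a saccade
  kinematics model; entropy levels are realistic in rank and order of
  magnitude, not calibrated per scenario.
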