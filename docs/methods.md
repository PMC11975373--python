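# Methods

This note documents the models, defaults, and numerical choices behind
`saccost`, and what the synthetic-data generator does and does not
emulate.

## Coordinate and binning conventions

Angles are 0° = rightward, counterclockwise positive, 90° = upward;
screen-native y-down data must be flipped at ingestion. All direction
analyses use 36 half-open 10° sectors centered on multiples of 10°
(e.g. 4.999° falls in bin 0°, 5.0° in bin 10°). Obliqueness is the
angular distance to the nearest cardinal axis in 10° steps, O ∈ {0…4};
verticalness and horizontalness are the unit-vector components sin θ and
cos θ. Target coordinates at fixed eccentricity are proportional to
these components, so standardized regression fits are unchanged by the
unit-vector choice.

## Ground-truth cost model

The generator parameterizes direction-dependent saccade cost (z-units)
as

    cost(θ) = c0 + c_obl·O(θ)/4 + c_down·(−sin θ) + c_left·(−cos θ)

with defaults c0 = 0, c_obl = 0.3, c_down = 0.1, c_left = 0.05: oblique
saccades cost up to 0.3 z more than cardinals, downward up to 0.2 z more
than upward, leftward up to 0.1 z more than rightward. These magnitudes
give cost maps whose anisotropy ordering (oblique > cardinal,
down > up, left > right) matches what pupil-based cost mapping shows in
humans; the absolute generative magnitude of effort-linked dilation in
raw tracker units is not established, so the pupil gain (1 a.u. per
z-unit) is a free parameter, not an estimate.

## Synthetic recordings

**Pupil.** Each trial adds `pupil_gain · cost(θ)` times an Erlang-family
impulse response h(t) = (t/t_max)^n · exp(n(1 − t/t_max)) (n = 10.1,
t_max = 930 ms, unit peak) locked to cue onset, on a baseline of
1000 a.u. plus white noise (sd `noise_sd`, default 0.2 a.u.). The kernel
is the canonical pupillometry impulse response and yields realistically
sluggish dilations: at cue offset (750–1250 ms after onset) the kernel
has risen to 0.8–1.0, so the cost signal is present in the measurement
window. Kernel support is truncated at 4·t_max (< 10⁻⁴ of peak).

**Kinematics.** Main sequence: duration D = 2.2·A + 21 ms; the velocity
profile is a raised cosine, which ties peak velocity to 2A/D — a
saturating function of amplitude (~465 deg/s at 10°, asymptote
~909 deg/s). Landing scatter is isotropic Gaussian (sd 0.5°). Blinks are
vendor-style zero runs of 80–200 ms at `blink_rate` (default 5/min).

**Fixational jitter.** Gaze noise is modelled as drift — an
Ornstein-Uhlenbeck velocity (sd 1.25·noise_sd deg/s, timescale 100 ms)
integrated into position with weak reversion (timescale 2 s), giving
~0.1° positional wander at defaults. White positional noise at 1 kHz is
deliberately not used: at any visible magnitude it implies hundreds of
deg/s of sample-to-sample velocity, which no tracker trace exhibits and
which would defeat any deg/s-scale offset criterion. Setting
`noise_sd = 0` removes both pupil noise and gaze jitter.

**Operational saccade onset.** Truth tables record each injected
saccade's onset as the first analytic crossing of the 75 deg/s detection
criterion on its noise-free speed profile (the kinematic motion start is
kept in a separate column). The raised-cosine profile reaches 75 deg/s
~5–6 ms after motion start, so a threshold detector can agree with the
operational onset to within sampling error but is structurally offset
from the kinematic start; latencies and recovery checks are therefore
defined against the operational onset. Likewise, detected amplitude
spans threshold-to-threshold and undershoots the full chord by up to
~0.19° at 10°.

**Trial timelines** (chosen for compactness; the pupil windows are the
task-relevant parts): planning trials run 400 ms fixation, 400 ms
targets-only, 750–1250 ms cue, saccade latency N(280, 60) clipped to
[120, 650] ms, then 300 ms on target; preference trials use a 150–400 ms
fixation, latency N(230, 40) clipped to [120, 450] ms. Between trials a
return saccade brings gaze back to fixation; it lies outside the trial
window and is simply an extra detection.

**Choices and curvature.** Preference choices are sampled with
P(A) = 1/(1 + exp((cost_A − cost_B)/τ)), τ = 0.5 z (a moderate
stochasticity: a 0.3 z cost gap yields ~65% choice of the cheaper
option). The executed saccade follows a quadratic Bézier whose control
point sits 2d off the chord midpoint, giving peak deviation exactly d at
the midpoint; d = 1.0 deg/z · |Δcost| + N(0, 0.25 deg), signed away
from the non-selected option. Negative draws bow toward it, so
toward-curving trials exist and concentrate at small cost differences —
which is what makes cost less predictive of choice in toward trials, as
the conflict analysis then finds.

**Search.** Outgoing saccade directions are drawn over the 36 bins with
probability ∝ exp(−κ·cost(θ)), κ_single = 2, κ_dual = 3 (stronger cost
sensitivity under load); inter-saccade intervals are Gamma (shape 10)
with means 300 ms (single) and 400 ms (dual), giving ~3.3 vs ~2.5
saccades/s. Each fixation carries luminance and saliency covariates
(standard normal, entering pupil with weights −0.1 and +0.05), gaze
position on a clamped random walk within ±16° × ±12° display bounds,
and duration/amplitude draws; 2% of fixations are planted outliers
(half extreme pupil, half off-display) to exercise the exclusion stage.
Saccade duration gets N(0, 3 ms) main-sequence scatter so that duration
and amplitude are not exactly collinear in covariate models.

## What the generator does not emulate

Pupil noise is white and the effort dilation is strictly additive and
direction-locked; real pupil data have autocorrelated noise, luminance
reflexes, and arousal drifts. Gaze has no microsaccades, pursuit, or
head movement. Search fixation positions are a clamped random walk, not
scene-driven, and luminance/saliency are synthetic covariates rather
than image measurements. Passing tests therefore demonstrate that the
pipeline recovers known ground truth under clean, assumption-satisfying
input — not that the scientific effect exists in real recordings.

## Preprocessing and detection defaults

- Blink criterion: pupil missing or ≤ 0 for ≥ 20 ms; padding 100 ms each
  side; overlapping padded intervals merged; linear interpolation
  between flanking valid samples (nearest-value fill at recording
  boundaries, flagged). The cited pupillometry recommendations leave the
  exact recipe open; these defaults are conservative and configurable.
- Downsampling 1000 → 100 Hz by block means (not decimation) to
  preserve low-frequency pupil content; output keeps the first time
  stamp of each block.
- Speed estimation: central differences over a 5-sample window
  ((g[i+2] − g[i−2])/4Δt); attenuates a 43 ms raised-cosine peak by
  < 1%.
- Saccade detection: onset ≥ 75 deg/s; offset ≤ 1 deg/s sustained for 3
  consecutive samples (the persistence rule avoids splitting a saccade
  on velocity ripples); minimum inter-saccade interval 20 ms; minimum
  fixation duration 40 ms; a saccade still open at the recording end is
  dropped.
- Curvature tie rule: a peak deviation of exactly 0 is classed neither
  toward nor away; such trials are flagged ambiguous and excluded from
  toward/away splits.
- z-transforms use only trials surviving exclusions, with sample SD.

## Analysis decisions

- Exclusion cascades are any-criterion; the report attributes each
  excluded trial to the first firing criterion in the canonical order
  (latency fast/slow, duration short/long, amplitude, landing, wrong
  target, practice) purely for reproducible reporting. Percentages are
  exposed on both the all-trials and the non-practice denominators.
- Selection-resolution boundary: a distance difference of exactly 1.5°
  is kept (the rule excludes strictly smaller differences).
- Preference-map denominators count offered directions over resolved
  trials only, so selected counts sum exactly to the number of resolved
  trials.
- Cost-based prediction uses the all-participants group cost map (no
  leave-one-out); cost ties and missing bins skip the trial and are
  counted separately.
- Mixed models delegate to statsmodels `MixedLM` (REML, lbfgs with bfgs
  fallback). On non-convergence or non-finite standard errors, random
  slopes are dropped one at a time in reverse of the listed order down
  to a random intercept, each step logged — a deterministic reduction
  path. Fixed-effect covariates are standardized before fitting.
- Bootstrap CIs are percentile intervals of the mean with participants
  as the resampling unit, n_boot = 10,000, seeded. All tests are
  two-sided; Cohen's d is mean/SD (one-sample) or mean-diff/SD-diff
  (paired).

## Problem sizes

The default study scale is 20 participants × 2 sessions × 360 trials
(14,400 trials) for the planning and preference tasks and 25
participants × 2 conditions × 20 trials × 8 s for search (~24,000
fixations). The full pipeline runs in well under a minute per task on a
single CPU; unit tests use smaller slices of the same generator.

## Known limitations

Exclusion percentages depend on the generator's latency and landing
distributions and sit near 4% at defaults — the cascade logic, not the
percentage, is the tested contract. The planning model's amplitude and
peak-velocity covariates are nearly collinear by construction (main
sequence), so their individual coefficients are unstable even though
the direction effects are not. MixedLM Wald p-values are asymptotic;
with 20 participants they are adequate for the strong synthetic effects
but small-sample inference on real data should use cluster-robust or
t-based intervals. Pupil foreshortening correction is intentionally
omitted (the measurement window precedes saccade onset).
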