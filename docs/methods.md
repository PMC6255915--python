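# Methods

`vefkit` analyses head-fixed-mouse sessions from a two-alternative
virtual-corridor foraging task: the animal runs down a corridor, a trigger
crossing displaces the target wall to the left (40 % of trials), centre
(20 %) or right (40 %), and the animal steers into the target or the
competing distractor wall.  Task difficulty is the orientation difference
ΔOri between target and distractor gratings (90° easiest … 5° hardest).
Each session is two text streams: a per-trial event log and a continuous
60 Hz readout of lateral/longitudinal position and licking.  Centre trials
and post-error repeat trials are instruction trials and are excluded from
every analysis.

## Primary single-trial metrics

For each included left/right trial with lateral position x(t), longitudinal
position y(t):

* **Hit index** ∈ {+1, 0, −1}: target touch, neither, distractor touch.
  The logged outcome event is authoritative; a geometric touch test
  (endpoint x within a wall span at the target row) is the fallback and the
  validator.
* **Target distance** TD = |X_T − X_M| / ΔX_T, where X_T is the target edge
  nearest the animal, X_M the animal's x at the target's y level (endpoint
  fallback when the trial ends short), and ΔX_T = 12 cm the spacing between
  adjacent target centres.  Hits give 0, a one-position miss ≈ 1, the far
  side ≈ 2.
* **Path reliability (PR)**: paths are binned along y from the trigger row
  to the target row in 2 cm steps (per-trial mean x per bin); per bin the
  pooled-SD Cohen's D between left-target and right-target trials is
  computed, and the PR score is the maximum |D| over the profile.  It needs
  at least two trials per side.  The **local PR** of a trial is the PR of
  the window from 7 trials before to 7 after (15 trials); it is undefined
  for the first and last 7 included trials of a session.
* **Reaction time (RT)**: for every sample t, the 20-sample lateral-path
  segment *ending at t* is regressed (least squares) against the same
  segment shifted forward by 5 samples; the slope b_t stays near 1 while
  running direction is constant and deviates at a turn.  RT is the sample
  maximising |b_t − 1| within 0.1–1.25 s after the target shift (earliest
  on ties, candidates limited to −0.5…+3 s around the shift).  If
  max |b_t − 1| < 0.1 the animal never substantially changed direction and
  RT is undefined; zero-variance segments define b_t = 1.
  *Why a trailing window:* with a centred window the |b_t − 1| spike occurs
  when the window's trailing edge first touches the change point, dating
  onsets ~8 samples (133 ms) early; attributing the statistic to the most
  recent sample recovers noiseless direction-change onsets within
  ±2 samples for linear and exponential steering laws, with or without
  locomotor jitter.
* **Path surplus** PS = L_R/L_i − 1: actual sample-to-sample path length
  from the RT sample to trial end, over the straight line from the RT
  position to the centre of the lateral target the animal ended closest to
  (the one it presumably chose, not necessarily the correct one).  Slightly
  negative values occur when the animal clips the near wall edge.
  Undefined RT leaves PS undefined, and such trials are excluded from the
  cognitive-load aggregates below.
* **Lick position**: mean signed y distance of lick samples from the target
  row within ±30 cm of it, spanning the approach and the following trial's
  first stretch (distance counted from that trial's start).  Negative =
  anticipatory licking.
* **Running speed**: mean virtual-plane displacement per sample × sample
  rate, from the target shift until the animal is within 10 cm of the
  target centre (to trial end, flagged, if it never gets that close).

## Psychometric thresholds

Per-level means of hit index and target distance (and the per-level PR
score, a set statistic) versus ΔOri are fitted with a logistic
f(ΔOri) = L / (1 + e^{−s(ΔOri−o)}).  Fits operate on a
performance-increasing, chance-floored transform — hit index as is
(chance 0), target distance as 1 − TD (chance 1), PR as PR − 1 (scores
below ~1 are chance) — so the logistic's zero floor matches each metric's
chance level.  Fits are weighted by per-level SEM (for PR, the
large-sample SD of a Cohen's-d estimate) with a deterministic multi-start
over slope/offset initialisations; bounds are L ∈ (0, 2·range], s ∈
(0, 5/°], o ∈ [0°, 90°].  The discrimination threshold is the smallest
ΔOri ∈ [0°, 90°] where the fitted curve reaches a criterion value
(closed-form inversion); curves that never reach it report "not reached"
and are excluded from the cross-metric average, which is the mean of the
defined hit/TD/PR thresholds.

Criteria sit just above chance and can be calibrated by bootstrap: per
animal, ΔOri and trial fraction (20/40/60/80 %, 10 repetitions each) a
subset is sampled without replacement and its SEM = SD/√n recorded; the
criterion shifts chance towards performance by the median of the pooled
SEM distribution.  For real cohorts the package defaults to the
conventional criteria 0.2 (hit index), 0.82 (target distance, falling) and
1.25 (PR).  For simulated cohorts the target-distance criterion is 0.52 —
the simulator's own calibration (see below) — because its commit-to-wall
error model yields a chance-level TD of ≈ 0.81, so a 0.82 criterion would
sit exactly at the chance floor.

## Alertness states and the sATT score

The local-PR distribution of an alertness-fluctuating animal is bimodal.
Bimodality is assessed with

    BC = (skew² + 1) / (kurt − 3 + 3(n−1)²/((n−2)(n−3))),

using sample skewness and the raw fourth standardised moment; BC > 0.55
flags bimodality (an equal two-Gaussian mixture crosses 0.55 at a mode
separation of ≈ 3.65 component SD in the large-n limit).  The cut between
modes maximises F = Var_all / mean(Var_below, Var_above) over the midpoints
of consecutive sorted unique values (exhaustive, earliest on ties; at least
two samples per side).  Trials above the cut are high-alert; the
**sATT score** is Σ high-alert trial durations / Σ all defined-trial
durations (durations = offset − onset from the event log).  Non-bimodal
animals (BC ≤ 0.55) get no state labels and no sATT.

A control guards against bimodality produced by isolated errors: every
error trial's trajectory is replaced by a resampled same-side hit
trajectory and local PR + BC recomputed; genuine state-driven path
variability keeps BC > 0.55, error-artifact bimodality collapses.

A 25-trial centred moving average of each primary metric, correlated with
the local-PR trace (Pearson, over trials where both are defined), shows
which aspects of performance co-fluctuate with alertness.

## Cognitive load, cATT, error prediction

Reaction time, target distance and path surplus are normalised per trial by
the 5th/95th percentiles of their overall distributions (linear
interpolation; values outside the band map outside [0, 1], unclipped) and
combined as

    CL = 0.5·NR + 0.25·NT + 0.25·NP,

reaction time carrying half the weight as the sole speed measure.  The
**cATT score** is (CL_noncued − CL_cued) / CL_all over defined choice
trials — the relative performance improvement under cueing (0.5 = 50 %
improvement).  The **EP index** averages the normalised hit-vs-miss
differences Δm = (m_miss − m_hit)/(m_miss + m_hit) of reaction time, path
surplus and lick position; components with mixed signs (lick position) are
shifted so the pooled minimum maps to zero before normalising, which
preserves antisymmetry under label swap.  Positive EP = the animal behaves
as if anticipating errors.  Group contrasts use dependent-samples t-tests
(and one-sample t-tests of correlation coefficients against zero) with the
Dunn–Šidák family-wise correction α_corr = 1 − (1 − α)^{1/n}.

## Synthetic sessions

The generator emulates the statistical structure the analyses assume, with
full ground truth:

* **Arena**: start y 0, trigger 20 cm, target row 48 cm, target centres at
  −12/0/+12 cm, wall width 9 cm, adjacent spacing 12 cm, lateral bound
  24 cm, treadmill-to-virtual translation factor 3.  (The corridor length
  is configurable; published descriptions of such arenas differ between
  ~48 and ~62 cm depending on whether treadmill or virtual units are
  meant.)
* **Trial structure**: 40/20/40 left/centre/right with exact counts in
  every complete 10-trial block; eight interleaved ΔOri levels
  {90, 70, 50, 30, 20, 15, 10, 5}°; exactly round(0.2 × n_choice) cued
  trials; optional flagged repeat trials after errors.
* **Choice model**: the animal commits to a side — the target side with
  probability q(ΔOri) = 0.5 + (0.5 − lapse)·g, g = expit(s(ΔOri − x0)) —
  and then navigates identically for either commit (aim uniform within the
  chosen wall span minus a 0.75 cm margin), so behaviour at chance is
  side-symmetric and the hit-index chance level is exactly 0.  Mid-course
  switches (first steering to the mirrored aim) and RT slowing couple to
  difficulty 1 − g, not to correctness, which yields a positive EP index
  without giving the animal knowledge it cannot have.  The midpoint x0 is
  placed analytically so that the population hit-index curve crosses 0.2
  exactly at the configured per-state threshold (default slope 0.8/°,
  lapse 0.02 high / 0.05 low); for lapse-dominated states whose hit curve
  never reaches 0.2, the threshold parameter anchors the midpoint instead.
* **Trajectory law**: forward speed 15 ± 1.5 cm/s white noise; lateral
  position mean-reverts around 0 until the drawn true RT
  (state-dependent: 0.40 ± 0.10 s high, 0.55 ± 0.15 s low, −0.1 s under a
  speed cue, +0.10·(1 − g) s difficulty penalty, clipped to 0.15–1.05 s),
  then proportional steering (gain 3 s⁻¹) towards the aim with additive
  noise.  Trials end at the first sample reaching the target row; the
  outcome is the wall-span test there.
* **Alertness**: alternating high/low renewal process with gamma dwells
  (default exponential, mean 300 s each).  High/low states differ in
  psychometric truth, RT stats, lick anticipation, and optionally
  kinematics.
* **Licks**: inhomogeneous Poisson, baseline 0.3 Hz plus a 6 Hz Gaussian
  bump (8 cm wide) centred at the target row shifted by the state's
  anticipation offset (−8 cm high, −1 cm low), plus a post-reward plateau
  at the start of the next trial.

What the generator does **not** emulate: closed-loop visual feedback,
session-scale fatigue or learning drift, eye/whisker/pupil signals,
inter-animal kinematic diversity, and reward-magnitude dynamics.  Passing
recovery tests therefore demonstrates the correctness and calibration of
the analysis chain under the assumed structure, not performance on any
particular real dataset.

## Recovery benchmarks and their calibrations

The benchmark suite (also run by `scripts/acceptance.py`) fixes its study
conditions as follows.  All values were set from design analysis and pilot
simulations (separate seeds) before the verification seeds were run.

* **Threshold recovery**: animals at true thresholds 6/10/18°, ~300 choice
  trials, identical high/low truth, no cue; criteria hit 0.2, TD 0.52
  (fitted TD-curve value at the anchor threshold, pilot median), PR 1.25.
* **sATT recovery**: occupancies 0.1/0.3/0.5/0.8 at 600 trials; easy
  levels {50, 70, 90}°; near-perfect high state (lapse 0.002) versus a
  heavily lapse-prone low state (lapse 0.40), separating the local-PR
  modes by > 4 SD; nearly regular dwells (gamma shape 100) with two
  high/low cycles per session.
* **cATT recovery**: a metric-level generator draws RT/TD/PS from normal
  distributions and shifts cued trials by amounts solved analytically
  (fixed-point on the pooled-mixture percentiles) so the population cued
  CL deficit equals the configured fraction of the grand mean.

## Known limitations

* **PR-score thresholds are late and noisy.**  For any commit-style
  trajectory population, the left/right Cohen's D depends on the commit
  rate q alone (the between-side mixture dominates the pooled SD), so the
  PR = 1.25 crossing sits at q ≈ 0.76 — a fixed ~2.3 logits above the
  hit-index criterion crossing at q = 0.6, i.e. ~3° at slope 0.8/°.
  Together with the sparse high-ΔOri level grid (20/30/50°), per-seed
  averaged-threshold errors at 300 trials have SD ≈ 1–2° (larger near an
  18° threshold); the three-metric average recovers true thresholds
  essentially without bias but not within ±2° in 95 % of single sessions.
* **Windowed state labels erode short episodes.**  Any low-state trial
  inside a 15-trial local-PR window collapses Cohen's D, so high-alert
  episodes lose up to a window length at each boundary; recovered sATT is
  biased low by roughly (window × n_high_episodes)/n_trials (≈ 0.03–0.07
  for 2 dwell cycles in 600 trials, worst at low occupancies where
  episodes barely exceed the window).  Fewer, longer episodes reduce the
  erosion but make the realised occupancy of a single session deviate
  more from the configured rate.  At 80 % occupancy the pooled
  distribution also approaches the bimodality coefficient's detection
  limit (an 80/20 mixture at the separation the window statistics allow
  hovers near BC = 0.55).
* The bootstrap criterion procedure inherits the cohort's difficulty mix:
  cohorts dominated by easy (or hard) levels shift the pooled median SEM
  and hence the criterion.
* The variance-ratio cut assumes modes of commensurate width; a much
  wider mode pulls the cut into itself.
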