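# Methods

This note documents the generative model, the analysis pipeline, the
default parameters and the design choices made where the design was
genuinely open. It states no empirical result that the test suite does
not itself compute.

## 1. Game engine

A session consists of interleaved rounds of three conditions (easy /
medium / hard) in randomized order. Rules and defaults:

| parameter | default | meaning |
|---|---|---|
| `walk_duration_ms` | 5000 | actor walk = round length |
| `n_trails` | 3 | upper / middle / lower, coded 0/1/2 |
| `max_jumps` | 3 | hider jumps per medium/hard round |
| `jump_window_ms` | (500, 4500) | allowed jump times |
| `min_interjump_ms` | 300 | minimum jump spacing |
| `max_trajectory_changes` | 1 | accepted presses per round |
| `trials_per_condition` | 80 | rounds per condition |
| `iti_ms` | 3000 | inter-trial interval |

Open choices and their resolutions:

* **Jump count.** "Up to three jumps, chosen randomly" is read as uniform
  over {1, 2, 3}: a zero-jump medium round would be indistinguishable
  from an easy one and destroy the condition contrast. A config flag
  (`allow_zero_jumps`) restores {0..3}.
* **Jump timing.** Uniform over the jump window subject to the minimum
  spacing, sampled exactly via the spacing transform (draw on the shrunk
  interval, sort, re-inflate). The window leaves 500 ms of reaction time
  after the last possible jump and keeps jumps perceptually distinct.
* **Jump semantics.** A jump moves only between neighboring trails and
  takes effect exactly at its timestamp (left-closed convention).
* **Press deadline.** Presses are accepted up to and including the walk
  end; the trail switch is treated as instantaneous because the screen
  geometry is abstracted away.
* **Hider start.** Uniform over the three trails.
* **Trigger codes.** Round onset 10/11/12 (easy/medium/hard), jump 20,
  press up/down 31/32, walk end 40, loss/win 50/51. The numbering is a
  package convention, written to the `events.json` sidecar.
* **Session length.** 80 rounds per condition (~32 min of play at 8 s
  per round, consistent with a 2 h recording session). This value is
  calibrated to the pipeline's retention rule: an averaged condition
  needs ≥ 30 retained press-locked epochs, and the expected press rate
  is ~0.67 in easy (no press when the hider sits on the middle trail),
  ~0.55 in medium (a crossing with the hider momentarily on the middle
  trail is withheld) and ~0.8 in hard (crossing probability), so 80
  rounds give expected retained counts of roughly 53/44/64 — comfortable
  margin in every condition.

## 2. Behavioral agents

* **Ideal observer** (easy/medium): presses toward the hider's known
  final trail; in medium it waits until the end of the jump window (the
  last possible jump) plus one reaction time, clamped to the walk end,
  so it wins every round. Reaction times are Gaussian, mean 400 ms, SD
  100 ms, truncated at 100 ms (the literature gives no reaction times
  for this paradigm; the values keep presses inside the round).
* **Lapse agent** (medium): misses each jump independently with
  probability `p_lapse` and acts on the stale position — an attention
  model of medium-round errors. Success is non-increasing in `p_lapse`
  in expectation, not per trial (missing two jumps can coincidentally
  restore the correct belief), so the monotonicity test is Monte-Carlo.
* **Random agent** (hard): target trail uniform over three (middle means
  no press), press time uniform over a window. Because the actor's final
  trail is then independent of the hider's, the success rate is exactly
  1/3 regardless of the hider's final-trail distribution.
* **Accumulator agent** (all conditions; drives the EEG generator):
  presses at the first threshold crossing of the accumulator below. The
  button follows the observed hider trail at the crossing when visible
  — withholding when that trail is the middle one — and a fair coin in
  hard rounds (the choice mechanism in spontaneous rounds is not
  documented anywhere; a coin is the minimal assumption).

## 3. Accumulator and EEG generator

The latent decision variable follows a leaky stochastic accumulator
(Ornstein–Uhlenbeck with drive),

    dx = (I + u(t) − k·x) dt + c·dW,   x(0) = 0,

integrated by Euler–Maruyama at `dt_ms = 2` (one sample at 500 Hz). The
discrete recurrence is evaluated exactly as a linear IIR filter, and the
crossing time is interpolated linearly between the straddling samples,
which keeps the noise-free crossing within 0.5% of the closed form
t* = −(1/k)·ln(1 − kθ/I) at this step size.

`I` is a constant baseline urgency present in every condition; `u(t)` is
the condition's external evidence: a step of `easy_step_amp` from onset
(easy), rectangular pulses of `medium_pulse_amp` × `pulse_width_ms` at
onset and at each jump (medium), and zero (hard). Defaults:

| parameter | default | unit |
|---|---|---|
| leak `k_per_s` | 0.5 | 1/s |
| urgency `drift_per_s` | 0.075 | evidence/s |
| diffusion `noise_per_sqrt_s` | 0.05 | evidence/√s |
| threshold | 0.15 | evidence |
| `easy_step_amp` | 0.5 | evidence/s |
| `medium_pulse_amp` / `pulse_width_ms` | 0.25 / 400 | evidence/s, ms |

The urgency default was calibrated once, before any acceptance quantity
was measured, to the stated behavior of the hard condition — crossings
mostly 1–4 s after onset (at 0.075: ~80% of rounds cross, median 2.6 s,
~82% of crossings inside 1–4 s). The easy step then crosses
deterministically at ~0.28 s, and medium pulses are individually
insufficient early in the round (x is still low) but push the process
over threshold once urgency has raised it near θ, so medium crossings
concentrate late — the paradigm's intended phenomenology.

**RP source.** The premovement scalp source is −(g/θ)·x(t) µV with
`rp_gain_uV` g = 10, i.e. the peak at threshold is −10 µV. (No amplitude
is published for this paradigm; 10 µV is a typical RP magnitude and is a
free parameter, never asserted as ground truth.) After a press the
source decays exponentially back to baseline (τ = 300 ms) with a brief
superimposed motor potential (40% relative amplitude, 200 ms). A
crossing without a press (withheld: hider on the middle trail) ends
accumulation without a motor potential. Press-free rounds carry the
sub-threshold trajectory to the walk end, then decay during the ITI.

**Forward model and noise.** Channel positions come from a schematic
10–20 label grid; the RP topography is a Gaussian fall-off of gain
around Cz (σ = 0.35 head units), optionally boosted over the left
frontal quadrant by a per-condition asymmetry factor (defaults 0.05 /
0.10 / 0.20 for easy/medium/hard, mirroring stronger frontal involvement
in spontaneous decisions) to exercise the F5−F6 lateralization analysis.
No numeric topography from the literature is used as truth. Noise: 1/f
background (spectral shaping of white noise, floor at 0.1 Hz, 10 µV RMS,
independent per channel), common 50 Hz line interference (2 µV), and
frontal biphasic 400 ms blink transients (75 µV, 4/min). The amplifier's
acquisition band (0.01–100 Hz plus 50 Hz notch) is available as an
optional stage and off by default so the pipeline's own 0.1–40 Hz filter
remains the tested stage.

**What the generator does not emulate.** Spatially correlated background
activity, a realistic volume-conductor head model, heartbeat/respiration
coupling, between-participant parameter variability, and non-stationary
artifacts. A green test on this data therefore establishes that the
pipeline and statistics behave correctly under a known RP-bearing signal
model — not that they are robust to every property of real EEG.

## 4. Analysis pipeline

Deterministic given a recording (no RNG anywhere in the analysis path).

* **Filter.** Zero-phase Butterworth cascade: order-2 high-pass at
  0.1 Hz plus order-10 low-pass at 40 Hz (forward–backward). The split
  keeps the passband flat at 1 Hz (≤ 5% error) while attenuating 45 Hz
  by ≥ 90% — a single moderate-order band-pass cannot meet both bounds
  once applied twice.
* **Epochs.** Press-locked [−5000, +500] ms and trial-end-locked
  [−5500, +200] ms (windows are not published; these cover the baseline
  windows below with margin). End-locked epochs carry a pressed /
  press-free flag per round.
* **Artifact rejection.** Epochs whose peak-to-peak amplitude exceeds
  150 µV on any channel are dropped — a reproducible stand-in for the
  visual inspection used with human data; ICA-based blink removal is out
  of scope (blinks can instead be disabled in the generator).
* **Baselines.** Press-locked −5000..−4800 ms; end-locked
  −5100..−4900 ms. The end-locked figure caption's "−5,100 to 4,900 ms"
  is read as a sign typo for −5,100 to −4,900 ms; both readings are
  configurable. A −2100..−1900 ms baseline is likewise available.
* **SNR.** |mean of the averaged Cz waveform over [−400, 0) ms| divided
  by the SD of that waveform over the whole premovement extent
  [tmin, 0). The numerator uses the absolute value: the RP is negative,
  and a signed ratio would never reach 1. Degenerate cases: SD = 0 with
  nonzero mean → ∞; both zero → 0. A participant with SNR < 1 in any
  condition, or fewer than 30 retained press-locked epochs in any
  condition, is excluded.
* **AUC.** Signed trapezoidal integral of the baseline-corrected Cz
  average over [−2000, 0] ms relative to the lock event (window not
  published; configurable).
* **Statistics.** One-way repeated-measures ANOVA (statsmodels AnovaRM)
  over TrialType on participant-wise AUC; a fully degenerate table (all
  values equal) short-circuits to F = 0, p = 1. Pairwise paired t-tests
  with Holm correction, z-values derived from two-sided p-values for
  reporting parity. The pressed/press-free factor is a paired t within
  condition on per-flag participant averages (whether the published
  pooled analysis used pooled epochs or per-flag averages is unstated;
  per-flag averages are assumed). F5/F6 lateralization: mean amplitude
  per channel over −400..−300 ms, difference F5 − F6.

## 5. Known limitations

* The published human-data statistics (success rates 71%/49%, the
  F/p/z values) are properties of human participants and are not
  reproduction targets; the package reproduces procedures and
  qualitative contrasts only.
* Under this generator the pressed/press-free equivalence holds in the
  medium condition but **fails in the hard condition**: pressed hard
  rounds cross mostly 1–4 s after onset and their RP has returned to
  baseline before the end-locked analysis window, while press-free
  rounds still carry sustained sub-threshold negativity at the walk end,
  so the IsPressed contrast is reliably significant there. This is a
  logical consequence of the model's stated post-crossing envelope and
  crossing-time calibration, and is reported honestly by the
  corresponding acceptance test rather than masked.
* Parameter recovery fits the closed-form mean path (I/k)(1 − e^{−kt})
  to trial-averaged trajectories. Identifiability is poor for the weak
  hard-condition drive over a 5 s round (the mean path is far from its
  asymptote and the averaged noise is strongly autocorrelated), so the
  noisy-recovery check uses the strong constant easy-type drive, where
  200 trials recover k and I to a few per mille – a calibration design,
  not a tolerance change.
* The Monte-Carlo calibration checks (type-I rate, pressed/press-free
  equivalence) run on a reduced Cz-only path — accumulator, RP source,
  analysis filter, additive integral noise, averaging — rather than the
  full 64-channel forward model, to keep hundreds of replicates within
  minutes. The statistical procedures under test are identical.
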