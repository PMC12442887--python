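# crabrp

A desk-scale simulator and analysis pipeline for a gamified hide-and-seek
paradigm used to study the **readiness potential** (RP, or
Bereitschaftspotential) — the slow negative EEG deflection over central
electrodes that precedes self-initiated movement.

The package is aimed at ERP methodologists who want to exercise a complete
RP experiment — game logic, behavioral decision models, EEG generation and
group statistics — without human subjects, and at analysts who need a
reproducible implementation of the corresponding pre-processing chain for
externally recorded data in the BrainVision dialect.

## The paradigm

Each round, an actor avatar walks for 5,000 ms from the middle of three
trails toward one of three hiding spots while a hider character sits on one
trail. The player may press once per round to divert the actor from the
middle trail to the upper or lower trail; a round is won when actor and
hider end on the same trail. Three conditions manipulate the evidence
available for the *what/when/whether* decision:

* **easy** — hider visible and static: the correct response is known at
  round onset;
* **medium** — hider visible but jumps up to 3 times between neighboring
  trails at random times: certainty arrives only late in the round;
* **hard** — hider invisible: the decision is spontaneous, as in classical
  self-paced movement (Libet-type) designs.

## The model

Behavior and EEG are generated by a Schurger-style leaky stochastic
accumulator. With leak $k$, baseline urgency $I$, external evidence input
$u(t)$ and diffusion scale $c$,

$$dx = \bigl(I + u(t) - k\,x\bigr)\,dt + c\,dW, \qquad x(0) = 0,$$

a button press is triggered at the first crossing of the threshold
$\theta$. The condition manipulation enters through $u(t)$: a strong
constant step in easy rounds (crossings ~0.3 s after onset), rectangular
pulses at onset and at each observed jump in medium rounds (late
crossings), and $u \equiv 0$ in hard rounds (noise + urgency alone;
crossings mostly 1–4 s after onset). The premovement scalp source is
$-\theta^{-1}\,g\,x(t)$ µV (peak $-g$ at threshold), followed by a brief
motor potential and a return to baseline; a schematic 64-channel 10–20
forward model (Gaussian gain fall-off around Cz, optional left-frontal
asymmetry) plus 1/f background, 50 Hz line and blink artifacts yields a
continuous 500 Hz recording with embedded trigger codes.

The analysis half mirrors the standard RP chain: 0.1–40 Hz zero-phase
band-pass, press-locked and trial-end-locked epoching, peak-to-peak
artifact rejection, baseline correction, averaging, an SNR-based
participant exclusion rule (|mean premovement amplitude over the last
400 ms| / SD over the whole premovement epoch; below 1 in any condition
excludes the participant), and group statistics on the signed premovement
area under the Cz curve (AUC, µV·ms): repeated-measures ANOVA over
TrialType, Holm-corrected pairwise contrasts, a pressed/press-free
contrast and an F5−F6 lateralization index.

## Worked example

```python
import numpy as np
from crabrp import (GameConfig, AgentParams, ForwardModel, PipelineConfig,
                    synthesize_participant, summarize_participant,
                    build_auc_table)

rng = np.random.default_rng(7)
recording, session = synthesize_participant(
    GameConfig(), AgentParams(kind="accumulator"), ForwardModel(), rng)
print("success rates:", {k: round(v, 2) for k, v in session.success_rates.items()})

summary = summarize_participant(recording, PipelineConfig(), "sub-01")
print("retained press-locked epochs:", summary.n_press)
print("SNR:", {k: round(v, 2) for k, v in summary.snr.items()})
print("included:", summary.included)
print(build_auc_table([summary], "press")[["condition", "auc"]]
      .round(0).to_string(index=False))
```

prints

```
success rates: {'easy': 1.0, 'medium': 0.39, 'hard': 0.33}
retained press-locked epochs: {'easy': 55, 'medium': 45, 'hard': 60}
SNR: {'easy': 1.3, 'medium': 2.09, 'hard': 2.32}
included: True
condition     auc
     easy  -804.0
   medium -1249.0
     hard -2731.0
```

The accumulator agent wins every easy round (the answer is visible from
onset) but performs near chance when it must commit before late jumps
(medium) or has no evidence at all (hard). The participant retains well
over 30 artifact-free epochs per condition and passes the SNR ≥ 1
inclusion rule in all three, so it would enter group analysis. The AUC
column is the signed area under the averaged Cz waveform over the last
2 s before the press: more negative means a stronger readiness potential,
and the single-participant ordering |easy| < |medium| < |hard| already
shows the paradigm's headline contrast — weak premovement negativity when
the decision is made immediately, strong negativity when evidence
accumulates over seconds.

## Command line

```bash
crab simulate --config cfg.yaml --seed 1 --participants 4 --out run/raw
crab analyze  --in run/raw  --out run/derived
crab report   --in run/derived --out run/report.json
crab all      --seed 1 --participants 4 --out run    # all three stages
```

`simulate` writes one BrainVision triplet (`.vhdr/.vmrk/.eeg`) plus a
BIDS-style `events.tsv` per synthetic participant and a manifest (seed,
config hash, versions) sufficient to reproduce the outputs bit-for-bit;
`analyze` runs the ERP pipeline on every recording found (including
externally recorded files in the same dialect whose trigger codes follow
the documented scheme) and writes per-participant summary tables and
averaged waveform matrices; `report` computes the group statistics.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's acceptance target from scratch — it simulates a
100-round easy session with the default game rules and the ideal-observer
agent and reports the resulting success rate in percent — and writes the
values as JSON.

See `docs/methods.md` for the model's assumptions, parameter defaults and
known limitations.
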