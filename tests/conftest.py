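"""Shared fixtures and reduced-scale simulation helpers.

The Cz-only helpers mirror the full generative chain (accumulator ->
RP source -> additive noise -> trial averaging -> AUC) without the
64-channel forward projection, so Monte-Carlo calibration checks with
hundreds of replicates stay fast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crabrp import (
    AccumulatorParams,
    AgentParams,
    ForwardModel,
    GameConfig,
    condition_evidence,
    make_trial,
    rp_source,
    simulate_accumulator,
    simulate_accumulator_batch,
)

# Effective per-trial noise on a 2-second AUC integral at Cz:
# ~10 µV band-limited background with a ~100 ms correlation time gives an
# integral SD on the order of a few thousand µV·ms.
TRIAL_AUC_NOISE_SD = 4000.0


@pytest.fixture(scope="session")
def small_game() -> GameConfig:
    return GameConfig(trials_per_condition=5)


@pytest.fixture(scope="session")
def quiet_forward() -> ForwardModel:
    """Noise-free forward model for identity checks."""
    return ForwardModel(noise_1f_uV=0.0, line_50hz_uV=0.0,
                        blink_rate_per_min=0.0,
                        frontal_asym={"easy": 0.0, "medium": 0.0, "hard": 0.0})


@pytest.fixture(scope="session")
def default_participant():
    """One full default-parameter synthetic participant (shared: slow)."""
    from crabrp import synthesize_participant

    rng = np.random.default_rng(7)
    recording, session = synthesize_participant(
        GameConfig(), AgentParams(kind="accumulator"), ForwardModel(), rng)
    return recording, session


# ---------------------------------------------------------------------------
# Reduced Cz-only AUC simulation
# ---------------------------------------------------------------------------

def _press_locked_auc(times_ms, source, crossing_ms, window_ms=(-2000.0, 0.0)):
    """AUC of a single-trial source in a press-locked window; the source
    is zero before round onset."""
    dt = times_ms[1] - times_ms[0]
    rel = times_ms - crossing_ms
    mask = (rel >= window_ms[0]) & (rel <= window_ms[1])
    # pad with zeros for the part of the window preceding round onset
    n_window = int(round((window_ms[1] - window_ms[0]) / dt)) + 1
    vals = source[mask]
    if vals.size < n_window:
        vals = np.concatenate([np.zeros(n_window - vals.size), vals])
    return float(np.trapezoid(vals, dx=dt))


def _pipeline_filter(source: np.ndarray, dt_ms: float) -> np.ndarray:
    """Apply the analysis band-pass to an isolated single-trial source
    (embedded in 6 s of silence on both sides, as in a quiet recording)."""
    from scipy import signal

    fs = 1000.0 / dt_ms
    sos = np.vstack([
        signal.butter(2, 0.1, btype="highpass", fs=fs, output="sos"),
        signal.butter(10, 40.0, btype="lowpass", fs=fs, output="sos"),
    ])
    pad = int(round(6000.0 / dt_ms))
    full = np.concatenate([np.zeros(pad), source, np.zeros(pad)])
    return signal.sosfiltfilt(sos, full)[pad:pad + source.size]


def cz_trial_aucs(condition: str, params: AccumulatorParams, n_trials: int,
                  rng: np.random.Generator, game: GameConfig | None = None,
                  lock: str = "press", rp_gain_uV: float = 10.0,
                  filtered: bool = True):
    """Per-trial Cz AUC values from the accumulator + RP source chain.

    Mirrors the full generator's press semantics: a crossing leads to a
    press unless the hider sits on the middle trail at the crossing
    (visible conditions), in which case the agent withholds (press-free,
    no motor potential).  Returns ``(aucs, pressed)``; for the press lock
    only pressed trials contribute.  Additive Gaussian noise models the
    residual EEG background in the single-trial integral.
    """
    from crabrp.game_engine import TRAIL_MIDDLE, hider_trail_at

    game = game or GameConfig()
    walk = float(game.walk_duration_ms)
    aucs, pressed_flags = [], []
    for _ in range(n_trials):
        trial = make_trial(game, condition, rng)
        u = condition_evidence(trial, params)
        times, x, crossing = simulate_accumulator(params, u, walk, rng)
        pressed = crossing is not None
        if pressed and trial.hider_visible:
            pressed = hider_trail_at(trial, crossing, walk) != TRAIL_MIDDLE
        source = rp_source(times, x, crossing, rp_gain_uV, params.threshold,
                           motor_amp_frac=0.4 if pressed else 0.0)
        if filtered:
            source = _pipeline_filter(source, params.dt_ms)
        if lock == "press":
            if not pressed:
                continue
            auc = _press_locked_auc(times, source, crossing)
            pressed_flags.append(True)
        else:
            auc = float(np.trapezoid(source[times >= walk - 2000.0],
                                     dx=times[1] - times[0]))
            pressed_flags.append(pressed)
        aucs.append(auc + rng.normal(0.0, TRIAL_AUC_NOISE_SD))
    return np.array(aucs), np.array(pressed_flags, dtype=bool)


def null_auc_table(n_participants: int, n_trials: int,
                   rng: np.random.Generator) -> pd.DataFrame:
    """AUC table in which the three condition labels share one generator
    (hard-type: no external evidence) — the TrialType null."""
    params = AccumulatorParams()
    rows = []
    for p in range(n_participants):
        pid = f"sub-{p:02d}"
        for cond in ("easy", "medium", "hard"):
            _, x, crossings = simulate_accumulator_batch(
                params, 0.0, 5000.0, rng, n_trials)
            times = np.arange(x.shape[1]) * params.dt_ms
            vals = []
            for i in range(n_trials):
                c = crossings[i]
                if np.isnan(c):
                    continue
                src = rp_source(times, x[i], c, 10.0, params.threshold)
                vals.append(_press_locked_auc(times, src, c)
                            + rng.normal(0.0, TRIAL_AUC_NOISE_SD))
            rows.append((pid, cond, "press", "pooled",
                         float(np.mean(vals)) if vals else 0.0))
    return pd.DataFrame(rows, columns=["participant", "condition", "lock",
                                       "pressed", "auc"])
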