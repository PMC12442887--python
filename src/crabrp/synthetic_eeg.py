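"""Synthetic EEG with condition-dependent readiness potentials.

The generative chain is:

1. A Schurger-style leaky stochastic accumulator integrates evidence,
   ``dx = (I + u(t) - k·x) dt + c·dW``, where ``I`` is a constant baseline
   urgency, ``u(t)`` the condition's external evidence input and ``c`` the
   diffusion scale.  The first threshold crossing triggers the button
   press.
2. The premovement scalp source is the (negated) accumulator trajectory:
   a slow negative drift peaking at the press — the readiness potential —
   followed by a brief motor potential and a return to baseline.
3. A schematic 64-channel 10–20 forward model projects the source to the
   scalp with a Gaussian fall-off centered on Cz (plus an optional left
   frontal asymmetry), and adds 1/f background noise, 50 Hz line noise and
   blink artifacts.

Condition evidence inputs (the paradigm's manipulation):

``easy``
    A strong constant step from round onset — evidence crosses a low
    effective barrier almost immediately.
``medium``
    Discrete rectangular pulses at onset and at each observed hider jump —
    individually insufficient, so crossings concentrate late in the round.
``hard``
    No external evidence at all; only urgency plus noise drive the
    accumulator (spontaneous, Libet-like decisions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import signal

from .game_engine import EventStream

__all__ = [
    "AccumulatorParams",
    "ForwardModel",
    "EEGRecording",
    "CHANNELS_64",
    "channel_position",
    "topography",
    "condition_evidence",
    "simulate_accumulator",
    "simulate_accumulator_batch",
    "closed_form_crossing_time_s",
    "deterministic_trajectory",
    "fit_accumulator",
    "rp_source",
    "pink_noise",
    "synthesize_participant",
]


# ---------------------------------------------------------------------------
# Accumulator
# ---------------------------------------------------------------------------

@dataclass
class AccumulatorParams:
    """Leaky stochastic accumulator parameters.

    Units: ``k_per_s`` [1/s] leak, ``drift_per_s`` [evidence/s] baseline
    urgency present in every condition, ``noise_per_sqrt_s`` [evidence/√s]
    diffusion scale, ``threshold`` [evidence] crossing barrier,
    ``dt_ms`` [ms] Euler–Maruyama step.

    Defaults are chosen so that with no external evidence (hard rounds)
    crossings occur mostly 1–4 s after onset, while the easy-round step
    input crosses within ~300 ms of onset.
    """

    k_per_s: float = 0.5
    drift_per_s: float = 0.075
    noise_per_sqrt_s: float = 0.05
    threshold: float = 0.15
    dt_ms: float = 2.0
    easy_step_amp: float = 0.5
    medium_pulse_amp: float = 0.25
    pulse_width_ms: float = 400.0

    def __post_init__(self) -> None:
        if self.k_per_s < 0:
            raise ValueError(f"k_per_s must be >= 0, got {self.k_per_s}")
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if self.noise_per_sqrt_s < 0:
            raise ValueError(f"noise_per_sqrt_s must be >= 0, got {self.noise_per_sqrt_s}")
        if self.dt_ms <= 0:
            raise ValueError(f"dt_ms must be > 0, got {self.dt_ms}")


def condition_evidence(trial, params: AccumulatorParams) -> Callable[[np.ndarray], np.ndarray]:
    """External evidence input u(t) for a round, as a function of time.

    ``trial`` needs ``condition`` and (for medium rounds) ``jump_schedule``
    attributes; both :class:`~crabrp.game_engine.TrialSpec` and
    :class:`~crabrp.game_engine.Observation` qualify.  Returned callable
    maps a time array [ms] to evidence units/s; it excludes the baseline
    urgency ``drift_per_s``, which the integrator adds itself — hard
    rounds therefore have u(t) identically zero.
    """
    cond = trial.condition
    if cond == "hard":
        return lambda t_ms: np.zeros_like(np.asarray(t_ms, dtype=float))
    if cond == "easy":
        amp = params.easy_step_amp
        return lambda t_ms: np.where(np.asarray(t_ms, dtype=float) >= 0.0, amp, 0.0)

    # medium: rectangular pulses at onset and at each jump
    starts = [0.0] + [j.time_ms for j in trial.jump_schedule]
    amp, width = params.medium_pulse_amp, params.pulse_width_ms

    def u(t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        for s in starts:
            out += np.where((t >= s) & (t < s + width), amp, 0.0)
        return out

    return u


def _integrate(inputs: np.ndarray, decay: float) -> np.ndarray:
    """Exact discrete recurrence x[n+1] = decay*x[n] + inputs[n], x[0]=0.

    Returns the full path including x[0]; implemented as an IIR filter so
    large batches stay fast.  ``inputs`` may be 1-D or (trials, steps).
    """
    y = signal.lfilter([1.0], [1.0, -decay], inputs, axis=-1)
    pad = np.zeros(inputs.shape[:-1] + (1,))
    return np.concatenate([pad, y], axis=-1)


def _first_crossing_ms(times_ms: np.ndarray, x: np.ndarray,
                       threshold: float) -> Optional[float]:
    idx = np.nonzero(x >= threshold)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(times_ms[0])
    # linear interpolation between the straddling samples
    x0, x1 = x[i - 1], x[i]
    frac = (threshold - x0) / (x1 - x0) if x1 != x0 else 1.0
    return float(times_ms[i - 1] + frac * (times_ms[i] - times_ms[i - 1]))


def simulate_accumulator(params: AccumulatorParams,
                         evidence_fn: Callable[[np.ndarray], np.ndarray],
                         duration_ms: float,
                         rng: np.random.Generator,
                         ) -> tuple[np.ndarray, np.ndarray, Optional[float]]:
    """Euler–Maruyama integration of the leaky accumulator from x(0)=0.

    Returns ``(times_ms, trajectory, crossing_ms)``; the trajectory runs
    for the full duration regardless of crossing, and ``crossing_ms`` is
    the first time x(t) >= threshold (interpolated between steps), or
    ``None`` if the threshold is never reached before the deadline.
    """
    dt_s = params.dt_ms / 1000.0
    n = int(round(duration_ms / params.dt_ms))
    times_ms = np.arange(n + 1) * params.dt_ms
    drive = params.drift_per_s + evidence_fn(times_ms[:-1])
    inputs = drive * dt_s
    if params.noise_per_sqrt_s > 0:
        inputs = inputs + params.noise_per_sqrt_s * math.sqrt(dt_s) * rng.standard_normal(n)
    x = _integrate(inputs, 1.0 - params.k_per_s * dt_s)
    crossing = _first_crossing_ms(times_ms, x, params.threshold)
    return times_ms, x, crossing


def simulate_accumulator_batch(params: AccumulatorParams,
                               evidence: np.ndarray,
                               duration_ms: float,
                               rng: np.random.Generator,
                               n_trials: int,
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized accumulator for many trials sharing one evidence input.

    ``evidence`` is the drive u(t) sampled at the step grid (length
    duration/dt) or a scalar.  Returns ``(times_ms, X, crossings_ms)``
    with X of shape (n_trials, n_steps+1) and NaN for trials that never
    cross.
    """
    dt_s = params.dt_ms / 1000.0
    n = int(round(duration_ms / params.dt_ms))
    times_ms = np.arange(n + 1) * params.dt_ms
    drive = params.drift_per_s + np.broadcast_to(np.asarray(evidence, dtype=float), (n,))
    inputs = drive * dt_s + params.noise_per_sqrt_s * math.sqrt(dt_s) \
        * rng.standard_normal((n_trials, n))
    x = _integrate(inputs, 1.0 - params.k_per_s * dt_s)
    crossings = np.full(n_trials, np.nan)
    any_hit = (x >= params.threshold).any(axis=1)
    for i in np.nonzero(any_hit)[0]:
        crossings[i] = _first_crossing_ms(times_ms, x[i], params.threshold)
    return times_ms, x, crossings


def closed_form_crossing_time_s(k_per_s: float, drive_per_s: float,
                                threshold: float) -> float:
    """Noise-free crossing time of the leaky integrator under constant drive.

    x(t) = (I/k)(1 − e^{−kt}) reaches θ at t* = −(1/k)·ln(1 − kθ/I),
    defined only when I > kθ.  With k → 0 this degenerates to θ/I.
    """
    if drive_per_s <= k_per_s * threshold:
        raise ValueError("constant drive never crosses: I <= k*theta")
    if k_per_s == 0:
        return threshold / drive_per_s
    return -math.log(1.0 - k_per_s * threshold / drive_per_s) / k_per_s


def deterministic_trajectory(times_s: np.ndarray, k_per_s: float,
                             drive_per_s: float) -> np.ndarray:
    """Mean path of the accumulator under constant drive, x(0)=0."""
    t = np.asarray(times_s, dtype=float)
    if k_per_s == 0:
        return drive_per_s * t
    return (drive_per_s / k_per_s) * (1.0 - np.exp(-k_per_s * t))


def fit_accumulator(times_ms: np.ndarray, mean_trajectory: np.ndarray,
                    ) -> tuple[float, float]:
    """Recover (k, I) by least squares on an averaged trajectory.

    The mean of the linear SDE equals the deterministic path
    (I/k)(1 − e^{−kt}), so fitting that form to a trial average recovers
    the leak and drive.  Returns ``(k_per_s, drift_per_s)``.
    """
    from scipy.optimize import curve_fit

    t_s = np.asarray(times_ms, dtype=float) / 1000.0
    y = np.asarray(mean_trajectory, dtype=float)
    slope0 = max((y[-1] - y[0]) / max(t_s[-1], 1e-9), 1e-6)
    popt, _ = curve_fit(
        lambda t, k, i: deterministic_trajectory(t, k, i),
        t_s, y, p0=(0.5, slope0), maxfev=20000,
    )
    return float(popt[0]), float(popt[1])


# ---------------------------------------------------------------------------
# RP source waveform
# ---------------------------------------------------------------------------

def rp_source(times_ms: np.ndarray, trajectory: np.ndarray,
              crossing_ms: Optional[float], rp_gain_uV: float,
              threshold: float, motor_amp_frac: float = 0.4,
              motor_width_ms: float = 200.0,
              return_tau_ms: float = 300.0) -> np.ndarray:
    """Single-trial cortical source waveform in µV (negative-going RP).

    Before the crossing the source tracks the accumulator,
    ``−rp_gain_uV·x/θ`` (so the amplitude at threshold is −rp_gain_uV).
    After the crossing a brief motor potential (a Hann bump of
    ``motor_amp_frac`` relative amplitude) is superimposed on an
    exponential return to baseline.  Press-free trials (no crossing)
    carry the sub-threshold trajectory for the whole round.
    """
    t = np.asarray(times_ms, dtype=float)
    x = np.asarray(trajectory, dtype=float)
    gain = rp_gain_uV / threshold
    source = -gain * x
    if crossing_ms is None:
        return source
    post = t > crossing_ms
    if not post.any():
        return source
    i0 = int(np.argmax(post))
    peak = source[max(i0 - 1, 0)]
    tau = (t[post] - crossing_ms) / return_tau_ms
    source[post] = peak * np.exp(-tau)
    # motor potential: short extra negativity right after the press
    in_bump = post & (t <= crossing_ms + motor_width_ms)
    if in_bump.any():
        phase = (t[in_bump] - crossing_ms) / motor_width_ms
        source[in_bump] += peak * motor_amp_frac * np.sin(np.pi * phase) ** 2
    return source


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

# Standard 64-channel extended 10-20 cap (BrainAmp-style ordering).
CHANNELS_64 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10", "AF7",
    "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6", "FT9", "FT7", "FC3", "FC4",
    "FT8", "FT10", "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
)

_ROW_Y = {"Fp": 4, "AF": 3, "F": 2, "FT": 1, "FC": 1, "T": 0, "C": 0,
          "TP": -1, "CP": -1, "P": -2, "PO": -3, "O": -4}


def channel_position(label: str) -> tuple[float, float]:
    """Schematic 2-D scalp position (x: left −1 .. right +1, y: back −1 ..
    front +1) derived from the 10–20 label grid; Cz sits at the origin."""
    i = 0
    while i < len(label) and label[i].isalpha() and label[i] != "z":
        i += 1
    prefix, suffix = label[:i], label[i:]
    if prefix not in _ROW_Y:
        raise ValueError(f"unrecognized channel label {label!r}")
    y = _ROW_Y[prefix] / 4.0
    if suffix == "z":
        x = 0.0
    else:
        n = int(suffix)
        side = -1.0 if n % 2 == 1 else 1.0
        x = side * math.ceil(n / 2) / 5.0
    return x, y


@dataclass
class ForwardModel:
    """Projection of the RP source to the scalp plus noise model.

    The RP topography is a Gaussian fall-off (width ``sigma_head`` in
    normalized head units) of per-channel gain around Cz, optionally
    boosted over the left frontal quadrant by a per-condition asymmetry
    factor (larger in hard rounds, mirroring stronger frontal involvement
    for spontaneous decisions).  Noise: 1/f background (independent per
    channel), common 50 Hz line interference and frontal blink artifacts.
    """

    channels: tuple[str, ...] = CHANNELS_64
    fs_hz: float = 500.0
    sigma_head: float = 0.35
    rp_gain_uV: float = 10.0  # source amplitude at threshold crossing
    frontal_asym: dict = field(
        default_factory=lambda: {"easy": 0.05, "medium": 0.10, "hard": 0.20}
    )
    noise_1f_uV: float = 10.0
    line_50hz_uV: float = 2.0
    blink_rate_per_min: float = 4.0
    blink_amp_uV: float = 75.0
    pre_pad_ms: float = 6000.0
    post_pad_ms: float = 2000.0
    apply_acquisition_band: bool = False  # 0.01–100 Hz + 50 Hz notch

    def __post_init__(self) -> None:
        if len(self.channels) != 64:
            raise ValueError(f"expected 64 channels, got {len(self.channels)}")
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be > 0, got {self.fs_hz}")
        for ch in ("Cz", "F5", "F6"):
            if ch not in self.channels:
                raise ValueError(f"montage must include {ch}")


def topography(forward: ForwardModel, condition: str) -> np.ndarray:
    """Per-channel gain of the RP source for one condition (max at Cz)."""
    pos = np.array([channel_position(c) for c in forward.channels])
    d2 = (pos ** 2).sum(axis=1)
    w = np.exp(-d2 / (2.0 * forward.sigma_head ** 2))
    asym = forward.frontal_asym.get(condition, 0.0)
    if asym:
        fl = np.maximum(0.0, -pos[:, 0]) * np.maximum(0.0, pos[:, 1])
        fmax = fl.max()
        if fmax > 0:
            w = w * (1.0 + asym * fl / fmax)
    return w


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def pink_noise(n_channels: int, n_samples: int, fs_hz: float, rms_uV: float,
               rng: np.random.Generator, f_floor_hz: float = 0.1) -> np.ndarray:
    """1/f-power background noise by spectral shaping of white noise.

    The amplitude spectrum is scaled by f^(−1/2) with a floor below
    ``f_floor_hz`` (the acquisition high-pass region); each channel is
    independent and normalized to ``rms_uV``.
    """
    if rms_uV == 0:
        return np.zeros((n_channels, n_samples), dtype=np.float32)
    from scipy import fft as sfft

    white = rng.standard_normal((n_channels, n_samples), dtype=np.float32)
    spec = sfft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    shape = 1.0 / np.sqrt(np.maximum(f, f_floor_hz))
    shape[0] = 0.0  # no DC
    out = sfft.irfft(spec * shape.astype(np.float32), n=n_samples, axis=1)
    rms = out.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return (out / rms * rms_uV).astype(np.float32)


def _blink_template(fs_hz: float) -> np.ndarray:
    """400 ms biphasic blink: a dominant positive lobe then a small
    negative rebound (frontal polarity)."""
    n1 = int(round(0.25 * fs_hz))
    n2 = int(round(0.15 * fs_hz))
    lobe1 = np.sin(np.pi * np.arange(n1) / max(n1, 1))
    lobe2 = -0.35 * np.sin(np.pi * np.arange(n2) / max(n2, 1))
    return np.concatenate([lobe1, lobe2])


def _blink_topography(forward: ForwardModel) -> np.ndarray:
    pos = np.array([channel_position(c) for c in forward.channels])
    return np.maximum(0.0, pos[:, 1]) ** 2


# ---------------------------------------------------------------------------
# Recording container and participant synthesis
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """Continuous multi-channel recording in µV with embedded events."""

    data: np.ndarray  # (n_channels, n_samples), µV
    fs_hz: float
    channels: tuple[str, ...]
    events: EventStream

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples)")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")
        n = self.data.shape[1]
        for e in self.events:
            s = int(round(e.time_ms / 1000.0 * self.fs_hz))
            if not (0 <= s < n):
                raise ValueError(f"event at {e.time_ms} ms outside recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs_hz * 1000.0

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label) if isinstance(self.channels, list) \
                else list(self.channels).index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]


def acquisition_filter(recording: EEGRecording, low_hz: float = 0.01,
                       high_hz: float = 100.0,
                       notch_hz: float = 50.0) -> EEGRecording:
    """Model of the amplifier's acquisition band: wide band-pass plus a
    line-frequency notch applied to the continuous signal."""
    fs = recording.fs_hz
    sos = signal.butter(2, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    data = signal.sosfiltfilt(sos, recording.data, axis=1)
    b, a = signal.iirnotch(notch_hz, Q=30.0, fs=fs)
    data = signal.filtfilt(b, a, data, axis=1)
    return EEGRecording(data.astype(np.float32), fs, recording.channels,
                        recording.events)


def synthesize_participant(game_config, agent_params, forward: ForwardModel,
                           rng: np.random.Generator):
    """Simulate one participant: play a session with the accumulator agent
    and render the continuous 64-channel recording.

    Returns ``(recording, session)`` where ``recording`` embeds trigger
    events at session times shifted by the pre-session pad.
    """
    from .agents import AccumulatorAgent  # local import avoids a cycle
    from .game_engine import run_session

    # the accumulator grid must align with the sampling grid for projection
    step = agent_params.accumulator.dt_ms * forward.fs_hz / 1000.0
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise ValueError(
            "accumulator dt_ms must be an integer multiple of the sampling "
            f"period (dt={agent_params.accumulator.dt_ms} ms at fs={forward.fs_hz} Hz)"
        )
    step = int(round(step))

    agent = AccumulatorAgent(agent_params)
    session = run_session(game_config, agent, rng)

    fs = forward.fs_hz
    walk = float(game_config.walk_duration_ms)
    period = walk + float(game_config.iti_ms)
    n_rounds = len(session.trials)
    total_ms = forward.pre_pad_ms + (n_rounds - 1) * period + walk + forward.post_pad_ms
    n_samples = int(round(total_ms / 1000.0 * fs))

    tail_ms = 5.0 * 300.0  # return-to-baseline extent after walk end
    if float(game_config.iti_ms) < tail_ms and n_rounds > 1:
        raise ValueError(
            f"rounds overlap: iti_ms={game_config.iti_ms} shorter than the "
            f"{tail_ms:.0f} ms return-to-baseline tail"
        )

    data = np.zeros((len(forward.channels), n_samples), dtype=np.float32)
    topos = {c: topography(forward, c) for c in ("easy", "medium", "hard")}

    for onset_ms, record in zip(session.round_onsets_ms, agent.rounds):
        # a crossing without a press (hider on the middle trail: the agent
        # withholds) terminates accumulation but produces no motor potential
        source = rp_source(
            record.times_ms, record.trajectory, record.crossing_ms,
            forward.rp_gain_uV, agent_params.accumulator.threshold,
            motor_amp_frac=0.4 if record.pressed else 0.0,
        )
        # decay the end-of-round value to baseline during the ITI
        dt_ms = agent_params.accumulator.dt_ms
        n_tail = int(round(tail_ms / dt_ms))
        if n_tail > 0 and source[-1] != 0.0:
            tail = source[-1] * np.exp(-np.arange(1, n_tail + 1) * dt_ms / 300.0)
            source = np.concatenate([source, tail])
        src = source[::step].astype(np.float32)
        i0 = int(round((forward.pre_pad_ms + onset_ms) / 1000.0 * fs))
        i1 = min(i0 + src.size, n_samples)
        data[:, i0:i1] += np.outer(topos[record.condition], src[: i1 - i0]).astype(
            np.float32)

    data += pink_noise(len(forward.channels), n_samples, fs, forward.noise_1f_uV, rng)

    if forward.line_50hz_uV > 0:
        t = np.arange(n_samples, dtype=np.float64) / fs
        line = forward.line_50hz_uV * np.sin(
            2.0 * np.pi * 50.0 * t + rng.uniform(0.0, 2.0 * np.pi))
        data += line.astype(np.float32)[None, :]

    if forward.blink_rate_per_min > 0 and forward.blink_amp_uV > 0:
        template = _blink_template(fs) * forward.blink_amp_uV
        btopo = _blink_topography(forward)
        n_blinks = rng.poisson(forward.blink_rate_per_min * total_ms / 60000.0)
        starts = rng.integers(0, max(n_samples - template.size, 1), size=n_blinks)
        for s in starts:
            seg = slice(int(s), int(s) + template.size)
            data[:, seg] += np.outer(btopo, template).astype(np.float32)

    events = session.events.shifted(forward.pre_pad_ms)
    recording = EEGRecording(data, fs, tuple(forward.channels), events)
    if forward.apply_acquisition_band:
        recording = acquisition_filter(recording)
    return recording, session
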