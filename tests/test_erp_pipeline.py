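"""ERP pipeline tests: filtering, epoching, rejection, baseline, SNR and
exclusion."""

import numpy as np
import pytest

from crabrp import (
    EEGRecording,
    Event,
    EventStream,
    EpochSet,
    ParticipantSummary,
    PipelineConfig,
    average,
    bandpass,
    baseline_correct,
    compute_snr,
    epoch,
    exclude_participants,
    grand_average,
    reject_artifacts,
)
from crabrp.game_engine import EVENT_CODES

FS = 500.0


def _recording(data, events=()):
    n_ch = data.shape[0]
    chans = tuple(f"C{i}" for i in range(n_ch - 1)) + ("Cz",)
    return EEGRecording(data, FS, chans, EventStream(list(events)))


def _sine(freq, dur_s=60.0, amp=1.0):
    t = np.arange(int(dur_s * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t)


def _steady_amplitude(trace):
    """Amplitude of a filtered sinusoid away from filtfilt edge
    transients: RMS * sqrt(2) over the central third."""
    n = trace.size
    mid = trace[n // 3: 2 * n // 3]
    return np.sqrt(2.0) * mid.std()


# ---------------------------------------------------------------------------
# Band-pass
# ---------------------------------------------------------------------------

def test_bandpass_preserves_1hz_amplitude():
    rec = _recording(_sine(1.0)[None, :])
    out = bandpass(rec, 0.1, 40.0)
    assert _steady_amplitude(out.data[0]) == pytest.approx(1.0, rel=0.05)


def test_bandpass_attenuates_45hz():
    rec = _recording(_sine(45.0)[None, :])
    out = bandpass(rec, 0.1, 40.0)
    assert _steady_amplitude(out.data[0]) < 0.1  # >= 90% attenuation


def test_bandpass_zero_in_zero_out():
    rec = _recording(np.zeros((2, 5000)))
    assert np.allclose(bandpass(rec).data, 0.0)


def test_bandpass_rejects_band_above_nyquist():
    rec = _recording(np.zeros((1, 5000)))
    with pytest.raises(ValueError):
        bandpass(rec, 0.1, 300.0)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def _press_events():
    return [
        Event(0.0, EVENT_CODES["TRIAL_ONSET_EASY"], "easy"),
        Event(6000.0, EVENT_CODES["PRESS_UP"], "easy"),
        Event(8000.0, EVENT_CODES["WALK_END"], "easy"),
        Event(10000.0, EVENT_CODES["TRIAL_ONSET_HARD"], "hard"),
        Event(18000.0, EVENT_CODES["WALK_END"], "hard"),
    ]


def test_press_locked_epoch_alignment():
    """Epoch sample 0 sits at press + tmin."""
    data = np.arange(20000 * FS / 1000.0)[None, :] * 0.001
    rec = _recording(data, _press_events())
    sets = epoch(rec, "press", -5000.0, 500.0)
    es = sets["easy"]
    assert len(es) == 1
    s0 = int(round((6000.0 - 5000.0) / 1000.0 * FS))
    assert es.data[0, 0, 0] == rec.data[0, s0]
    assert es.times_ms[0] == -5000.0


def test_press_free_round_contributes_no_press_epoch():
    rec = _recording(np.zeros((1, 10000)), _press_events())
    sets = epoch(rec, "press", -5000.0, 500.0)
    assert "hard" not in sets


def test_end_locked_flags_match_session():
    rec = _recording(np.zeros((1, 10000)), _press_events())
    sets = epoch(rec, "trial_end", -5500.0, 200.0)
    assert sets["easy"].pressed.tolist() == [True]
    assert sets["hard"].pressed.tolist() == [False]


def test_epoch_beyond_recording_is_dropped():
    events = [Event(100.0, EVENT_CODES["PRESS_UP"], "easy")]
    rec = _recording(np.zeros((1, 10000)), events)
    sets = epoch(rec, "press", -5000.0, 500.0)
    assert sets == {}


# ---------------------------------------------------------------------------
# Artifact rejection
# ---------------------------------------------------------------------------

def _epochs(data, pressed=None):
    n, _, s = data.shape
    times = -1000.0 + np.arange(s) / FS * 1000.0
    pressed = np.ones(n, bool) if pressed is None else pressed
    return EpochSet("easy", "press", times[0], times[-1] + 1000 / FS, times,
                    data, pressed, ("Cz",), FS)


def test_infinite_threshold_retains_all():
    es = _epochs(np.random.default_rng(0).normal(size=(10, 1, 100)))
    assert len(reject_artifacts(es, np.inf)) == 10


def test_spike_epoch_rejected():
    data = np.zeros((5, 1, 100))
    data[2, 0, 50] = 500.0  # injected 500 µV spike
    kept = reject_artifacts(_epochs(data), 150.0)
    assert len(kept) == 4
    assert np.abs(kept.data).max() == 0.0


# ---------------------------------------------------------------------------
# Baseline correction
# ---------------------------------------------------------------------------

def test_baseline_constant_epoch_becomes_zero():
    es = _epochs(np.full((3, 1, 100), 5.0))
    out = baseline_correct(es, (-1000.0, -900.0))
    assert np.allclose(out.data, 0.0)


def test_baseline_subtracts_window_mean_of_ramp():
    data = np.tile(np.linspace(0.0, 10.0, 100), (2, 1, 1))
    es = _epochs(data)
    window = (-1000.0, -900.0)
    mask = (es.times_ms >= window[0]) & (es.times_ms <= window[1])
    m = data[0, 0, mask].mean()
    out = baseline_correct(es, window)
    assert np.allclose(out.data, data - m)


def test_baseline_idempotent():
    rng = np.random.default_rng(1)
    es = _epochs(rng.normal(size=(4, 1, 100)))
    once = baseline_correct(es, (-1000.0, -800.0))
    twice = baseline_correct(once, (-1000.0, -800.0))
    assert np.allclose(once.data, twice.data)


def test_baseline_window_outside_epoch_raises():
    es = _epochs(np.zeros((2, 1, 100)))
    with pytest.raises(ValueError):
        baseline_correct(es, (-9000.0, -8000.0))


def test_baseline_and_averaging_commute():
    """Both are linear: correcting epochs then averaging equals averaging
    then correcting (tolerance 1e-9 µV)."""
    rng = np.random.default_rng(2)
    es = _epochs(rng.normal(size=(8, 1, 200)))
    a = average(baseline_correct(es, (-1000.0, -700.0)))
    avg_set = _epochs(average(es)[None, :, :])
    b = average(baseline_correct(avg_set, (-1000.0, -700.0)))
    assert np.allclose(a, b, atol=1e-9)


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

def test_snr_flat_zero_waveform_is_zero():
    times = np.arange(-5000.0, 500.0, 2.0)
    assert compute_snr(np.zeros(times.size), times) == 0.0


def test_snr_constant_signal_with_unit_sd():
    """|mean over [-400,0)| / SD over [tmin,0): constructed to give 2.0."""
    times = np.arange(-2000.0, 500.0, 2.0)
    w = np.zeros(times.size)
    pre = times < 0.0
    w[(times >= -400.0) & pre] = -2.0
    # scale so the SD over the premovement extent is exactly 1 µV
    sd = w[pre].std()
    w[pre] = w[pre] * (1.0 / sd) + 0.0
    # the mean over [-400, 0) scaled identically
    expected = abs(w[(times >= -400.0) & pre].mean()) / w[pre].std()
    got = compute_snr(w, times)
    assert got == pytest.approx(expected)
    assert got == pytest.approx(abs(-2.0 / sd) / 1.0)


def test_snr_infinite_when_sd_zero_mean_nonzero():
    times = np.arange(-1000.0, 100.0, 2.0)
    w = np.full(times.size, -3.0)
    w[times >= 0] = 0.0
    assert compute_snr(w, times) == np.inf


def test_pure_noise_snr_below_one():
    """With no RP the premovement mean is far smaller than the SD."""
    rng = np.random.default_rng(0)
    times = np.arange(-5000.0, 500.0, 2.0)
    snrs = [compute_snr(rng.normal(size=times.size), times) for _ in range(50)]
    assert np.mean(np.array(snrs) < 1.0) > 0.9


# ---------------------------------------------------------------------------
# Exclusion and grand averages
# ---------------------------------------------------------------------------

def _summary(pid, snrs, n=40):
    s = ParticipantSummary(pid, ("Cz",), FS, np.arange(10.0), np.arange(10.0))
    s.snr = dict(snrs)
    s.n_press = {c: n for c in snrs}
    return s


def test_all_snr_above_one_none_excluded():
    summaries = [_summary(f"p{i}", {"easy": 1.2, "medium": 2.0, "hard": 3.0})
                 for i in range(4)]
    assert len(exclude_participants(summaries)) == 4


def test_single_low_snr_condition_excludes():
    good = _summary("good", {"easy": 1.5, "medium": 1.5, "hard": 1.5})
    bad = _summary("bad", {"easy": 1.5, "medium": 0.5, "hard": 1.5})
    kept = exclude_participants([good, bad])
    assert [s.participant for s in kept] == ["good"]


def test_zero_threshold_excludes_none():
    bad = _summary("bad", {"easy": 0.1, "medium": 0.2, "hard": 0.3})
    assert exclude_participants([bad], snr_threshold=0.0) == [bad]


def test_min_epoch_retention_rule():
    few = _summary("few", {"easy": 2.0, "medium": 2.0, "hard": 2.0}, n=10)
    assert exclude_participants([few], min_epochs=30) == []


def test_grand_average_single_and_symmetric():
    w = np.ones((1, 10))
    a = _summary("a", {"easy": 2.0})
    a.avg_press = {"easy": w}
    mean, se = grand_average([a], "easy")
    assert np.allclose(mean, w) and np.allclose(se, 0.0)

    b = _summary("b", {"easy": 2.0})
    b.avg_press = {"easy": -w}
    mean2, _ = grand_average([a, b], "easy")
    assert np.allclose(mean2, 0.0)


def test_grand_average_empty_raises():
    with pytest.raises(ValueError):
        grand_average([], "easy")
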