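"""File I/O: BIDS-style events tables and BrainVision-dialect recordings.

Events go to a tab-separated ``*_events.tsv`` (onset in seconds, duration,
trial_type, value, sample) with a JSON sidecar documenting the trigger
codes.  Continuous EEG goes to the BrainVision triplet — an INI-style
``.vhdr`` header, a ``.vmrk`` marker file and a little-endian int16
multiplexed ``.eeg`` payload at 0.1 µV resolution — readable back into an
:class:`~crabrp.synthetic_eeg.EEGRecording`.  Both writers derive their
times from the same event stream, so table onsets and markers cannot
drift apart.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .game_engine import (
    CONDITION_BY_ONSET_CODE,
    EVENT_CODES,
    Event,
    EventStream,
)
from .synthetic_eeg import EEGRecording

__all__ = [
    "write_events",
    "read_events",
    "write_recording",
    "read_recording",
    "write_manifest",
]

RESOLUTION_UV = 0.1  # int16 step of the binary payload


# ---------------------------------------------------------------------------
# events.tsv
# ---------------------------------------------------------------------------

def write_events(stream: EventStream, path: str | Path,
                 fs_hz: float = 500.0) -> None:
    """Write a BIDS-style events table plus a JSON code sidecar."""
    path = Path(path)
    lines = ["onset\tduration\ttrial_type\tvalue\tsample"]
    for e in stream:
        onset_s = e.time_ms / 1000.0
        sample = int(round(e.time_ms / 1000.0 * fs_hz))
        lines.append(f"{onset_s:.3f}\t0.0\t{e.condition}\t{e.code}\t{sample}")
    path.write_text("\n".join(lines) + "\n")

    sidecar = {
        "value": {"Description": "trigger code",
                  "Levels": {str(v): k for k, v in EVENT_CODES.items()}},
        "trial_type": {"Description": "game condition of the round"},
        "SamplingFrequency": fs_hz,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_events(path: str | Path) -> EventStream:
    """Read an events table back; malformed rows or non-monotone onsets
    raise with the 1-based line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["onset", "duration"]:
        raise ValueError(f"{path.name}:1: missing events header")
    events: list[Event] = []
    prev = -np.inf
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"{path.name}:{i}: expected 5 columns, got {len(parts)}")
        try:
            onset_s = float(parts[0])
            code = int(parts[3])
        except ValueError as exc:
            raise ValueError(f"{path.name}:{i}: {exc}") from None
        if onset_s < prev:
            raise ValueError(f"{path.name}:{i}: onsets are not non-decreasing")
        prev = onset_s
        events.append(Event(onset_s * 1000.0, code, parts[2]))
    return EventStream(events)


# ---------------------------------------------------------------------------
# BrainVision triplet
# ---------------------------------------------------------------------------

def write_recording(recording: EEGRecording, basepath: str | Path) -> None:
    """Write ``<basepath>.vhdr/.vmrk/.eeg`` (int16 multiplexed, µV)."""
    base = Path(basepath)
    name = base.name
    n_ch, n_samp = recording.data.shape
    interval_us = int(round(1e6 / recording.fs_hz))

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by crabrp",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        f"MarkerFile={name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={interval_us}",
        "",
        "[Binary Infos]",
        "BinaryFormat=INT_16",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(recording.channels, start=1):
        header.append(f"Ch{i}={ch},,{RESOLUTION_UV},µV")
    base.with_suffix(".vhdr").write_text("\n".join(header) + "\n",
                                         encoding="utf-8")

    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, e in enumerate(recording.events, start=2):
        sample = int(round(e.time_ms / 1000.0 * recording.fs_hz)) + 1  # 1-based
        markers.append(f"Mk{k}=Stimulus,S{e.code:>3},{sample},1,0")
    base.with_suffix(".vmrk").write_text("\n".join(markers) + "\n",
                                         encoding="utf-8")

    scaled = np.round(np.asarray(recording.data, dtype=np.float64)
                      / RESOLUTION_UV)
    scaled = np.clip(scaled, -32768, 32767).astype("<i2")
    # multiplexed: sample-major interleaving of channels
    base.with_suffix(".eeg").write_bytes(scaled.T.tobytes())


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: Optional[dict[str, str]] = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
        elif "=" in line and current is not None:
            key, _, value = line.partition("=")
            current[key.strip()] = value.strip()
    return sections


def read_recording(basepath: str | Path) -> EEGRecording:
    """Read a BrainVision triplet written by :func:`write_recording`
    (INT_16 multiplexed dialect)."""
    base = Path(basepath)
    vhdr = base.with_suffix(".vhdr")
    if not vhdr.exists():
        raise FileNotFoundError(f"missing header file {vhdr}")
    sections = _parse_ini(vhdr.read_text(encoding="utf-8"))
    common = sections.get("Common Infos", {})
    binary = sections.get("Binary Infos", {})
    if binary.get("BinaryFormat", "INT_16") != "INT_16":
        raise ValueError(f"unsupported BinaryFormat {binary.get('BinaryFormat')!r}")
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    n_ch = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])

    channels, resolutions = [], []
    chinfo = sections.get("Channel Infos", {})
    for i in range(1, n_ch + 1):
        entry = chinfo.get(f"Ch{i}")
        if entry is None:
            raise ValueError(f"header missing Ch{i}")
        parts = entry.split(",")
        channels.append(parts[0])
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)

    eeg_path = base.parent / common.get("DataFile", base.name + ".eeg")
    if not eeg_path.exists():
        raise FileNotFoundError(f"missing data file {eeg_path}")
    payload = np.frombuffer(eeg_path.read_bytes(), dtype="<i2")
    if payload.size % n_ch != 0:
        raise ValueError(
            f"length mismatch: {eeg_path.name} holds {payload.size} values, "
            f"not a multiple of {n_ch} channels"
        )
    n_samp = payload.size // n_ch
    data = payload.reshape(n_samp, n_ch).T.astype(np.float64)
    data *= np.asarray(resolutions)[:, None]

    vmrk_path = base.parent / common.get("MarkerFile", base.name + ".vmrk")
    if not vmrk_path.exists():
        raise FileNotFoundError(f"missing marker file {vmrk_path}")
    events = _read_markers(vmrk_path, fs)
    return EEGRecording(data, fs, tuple(channels), events)


def _read_markers(path: Path, fs_hz: float) -> EventStream:
    sections = _parse_ini(path.read_text(encoding="utf-8"))
    markers = sections.get("Marker Infos", {})
    onset_codes = set(CONDITION_BY_ONSET_CODE)
    events: list[Event] = []
    condition = "n/a"
    for key in sorted(markers, key=lambda k: int(k[2:])):
        parts = markers[key].split(",")
        if parts[0] != "Stimulus":
            continue
        code = int(parts[1].lstrip("S").strip())
        sample = int(parts[2]) - 1
        if code in onset_codes:
            condition = CONDITION_BY_ONSET_CODE[code]
        events.append(Event(sample / fs_hz * 1000.0, code, condition))
    return EventStream(events)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, seed: int, cfg_hash: str) -> None:
    """Record what is needed to reproduce the simulation bit-for-bit."""
    from . import __version__

    manifest = {"seed": seed, "config_sha256": cfg_hash,
                "crabrp_version": __version__,
                "numpy_version": np.__version__}
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
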