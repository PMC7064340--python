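"""Shared file I/O: WAV audio, trace CSVs, scenario configs, run logs."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .simulate import Segment, SongScenario
from .synthesis import AudioClip

__all__ = [
    "read_wav",
    "write_wav",
    "write_trace_csv",
    "read_trace_csv",
    "read_scenario",
    "write_scenario",
    "write_run_log",
]

_INT_SCALES = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31}


def read_wav(path) -> AudioClip:
    """Read a WAV file to a mono clip normalized to [-1, 1].

    PCM 16/24/32-bit and float formats are accepted; stereo is averaged to
    mono with a warning.
    """
    try:
        fs, data = wavfile.read(path)
    except Exception as exc:
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.size == 0:
        raise IOError(f"WAV file {path} contains no samples")
    if data.ndim == 2:
        warnings.warn("stereo WAV averaged to mono")
        data = data.mean(axis=1)
    if data.dtype in _INT_SCALES:
        samples = data.astype(float) / _INT_SCALES[data.dtype]
    elif data.dtype == np.dtype("uint8"):
        samples = (data.astype(float) - 128.0) / 128.0
    else:
        samples = data.astype(float)
    return AudioClip(samples=samples, fs=float(fs))


def write_wav(clip: AudioClip, path, subtype: str = "float32") -> None:
    """Write a clip as mono WAV (``float32`` or ``pcm16``)."""
    if subtype == "float32":
        wavfile.write(path, int(clip.fs), clip.samples.astype(np.float32))
    elif subtype == "pcm16":
        x = np.clip(clip.samples, -1.0, 1.0)
        wavfile.write(path, int(clip.fs), (x * 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r}")


def write_trace_csv(times, values, path, value_name: str = "eR") -> None:
    pd.DataFrame({"time_s": times, value_name: values}).to_csv(path, index=False)


def read_trace_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_scenario(path) -> SongScenario:
    """Load a song scenario from a YAML config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = {"duration", "f0_hz", "segments", "transition_ms", "vibrato", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    vib = raw.get("vibrato", {}) or {}
    segments = [
        Segment(
            t_start=float(s["t_start"]),
            state=str(s["state"]),
            focus_hz=s.get("focus_hz"),
            second_focus_hz=s.get("second_focus_hz"),
        )
        for s in raw.get("segments", [])
    ]
    return SongScenario(
        duration=float(raw["duration"]),
        f0_hz=float(raw["f0_hz"]),
        segments=segments,
        transition_ms=float(raw.get("transition_ms", 50.0)),
        vibrato_rate_hz=float(vib.get("rate_hz", 0.0)),
        vibrato_depth_cents=float(vib.get("depth_cents", 0.0)),
        seed=int(raw.get("seed", 0)),
    )


def write_scenario(scenario: SongScenario, path) -> None:
    doc = {
        "duration": scenario.duration,
        "f0_hz": scenario.f0_hz,
        "transition_ms": scenario.transition_ms,
        "vibrato": {
            "rate_hz": scenario.vibrato_rate_hz,
            "depth_cents": scenario.vibrato_depth_cents,
        },
        "seed": scenario.seed,
        "segments": [
            {
                "t_start": s.t_start,
                "state": s.state,
                **({"focus_hz": s.focus_hz} if s.focus_hz is not None else {}),
                **(
                    {"second_focus_hz": s.second_focus_hz}
                    if s.second_focus_hz is not None
                    else {}
                ),
            }
            for s in scenario.segments
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_run_log(path, config: dict) -> None:
    """Write the full effective configuration of a run as YAML."""
    from . import __version__

    doc = {"khoomei_version": __version__, **config}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
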