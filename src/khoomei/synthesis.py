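"""Linear source/filter synthesis of drone and focused-state song.

The glottal source is a harmonic comb at f0 with a power-law spectral tilt
(default -12 dB/octave) and optional sinusoidal vibrato; the vocal tract
acts as a multiplicative filter in the spectral domain.  Static synthesis
is plain additive synthesis with per-harmonic amplitudes
``source_level(k) * |H(k f0)|``; dynamic synthesis re-filters frame by
frame while the tract morphs between a normal and a focused configuration,
reproducing the fast (~40-60 ms) transitions into the focused state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acoustics import (
    AcousticConstants,
    FocusOptions,
    FrequencyResponse,
    perturb_to_focus,
    steer_formant,
    transfer_function,
)
from .geometry import AreaFunction
from .simulate import SongScenario

__all__ = [
    "GlottalSourceSpec",
    "AudioClip",
    "harmonic_frequency",
    "source_level_db",
    "synthesize_static",
    "interpolate_area_functions",
    "synthesize_dynamic",
    "build_focused_tract",
]


def build_focused_tract(
    af_normal: AreaFunction,
    focus_hz: float,
    second_focus_hz: float | None = None,
    const: AcousticConstants = AcousticConstants(),
    opts: FocusOptions = FocusOptions(),
) -> AreaFunction:
    """Focused-state tract for a scenario: merge F2/F3 on ``focus_hz``.

    With ``second_focus_hz`` set, F4 is subsequently steered onto the
    secondary focus (the sharpened-F4 state some singers produce at
    3-3.5 kHz).  Raises if the merge does not converge.
    """
    res = perturb_to_focus(af_normal, const, focus_hz, (2, 3), opts)
    if not res.converged:
        raise RuntimeError(f"formant merge onto {focus_hz} Hz did not converge")
    af = res.af
    if second_focus_hz is not None:
        res2 = steer_formant(af, const, 3, second_focus_hz, opts)
        if res2.converged:
            af = res2.af
    return af


@dataclass(frozen=True)
class GlottalSourceSpec:
    """Harmonic glottal source: f0, harmonic count, tilt, vibrato."""

    f0: float = 150.0
    n_harmonics: int = 40
    tilt_db_per_octave: float = -12.0
    vibrato_rate: float = 0.0
    vibrato_depth_cents: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")


@dataclass
class AudioClip:
    """Peak-normalized mono pressure waveform."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def harmonic_frequency(f0: float, n: int) -> float:
    """Frequency of the n-th harmonic: ``n * f0`` (n=1 is the fundamental)."""
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if n < 1:
        raise ValueError("harmonic number must be >= 1")
    return n * f0


def source_level_db(n: int, tilt_db_per_octave: float) -> float:
    """Source spectrum level of harmonic n re the fundamental (dB)."""
    return tilt_db_per_octave * np.log2(n)


def _harmonic_amplitudes(
    src: GlottalSourceSpec, filter_gain_db: np.ndarray
) -> np.ndarray:
    k = np.arange(1, len(filter_gain_db) + 1)
    level_db = src.tilt_db_per_octave * np.log2(k) + filter_gain_db
    return 10.0 ** (level_db / 20.0)


def synthesize_static(
    src: GlottalSourceSpec,
    fr: FrequencyResponse,
    duration: float = 2.0,
    fs: float = 44100.0,
) -> AudioClip:
    """Additive synthesis of a stationary clip through a fixed filter.

    Each harmonic k gets amplitude ``source_level(k) * gain(k * f0)``;
    harmonics above the filter range or Nyquist are dropped with a warning.
    The output is peak-normalized.
    """
    n_harm = src.n_harmonics
    f_harm = src.f0 * np.arange(1, n_harm + 1)
    usable = (f_harm <= fr.freq[-1]) & (f_harm < fs / 2)
    if not np.all(usable):
        warnings.warn("harmonics above the filter range were truncated")
        n_harm = int(np.sum(usable))
        f_harm = f_harm[:n_harm]

    amps = _harmonic_amplitudes(
        GlottalSourceSpec(src.f0, n_harm, src.tilt_db_per_octave),
        fr.gain_at(f_harm),
    )
    t = np.arange(int(round(duration * fs))) / fs
    if src.vibrato_depth_cents > 0 and src.vibrato_rate > 0:
        dev = 2.0 ** (
            src.vibrato_depth_cents
            / 1200.0
            * np.sin(2 * np.pi * src.vibrato_rate * t)
        )
        phase0 = 2 * np.pi * np.cumsum(src.f0 * dev) / fs
    else:
        phase0 = 2 * np.pi * src.f0 * t
    x = np.zeros_like(t)
    for k in range(1, n_harm + 1):
        x += amps[k - 1] * np.sin(k * phase0)
    peak = np.max(np.abs(x))
    if peak > 0:
        x /= peak
    return AudioClip(samples=x, fs=fs)


def interpolate_area_functions(
    af_a: AreaFunction, af_b: AreaFunction, w: float
) -> AreaFunction:
    """Section-wise geometric interpolation ``A_a^(1-w) * A_b^w`` (w in [0,1])."""
    if len(af_a.x) != len(af_b.x) or not np.allclose(af_a.x, af_b.x):
        raise ValueError("area functions must share the same section grid")
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    return AreaFunction(x=af_a.x.copy(), A=af_a.A ** (1.0 - w) * af_b.A**w)


def synthesize_dynamic(
    scenario: SongScenario,
    af_normal: AreaFunction,
    af_focused: AreaFunction,
    const: AcousticConstants = AcousticConstants(),
    fs: float = 44100.0,
    src: GlottalSourceSpec | None = None,
    hop_s: float = 0.010,
    n_weight_cache: int = 64,
    kind: str = "radiated_pressure",
) -> AudioClip:
    """Frame-wise synthesis of a normal→focused song.

    Every 10 ms frame the tract is interpolated between the normal and
    focused configurations according to the scenario's focus weight, the
    filter gains at the harmonic frequencies are recomputed (cached over a
    quantized weight grid), and the frame is joined by Hann-windowed
    overlap-add (20 ms frames, 50% overlap).  Harmonic phases accumulate
    continuously across frames, so a constant-weight scenario degenerates
    to the static synthesis.

    The default transfer ``kind`` is radiated pressure — the quantity a
    microphone records — which adds the radiation high-pass to the
    volume-velocity response.
    """
    if src is None:
        src = GlottalSourceSpec(
            f0=scenario.f0_hz,
            vibrato_rate=scenario.vibrato_rate_hz,
            vibrato_depth_cents=scenario.vibrato_depth_cents,
        )
    if scenario.transition_ms / 1000.0 < hop_s:
        warnings.warn("transition shorter than one frame; clamped to one frame")

    n_total = int(round(scenario.duration * fs))
    hop = int(round(hop_s * fs))
    win_len = 2 * hop
    window = np.hanning(win_len + 1)[:-1]  # periodic Hann: 50% overlap COLA

    f_harm = src.f0 * np.arange(1, src.n_harmonics + 1)
    keep = f_harm < fs / 2
    f_harm = f_harm[keep]
    n_harm = len(f_harm)
    k_arr = np.arange(1, n_harm + 1)
    tilt_amp = 10.0 ** (src.tilt_db_per_octave * np.log2(k_arr) / 20.0)

    # continuous phase track (vibrato-modulated instantaneous f0)
    t = np.arange(n_total) / fs
    if src.vibrato_depth_cents > 0 and src.vibrato_rate > 0:
        dev = 2.0 ** (
            src.vibrato_depth_cents / 1200.0 * np.sin(2 * np.pi * src.vibrato_rate * t)
        )
        phase0 = 2 * np.pi * np.cumsum(src.f0 * dev) / fs
    else:
        phase0 = 2 * np.pi * src.f0 * t

    gain_cache: dict[int, np.ndarray] = {}

    def gains_for_weight(w: float) -> np.ndarray:
        q = int(round(w * (n_weight_cache - 1)))
        if q not in gain_cache:
            af = interpolate_area_functions(af_normal, af_focused, q / (n_weight_cache - 1))
            H = transfer_function(af, const, f_harm, kind=kind)
            gain_cache[q] = np.abs(H)
        return gain_cache[q]

    out = np.zeros(n_total + win_len)
    for start in range(0, n_total, hop):
        sl = slice(start, start + win_len)
        ph = phase0[sl]
        if len(ph) < win_len:
            ph = np.pad(ph, (0, win_len - len(ph)), mode="edge")
        t_center = (start + win_len / 2) / fs
        w = float(scenario.focus_weight(t_center)[0])
        amps = tilt_amp * gains_for_weight(w)
        frame = np.zeros(win_len)
        for k in range(1, n_harm + 1):
            frame += amps[k - 1] * np.sin(k * ph)
        out[start : start + win_len] += window * frame

    x = out[:n_total]
    peak = np.max(np.abs(x))
    if peak > 0:
        x /= peak
    return AudioClip(samples=x, fs=fs)
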