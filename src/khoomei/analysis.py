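"""Spectral analysis: spectrograms, harmonic tracking, and the eR focus statistic.

The analysis mirrors how overtone-singing recordings are quantified:

* STFT spectrograms with 4096-sample Hamming windows and 95% overlap;
* per-frame f0 from the strongest peak below 500 Hz, then a harmonic
  ladder picked around integer multiples of f0;
* a "formant trend" obtained by band-limited 10x upsampling of the
  harmonic-peak levels, whose local maxima serve as formant estimates;
* the band energy ratio eR(fL, fH) — spectral magnitude integrated over
  [fL, fH] divided by the integral over [0, fmax], squared — which is
  near 0 for normal singing and rises above 0.5 in the focused state;
* hysteresis-based detection of transitions into/out of the focused state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import ShortTimeFFT, find_peaks, get_window, resample_poly

from .synthesis import AudioClip

__all__ = [
    "StftParams",
    "Spectrogram",
    "HarmonicLadder",
    "FormantTrendFrame",
    "FocusTrace",
    "compute_spectrogram",
    "estimate_f0",
    "pick_harmonics",
    "estimate_formant_trend",
    "energy_ratio",
    "focus_trace",
    "detect_transitions",
]

DB_FLOOR = -120.0


@dataclass(frozen=True)
class StftParams:
    """Spectrogram settings (defaults match the recording-analysis practice)."""

    window_samples: int = 4096
    overlap: float = 0.95
    window: str = "hamming"
    floor_db: float = DB_FLOOR

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.window_samples < 8:
            raise ValueError("window too short")

    @property
    def hop(self) -> int:
        # 5% of the window, rounded down (e.g. 4096 -> 204 samples)
        return int(self.window_samples * (1.0 - self.overlap))


@dataclass
class Spectrogram:
    """STFT magnitude in dB re the global maximum."""

    times: np.ndarray
    freqs: np.ndarray
    mag_db: np.ndarray  # shape (n_freqs, n_frames)
    params: StftParams
    fs: float
    n_samples: int = 0

    @property
    def hop_s(self) -> float:
        return self.params.hop / self.fs

    def frame(self, i: int) -> np.ndarray:
        return self.mag_db[:, i]


@dataclass
class HarmonicLadder:
    """Per-frame f0 estimates with harmonic frequencies and levels.

    Missing harmonics are NaN.
    """

    times: np.ndarray
    f0: np.ndarray  # NaN where undefined
    harmonic_freqs: np.ndarray  # (n_frames, n_max)
    harmonic_levels: np.ndarray  # (n_frames, n_max), dB


@dataclass
class FormantTrendFrame:
    """Interpolated spectral envelope of one frame with its picked peaks."""

    env_freqs: np.ndarray
    env_levels: np.ndarray
    peak_freqs: np.ndarray
    peak_levels: np.ndarray


@dataclass
class FocusTrace:
    """eR(fL, fH) per spectrogram frame; NaN where energy is undefined."""

    times: np.ndarray
    eR: np.ndarray
    band: tuple[float, float]
    fmax: float
    hop_s: float = field(default=0.0)


def compute_spectrogram(audio: AudioClip, params: StftParams = StftParams()) -> Spectrogram:
    """STFT magnitude spectrogram in dB re the global maximum."""
    x = audio.samples
    if len(x) == 0:
        raise ValueError("empty audio")
    if params.window_samples > len(x):
        raise ValueError("window longer than the signal")
    win = get_window(params.window, params.window_samples)
    sft = ShortTimeFFT(win, hop=params.hop, fs=audio.fs)
    S = np.abs(sft.stft(x))
    ref = S.max()
    if ref <= 0:
        mag_db = np.full_like(S, params.floor_db)
    else:
        mag_db = 20.0 * np.log10(np.maximum(S / ref, 10.0 ** (params.floor_db / 20.0)))
    times = sft.t(len(x))
    return Spectrogram(
        times=times, freqs=sft.f, mag_db=mag_db, params=params, fs=audio.fs,
        n_samples=len(x),
    )


def _quad_refine(freqs: np.ndarray, levels: np.ndarray, i: int) -> tuple[float, float]:
    if i <= 0 or i >= len(levels) - 1:
        return float(freqs[i]), float(levels[i])
    y0, y1, y2 = levels[i - 1], levels[i], levels[i + 1]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-12:
        return float(freqs[i]), float(levels[i])
    d = float(np.clip(0.5 * (y0 - y2) / denom, -1, 1))
    df = freqs[1] - freqs[0]
    return float(freqs[i] + d * df), float(y1 - 0.25 * (y0 - y2) * d)


def estimate_f0(freqs: np.ndarray, frame_db: np.ndarray, f_limit: float = 500.0) -> float:
    """f0 of a frame from the strongest spectral peak below ``f_limit`` Hz.

    Because radiated spectra rise ~6 dB/oct, the strongest low peak may be a
    low harmonic rather than the fundamental; if a consistent peak exists at
    1/2, 1/3 or 1/4 of the strongest peak (within 30 dB of it), the lowest
    such subdivision is returned.  Peak frequencies are refined by quadratic
    interpolation; NaN when the frame has no peak below the limit.
    """
    mask = freqs < f_limit
    idx, _ = find_peaks(frame_db[mask], prominence=3.0)
    if len(idx) == 0:
        return float("nan")
    best = int(idx[np.argmax(frame_db[mask][idx])])
    fc, lc = _quad_refine(freqs[mask], frame_db[mask], best)
    peak_f = freqs[mask][idx]
    peak_l = frame_db[mask][idx]
    for d in (4, 3, 2):
        f_test = fc / d
        near = np.abs(peak_f - f_test) < max(0.04 * f_test, 2.0 * (freqs[1] - freqs[0]))
        if np.any(near & (peak_l > lc - 30.0)):
            j = int(idx[np.argmax(np.where(near, peak_l, -np.inf))])
            return _quad_refine(freqs[mask], frame_db[mask], j)[0]
    return fc


def pick_harmonics(
    freqs: np.ndarray,
    frame_db: np.ndarray,
    f0: float,
    n_max: int = 40,
    rel_floor_db: float = -100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic ladder of a frame: local peak within ±f0/2 of each k*f0.

    Returns (frequencies, levels); harmonics without a usable local peak in
    their search window are NaN.
    """
    if not np.isfinite(f0):
        raise ValueError("f0 undefined for this frame")
    hf = np.full(n_max, np.nan)
    hl = np.full(n_max, np.nan)
    for k in range(1, n_max + 1):
        lo, hi = (k - 0.5) * f0, (k + 0.5) * f0
        m = (freqs >= lo) & (freqs <= hi)
        if not np.any(m):
            continue
        seg = frame_db[m]
        idx, _ = find_peaks(seg)
        if len(idx) == 0 or np.max(seg[idx]) < rel_floor_db:
            continue
        best = idx[np.argmax(seg[idx])]
        f_ref, l_ref = _quad_refine(freqs[m], seg, int(best))
        hf[k - 1], hl[k - 1] = f_ref, l_ref
    return hf, hl


def harmonic_ladder(spec: Spectrogram, n_max: int = 40) -> HarmonicLadder:
    """Track f0 and the harmonic ladder across all spectrogram frames."""
    n_frames = spec.mag_db.shape[1]
    f0s = np.full(n_frames, np.nan)
    hf = np.full((n_frames, n_max), np.nan)
    hl = np.full((n_frames, n_max), np.nan)
    for i in range(n_frames):
        frame = spec.frame(i)
        f0 = estimate_f0(spec.freqs, frame)
        f0s[i] = f0
        if np.isfinite(f0):
            hf[i], hl[i] = pick_harmonics(spec.freqs, frame, f0, n_max=n_max)
    return HarmonicLadder(times=spec.times, f0=f0s, harmonic_freqs=hf, harmonic_levels=hl)


def estimate_formant_trend(
    harm_freqs: np.ndarray,
    harm_levels: np.ndarray,
    upsample_factor: int = 10,
) -> FormantTrendFrame | None:
    """Spectral-envelope trend from one frame's harmonic peaks.

    The harmonic levels (uniformly spaced at f0) are upsampled by a lowpass
    interpolating (polyphase FIR) filter; peaks of the resulting envelope
    are the frame's formant estimates.  Returns None with fewer than 4
    usable harmonics.
    """
    ok = np.isfinite(harm_freqs) & np.isfinite(harm_levels)
    if np.sum(ok) < 4:
        return None
    f = harm_freqs[ok]
    lv = harm_levels[ok]
    # regrid onto exact harmonic spacing before polyphase upsampling
    grid = np.linspace(f[0], f[-1], len(f))
    lv_u = np.interp(grid, f, lv)
    env = resample_poly(lv_u, upsample_factor, 1, padtype="line")
    env_f = f[0] + (f[-1] - f[0]) * np.arange(len(env)) / len(env)
    idx, _ = find_peaks(env, prominence=1.0)
    pf, pl = [], []
    for i in idx:
        a, b = _quad_refine(env_f, env, int(i))
        pf.append(a)
        pl.append(b)
    return FormantTrendFrame(
        env_freqs=env_f,
        env_levels=env,
        peak_freqs=np.array(pf),
        peak_levels=np.array(pl),
    )


def energy_ratio(
    freqs: np.ndarray,
    frame_db: np.ndarray,
    fL: float = 1000.0,
    fH: float = 2000.0,
    fmax: float = 8000.0,
    variant: str = "printed",
) -> float:
    """Band energy ratio eR(fL, fH) of one spectral frame.

    ``printed`` (default): integrate linear magnitude over [fL, fH] and over
    [0, fmax], take the ratio, then square it.  ``power``: square the linear
    magnitude before integrating and do not square the ratio.  Both lie in
    [0, 1].  NaN when the frame carries no energy.
    """
    if not (0 <= fL < fH <= fmax):
        raise ValueError("need 0 <= fL < fH <= fmax")
    P = 10.0 ** (np.asarray(frame_db, dtype=float) / 20.0)
    if variant == "power":
        P = P**2
    elif variant != "printed":
        raise ValueError(f"unknown eR variant {variant!r}")
    full = (freqs >= 0) & (freqs <= fmax)
    band = (freqs >= fL) & (freqs <= fH)
    denom = np.trapezoid(P[full], freqs[full])
    if denom <= 0:
        return float("nan")
    ratio = np.trapezoid(P[band], freqs[band]) / denom
    return float(ratio**2) if variant == "printed" else float(ratio)


def focus_trace(
    spec: Spectrogram,
    fL: float = 1000.0,
    fH: float = 2000.0,
    fmax: float = 8000.0,
    variant: str = "printed",
) -> FocusTrace:
    """eR(fL, fH) for every spectrogram frame.

    Frames whose magnitude sits entirely at the dB floor (silence), and
    edge frames whose analysis window extends beyond the signal, are NaN.
    """
    fmax = min(fmax, float(spec.freqs[-1]))
    n_frames = spec.mag_db.shape[1]
    vals = np.full(n_frames, np.nan)
    half_win = 0.5 * spec.params.window_samples / spec.fs
    t_hi = spec.n_samples / spec.fs - half_win if spec.n_samples else np.inf
    for i in range(n_frames):
        if not (half_win <= spec.times[i] <= t_hi):
            continue  # partial window: eR undefined
        frame = spec.frame(i)
        if np.max(frame) <= spec.params.floor_db + 1e-9:
            continue  # silent frame: eR undefined
        vals[i] = energy_ratio(spec.freqs, frame, fL, fH, fmax, variant=variant)
    return FocusTrace(times=spec.times, eR=vals, band=(fL, fH), fmax=fmax, hop_s=spec.hop_s)


def detect_transitions(
    trace: FocusTrace,
    threshold: float = 0.35,
    hysteresis: float = 0.1,
    min_hold: float = 0.1,
) -> tuple[list[float], list[float]]:
    """Entry/exit times of the focused state from an eR trace.

    An entry fires at an upward crossing of ``threshold`` whose following
    ``min_hold`` seconds stay above ``threshold - hysteresis`` and reach
    ``threshold + hysteresis``; exits are symmetric (stay below
    ``threshold + hysteresis`` and reach ``threshold - hysteresis``).
    Chatter within the hysteresis band produces no events.
    """
    t = trace.times
    v = trace.eR
    ok = np.isfinite(v)
    hold_frames = max(1, int(round(min_hold / trace.hop_s))) if trace.hop_s > 0 else 1

    entries: list[float] = []
    exits: list[float] = []
    inside = False
    n = len(v)
    for i in range(n):
        if not ok[i]:
            continue
        if not inside and v[i] >= threshold and (i == 0 or not ok[i - 1] or v[i - 1] < threshold):
            seg = v[i : i + hold_frames]
            seg = seg[np.isfinite(seg)]
            if (
                len(seg) > 0
                and np.all(seg >= threshold - hysteresis)
                and np.max(seg) >= threshold + hysteresis
            ):
                inside = True
                entries.append(float(t[i]))
        elif inside and v[i] < threshold:
            seg = v[i : i + hold_frames]
            seg = seg[np.isfinite(seg)]
            if (
                len(seg) > 0
                and np.all(seg <= threshold + hysteresis)
                and np.min(seg) <= threshold - hysteresis
            ):
                inside = False
                exits.append(float(t[i]))
    return entries, exits
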