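"""Spectrograms, harmonic tracking, the eR statistic and transition detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from khoomei.analysis import (
    FocusTrace,
    StftParams,
    compute_spectrogram,
    detect_transitions,
    energy_ratio,
    estimate_f0,
    estimate_formant_trend,
    focus_trace,
    pick_harmonics,
)
from khoomei.synthesis import AudioClip


def comb_frame(freqs, f0, levels_db, width=2):
    """Construct a dB frame with harmonic 'peaks' at k*f0."""
    frame = np.full(len(freqs), -120.0)
    df = freqs[1] - freqs[0]
    for k, lvl in enumerate(levels_db, start=1):
        i = int(round(k * f0 / df - freqs[0] / df))
        if 0 < i < len(freqs) - 1:
            frame[i] = lvl
            frame[i - 1] = lvl - 6
            frame[i + 1] = lvl - 6
    return frame


class TestSpectrogram:
    def test_pure_tone_gives_single_ridge(self):
        fs = 44100.0
        t = np.arange(int(fs)) / fs
        clip = AudioClip(np.sin(2 * np.pi * 1000.0 * t), fs)
        spec = compute_spectrogram(clip, StftParams(window_samples=2048, overlap=0.9))
        for i in range(2, spec.mag_db.shape[1] - 2):
            peak = spec.freqs[np.argmax(spec.frame(i))]
            assert peak == pytest.approx(1000.0, abs=spec.freqs[1] - spec.freqs[0])

    def test_white_noise_frame_average_is_flat(self):
        rng = np.random.default_rng(42)
        fs = 44100.0
        clip = AudioClip(rng.standard_normal(int(2 * fs)), fs)
        spec = compute_spectrogram(clip, StftParams(window_samples=1024, overlap=0.5))
        mean_db = 20 * np.log10(np.mean(10 ** (spec.mag_db / 20.0), axis=1))
        inner = (spec.freqs > 500) & (spec.freqs < 20000)
        assert np.max(mean_db[inner]) - np.min(mean_db[inner]) < 3.0

    def test_default_grid_arithmetic_at_96k(self):
        params = StftParams()  # 4096-sample window, 95% overlap
        fs = 96000.0
        clip = AudioClip(np.sin(2 * np.pi * 440 * np.arange(int(fs)) / fs), fs)
        spec = compute_spectrogram(clip, params)
        assert params.hop == 204  # 5% of 4096, rounded down
        assert spec.freqs[1] - spec.freqs[0] == pytest.approx(96000 / 4096)
        assert spec.hop_s == pytest.approx(204 / 96000)

    def test_window_longer_than_signal_rejected(self):
        clip = AudioClip(np.zeros(1000), 44100.0)
        with pytest.raises(ValueError):
            compute_spectrogram(clip, StftParams(window_samples=4096))


class TestEstimateF0:
    def test_recovers_synthetic_f0(self, focused_spec):
        mid = focused_spec.mag_db.shape[1] // 2
        f0 = estimate_f0(focused_spec.freqs, focused_spec.frame(mid))
        assert f0 == pytest.approx(150.0, abs=1.0)

    def test_silence_is_undefined(self):
        freqs = np.arange(0.0, 8000.0, 10.0)
        assert np.isnan(estimate_f0(freqs, np.full(len(freqs), -120.0)))


class TestPickHarmonics:
    def test_full_comb_recovered(self):
        freqs = np.arange(0.0, 8000.0, 10.0)
        frame = comb_frame(freqs, 150.0, [0.0] * 20)
        hf, hl = pick_harmonics(freqs, frame, 150.0, 20)
        assert np.all(np.isfinite(hf))
        assert np.allclose(hf, 150.0 * np.arange(1, 21), atol=10.0)

    def test_missing_harmonic_flagged(self):
        freqs = np.arange(0.0, 8000.0, 10.0)
        levels = [0.0] * 12
        levels[4] = -120.0  # harmonic 5 removed
        frame = comb_frame(freqs, 150.0, levels)
        hf, hl = pick_harmonics(freqs, frame, 150.0, 12)
        assert np.isnan(hf[4])
        assert np.isfinite(hf[[0, 1, 2, 3, 5, 6]]).all()

    def test_inharmonic_partials_not_matched(self):
        freqs = np.arange(0.0, 8000.0, 10.0)
        frame = np.full(len(freqs), -120.0)
        for f in (440.0, 1234.0):  # partials unrelated to a 150 Hz comb
            i = int(round(f / 10.0))
            frame[i] = 0.0
        hf, _ = pick_harmonics(freqs, frame, 150.0, 10)
        found = hf[np.isfinite(hf)]
        assert all(min(abs(f - 440.0), abs(f - 1234.0)) < 20.0 for f in found)
        assert len(found) <= 3  # 440 matches k=3, 1234 matches k=8 windows


class TestFormantTrend:
    def test_single_peak_filter_gives_single_envelope_peak(self, focused_spec):
        """A frame through the merged-formant filter shows one envelope peak
        near 1.8 kHz in the 1-3 kHz region."""
        mid = focused_spec.mag_db.shape[1] // 2
        frame = focused_spec.frame(mid)
        f0 = estimate_f0(focused_spec.freqs, frame)
        hf, hl = pick_harmonics(focused_spec.freqs, frame, f0, 25)
        trend = estimate_formant_trend(hf, hl)
        assert trend is not None
        in_band = trend.peak_freqs[(trend.peak_freqs > 1000) & (trend.peak_freqs < 3000)]
        assert len(in_band) >= 1
        strongest = in_band[
            np.argmax(trend.peak_levels[(trend.peak_freqs > 1000) & (trend.peak_freqs < 3000)])
        ]
        assert strongest == pytest.approx(1800.0, abs=80.0)

    def test_flat_comb_gives_flat_envelope(self):
        hf = 150.0 * np.arange(1, 21)
        hl = np.zeros(20)
        trend = estimate_formant_trend(hf, hl)
        inner = (trend.env_freqs > 300) & (trend.env_freqs < 2700)
        assert np.ptp(trend.env_levels[inner]) < 1.0

    def test_neutral_filter_gives_multiple_envelope_peaks(self, normal_spec):
        """The pre-merge neutral filter has several separated formants below
        4 kHz."""
        mid = normal_spec.mag_db.shape[1] // 2
        frame = normal_spec.frame(mid)
        f0 = estimate_f0(normal_spec.freqs, frame)
        hf, hl = pick_harmonics(normal_spec.freqs, frame, f0, 26)
        trend = estimate_formant_trend(hf, hl)
        assert trend is not None
        assert np.sum(trend.peak_freqs < 4000.0) >= 3

    def test_too_few_harmonics_skipped(self):
        assert estimate_formant_trend(np.array([150.0, 300.0, np.nan]), np.zeros(3)) is None


class TestEnergyRatio:
    freqs = np.arange(0.0, 8001.0, 10.0)

    def test_single_tone_in_band_gives_unity(self):
        frame = np.full(len(self.freqs), -300.0)
        frame[150] = 0.0  # 1.5 kHz
        assert energy_ratio(self.freqs, frame, 1000, 2000, 8000) == pytest.approx(1.0, abs=1e-6)

    def test_flat_spectrum_gives_squared_band_fraction(self):
        frame = np.zeros(len(self.freqs))
        eR = energy_ratio(self.freqs, frame, 1000, 2000, 8000)
        assert eR == pytest.approx((1.0 / 8.0) ** 2, rel=0.01)

    def test_two_tone_arithmetic(self):
        # in-band magnitude 3, out-of-band magnitude 1 -> (3/4)^2
        frame = np.full(len(self.freqs), -300.0)
        frame[150] = 20 * np.log10(3.0)
        frame[400] = 0.0
        assert energy_ratio(self.freqs, frame, 1000, 2000, 8000) == pytest.approx(0.5625, rel=1e-3)

    def test_power_variant_two_tones(self):
        # prose form: squared magnitudes 9 vs 1, ratio not squared -> 0.9
        frame = np.full(len(self.freqs), -300.0)
        frame[150] = 20 * np.log10(3.0)
        frame[400] = 0.0
        eR = energy_ratio(self.freqs, frame, 1000, 2000, 8000, variant="power")
        assert eR == pytest.approx(0.9, rel=1e-3)

    def test_full_band_is_unity(self):
        rng = np.random.default_rng(3)
        frame = rng.uniform(-60, 0, len(self.freqs))
        assert energy_ratio(self.freqs, frame, 0, 8000, 8000) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        lo=st.floats(min_value=0, max_value=3000),
        width=st.floats(min_value=100, max_value=4000),
        grow=st.floats(min_value=10, max_value=1000),
    )
    def test_monotone_in_band_width(self, lo, width, grow):
        rng = np.random.default_rng(7)
        frame = rng.uniform(-60, 0, len(self.freqs))
        hi = min(lo + width, 8000.0)
        hi2 = min(hi + grow, 8000.0)
        narrow = energy_ratio(self.freqs, frame, lo, hi, 8000)
        wide = energy_ratio(self.freqs, frame, lo, hi2, 8000)
        assert 0.0 <= narrow <= wide <= 1.0


class TestFocusTrace:
    def test_constant_focused_clip_is_constant(self, focused_spec, focused_clip):
        tr = focus_trace(focused_spec)
        half_win = 0.5 * focused_spec.params.window_samples / focused_spec.fs
        interior = (tr.times > half_win) & (tr.times < focused_clip.duration - half_win)
        vals = tr.eR[interior & np.isfinite(tr.eR)]
        assert np.ptp(vals) < 0.05
        assert np.all((vals >= 0) & (vals <= 1))

    def test_silent_clip_all_undefined(self):
        clip = AudioClip(np.zeros(44100), 44100.0)
        spec = compute_spectrogram(clip, StftParams(window_samples=2048, overlap=0.9))
        tr = focus_trace(spec)
        assert np.all(np.isnan(tr.eR))


class TestDetectTransitions:
    def make_trace(self, values, hop=0.01):
        times = np.arange(len(values)) * hop
        return FocusTrace(times=times, eR=np.asarray(values), band=(1000, 2000), fmax=8000, hop_s=hop)

    def test_step_gives_single_entry_at_step_time(self):
        v = [0.1] * 200 + [0.7] * 200
        tr = self.make_trace(v)
        entries, exits = detect_transitions(tr, threshold=0.35, hysteresis=0.1, min_hold=0.1)
        assert len(entries) == 1
        assert entries[0] == pytest.approx(2.0, abs=tr.hop_s)
        assert exits == []

    def test_constant_trace_gives_no_events(self):
        tr = self.make_trace([0.5] * 300)
        entries, exits = detect_transitions(tr, threshold=0.35)
        # already inside at t=0: a single initial entry at most
        assert len(entries) <= 1
        assert exits == []
        tr_low = self.make_trace([0.1] * 300)
        assert detect_transitions(tr_low, threshold=0.35) == ([], [])

    def test_chatter_around_threshold_suppressed(self):
        rng = np.random.default_rng(0)
        v = 0.35 + 0.02 * rng.choice([-1.0, 1.0], size=500)
        tr = self.make_trace(v)
        entries, exits = detect_transitions(tr, threshold=0.35, hysteresis=0.1, min_hold=0.1)
        assert entries == []
        assert exits == []

    def test_entry_and_exit_pair(self):
        v = [0.05] * 150 + [0.6] * 150 + [0.05] * 150
        tr = self.make_trace(v)
        entries, exits = detect_transitions(tr, threshold=0.35, hysteresis=0.1, min_hold=0.1)
        assert len(entries) == 1 and len(exits) == 1
        assert entries[0] == pytest.approx(1.5, abs=tr.hop_s)
        assert exits[0] == pytest.approx(3.0, abs=tr.hop_s)
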