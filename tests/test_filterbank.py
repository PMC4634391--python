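"""Filterbank: design rules, band behaviour, decimation."""

import numpy as np
import pytest
from scipy import signal as sps

from stressmon.filterbank import (
    ECG_FS,
    TEB_FS,
    FilterSpec,
    apply_filter,
    decimate_to_if,
    design_filter,
    ecg_filter_chain,
    frequency_response,
    teb_filter_chain,
)


def tone(freq, fs, duration=240.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t + phase)


def rms_mid(x, frac=0.5):
    """RMS over the central fraction of a signal (avoids edge transients)."""
    n = len(x)
    lo = int(n * (1 - frac) / 2)
    return float(np.sqrt(np.mean(x[lo : n - lo] ** 2)))


class TestDesign:
    def test_fir_lowpass_dc_gain_is_unity(self):
        spec = FilterSpec("fir_lowpass", 100, (30.0,), ECG_FS)
        h = design_filter(spec)
        assert np.sum(h) == pytest.approx(1.0, abs=0.01)

    def test_ifir_lowpass_passband_and_stopband(self):
        spec = FilterSpec("ifir_lowpass", 1150, (0.1,), ECG_FS, stretch=25)
        mags = np.abs(frequency_response(spec, [0.05, 0.5]))
        assert mags[0] > 0.9
        assert mags[1] < 0.05

    def test_ifir_stores_only_sparse_taps(self):
        spec = FilterSpec("ifir_lowpass", 1150, (0.1,), ECG_FS, stretch=25)
        taps = design_filter(spec)
        assert len(taps) == 1151
        nonzero = np.flatnonzero(taps)
        assert np.all(nonzero % 25 == 0)
        assert len(nonzero) <= 1150 // 25 + 1

    @pytest.mark.parametrize("spec", [
        FilterSpec("fir_lowpass", 100, (0.5,), ECG_FS),
        FilterSpec("fir_lowpass", 100, (30.0,), ECG_FS),
        FilterSpec("ifir_lowpass", 400, (0.1,), TEB_FS, stretch=10),
        FilterSpec("ifir_bandpass", 1150, (0.1, 0.5), ECG_FS, stretch=25),
    ])
    def test_linear_phase_group_delay_is_half_order(self, spec):
        taps = design_filter(spec)
        assert np.allclose(taps, taps[::-1], atol=1e-12)  # symmetric
        assert spec.group_delay == spec.order // 2

    def test_ifir_matches_direct_narrowband_design_in_passband(self):
        """The zero-stuffed realisation equals a direct design of the same
        band specs over the passband (images live far outside it)."""
        spec = FilterSpec("ifir_lowpass", 400, (0.1,), TEB_FS, stretch=10)
        direct = sps.firwin(401, 0.1, fs=TEB_FS)
        freqs = np.linspace(0.005, 0.05, 12)
        h_ifir = np.abs(frequency_response(spec, freqs))
        _, h_dir = sps.freqz(direct, worN=freqs, fs=TEB_FS)
        assert np.allclose(h_ifir, np.abs(h_dir), atol=0.08)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec("fir_lowpass", 100, (200.0,), ECG_FS)  # >= Nyquist
        with pytest.raises(ValueError):
            FilterSpec("fir_lowpass", 0, (1.0,), ECG_FS)
        with pytest.raises(ValueError):
            FilterSpec("ifir_lowpass", 401, (0.1,), TEB_FS, stretch=10)  # not divisible


class TestChains:
    def test_slow_tone_routed_to_fe1(self):
        x = tone(0.02, ECG_FS)
        out = ecg_filter_chain(x)
        assert rms_mid(out.fe1) > 10 * rms_mid(out.fe2)
        assert rms_mid(out.fe1) == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_respiration_tone_routed_to_fe2(self):
        x = tone(0.3, ECG_FS)
        out = ecg_filter_chain(x)
        assert rms_mid(out.fe2) > 10 * rms_mid(out.fe1)

    def test_band_partition_sweep(self):
        """Exactly one of FE1/FE2 dominates for tones outside the
        transition region around the 0.1 Hz band edge."""
        for f in [0.02, 0.04, 0.3, 0.4]:
            out = ecg_filter_chain(tone(f, ECG_FS))
            r1, r2 = rms_mid(out.fe1), rms_mid(out.fe2)
            ratio = r1 / r2 if f < 0.1 else r2 / r1
            assert ratio > 10, f"no dominance at {f} Hz (ratio {ratio:.2f})"

    def test_cardiac_tone_rejected_from_respiration_band(self):
        out = ecg_filter_chain(tone(1.2, ECG_FS, duration=120.0))
        assert rms_mid(out.fe2) < 0.02
        assert rms_mid(out.fe3) == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_zero_in_zero_out(self):
        out = ecg_filter_chain(np.zeros(40000))
        assert np.allclose(out.fe1, 0) and np.allclose(out.fe2, 0)
        assert np.allclose(out.fe3, 0)

    def test_linearity_superposition(self, rng):
        x = rng.standard_normal(8000)
        y = rng.standard_normal(8000)
        a, b = 2.5, -0.7
        out_sum = teb_filter_chain(a * x + b * y)
        out_x = teb_filter_chain(x)
        out_y = teb_filter_chain(y)
        assert np.allclose(out_sum.fe2, a * out_x.fe2 + b * out_y.fe2, atol=1e-9)

    def test_teb_band_routing(self):
        resp = teb_filter_chain(tone(0.25, TEB_FS, duration=120.0))
        assert rms_mid(resp.fe2) > 5 * rms_mid(resp.fe3)
        pulse = teb_filter_chain(tone(1.2, TEB_FS, duration=120.0))
        assert rms_mid(pulse.fe3) > 20 * rms_mid(pulse.fe2)

    def test_too_short_input_flagged(self):
        with pytest.raises(ValueError, match="at least"):
            ecg_filter_chain(np.zeros(100))


class TestDecimation:
    def test_constant_preserved(self):
        y = decimate_to_if(np.full(1000, 3.7), ECG_FS)
        assert np.all(y == 3.7)

    def test_length_arithmetic(self):
        assert len(decimate_to_if(np.zeros(3000), ECG_FS)) == 600
        assert len(decimate_to_if(np.zeros(3001), ECG_FS)) == 600
        assert len(decimate_to_if(np.zeros(200), TEB_FS)) == 100

    def test_slow_sinusoid_matches_analytic_resampling(self):
        t = np.arange(30000) / ECG_FS
        x = np.sin(2 * np.pi * 0.05 * t)
        y = decimate_to_if(x, ECG_FS)
        t50 = np.arange(len(y)) / 50.0
        assert np.max(np.abs(y - np.sin(2 * np.pi * 0.05 * t50))) < 1e-6

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            decimate_to_if(np.zeros(100), 130.0)


def test_apply_filter_compensates_group_delay():
    """A tone passed through a linear-phase filter keeps its phase."""
    spec = FilterSpec("fir_lowpass", 100, (30.0,), ECG_FS)
    taps = design_filter(spec)
    t = np.arange(5000) / ECG_FS
    x = np.sin(2 * np.pi * 1.0 * t)
    y = apply_filter(taps, x)
    mid = slice(1000, 4000)
    assert np.allclose(y[mid], x[mid], atol=0.01)
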