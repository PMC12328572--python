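"""Stimulus synthesis: calibration, notch geometry, trial assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import signal as sps

from envlock import stimuli as st

FS = 48000.0


class TestSynthSam:
    @pytest.mark.parametrize("level", [20.0, 45.0, 65.0, 80.0])
    @pytest.mark.parametrize("f_c", [2000.0, 4000.0, 7500.0])
    def test_level_calibration_within_0p1_db(self, level, f_c):
        s = st.synth_sam(f_c, 128.0, level, 0.5, 0.02, FS)
        assert abs(st.measure_level(s) - level) < 0.1

    def test_65_db_rms_matches_closed_form(self):
        # 20e-6 * 10^(65/20) Pa, from the dB SPL definition
        s = st.synth_sam(4000.0, 128.0, 65.0, 0.5, 0.02, FS)
        k = int(0.02 * FS)
        rms = np.sqrt(np.mean(s.waveform[k:-k] ** 2))
        assert rms == pytest.approx(20e-6 * 10 ** (65 / 20), rel=1e-3)

    def test_full_depth_envelope_reaches_zero(self):
        s = st.synth_sam(4000.0, 128.0, 60.0, 0.5, 0.0, FS)
        env = np.abs(sps.hilbert(s.waveform))
        # steady region away from filter edge effects
        assert env[2000:-2000].min() < 0.02 * env.max()

    def test_sample_count_and_ramp_extent(self):
        s = st.synth_sam(4000.0, 128.0, 65.0, 0.3, 0.02, FS)
        assert s.n_samples == int(0.3 * FS)
        n_ramp = int(0.02 * FS)
        unramped_rms = np.sqrt(np.mean(s.waveform[n_ramp:-n_ramp] ** 2))
        ramp_rms = np.sqrt(np.mean(s.waveform[:n_ramp] ** 2))
        assert ramp_rms < 0.7 * unramped_rms

    def test_rejects_aliasing_and_bad_duration(self):
        with pytest.raises(ValueError):
            st.synth_sam(30000.0, 128.0, 65.0, 0.3, 0.02, FS)
        with pytest.raises(ValueError):
            st.synth_sam(4000.0, 128.0, 65.0, -1.0, 0.02, FS)
        with pytest.raises(ValueError):
            st.synth_sam(4000.0, 128.0, 65.0, 0.03, 0.02, FS)


class TestNotchedNoise:
    @pytest.mark.parametrize("f_c,w,lo,hi", [
        (4000.0, 20.0, 3600.0, 4400.0),   # the published example geometry
        (4000.0, 30.0, 3400.0, 4600.0),
        (5000.0, 20.0, 4500.0, 5500.0),
    ])
    def test_notch_edges_linear_in_percent(self, f_c, w, lo, hi):
        spec = st.NotchedNoiseSpec(f_c=f_c, w=w, spectral_level=30.0,
                                   f_hi=8500.0)
        assert spec.notch_edges == (pytest.approx(lo), pytest.approx(hi))

    def test_notch_wider_than_band_rejected(self):
        spec = st.NotchedNoiseSpec(f_c=4000.0, w=20.0, spectral_level=30.0,
                                   f_lo=3700.0, f_hi=8500.0)
        with pytest.raises(ValueError):
            spec.validate()

    def test_spectral_level_and_notch_floor(self, notch_spec):
        nz = st.synth_noise(notch_spec, 1.0, FS)
        passband = st.measure_spectral_level(nz, (1000.0, 3500.0))
        in_notch = st.measure_spectral_level(nz, (3700.0, 4300.0),
                                             check_line=False)
        assert passband == pytest.approx(30.0, abs=0.5)
        assert passband - in_notch >= 40.0

    def test_uncorrelated_ears(self, notch_spec):
        nz = st.synth_noise(notch_spec, 1.0, FS)
        r = np.corrcoef(nz.channel(0), nz.channel(1))[0, 1]
        assert abs(r) < 0.05

    def test_seeded_determinism_bit_identical(self, notch_spec):
        a = st.synth_noise(notch_spec, 0.3, FS)
        b = st.synth_noise(notch_spec, 0.3, FS)
        assert np.array_equal(a.waveform, b.waveform)

    def test_interaural_modes(self, notch_spec):
        from dataclasses import replace
        diotic = st.synth_noise(replace(notch_spec, interaural="diotic"), 0.2, FS)
        assert np.array_equal(diotic.channel(0), diotic.channel(1))
        left = st.synth_noise(replace(notch_spec, interaural="left_only"), 0.2, FS)
        assert np.all(left.channel(1) == 0)
        assert np.any(left.channel(0) != 0)


class TestSpectralMeasurement:
    def test_flat_noise_total_vs_spectral_level(self):
        # L_total = spectral level + 10*log10(bandwidth), Parseval identity
        spec = st.NotchedNoiseSpec(f_c=4000.0, w=20.0, spectral_level=40.0,
                                   f_lo=100.0, f_hi=8000.0, seed=3,
                                   interaural="diotic")
        nz = st.synth_noise(spec, 1.0, FS)
        bw = (3600 - 100) + (8000 - 4400)
        assert st.measure_level(nz) == pytest.approx(
            40.0 + 10 * math.log10(bw), abs=0.5)

    def test_pure_tone_rejected(self):
        tone = st.synth_sam(4000.0, 128.0, 65.0, 0.5, 0.02, FS, depth=0.0)
        with pytest.raises(ValueError):
            st.measure_spectral_level(tone, (3500.0, 4500.0))

    def test_empty_band_rejected(self, notch_spec):
        nz = st.synth_noise(notch_spec, 0.2, FS)
        with pytest.raises(ValueError):
            st.measure_spectral_level(nz, (5000.0, 4000.0))


class TestLevelArithmetic:
    @pytest.mark.parametrize("spectral,sam,g", [
        (30.0, 65.0, -35.0),
        (25.0, 60.0, -35.0),
        (50.0, 50.0, 0.0),
    ])
    def test_relative_spectral_level(self, spectral, sam, g):
        assert st.relative_spectral_level(spectral, sam) == pytest.approx(g)
        assert st.spectral_level_from_relative(g, sam) == pytest.approx(spectral)

    @pytest.mark.parametrize("ipd,f_m,itd_ms", [
        (0.8 * math.pi, 128.0, 3.125),
        (0.0, 128.0, 0.0),
        (2 * math.pi, 128.0, 7.8125),  # one full modulation period
    ])
    def test_ipd_itd_values(self, ipd, f_m, itd_ms):
        assert st.ipd_to_itd(ipd, f_m) * 1e3 == pytest.approx(itd_ms)

    @settings(deadline=None, max_examples=50)
    @given(ipd=hst.floats(0, 2 * math.pi), f_m=hst.floats(1.0, 2000.0))
    def test_ipd_itd_roundtrip(self, ipd, f_m):
        assert st.itd_to_ipd(st.ipd_to_itd(ipd, f_m), f_m) == pytest.approx(
            ipd, abs=1e-12)

    def test_nonpositive_fm_rejected(self):
        with pytest.raises(ValueError):
            st.ipd_to_itd(0.4 * math.pi, 0.0)


def _envelope_delay(left: np.ndarray, right: np.ndarray, fs: float) -> float:
    """Interaural envelope delay via cross-correlation (oracle).

    Band-passes around the carrier first (the envelope cue lives in the
    carrier band; the diotic low-pass masker below 1.3 kHz must not enter
    the comparison).  A left-ear lead yields a negative lag.
    """
    sos = sps.butter(4, [2000.0, 6000.0], btype="bandpass", fs=fs,
                     output="sos")
    left = sps.sosfiltfilt(sos, left)
    right = sps.sosfiltfilt(sos, right)
    el = np.abs(sps.hilbert(left))
    er = np.abs(sps.hilbert(right))
    el -= el.mean()
    er -= er.mean()
    lags = sps.correlation_lags(el.size, er.size)
    cc = sps.correlate(el, er)
    keep = np.abs(lags) < fs / 128 / 2  # within half a modulation period
    return lags[keep][np.argmax(cc[keep])] / fs


class Test2AFCTrial:
    def _spec(self, delta):
        return st.BinauralTrialSpec(delta_ipd_env=delta, fs=FS)

    def test_interval_symmetry_fields(self):
        spec = self._spec(0.4 * math.pi)
        assert spec.ipd_env == pytest.approx(0.2 * math.pi)
        assert spec.delta_itd_env == pytest.approx(
            0.4 * math.pi / (2 * math.pi * 128.0))

    def test_envelope_lag_difference_recoverable(self):
        # quiet condition, delta = 0.8*pi: the inter-interval difference of
        # the interaural envelope lags must equal 3.125 ms
        trial = st.assemble_2afc_trial(self._spec(0.8 * math.pi), "Q", 65.0,
                                       seed=3)
        d1 = _envelope_delay(trial.interval1.channel(0),
                             trial.interval1.channel(1), FS)
        d2 = _envelope_delay(trial.interval2.channel(0),
                             trial.interval2.channel(1), FS)
        assert abs(d2 - d1) * 1e3 == pytest.approx(3.125, abs=0.15)
        leading = "left" if (d2 - d1) < 0 else "right"
        assert leading == trial.correct_answer

    def test_monaural_noise_lateralization(self, notch_spec):
        trial = st.assemble_2afc_trial(self._spec(0.4 * math.pi), "Mon_left",
                                       65.0, noise=notch_spec, seed=1)
        for iv in (trial.interval1, trial.interval2):
            levels = [st.measure_spectral_level(iv, (4600.0, 8000.0), ch)
                      for ch in (0, 1)]
            # notched noise occupies the left channel only; the right holds
            # just the low-pass masker, far quieter above the notch
            assert levels[0] > levels[1] + 20.0

    def test_condition_noise_consistency_enforced(self, notch_spec):
        with pytest.raises(ValueError):
            st.assemble_2afc_trial(self._spec(0.4 * math.pi), "Q", 65.0,
                                   noise=notch_spec)
        with pytest.raises(ValueError):
            st.assemble_2afc_trial(self._spec(0.4 * math.pi), "Bin", 65.0)

    def test_cap_enforced(self):
        with pytest.raises(ValueError):
            st.assemble_2afc_trial(self._spec(0.9 * math.pi), "Q", 65.0)
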