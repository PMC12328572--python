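"""Vector strength, Rayleigh statistics, windows, level functions."""

import math

import numpy as np
import pytest

from envlock import spike_analysis as sa
from envlock import stimuli as st
from envlock.periphery import FiberParams, SpikeTrainSet

F_M = 128.0
PERIOD = 1.0 / F_M


def spikes_at_phases(phases, n_cycles=1, f_m=F_M):
    """Spike times hitting the given phases over consecutive cycles."""
    out = []
    for c in range(n_cycles):
        for ph in phases:
            out.append((c + ph / (2 * math.pi)) / f_m)
    return np.array(out)


class TestVectorStrength:
    def test_single_phase_gives_one(self):
        t = spikes_at_phases([0.3], n_cycles=20)
        assert sa.vector_strength(t, F_M).vs == pytest.approx(1.0)

    def test_four_symmetric_phases_give_zero(self):
        t = spikes_at_phases([0, math.pi / 2, math.pi, 3 * math.pi / 2],
                             n_cycles=5)
        assert sa.vector_strength(t, F_M).vs == pytest.approx(0.0, abs=1e-12)

    def test_two_orthogonal_phases(self):
        # |(1 + i)/2| = sqrt(2)/2, by the direct complex-sum definition
        t = spikes_at_phases([0, math.pi / 2])
        assert sa.vector_strength(t, F_M).vs == pytest.approx(
            math.sqrt(2) / 2)

    def test_empty_window_flagged_not_zero(self):
        r = sa.vector_strength(np.array([5.0]), F_M, window=(0.0, 1.0))
        assert r.vs is None and r.p is None and not r.significant
        assert not r.defined

    def test_invariant_to_whole_period_shift(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.random(200))
        v0 = sa.vector_strength(t, F_M).vs
        v1 = sa.vector_strength(t + 7 * PERIOD, F_M).vs
        assert v1 == pytest.approx(v0, abs=1e-9)

    def test_uniform_spikes_expected_vs(self):
        # E[VS] for K uniform phases ~ sqrt(pi)/(2*sqrt(K))
        rng = np.random.default_rng(42)
        K = 100
        draws = [abs(np.mean(np.exp(2j * math.pi * rng.random(K))))
                 for _ in range(1000)]
        expected = math.sqrt(math.pi) / (2 * math.sqrt(K))
        assert np.mean(draws) == pytest.approx(expected, rel=0.1)


class TestRayleigh:
    def test_zero_vs_gives_p_one(self):
        assert sa.rayleigh_p(0.0, 500) == 1.0

    def test_formula_value(self):
        assert sa.rayleigh_p(0.3, 100) == pytest.approx(math.exp(-9.0))

    def test_significance_rule(self):
        res = sa.vector_strength(
            spikes_at_phases([0.0, 0.4], n_cycles=26)[:51] * 1.0, F_M)
        # 51 spikes, strongly modulated: K > 50 and p < 0.001
        assert res.K == 51 and res.significant
        # K = 50 can never be significant regardless of vs
        res50 = sa.vector_strength(spikes_at_phases([0.1], n_cycles=50), F_M)
        assert res50.K == 50 and not res50.significant

    def test_p_monotone_in_k_and_vs(self):
        for vs in (0.1, 0.3, 0.6):
            ps = [sa.rayleigh_p(vs, k) for k in range(0, 200, 10)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))
        for k in (10, 100):
            ps = [sa.rayleigh_p(v, k) for v in np.linspace(0, 1, 20)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestPhaseHistogram:
    def test_single_phase_single_bin(self):
        t = spikes_at_phases([0.31 * 2 * math.pi], n_cycles=30)
        centers, rate = sa.phase_histogram(t, F_M, n_bins=16,
                                           window=(0.0, 30 * PERIOD))
        assert np.count_nonzero(rate) == 1

    def test_rates_sum_to_total_rate(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.random(400))
        _, rate = sa.phase_histogram(t, F_M, n_bins=32, window=(0.0, 1.0),
                                     n_reps=2)
        assert rate.sum() == pytest.approx(400 / 2 / 1.0)

    def test_binned_vs_matches_unbinned(self):
        rng = np.random.default_rng(2)
        # von-Mises-ish spikes concentrated near one phase
        phases = np.mod(rng.normal(1.0, 0.8, 2000), 2 * math.pi)
        t = phases / (2 * math.pi * F_M)
        n_bins = 64
        centers, rate = sa.phase_histogram(t, F_M, n_bins=n_bins,
                                           window=(0.0, PERIOD))
        binned_vs = abs(np.sum(rate * np.exp(1j * centers))) / rate.sum()
        exact = sa.vector_strength(t, F_M).vs
        assert binned_vs == pytest.approx(exact, abs=2.0 / n_bins)

    def test_requires_two_bins(self):
        with pytest.raises(ValueError):
            sa.phase_histogram(np.array([0.1]), F_M, n_bins=1)


class TestAnalysisWindow:
    @pytest.mark.parametrize("duration", [2.4, 3.0])
    def test_window_skips_onset_response(self, duration):
        assert sa.analysis_window(duration) == (0.02, duration)

    def test_too_short_stimulus_rejected(self):
        with pytest.raises(ValueError):
            sa.analysis_window(0.01)


def _make_set(trains, duration=1.0, f_m=F_M):
    return SpikeTrainSet(trains=[np.asarray(t, dtype=float) for t in trains],
                         fiber=FiberParams(), duration=duration, f_m=f_m)


class TestLevelFunctions:
    def test_identical_repetitions_zero_sd(self):
        t = spikes_at_phases([0.5], n_cycles=100)
        lf = sa.level_functions({40.0: _make_set([t, t, t])})
        assert lf.rate_sd[0] == 0.0 and lf.vs_sd[0] == 0.0

    def test_zero_spike_level_flagged_undefined(self):
        t = spikes_at_phases([0.5], n_cycles=100)
        lf = sa.level_functions({0.0: _make_set([np.array([])] * 3),
                                 40.0: _make_set([t, t])})
        assert lf.rate_mean[0] == 0.0 and np.isnan(lf.vs_mean[0])
        assert not lf.significant[0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sa.level_functions({})


class TestUnitCharacterization:
    def test_cf_recovered_from_synthetic_tuning_curve(self):
        freqs = np.linspace(3000, 6000, 31)
        rates = 5 + 120 * np.exp(-0.5 * ((freqs - 4500) / 500) ** 2)
        rates += np.random.default_rng(0).normal(0, 4, freqs.size)
        out = sa.estimate_cf_threshold_sr(freq_response=(freqs, rates))
        assert abs(out["cf"] - 4500) <= 2 * (freqs[1] - freqs[0])

    def test_flat_curve_flagged(self):
        out = sa.estimate_cf_threshold_sr(
            freq_response=(np.arange(5.0), np.full(5, 7.0)))
        assert out["cf"] is None and out["flags"]

    def test_threshold_from_rate_level(self):
        levels = np.arange(0.0, 80.0, 5.0)
        rates = np.where(levels >= 30, 100.0, 8.0)
        out = sa.estimate_cf_threshold_sr(
            rate_level=(levels, rates), silence_counts=(192, 24.0))
        assert out["threshold"] == 30.0

    def test_all_spontaneous_threshold_undefined(self):
        out = sa.estimate_cf_threshold_sr(
            rate_level=(np.arange(5.0), np.full(5, 8.0)),
            silence_counts=(192, 24.0))
        assert out["threshold"] is None and out["flags"]

    def test_sr_class_boundary(self):
        out = sa.estimate_cf_threshold_sr(silence_counts=(240, 24.0))
        assert out["sr"] == pytest.approx(10.0) and out["sr_class"] == "low"
        out_hi = sa.estimate_cf_threshold_sr(silence_counts=(480, 24.0))
        assert out_hi["sr_class"] == "high"


class TestReanalysis:
    def test_spike_table_analysis_shape(self):
        t = spikes_at_phases([0.5], n_cycles=60)
        df = sa.analyze_spike_table({"A": [t, t], "B": [t]}, f_m=F_M,
                                    duration=1.0)
        assert list(df["fiber_id"]) == ["A", "B"]
        assert (df["vs"] > 0.99).all()
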