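"""Seeded generators for virtual auditory-nerve fiber populations and
simulated observer cohorts.

The distributions emulate the recorded sample's reported structure — CFs
between 2 and 7.5 kHz, a bimodal spontaneous-rate (SR) mixture split at
18 spikes/s, SR-dependent thresholds, and observers whose envelope-IPD
thresholds all fall below the 0.8*pi inclusion cap — but their exact
shapes are this package's own choices, recorded here in one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import periphery, spike_analysis, stimuli
from .periphery import SR_CLASS_BOUNDARY, FiberParams, SpikeTrainSet
from .psychophysics import CAP_DELTA_IPD, ObserverParams

LOW_SR_SAT_RATE = 180.0
HIGH_SR_SAT_RATE = 250.0


@dataclass
class CohortSpec:
    """Parameters of the virtual fiber population and observer cohort."""

    n_fibers: int = 24
    cf_range: Tuple[float, float] = (2000.0, 7500.0)
    low_sr_fraction: float = 0.4
    low_sr_scale: float = 6.0            # exponential scale, spikes/s
    high_sr_mean: float = 70.0           # truncated-normal mean, spikes/s
    high_sr_sd: float = 25.0
    threshold_base: float = 15.0         # dB SPL, high-SR fibers
    threshold_sr_offset: float = 5.0     # extra dB for low-SR fibers
    threshold_jitter_sd: float = 2.0
    n_observers: int = 7
    alpha_range: Tuple[float, float] = (0.1 * math.pi, 0.6 * math.pi)
    lapse_range: Tuple[float, float] = (0.0, 0.04)
    master_seed: int = 0


def _rng(spec: CohortSpec, label: str) -> np.random.Generator:
    ss = np.random.SeedSequence(spec.master_seed)
    # stable per-purpose streams derived from the master seed
    offsets = {"fibers": 0, "observers": 1}
    return np.random.default_rng(ss.spawn(2)[offsets[label]])


def sample_fiber_population(spec: CohortSpec) -> List[FiberParams]:
    """Draw a fiber population: log-uniform CFs, a two-component SR mixture
    (exponential low-SR, truncated-normal high-SR), and thresholds higher
    for low-SR fibers.  Identical master seed -> identical population."""
    if spec.n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    lo, hi = spec.cf_range
    if not (0 < lo < hi):
        raise ValueError("empty or invalid CF range")
    rng = _rng(spec, "fibers")
    fibers: List[FiberParams] = []
    for _ in range(spec.n_fibers):
        cf = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        if rng.random() < spec.low_sr_fraction:
            sr = float(rng.exponential(spec.low_sr_scale))
            while sr >= SR_CLASS_BOUNDARY:
                sr = float(rng.exponential(spec.low_sr_scale))
        else:
            sr = float(rng.normal(spec.high_sr_mean, spec.high_sr_sd))
            while not (SR_CLASS_BOUNDARY <= sr <= 200.0):
                sr = float(rng.normal(spec.high_sr_mean, spec.high_sr_sd))
        low = sr < SR_CLASS_BOUNDARY
        threshold = (spec.threshold_base
                     + (spec.threshold_sr_offset if low else 0.0)
                     + float(rng.normal(0.0, spec.threshold_jitter_sd)))
        fibers.append(FiberParams(
            cf=cf, sr=sr, threshold=threshold,
            sat_rate=LOW_SR_SAT_RATE if low else HIGH_SR_SAT_RATE,
        ))
    return fibers


def make_fiber(cf: float, sr: float, threshold: Optional[float] = None,
               **overrides) -> FiberParams:
    """Instantiate a single fiber directly, e.g. the example units
    (CF 4.5 kHz / SR 11.3) and (CF 4.1 kHz / SR 78.5)."""
    low = sr < SR_CLASS_BOUNDARY
    if threshold is None:
        threshold = 15.0 + (5.0 if low else 0.0)
    return FiberParams(
        cf=cf, sr=sr, threshold=threshold,
        sat_rate=overrides.pop("sat_rate",
                               LOW_SR_SAT_RATE if low else HIGH_SR_SAT_RATE),
        **overrides,
    )


def sample_observer_cohort(spec: CohortSpec) -> List[ObserverParams]:
    """Draw simulated listeners: alpha log-uniform below the 0.8*pi cap,
    lapse uniform in ``lapse_range``."""
    if spec.n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    a_lo, a_hi = spec.alpha_range
    if a_hi > CAP_DELTA_IPD:
        raise ValueError("alpha_range exceeds the 0.8*pi inclusion cap")
    rng = _rng(spec, "observers")
    out = []
    for i in range(spec.n_observers):
        alpha = float(np.exp(rng.uniform(math.log(a_lo), math.log(a_hi))))
        lapse = float(rng.uniform(*spec.lapse_range))
        out.append(ObserverParams(alpha=alpha, lapse=lapse,
                                  seed=int(rng.integers(2**31))))
    return out


# ---------------------------------------------------------------------------
# virtual recording sessions
# ---------------------------------------------------------------------------

#: notch width (%) x relative spectral level (dB/Hz) grid of the single-unit
#: experiment, plus the in-quiet reference
NOTCH_GRID = [(20, -55.0), (20, -45.0), (20, -35.0),
              (30, -55.0), (30, -45.0), (30, -35.0)]


@dataclass
class RecordingSession:
    """Everything the per-unit characterization protocol yields."""

    fiber: FiberParams
    freq_response: Tuple[np.ndarray, np.ndarray]   # probe freqs, mean rates
    rate_level: Tuple[np.ndarray, np.ndarray]      # probe levels, mean rates
    silence_counts: Tuple[float, float]            # (n spikes, seconds)
    sam_sets: Dict[str, SpikeTrainSet] = field(default_factory=dict)

    def characterize(self) -> dict:
        return spike_analysis.estimate_cf_threshold_sr(
            freq_response=self.freq_response,
            rate_level=self.rate_level,
            silence_counts=self.silence_counts,
        )


def _burst_rates(fiber, freqs, levels, duration, ramp, fs, n_reps, ss):
    """Mean driven rate for tone bursts over a (freq, level) probe list."""
    rates = []
    for (f, lv), child in zip([(f, l) for f, l in zip(freqs, levels)], ss):
        tone = stimuli.synth_sam(f, 16.0, lv, duration, ramp, fs, depth=0.0)
        st = periphery.simulate_fiber_response(
            tone, fiber, n_reps=n_reps,
            seed=int(child.generate_state(1)[0] % 2**31))
        counts = [t.size for t in st.trains]
        rates.append(np.mean(counts) / duration)
    return np.asarray(rates)


def generate_recording_session(
    fiber: FiberParams,
    seed: int = 0,
    fs: float = stimuli.FS_RECORDING,
    sam_level: float = 60.0,
    sam_duration: float = 2.4,
    sam_reps: int = 10,
    silence_duration: float = 24.0,
    burst_duration: float = 0.05,
    noise_band: Tuple[float, float] = (300.0, 16300.0),
    include_sam: bool = True,
) -> RecordingSession:
    """Render the full per-unit protocol through the periphery model.

    Tone bursts across frequency (5 reps, 10 dB above nominal threshold) to
    probe CF; tone bursts across level at CF (10 reps) for the rate-level
    function; a silence epoch for SR; then SAM tones in quiet and at the
    six-condition notched-noise grid.
    """
    ss = np.random.SeedSequence(seed)
    s_tune, s_rl, s_sil, s_sam = ss.spawn(4)

    # CF probe: 13 frequencies over +/- 0.75 octave at threshold + 10 dB
    probe_f = fiber.cf * 2.0 ** np.linspace(-0.75, 0.75, 13)
    probe_f = probe_f[probe_f < fs / 2 / 1.2]
    tune_rates = _burst_rates(
        fiber, probe_f, [fiber.threshold + 10.0] * probe_f.size,
        burst_duration, 0.005, fs, 5, s_tune.spawn(probe_f.size))

    # rate-level at CF, 0..80 dB in 5-dB steps
    probe_l = np.arange(0.0, 81.0, 5.0)
    rl_rates = _burst_rates(
        fiber, [fiber.cf] * probe_l.size, probe_l,
        burst_duration, 0.005, fs, 10, s_rl.spawn(probe_l.size))

    # spontaneous rate from silence (constant-rate draw; the cascade is at
    # rest so the rate trace is sr everywhere)
    sil_rng = np.random.default_rng(s_sil)
    sil_train = periphery.generate_spikes(
        np.full(int(silence_duration * 1000), fiber.sr), fiber,
        sil_rng, fs=1000.0)
    silence_counts = (float(sil_train.size), silence_duration)

    sam_sets: Dict[str, SpikeTrainSet] = {}
    if include_sam:
        sam_children = s_sam.spawn(1 + len(NOTCH_GRID))
        quiet = stimuli.synth_sam(fiber.cf, 128.0, sam_level, sam_duration,
                                  0.02, fs)
        sam_sets["quiet"] = periphery.simulate_fiber_response(
            quiet, fiber, n_reps=sam_reps,
            seed=int(sam_children[0].generate_state(1)[0] % 2**31))
        for (w, g), child in zip(NOTCH_GRID, sam_children[1:]):
            def factory(nseed, w=w, g=g):
                sam = stimuli.synth_sam(fiber.cf, 128.0, sam_level,
                                        sam_duration, 0.02, fs)
                nspec = stimuli.NotchedNoiseSpec(
                    f_c=fiber.cf, w=w,
                    spectral_level=stimuli.spectral_level_from_relative(g, sam_level),
                    f_lo=noise_band[0], f_hi=min(noise_band[1], 0.45 * fs),
                    interaural="diotic", seed=nseed)
                noise = stimuli.synth_noise(nspec, sam_duration, fs)
                wav = sam.waveform + noise.channel(0)
                from dataclasses import replace
                return replace(sam, waveform=wav)
            sam_sets[f"w{w}_g{int(g)}"] = periphery.simulate_fiber_response(
                factory, fiber, n_reps=sam_reps,
                seed=int(child.generate_state(1)[0] % 2**31))

    return RecordingSession(
        fiber=fiber,
        freq_response=(probe_f, tune_rates),
        rate_level=(probe_l, rl_rates),
        silence_counts=silence_counts,
        sam_sets=sam_sets,
    )


def session_delta_vs(session: RecordingSession) -> pd.DataFrame:
    """Fig-4-style table: VS per notched-noise condition and its change
    relative to quiet."""
    if "quiet" not in session.sam_sets:
        raise ValueError("session has no SAM responses; delta-VS unavailable")
    base = spike_analysis.summarize_set(session.sam_sets["quiet"])
    rows = []
    for name, st in session.sam_sets.items():
        if name == "quiet":
            continue
        s = spike_analysis.summarize_set(st)
        w, g = name[1:].split("_g")
        rows.append({
            "w_percent": int(w), "g_db_hz": int(g),
            "vs_quiet": base.vs_mean, "vs_noise": s.vs_mean,
            "delta_vs": (None if (s.vs_mean is None or base.vs_mean is None)
                         else s.vs_mean - base.vs_mean),
            "significant": s.significant and base.significant,
        })
    return pd.DataFrame(rows)
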