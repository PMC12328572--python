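"""Spike-train statistics: vector strength, Rayleigh significance, phase
histograms, rate/VS-level functions, and unit characterization.

Vector strength (VS) quantifies phase locking: each in-window spike at time
``t_k`` becomes a unit vector at phase ``alpha_k = 2*pi*f_m*t_k``, and VS
is the modulus of the mean vector.  Significance follows the Rayleigh
statistic ``p = exp(-K * VS**2)``; VS is considered significant when
``K > 50`` and ``p < 0.001``.  An empty window leaves VS *undefined*
(flagged), never zero, so level functions cannot be silently biased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .periphery import SR_CLASS_BOUNDARY, SpikeTrainSet
from .stimuli import Stimulus

ONSET_SKIP = 0.020  # s excluded after stimulus onset (onset response)

SIG_MIN_COUNT = 50
SIG_MAX_P = 1e-3


@dataclass
class VSResult:
    """Vector strength with its Rayleigh significance bookkeeping."""

    vs: Optional[float]          # None when no spikes fell in the window
    K: int
    p: Optional[float]
    significant: bool
    f_m: float
    window: Tuple[float, float]

    @property
    def defined(self) -> bool:
        return self.vs is not None


def rayleigh_p(vs: float, K: int) -> float:
    """Rayleigh probability of observing vector strength ``vs`` from ``K``
    uniformly distributed spikes: exp(-K * vs**2)."""
    if K < 0:
        raise ValueError("spike count cannot be negative")
    return math.exp(-K * vs * vs)


def vector_strength(
    spike_times: Sequence[float],
    f_m: float,
    window: Optional[Tuple[float, float]] = None,
) -> VSResult:
    """Vector strength of spike times relative to the modulation cycle.

    Phase zero is the modulator sine zero-crossing at stimulus onset
    (matching the synthesis convention).
    """
    if f_m <= 0:
        raise ValueError("modulation frequency must be positive")
    t = np.asarray(spike_times, dtype=float)
    if window is not None:
        lo, hi = window
        if hi <= lo:
            raise ValueError("empty analysis window")
        t = t[(t >= lo) & (t < hi)]
    else:
        window = (float("-inf"), float("inf"))
    K = int(t.size)
    if K == 0:
        return VSResult(vs=None, K=0, p=None, significant=False,
                        f_m=f_m, window=window)
    vec = np.exp(1j * 2.0 * math.pi * f_m * t)
    vs = float(abs(vec.mean()))
    p = rayleigh_p(vs, K)
    return VSResult(vs=vs, K=K, p=p,
                    significant=(K > SIG_MIN_COUNT and p < SIG_MAX_P),
                    f_m=f_m, window=window)


def phase_histogram(
    spike_times: Sequence[float],
    f_m: float,
    n_bins: int = 32,
    window: Optional[Tuple[float, float]] = None,
    n_reps: int = 1,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-phase-bin firing rate (spikes/s), normalized by reps x duration.

    Returns ``(bin_centers_rad, rate_per_bin)``; the rates sum to the total
    in-window rate.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    t = np.asarray(spike_times, dtype=float)
    if window is not None:
        lo, hi = window
        t = t[(t >= lo) & (t < hi)]
        dur = hi - lo
    else:
        dur = float(t.max()) if t.size else 1.0
    phases = np.mod(2.0 * math.pi * f_m * t, 2.0 * math.pi)
    counts, edges = np.histogram(phases, bins=n_bins, range=(0.0, 2.0 * math.pi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    rate = counts / (n_reps * dur)
    return centers, rate


def analysis_window(stim_or_duration, onset: float = 0.0) -> Tuple[float, float]:
    """Spike-inclusion window: 20 ms after onset until stimulus offset."""
    if isinstance(stim_or_duration, Stimulus):
        duration = stim_or_duration.duration
    else:
        duration = float(stim_or_duration)
    if duration <= ONSET_SKIP:
        raise ValueError("stimulus too short for the 20-ms onset exclusion")
    return (onset + ONSET_SKIP, onset + duration)


# ---------------------------------------------------------------------------
# per-set summaries
# ---------------------------------------------------------------------------

@dataclass
class SetSummary:
    """Per-repetition-then-averaged rate and VS for one SpikeTrainSet."""

    rate_mean: float
    rate_sd: float
    vs_mean: Optional[float]     # mean over repetitions with defined VS
    vs_sd: Optional[float]
    vs_pooled: VSResult          # VS over all spikes pooled across reps
    n_reps: int
    significant: bool            # pooled-significance flag


def summarize_set(st: SpikeTrainSet,
                  window: Optional[Tuple[float, float]] = None) -> SetSummary:
    """Rate and VS per repetition, then averaged across repetitions;
    pooled-spike VS reported alongside."""
    if window is None:
        window = analysis_window(st.duration, st.onset)
    lo, hi = window
    dur = hi - lo
    rates = []
    vss = []
    pooled: List[float] = []
    for train in st.trains:
        sel = train[(train >= lo) & (train < hi)]
        rates.append(sel.size / dur)
        pooled.extend(sel.tolist())
        r = vector_strength(train, st.f_m, window) if st.f_m else None
        if r is not None and r.defined:
            vss.append(r.vs)
    vs_pooled = (vector_strength(pooled, st.f_m, window) if st.f_m
                 else VSResult(None, 0, None, False, 0.0, window))
    return SetSummary(
        rate_mean=float(np.mean(rates)),
        rate_sd=float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0,
        vs_mean=float(np.mean(vss)) if vss else None,
        vs_sd=(float(np.std(vss, ddof=1)) if len(vss) > 1 else 0.0) if vss else None,
        vs_pooled=vs_pooled,
        n_reps=st.n_reps,
        significant=vs_pooled.significant,
    )


@dataclass
class LevelFunction:
    """Rate- and VS-level functions across a level series."""

    levels: np.ndarray
    rate_mean: np.ndarray
    rate_sd: np.ndarray
    vs_mean: np.ndarray          # NaN where undefined
    vs_sd: np.ndarray
    significant: np.ndarray      # bool per level (pooled criterion)
    n_reps: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "level_db_spl": self.levels,
            "rate_mean": self.rate_mean,
            "rate_sd": self.rate_sd,
            "vs_mean": self.vs_mean,
            "vs_sd": self.vs_sd,
            "significant": self.significant,
        })


def level_functions(sets_by_level: dict, f_m: Optional[float] = None) -> LevelFunction:
    """Build rate/VS-level functions from {level: SpikeTrainSet}."""
    if not sets_by_level:
        raise ValueError("no levels provided")
    levels = np.array(sorted(sets_by_level))
    rm, rs, vm, vs_sd, sig = [], [], [], [], []
    n_reps = 0
    for lv in levels:
        st = sets_by_level[lv]
        if f_m is not None:
            st.f_m = f_m
        s = summarize_set(st)
        rm.append(s.rate_mean)
        rs.append(s.rate_sd)
        vm.append(s.vs_mean if s.vs_mean is not None else np.nan)
        vs_sd.append(s.vs_sd if s.vs_sd is not None else np.nan)
        sig.append(s.significant)
        n_reps = s.n_reps
    return LevelFunction(
        levels=levels, rate_mean=np.array(rm), rate_sd=np.array(rs),
        vs_mean=np.array(vm), vs_sd=np.array(vs_sd),
        significant=np.array(sig, dtype=bool), n_reps=n_reps,
    )


# ---------------------------------------------------------------------------
# unit characterization
# ---------------------------------------------------------------------------

def estimate_cf_threshold_sr(
    freq_response: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    rate_level: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    silence_counts: Optional[Tuple[float, float]] = None,
    spont_count_sd: Optional[float] = None,
) -> dict:
    """Estimate CF, rate threshold, and spontaneous rate from probe data.

    * CF: arg-max of the 3-point-smoothed frequency-response curve.
    * threshold: lowest level whose driven rate exceeds the spontaneous
      mean + 2 SD at matched window length (the configurable significance
      rule for a "significant increase in firing rate").
    * SR: spikes per second over silence epochs; class split at 18 spikes/s.

    ``silence_counts`` is ``(n_spikes, total_seconds)``.  Undefined
    quantities are returned as ``None`` with the reason in ``flags``.
    """
    out = {"cf": None, "threshold": None, "sr": None, "sr_class": None,
           "flags": []}

    sr = None
    if silence_counts is not None:
        n_sp, t_total = silence_counts
        if t_total <= 0:
            raise ValueError("silence duration must be positive")
        sr = n_sp / t_total
        out["sr"] = sr
        out["sr_class"] = "high" if sr >= SR_CLASS_BOUNDARY else "low"

    if freq_response is not None:
        freqs, rates = (np.asarray(a, dtype=float) for a in freq_response)
        if freqs.size == 0:
            raise ValueError("empty frequency-response curve")
        if rates.size >= 3:
            padded = np.pad(rates, 1, mode="edge")
            sm = np.convolve(padded, np.ones(3) / 3.0, mode="valid")
        else:
            sm = rates
        if np.ptp(sm) <= 1e-12:
            out["flags"].append("flat frequency response; CF undefined")
        else:
            out["cf"] = float(freqs[int(np.argmax(sm))])

    if rate_level is not None:
        levels, rates = (np.asarray(a, dtype=float) for a in rate_level)
        base = sr if sr is not None else float(np.min(rates))
        sd = spont_count_sd if spont_count_sd is not None else max(math.sqrt(max(base, 1.0)), 1.0)
        crit = base + 2.0 * sd
        above = np.nonzero(rates > crit)[0]
        if above.size == 0:
            out["flags"].append("no level exceeds the spontaneous criterion; threshold undefined")
        else:
            out["threshold"] = float(levels[above[0]])

    return out


# ---------------------------------------------------------------------------
# re-analysis of external spike tables
# ---------------------------------------------------------------------------

def analyze_spike_table(
    trains_by_fiber: dict,
    f_m: float,
    duration: float,
    onset: float = 0.0,
) -> pd.DataFrame:
    """Per-fiber VS/rate from a {fiber_id: [spike-time arrays]} mapping
    (the spike-table CSV format; applicable to deposited recordings given
    the documented column mapping)."""
    window = analysis_window(duration, onset)
    rows = []
    for fiber_id, trains in trains_by_fiber.items():
        st = SpikeTrainSet(trains=[np.asarray(t) for t in trains],
                           fiber=None, duration=duration, f_m=f_m, onset=onset)
        s = summarize_set(st, window)
        rows.append({
            "fiber_id": fiber_id,
            "rate": s.rate_mean,
            "vs": s.vs_mean,
            "K": s.vs_pooled.K,
            "p": s.vs_pooled.p,
            "significant": s.significant,
        })
    return pd.DataFrame(rows)
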