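"""Phenomenological auditory-nerve periphery with cochlear gain control.

A deliberately minimal cascade that carries the causal ingredients behind
level-dependent envelope phase locking and its restoration by notched
noise:

1. middle-ear band-pass (0.3–8.5 kHz);
2. a *control path* measuring sound energy in two flanking bands around the
   characteristic frequency (CF) — energy close to, but not at, CF drives a
   sigmoidal reduction of the cochlear gain (suppression);
3. a *signal path*: the input scaled by the instantaneous gain, then a
   4th-order gammatone filter at CF with human ERB bandwidth;
4. an inner-hair-cell stage: half-wave rectification with a saturating
   hyperbolic nonlinearity, then a 2nd-order low-pass at 3 kHz (so for a
   4-kHz carrier the envelope, not the fine structure, drives the synapse);
5. a synapse: threshold-linear drive with saturation and short-term
   adaptation, riding on the spontaneous rate;
6. a stochastic spike generator: inhomogeneous Poisson thinning with an
   absolute dead time and relative (exponential-recovery) refractoriness.

The saturating transduction makes envelope phase locking first rise and
then fall with level; the control path lets flanking noise shift the
operating point back down, restoring phase locking at moderate levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
from scipy import signal as sps

from .stimuli import P_REF, Stimulus, rms_from_db

# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

SR_CLASS_BOUNDARY = 18.0  # spikes/s; low- vs high-SR split


def erb(f: float) -> float:
    """Equivalent rectangular bandwidth (Hz) of the human auditory filter."""
    return 24.7 * (4.37 * f / 1000.0 + 1.0)


@dataclass
class FiberParams:
    """One model auditory-nerve fiber (and its IHC/OHC front end).

    The gain sigmoid maps the control-path level L (dB SPL) to a cochlear
    gain ``gain_min + (gain_max - gain_min) / (1 + exp((L - gain_L50) /
    gain_slope))``: full gain for weak flanking energy, approaching
    ``gain_min`` when the flanking bands are intense.
    """

    cf: float = 4000.0
    sr: float = 4.0                  # spontaneous rate, spikes/s
    threshold: float = 15.0          # dB SPL at CF
    t_abs: float = 450e-6            # absolute refractory time, s
    t_rel: float = 513e-6            # relative refractory time, s
    gain_max: float = 45.0           # dB, cochlear gain at low level
    gain_min: float = 0.0            # dB
    gain_L50: float = 38.0           # control level of half gain, dB SPL
    gain_slope: float = 6.0          # sigmoid scale, dB
    ctrl_bw_factor: float = 5.0      # control-path span / signal bandwidth
    sat_rate: float = 250.0          # saturated driven rate, spikes/s
    ihc_knee: float = 0.05           # IHC saturation knee, Pa
    ihc_cutoff: float = 3000.0       # IHC membrane low-pass, Hz
    syn_half: float = 0.08           # synaptic half-saturation drive
    syn_soft: float = 0.03           # softness of the synaptic threshold
    adapt_tau: float = 0.060         # short-term adaptation, s
    adapt_strength: float = 0.5      # fraction of steady drive adapted away
    gain_tau: float = 0.005          # gain-control smoothing, s

    def __post_init__(self) -> None:
        if self.cf <= 0 or self.sr < 0:
            raise ValueError("need cf > 0 and sr >= 0")
        if self.t_abs <= 0 or self.t_rel <= 0:
            raise ValueError("refractory times must be positive")

    @property
    def sr_class(self) -> str:
        return "high" if self.sr >= SR_CLASS_BOUNDARY else "low"


@dataclass
class ChannelResponse:
    """Deterministic instantaneous firing rate of one fiber, plus the gain."""

    rate: np.ndarray        # spikes/s over time, >= 0
    gain_track: np.ndarray  # applied cochlear gain over time, dB
    cf: float
    fs: float

    @property
    def duration(self) -> float:
        return self.rate.size / self.fs


@dataclass
class SpikeTrainSet:
    """Spike times per repetition for one fiber/stimulus pair."""

    trains: List[np.ndarray]      # spike times (s), one array per repetition
    fiber: FiberParams
    duration: float               # stimulus duration, s
    f_m: Optional[float] = None
    onset: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_reps(self) -> int:
        return len(self.trains)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _gammatone(x: np.ndarray, fs: float, f0: float, bw_erb: float,
               order: int = 4) -> np.ndarray:
    """All-pole gammatone: cascade of identical complex one-pole sections.

    ``bw_erb`` is the equivalent rectangular bandwidth in Hz; the pole
    bandwidth uses the standard 1.019 factor for a 4th-order gammatone.
    The response is normalized to unit gain at ``f0``.
    """
    b = 1.019 * bw_erb
    pole = math.exp(-2.0 * math.pi * b / fs) * np.exp(2j * math.pi * f0 / fs)
    a = np.array([1.0, -pole])
    gain_1 = abs(1.0 - pole * np.exp(-2j * math.pi * f0 / fs))
    y = x.astype(complex)
    for _ in range(order):
        y = sps.lfilter([gain_1], a, y)
    return y.real


def _middle_ear(x: np.ndarray, fs: float,
                lo: float = 300.0, hi: float = 8500.0) -> np.ndarray:
    hi = min(hi, 0.95 * fs / 2)
    sos = sps.butter(1, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfilt(sos, x)


def _lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 2) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfilt(sos, x)


def _smooth_power(x2: np.ndarray, fs: float, tau: float) -> np.ndarray:
    """One-pole (leaky-integrator) smoothing of an instantaneous power."""
    a = math.exp(-1.0 / (tau * fs))
    return sps.lfilter([1.0 - a], [1.0, -a], x2)


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def _control_level(xme: np.ndarray, fiber: FiberParams, fs: float) -> np.ndarray:
    """Control-path level (dB SPL) over time.

    Two steep (8th-order) gammatone bands flank the signal filter at
    ``cf ± (ctrl_bw_factor/2) * ERB``; together they span
    ~``ctrl_bw_factor`` signal bandwidths around CF while excluding the
    on-CF core, so suppression is driven by energy close to, but not at,
    CF.  The control level is the dB *average* (geometric mean of powers)
    of the two flanks: gain reduction requires spectrally flanking energy
    on both sides of CF (the signature of a notched or broadband masker),
    so an isolated tone never suppresses neighbouring channels into
    silence through a single flank.
    The high filter order keeps on-frequency leakage into the flanks
    negligible, which is what lets flanking noise well below the signal
    level still dominate the gain.
    """
    bw = erb(fiber.cf)
    offset = fiber.ctrl_bw_factor / 2.0 * bw  # Hz from CF to flank center
    flank_levels = []
    for fc in (fiber.cf - offset, fiber.cf + offset):
        if fc <= 0 or fc >= fs / 2:
            continue
        y = _gammatone(xme, fs, fc, erb(fc), order=8)
        power = _smooth_power(y * y, fs, fiber.gain_tau)
        flank_levels.append(
            10.0 * np.log10(np.maximum(power, 1e-30) / P_REF**2))
    if not flank_levels:
        return np.full_like(xme, -300.0)
    return np.mean(flank_levels, axis=0)


def _gain_db(level: np.ndarray, fiber: FiberParams) -> np.ndarray:
    span = fiber.gain_max - fiber.gain_min
    return fiber.gain_min + span / (
        1.0 + np.exp((level - fiber.gain_L50) / fiber.gain_slope)
    )


def _ihc_mean_response(p_pk: float, knee: float) -> float:
    """Cycle-mean IHC output for a sinusoid of peak pressure ``p_pk``:
    (1/2*pi) * integral of P*sin(theta)/(P*sin(theta) + knee) over the
    positive half-cycle (what the membrane low-pass extracts)."""
    theta = np.linspace(0.0, math.pi, 256)
    u = p_pk * np.sin(theta)
    return float(np.trapezoid(u / (u + knee), theta)) / (2.0 * math.pi)


def _ihc_threshold_drive(fiber: FiberParams) -> float:
    """IHC output of a CF tone at the fiber's threshold (with full gain);
    the synaptic threshold sits exactly there, so the pure-tone rate
    threshold matches the ``threshold`` parameter."""
    p_pk = math.sqrt(2.0) * rms_from_db(fiber.threshold + fiber.gain_max)
    return _ihc_mean_response(p_pk, fiber.ihc_knee)


def simulate_channel(stim: Stimulus, fiber: FiberParams) -> ChannelResponse:
    """Run the deterministic cascade; returns rate and gain tracks."""
    if stim.channels != 1:
        raise ValueError("simulate_channel takes a single-channel stimulus; "
                         "use Stimulus.as_mono(ear)")
    fs = stim.fs
    if fiber.cf >= fs / 2:
        raise ValueError("fiber CF above Nyquist for this stimulus")

    x = np.asarray(stim.waveform, dtype=float)
    xme = _middle_ear(x, fs)

    level = _control_level(xme, fiber, fs)
    gain = _gain_db(level, fiber)

    y = _gammatone(xme * 10.0 ** (gain / 20.0), fs, fiber.cf, erb(fiber.cf))

    # IHC: asymmetric saturating rectifier, then membrane low-pass.
    u = np.maximum(y, 0.0)
    v = u / (u + fiber.ihc_knee)
    m = _lowpass(v, fs, fiber.ihc_cutoff)

    # synapse: soft threshold (real transduction is graded, so near-
    # threshold crests drive partial, spont-diluted responses and the VS
    # peak sits a few dB above rate threshold) + saturation + adaptation
    m0 = _ihc_threshold_drive(fiber)
    eps = fiber.syn_soft
    if eps > 0:
        # resting drive subtracted so the rate settles to exactly sr in
        # silence; the soft knee only matters near threshold
        d_rest = eps * np.logaddexp(0.0, -m0 / eps)
        d = np.maximum(eps * np.logaddexp(0.0, (m - m0) / eps) - d_rest, 0.0)
    else:
        d = np.maximum(m - m0, 0.0)
    s = d / (d + fiber.syn_half)
    w = _lowpass(s, fs, 1.0 / (2.0 * math.pi * fiber.adapt_tau), order=1)
    drive = np.maximum(s - fiber.adapt_strength * w, 0.0) / (1.0 - fiber.adapt_strength)

    rate = fiber.sr + fiber.sat_rate * drive
    return ChannelResponse(rate=rate, gain_track=gain, cf=fiber.cf, fs=fs)


# ---------------------------------------------------------------------------
# spike generation
# ---------------------------------------------------------------------------

def generate_spikes(
    resp: Union[ChannelResponse, np.ndarray],
    fiber: FiberParams,
    seed: Union[int, np.random.SeedSequence, np.random.Generator] = 0,
    fs: Optional[float] = None,
) -> np.ndarray:
    """Draw one spike train from a rate trace.

    Inhomogeneous Poisson thinning followed by refractoriness: no spike can
    occur within ``t_abs`` of the previous one, and within the relative
    period the acceptance probability recovers as
    ``1 - exp(-(dt - t_abs)/t_rel)``.
    """
    if isinstance(resp, ChannelResponse):
        rate, fs_ = resp.rate, resp.fs
    else:
        rate = np.asarray(resp, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare rate array")
        fs_ = fs
    if not np.all(np.isfinite(rate)):
        raise ValueError("rate trace must be finite")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_max = float(np.max(rate))
    duration = rate.size / fs_
    if r_max <= 0:
        return np.empty(0)

    n_cand = rng.poisson(r_max * duration)
    if n_cand == 0:
        return np.empty(0)
    cand = np.sort(rng.random(n_cand) * duration)
    accept_p = rate[np.minimum((cand * fs_).astype(int), rate.size - 1)] / r_max
    u = rng.random(n_cand)
    u2 = rng.random(n_cand)

    spikes: List[float] = []
    t_last = -np.inf
    t_abs, t_rel = fiber.t_abs, fiber.t_rel
    for i in range(n_cand):
        if u[i] >= accept_p[i]:
            continue
        dt = cand[i] - t_last
        if dt < t_abs:
            continue
        if u2[i] >= 1.0 - math.exp(-(dt - t_abs) / t_rel):
            continue
        spikes.append(cand[i])
        t_last = cand[i]
    return np.asarray(spikes)


StimOrFactory = Union[Stimulus, Callable[[int], Stimulus]]


def simulate_fiber_response(
    stim: StimOrFactory,
    fiber: FiberParams,
    n_reps: int = 10,
    seed: int = 0,
) -> SpikeTrainSet:
    """Simulate ``n_reps`` repetitions of one stimulus for one fiber.

    ``stim`` may be a :class:`Stimulus` (frozen across repetitions) or a
    callable ``seed -> Stimulus`` producing a fresh realization per
    repetition (running noise, the default policy for noise stimuli).
    Per-repetition seeds derive from the master seed, so the same master
    seed reproduces the set exactly.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    stim_seeds = ss.spawn(n_reps)
    spike_seeds = ss.spawn(n_reps)

    trains: List[np.ndarray] = []
    resp_cache: Optional[ChannelResponse] = None
    f_m = None
    duration = 0.0
    for i in range(n_reps):
        if callable(stim):
            s = stim(int(stim_seeds[i].generate_state(1)[0] % 2**31))
            resp = simulate_channel(s, fiber)
        else:
            s = stim
            if resp_cache is None:
                resp_cache = simulate_channel(s, fiber)
            resp = resp_cache
        f_m = s.f_m
        duration = s.duration or resp.duration
        trains.append(generate_spikes(resp, fiber,
                                      np.random.default_rng(spike_seeds[i])))
    return SpikeTrainSet(trains=trains, fiber=fiber, duration=duration, f_m=f_m)


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def cf_grid(n: int = 25, lo: float = 2000.0, hi: float = 7500.0) -> np.ndarray:
    """CFs equidistant along a log-place (Greenwood-type) tonotopic axis."""
    if n < 1 or lo <= 0 or hi <= lo:
        raise ValueError("need n >= 1 and 0 < lo < hi")
    return np.geomspace(lo, hi, n)


def simulate_population(
    stim: StimOrFactory,
    cfs: Sequence[float],
    fiber_template: Optional[FiberParams] = None,
    n_reps: int = 10,
    seed: int = 0,
) -> Dict[float, SpikeTrainSet]:
    """One fiber per CF, identical non-CF parameters; seeded per fiber."""
    cfs = np.asarray(cfs, dtype=float)
    if np.any(np.diff(cfs) <= 0):
        raise ValueError("cfs must be strictly increasing")
    template = fiber_template or FiberParams()
    ss = np.random.SeedSequence(seed)
    out: Dict[float, SpikeTrainSet] = {}
    for cf, child in zip(cfs, ss.spawn(len(cfs))):
        fiber = FiberParams(**{**template.__dict__, "cf": float(cf)})
        out[float(cf)] = simulate_fiber_response(
            stim, fiber, n_reps=n_reps,
            seed=int(child.generate_state(1)[0] % 2**31),
        )
    return out


# ---------------------------------------------------------------------------
# spike-table serialization
# ---------------------------------------------------------------------------

def spike_table(sets: Dict[str, SpikeTrainSet]):
    """Flatten spike-train sets into a columnar table.

    Columns: fiber_id, repetition, spike_time_s — the interchange format
    shared with re-analysis of external recordings.
    """
    import pandas as pd

    rows = []
    for fiber_id, st in sets.items():
        for rep, train in enumerate(st.trains):
            for t in train:
                rows.append((fiber_id, rep, float(t)))
    return pd.DataFrame(rows, columns=["fiber_id", "repetition", "spike_time_s"])


def write_spike_table(sets: Dict[str, SpikeTrainSet], path: str) -> None:
    df = spike_table(sets)
    df.to_csv(path, index=False)


def read_spike_table(path: str) -> Dict[str, List[np.ndarray]]:
    """Read a spike-table CSV back into per-fiber lists of spike-time arrays."""
    import pandas as pd

    df = pd.read_csv(path)
    out: Dict[str, List[np.ndarray]] = {}
    for fiber_id, g in df.groupby("fiber_id", sort=False):
        reps = []
        for _, gr in g.groupby("repetition", sort=True):
            reps.append(np.sort(gr["spike_time_s"].to_numpy(dtype=float)))
        out[str(fiber_id)] = reps
    return out
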