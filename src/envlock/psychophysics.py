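"""Envelope-ITD psychophysics: simulated observers, the four-down/one-up
adaptive staircase, fixed-level condition blocks, and a channel-matching
binaural decision model.

The task is a two-interval, two-alternative forced choice (2I-2AFC): the
listener reports whether the SAM tone in the second interval was heard to
the left or right of the first.  The two intervals carry envelope IPDs
symmetric around zero, so the cue is the inter-interval difference
``delta_ipd_env``.  A four-down/one-up transformed staircase converges on
the level where P(correct)^4 = 0.5, i.e. ~0.84 proportion correct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import periphery, stimuli
from .stimuli import BinauralTrialSpec, NotchedNoiseSpec, TrialStimuli

START_DELTA_IPD = 0.4 * math.pi
CAP_DELTA_IPD = 0.8 * math.pi
STEP_FACTORS = (2.0, 2.0 ** 0.5, 2.0 ** 0.25)
MIN_STEP_REVERSALS = 10


def staircase_target_pc(n_down: int, n_up: int = 1) -> float:
    """Asymptotic proportion correct of an n-down/1-up transformed rule.

    The track equilibrates where the probability of a down step equals that
    of an up step: p**n_down = 0.5.
    """
    if n_down < 1 or n_up < 1:
        raise ValueError("rule counts must be >= 1")
    if n_up != 1:
        raise NotImplementedError("only n-down/1-up rules are supported")
    return 0.5 ** (1.0 / n_down)


# ---------------------------------------------------------------------------
# simulated observers
# ---------------------------------------------------------------------------

@dataclass
class ObserverParams:
    """A stationary simulated listener with a logistic psychometric function
    over log envelope-IPD."""

    alpha: float                  # delta-IPD at the inflection, radians
    beta: float = 8.0             # slope per log-unit of delta-IPD
    lapse: float = 0.02
    guess: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse <= 0.1):
            raise ValueError("lapse must lie in [0, 0.1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def p_correct(self, delta_ipd: float) -> float:
        """P(correct) = guess + (1 - guess - lapse) * logistic(...)."""
        if delta_ipd <= 0:
            return self.guess
        x = self.beta * (math.log(delta_ipd) - math.log(self.alpha))
        return self.guess + (1.0 - self.guess - self.lapse) / (1.0 + math.exp(-x))


def observer_response(
    obs: ObserverParams,
    delta_ipd: float,
    rng: Optional[np.random.Generator] = None,
) -> bool:
    """One Bernoulli trial: True when the observer answers correctly."""
    if delta_ipd < 0:
        raise ValueError("delta_ipd must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(obs.seed)
    return bool(rng.random() < obs.p_correct(delta_ipd))


Responder = Callable[[float, np.random.Generator], bool]


def observer_responder(obs: ObserverParams) -> Responder:
    return lambda delta_ipd, rng: observer_response(obs, delta_ipd, rng)


# ---------------------------------------------------------------------------
# adaptive staircase
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    trial: int
    delta_ipd: float
    correct: bool
    reversal: bool
    step_factor: float


@dataclass
class StaircaseTrack:
    """One adaptive track with reversal bookkeeping.

    ``threshold`` is the geometric mean of the delta-IPD values at the ten
    reversals that occurred at the minimum step size (step sizes are
    multiplicative, so the geometric mean is the natural average).
    """

    trials: List[TrialRecord] = field(default_factory=list)
    min_step_reversal_levels: List[float] = field(default_factory=list)
    threshold: Optional[float] = None
    converged: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def run_staircase(
    responder,
    start: float = START_DELTA_IPD,
    cap: float = CAP_DELTA_IPD,
    rule: Tuple[int, int] = (4, 1),
    max_trials: int = 400,
    seed: int = 0,
) -> StaircaseTrack:
    """Run one transformed up-down track.

    ``responder`` is an :class:`ObserverParams` or a callable
    ``(delta_ipd, rng) -> bool``.  The tracking variable starts at
    ``start`` (default 0.4*pi), never exceeds ``cap`` (default 0.8*pi), is
    divided by the current step factor after ``rule[0]`` consecutive
    correct responses and multiplied after each error.  The step factor
    shrinks 2 -> 2**(1/2) -> 2**(1/4) after the first and second down-up
    reversal; the track terminates after ten reversals at the minimum step
    size.  Hitting ``max_trials`` first marks the track as non-converged.
    """
    if start > cap:
        raise ValueError("start must not exceed the cap")
    n_down, n_up = rule
    if n_up != 1:
        raise NotImplementedError("only n-down/1-up rules are supported")
    if isinstance(responder, ObserverParams):
        responder = observer_responder(responder)

    rng = np.random.default_rng(seed)
    track = StaircaseTrack()
    level = start
    factor_idx = 0
    n_correct_run = 0
    last_move: Optional[int] = None      # -1 down, +1 up
    down_up_reversals = 0

    for trial in range(max_trials):
        correct = bool(responder(level, rng))
        move = 0
        if correct:
            n_correct_run += 1
            if n_correct_run >= n_down:
                move = -1
                n_correct_run = 0
        else:
            n_correct_run = 0
            move = +1

        reversal = move != 0 and last_move is not None and move != last_move
        at_min_step = factor_idx == len(STEP_FACTORS) - 1
        track.trials.append(TrialRecord(trial, level, correct, reversal,
                                        STEP_FACTORS[factor_idx]))
        if reversal and at_min_step:
            track.min_step_reversal_levels.append(level)
            if len(track.min_step_reversal_levels) >= MIN_STEP_REVERSALS:
                track.converged = True
                track.threshold = float(
                    np.exp(np.mean(np.log(track.min_step_reversal_levels))))
                return track
        if reversal and move == +1 and down_up_reversals < 2:
            down_up_reversals += 1
            factor_idx = min(down_up_reversals, len(STEP_FACTORS) - 1)

        if move != 0:
            f = STEP_FACTORS[factor_idx]
            level = min(level / f if move < 0 else level * f, cap)
            last_move = move

    # guard hit: non-converged, report geometric mean of whatever minimum-
    # step reversals exist (None if none)
    if track.min_step_reversal_levels:
        track.threshold = float(
            np.exp(np.mean(np.log(track.min_step_reversal_levels))))
    return track


def validate_track(track: StaircaseTrack, cap: float = CAP_DELTA_IPD) -> None:
    """Replay validator for the staircase invariants; raises on violation."""
    allowed = set(STEP_FACTORS)
    seen = []
    for rec in track.trials:
        if rec.delta_ipd > cap + 1e-12:
            raise AssertionError("tracking variable exceeded the cap")
        if rec.step_factor not in allowed:
            raise AssertionError("illegal step factor")
        if not seen or rec.step_factor != seen[-1]:
            seen.append(rec.step_factor)
    # factors may only shrink along the schedule
    sched = list(STEP_FACTORS)
    idx = -1
    for f in seen:
        j = sched.index(f)
        if j < idx:
            raise AssertionError("step factor grew back")
        idx = j
    if track.converged and len(track.min_step_reversal_levels) < MIN_STEP_REVERSALS:
        raise AssertionError("converged without ten minimum-step reversals")


def repeated_thresholds(
    responder, n_tracks: int = 3, seed: int = 0, **kwargs
) -> Tuple[float, float, List[StaircaseTrack]]:
    """Geometric mean and geometric SD of thresholds over repeated tracks."""
    ss = np.random.SeedSequence(seed)
    tracks = [run_staircase(responder, seed=int(s.generate_state(1)[0] % 2**31),
                            **kwargs)
              for s in ss.spawn(n_tracks)]
    ths = [t.threshold for t in tracks if t.threshold is not None]
    if not ths:
        return math.nan, math.nan, tracks
    logs = np.log(ths)
    gmean = float(np.exp(np.mean(logs)))
    gsd = float(np.exp(np.std(logs, ddof=1))) if len(ths) > 1 else 1.0
    return gmean, gsd, tracks


# ---------------------------------------------------------------------------
# constant-stimulus blocks
# ---------------------------------------------------------------------------

@dataclass
class BlockResult:
    n_correct: int
    n_trials: int
    proportion: float
    ci_low: float
    ci_high: float
    p_vs_chance: float

    @property
    def above_chance(self) -> bool:
        return self.ci_low > 0.5


def constant_stimuli_block(
    responder,
    delta_ipd: float,
    n_trials: int = 100,
    seed: int = 0,
) -> BlockResult:
    """Proportion correct at a fixed delta-IPD with an exact
    (Clopper-Pearson) 95% confidence interval and a two-sided binomial test
    against chance."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if isinstance(responder, ObserverParams):
        responder = observer_responder(responder)
    rng = np.random.default_rng(seed)
    k = sum(bool(responder(delta_ipd, rng)) for _ in range(n_trials))
    bt = stats.binomtest(k, n_trials, p=0.5)
    ci = bt.proportion_ci(confidence_level=0.95, method="exact")
    return BlockResult(
        n_correct=k, n_trials=n_trials, proportion=k / n_trials,
        ci_low=float(ci.low), ci_high=float(ci.high),
        p_vs_chance=float(bt.pvalue),
    )


# ---------------------------------------------------------------------------
# binaural channel-matching decision model
# ---------------------------------------------------------------------------

Condition = Literal["Q", "Mon_left", "Mon_right", "Bin"]


@dataclass
class BinauralModel:
    """Lateralization via interaurally matched frequency channels.

    Each ear's sound is run through the periphery at a shared CF grid.  Per
    channel, the envelope delay between the ears is read off the phase of
    the modulation-frequency component of the two rate waveforms (the
    narrowband equivalent of cross-correlating them), and the channel's
    weight is the *product* of the left- and right-ear modulation
    amplitudes in that same channel: a channel only contributes when both
    ears carry envelope information there.  The decision variable is the
    weight-summed delay difference between the two intervals plus a single
    additive Gaussian internal noise.
    """

    cfs: Sequence[float] = field(default_factory=lambda: periphery.cf_grid(9))
    fiber_template: periphery.FiberParams = field(default_factory=periphery.FiberParams)
    fibers_per_channel: int = 2
    internal_noise_sd: float = 0.0      # extra Gaussian on the decision variable
    analysis_skip: float = 0.06         # s of onset transient ignored

    def _ear_components(self, iv: stimuli.Stimulus, f_m: float,
                        rng: np.random.Generator):
        """Per-CF complex f_m spike vectors of the left/right ears.

        Each channel pools ``fibers_per_channel`` spike trains; the complex
        vector sum over spike times carries synchronized count K*VS in its
        modulus and the envelope phase in its angle.  Spiking noise makes
        weakly synchronized channels both low-weight and phase-unreliable.
        """
        comps = np.zeros((2, len(self.cfs)), dtype=complex)
        # the cue is the *ongoing* envelope phase: exclude the onset
        # adaptation transient and the offset ramp (gating is synchronous
        # across ears and its transients carry no reliable interaural cue)
        t0 = self.analysis_skip
        t1 = iv.duration - iv.ramp if iv.duration else None
        for e in range(2):
            mono = iv.as_mono(e)
            for i, cf in enumerate(self.cfs):
                fiber = periphery.FiberParams(
                    **{**self.fiber_template.__dict__, "cf": float(cf)})
                resp = periphery.simulate_channel(mono, fiber)
                vec = 0.0 + 0.0j
                for _ in range(self.fibers_per_channel):
                    spikes = periphery.generate_spikes(resp, fiber, rng)
                    spikes = spikes[spikes >= t0]
                    if t1 is not None:
                        spikes = spikes[spikes < t1]
                    vec += np.sum(np.exp(2j * math.pi * f_m * spikes))
                comps[e, i] = vec
        return comps

    def interval_delay_variable(self, iv: stimuli.Stimulus, f_m: float,
                                rng: np.random.Generator) -> float:
        """Weight-summed envelope delay (left re right) for one interval."""
        comps = self._ear_components(iv, f_m, rng)
        cl, cr = comps[0], comps[1]
        weights = np.abs(cl) * np.abs(cr)
        # left spikes earlier by delta -> C_L = C_R * exp(-i*2*pi*f_m*delta),
        # so the left-leads delay is the angle of C_R * conj(C_L)
        delays = np.angle(cr * np.conj(cl)) / (2.0 * math.pi * f_m)
        return float(np.sum(weights * delays))

    def decide_trial(self, trial: TrialStimuli,
                     rng: np.random.Generator) -> str:
        f_m = trial.spec.f_m
        if len(self.cfs) == 0:
            raise ValueError("empty CF grid")
        d1 = self.interval_delay_variable(trial.interval1, f_m, rng)
        d2 = self.interval_delay_variable(trial.interval2, f_m, rng)
        dv = (d2 - d1) + (rng.normal(0.0, self.internal_noise_sd)
                          if self.internal_noise_sd > 0 else 0.0)
        return "left" if dv > 0 else "right"

    def responder(
        self,
        condition: Condition,
        sam_level: float = 65.0,
        noise: Optional[NotchedNoiseSpec] = None,
        trial_spec: Optional[BinauralTrialSpec] = None,
    ) -> Responder:
        """A staircase/block-compatible responder running full trials."""
        base_spec = trial_spec or BinauralTrialSpec(delta_ipd_env=START_DELTA_IPD)

        def respond(delta_ipd: float, rng: np.random.Generator) -> bool:
            from dataclasses import replace
            spec = replace(base_spec, delta_ipd_env=delta_ipd)
            trial = stimuli.assemble_2afc_trial(
                spec, condition, sam_level,
                noise=None if condition == "Q" else noise,
                seed=int(rng.integers(2**31)),
            )
            return self.decide_trial(trial, rng) == trial.correct_answer

        return respond
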