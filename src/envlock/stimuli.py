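"""Acoustic stimulus synthesis and calibration.

Sinusoidally amplitude-modulated (SAM) tones, notched noise with exact
spectral notches, low-pass masking noise, and binaural two-interval trial
assembly for envelope-ITD lateralization experiments.

Conventions
-----------
* Pressure waveforms are in pascal; level is dB SPL re 20 µPa, measured as
  RMS over the un-ramped steady state.
* The SAM modulator is ``1 + sin(2*pi*f_m*t + phase)``; full modulation
  depth (100 %) is the default.
* Notched noise is synthesized in the spectral domain (complex-Gaussian
  bins with prescribed magnitude, zeroed inside the notch), which gives
  brick-wall band edges and a directly testable notch floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Tuple

import numpy as np
from scipy import signal as sps

P_REF = 20e-6  # reference pressure, Pa

#: Default sampling rates per experimental context (Hz).
FS_MODEL = 100_000.0
FS_RECORDING = 48_828.0
FS_PSYCHO = 48_000.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Stimulus:
    """A calibrated pressure waveform plus its full generation metadata.

    ``waveform`` has shape (n_samples,) for single-channel stimuli or
    (2, n_samples) for binaural ones.
    """

    waveform: np.ndarray
    fs: float
    f_c: Optional[float] = None
    f_m: Optional[float] = None
    depth: float = 1.0
    level: Optional[float] = None
    ramp: float = 0.0
    duration: float = 0.0
    channels: int = 1

    @property
    def n_samples(self) -> int:
        return self.waveform.shape[-1]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, i: int) -> np.ndarray:
        if self.channels == 1:
            if i != 0:
                raise IndexError("single-channel stimulus")
            return np.atleast_2d(self.waveform)[0]
        return self.waveform[i]

    def as_mono(self, i: int = 0) -> "Stimulus":
        """A single-channel view (used when feeding one ear to the periphery)."""
        return replace(self, waveform=self.channel(i), channels=1)


InterauralMode = Literal["uncorrelated", "left_only", "right_only", "diotic", "absent"]


@dataclass
class NotchedNoiseSpec:
    """Band-limited Gaussian noise with a spectral notch centered at ``f_c``.

    The notch is linear around the center: edges at ``f_c*(1 - w/200)`` and
    ``f_c*(1 + w/200)`` for a width ``w`` in percent of ``f_c``.
    """

    f_c: float
    w: float                      # notch width, % of f_c
    spectral_level: float         # dB SPL per Hz in the passbands
    f_lo: float = 1.0
    f_hi: float = 8500.0
    interaural: InterauralMode = "uncorrelated"
    seed: int = 0

    @property
    def notch_edges(self) -> Tuple[float, float]:
        return (self.f_c * (1 - self.w / 200.0), self.f_c * (1 + self.w / 200.0))

    def validate(self) -> None:
        lo, hi = self.notch_edges
        if not (self.f_lo < lo < hi < self.f_hi):
            raise ValueError(
                f"notch [{lo:.0f}, {hi:.0f}] Hz must lie strictly inside the "
                f"noise band [{self.f_lo:.0f}, {self.f_hi:.0f}] Hz"
            )


@dataclass
class BinauralTrialSpec:
    """Geometry of one 2I-2AFC envelope-ITD trial.

    The two intervals carry envelope IPDs symmetric around zero, so the
    inter-interval difference is ``delta_ipd_env = 2 * ipd_env``.
    """

    delta_ipd_env: float          # radians, inter-interval difference
    f_c: float = 4000.0
    f_m: float = 128.0
    sam_duration: float = 0.3
    ramp: float = 0.02
    gap: float = 0.05
    lowpass_masker_cutoff: float = 1300.0
    fs: float = FS_PSYCHO

    @property
    def ipd_env(self) -> float:
        return self.delta_ipd_env / 2.0

    @property
    def delta_itd_env(self) -> float:
        return ipd_to_itd(self.delta_ipd_env, self.f_m)


# ---------------------------------------------------------------------------
# level arithmetic
# ---------------------------------------------------------------------------

def db_spl(rms: float) -> float:
    """Sound pressure level of an RMS pressure, dB SPL re 20 µPa."""
    if rms <= 0:
        raise ValueError("RMS pressure must be positive")
    return 20.0 * math.log10(rms / P_REF)


def rms_from_db(level: float) -> float:
    """RMS pressure (Pa) of a given dB SPL level."""
    return P_REF * 10.0 ** (level / 20.0)


def relative_spectral_level(noise_spectral_level: float, sam_level: float) -> float:
    """Relative spectral noise level g = spectral level − tone level (dB/Hz)."""
    return noise_spectral_level - sam_level


def spectral_level_from_relative(g: float, sam_level: float) -> float:
    """Inverse of :func:`relative_spectral_level`."""
    return g + sam_level


def ipd_to_itd(delta_ipd: float, f_m: float) -> float:
    """Convert an envelope interaural phase difference (rad) to time (s)."""
    if f_m <= 0:
        raise ValueError("modulation frequency must be positive")
    return delta_ipd / (2.0 * math.pi * f_m)


def itd_to_ipd(delta_itd: float, f_m: float) -> float:
    """Convert an envelope interaural time difference (s) to phase (rad)."""
    if f_m <= 0:
        raise ValueError("modulation frequency must be positive")
    return delta_itd * 2.0 * math.pi * f_m


# ---------------------------------------------------------------------------
# synthesis
# ---------------------------------------------------------------------------

def _cos2_ramp(n_total: int, n_ramp: int) -> np.ndarray:
    """Squared-cosine on/off gate of length ``n_total``."""
    gate = np.ones(n_total)
    if n_ramp > 0:
        ph = np.linspace(0.0, math.pi / 2.0, n_ramp, endpoint=False)
        rise = np.sin(ph) ** 2
        gate[:n_ramp] = rise
        gate[-n_ramp:] = rise[::-1]
    return gate


def synth_sam(
    f_c: float,
    f_m: float,
    level: float,
    duration: float,
    ramp: float = 0.02,
    fs: float = FS_MODEL,
    env_phase: float = 0.0,
    depth: float = 1.0,
) -> Stimulus:
    """Synthesize a SAM tone calibrated to ``level`` dB SPL.

    The un-ramped waveform is ``A * (1 + depth*sin(2*pi*f_m*t + env_phase))
    * sin(2*pi*f_c*t)`` with ``A`` chosen so the steady-state RMS matches
    the requested level.  Squared-cosine ramps of ``ramp`` seconds are then
    applied at both ends.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not (f_m < f_c < fs / 2):
        raise ValueError("need f_m < f_c < fs/2 (aliasing)")
    if duration <= 2 * ramp:
        raise ValueError("duration must exceed twice the ramp time")

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    env = 1.0 + depth * np.sin(2.0 * math.pi * f_m * t + env_phase)
    x = env * np.sin(2.0 * math.pi * f_c * t)

    n_ramp = int(round(ramp * fs))
    steady = x[n_ramp: n - n_ramp] if n_ramp else x
    rms = math.sqrt(float(np.mean(steady**2)))
    x *= rms_from_db(level) / rms
    x *= _cos2_ramp(n, n_ramp)

    return Stimulus(
        waveform=x, fs=fs, f_c=f_c, f_m=f_m, depth=depth,
        level=level, ramp=ramp, duration=duration, channels=1,
    )


def _noise_channel(
    rng: np.random.Generator,
    n: int,
    fs: float,
    bands: list[tuple[float, float]],
    spectral_level: float,
) -> np.ndarray:
    """One realization of Gaussian noise with flat PSD over ``bands``."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    psd = (rms_from_db(spectral_level)) ** 2  # Pa^2 per Hz, one-sided
    mask = np.zeros(freqs.size, dtype=bool)
    for lo, hi in bands:
        mask |= (freqs >= lo) & (freqs <= hi)
    mask[0] = False
    if n % 2 == 0:
        mask[-1] = False
    # Complex-Gaussian bins.  With X_k = (a + ib)*sigma, a,b ~ N(0,1), the
    # inverse rfft gives E[x^2] = (4*sigma^2/n^2) * (#bins); matching the
    # target E[x^2] = psd * (#bins) * fs/n requires sigma = sqrt(psd*fs*n)/2.
    sigma = math.sqrt(psd * fs * n) / 2.0
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    spec = np.where(mask, z * sigma, 0.0)
    return np.fft.irfft(spec, n=n)


def synth_noise(spec: NotchedNoiseSpec, duration: float, fs: float = FS_MODEL) -> Stimulus:
    """Synthesize notched (or plain band-limited) Gaussian noise.

    Returns a 1- or 2-channel :class:`Stimulus` depending on
    ``spec.interaural``.  For ``uncorrelated`` the two ears get independent
    realizations derived from ``spec.seed``; for ``diotic`` they are
    identical; ``left_only``/``right_only`` zero the other ear.  The same
    seed always yields bit-identical waveforms.
    """
    spec.validate()
    if spec.f_hi >= fs / 2:
        raise ValueError("noise band edge above Nyquist")
    n = int(round(duration * fs))
    lo_edge, hi_edge = spec.notch_edges
    bands = [(spec.f_lo, lo_edge), (hi_edge, spec.f_hi)]

    ss = np.random.SeedSequence(spec.seed)
    if spec.interaural == "absent":
        wav = np.zeros((2, n))
        channels = 2
    elif spec.interaural == "uncorrelated":
        s1, s2 = ss.spawn(2)
        wav = np.stack([
            _noise_channel(np.random.default_rng(s1), n, fs, bands, spec.spectral_level),
            _noise_channel(np.random.default_rng(s2), n, fs, bands, spec.spectral_level),
        ])
        channels = 2
    elif spec.interaural == "diotic":
        x = _noise_channel(np.random.default_rng(ss), n, fs, bands, spec.spectral_level)
        wav = np.stack([x, x])
        channels = 2
    elif spec.interaural in ("left_only", "right_only"):
        x = _noise_channel(np.random.default_rng(ss), n, fs, bands, spec.spectral_level)
        wav = np.zeros((2, n))
        wav[0 if spec.interaural == "left_only" else 1] = x
        channels = 2
    else:  # pragma: no cover - guarded by typing
        raise ValueError(f"unknown interaural mode {spec.interaural!r}")

    return Stimulus(
        waveform=wav, fs=fs, f_c=spec.f_c, channels=channels,
        duration=duration, level=None,
    )


def synth_lowpass_noise(
    cutoff: float,
    spectral_level: float,
    duration: float,
    fs: float = FS_PSYCHO,
    seed: int = 0,
) -> Stimulus:
    """Diotic low-pass Gaussian noise (the distortion-product masker)."""
    n = int(round(duration * fs))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = _noise_channel(rng, n, fs, [(1.0, cutoff)], spectral_level)
    return Stimulus(waveform=np.stack([x, x]), fs=fs, channels=2, duration=duration)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def measure_level(stim: Stimulus, channel: int = 0, steady_only: bool = True) -> float:
    """Re-measure broadband level (dB SPL) of a stimulus channel."""
    x = stim.channel(channel)
    if steady_only and stim.ramp > 0:
        k = int(round(stim.ramp * stim.fs))
        x = x[k: x.size - k]
    return db_spl(math.sqrt(float(np.mean(x**2))))


def measure_spectral_level(
    stim: Stimulus,
    band: Tuple[float, float],
    channel: int = 0,
    nperseg: Optional[int] = None,
    check_line: bool = True,
) -> float:
    """Welch PSD averaged over ``band``, in dB SPL per Hz.

    Raises if the band is empty or if the content looks like a pure tone
    (spectral density per Hz is not defined for a line spectrum).
    """
    lo, hi = band
    if not (0 <= lo < hi <= stim.fs / 2):
        raise ValueError("band must be a nonempty interval below Nyquist")
    x = stim.channel(channel)
    if nperseg is None:
        nperseg = min(x.size, 8192)
    f, pxx = sps.welch(x, fs=stim.fs, nperseg=nperseg)
    sel = (f >= lo) & (f <= hi)
    if not np.any(sel):
        raise ValueError("band narrower than one analysis bin")
    p_band = pxx[sel]
    mean_p = float(np.mean(p_band))
    if mean_p <= 0:
        return -np.inf
    # A line spectrum concentrates the band power in a few bins (the Welch
    # window's main lobe); flat noise keeps max/mean within a small factor.
    # Disable via check_line when probing a stop band, whose leakage
    # residue is legitimately spiky.
    if (check_line and p_band.size >= 16
            and float(np.max(p_band)) > 0.1 * p_band.size * mean_p):
        raise ValueError("band content is a spectral line; density per Hz undefined")
    return 10.0 * math.log10(mean_p / P_REF**2)


# ---------------------------------------------------------------------------
# 2I-2AFC trial assembly
# ---------------------------------------------------------------------------

Condition = Literal["Q", "Mon_left", "Mon_right", "Bin"]


@dataclass
class TrialStimuli:
    """The two binaural intervals of a 2I-2AFC trial plus the answer key."""

    interval1: Stimulus
    interval2: Stimulus
    correct_answer: Literal["left", "right"]
    spec: BinauralTrialSpec = field(repr=False, default=None)
    condition: str = "Q"


def _binaural_sam(spec: BinauralTrialSpec, sam_level: float, ipd_env: float) -> Stimulus:
    """One binaural SAM interval; only the ongoing envelope phase differs.

    Positive ``ipd_env`` means the left-ear envelope leads (its phase is
    advanced by ``+ipd_env/2``, the right delayed by the same amount).
    Onset/offset gating is synchronous across ears.
    """
    left = synth_sam(spec.f_c, spec.f_m, sam_level, spec.sam_duration,
                     spec.ramp, spec.fs, env_phase=+ipd_env / 2.0)
    right = synth_sam(spec.f_c, spec.f_m, sam_level, spec.sam_duration,
                      spec.ramp, spec.fs, env_phase=-ipd_env / 2.0)
    wav = np.stack([left.waveform, right.waveform])
    return Stimulus(waveform=wav, fs=spec.fs, f_c=spec.f_c, f_m=spec.f_m,
                    level=sam_level, ramp=spec.ramp,
                    duration=spec.sam_duration, channels=2)


def assemble_2afc_trial(
    spec: BinauralTrialSpec,
    condition: Condition,
    sam_level: float,
    noise: Optional[NotchedNoiseSpec] = None,
    seed: int = 0,
    masker_relative_level: float = -35.0,
) -> TrialStimuli:
    """Assemble the two intervals of one lateralization trial.

    The intervals carry opposite-sign envelope IPDs of magnitude
    ``delta_ipd_env / 2``; which ear leads in interval 2 is randomized per
    trial.  Notched noise is added per ``condition``; a diotic low-pass
    masker at ``masker_relative_level`` dB/Hz re the SAM level is always
    added.  The correct answer is the ear leading in interval 2.
    """
    if spec.delta_ipd_env > 0.8 * math.pi + 1e-12:
        raise ValueError("delta_ipd_env exceeds the 0.8*pi cap")
    if condition == "Q" and noise is not None:
        raise ValueError("condition Q cannot carry a notched-noise spec")
    if condition != "Q" and noise is None:
        raise ValueError(f"condition {condition} requires a notched-noise spec")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # interval 2 leading ear: +1 -> left leads in interval 2
    sign = 1 if rng.random() < 0.5 else -1
    ipd = spec.ipd_env
    iv1 = _binaural_sam(spec, sam_level, -sign * ipd)
    iv2 = _binaural_sam(spec, sam_level, +sign * ipd)

    def add_noise(iv: Stimulus, k: int) -> Stimulus:
        wav = np.stack([iv.channel(0), iv.channel(1)])
        if condition != "Q":
            mode: InterauralMode
            if condition == "Bin":
                mode = "uncorrelated"
            elif condition == "Mon_left":
                mode = "left_only"
            else:
                mode = "right_only"
            nspec = replace(noise, interaural=mode,
                            seed=int(rng.integers(2**31)))
            nz = synth_noise(nspec, iv.duration, iv.fs)
            wav = wav + nz.waveform
        masker = synth_lowpass_noise(
            spec.lowpass_masker_cutoff,
            sam_level + masker_relative_level,
            iv.duration, iv.fs, seed=int(rng.integers(2**31)),
        )
        wav = wav + masker.waveform
        return replace(iv, waveform=wav)

    iv1 = add_noise(iv1, 0)
    iv2 = add_noise(iv2, 1)
    return TrialStimuli(
        interval1=iv1, interval2=iv2,
        correct_answer="left" if sign > 0 else "right",
        spec=spec, condition=condition,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_wav(stim: Stimulus, path: str, normalize: bool = True) -> None:
    """Write a stimulus to a float32 WAV file (per-channel)."""
    from scipy.io import wavfile

    wav = np.atleast_2d(stim.waveform).T.astype(np.float32)
    if normalize:
        peak = float(np.max(np.abs(wav)))
        if peak > 0:
            wav = wav / peak * 0.99
    wavfile.write(path, int(stim.fs), wav)
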