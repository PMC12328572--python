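# envlock

Envelope phase locking of auditory-nerve fibers under notched noise:
stimulus synthesis, a gain-controlled periphery model, vector-strength
analytics, and envelope-ITD psychophysics.

## The problem

Auditory-nerve fibers time their spikes to the envelope of amplitude-
modulated sounds. For a SAM tone — a carrier at *f<sub>c</sub>* modulated
as (1 + sin 2π*f<sub>m</sub>t*) — phase locking to the envelope is strong
just above a fiber's rate threshold but collapses at the moderate sound
levels of everyday listening (60–70 dB SPL), because the inner-hair-cell
drive saturates throughout most of the modulation cycle. At those levels
the envelope is instead carried by *off-frequency* channels, fibers tuned
half an octave away from the carrier.

Notched noise — band noise with a spectral gap centered on
*f<sub>c</sub>* — changes that picture: energy flanking a fiber's
characteristic frequency reduces the cochlear gain (suppression), shifts
the fiber's operating point downward, and *restores* on-frequency envelope
phase locking at moderate levels, while masking the off-frequency
channels. This package implements that full analysis chain for modelers
and psychophysicists: synthesize the stimuli, run a phenomenological
auditory periphery over fiber populations, quantify phase locking, and
simulate the binaural lateralization experiment that tests the mechanism
in humans.

## What is inside

| module | contents |
| --- | --- |
| `envlock.stimuli` | calibrated SAM tones, spectral-domain notched noise, low-pass maskers, binaural 2I-2AFC trial assembly, IPD↔ITD conversion |
| `envlock.periphery` | middle ear → flanking-band gain control → gammatone → saturating IHC → adapting synapse → refractory Poisson spikes |
| `envlock.spike_analysis` | vector strength VS = \|K⁻¹ Σ e^{iα_k}\|, Rayleigh significance p = e^{−K·VS²} (significant iff K > 50 and p < 0.001), phase histograms, rate/VS-level functions, CF/threshold/SR estimation |
| `envlock.psychophysics` | logistic simulated observers, the four-down/one-up staircase (target p = 0.5^{1/4} ≈ 0.84), exact binomial condition blocks, a channel-matching binaural decision model |
| `envlock.stats_util` | paired t, Wilcoxon fallback behind an Anderson–Darling gate, Bonferroni–Holm, 2×2 χ², Pearson correlation |
| `envlock.synthetic_data` | seeded virtual fiber populations (bimodal spontaneous rates split at 18 spikes/s) and observer cohorts; full virtual recording sessions |
| `envlock.experiments` | figure-level recipes (`level_series`, `population_sweep`, `notch_grid`, `shift_curves`, `staircase_thresholds`, `condition_blocks`, …) with manifests |

A CLI mirrors the main entry points: `envlock stimuli | simulate | analyze
| staircase | conditions | experiment <recipe>`.

## Worked example: notched noise restores on-frequency phase locking

```python
import numpy as np
from envlock import FiberParams, synth_sam, simulate_fiber_response
from envlock.stimuli import NotchedNoiseSpec, synth_noise, spectral_level_from_relative
from envlock.spike_analysis import summarize_set

fiber = FiberParams(cf=4000.0, sr=4.0)          # on-frequency model fiber
fs, dur, level = 48_000.0, 1.5, 65.0

quiet = synth_sam(4000.0, 128.0, level, dur, fs=fs)
resp_q = summarize_set(simulate_fiber_response(quiet, fiber, n_reps=10, seed=1))

def sam_in_notched_noise(seed):                 # fresh noise per repetition
    from dataclasses import replace
    sam = synth_sam(4000.0, 128.0, level, dur, fs=fs)
    spec = NotchedNoiseSpec(f_c=4000.0, w=20.0,
                            spectral_level=spectral_level_from_relative(-35.0, level),
                            f_hi=8500.0, seed=seed, interaural="diotic")
    return replace(sam, waveform=sam.waveform + synth_noise(spec, dur, fs).channel(0))

resp_n = summarize_set(simulate_fiber_response(sam_in_notched_noise, fiber, n_reps=10, seed=1))

print(f"quiet:          rate {resp_q.rate_mean:6.1f} sp/s   VS {resp_q.vs_mean:.3f}")
print(f"notched noise:  rate {resp_n.rate_mean:6.1f} sp/s   VS {resp_n.vs_mean:.3f}")
print(f"delta VS = {resp_n.vs_mean - resp_q.vs_mean:+.3f}")
```

prints

```
quiet:          rate  164.4 sp/s   VS 0.068
notched noise:  rate   92.2 sp/s   VS 0.418
delta VS = +0.350
```

At 65 dB SPL the on-frequency fiber's envelope phase locking is nearly
abolished in quiet (VS 0.07; the rate is saturated through most of the
modulation cycle). Adding notched noise at a relative spectral level of
g = −35 dB/Hz (a 20 % notch, 3600–4400 Hz) drives the flanking-band gain
control, lowers the firing rate, and restores the envelope code
(VS 0.42). The same machinery reproduces the level dependence of VS, the
off-frequency shift of the population VS profile, the rightward shift of
the VS-level function under fixed-level noise, the stronger effect on
low-spontaneous-rate fibers, and the collapse of envelope-ITD
lateralization when the notched noise is presented to one ear only.

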