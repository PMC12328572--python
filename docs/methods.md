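# Methods

This note documents the models implemented in `envlock`: what they
compute, the defaults and why, what the synthetic data emulate, and where
the simplifications matter.

## Stimuli

All stimuli are pressure waveforms in pascal; level is dB SPL re 20 µPa,
measured as RMS over the un-ramped steady state (calibration is exact by
construction: the waveform is scaled to the numerically measured
steady-state RMS). SAM tones are
`A·(1 + depth·sin(2πf_m t + φ))·sin(2πf_c t)` with squared-cosine ramps;
the default modulation depth is 1 (full).

Notched noise is synthesized in the spectral domain: complex-Gaussian
rFFT bins with variance `psd·fs·n/4` inside the passbands
`[f_lo, f_c(1−w/200)] ∪ [f_c(1+w/200), f_hi]` and exactly zero elsewhere.
This yields brick-wall band edges, an arbitrarily deep notch floor
(testable at ≥ 40 dB below the passband density), Gaussian statistics,
and bit-reproducibility per seed. The real stimuli had finite filter
slopes; we treat the edges as ideal because nothing downstream depends on
the slope at the scales probed here. Binaural noise is interaurally
uncorrelated (independent realizations per ear) unless requested
otherwise. Noise is re-drawn fresh for every stimulus repetition
("running noise"); frozen noise is available by reusing a seed.

2I-2AFC trials place envelope IPDs of ±ΔIPD/2 in the two intervals
(synchronous gating; only the ongoing modulator phase differs between the
ears), randomize which ear leads in interval 2, and always add a diotic
low-pass masker (cutoff 1.3 kHz, −35 dB/Hz re the tone) to exclude
low-frequency distortion-product cues. Conversion between envelope phase
and time differences is `ITD = IPD/(2πf_m)`.

Default sampling rates per context: 100 kHz (periphery modeling),
48 828 Hz (recording emulation), 48 kHz (psychophysics); any rate above
the stimulus bandwidth is accepted. Tests and the property suite run at
32–48 kHz with sub-second to 2.4-s stimuli and 4–10 repetitions — problem
sizes chosen so the statistical power matches what each assertion needs.

## Periphery model

A deliberately minimal cascade that carries the causal ingredients of the
mechanism under study — level-dependent cochlear gain with *flanking-band*
control (suppression), saturating transduction, adaptation, refractory
stochastic spiking. It is a phenomenological model built for this
package, not a re-implementation of any published periphery model; its
claims are directional, not waveform-faithful.

Stages, per fiber with characteristic frequency CF:

1. **Middle ear** — 2nd-order Butterworth band-pass, 0.3–8.5 kHz.
2. **Control path** — two 8th-order gammatone bands at
   `CF ± (ctrl_bw_factor/2)·ERB(CF)` (default span 5 signal bandwidths,
   i.e. flanks at ±2.5 ERB), power-smoothed with τ = 5 ms. The control
   level is the **dB average of the two flanks**, so gain reduction
   requires energy on *both* sides of CF — the signature of a notched or
   broadband masker. Two design constraints force this form:
   * the on-frequency signal must leak only negligibly into the control
     path, otherwise a masker 9 dB below the tone (the g = −35 dB/Hz
     condition) could never move the gain — hence the steep 8th-order
     flanks placed 2.5 ERB out;
   * a single flank must not be able to silence a channel, otherwise an
     intense tone kills the channels tuned ±0.4 octave away (whose flank
     sits on the tone) and off-frequency listening in quiet disappears —
     hence the both-sides (dB-mean) rule.
3. **Gain** — sigmoid in the control level L:
   `gain = gain_min + (gain_max−gain_min)/(1+exp((L−L50)/slope))`,
   defaults gain_max 45 dB, gain_min 0 dB, L50 38 dB SPL, slope 6 dB.
   With these values a 25–30 dB SPL/Hz notched noise pulls the gain to
   ~5–10 dB while the quiet-stimulus leakage leaves it at ~45 dB; the
   operating point therefore shifts by roughly 30–37 dB, consistent with
   the level shifts the mechanism is supposed to produce.
4. **Signal path** — input scaled by the instantaneous gain, then a
   4th-order gammatone at CF with human ERB bandwidth
   (24.7·(4.37f/kHz + 1)).
5. **IHC** — half-wave rectification through a saturating hyperbola
   `u/(u + knee)` (knee 0.05 Pa), then a 2nd-order 3-kHz low-pass: for a
   4-kHz carrier the fine structure is removed and the envelope drives
   the synapse.
6. **Synapse** — soft-thresholded drive (softplus with scale 0.03 around
   the threshold drive), saturating as `d/(d + 0.08)`, minus a
   fractional short-term adaptation (τ = 60 ms, strength 0.5), riding on
   the spontaneous rate, scaled by `sat_rate` (250 spikes/s; 180 for
   low-SR fibers). The threshold drive is computed by quadrature as the
   cycle-mean IHC output of a CF tone at the fiber's `threshold`
   parameter under full gain, so the pure-tone rate threshold equals that
   parameter. The soft knee matters near threshold: transduction is
   graded, the rate rises over ~10 dB, and the VS-level peak lands ~5 dB
   above the measured rate threshold rather than exactly at it.
7. **Spike generator** — inhomogeneous Poisson thinning with an absolute
   dead time t_abs = 450 µs and relative refractoriness with recovery
   `1 − exp(−(Δt − t_abs)/t_rel)`, t_rel = 513 µs. ISIs of a
   constant-rate run follow the dead-time-modified renewal distribution
   implied by that hazard (verified by Kolmogorov–Smirnov in the suite).

Populations place one fiber per CF on a log-spaced (Greenwood-type) grid,
default 25 CFs from 2 to 7.5 kHz. Low- vs high-spontaneous-rate classes
split at 18 spikes/s; low-SR fibers get a +5 dB threshold offset and a
reduced saturated rate. The stronger notched-noise benefit of low-SR
fibers in this model is carried mainly by spontaneous-rate dilution of
VS (spontaneous spikes are envelope-blind, so a high-SR fiber's restored
synchrony is diluted); a larger threshold offset would push the
noise-restored operating point of low-SR fibers below threshold and
invert the effect, which is why the offset is modest.

What the defaults were tuned against: the gain and synapse constants
(`gain_L50`, `gain_slope`, `syn_half`, `syn_soft`, `ihc_knee`) were fixed
once so that the invariant suite holds — VS-level non-monotonicity with a
peak a few dB above threshold and a ≥ 0.15 decline by 80 dB SPL, an
off-frequency VS maximum at 65 dB in quiet, an on-frequency maximum with
notched noise, a ≥ 15 dB operating-point shift under fixed 25 dB SPL/Hz
noise, and the SR ordering — and were not revisited afterwards.

## Spike analysis

Vector strength of in-window spikes at phases α_k = 2πf_m·t_k (phase 0 =
modulator zero-crossing at stimulus onset):
`VS = |K⁻¹ Σ e^{iα_k}|`, Rayleigh probability `p = exp(−K·VS²)`,
significant iff K > 50 and p < 0.001. A window with zero spikes leaves
VS *undefined* (None/NaN), never zero — zeros would silently bias level
functions. The analysis window runs from 20 ms after onset (excluding
the onset response) to stimulus offset. Rate and VS are computed per
repetition and then averaged (the pooled-spike VS is reported alongside;
neither ordering of the two is asserted anywhere because either can
occur). Unit characterization: CF as the arg-max of an edge-padded
3-point moving average of the frequency-response curve; rate threshold
as the lowest level whose rate exceeds the spontaneous mean + 2 SD at
matched window length (the criterion is configurable — the original
analysis did not state one); SR from silence epochs.

## Psychophysics

Simulated observers have logistic psychometric functions in log ΔIPD:
`P = ½ + (½ − lapse)·σ(β(log Δ − log α))`, default slope β = 8, lapse
≤ 0.04. The four-down/one-up staircase starts at 0.4π, is capped at
0.8π, steps by ×2 → ×2^½ → ×2^¼ (shrinking after the first and second
down-up reversal), and terminates after ten reversals at the minimum
step. A track's threshold is the geometric mean of the ΔIPD values at
those ten reversals — geometric because the steps are multiplicative —
and repeated tracks are summarized by geometric mean and geometric SD.
Across 500 simulated tracks the observer's psychometric function
evaluates to 0.83 at the recovered thresholds, i.e. within 0.01–0.02 of
the 0.5^{1/4} ≈ 0.8409 asymptote of the rule (slightly low, as expected
for finite tracks with asymmetric steps). Condition blocks report exact
(Clopper–Pearson) 95 % binomial intervals — conservative and
assumption-free, since the original interval method was not stated.

The binaural decision model embodies the channel-matching hypothesis:
each ear is run through the periphery on a shared CF grid (default 9
channels, 2 fibers per channel); per channel, the complex spike vector at
f_m is formed per ear; the channel's envelope delay estimate is the phase
of `C_R·C̄_L` divided by 2πf_m (the narrowband equivalent of
cross-correlating the two rate waveforms), and its weight is
`|C_L|·|C_R|` — synchronized rate on *both* sides, so a channel only
votes when both ears carry envelope information there. The decision
variable is the weight-summed delay difference between the two intervals;
its sign gives the response. Only the ongoing response enters (the first
60 ms and the offset ramp are excluded: gating is synchronous and its
transients carry no reliable interaural cue). Internal noise beyond the
spiking noise is available in the config but defaults to zero — finite
spike counts already limit performance, placing the binaural-notched-
noise condition near the staircase's 0.84 target at 0.4π ΔIPD while the
monaural-noise condition collapses toward chance (its informative
channels are disjoint across ears, so every product weight is small and
every surviving delay estimate is phase-noisy).

## Statistics

Paired two-sided t (df = n−1), Wilcoxon signed-rank as the nonparametric
fallback, routed by an Anderson–Darling normality gate at p < 0.05;
Bonferroni–Holm step-down for multiplicity (monotonicity enforced,
order-preserving); Pearson 2×2 χ² without continuity correction (the
correction is immaterial at n = 100 per cell and is configurable);
Pearson correlation with two-sided p. Identical paired samples return
t = 0, p = 1; constant nonzero differences are flagged degenerate rather
than silently tested.

## Synthetic data

The generators emulate the *structure* of the empirical material — CFs
log-uniform in 2–7.5 kHz; spontaneous rates from a two-component mixture
(exponential low-SR, scale 6; truncated-normal high-SR, 70 ± 25;
low-SR fraction 0.4) split at 18 spikes/s; SR-linked thresholds;
observer thresholds log-uniform in 0.1π–0.6π, all below the 0.8π
inclusion cap — but all distribution shapes are this package's own
choices; only the ranges and the 18 spikes/s boundary are anchored.
Virtual recording sessions render the full per-unit protocol through the
periphery (tuning probe at threshold + 10 dB, rate-level probe, 24-s
silence for SR, then the six-condition notched-noise grid:
w ∈ {20, 30} % × g ∈ {−55, −45, −35} dB/Hz at 60 dB SPL).

What passing tests on these data do **not** show: the generators contain
no gerbil-specific tuning sharpness (the periphery uses human ERBs), no
efferent feedback, no threshold microstructure, no CF-estimation error —
so quantitative agreement with any particular recorded fiber is out of
scope; the claims under test are the direction and rough magnitude of
the mechanism's effects.

## Numerical choices and degenerate inputs

Seeding uses `numpy.random.SeedSequence` throughout: every repetition,
fiber, and trial derives a child seed from the master seed, so all
outputs are bit-reproducible per seed and independent across units.
Gammatones are cascades of complex one-pole sections (pole bandwidth
1.019·ERB), gain-normalized exactly at their center frequency. Welch
PSDs flag line spectra (max bin > 0.1·n_bins × band mean) because a
density per Hz is undefined for a tone; stop-band probes disable the
check. Degenerate analysis inputs (zero spikes, flat tuning curves,
all-spontaneous rate-level functions, constant samples) are flagged or
rejected, never coerced to numbers.

## Known limitations

* The periphery is phenomenological: no power-law synaptic adaptation,
  no fractional Gaussian noise in the synapse, no level-dependent filter
  bandwidths, no medial olivocochlear feedback. Fine-timing phenomena
  and quantitative rate statistics of real fibers are outside its remit.
* Suppression requires flanking energy on both sides of CF; single-sided
  suppressors (classical two-tone suppression) do not reduce gain in
  this model.
* The binaural model is stationary and feedback-free; real listeners'
  trial-to-trial criterion shifts and the loudness-difference confound of
  monaural maskers are not modeled.
* Psychophysical "continuous" maskers are approximated by noise spanning
  each trial interval; only the steady-state masker statistics matter
  for the mechanism modeled here.
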