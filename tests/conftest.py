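"""Shared fixtures: small, fast stimuli and fibers for unit tests.

Unit tests run the periphery at 32-48 kHz with sub-second stimuli and few
repetitions; the longer figure-level settings live in the acceptance tests.
"""

import numpy as np
import pytest

from envlock import periphery, stimuli

FAST_FS = 32000.0


@pytest.fixture
def fiber():
    return periphery.FiberParams()


@pytest.fixture
def sam_65():
    return stimuli.synth_sam(4000.0, 128.0, 65.0, 0.5, 0.02, FAST_FS)


@pytest.fixture
def notch_spec():
    return stimuli.NotchedNoiseSpec(
        f_c=4000.0, w=20.0, spectral_level=30.0,
        f_lo=1.0, f_hi=0.45 * FAST_FS, seed=7)


def sam_plus_notch_factory(level, spectral_level, w=20.0, duration=0.5,
                           fs=FAST_FS, f_c=4000.0):
    """Stimulus factory producing a SAM tone in fresh notched noise."""
    from dataclasses import replace

    def make(seed):
        sam = stimuli.synth_sam(f_c, 128.0, level, duration, 0.02, fs)
        spec = stimuli.NotchedNoiseSpec(
            f_c=f_c, w=w, spectral_level=spectral_level,
            f_lo=1.0, f_hi=0.45 * fs, seed=seed, interaural="diotic")
        noise = stimuli.synth_noise(spec, duration, fs)
        return replace(sam, waveform=sam.waveform + noise.channel(0))

    return make
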