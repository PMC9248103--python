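import numpy as np
import pytest

from voxfrail.acoustics import VoiceRecording

FS = 10_000.0


def sine(freq_hz: float, duration_s: float = 1.0, fs: float = FS, amp: float = 0.9) -> VoiceRecording:
    t = np.arange(int(round(duration_s * fs))) / fs
    return VoiceRecording(amp * np.sin(2 * np.pi * freq_hz * t), fs, id=f"sine{freq_hz:g}")


def alternating_peak_fixture(
    peak_hi: float = 1.0, peak_lo: float = 0.8, f0: float = 100.0, n_cycles: int = 60, fs: float = FS
) -> VoiceRecording:
    """Sine cycles whose amplitude alternates peak_hi/peak_lo, valleys mirrored.

    The cycle length (fs/f0 = 100 samples) is divisible by 4, so each
    cycle's sampled extrema hit the amplitude exactly.
    """
    cycle = int(round(fs / f0))
    t = np.arange(cycle) / fs
    one = np.sin(2 * np.pi * f0 * t)
    x = np.concatenate([(peak_hi if i % 2 == 0 else peak_lo) * one for i in range(n_cycles)])
    return VoiceRecording(x, fs, id="altpeaks")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def clean_vowel():
    from voxfrail.synthdata import VowelSpec, synthesize_vowel

    return synthesize_vowel(
        VowelSpec(f0_hz=120.0, jitter_rel=0.004, shimmer_rel=0.02, seed=11)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One shared 60-participant cohort with moderate effects."""
    from voxfrail.synthdata import CohortConfig, simulate_cohort

    return simulate_cohort(
        CohortConfig(n_participants=60, seed=421, effect_ors={"A3": 1.06, "A4": 1.35})
    )
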