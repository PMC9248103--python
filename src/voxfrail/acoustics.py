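"""Acoustic feature extraction from sustained-vowel recordings.

Computes four scalar voice parameters from a short (~1 s) sustained /a/
phonation sampled at a nominal 10 kHz:

* **A1** — average zero-crossing rate: sign changes per sample, averaged
  over short analysis frames.  Tracks the dominant frequency content of
  the waveform.
* **A2** — variation of local peaks and valleys: the mean absolute
  deviation of cycle-peak (and cycle-valley) amplitudes, a shimmer-like
  index of amplitude instability.
* **A3** — variation of the first and second formant frequencies: mean
  absolute deviation of the per-frame F1 and F2 tracks (Hz), estimated by
  autocorrelation-method linear prediction.  Indexes resonance
  instability of the vocal tract.
* **A4** — spectral energy ratio: fraction of total spectral power above
  an *end frequency* of 3 kHz.  Rises with breathy or noisy phonation
  and with an indistinct formant structure.

All extraction parameters (frame length, LPC order, pre-emphasis, end
frequency) are collected in :class:`AcousticConfig` and default to
standard speech-analysis settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "VoiceRecording",
    "AcousticConfig",
    "AcousticFeatures",
    "FrameSet",
    "FormantTrack",
    "SilentRecordingError",
    "FeatureError",
    "preprocess",
    "make_frames",
    "estimate_f0",
    "compute_a1",
    "compute_a2",
    "compute_a3",
    "compute_a4",
    "formant_track",
    "estimate_formants",
    "extract_features",
    "extract_features_batch",
]


class SilentRecordingError(ValueError):
    """Raised when a recording carries no signal after DC removal."""


class FeatureError(ValueError):
    """Raised when a feature cannot be computed from the given signal."""


@dataclass
class VoiceRecording:
    """A mono sampled waveform with rate and bit-depth metadata.

    ``samples`` are dimensionless amplitudes on a nominal full scale of
    ±1 after decoding.
    """

    samples: np.ndarray
    sample_rate_hz: float
    bit_depth: int = 16
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("VoiceRecording requires a mono (1-D) signal")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass(frozen=True)
class AcousticConfig:
    """Extraction settings; defaults are standard speech-analysis values."""

    frame_ms: float = 25.0
    hop_ms: float = 10.0
    end_frequency_hz: float = 3000.0
    preemphasis: float = 0.97
    lpc_order: int | None = None  # None -> 2 + fs/1000
    formant_min_hz: float = 90.0
    formant_max_hz: float = 4000.0
    max_bandwidth_hz: float = 400.0
    f0_min_hz: float = 50.0
    f0_max_hz: float = 400.0
    a2_lowpass_hz: float | None = 450.0  # ripple/noise suppression before extrema picking
    target_rate_hz: float = 10000.0
    trim_to_s: float = 1.0
    deviation: str = "mad"  # mean absolute deviation; "std" also accepted

    def order_for(self, fs: float) -> int:
        return self.lpc_order if self.lpc_order is not None else int(round(2 + fs / 1000.0))


@dataclass
class FrameSet:
    """Fixed-length analysis windows cut from a signal."""

    frames: np.ndarray  # (n_frames, frame_len)
    frame_len_samples: int
    hop_samples: int

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass
class FormantTrack:
    """Per-frame (F1, F2) estimates in Hz with a validity flag per frame."""

    f1_hz: np.ndarray
    f2_hz: np.ndarray
    valid: np.ndarray

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))


@dataclass
class AcousticFeatures:
    """The four voice parameters for one recording.

    Features that could not be computed are NaN, with the cause recorded
    in ``reasons`` under the feature name.
    """

    a1: float
    a2: float
    a3: float
    a4: float
    end_frequency_hz: float = 3000.0
    id: str = ""
    reasons: dict = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite([self.a1, self.a2, self.a3, self.a4])))

    def as_dict(self) -> dict:
        return {
            "id": self.id,
            "A1": self.a1,
            "A2": self.a2,
            "A3": self.a3,
            "A4": self.a4,
            "valid": self.complete,
            "reasons": ";".join(f"{k}:{v}" for k, v in self.reasons.items()),
        }


# ---------------------------------------------------------------------------
# preprocessing & framing
# ---------------------------------------------------------------------------

def preprocess(recording: VoiceRecording, config: AcousticConfig = AcousticConfig()) -> VoiceRecording:
    """DC-remove, resample to the target rate, trim, and peak-normalize.

    The output has zero mean, at most ``config.trim_to_s`` seconds kept
    (the contiguous window of maximal RMS), and a peak amplitude of 0.9
    full scale.  A signal that is zero after DC removal raises
    :class:`SilentRecordingError`.
    """
    x = recording.samples - np.mean(recording.samples)
    if np.max(np.abs(x)) == 0.0:
        raise SilentRecordingError("silent recording")

    fs = recording.sample_rate_hz
    if fs != config.target_rate_hz:
        from fractions import Fraction

        frac = Fraction(int(round(config.target_rate_hz)), int(round(fs))).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
        fs = config.target_rate_hz

    n_keep = int(round(config.trim_to_s * fs))
    if len(x) > n_keep:
        # contiguous window of maximal RMS via cumulative energy
        e = np.concatenate([[0.0], np.cumsum(x**2)])
        win = e[n_keep:] - e[:-n_keep]
        start = int(np.argmax(win))
        x = x[start : start + n_keep]

    peak = np.max(np.abs(x))
    if peak == 0.0:
        raise SilentRecordingError("silent recording")
    x = x * (0.9 / peak)
    return VoiceRecording(x, fs, recording.bit_depth, recording.id)


def make_frames(x: np.ndarray, fs: float, frame_ms: float = 25.0, hop_ms: float = 10.0) -> FrameSet:
    """Cut a signal into fixed-length frames (rectangular, no padding)."""
    frame_len = int(round(frame_ms * fs / 1000.0))
    hop = int(round(hop_ms * fs / 1000.0))
    if frame_len > len(x):
        raise FeatureError("frame longer than signal")
    if hop <= 0:
        raise ValueError("hop must be positive")
    n_frames = 1 + (len(x) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return FrameSet(x[idx], frame_len, hop)


def estimate_f0(x: np.ndarray, fs: float, f0_min: float = 50.0, f0_max: float = 400.0) -> float:
    """Fundamental frequency by the autocorrelation peak within [f0_min, f0_max]."""
    x = x - np.mean(x)
    if len(x) > 4096:  # a 0.4 s slice at 10 kHz is ample for a sustained vowel
        x = x[:4096]
    n = len(x)
    # FFT-based autocorrelation
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec))[:n]
    lag_min = max(2, int(np.floor(fs / f0_max)))
    lag_max = min(n - 1, int(np.ceil(fs / f0_min)))
    if lag_max <= lag_min:
        raise FeatureError("signal too short for f0 estimation")
    lag = lag_min + int(np.argmax(r[lag_min : lag_max + 1]))
    return fs / lag


# ---------------------------------------------------------------------------
# A1: zero-crossing rate
# ---------------------------------------------------------------------------

def _signs_zero_inherit(x: np.ndarray) -> np.ndarray:
    """Signs of x where exact zeros inherit the previous nonzero sign."""
    s = np.sign(x)
    nz = s != 0
    if not nz.any():
        return s
    idx = np.where(nz, np.arange(len(s)), 0)
    np.maximum.accumulate(idx, out=idx)
    out = s[idx]
    # leading zeros (before the first nonzero) keep sign 0 -> no crossing
    first = np.argmax(nz)
    out[:first] = 0
    return out


def compute_a1(recording: VoiceRecording, config: AcousticConfig = AcousticConfig()) -> float:
    """Average zero-crossing rate.

    Per frame, the number of sign changes between consecutive samples is
    divided by the frame length in samples; A1 is the mean across
    frames.  Frames tile the signal without overlap, and each frame owns
    the L sample-to-sample gaps starting at its first sample (the gap to
    the next frame's first sample included): overlapping or gap-dropping
    frame layouts alias against periodic signals whose crossing spacing
    divides the hop, biasing the mean.  A frame at the very end of the
    signal has only L-1 gaps.  Dimensionless, in [0, 1].
    """
    x = recording.samples
    fs = recording.sample_rate_hz
    fset = make_frames(x, fs, config.frame_ms, config.frame_ms)
    s = _signs_zero_inherit(x)
    crossings = (s[1:] * s[:-1]) < 0  # crossing between samples i and i+1
    L = fset.frame_len_samples
    starts = fset.hop_samples * np.arange(len(fset))
    c = np.concatenate([[0], np.cumsum(crossings)])
    per_frame = (c[np.minimum(starts + L, len(x) - 1)] - c[starts]) / L
    return float(np.mean(per_frame))


# ---------------------------------------------------------------------------
# A2: peak/valley amplitude variation
# ---------------------------------------------------------------------------

def _fft_lowpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase low-pass: unity gain below the cutoff, raised-cosine
    roll-off over half an octave above it.  Exact passband gain matters
    here because A2 is an absolute amplitude measure."""
    n = len(x)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    hi = 1.5 * cutoff_hz
    gain = np.ones_like(f)
    ramp = (f > cutoff_hz) & (f < hi)
    gain[ramp] = 0.5 * (1 + np.cos(np.pi * (f[ramp] - cutoff_hz) / (hi - cutoff_hz)))
    gain[f >= hi] = 0.0
    return np.fft.irfft(spec * gain, n)


def _deviation(v: np.ndarray, kind: str) -> float:
    if kind == "std":
        return float(np.std(v))
    return float(np.mean(np.abs(v - np.mean(v))))


def compute_a2(recording: VoiceRecording, config: AcousticConfig = AcousticConfig()) -> float:
    """Mean absolute deviation of local peak and valley amplitudes.

    Local maxima and minima are detected over the whole utterance with a
    minimum spacing of half the estimated glottal period, which
    suppresses within-cycle ripple.  A mild zero-phase low-pass
    (``config.a2_lowpass_hz``) is applied first so that high-frequency
    noise riding on the waveform does not masquerade as amplitude
    instability.  A2 is the average of the peak MAD and the valley MAD,
    in full-scale amplitude units.
    """
    x = recording.samples
    fs = recording.sample_rate_hz
    f0 = estimate_f0(x, fs, config.f0_min_hz, config.f0_max_hz)
    dist = max(1, int(round(0.5 * fs / f0)))
    # oscillation check on the raw waveform: the band-limiting below can
    # ring on pathological (non-oscillating) inputs and fake extrema
    if len(sps.find_peaks(x, distance=dist)[0]) < 4 or len(sps.find_peaks(-x, distance=dist)[0]) < 4:
        raise FeatureError("too few extrema for A2 (non-oscillating signal)")
    if config.a2_lowpass_hz is not None and config.a2_lowpass_hz < fs / 2:
        x = _fft_lowpass(x, fs, config.a2_lowpass_hz)
    peaks, _ = sps.find_peaks(x, distance=dist)
    valleys, _ = sps.find_peaks(-x, distance=dist)
    # keep cycle crests only: residual ripple bumps between glottal
    # cycles sit far below the true maxima and would dominate the MAD
    if len(peaks):
        peaks = peaks[x[peaks] >= 0.25 * np.percentile(x[peaks], 90)]
    if len(valleys):
        valleys = valleys[x[valleys] <= 0.25 * np.percentile(x[valleys], 10)]
    if len(peaks) < 4 or len(valleys) < 4:
        raise FeatureError("too few extrema for A2 (non-oscillating signal)")
    return 0.5 * (_deviation(x[peaks], config.deviation) + _deviation(x[valleys], config.deviation))


# ---------------------------------------------------------------------------
# A3: formant-frequency variation (LPC)
# ---------------------------------------------------------------------------

def _lpc_batch(r: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Levinson-Durbin over a batch of autocorrelation rows.

    Parameters
    ----------
    r : (n, order+1) autocorrelation values r[0..order] per frame.

    Returns
    -------
    a : (n, order+1) prediction polynomials (a[:,0] == 1).
    ok : (n,) boolean, False where the recursion became unstable.
    """
    n = r.shape[0]
    a = np.zeros((n, order + 1))
    a[:, 0] = 1.0
    e = r[:, 0].copy()
    ok = e > 0
    e = np.where(ok, e, 1.0)
    for i in range(1, order + 1):
        acc = np.einsum("nj,nj->n", a[:, :i], r[:, i:0:-1])
        k = -acc / e
        ok &= np.abs(k) < 1.0
        k = np.where(ok, k, 0.0)
        a[:, 1 : i + 1] = a[:, 1 : i + 1] + k[:, None] * a[:, i - 1 :: -1][:, :i]
        e = e * (1.0 - k**2)
        ok &= e > 0
        e = np.where(ok, e, 1.0)
    return a, ok


def _poly_roots_batch(a: np.ndarray) -> np.ndarray:
    """Roots of a batch of monic polynomials via batched companion eigvals."""
    n, m = a.shape
    p = m - 1
    comp = np.zeros((n, p, p))
    comp[:, 0, :] = -a[:, 1:] / a[:, 0:1]
    i = np.arange(p - 1)
    comp[:, i + 1, i] = 1.0
    return np.linalg.eigvals(comp)


def estimate_formants(
    frame: np.ndarray,
    fs: float,
    lpc_order: int | None = None,
    config: AcousticConfig = AcousticConfig(),
) -> tuple[float, float, bool]:
    """Estimate (F1, F2) from one frame by autocorrelation-method LPC.

    The frame is pre-emphasized and Hamming-windowed; prediction-polynomial
    roots with positive imaginary part are converted to (frequency,
    bandwidth) pairs; candidates are kept when the bandwidth is below
    ``config.max_bandwidth_hz`` and the frequency lies in
    [``formant_min_hz``, ``formant_max_hz``].  The two lowest surviving
    frequencies are returned; validity is False when fewer than two
    survive or the LPC recursion is unstable.
    """
    order = lpc_order if lpc_order is not None else config.order_for(fs)
    track = _formants_from_frames(frame[None, :], fs, order, config)
    return float(track.f1_hz[0]), float(track.f2_hz[0]), bool(track.valid[0])


def _formants_from_frames(frames: np.ndarray, fs: float, order: int, config: AcousticConfig) -> FormantTrack:
    n, L = frames.shape
    w = np.hamming(L)
    y = np.empty_like(frames)
    y[:, 0] = frames[:, 0]
    y[:, 1:] = frames[:, 1:] - config.preemphasis * frames[:, :-1]
    y = y * w
    # autocorrelation r[0..order] per frame
    nfft = int(2 ** np.ceil(np.log2(2 * L)))
    spec = np.fft.rfft(y, nfft, axis=1)
    acf = np.fft.irfft(spec * np.conj(spec), axis=1)[:, : order + 1]
    a, ok = _lpc_batch(acf, order)
    f1 = np.full(n, np.nan)
    f2 = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    if ok.any():
        roots = _poly_roots_batch(a)
        mag = np.abs(roots)
        ang = np.angle(roots)
        with np.errstate(divide="ignore"):
            freq = ang * fs / (2 * np.pi)
            bw = -np.log(np.clip(mag, 1e-12, None)) * fs / np.pi
        keep = (
            (ang > 0)
            & (mag < 1.0)
            & (bw < config.max_bandwidth_hz)
            & (freq >= config.formant_min_hz)
            & (freq <= config.formant_max_hz)
        )
        for i in np.nonzero(ok)[0]:
            cand = np.sort(freq[i][keep[i]])
            if len(cand) >= 2:
                f1[i], f2[i] = cand[0], cand[1]
                valid[i] = True
    return FormantTrack(f1, f2, valid)


def formant_track(recording: VoiceRecording, config: AcousticConfig = AcousticConfig()) -> FormantTrack:
    """Per-frame (F1, F2) track over standard analysis frames."""
    x = recording.samples
    fs = recording.sample_rate_hz
    fset = make_frames(x, fs, config.frame_ms, config.hop_ms)
    order = config.order_for(fs)
    return _formants_from_frames(fset.frames, fs, order, config)


def compute_a3(track: FormantTrack, config: AcousticConfig = AcousticConfig()) -> float:
    """Mean absolute deviation of the F1 and F2 tracks, averaged, in Hz."""
    if track.n_valid < 5:
        raise FeatureError("too few valid formant frames for A3")
    f1 = track.f1_hz[track.valid]
    f2 = track.f2_hz[track.valid]
    return 0.5 * (_deviation(f1, config.deviation) + _deviation(f2, config.deviation))


# ---------------------------------------------------------------------------
# A4: spectral energy ratio
# ---------------------------------------------------------------------------

def compute_a4(recording: VoiceRecording, config: AcousticConfig = AcousticConfig()) -> float:
    """Fraction of spectral power above the end frequency (default 3 kHz).

    Welch periodogram with Hamming-windowed 25 ms segments at 50%
    overlap; the DC bin is excluded from both numerator and denominator.
    """
    fs = recording.sample_rate_hz
    if fs <= 2 * config.end_frequency_hz:
        raise FeatureError(
            f"sample rate {fs} Hz leaves no band above the end frequency {config.end_frequency_hz} Hz"
        )
    nperseg = min(len(recording.samples), int(round(0.025 * fs)))
    f, p = sps.welch(
        recording.samples,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
    )
    keep = f > 0  # exclude DC bin
    f, p = f[keep], p[keep]
    total = float(np.sum(p))
    if total == 0.0:
        raise FeatureError("zero spectral energy")
    return float(np.sum(p[f > config.end_frequency_hz]) / total)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def extract_features(recording: VoiceRecording, config: AcousticConfig = AcousticConfig()) -> AcousticFeatures:
    """Run the full extraction chain on one recording.

    Per-feature failures are recorded as NaN with a reason rather than
    raised, so a batch never dies on one bad recording.
    """
    reasons: dict[str, str] = {}
    try:
        rec = preprocess(recording, config)
    except (SilentRecordingError, ValueError) as exc:
        msg = str(exc)
        return AcousticFeatures(
            np.nan, np.nan, np.nan, np.nan,
            config.end_frequency_hz, recording.id,
            {k: msg for k in ("A1", "A2", "A3", "A4")},
        )

    def _try(name: str, fn):
        try:
            return fn()
        except (FeatureError, ValueError) as exc:
            reasons[name] = str(exc)
            return np.nan

    a1 = _try("A1", lambda: compute_a1(rec, config))
    a2 = _try("A2", lambda: compute_a2(rec, config))
    a3 = _try("A3", lambda: compute_a3(formant_track(rec, config), config))
    a4 = _try("A4", lambda: compute_a4(rec, config))
    return AcousticFeatures(a1, a2, a3, a4, config.end_frequency_hz, recording.id, reasons)


def extract_features_batch(recordings: Sequence[VoiceRecording], config: AcousticConfig = AcousticConfig()):
    """Extract features for many recordings into a pandas DataFrame."""
    import pandas as pd

    rows = [extract_features(r, config).as_dict() for r in recordings]
    return pd.DataFrame(rows)
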