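"""Synthetic sustained-vowel and cohort generation.

Provides a source-filter vowel synthesizer with controllable fundamental
frequency, jitter, shimmer, formant drift and high-frequency noise, plus
a cohort simulator that links those voice-synthesis knobs to frailty
status through configurable odds ratios, so the whole downstream
pipeline (extraction -> scoring -> association) can be exercised and its
parameter recovery checked without any external recordings.

Synthesis model
---------------
A glottal pulse train at ``f0_hz`` is perturbed per cycle (multiplicative
Gaussian jitter on the period and shimmer on the amplitude, clipped at
±3 SD), shaped by a two-stage one-pole low-pass giving roughly
-12 dB/oct spectral tilt, passed through a cascade of second-order
resonators at the formant centers/bandwidths (F1 and F2 centers follow a
reflected Gaussian random walk updated every 10 ms, bounded to ±20% of
the nominal center), and finally mixed with high-pass (>3 kHz) noise at
a configurable power relative to the vowel.  Output is peak-normalized
to 0.9 full scale and fully determined by the spec's seed.

Cohort model
------------
Frailty status is drawn at the configured prevalence; each participant's
acoustic target values are drawn from Gaussians whose frail/non-frail
mean shift is ``delta = ln(OR)/unit * sd**2``, the classic Gaussian
discriminant construction under which the implied univariate logistic
slope per reporting unit is exactly ``ln(OR)``.  Criterion fields are
then filled so all three frailty scorers reproduce the latent status,
and a vowel spec per participant is calibrated so extracted features
approximate the drawn targets.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .acoustics import (
    AcousticConfig,
    VoiceRecording,
    extract_features,
)

__all__ = [
    "VowelSpec",
    "CohortConfig",
    "Cohort",
    "SpecValidationError",
    "CalibrationError",
    "synthesize_vowel",
    "calibrate_spec_for_features",
    "calibration_ranges",
    "simulate_cohort",
    "FEATURE_UNITS",
    "DEFAULT_FEATURE_MEANS",
    "DEFAULT_FEATURE_SDS",
]

#: Reporting-scale unit per feature: odds ratios are expressed per this
#: much change in the raw feature (A1 per 1, A2 per 0.1, A3 per 10 Hz,
#: A4 per 0.1).
FEATURE_UNITS: dict[str, float] = {"A1": 1.0, "A2": 0.1, "A3": 10.0, "A4": 0.1}

#: Baseline (non-frail) feature means/SDs used by the cohort simulator.
#: Chosen to sit comfortably inside the synthesizer's achievable ranges;
#: see docs/methods.md.
DEFAULT_FEATURE_MEANS: dict[str, float] = {"A1": 0.18, "A2": 0.010, "A3": 18.0, "A4": 0.10}
DEFAULT_FEATURE_SDS: dict[str, float] = {"A1": 0.011, "A2": 0.003, "A3": 6.0, "A4": 0.035}


class SpecValidationError(ValueError):
    """Invalid synthesis specification; the message names the field."""


class CalibrationError(ValueError):
    """A feature target is outside the synthesizer's achievable range."""


@dataclass(frozen=True)
class VowelSpec:
    """Parameters of one synthetic sustained /a/ phonation."""

    duration_s: float = 1.0
    f0_hz: float = 140.0
    jitter_rel: float = 0.0
    shimmer_rel: float = 0.0
    formants: tuple = ((700.0, 80.0), (1200.0, 90.0), (2600.0, 120.0))
    formant_drift_hz: float = 0.0
    noise_hf_rel: float = 0.0
    noise_mid_rel: float = 0.0  # aspiration noise, 1.5-2.8 kHz band, relative power
    sample_rate_hz: float = 10000.0
    tilt_cutoff_hz: float = 500.0  # glottal spectral-tilt low-pass (two passes)
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise SpecValidationError("duration_s must be > 0")
        if not (0 < self.f0_hz < self.sample_rate_hz / 2):
            raise SpecValidationError("f0_hz must lie in (0, sample_rate_hz/2)")
        centers = [f for f, _ in self.formants]
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise SpecValidationError("formants centers must be strictly increasing")
        if any(c >= self.sample_rate_hz / 2 for c in centers):
            raise SpecValidationError("formants centers must be below Nyquist")
        for name in ("jitter_rel", "shimmer_rel", "formant_drift_hz", "noise_hf_rel", "noise_mid_rel"):
            if getattr(self, name) < 0:
                raise SpecValidationError(f"{name} must be >= 0")
        if self.sample_rate_hz <= 0:
            raise SpecValidationError("sample_rate_hz must be > 0")


def _resonator_sos(center_hz: float, bw_hz: float, fs: float) -> np.ndarray:
    """Second-order resonator section with unit DC gain."""
    r = np.exp(-np.pi * bw_hz / fs)
    theta = 2 * np.pi * center_hz / fs
    a1, a2 = -2 * r * np.cos(theta), r * r
    b0 = 1 + a1 + a2
    return np.array([b0, 0.0, 0.0, 1.0, a1, a2])


def synthesize_vowel(spec: VowelSpec) -> VoiceRecording:
    """Render one sustained-vowel recording from a :class:`VowelSpec`.

    Deterministic given ``spec.seed``; returns a mono waveform of
    ``round(duration_s * sample_rate_hz)`` samples peak-normalized to
    0.9 full scale.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))

    # --- glottal pulse train with per-cycle jitter/shimmer -----------------
    period = fs / spec.f0_hz
    x = np.zeros(n + int(np.ceil(period)) + 2)
    t = 0.0
    while t < n:
        jit = np.clip(rng.normal(0.0, 1.0), -3.0, 3.0) * spec.jitter_rel
        shi = np.clip(rng.normal(0.0, 1.0), -3.0, 3.0) * spec.shimmer_rel
        x[int(round(t))] += 1.0 + shi
        t += period * max(1.0 + jit, 0.05)
    x = x[:n]

    # --- spectral tilt: one-pole low-pass applied twice (about -12 dB/oct)
    a = np.exp(-2 * np.pi * spec.tilt_cutoff_hz / fs)
    for _ in range(2):
        x = sps.lfilter([1 - a], [1, -a], x)

    # --- formant resonator cascade with drifting F1/F2 ---------------------
    frame = max(1, int(round(0.010 * fs)))
    n_frames = int(np.ceil(n / frame))
    centers = np.array([f for f, _ in spec.formants], dtype=float)
    bands = np.array([b for _, b in spec.formants], dtype=float)
    # mean-reverting Gaussian wander of F1/F2 centers, updated per 10 ms
    # frame and reflected at ±20% of the nominal center.  Mean reversion
    # (correlation time ~30 ms) keeps the realized per-recording
    # deviation close to its expectation, unlike a free random walk
    # whose excursion size varies wildly between recordings.
    tracks = np.tile(centers[:, None], (1, n_frames))
    if spec.formant_drift_hz > 0:
        phi = np.exp(-1.0 / 3.0)  # 10 ms step / 30 ms correlation time
        for k in (0, 1):
            lo, hi = 0.8 * centers[k], 1.2 * centers[k]
            steps = rng.normal(0.0, spec.formant_drift_hz, n_frames)
            dev = 0.0
            for j in range(n_frames):
                dev = phi * dev + steps[j]
                pos = centers[k] + dev
                if pos > hi:
                    pos = 2 * hi - pos
                if pos < lo:
                    pos = 2 * lo - pos
                pos = min(max(pos, lo), hi)
                tracks[k, j] = pos
                dev = pos - centers[k]
    if spec.formant_drift_hz > 0:
        # drifting F1/F2: per-frame coefficient update with carried state
        y = np.empty(n)
        zi = np.zeros((2, 2))
        for j in range(n_frames):
            sl = slice(j * frame, min((j + 1) * frame, n))
            soss = [_resonator_sos(tracks[k, j], bands[k], fs) for k in (0, 1)]
            y[sl], zi = sps.sosfilt(np.stack(soss), x[sl], zi=zi)
        static = [_resonator_sos(centers[k], bands[k], fs) for k in range(2, len(centers))]
    else:
        y = x
        static = [_resonator_sos(centers[k], bands[k], fs) for k in range(len(centers))]
    if static:
        y = sps.sosfilt(np.stack(static), y)

    # --- additive aspiration (mid-band) and high-pass noise ----------------
    p_sig = np.mean(y**2)
    if spec.noise_mid_rel > 0 and p_sig > 0:
        w = rng.standard_normal(n)
        sos_bp = sps.butter(4, [1500.0, 2800.0], "bandpass", fs=fs, output="sos")
        w = sps.sosfilt(sos_bp, w)
        p_noise = np.mean(w**2)
        if p_noise > 0:
            y = y + w * np.sqrt(spec.noise_mid_rel * p_sig / p_noise)
    if spec.noise_hf_rel > 0 and p_sig > 0:
        w = rng.standard_normal(n)
        sos_hp = sps.butter(4, 3000.0, "highpass", fs=fs, output="sos")
        w = sps.sosfilt(sos_hp, w)
        p_noise = np.mean(w**2)
        if p_noise > 0:
            y = y + w * np.sqrt(spec.noise_hf_rel * p_sig / p_noise)

    peak = np.max(np.abs(y))
    if peak > 0:
        y *= 0.9 / peak
    return VoiceRecording(y, fs, 16, f"synth-{spec.seed}")


# ---------------------------------------------------------------------------
# knob -> feature calibration
# ---------------------------------------------------------------------------

_BASELINE = VowelSpec(
    f0_hz=128.0, jitter_rel=0.004, shimmer_rel=0.03,
    formant_drift_hz=5.0, noise_hf_rel=0.02, tilt_cutoff_hz=500.0,
)

# per-feature knob grids used to build the monotone calibration curves.
# A1 is steered through the F1 center frequency (the zero-crossing rate
# of a vowel tracks its dominant resonance); A2 via shimmer, A3 via
# formant drift, A4 via relative high-frequency noise power.  The F1
# span covers the natural across-speaker range for an open vowel.
_KNOB_GRIDS: dict[str, tuple[str, np.ndarray]] = {
    "A1": ("f1_center_hz", np.linspace(600.0, 950.0, 9)),
    "A2": ("shimmer_rel", np.linspace(0.0, 0.18, 9)),
    "A3": ("formant_drift_hz", np.array([0.0, 2.0, 4.0, 7.0, 11.0, 16.0, 23.0, 33.0, 45.0])),
    "A4": ("noise_hf_rel", np.linspace(0.0, 0.45, 9)),
}


def _with_knob(base: VowelSpec, knob: str, value: float, seed: int) -> VowelSpec:
    """Apply one calibration knob; ``f1_center_hz`` edits the formant list."""
    if knob == "f1_center_hz":
        (f1, b1), *rest = base.formants
        return replace(base, formants=((float(value), b1), *rest), seed=seed)
    return replace(base, **{knob: float(value)}, seed=seed)
_CAL_SEEDS = (101, 202, 303)


@dataclass(frozen=True)
class _KnobSweep:
    knob: str
    grid: np.ndarray
    main: np.ndarray  # monotonicized response of the paired feature
    direction: int
    cross: tuple  # ((feature, raw response values along this sweep), ...)

    def invert(self, target: float, clip: bool = False) -> float:
        lo, hi = float(np.min(self.main)), float(np.max(self.main))
        if not (lo <= target <= hi):
            if not clip:
                raise CalibrationError(
                    f"target {target:.4g} outside achievable interval [{lo:.4g}, {hi:.4g}]"
                )
            target = float(np.clip(target, lo, hi))
        if self.direction > 0:
            return float(np.interp(target, self.main, self.grid))
        return float(np.interp(target, self.main[::-1], self.grid[::-1]))

    def cross_shift(self, feature: str, knob_value: float, knob_base: float) -> float:
        """Expected change in another feature caused by moving this knob."""
        for feat, vals in self.cross:
            if feat == feature:
                return float(
                    np.interp(knob_value, self.grid, vals) - np.interp(knob_base, self.grid, vals)
                )
        return 0.0


@functools.lru_cache(maxsize=8)
def _calibration_curves(baseline: VowelSpec) -> dict[str, _KnobSweep]:
    """Measured knob->feature response curves around a baseline spec.

    For each feature the paired knob is swept over a fixed grid (other
    knobs at baseline) and all four features are extracted from a few
    seeded renderings and averaged.  The paired feature's response is
    monotonicized for inversion; the responses of the other three
    features are kept as cross-talk curves.
    """
    cfg = AcousticConfig()
    feats = list(_KNOB_GRIDS)
    sweeps: dict[str, _KnobSweep] = {}
    for feat, (knob, grid) in _KNOB_GRIDS.items():
        vals = np.empty((len(grid), len(feats)))
        for i, g in enumerate(grid):
            acc = []
            for s in _CAL_SEEDS:
                spec = _with_knob(baseline, knob, float(g), s)
                fx = extract_features(synthesize_vowel(spec), cfg)
                acc.append([getattr(fx, f.lower()) for f in feats])
            vals[i] = np.nanmean(acc, axis=0)
        j = feats.index(feat)
        direction = 1 if vals[-1, j] >= vals[0, j] else -1
        mono = np.maximum.accumulate(direction * vals[:, j]) * direction
        cross = tuple((f, vals[:, k].copy()) for k, f in enumerate(feats) if f != feat)
        sweeps[feat] = _KnobSweep(knob, grid, mono, direction, cross)
    return sweeps


def calibration_ranges(baseline: VowelSpec = _BASELINE) -> dict[str, tuple[float, float]]:
    """Achievable (min, max) extracted-feature interval per feature."""
    sweeps = _calibration_curves(baseline)
    return {f: (float(np.min(s.main)), float(np.max(s.main))) for f, s in sweeps.items()}


def _knob_base(baseline: VowelSpec, knob: str) -> float:
    if knob == "f1_center_hz":
        return baseline.formants[0][0]
    return getattr(baseline, knob)


#: resolution order: each feature's knob is set after the knobs whose
#: cross-talk on it is corrected for
_RESOLVE_ORDER = ("A4", "A3", "A1", "A2")


def calibrate_spec_for_features(
    targets: Mapping[str, float],
    baseline: VowelSpec = _BASELINE,
    seed: int = 0,
) -> VowelSpec:
    """Invert the measured knob->feature curves to hit the requested targets.

    A1 is steered via the F1 center frequency, A2 via shimmer, A3 via
    formant drift, A4 via high-frequency noise power.  Knobs are
    resolved in the order A4, A3, A1, A2; each step subtracts the
    cross-talk the already-fixed knobs exert on the current feature
    (measured cross-response curves) before inverting its own monotone
    curve.  A raw target outside the achievable interval raises
    :class:`CalibrationError` naming that interval; small overshoots
    introduced by the cross-talk correction are clipped.
    """
    sweeps = _calibration_curves(baseline)
    unknown = set(targets) - set(sweeps)
    if unknown:
        raise KeyError(f"unknown feature(s) {sorted(unknown)!r}")
    knob_values: dict[str, float] = {}  # feature -> chosen knob value
    for feat in _RESOLVE_ORDER:
        if feat not in targets:
            continue
        sweep = sweeps[feat]
        target = float(targets[feat])
        sweep.invert(target)  # raw-target range check
        corrected = target
        # A1 is left uncorrected: the zero-crossing rate responds to the
        # noise level far more strongly than the F1 span can offset, so
        # correcting it would only pin F1 at its lower bound and distort
        # the other features' operating points.
        if feat != "A1":
            for prev_feat, prev_value in knob_values.items():
                prev_sweep = sweeps[prev_feat]
                corrected -= prev_sweep.cross_shift(
                    feat, prev_value, _knob_base(baseline, prev_sweep.knob)
                )
        knob_values[feat] = sweep.invert(corrected, clip=True)
    out = baseline
    for feat, value in knob_values.items():
        out = _with_knob(out, sweeps[feat].knob, value, seed)
    return replace(out, seed=seed)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic frailty cohort.

    ``effect_ors`` are target odds ratios per reporting-scale unit
    (A1 per 1, A2 per 0.1, A3 per 10, A4 per 0.1).  ``sex_interaction``
    optionally multiplies a feature's OR for one sex, e.g.
    ``{"A4": ("female", 2.0)}``.
    """

    n_participants: int = 277
    prop_female: float = 0.632
    frailty_prevalence: float = 0.18
    effect_ors: Mapping[str, float] = field(default_factory=dict)
    feature_means_robust: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FEATURE_MEANS))
    feature_sds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FEATURE_SDS))
    sex_interaction: Mapping[str, tuple] = field(default_factory=dict)
    extra_flag_rate: float = 0.15
    duration_s: float = 1.0
    sample_rate_hz: float = 10000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not (0 <= self.prop_female <= 1):
            raise ValueError("prop_female must lie in [0, 1]")
        if not (0 < self.frailty_prevalence < 1):
            raise ValueError("frailty_prevalence must lie in (0, 1)")
        for k, v in self.effect_ors.items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"effect OR for {k} must be positive and finite")


@dataclass
class Cohort:
    """Output of :func:`simulate_cohort`."""

    participants: pd.DataFrame
    recordings: list
    truth: pd.DataFrame  # per-participant latent status, feature targets, knobs


# criterion fields and the indices they feed
_FIELD_INDEX = {
    "weight_loss": ("CHS", "SOF", "FRAIL"),
    "exhaustion": ("CHS", "FRAIL"),
    "grip_low": ("CHS",),
    "gait_slow": ("CHS", "FRAIL"),
    "adl": ("CHS",),
    "chair_unable": ("SOF", "FRAIL"),
    "energy_low": ("SOF",),
    "polypharmacy": ("FRAIL",),
}
_THRESHOLDS = {"CHS": 3, "SOF": 2, "FRAIL": 3}


def _index_scores(flags: dict[str, bool]) -> dict[str, int]:
    scores = {k: 0 for k in _THRESHOLDS}
    for f, on in flags.items():
        if on:
            for idx in _FIELD_INDEX[f]:
                scores[idx] += 1
    return scores


def _draw_flags(rng: np.random.Generator, frail: bool, extra_rate: float) -> dict[str, bool]:
    """Criterion flags consistent with the latent status on all three indices."""
    names = list(_FIELD_INDEX)
    if frail:
        flags = {f: False for f in names}
        order = list(rng.permutation(names))
        while any(s < _THRESHOLDS[i] for i, s in _index_scores(flags).items()):
            flags[order.pop(0)] = True
        # extra flags only add criteria, so frail status on every index holds
        for f in names:
            if not flags[f] and rng.random() < extra_rate:
                flags[f] = True
        return flags
    # non-frail: independent sparse flags, then trim any index at threshold
    flags = {f: bool(rng.random() < extra_rate) for f in names}
    while True:
        scores = _index_scores(flags)
        bad = [i for i, s in scores.items() if s >= _THRESHOLDS[i]]
        if not bad:
            return flags
        candidates = [f for f in names if flags[f] and any(i in _FIELD_INDEX[f] for i in bad)]
        flags[candidates[int(rng.integers(len(candidates)))]] = False


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate a cohort of participants with linked voices and frailty.

    Deterministic given ``config.seed``; per-participant random streams
    are derived by counter-based seed splitting, so enlarging the cohort
    never reshuffles earlier participants.
    """
    config.validate()
    features = list(FEATURE_UNITS)
    means = dict(config.feature_means_robust)
    sds = dict(config.feature_sds)
    ranges = calibration_ranges()

    participants: list[dict] = []
    truth_rows: list[dict] = []
    recordings: list[VoiceRecording] = []

    for i in range(config.n_participants):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        sex = "female" if rng.random() < config.prop_female else "male"
        frail = bool(rng.random() < config.frailty_prevalence)

        # acoustic targets: Gaussian discriminant construction so the
        # univariate logistic slope per reporting unit is exactly ln(OR)
        targets: dict[str, float] = {}
        for feat in features:
            or_eff = float(config.effect_ors.get(feat, 1.0))
            if feat in config.sex_interaction:
                mod_sex, mod = config.sex_interaction[feat]
                if sex == mod_sex:
                    or_eff *= float(mod)
            beta = np.log(or_eff) / FEATURE_UNITS[feat]
            delta = beta * sds[feat] ** 2
            val = rng.normal(means[feat] + (delta if frail else 0.0), sds[feat])
            lo, hi = ranges[feat]
            targets[feat] = float(np.clip(val, lo, hi))

        # voice
        voice_seed = int(ss.generate_state(1, np.uint32)[0] % (2**31))
        spec = calibrate_spec_for_features(targets, seed=voice_seed)
        spec = replace(spec, duration_s=config.duration_s, sample_rate_hz=config.sample_rate_hz)
        rec = synthesize_vowel(spec)
        rec.id = f"P{i:04d}"
        recordings.append(rec)

        # criterion fields
        flags = _draw_flags(rng, frail, config.extra_flag_rate)
        age = float(np.clip(rng.normal(76.8 if frail else 73.7, 7.0), 60, 100))
        weight = float(np.clip(rng.normal(52.5 if frail else 59.3, 9.5), 32, 110))
        height_m = float(rng.normal(1.58 if sex == "female" else 1.67, 0.06))
        cannot_walk = bool(flags["gait_slow"] and rng.random() < 0.05)
        row = {
            "id": rec.id,
            "sex": sex,
            "age_years": round(age, 1),
            "body_weight_kg": round(weight, 1),
            "bmi": round(weight / height_m**2, 1),
            "weight_loss_pct_year": round(float(rng.uniform(6, 12) if flags["weight_loss"] else rng.uniform(0, 3)), 1),
            "unintentional": bool(flags["weight_loss"] or rng.random() < 0.3),
            "exhaustion_answer": "yes" if flags["exhaustion"] else "no",
            "grip_kg": round(
                float(
                    rng.uniform(8, 17.5) if (flags["grip_low"] and sex == "female")
                    else rng.uniform(18.5, 30) if sex == "female"
                    else rng.uniform(14, 27) if flags["grip_low"]
                    else rng.uniform(29, 46)
                ),
                1,
            ),
            "gait_speed_m_s": (
                np.nan if cannot_walk
                else round(float(rng.uniform(0.4, 0.95) if flags["gait_slow"] else rng.uniform(1.05, 1.6)), 2)
            ),
            "cannot_walk": cannot_walk,
            "adl_deterioration": "yes" if flags["adl"] else "no",
            "chair_stand_able": not flags["chair_unable"],
            "energy_full_answer": "no" if flags["energy_low"] else "yes",
            "drug_count": int(rng.integers(8, 16) if flags["polypharmacy"] else rng.integers(0, 8)),
            "frail_true": frail,
        }
        row["weight_loss_kg_year"] = round(row["weight_loss_pct_year"] / 100.0 * weight, 1)
        participants.append(row)
        truth_rows.append(
            {
                "id": rec.id,
                "frail_true": frail,
                **{f"target_{k}": v for k, v in targets.items()},
                "f0_hz": spec.f0_hz,
                "shimmer_rel": spec.shimmer_rel,
                "formant_drift_hz": spec.formant_drift_hz,
                "noise_hf_rel": spec.noise_hf_rel,
                "voice_seed": voice_seed,
            }
        )

    return Cohort(pd.DataFrame(participants), recordings, pd.DataFrame(truth_rows))
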