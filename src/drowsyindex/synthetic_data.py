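"""Synthetic two-stage EEG fragments with controllable band-power contrast.

Each fragment mimics the study material: six channels at 200 Hz, 600 s
long, wakefulness (W) for the first half and stage-1 sleep (S1) for the
second, with the stage change realized as a linear amplitude cross-fade of
roughly one minute centred on the boundary.  Each rhythm band is band-
limited Gaussian noise (4th-order Butterworth-filtered white noise) scaled
to a stage-dependent RMS amplitude, on top of a stationary pink-noise
floor; a sinusoid mode replaces each band by a tone at its centre
frequency for analytic tests.

Default stage contrast follows the drowsiness literature the study builds
on: going W -> S1, delta and alpha rise (x1.8), theta rises (x1.4), beta
falls (x0.7).  Alpha is emphasized occipitally (O1/O2 x1.5) and delta
frontally (F3/F4 x1.3), so discovered indices can plausibly localize the
way the published ones do — a modelling choice of this generator, not a
property measured from any recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .band_features import CHANNELS, EegFragment

__all__ = [
    "GENERATOR_BANDS",
    "StageSpectrumProfile",
    "CohortSpec",
    "Cohort",
    "default_w_profile",
    "default_s1_profile",
    "generate_fragment",
    "generate_cohort",
]

#: The five disjoint bands the generator synthesizes (sigma and the alpha
#: sub-bands are automatically contained in beta/alpha).
GENERATOR_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 40.0),
}

#: Default W-stage RMS amplitudes (µV) per band, awake posterior rhythm
#: dominated by alpha/beta with a modest delta/theta background.
_W_AMPLITUDES = {"delta": 4.0, "theta": 3.0, "alpha": 4.0, "beta": 4.0,
                 "gamma": 1.5}

#: Default W -> S1 multiplicative contrast.
DEFAULT_CONTRAST = {"delta": 1.8, "theta": 1.4, "alpha": 1.8, "beta": 0.7,
                    "gamma": 1.0}

#: Default per-channel gains (F3, F4, C3, C4, O1, O2).
_CHANNEL_GAINS = {
    "alpha": (1.0, 1.0, 1.0, 1.0, 1.5, 1.5),   # occipital alpha emphasis
    "delta": (1.3, 1.3, 1.0, 1.0, 1.0, 1.0),   # frontal delta emphasis
}


@dataclass
class StageSpectrumProfile:
    """Per-band RMS amplitudes (µV) for one stage, plus a pink-noise floor.

    ``channel_gains`` maps a band to six per-channel multipliers; bands
    absent from it use gain 1 everywhere.
    """

    band_amplitudes: dict[str, float]
    pink_floor: float = 1.0
    stage: str = "W"
    channel_gains: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in _CHANNEL_GAINS.items()}
    )

    def __post_init__(self) -> None:
        for band, amp in self.band_amplitudes.items():
            if band not in GENERATOR_BANDS:
                raise ValueError(f"unknown generator band {band!r}")
            if amp < 0:
                raise ValueError("amplitudes must be non-negative")
        if self.pink_floor < 0:
            raise ValueError("pink floor must be non-negative")

    def gain(self, band: str) -> np.ndarray:
        return np.asarray(self.channel_gains.get(band,
                                                 (1.0,) * len(CHANNELS)))


def default_w_profile() -> StageSpectrumProfile:
    return StageSpectrumProfile(dict(_W_AMPLITUDES), stage="W")


def default_s1_profile(
    contrast: dict[str, float] | None = None,
) -> StageSpectrumProfile:
    contrast = contrast or DEFAULT_CONTRAST
    amps = {b: a * contrast.get(b, 1.0) for b, a in _W_AMPLITUDES.items()}
    return StageSpectrumProfile(amps, stage="S1")


@dataclass
class CohortSpec:
    """Cohort recipe: stage profiles, transition, noise seed, jitter."""

    n_subjects: int = 28
    seed: int = 0
    w_profile: StageSpectrumProfile = field(default_factory=default_w_profile)
    s1_profile: StageSpectrumProfile = field(default_factory=default_s1_profile)
    transition_seconds: float = 60.0
    scale_jitter_sigma: float = 0.2    # log-normal sigma of per-subject gain
    fs: float = 200.0
    stage_boundary: float = 300.0
    total_duration: float = 600.0
    mode: str = "noise"                # "noise" | "sinusoid"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        min_stage = min(self.stage_boundary,
                        self.total_duration - self.stage_boundary)
        if not (0.0 <= self.transition_seconds < 2 * min_stage):
            raise ValueError("transition must fit inside the stages")
        if self.mode not in ("noise", "sinusoid"):
            raise ValueError("mode must be 'noise' or 'sinusoid'")


@dataclass
class Cohort:
    """Generated fragments with a train/test partition (16/12 proportions)."""

    fragments: list[EegFragment]
    train_indices: list[int]
    test_indices: list[int]

    def __iter__(self):
        return iter(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def train(self) -> list[EegFragment]:
        return [self.fragments[i] for i in self.train_indices]

    @property
    def test(self) -> list[EegFragment]:
        return [self.fragments[i] for i in self.test_indices]


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    low, high = band
    high = min(high, 0.999 * fs / 2)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via spectral shaping."""
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _stage_envelope(t: np.ndarray, boundary: float,
                    transition: float) -> np.ndarray:
    """Weight of the W profile over time: 1 before, 0 after, linear fade."""
    if transition <= 0:
        return (t < boundary).astype(float)
    return np.clip(0.5 - (t - boundary) / transition, 0.0, 1.0)


def generate_fragment(spec: CohortSpec, subject_index: int) -> EegFragment:
    """One deterministic fragment for ``(spec.seed, subject_index)``."""
    n = int(round(spec.fs * spec.total_duration))
    rng = np.random.default_rng([spec.seed, subject_index])
    t = np.arange(n) / spec.fs
    w_weight = _stage_envelope(t, spec.stage_boundary, spec.transition_seconds)

    scale = float(np.exp(rng.normal(0.0, spec.scale_jitter_sigma))) \
        if spec.scale_jitter_sigma > 0 else 1.0

    samples = np.zeros((len(CHANNELS), n))
    for band, edges in GENERATOR_BANDS.items():
        amp_w = spec.w_profile.band_amplitudes.get(band, 0.0)
        amp_s1 = spec.s1_profile.band_amplitudes.get(band, 0.0)
        gains_w = spec.w_profile.gain(band)
        gains_s1 = spec.s1_profile.gain(band)
        if amp_w == 0.0 and amp_s1 == 0.0:
            continue
        for c in range(len(CHANNELS)):
            if spec.mode == "noise":
                carrier = _band_noise(rng, n, spec.fs, edges)
            else:
                f0 = 0.5 * (edges[0] + edges[1])
                phase = rng.uniform(0, 2 * np.pi)
                carrier = np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t + phase)
            env = (amp_w * gains_w[c] * w_weight
                   + amp_s1 * gains_s1[c] * (1.0 - w_weight))
            samples[c] += env * carrier

    floor_w = spec.w_profile.pink_floor
    floor_s1 = spec.s1_profile.pink_floor
    if floor_w > 0 or floor_s1 > 0:
        for c in range(len(CHANNELS)):
            env = floor_w * w_weight + floor_s1 * (1.0 - w_weight)
            samples[c] += env * _pink_noise(rng, n)

    samples *= scale
    return EegFragment(samples=samples, fs=spec.fs,
                       stage_boundary=spec.stage_boundary,
                       total_duration=spec.total_duration,
                       subject_id=f"syn-{spec.seed}-{subject_index:02d}")


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate ``n_subjects`` independent fragments and split 16:12.

    The train fraction mirrors the 16-of-28 proportion; at least one
    subject always lands in the training split.
    """
    fragments = [generate_fragment(spec, i) for i in range(spec.n_subjects)]
    n_train = max(1, int(round(spec.n_subjects * 16 / 28)))
    train = list(range(n_train))
    test = list(range(n_train, spec.n_subjects))
    return Cohort(fragments=fragments, train_indices=train, test_indices=test)
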