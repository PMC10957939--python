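"""Training-set corruption: the three artificial noise types plus
noise-only spectra, and the five-copy epoch composition.

Phase-1 (self-supervised) training regenerates, every epoch, a set made
of one clean copy of the raw training data, three corrupted copies, and
one copy of pure-noise spectra.  Each corrupted copy receives, in
acquisition order: random range clipping that always preserves the
800-1500 cm^-1 fingerprint region, a quartic calibration-drift
distortion of the axis, and additive Gaussian intensity noise whose
variance sits a fixed number of dB below the per-spectrum mean-square
intensity.  Every corrupted member keeps a reference to its clean
clipped twin, which is the reconstruction target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .freqpoly import distort_axis
from .spectra_io import NULL_LABEL, Spectrum, SpectrumBatch, resample

__all__ = [
    "AugmentConfig",
    "TrainingPair",
    "EpochSet",
    "add_intensity_noise",
    "clip_range",
    "make_noise_only",
    "build_epoch_set",
    "max_clipped_fraction",
]


@dataclass
class AugmentConfig:
    noise_level_db: float = -5.0  # noise variance re. mean-square intensity
    clip_start_max: float = 800.0  # cm^-1; random start drawn below this
    clip_stop_min: float = 1500.0  # cm^-1; random stop drawn above this
    distort_fraction: float = 0.02  # +-2% of each quartic coefficient
    seed: int = 0

    def __post_init__(self):
        if self.clip_start_max >= self.clip_stop_min:
            raise ValueError("clip_start_max must be below clip_stop_min")
        if self.distort_fraction < 0:
            raise ValueError("distort_fraction must be >= 0")


class TrainingPair(NamedTuple):
    """A corrupted input and its clean reconstruction target."""

    noisy: Spectrum
    target: Spectrum


@dataclass
class EpochSet:
    """One epoch's worth of (input, target) pairs, pre-shuffled."""

    pairs: list = field(default_factory=list)

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]

    def inputs(self) -> SpectrumBatch:
        return SpectrumBatch([p.noisy for p in self.pairs])

    def targets(self) -> SpectrumBatch:
        return SpectrumBatch([p.target for p in self.pairs])


def add_intensity_noise(spectrum: Spectrum, level_db: float, rng: np.random.Generator) -> Spectrum:
    """Additive i.i.d. Gaussian noise, variance = 10^(level_db/10) * RMS(I)^2.

    RMS(I) = sqrt(mean(I^2)) of the clean intensity, per spectrum, so the
    relative significance of the noise is comparable across spectra of
    very different magnitudes.  The axis is untouched.
    """
    if level_db is None or level_db == -np.inf:
        return spectrum.with_()
    sigma = float(np.sqrt(np.mean(spectrum.intensities**2) * 10.0 ** (level_db / 10.0)))
    noisy = spectrum.intensities + sigma * rng.standard_normal(len(spectrum))
    return spectrum.with_(intensities=noisy)


def clip_range(
    spectrum: Spectrum, clip_start_max: float, clip_stop_min: float, rng: np.random.Generator
) -> Spectrum:
    """Randomly clip the acquisition range, keeping the fingerprint region.

    start ~ U[range_min, clip_start_max], stop ~ U[clip_stop_min, range_max];
    samples outside [start, stop] are removed.  The spectrum must cover
    the [clip_start_max, clip_stop_min] window.
    """
    lo, hi = spectrum.range
    if lo > clip_start_max or hi < clip_stop_min:
        raise ValueError(
            f"spectrum range [{lo:.1f}, {hi:.1f}] does not cover the fingerprint "
            f"window [{clip_start_max}, {clip_stop_min}]"
        )
    start = rng.uniform(lo, clip_start_max)
    stop = rng.uniform(clip_stop_min, hi)
    keep = (spectrum.wavenumbers >= start) & (spectrum.wavenumbers <= stop)
    return spectrum.with_(
        wavenumbers=spectrum.wavenumbers[keep], intensities=spectrum.intensities[keep]
    )


def max_clipped_fraction(
    range_min: float, range_max: float, clip_start_max: float, clip_stop_min: float
) -> float:
    """Worst-case fraction of the span removable by the clipping draw."""
    span = range_max - range_min
    return ((clip_start_max - range_min) + (range_max - clip_stop_min)) / span


def _noise_floor(intensities: np.ndarray) -> float:
    """Robust noise-sigma estimate from the first difference.

    For white noise on a smooth signal, diff(I) is ~N(0, 2 sigma^2); the
    median absolute value is robust to the sparse band structure.
    """
    mad = np.median(np.abs(np.diff(intensities)))
    sigma = mad / (0.67448975 * np.sqrt(2.0))
    return float(max(sigma, 1e-12))


def make_noise_only(template: Spectrum, rng: np.random.Generator) -> Spectrum:
    """Zero-signal spectrum: the template's axis carrying pure Gaussian noise.

    Emulates the no-trapped-particle condition; sigma is matched to the
    template's estimated noise floor, mean is zero, and the spectrum
    receives the reserved null label (excluded from classification).
    """
    sigma = _noise_floor(template.intensities)
    noise = sigma * rng.standard_normal(len(template))
    return template.with_(intensities=noise, label=NULL_LABEL)


def build_epoch_set(
    raw_set: SpectrumBatch, config: AugmentConfig, rng: np.random.Generator
) -> EpochSet:
    """Compose one training epoch: 1 clean + 3 corrupted + 1 noise-only copy.

    Corruption order follows acquisition: clip -> distort axis -> add
    intensity noise.  Clipped members (and their clean-clipped targets)
    are re-resampled to the raw set's model length so the epoch set is
    shape-homogeneous.  The result is shuffled; the composition is fully
    determined by `rng`.
    """
    if len(raw_set) == 0:
        raise ValueError("raw set is empty")
    length = raw_set.length
    pairs: list[TrainingPair] = []
    # copy 1: unmodified
    for s in raw_set:
        pairs.append(TrainingPair(s, s))
    # copies 2-4: clip + axis distortion + intensity noise
    for _ in range(3):
        for s in raw_set:
            clipped = clip_range(s, config.clip_start_max, config.clip_stop_min, rng)
            target = resample(clipped, length)
            axis = distort_axis(target.wavenumbers, config.distort_fraction, rng)
            noisy = add_intensity_noise(target.with_(wavenumbers=axis), config.noise_level_db, rng)
            pairs.append(TrainingPair(noisy, target))
    # copy 5: pure noise (its own target; the model must represent the
    # zero-signal state, there is no cleaner original to recover)
    for s in raw_set:
        n = make_noise_only(s, rng)
        pairs.append(TrainingPair(n, n))
    order = rng.permutation(len(pairs))
    return EpochSet([pairs[i] for i in order])
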