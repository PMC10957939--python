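"""Synthetic single-particle Raman spectra with lab-dependent acquisition.

The real extracellular-vesicle dataset this package was designed around
is not publicly deposited, so this module generates labelled spectra
that reproduce its *statistical* structure: class-specific biomolecular
bands on a smooth fluorescence baseline, two virtual instruments with
very different wavenumber ranges and signal-to-noise ratios, and
reproducible randomness throughout.  The class profiles are chemically
plausible stand-ins (band positions echo standard Raman assignments,
e.g. the phenylalanine ring-breathing mode at 1003.6 cm^-1), not claims
about EV chemistry.

Bands are pseudo-Voigt (Lorentzian fraction 0.7, a typical Raman line
shape); the baseline is a nonnegative random cubic plus one broad
Gaussian hump; noise is additive Gaussian calibrated so that the
band-signal power over the noise power matches the preset SNR in dB.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra_io import Spectrum, write_spectrum

__all__ = [
    "BandProfile",
    "ClassProfile",
    "LabPreset",
    "make_spectrum",
    "make_dataset",
    "make_labelled_set",
    "default_classes",
    "default_labs",
    "LAB_PRESETS",
]

LORENTZ_FRACTION = 0.7


@dataclass
class BandProfile:
    """One vibrational band: position, width, and amplitude statistics."""

    center: float  # cm^-1
    fwhm: float  # cm^-1
    amplitude_mean: float  # counts
    amplitude_cv: float = 0.15  # coefficient of variation of the amplitude

    def __post_init__(self):
        if self.center <= 0 or self.fwhm <= 0:
            raise ValueError("band center and fwhm must be positive")
        if self.amplitude_mean < 0 or self.amplitude_cv < 0:
            raise ValueError("amplitude mean and cv must be nonnegative")


@dataclass
class ClassProfile:
    name: str
    bands: list
    baseline_scale: float = 10_000.0

    def __post_init__(self):
        if not self.bands:
            raise ValueError(f"class {self.name!r} needs at least one band")


@dataclass
class LabPreset:
    """A virtual instrument: acquisition range, resolution and SNR.

    `snr_db = None` disables detector noise; `axis_warp` adds a small
    fixed quartic bow to the otherwise linear pixel-to-wavenumber map
    (calibration drift proper is an augmentation, not a lab property).
    """

    name: str
    range: tuple = (300.0, 3674.0)
    native_points: int = 2048
    snr_db: float | None = 20.0
    axis_warp: float = 0.0

    def __post_init__(self):
        if self.range[0] >= self.range[1]:
            raise ValueError("lab range start must be below stop")
        if self.native_points < 64:
            raise ValueError("native_points must be >= 64")


def default_classes() -> list[ClassProfile]:
    """Three pairwise-separable biomolecular class profiles.

    protein-rich: sharp phenylalanine 1003.6, amide I 1655, CH3 2930;
    lipid-rich: CH2 twist 1302, CH2 bend 1440, CH2/CH3 stretches 2850/2880;
    carotenoid-rich: C-C 1157 and C=C 1520 resonance bands plus weak
    protein bands.
    """
    return [
        ClassProfile(
            "protein-rich",
            [
                BandProfile(1003.6, 8.0, 60_000.0),
                BandProfile(1655.0, 45.0, 45_000.0),
                BandProfile(2930.0, 60.0, 75_000.0),
            ],
        ),
        ClassProfile(
            "lipid-rich",
            [
                BandProfile(1302.0, 30.0, 40_000.0),
                BandProfile(1440.0, 35.0, 55_000.0),
                BandProfile(2850.0, 40.0, 80_000.0),
                BandProfile(2880.0, 40.0, 60_000.0),
            ],
        ),
        ClassProfile(
            "carotenoid-rich",
            [
                BandProfile(1157.0, 18.0, 90_000.0),
                BandProfile(1520.0, 20.0, 110_000.0),
                BandProfile(1003.6, 8.0, 15_000.0),
                BandProfile(1655.0, 45.0, 12_000.0),
            ],
        ),
    ]


#: Two virtual instruments mirroring the narrow/noisy vs wide/clean split
#: seen between typical grating and prism spectrometer configurations.
LAB_PRESETS: dict[str, LabPreset] = {
    "labP": LabPreset("labP", range=(309.0, 2035.0), native_points=1340, snr_db=8.0),
    "labT": LabPreset("labT", range=(300.0, 3674.0), native_points=2048, snr_db=20.0),
}


def default_labs() -> list[LabPreset]:
    return [LAB_PRESETS["labP"], LAB_PRESETS["labT"]]


def _pseudo_voigt(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-amplitude pseudo-Voigt profile."""
    hwhm = fwhm / 2.0
    gauss = np.exp(-4.0 * np.log(2.0) * ((x - center) / fwhm) ** 2)
    lorentz = hwhm**2 / ((x - center) ** 2 + hwhm**2)
    return (1.0 - LORENTZ_FRACTION) * gauss + LORENTZ_FRACTION * lorentz


def _axis(lab: LabPreset, rng: np.random.Generator) -> np.ndarray:
    lo, hi = lab.range
    axis = np.linspace(lo, hi, lab.native_points)
    if lab.axis_warp > 0:
        u = np.linspace(0.0, 1.0, lab.native_points)
        span = hi - lo
        bow = rng.uniform(-1, 1, size=3)
        warp = lab.axis_warp * span * (bow[0] * u * (1 - u) + bow[1] * (u * (1 - u)) ** 2 + bow[2] * u**2 * (1 - u))
        axis = axis + warp
        if np.any(np.diff(axis) <= 0):  # warp too strong for the grid
            axis = np.sort(axis)
    return axis


def make_spectrum(
    class_profile: ClassProfile,
    lab: LabPreset,
    rng: np.random.Generator,
    parts: bool = False,
):
    """Draw one synthetic spectrum of `class_profile` as seen by `lab`.

    intensity = sum of pseudo-Voigt bands (amplitudes jittered by their
    CV) + nonnegative smooth baseline + Gaussian noise with variance
    sigma^2 = mean(signal^2) * 10^(-snr_db/10).

    With `parts=True` also returns a dict with the clean components and
    the noise sigma (used for calibrating tests).
    """
    axis = _axis(lab, rng)
    lo, hi = lab.range
    in_range = [b for b in class_profile.bands if lo <= b.center <= hi]
    if not in_range:
        raise ValueError(
            f"no band of class {class_profile.name!r} falls inside the "
            f"{lab.name!r} range {lab.range}; this would be an unintended null-class spectrum"
        )
    signal = np.zeros_like(axis)
    for band in class_profile.bands:
        amp = band.amplitude_mean
        if band.amplitude_cv > 0:
            amp *= max(0.0, 1.0 + band.amplitude_cv * rng.standard_normal())
        signal += amp * _pseudo_voigt(axis, band.center, band.fwhm)
    # nonnegative baseline: random cubic (coefficients >= 0 on u in [0,1])
    # plus one broad fluorescence hump
    u = (axis - lo) / (hi - lo)
    c = rng.uniform(0.0, 0.3, size=4)
    hump_center = rng.uniform(0.2, 0.8)
    hump_width = rng.uniform(0.25, 0.5)
    hump_amp = rng.uniform(0.5, 1.0)
    baseline = class_profile.baseline_scale * (
        c[0] + c[1] * u + c[2] * u**2 + c[3] * u**3 + hump_amp * np.exp(-(((u - hump_center) / hump_width) ** 2))
    )
    clean = signal + baseline
    sigma = 0.0
    intensity = clean
    if lab.snr_db is not None and np.isfinite(lab.snr_db):
        sigma = float(np.sqrt(np.mean(signal**2) * 10.0 ** (-lab.snr_db / 10.0)))
        intensity = clean + sigma * rng.standard_normal(len(axis))
    spec = Spectrum(axis, intensity, label=class_profile.name, lab=lab.name)
    if parts:
        return spec, {"signal": signal, "baseline": baseline, "clean": clean, "sigma": sigma}
    return spec


def make_dataset(
    n_per_class: int,
    classes: list[ClassProfile] | None = None,
    labs: list[LabPreset] | None = None,
    rng: np.random.Generator | None = None,
) -> list[Spectrum]:
    """In-memory dataset: `n_per_class` spectra per (class, lab) pair."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    classes = default_classes() if classes is None else classes
    labs = default_labs() if labs is None else labs
    if not classes or not labs:
        raise ValueError("classes and labs must be nonempty")
    rng = np.random.default_rng() if rng is None else rng
    out = []
    for cls in classes:
        for lab in labs:
            for i in range(n_per_class):
                s = make_spectrum(cls, lab, rng)
                out.append(s.with_(id=f"{cls.name}_{lab.name}_{i:04d}"))
    return out


def make_labelled_set(
    n_per_class: int,
    classes: list[ClassProfile] | None = None,
    labs: list[LabPreset] | None = None,
    rng: np.random.Generator | None = None,
    out_dir: str = ".",
) -> pd.DataFrame:
    """Write a labelled synthetic dataset plus ``manifest.csv``.

    Returns the manifest (columns ``path,label,lab``, paths relative to
    `out_dir`).  Fully reproducible: the same seed yields byte-identical
    files and manifest.
    """
    spectra = make_dataset(n_per_class, classes, labs, rng)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for s in spectra:
        fname = f"{s.id}.txt"
        write_spectrum(s, os.path.join(out_dir, fname))
        rows.append({"path": fname, "label": s.label, "lab": s.lab})
    manifest = pd.DataFrame(rows, columns=["path", "label", "lab"])
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
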