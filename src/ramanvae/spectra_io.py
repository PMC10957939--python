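"""Reading, writing and resampling of single-particle Raman spectra.

A spectrum is a pair of equal-length vectors: Raman shift (wavenumber,
cm^-1, strictly increasing) and intensity (detector counts).  Files are
two-column delimited text (whitespace or comma), with ``#`` comment
lines and optional ``# key=value`` metadata headers — the least common
denominator of spectrometer exports.  Datasets are described by a CSV
manifest with columns ``path,label,lab``.

Intensities are deliberately left in raw detector counts: the modelling
stages compensate scale differences through loss weighting rather than
per-spectrum normalization.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumBatch",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "load_dataset",
]

#: Reserved label for zero-signal (pure noise) spectra.
NULL_LABEL = "__noise__"

#: Default model input length. A power of two keeps the one-sided DFT of
#: the Fourier loss simple and lets the strided convolution stack halve
#: the signal cleanly.
DEFAULT_LENGTH = 1024


@dataclass
class Spectrum:
    """One Raman measurement: wavenumber axis, intensities, metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    label: str | None = None
    lab: str | None = None
    id: str = ""

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D vectors")
        if len(self.wavenumbers) != len(self.intensities):
            raise ValueError("wavenumbers and intensities must have identical length")
        if len(self.wavenumbers) < 2:
            raise ValueError("a spectrum needs at least 2 samples")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValueError("wavenumbers must be finite")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite (no NaN/Inf)")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    @property
    def range(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def with_(self, **kw) -> "Spectrum":
        return replace(self, **kw)


@dataclass
class SpectrumBatch:
    """A list of spectra resampled to a common model length L."""

    spectra: list = field(default_factory=list)

    def __post_init__(self):
        lengths = {len(s) for s in self.spectra}
        if len(lengths) > 1:
            raise ValueError(f"batch members must share one length, got {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    @property
    def length(self) -> int:
        return len(self.spectra[0]) if self.spectra else 0

    def intensity_matrix(self) -> np.ndarray:
        return np.stack([s.intensities for s in self.spectra])

    def axis_matrix(self) -> np.ndarray:
        return np.stack([s.wavenumbers for s in self.spectra])

    def labels(self) -> list:
        return [s.label for s in self.spectra]


def read_spectrum(path) -> Spectrum:
    """Parse a two-column text file into a :class:`Spectrum`.

    Rows are sorted by wavenumber if not already ascending; duplicated
    wavenumbers are an error (the axis must be strictly increasing).
    ``# key=value`` header lines populate label/lab/id metadata.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"spectrum file not found: {path}")
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) == 0):
        raise ValueError(f"{path}: duplicate wavenumbers")
    return Spectrum(
        arr[:, 0],
        arr[:, 1],
        label=meta.get("label") or None,
        lab=meta.get("lab") or None,
        id=meta.get("id", os.path.splitext(os.path.basename(path))[0]),
    )


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column text with a metadata header.

    Values are printed with 12 significant digits so a read/write
    round-trip is lossless to well below 1e-6 relative error.
    """
    path = os.fspath(path)
    with open(path, "w", encoding="utf-8") as fh:
        if spectrum.id:
            fh.write(f"# id={spectrum.id}\n")
        if spectrum.label is not None:
            fh.write(f"# label={spectrum.label}\n")
        if spectrum.lab is not None:
            fh.write(f"# lab={spectrum.lab}\n")
        fh.write("# wavenumber_cm-1 intensity_counts\n")
        for w, i in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{w:.12g} {i:.12g}\n")


def resample(spectrum: Spectrum, length: int) -> Spectrum:
    """Resample onto `length` linearly spaced points over the same range.

    Intensities are linearly interpolated (monotone, artifact-free for
    noisy data); the range endpoints are preserved exactly.
    """
    if length < 2:
        raise ValueError("resample length must be >= 2")
    lo, hi = spectrum.range
    new_w = np.linspace(lo, hi, length)
    new_i = np.interp(new_w, spectrum.wavenumbers, spectrum.intensities)
    return spectrum.with_(wavenumbers=new_w, intensities=new_i)


def load_dataset(manifest, length: int = DEFAULT_LENGTH) -> SpectrumBatch:
    """Read every spectrum of a manifest, resampled to `length`.

    `manifest` is a CSV path (columns ``path,label,lab``; paths relative
    to the manifest directory) or an equivalent DataFrame with absolute
    paths.  Manifest labels override any label stored in the files.
    """
    if isinstance(manifest, pd.DataFrame):
        df, base = manifest, ""
    else:
        df = pd.read_csv(manifest, dtype=str)
        base = os.path.dirname(os.fspath(manifest))
    for col in ("path", "label", "lab"):
        if col not in df.columns:
            raise ValueError(f"manifest is missing the {col!r} column")
    if df["path"].duplicated().any():
        dup = df["path"][df["path"].duplicated()].iloc[0]
        raise ValueError(f"duplicate manifest path: {dup}")
    if df["label"].isna().any():
        raise ValueError("manifest has missing labels")
    spectra = []
    for row in df.itertuples(index=False):
        full = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        s = read_spectrum(full)
        s = resample(s, length)
        spectra.append(s.with_(label=row.label, lab=row.lab))
    return SpectrumBatch(spectra)
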