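"""Quartic-polynomial model of the wavenumber axis.

A spectrometer's calibration maps detector pixel index to Raman shift;
a fourth-degree polynomial in the sample index,

    P4[i; beta] = b4*i^4 + b3*i^3 + b2*i^2 + b1*i + b0  ~  nu[i],

captures that map compactly.  The five coefficients are the
frequency-channel representation the autoencoder consumes and emits,
and calibration drift is emulated by perturbing each coefficient by a
small random fraction of itself.

Fitting is done internally on the rescaled index u = i/(N-1) in [0, 1]
(raw index powers up to 2048^4 make the normal equations hopeless) and
converted back to index-basis coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P

__all__ = ["PolyParams", "fit_quartic", "eval_quartic", "distort_axis", "scaled_coeffs"]

DEGREE = 4


@dataclass
class PolyParams:
    """Index-basis quartic coefficients (beta0..beta4), units cm^-1/index^n."""

    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.beta.shape != (DEGREE + 1,):
            raise ValueError("PolyParams needs exactly 5 coefficients")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("coefficients must be finite")


def fit_quartic(wavenumbers: np.ndarray) -> PolyParams:
    """Least-squares quartic over the integer sample index 0..N-1."""
    w = np.asarray(wavenumbers, dtype=np.float64)
    n = len(w)
    if n < DEGREE + 1:
        raise ValueError("need at least 5 samples to fit a quartic")
    u = np.arange(n) / (n - 1)
    c = P.polyfit(u, w, DEGREE)
    beta = c / (n - 1.0) ** np.arange(DEGREE + 1)
    return PolyParams(beta)


def eval_quartic(params: PolyParams, length: int) -> np.ndarray:
    """Evaluate v[i] = P4[i; beta] for i = 0..length-1."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return P.polyval(np.arange(length, dtype=np.float64), params.beta)


def scaled_coeffs(wavenumbers: np.ndarray) -> np.ndarray:
    """Quartic coefficients over u = i/(N-1); all of order the axis span.

    This is the well-conditioned representation fed to the network's
    frequency channel (index-basis betas differ by ~10 orders of
    magnitude between b0 and b4).
    """
    w = np.asarray(wavenumbers, dtype=np.float64)
    n = len(w)
    if n < DEGREE + 1:
        raise ValueError("need at least 5 samples to fit a quartic")
    u = np.arange(n) / (n - 1)
    return P.polyfit(u, w, DEGREE)


def eval_scaled(coeffs: np.ndarray, length: int) -> np.ndarray:
    """Evaluate scaled-basis coefficients on u = i/(length-1)."""
    u = np.arange(length) / (length - 1)
    return P.polyval(u, np.asarray(coeffs, dtype=np.float64))


def distort_axis(
    wavenumbers: np.ndarray, fraction: float = 0.02, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Emulate calibration drift: nu_N[i] = nu[i] + P4[i; beta_hat].

    The axis is fitted with a quartic; each perturbation coefficient
    beta_hat_n is drawn uniformly from +-`fraction` * |beta_n| (drift is
    bidirectional, as real calibration error is).  If the perturbed axis
    is not strictly increasing the draw is repeated, up to 10 times.
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    w = np.asarray(wavenumbers, dtype=np.float64)
    if fraction == 0:
        return w.copy()
    if rng is None:
        rng = np.random.default_rng()
    beta = fit_quartic(w).beta
    bound = fraction * np.abs(beta)
    idx = np.arange(len(w), dtype=np.float64)
    for _ in range(10):
        beta_hat = rng.uniform(-bound, bound)
        out = w + P.polyval(idx, beta_hat)
        if np.all(np.diff(out) > 0):
            return out
    raise RuntimeError("could not produce a monotone distorted axis in 10 draws")
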