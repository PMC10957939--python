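"""Evaluation: classification metrics, residual Gaussianity, latent
projection, and robustness to acquisition degradation.

Sensitivity is the micro true-positive rate (trace of the confusion
matrix over its total — the overall correct-classification rate);
selectivity is the macro-averaged one-vs-rest true-negative rate.
Residual Gaussianity quantifies denoising: if the autoencoder removed
only noise, the residual (original minus reconstruction) should be
Gaussian, so its histogram divergence from a standard normal should be
much smaller than that of the original intensities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import confusion_matrix as _sk_confusion

from .augment import AugmentConfig, add_intensity_noise, clip_range
from .freqpoly import distort_axis
from .model import Autoencoder, Classifier, batch_coeffs, encode, predict
from .spectra_io import SpectrumBatch, resample

__all__ = [
    "confusion_matrix",
    "sensitivity_selectivity",
    "residual_gaussianity",
    "project_latent",
    "robustness_sweep",
    "reconstruct",
]

HIST_BINS = 64
HIST_RANGE = 5.0  # +- standard deviations


def confusion_matrix(true_labels, predicted_labels, class_order) -> np.ndarray:
    """Rows true, columns predicted, ordered by `class_order`."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    known = set(class_order)
    for l in list(true_labels) + list(predicted_labels):
        if l not in known:
            raise ValueError(f"unknown label {l!r}")
    return _sk_confusion(true_labels, predicted_labels, labels=list(class_order))


def sensitivity_selectivity(confusion: np.ndarray) -> tuple[float, float]:
    """(sensitivity %, selectivity %), each rounded to one decimal.

    sensitivity = 100 * trace / total (micro TPR); selectivity = macro
    average over classes of TN / (TN + FP) from one-vs-rest reductions.
    """
    cm = np.asarray(confusion, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    sensitivity = 100.0 * np.trace(cm) / total
    tnrs = []
    for k in range(cm.shape[0]):
        fp = cm[:, k].sum() - cm[k, k]
        tn = total - cm[k, :].sum() - cm[:, k].sum() + cm[k, k]
        denom = tn + fp
        if denom > 0:
            tnrs.append(tn / denom)
    selectivity = 100.0 * float(np.mean(tnrs))
    return round(float(sensitivity), 1), round(selectivity, 1)


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / (s if s > 0 else 1.0)


def _normalized_divergence(samples: np.ndarray) -> float:
    """Discrete KL of the standardized empirical distribution against a
    standard Gaussian on 64 equal bins over +-5 sigma, divided by ln(64)."""
    from scipy.stats import norm

    edges = np.linspace(-HIST_RANGE, HIST_RANGE, HIST_BINS + 1)
    z = np.clip(_standardize(samples), -HIST_RANGE + 1e-9, HIST_RANGE - 1e-9)
    p, _ = np.histogram(z, bins=edges)
    p = p / p.sum()
    q = np.diff(norm.cdf(edges))
    q = q / q.sum()
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] / q[nz])))
    return kl / np.log(HIST_BINS)


def residual_gaussianity(originals: SpectrumBatch, reconstructions: SpectrumBatch):
    """(div_residual, div_original, ratio) of pooled standardized samples.

    ratio = div_original / div_residual; values well above 1 mean the
    residual is much closer to Gaussian than the spectra themselves,
    i.e. the model removed mostly noise.
    """
    if len(originals) != len(reconstructions) or originals.length != reconstructions.length:
        raise ValueError("originals and reconstructions must pair up with equal lengths")
    orig = originals.intensity_matrix().ravel()
    resid = orig - reconstructions.intensity_matrix().ravel()
    if orig.size < 1000:
        raise ValueError("need at least 1000 pooled samples for a stable histogram")
    div_orig = _normalized_divergence(orig)
    div_resid = _normalized_divergence(resid)
    if np.allclose(resid, orig):
        return div_resid, div_orig, 1.0
    return div_resid, div_orig, div_orig / max(div_resid, 1e-12)


def project_latent(latent_means: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding of latent means (n, D) -> (n, 2), seeded."""
    X = np.asarray(latent_means, dtype=np.float64)
    if len(X) <= 3 * perplexity:
        raise ValueError(f"need n > 3 * perplexity = {3 * perplexity:.0f}, got n = {len(X)}")
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return ts.fit_transform(X)


def reconstruct(model: Autoencoder, batch: SpectrumBatch) -> SpectrumBatch:
    """Inference-mode reconstructions of a batch (axis may be non-monotone,
    so results are returned on the inputs' axes with reconstructed intensities
    paired into Spectrum objects for pooling)."""
    I = batch.intensity_matrix()
    coeffs = batch_coeffs(batch)
    _mu, _lv, _z, _axis, intens = model.forward(I, coeffs, training=False)
    out = [s.with_(intensities=np.nan_to_num(intens.data[i])) for i, s in enumerate(batch)]
    return SpectrumBatch(out)


def _degrade(batch: SpectrumBatch, config: AugmentConfig, rng, clip=True, noise=False, distort=False):
    length = batch.length
    out = []
    for s in batch:
        t = s
        if clip:
            t = resample(clip_range(t, config.clip_start_max, config.clip_stop_min, rng), length)
        if distort:
            t = t.with_(wavenumbers=distort_axis(t.wavenumbers, config.distort_fraction, rng))
        if noise:
            t = add_intensity_noise(t, config.noise_level_db, rng)
        out.append(t)
    return SpectrumBatch(out)


def robustness_sweep(
    encoder: Autoencoder,
    classifier: Classifier,
    test_data: SpectrumBatch,
    augment_config: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
    class_order: list | None = None,
) -> pd.DataFrame:
    """Sensitivity/selectivity on clean, clipped, and fully degraded test data.

    Mirrors the robustness protocol used to probe the classifier: the
    same corruptions applied in training are applied to the held-out
    test set at evaluation time.
    """
    config = augment_config or AugmentConfig()
    rng = np.random.default_rng() if rng is None else rng
    if class_order is None:
        class_order = sorted({s.label for s in test_data})
    conditions = [
        ("clean", dict(clip=False, noise=False, distort=False)),
        ("clipped", dict(clip=True, noise=False, distort=False)),
        ("clipped+noise+distorted", dict(clip=True, noise=True, distort=True)),
    ]
    rows = []
    true = [s.label for s in test_data]
    for name, kw in conditions:
        degraded = _degrade(test_data, config, rng, **kw)
        codes = encode(encoder, degraded)
        probs = predict(classifier, codes)
        pred = [class_order[i] for i in probs.argmax(axis=1)]
        cm = confusion_matrix(true, pred, class_order)
        sens, sel = sensitivity_selectivity(cm)
        rows.append({"condition": name, "sensitivity": sens, "selectivity": sel})
    return pd.DataFrame(rows)
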