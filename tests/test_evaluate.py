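"""Metric operations: confusion matrices, sensitivity/selectivity,
residual Gaussianity and the t-SNE projection plumbing."""

import numpy as np
import pytest

from ramanvae.evaluate import (
    _normalized_divergence,
    confusion_matrix,
    project_latent,
    residual_gaussianity,
    sensitivity_selectivity,
)
from ramanvae.spectra_io import Spectrum, SpectrumBatch


def brute_force_macro_tnr(cm: np.ndarray) -> float:
    """One-vs-rest TN/(TN+FP) averaged over classes, by direct counting."""
    n = cm.shape[0]
    total = cm.sum()
    rates = []
    for k in range(n):
        tp = cm[k, k]
        fp = cm[:, k].sum() - tp
        fn = cm[k, :].sum() - tp
        tn = total - tp - fp - fn
        rates.append(tn / (tn + fp))
    return 100.0 * float(np.mean(rates))


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = ["a"] * 3 + ["b"] * 2
        cm = confusion_matrix(y, y, ["a", "b"])
        np.testing.assert_array_equal(cm, [[3, 0], [0, 2]])

    def test_degenerate_predictor_single_column(self):
        y = ["a", "b", "c", "b"]
        cm = confusion_matrix(y, ["a"] * 4, ["a", "b", "c"])
        assert cm[:, 1:].sum() == 0
        assert cm[:, 0].sum() == 4

    def test_total_conservation(self):
        rng = np.random.default_rng(0)
        classes = ["a", "b", "c"]
        y = rng.choice(classes, 50)
        p = rng.choice(classes, 50)
        assert confusion_matrix(y, p, classes).sum() == 50

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion_matrix(["a"], ["z"], ["a", "b"])


class TestSensitivitySelectivity:
    def test_709_of_769_gives_92_2(self):
        """The micro TPR of a 13-class matrix with 709 correct of 769."""
        cm = np.zeros((13, 13), dtype=int)
        np.fill_diagonal(cm, [55] * 12 + [49])  # 709 correct
        cm[0, 1] = 25
        cm[5, 2] = 20
        cm[12, 7] = 15  # 60 errors
        assert cm.trace() == 709 and cm.sum() == 769
        sens, _sel = sensitivity_selectivity(cm)
        assert sens == 92.2

    def test_perfect_classifier(self):
        cm = np.diag([5, 8, 11])
        assert sensitivity_selectivity(cm) == (100.0, 100.0)

    def test_two_class_matrix_against_brute_force(self):
        cm = np.array([[8, 2], [3, 7]])
        sens, sel = sensitivity_selectivity(cm)
        assert sens == 75.0
        assert sel == round(brute_force_macro_tnr(cm), 1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_matrices_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cm = rng.integers(0, 30, (5, 5))
        sens, sel = sensitivity_selectivity(cm)
        assert sens == round(100.0 * cm.trace() / cm.sum(), 1)
        assert sel == round(brute_force_macro_tnr(cm), 1)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_selectivity(np.zeros((3, 3)))


class TestResidualGaussianity:
    def test_gaussian_divergence_floor(self):
        """The estimator reads ~0 for genuinely Gaussian samples."""
        x = np.random.default_rng(0).standard_normal(100_000)
        assert _normalized_divergence(x) <= 0.02

    def test_identical_inputs_ratio_one(self):
        rng = np.random.default_rng(1)
        w = np.linspace(300, 2000, 200)
        originals = SpectrumBatch([Spectrum(w, rng.uniform(1, 100, 200)) for _ in range(10)])
        zeros = SpectrumBatch([s.with_(intensities=np.zeros(200)) for s in originals])
        div_r, div_o, ratio = residual_gaussianity(originals, zeros)
        assert ratio == 1.0
        assert div_r == div_o

    def test_peaky_original_gaussian_residual(self):
        """Bimodal originals with Gaussian residuals give ratio > 1."""
        rng = np.random.default_rng(2)
        w = np.linspace(300, 2000, 500)
        origs, recons = [], []
        for _ in range(20):
            clean = np.where(rng.random(500) < 0.5, 10.0, 200.0)  # strongly bimodal
            noise = rng.standard_normal(500) * 5.0
            origs.append(Spectrum(w, clean + noise))
            recons.append(Spectrum(w, clean))
        div_r, div_o, ratio = residual_gaussianity(SpectrumBatch(origs), SpectrumBatch(recons))
        assert ratio > 1

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        w = np.linspace(300, 2000, 300)
        origs = [Spectrum(w, rng.gamma(2.0, 50.0, 300)) for _ in range(5)]
        recons = [Spectrum(w, s.intensities * 0.9 + rng.standard_normal(300)) for s in origs]
        r1 = residual_gaussianity(SpectrumBatch(origs), SpectrumBatch(recons))
        scaled_o = [s.with_(intensities=3.0 * s.intensities + 7.0) for s in origs]
        scaled_r = [s.with_(intensities=3.0 * s.intensities + 7.0) for s in recons]
        r2 = residual_gaussianity(SpectrumBatch(scaled_o), SpectrumBatch(scaled_r))
        assert r1[2] == pytest.approx(r2[2], rel=1e-9)

    def test_too_few_samples_rejected(self):
        w = np.linspace(300, 2000, 50)
        b = SpectrumBatch([Spectrum(w, np.ones(50))])
        with pytest.raises(ValueError, match="1000"):
            residual_gaussianity(b, b)


class TestProjectLatent:
    def test_shape_and_reproducibility(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((120, 16))
        a = project_latent(X, perplexity=20, seed=5)
        b = project_latent(X, perplexity=20, seed=5)
        assert a.shape == (120, 2)
        np.testing.assert_array_equal(a, b)

    def test_separated_classes_stay_separated(self):
        """Two well-separated clusters keep a high 2-D silhouette."""
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(1)
        X = np.vstack([rng.standard_normal((60, 16)), rng.standard_normal((60, 16)) + 12.0])
        labels = np.array([0] * 60 + [1] * 60)
        xy = project_latent(X, perplexity=20, seed=2)
        assert silhouette_score(xy, labels) > 0.5

    def test_perplexity_too_large(self):
        with pytest.raises(ValueError, match="perplexity"):
            project_latent(np.zeros((10, 4)), perplexity=30)
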