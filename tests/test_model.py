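"""Architecture contracts: shapes, determinism, latent code semantics,
decoded-axis structure and checkpoint round-trips."""

import numpy as np
import pytest

import ramanvae as rv
from ramanvae.freqpoly import fit_quartic
from ramanvae.model import LatentCode, save_checkpoint, load_checkpoint
from ramanvae.spectra_io import SpectrumBatch, resample

from conftest import reduced_config


@pytest.fixture(scope="module")
def small_batch():
    rng = np.random.default_rng(0)
    specs = rv.make_dataset(2, rng=rng)  # 12 spectra
    return SpectrumBatch([resample(s, 256) for s in specs])


@pytest.fixture(scope="module")
def model():
    return rv.build_autoencoder(reduced_config(), np.random.default_rng(1))


class TestAutoencoder:
    def test_default_latent_is_100_dimensional(self):
        """The full-scale configuration emits 100-dim mu and sigma^2."""
        m = rv.build_autoencoder(rv.ModelConfig(), np.random.default_rng(0))
        rng = np.random.default_rng(2)
        spec = resample(rv.make_spectrum(rv.default_classes()[0], rv.default_labs()[1], rng), 1024)
        codes = rv.encode(m, SpectrumBatch([spec]))
        assert codes[0].mu.shape == (100,) and codes[0].sigma2.shape == (100,)

    def test_encode_count_and_determinism(self, model, small_batch):
        codes = rv.encode(model, small_batch)
        assert len(codes) == len(small_batch)
        dup = SpectrumBatch([small_batch[0], small_batch[0]])
        c = rv.encode(model, dup)
        np.testing.assert_array_equal(c[0].mu, c[1].mu)
        np.testing.assert_array_equal(c[0].sigma2, c[1].sigma2)

    def test_sigma2_strictly_positive(self, model, small_batch):
        for code in rv.encode(model, small_batch):
            assert np.all(code.sigma2 > 0)

    def test_same_seed_identical_parameters(self):
        a = rv.build_autoencoder(reduced_config(), np.random.default_rng(5))
        b = rv.build_autoencoder(reduced_config(), np.random.default_rng(5))
        for (na, pa), (nb, pb) in zip(a.params_named(), b.params_named()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_stride_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            rv.ModelConfig(input_length=100, conv_channels=(8, 16, 32), conv_kernels=(7, 5, 5))

    def test_freq_block_must_fit_latent(self):
        with pytest.raises(ValueError):
            rv.ModelConfig(latent_dim=8, freq_block_dims=8)


class TestDecode:
    def test_output_lengths_and_determinism(self, model):
        z = np.random.default_rng(3).standard_normal(16)
        r1 = rv.decode(model, z)
        r2 = rv.decode(model, z)
        assert len(r1.wavenumbers) == len(r1.intensities) == 256
        np.testing.assert_array_equal(r1.intensities, r2.intensities)

    def test_decoded_axis_is_exactly_quartic(self, model):
        """Refitting the decoded axis leaves a numerically zero residual."""
        z = np.random.default_rng(4).standard_normal(16)
        r = rv.decode(model, z)
        axis = r.wavenumbers
        span = max(axis.max() - axis.min(), 1e-9)
        from ramanvae.freqpoly import eval_quartic

        refit = eval_quartic(fit_quartic(axis), len(axis))
        assert np.sqrt(np.mean((refit - axis) ** 2)) <= 1e-4 * span

    def test_validity_flag_reports_monotonicity(self, model):
        z = np.random.default_rng(5).standard_normal(16)
        r = rv.decode(model, z)
        assert r.axis_valid == bool(np.all(np.diff(r.wavenumbers) > 0))

    def test_wrong_latent_length(self, model):
        with pytest.raises(ValueError):
            rv.decode(model, np.zeros(7))


class TestReparameterize:
    def test_inference_returns_mu(self):
        code = LatentCode(np.arange(5.0), np.ones(5))
        np.testing.assert_array_equal(rv.reparameterize(code, np.random.default_rng(0), training=False), code.mu)

    def test_degenerate_variance(self):
        code = LatentCode(np.arange(5.0), np.full(5, 1e-12))
        z = rv.reparameterize(code, np.random.default_rng(1), training=True)
        np.testing.assert_allclose(z, code.mu, atol=1e-5)

    def test_sample_mean_clt(self):
        mu, s2 = np.array([1.0, -2.0]), np.array([0.5, 2.0])
        code = LatentCode(mu, s2)
        rng = np.random.default_rng(2)
        draws = np.stack([rv.reparameterize(code, rng) for _ in range(10_000)])
        se = np.sqrt(s2 / 10_000)
        assert np.all(np.abs(draws.mean(axis=0) - mu) < 3 * se)


class TestClassifier:
    @pytest.fixture
    def clf(self):
        return rv.build_classifier(rv.ClassifierConfig(n_classes=13, latent_dim=16), np.random.default_rng(0))

    def test_softmax_rows(self, clf):
        codes = [LatentCode(np.random.default_rng(i).standard_normal(16), np.ones(16)) for i in range(7)]
        probs = rv.predict(clf, codes)
        assert probs.shape == (7, 13)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_codes_identical_rows(self, clf):
        code = LatentCode(np.ones(16), np.ones(16))
        probs = rv.predict(clf, [code, code])
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_inference_deterministic_despite_dropout(self):
        clf = rv.build_classifier(
            rv.ClassifierConfig(n_classes=3, latent_dim=16, dropout=0.5), np.random.default_rng(1)
        )
        code = LatentCode(np.arange(16.0), np.ones(16))
        a = rv.predict(clf, [code])
        b = rv.predict(clf, [code])
        np.testing.assert_array_equal(a, b)

    def test_latent_dim_mismatch(self, clf):
        with pytest.raises(ValueError):
            rv.predict(clf, [LatentCode(np.zeros(5), np.ones(5))])


class TestCheckpoints:
    def test_autoencoder_round_trip(self, model, small_batch, tmp_path):
        path = tmp_path / "ae.npz"
        save_checkpoint(model, path, seed=123)
        loaded, seed = load_checkpoint(path)
        assert seed == 123
        a = rv.encode(model, small_batch)
        b = rv.encode(loaded, small_batch)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.mu, cb.mu)

    def test_classifier_round_trip(self, tmp_path):
        clf = rv.build_classifier(rv.ClassifierConfig(n_classes=3, latent_dim=16), np.random.default_rng(2))
        clf.fit_input_scaler(np.random.default_rng(3).standard_normal((20, 16)) * 5 + 1)
        path = tmp_path / "clf.npz"
        save_checkpoint(clf, path)
        loaded, _ = load_checkpoint(path)
        codes = [LatentCode(np.random.default_rng(4).standard_normal(16), np.ones(16))]
        np.testing.assert_array_equal(rv.predict(clf, codes), rv.predict(loaded, codes))
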