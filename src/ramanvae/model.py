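"""Dual-channel variational autoencoder and latent-space classifier.

The encoder consumes a spectrum on two channels.  The intensity vector
passes through a stack of strided 1-D convolution blocks with residual
(projection) skip connections; the wavenumber vector is reduced to the
five coefficients of a fitted quartic, pre-processed by a small feed
forward block, and concatenated with the convolutional features before
the main feed-forward block emits the latent means and log-variances.
The decoder splits the latent vector the same way: the last
``freq_block_dims`` dimensions pass through two feed-forward blocks
into quartic coefficients which are evaluated into the reconstructed
axis (so the decoded axis is exactly quartic by construction), while
the full latent vector drives a feed-forward block and an up-sampling
convolution stack that reconstructs the intensity vector.

The classifier head only observes the latent space: a stack of dense
blocks (width 128 by default) with batch normalization, dropout and
additive skips, closed by a softmax layer over the particle classes.

Everything runs on the package's own numpy autodiff tape; inference is
deterministic and all training-time stochasticity flows from explicit
generators.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._autograd import Tensor, concat, conv1d, softmax, upsample_zeros
from .freqpoly import scaled_coeffs
from .spectra_io import SpectrumBatch

__all__ = [
    "ModelConfig",
    "ClassifierConfig",
    "LatentCode",
    "Reconstruction",
    "Autoencoder",
    "Classifier",
    "build_autoencoder",
    "build_classifier",
    "encode",
    "reparameterize",
    "decode",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

#: The frequency channel works in units of 1000 cm^-1 so the network
#: sees O(1) numbers on both sides of the quartic representation.
COEFF_SCALE = 1000.0

#: The intensity channel works in units of 1e4 detector counts for the
#: same reason.  This is a fixed unit constant, not a per-spectrum
#: normalization: relative magnitudes between spectra are preserved
#: exactly, and all losses are computed back on the raw-count scale.
INTENSITY_SCALE = 1e4

LEAKY_SLOPE = 0.01


@dataclass
class ModelConfig:
    input_length: int = 1024
    latent_dim: int = 100
    freq_block_dims: int = 10  # latent dims carrying frequency-range information
    conv_channels: tuple = (8, 16, 32, 64, 64, 128)
    conv_kernels: tuple = (7, 5, 5, 3, 3, 3)
    ff_width: int = 256
    freq_ff_width: int = 32
    dropout: float = 0.0

    def __post_init__(self):
        self.conv_channels = tuple(self.conv_channels)
        self.conv_kernels = tuple(self.conv_kernels)
        if self.freq_block_dims >= self.latent_dim:
            raise ValueError("freq_block_dims must be smaller than latent_dim")
        if len(self.conv_kernels) != len(self.conv_channels):
            raise ValueError("need one kernel size per conv channel count")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        stride_product = 2 ** len(self.conv_channels)
        if self.input_length % stride_product:
            raise ValueError(
                f"input_length {self.input_length} is not divisible by the "
                f"stride product {stride_product}"
            )

    @property
    def reduced_length(self) -> int:
        return self.input_length // 2 ** len(self.conv_channels)


@dataclass
class ClassifierConfig:
    n_classes: int = 13
    blocks: int = 5
    width: int = 128
    dropout: float = 0.1
    latent_dim: int = 100

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class LatentCode:
    """Diagonal-Gaussian latent distribution of one spectrum."""

    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma2 = np.asarray(self.sigma2, dtype=np.float64)
        if self.mu.shape != self.sigma2.shape or self.mu.ndim != 1:
            raise ValueError("mu and sigma2 must be 1-D vectors of equal length")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be strictly positive")


@dataclass
class Reconstruction:
    """Decoder output; the axis is quartic but not guaranteed monotone."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    @property
    def axis_valid(self) -> bool:
        return bool(np.all(np.diff(self.wavenumbers) > 0))


# -- layers ---------------------------------------------------------------


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [("W", self.W), ("b", self.b)]


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator):
        fan_in = c_in * k
        self.W = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad = stride, k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.W, self.b, stride=self.stride, pad=self.pad)

    def params(self):
        return [("W", self.W), ("b", self.b)]


class _BatchNorm:
    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n), requires_grad=True)
        self.beta = Tensor(np.zeros(n), requires_grad=True)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            m = x.mean(axis=0)
            v = ((x - m) ** 2).mean(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * m.data
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * v.data
            xn = (x - m) / (v + self.eps).sqrt()
        else:
            xn = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xn * self.gamma + self.beta

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def stats(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]


def _dropout(x: Tensor, p: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    if not training or p <= 0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask


# -- autoencoder ----------------------------------------------------------


class Autoencoder:
    """Parameter container + differentiable forward passes."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        c = config
        # encoder: intensity branch (residual strided conv blocks)
        self.enc_convs, self.enc_skips = [], []
        ch = 1
        for c_out, k in zip(c.conv_channels, c.conv_kernels):
            self.enc_convs.append(_Conv(ch, c_out, k, 2, rng))
            self.enc_skips.append(_Conv(ch, c_out, 1, 2, rng))
            ch = c_out
        feat = c.conv_channels[-1] * c.reduced_length
        # encoder: frequency branch (quartic coefficients -> small FF block)
        self.enc_freq = [_Dense(5, c.freq_ff_width, rng), _Dense(c.freq_ff_width, c.freq_ff_width, rng)]
        # main feed-forward block and the two latent heads
        self.enc_ff = [_Dense(feat + c.freq_ff_width, c.ff_width, rng), _Dense(c.ff_width, c.ff_width, rng)]
        self.head_mu = _Dense(c.ff_width, c.latent_dim, rng)
        self.head_logvar = _Dense(c.ff_width, c.latent_dim, rng)
        # start the latent code near the prior with a small sampling variance:
        # a full-scale init would put the KL term far above the reconstruction
        # terms at step 0, and sigma ~ 1 latent noise masks the reconstruction
        # signal before the encoder has learned anything
        self.head_mu.W.data *= 0.01
        self.head_logvar.W.data *= 0.01
        self.head_logvar.b.data[:] = -4.0
        # decoder: frequency path (last freq_block_dims dims -> quartic coeffs)
        self.dec_freq = [_Dense(c.freq_block_dims, c.freq_ff_width, rng), _Dense(c.freq_ff_width, 5, rng)]
        # decoder: intensity path (full latent -> FF -> upsampling convs)
        self.dec_ff = [_Dense(c.latent_dim, c.ff_width, rng), _Dense(c.ff_width, feat, rng)]
        self.dec_convs, self.dec_skips = [], []
        rev = list(c.conv_channels[::-1])
        rev_k = list(c.conv_kernels[::-1])
        for i in range(len(rev)):
            c_in = rev[i]
            c_out = rev[i + 1] if i + 1 < len(rev) else rev[-1]
            self.dec_convs.append(_Conv(c_in, c_out, rev_k[i], 1, rng))
            self.dec_skips.append(_Conv(c_in, c_out, 1, 1, rng))
        self.dec_out = _Conv(rev[-1], 1, 5, 1, rng)
        # constant scaled-index Vandermonde: coeffs (B,5) @ V -> axis (B,L)
        u = np.arange(c.input_length) / (c.input_length - 1)
        self._V = np.stack([u**n for n in range(5)]) * COEFF_SCALE  # (5, L)

    # parameters ----------------------------------------------------------

    def _layer_map(self):
        m = {}
        for i, (cv, sk) in enumerate(zip(self.enc_convs, self.enc_skips)):
            m[f"enc_conv{i}"], m[f"enc_skip{i}"] = cv, sk
        for i, d in enumerate(self.enc_freq):
            m[f"enc_freq{i}"] = d
        for i, d in enumerate(self.enc_ff):
            m[f"enc_ff{i}"] = d
        m["head_mu"], m["head_logvar"] = self.head_mu, self.head_logvar
        for i, d in enumerate(self.dec_freq):
            m[f"dec_freq{i}"] = d
        for i, d in enumerate(self.dec_ff):
            m[f"dec_ff{i}"] = d
        for i, (cv, sk) in enumerate(zip(self.dec_convs, self.dec_skips)):
            m[f"dec_conv{i}"], m[f"dec_skip{i}"] = cv, sk
        m["dec_out"] = self.dec_out
        return m

    def params_named(self):
        out = []
        for lname, layer in self._layer_map().items():
            for pname, p in layer.params():
                out.append((f"{lname}.{pname}", p))
        return out

    def params(self):
        return [p for _, p in self.params_named()]

    # forward passes ------------------------------------------------------

    def encode_t(self, intensities: np.ndarray, coeffs: np.ndarray):
        """(B, L) intensities + (B, 5) scaled quartic coefficients -> (mu, logvar)."""
        B, L = intensities.shape
        if L != self.config.input_length:
            raise ValueError(f"expected length {self.config.input_length}, got {L}")
        x = Tensor(intensities.reshape(B, 1, L) / INTENSITY_SCALE)
        for cv, sk in zip(self.enc_convs, self.enc_skips):
            x = (cv(x) + sk(x)).leaky_relu(LEAKY_SLOPE)
        h = x.reshape(B, -1)
        f = Tensor(coeffs / COEFF_SCALE)
        for d in self.enc_freq:
            f = d(f).leaky_relu(LEAKY_SLOPE)
        h = concat([h, f], axis=1)
        for d in self.enc_ff:
            h = d(h).leaky_relu(LEAKY_SLOPE)
        mu = self.head_mu(h)
        logvar = self.head_logvar(h).clip(-15.0, 10.0)
        return mu, logvar

    def decode_t(self, z: Tensor):
        """Latent (B, D) -> (axis (B, L), intensity (B, L)) tensors."""
        c = self.config
        zf = z[:, c.latent_dim - c.freq_block_dims :]
        for i, d in enumerate(self.dec_freq):
            zf = d(zf)
            if i < len(self.dec_freq) - 1:
                zf = zf.leaky_relu(LEAKY_SLOPE)
        axis = zf @ self._V  # exactly quartic in the sample index
        h = z
        for d in self.dec_ff:
            h = d(h).leaky_relu(LEAKY_SLOPE)
        B = z.shape[0]
        x = h.reshape(B, c.conv_channels[-1], c.reduced_length)
        for cv, sk in zip(self.dec_convs, self.dec_skips):
            x = upsample_zeros(x, 2)
            x = (cv(x) + sk(x)).leaky_relu(LEAKY_SLOPE)
        x = self.dec_out(x) * INTENSITY_SCALE  # linear output, back to raw counts
        return axis, x.reshape(B, c.input_length)

    def forward(self, intensities, coeffs, rng=None, training=False):
        """Full pass; returns (mu, logvar, z, axis_recon, intensity_recon)."""
        mu, logvar = self.encode_t(intensities, coeffs)
        if training and rng is not None:
            eps = rng.standard_normal(mu.shape)
            z = mu + (logvar * 0.5).exp() * eps
        else:
            z = mu
        axis, intens = self.decode_t(z)
        return mu, logvar, z, axis, intens

    # state ---------------------------------------------------------------

    def state_arrays(self):
        return {name: p.data for name, p in self.params_named()}

    def load_state(self, arrays):
        for name, p in self.params_named():
            p.data = np.array(arrays[name], dtype=np.float64)


# -- classifier -----------------------------------------------------------


class Classifier:
    def __init__(self, config: ClassifierConfig, rng: np.random.Generator):
        self.config = config
        # input standardization fitted on the training latents (latent means
        # are unnormalized; raw scales destabilize the dense stack)
        self.input_mean = np.zeros(config.latent_dim)
        self.input_std = np.ones(config.latent_dim)
        self.dense_in = _Dense(config.latent_dim, config.width, rng)
        self.blocks = []
        for _ in range(config.blocks):
            self.blocks.append((_Dense(config.width, config.width, rng), _BatchNorm(config.width)))
        self.dense_out = _Dense(config.width, config.n_classes, rng)

    def params_named(self):
        out = [("dense_in." + n, p) for n, p in self.dense_in.params()]
        for i, (d, bn) in enumerate(self.blocks):
            out += [(f"block{i}.dense.{n}", p) for n, p in d.params()]
            out += [(f"block{i}.bn.{n}", p) for n, p in bn.params()]
        out += [("dense_out." + n, p) for n, p in self.dense_out.params()]
        return out

    def params(self):
        return [p for _, p in self.params_named()]

    def fit_input_scaler(self, X: np.ndarray) -> None:
        self.input_mean = X.mean(axis=0)
        self.input_std = np.maximum(X.std(axis=0), 1e-8)

    def forward(self, X, rng=None, training=False) -> Tensor:
        X = (np.asarray(X, dtype=np.float64) - self.input_mean) / self.input_std
        h = self.dense_in(Tensor.as_tensor(X)).leaky_relu(LEAKY_SLOPE)
        for d, bn in self.blocks:
            b = bn(d(h), training).leaky_relu(LEAKY_SLOPE)
            b = _dropout(b, self.config.dropout, rng, training)
            h = h + b  # additive skip
        return self.dense_out(h)

    def state_arrays(self):
        arrays = {name: p.data for name, p in self.params_named()}
        for i, (_, bn) in enumerate(self.blocks):
            for n, a in bn.stats():
                arrays[f"block{i}.bn.{n}"] = a
        arrays["input_mean"] = self.input_mean
        arrays["input_std"] = self.input_std
        return arrays

    def load_state(self, arrays):
        for name, p in self.params_named():
            p.data = np.array(arrays[name], dtype=np.float64)
        for i, (_, bn) in enumerate(self.blocks):
            bn.running_mean = np.array(arrays[f"block{i}.bn.running_mean"])
            bn.running_var = np.array(arrays[f"block{i}.bn.running_var"])
        self.input_mean = np.array(arrays["input_mean"])
        self.input_std = np.array(arrays["input_std"])


# -- public operations ----------------------------------------------------


def build_autoencoder(config: ModelConfig, rng: np.random.Generator) -> Autoencoder:
    return Autoencoder(config, rng)


def build_classifier(config: ClassifierConfig, rng: np.random.Generator) -> Classifier:
    return Classifier(config, rng)


def batch_coeffs(batch: SpectrumBatch) -> np.ndarray:
    """Scaled-basis quartic coefficients of every axis in a batch, (B, 5)."""
    return np.stack([scaled_coeffs(s.wavenumbers) for s in batch])


def encode(model: Autoencoder, batch: SpectrumBatch, chunk: int = 256) -> list[LatentCode]:
    """Deterministic (inference-mode) latent codes, one per spectrum.

    Processes `chunk` spectra at a time: the im2col convolution buffers
    grow with batch size, so bounding the chunk bounds peak memory.
    """
    I = batch.intensity_matrix()
    coeffs = batch_coeffs(batch)
    codes: list[LatentCode] = []
    for start in range(0, len(batch), chunk):
        mu, logvar = model.encode_t(I[start : start + chunk], coeffs[start : start + chunk])
        s2 = np.exp(logvar.data)
        codes.extend(LatentCode(mu.data[i], s2[i]) for i in range(mu.shape[0]))
    return codes


def reparameterize(code: LatentCode, rng: np.random.Generator, training: bool = True) -> np.ndarray:
    """Gaussian re-sampling z = mu + sigma * eps (training); z = mu (inference)."""
    if not training:
        return code.mu.copy()
    return code.mu + np.sqrt(code.sigma2) * rng.standard_normal(code.mu.shape)


def decode(model: Autoencoder, z: np.ndarray) -> Reconstruction:
    """Decode one latent vector; the axis validity flag reports monotonicity."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape != (model.config.latent_dim,):
        raise ValueError(f"latent vector must have length {model.config.latent_dim}")
    axis, intens = model.decode_t(Tensor(z[None, :]))
    return Reconstruction(axis.data[0], intens.data[0])


def predict(classifier: Classifier, codes: list[LatentCode]) -> np.ndarray:
    """Class-probability matrix from latent means (inference mode)."""
    X = np.stack([c.mu for c in codes])
    if X.shape[1] != classifier.config.latent_dim:
        raise ValueError("latent dimensionality does not match the classifier")
    logits = classifier.forward(X, training=False)
    return softmax(logits.data)


# -- checkpoints ----------------------------------------------------------


def save_checkpoint(obj, path, seed: int | None = None) -> None:
    """Single-file .npz checkpoint: parameters + config + seed."""
    kind = "autoencoder" if isinstance(obj, Autoencoder) else "classifier"
    meta = json.dumps({"kind": kind, "config": asdict(obj.config), "seed": seed})
    arrays = {f"arr:{k}": v for k, v in obj.state_arrays().items()}
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_checkpoint(path):
    """Rebuild an Autoencoder or Classifier from a checkpoint file."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        arrays = {k[4:]: data[k] for k in data.files if k.startswith("arr:")}
    rng = np.random.default_rng(0)  # values are overwritten by load_state
    if meta["kind"] == "autoencoder":
        obj = Autoencoder(ModelConfig(**meta["config"]), rng)
    else:
        obj = Classifier(ClassifierConfig(**meta["config"]), rng)
    obj.load_state(arrays)
    return obj, meta.get("seed")
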