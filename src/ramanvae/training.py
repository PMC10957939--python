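"""Two-phase training protocol.

Phase 1 (self-supervised): the autoencoder trains on epoch sets that
are regenerated from the raw training spectra every epoch — one clean
copy, three corrupted copies (clipping, calibration drift, intensity
noise) and one noise-only copy — minimizing the composite
spatial/KL/Fourier loss with Adam.

Phase 2 (supervised): the trained encoder maps the (clean) training
spectra to latent means; a feed-forward classifier head learns the
particle origins from those means with a class-weighted cross-entropy.
The class weight is a sigmoid of the representation fraction p of each
class: rare classes (p -> 0) weigh ~1, dominant classes (p -> 1) weigh
~0.1, softly balancing a dataset in which origins differ in abundance
by an order of magnitude.

The raw 70/30 train/test split is stratified by class so that no
origin is orphaned on either side.  Everything is reproducible from
the integer seeds in the configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autograd import Adam, softmax_cross_entropy
from .augment import AugmentConfig, build_epoch_set
from .losses import LossWeights, default_mask, fourier_loss_t, kl_loss_t, spatial_loss_t, total_loss
from .model import Autoencoder, Classifier, batch_coeffs, encode
from .spectra_io import NULL_LABEL, SpectrumBatch, load_dataset

__all__ = [
    "TrainConfig",
    "ClassWeighting",
    "split_dataset",
    "class_weights",
    "representation_weight",
    "train_phase1",
    "train_phase2",
]

#: Steepness of the class-weight sigmoid: the smallest integer for which
#: the weight is within 0.01 of its limits (1 and 0.1) at p = 0 and p = 1.
SIGMOID_STEEPNESS = 12.0


@dataclass
class TrainConfig:
    epochs_phase1: int = 100
    lr_phase1: float = 1e-4
    epochs_phase2: int = 200
    lr_phase2: float = 1e-3
    batch_size: int = 32
    train_fraction: float = 0.7
    val_fraction: float = 0.1  # carved from phase-2 training data for early stopping
    patience: int = 60
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ClassWeighting:
    weights: dict = field(default_factory=dict)


def representation_weight(p: float) -> float:
    """Sigmoid class weight w(p) = 0.1 + 0.9 * logistic(-k (p - 0.5)), k = 12."""
    return 0.1 + 0.9 / (1.0 + np.exp(SIGMOID_STEEPNESS * (p - 0.5)))


def class_weights(counts: dict) -> ClassWeighting:
    """Per-class loss weights from the class counts of a training set."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total class count must be positive")
    return ClassWeighting({c: float(representation_weight(n / total)) for c, n in counts.items()})


def split_dataset(manifest: pd.DataFrame, fraction: float, rng: np.random.Generator):
    """Stratified, disjoint and exhaustive train/test split of a manifest."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    train_idx, test_idx = [], []
    for label, group in manifest.groupby("label", sort=True):
        n = len(group)
        if n < 2:
            raise ValueError(f"class {label!r} has fewer than 2 members and cannot be stratified")
        order = rng.permutation(n)
        n_tr = int(round(n * fraction))
        n_tr = min(max(n_tr, 1), n - 1)
        idx = group.index.to_numpy()[order]
        train_idx.extend(idx[:n_tr])
        test_idx.extend(idx[n_tr:])
    train = manifest.loc[sorted(train_idx)].reset_index(drop=True)
    test = manifest.loc[sorted(test_idx)].reset_index(drop=True)
    return train, test


def _as_batch(data, length: int) -> SpectrumBatch:
    if isinstance(data, SpectrumBatch):
        if data.length != length:
            raise ValueError(f"batch length {data.length} != model input length {length}")
        return data
    return load_dataset(data, length)


def train_phase1(
    model: Autoencoder,
    train_data,
    augment_config: AugmentConfig | None = None,
    train_config: TrainConfig | None = None,
    loss_weights: LossWeights | None = None,
):
    """Self-supervised autoencoder training; returns (model, log DataFrame).

    `train_data` is a manifest (path or DataFrame) or a SpectrumBatch
    already resampled to the model length.  A fresh corrupted epoch set
    is drawn every epoch from an epoch-derived seed.  The log has one
    row per epoch with every loss component.
    """
    aug = augment_config or AugmentConfig()
    cfg = train_config or TrainConfig()
    w = loss_weights or LossWeights()
    batch = _as_batch(train_data, model.config.input_length)
    mask = default_mask(model.config.input_length)
    # raw-count targets: start the output layers at the training means so the
    # first epochs refine structure instead of crawling up in absolute scale
    from .model import COEFF_SCALE, INTENSITY_SCALE

    model.dec_out.b.data[:] = float(np.mean(batch.intensity_matrix())) / INTENSITY_SCALE
    model.dec_freq[-1].b.data[:] = batch_coeffs(batch).mean(axis=0) / COEFF_SCALE
    opt = Adam(model.params(), lr=cfg.lr_phase1)
    rows = []
    for epoch in range(cfg.epochs_phase1):
        rng_aug = np.random.default_rng([cfg.seed, epoch, 1])
        rng_eps = np.random.default_rng([cfg.seed, epoch, 2])
        es = build_epoch_set(batch, aug, rng_aug)
        sums = np.zeros(5)
        n_batches = 0
        for start in range(0, len(es), cfg.batch_size):
            pairs = es.pairs[start : start + cfg.batch_size]
            I_in = np.stack([p.noisy.intensities for p in pairs])
            coeffs = batch_coeffs(SpectrumBatch([p.noisy for p in pairs]))
            T_I = np.stack([p.target.intensities for p in pairs])
            T_axis = np.stack([p.target.wavenumbers for p in pairs])
            mu, logvar, _z, axis_r, int_r = model.forward(I_in, coeffs, rng=rng_eps, training=True)
            L_I = spatial_loss_t(T_I, int_r)
            L_axis = spatial_loss_t(T_axis, axis_r)
            L_KL = kl_loss_t(mu, logvar)
            L_F = fourier_loss_t(T_I, int_r, mask)
            L_tot = total_loss(L_I, L_axis, L_KL, L_F, w)
            if not np.isfinite(L_tot.data):
                raise RuntimeError(f"phase-1 loss diverged at epoch {epoch}")
            opt.zero_grad()
            L_tot.backward()
            opt.step()
            sums += [L_I.data, L_axis.data, L_KL.data, L_F.data, L_tot.data]
            n_batches += 1
        m = sums / n_batches
        rows.append(
            {"epoch": epoch, "L_I": m[0], "L_axis": m[1], "L_KL": m[2], "L_F": m[3], "L_total": m[4]}
        )
    return model, pd.DataFrame(rows)


def _xent(logits: np.ndarray, onehot: np.ndarray, sw: np.ndarray) -> float:
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-(sw * (onehot * logp).sum(axis=1)).sum() / sw.sum())


def train_phase2(
    classifier: Classifier,
    encoder: Autoencoder,
    train_data,
    train_config: TrainConfig | None = None,
):
    """Supervised classifier training on latent means.

    Spectra carrying the reserved null (noise-only) label are excluded;
    every remaining spectrum must be labelled.  A stratified validation
    share of the training data drives early stopping; the best
    validation state is restored.  Returns (classifier, log DataFrame).
    """
    cfg = train_config or TrainConfig()
    batch = _as_batch(train_data, encoder.config.input_length)
    keep = [s for s in batch if s.label != NULL_LABEL]
    if any(s.label is None for s in keep):
        raise ValueError("phase-2 training requires a label for every non-null spectrum")
    if not keep:
        raise ValueError("no labelled spectra to train on")
    batch = SpectrumBatch(keep)
    codes = encode(encoder, batch)
    X = np.stack([c.mu for c in codes])
    labels = np.array([s.label for s in batch])
    class_order = sorted(set(labels))
    if len(class_order) != classifier.config.n_classes:
        raise ValueError(
            f"classifier expects {classifier.config.n_classes} classes, data has {len(class_order)}"
        )
    y = np.array([class_order.index(l) for l in labels])
    onehot = np.eye(len(class_order))[y]
    rng = np.random.default_rng([cfg.seed, 7])
    # stratified validation carve-out
    val_mask = np.zeros(len(y), dtype=bool)
    for k in range(len(class_order)):
        idx = np.flatnonzero(y == k)
        n_val = int(round(len(idx) * cfg.val_fraction))
        if len(idx) - n_val < 1:
            n_val = 0
        val_mask[rng.permutation(idx)[:n_val]] = True
    tr, va = ~val_mask, val_mask
    classifier.fit_input_scaler(X[tr])
    cw = class_weights({c: int((labels[tr] == c).sum()) for c in class_order})
    sample_w = np.array([cw.weights[l] for l in labels])
    opt = Adam(classifier.params(), lr=cfg.lr_phase2)
    tr_idx = np.flatnonzero(tr)
    best_val, best_state, since_best = np.inf, None, 0
    rows = []
    for epoch in range(cfg.epochs_phase2):
        order = rng.permutation(len(tr_idx))
        ep_loss, nb = 0.0, 0
        for start in range(0, len(tr_idx), cfg.batch_size):
            sel = tr_idx[order[start : start + cfg.batch_size]]
            if len(sel) < 2:
                continue  # batch statistics need at least two samples
            logits = classifier.forward(X[sel], rng=rng, training=True)
            loss = softmax_cross_entropy(logits, onehot[sel], sample_w[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
            nb += 1
        row = {"epoch": epoch, "train_loss": ep_loss / max(nb, 1)}
        if va.any():
            vlogits = classifier.forward(X[va], training=False)
            vloss = _xent(vlogits.data, onehot[va], sample_w[va])
            row["val_loss"] = vloss
            if vloss < best_val - 1e-6:
                best_val, since_best = vloss, 0
                best_state = {k: v.copy() for k, v in classifier.state_arrays().items()}
            else:
                since_best += 1
        rows.append(row)
        if va.any() and since_best >= cfg.patience:
            break
    if best_state is not None:
        classifier.load_state(best_state)
    return classifier, pd.DataFrame(rows)
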