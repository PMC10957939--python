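"""Shared fixtures: small synthetic datasets and a reduced-scale trained
pipeline (built once per session) used by the end-to-end tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ramanvae as rv
from ramanvae.spectra_io import SpectrumBatch, resample

MODEL_LENGTH = 256
LATENT_DIM = 16
PIPELINE_SEED = 0


def reduced_config() -> rv.ModelConfig:
    """Desk-scale model: length 256, latent 16, three conv blocks."""
    return rv.ModelConfig(
        input_length=MODEL_LENGTH,
        latent_dim=LATENT_DIM,
        freq_block_dims=4,
        conv_channels=(8, 16, 32),
        conv_kernels=(7, 5, 5),
        ff_width=64,
        freq_ff_width=16,
    )


def make_split_batches(seed: int, n_per_class: int = 33, length: int = MODEL_LENGTH):
    """Synthetic 3-class / 2-lab dataset, stratified 70/30 split."""
    rng = np.random.default_rng(seed)
    specs = rv.make_dataset(n_per_class, rng=rng)
    batch = SpectrumBatch([resample(s, length) for s in specs])
    df = pd.DataFrame(
        {
            "path": [s.id for s in specs],
            "label": [s.label for s in specs],
            "lab": [s.lab for s in specs],
        }
    )
    tr, te = rv.split_dataset(df, 0.7, np.random.default_rng(seed + 1))
    idx = {p: i for i, p in enumerate(df.path)}
    train = SpectrumBatch([batch[idx[p]] for p in tr.path])
    test = SpectrumBatch([batch[idx[p]] for p in te.path])
    return train, test


@pytest.fixture(scope="session")
def trained_pipeline():
    """Full phase-1 + phase-2 run at reduced scale, shared across tests.

    Returns (encoder, classifier, train batch, test batch, phase-1 log).
    """
    seed = PIPELINE_SEED
    train, test = make_split_batches(seed)
    model = rv.build_autoencoder(reduced_config(), np.random.default_rng(seed + 2))
    model, log1 = rv.train_phase1(
        model,
        train,
        rv.AugmentConfig(),
        rv.TrainConfig(epochs_phase1=15, lr_phase1=1e-3, batch_size=16, seed=seed + 3),
    )
    clf = rv.build_classifier(
        rv.ClassifierConfig(n_classes=3, latent_dim=LATENT_DIM), np.random.default_rng(seed + 4)
    )
    clf, _ = rv.train_phase2(clf, model, train, rv.TrainConfig(seed=seed + 5))
    return model, clf, train, test, log1
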