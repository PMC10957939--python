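# ramanvae

A frequency-adaptive variational autoencoder for Raman spectra of
extracellular vesicles (EVs) and lipoproteins, with a latent-space
classifier.

## The problem

Single-particle Raman spectra of EVs are a promising label-free route
to attributing nanoparticles to their biological origin — but data from
different laboratories come with different wavenumber ranges, very
different signal-to-noise ratios, and calibration drift along the
wavenumber axis. Conventional pipelines force all spectra onto one
common grid by truncation and interpolation, discarding information.
This package implements an architecture that instead treats a spectrum
as *two* channels — the intensity vector `I[n]` and the wavenumber
vector `ν̃[n]` — so the model can adapt to the acquisition range
explicitly rather than assuming it away.

## The model

**Encoder.** The intensity channel passes through strided 1-D
convolution blocks with residual (projection) skip connections. The
wavenumber channel is compressed to the five coefficients of a quartic
fitted over the sample index, `P₄[i; β] = β₄i⁴ + … + β₀ ≈ ν̃[i]`
(the form of a spectrometer's pixel-to-wavenumber calibration), and
pre-processed by a small feed-forward block. Both streams merge in a
main feed-forward block that emits the mean μ and variance σ² of a
100-dimensional diagonal-Gaussian latent code (16 at the reduced test
scale); training samples `z = μ + σ·ε` (the reparameterization trick).

**Decoder.** The last 10 latent dimensions carry the frequency
information: two feed-forward blocks map them back to quartic
coefficients, so the reconstructed axis is exactly quartic in the
sample index. The full latent vector drives a feed-forward block and an
up-sampling convolution stack that reconstructs the intensity vector.

**Loss (phase 1, self-supervised).**

    L_Σ = (1 − α)·(L_RMS,I + γ·L_RMS,ν̃ + β·L_KL) + α·L_Fourier

with α = 0.3, β = 5, γ = 100: RMS reconstruction errors for both
channels, a KL divergence of the latent code against N(0, I), and a
Fourier-domain term comparing masked magnitude and phase spectra. The
Fourier mask attenuates intermediate frequencies so the model must
preserve both smooth slopes and sharp peaks instead of learning an
implicit low-pass filter.

**Training scheme.** Each phase-1 epoch regenerates a corrupted
training set: one clean copy, three copies with random range clipping
(the 800–1500 cm⁻¹ fingerprint region is always kept; up to 79 % of a
full-range spectrum can be removed), quartic calibration-drift
distortion (±2 % of each fitted coefficient), and additive Gaussian
noise at −5 dB of the per-spectrum RMS intensity — plus one copy of
pure-noise spectra emulating an empty optical trap. Phase 2 trains a
small classifier head (five dense blocks of 128 units with batch
normalization, dropout and skips, softmax output) on the latent means
of the training spectra, with a sigmoid class weight that moves from 1
for vanishing classes to 0.1 for dominating ones.

Because the clinical dataset behind the method is not public, the
package ships a synthetic-spectrum generator (`ramanvae.synth`) that
emulates its structure: three biomolecular class profiles
(protein-rich, lipid-rich, carotenoid-rich) built from pseudo-Voigt
bands (e.g. phenylalanine at 1003.6 cm⁻¹) on fluorescence baselines,
observed by two virtual instruments — `labP` (309–2035 cm⁻¹, 8 dB SNR)
and `labT` (300–3674 cm⁻¹, 20 dB SNR).

All networks run on a small numpy reverse-mode autodiff engine included
in the package; no deep-learning framework is required.

## Worked example

Generate a two-lab synthetic dataset, train both phases at reduced
scale, and evaluate on the held-out 30 %:

```python
import numpy as np
import ramanvae as rv

rng = np.random.default_rng(0)
manifest = rv.make_labelled_set(33, rng=rng, out_dir="data")   # 198 spectra
train_m, test_m = rv.split_dataset(manifest, 0.7, np.random.default_rng(1))
train_m.to_csv("data/train.csv", index=False)
test_m.to_csv("data/test.csv", index=False)

cfg = rv.ModelConfig(input_length=256, latent_dim=16, freq_block_dims=4,
                     conv_channels=(8, 16, 32), conv_kernels=(7, 5, 5),
                     ff_width=64, freq_ff_width=16)
model = rv.build_autoencoder(cfg, np.random.default_rng(2))
model, log = rv.train_phase1(model, "data/train.csv", rv.AugmentConfig(),
                             rv.TrainConfig(epochs_phase1=15, lr_phase1=1e-3,
                                            batch_size=16, seed=3))
clf = rv.build_classifier(rv.ClassifierConfig(n_classes=3, latent_dim=16),
                          np.random.default_rng(4))
clf, _ = rv.train_phase2(clf, model, "data/train.csv", rv.TrainConfig(seed=5))

test = rv.load_dataset("data/test.csv", 256)
probs = rv.predict(clf, rv.encode(model, test))
order = sorted({s.label for s in test})
pred = [order[i] for i in probs.argmax(axis=1)]
cm = rv.confusion_matrix([s.label for s in test], pred, order)
sens, sel = rv.sensitivity_selectivity(cm)
div_r, div_o, ratio = rv.residual_gaussianity(test, rv.reconstruct(model, test))
print(f"phase-1 composite loss: {log.L_total.iloc[0]:.0f} -> {log.L_total.iloc[-1]:.0f}")
print(f"test sensitivity {sens}%, selectivity {sel}%")
print(f"residual divergence {div_r:.3f} vs original {div_o:.3f} (ratio {ratio:.1f})")
```

Output:

```
phase-1 composite loss: 33526 -> 10182
test sensitivity 100.0%, selectivity 100.0%
residual divergence 0.011 vs original 0.138 (ratio 12.4)
```

The composite loss falls as the autoencoder learns; the classifier
separates the three synthetic origins perfectly on held-out spectra
from both virtual labs; and the reconstruction residual is an order of
magnitude closer to Gaussian than the spectra themselves — i.e. what
the model removes is mostly noise.

The same pipeline is available from the shell: `ramanvae simulate`,
`ramanvae augment`, `ramanvae train-ae`, `ramanvae train-clf`,
`ramanvae encode`, `ramanvae evaluate`.

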