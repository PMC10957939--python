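# Methods

## Model

The autoencoder treats a Raman spectrum as two coupled channels. The
intensity vector is processed convolutionally (spectra are continuous
along the frequency axis, so weight sharing across the axis is the
natural prior); residual projection skips keep gradients healthy
through the strided stack. The wavenumber axis is not fed pointwise:
it is reduced to the five coefficients of a least-squares quartic over
the sample index, which is the algebraic form of a spectrometer's
pixel-to-wavenumber calibration. This gives the model an explicit,
low-dimensional handle on the acquisition range, and gives the decoder
a reconstruction target that is quartic by construction — the decoded
axis can stretch or shift but cannot wiggle unphysically.

The latent code is a diagonal Gaussian (μ, σ²) regularized toward
N(0, I); sampling uses z = μ + σ·ε during training and z = μ at
inference. The intent of the variational constraint is that separate
biochemical degrees of freedom land in separate latent dimensions.
The last `freq_block_dims` latent dimensions (10 of 100 at full scale)
are wired to the decoder's frequency path, which is what designates
them as the frequency-information block; the encoder side is left
unconstrained.

Numerical conditioning choices that are part of the architecture, not
of the data pipeline:

* Both channels use fixed internal units — wavenumbers in units of
  1000 cm⁻¹ and intensities in units of 10⁴ counts (divide on entry,
  multiply on exit). These are global constants, not per-spectrum
  normalization: relative magnitudes between spectra are preserved
  exactly and every loss is computed on the raw-count scale. Without
  them a raw-count network is so badly scaled that first-order
  optimization crawls.
* The quartic fit itself runs on the rescaled index u = i/(N−1)
  (index powers up to 2048⁴ are numerically hopeless) and converts
  back to index-basis coefficients.
* Latent-head weights are initialized 100× smaller than the He default
  and the log-variance head bias starts at −4, so training begins near
  the prior with small sampling noise. Decoder output biases are set
  to the training means (intensity level and mean axis coefficients)
  at the start of phase 1. All of this only accelerates early
  optimization; none of it changes the model class.
* σ² is produced as exp(log σ²), clamped to [e⁻¹⁵, e¹⁰], guaranteeing
  positivity.
* Nonlinearities are leaky rectifiers (slope 0.01); the intensity
  output layer is linear because detector counts are unbounded.

The exact layer table is configurable; defaults are encoder channels
(8, 16, 32, 64, 64, 128) with kernels (7, 5, 5, 3, 3, 3), all stride
2, a 2×256 main feed-forward block, 2×32 frequency blocks, and a
mirrored decoder using zero-insertion upsampling followed by
convolution (equivalent to transposed convolution). None of the
package's checks depend on these counts.

All networks, including the classifier, run on a ~400-line reverse-mode
autodiff tape (`ramanvae._autograd`) written for this package; its
gradients are verified against central finite differences in the test
suite, and Adam is the optimizer throughout.

## Losses

    L_Σ = (1 − α)(L_RMS,I + γ L_RMS,ν̃ + β L_KL) + α L_Fourier,
    α = 0.3, β = 5, γ = 100.

γ compensates the scale mismatch between intensities (up to ~10⁵
counts) and wavenumbers (~10³ cm⁻¹). The Fourier term compares
one-sided DFT magnitude and phase spectra; the magnitude difference is
normalized by the target's mean spectral power so the two terms are
commensurate, and the phase difference is wrapped to (−π, π] and gated
off for bins whose magnitudes both sit below 10⁻⁸ of the maximum
(phase of an empty bin is noise). The mask is a Gaussian notch over
the one-sided bins, depth 0.5, width 0.2 of the Nyquist frequency,
centered mid-band: unity (within 10⁻³) at DC and Nyquist, 0.5 at
mid-band. Only "attenuate intermediate frequencies" is essential; the
notch shape, depth, and width are design choices exposed in
configuration. The width was set at 0.2·f_nyq because that is the
widest notch whose end-bin weights stay within 10⁻³ of one.

The DFT is applied as a cached matrix product rather than an FFT so
that the loss differentiates through the same tape as everything else;
at the model lengths used (256–1024) this costs nothing measurable.

## Training protocol

Phase 1 regenerates the corrupted set every epoch: 1 clean copy + 3
corrupted copies + 1 noise-only copy, shuffled. A corrupted copy is
produced in acquisition order — clip, distort axis, add noise:

* **Clipping** draws the start uniformly in [range-min, 800 cm⁻¹] and
  the stop in [1500 cm⁻¹, range-max], so the fingerprint region
  (800–1500 cm⁻¹) always survives; on a 300–3674 cm⁻¹ axis up to
  79 % of the span can be removed. Clipped members are re-resampled
  to the model length, and the reconstruction target is the *clean*
  spectrum clipped to the same range — so the model learns to denoise
  and to undo calibration drift, but not to extrapolate the removed
  range.
* **Axis distortion** perturbs each fitted quartic coefficient by a
  uniform draw on ±2 % of its own magnitude (the distribution is a
  design choice; a bidirectional draw matches real calibration error),
  redrawing up to 10 times if monotonicity breaks.
* **Intensity noise** is additive Gaussian with variance
  10^(−5/10)·RMS(I)², per spectrum — the only dimensionally coherent
  reading of a noise variance specified in dB relative to an RMS.
* **Noise-only spectra** keep the template axis, draw white Gaussian
  noise at the template's estimated noise floor (median absolute first
  difference / (0.6745·√2)), carry the reserved null label, and are
  their own reconstruction target — there is no cleaner original for
  the empty-trap condition. They are excluded from phase 2.

Whether the three corrupted copies each receive all three corruption
types or one each is ambiguous in principle; here each corrupted copy
receives all three.

Phase-1 defaults are 100 epochs at learning rate 10⁻⁴, batch 32.
Phase 2 encodes the (clean) training spectra to latent means,
standardizes them with training-set statistics stored in the
classifier, and minimizes class-weighted cross-entropy (Adam, 10⁻³,
up to 200 epochs, early stopping with patience 60 on a stratified 10 %
validation carve-out, best state restored). The class weight is
w(p) = 0.1 + 0.9·logistic(−k(p − 0.5)) of the representation fraction
p, with k = 12 — the smallest integer steepness for which w(0) is
within 0.01 of 1 and w(1) within 0.01 of 0.1, the two required limits.
The 70/30 split is stratified by class; with 13 classes and classes of
~20 members an unstratified split can orphan a class entirely.

## Synthetic data

The generator stands in for a two-laboratory clinical dataset that is
not publicly available. It emulates the *statistical* structure that
matters to the method, per (class, lab) pair: class-specific
pseudo-Voigt band sets (Lorentzian fraction 0.7) with log-plausible
positions — protein-rich {1003.6 sharp, 1655, 2930}, lipid-rich
{1302, 1440, 2850, 2880}, carotenoid-rich {1157, 1520 + weak protein
bands}; amplitudes jittered with CV 0.15; peak intensities approaching
10⁵ counts over baselines of ~10⁴ (the magnitude regime the γ = 100
balance is designed for); a nonnegative random cubic + broad Gaussian
hump fluorescence baseline; and two instruments, `labP`
(309–2035 cm⁻¹, 1340 points, 8 dB) and `labT` (300–3674 cm⁻¹, 2048
points, 20 dB), so one lab is narrow and noisy and the other wide and
clean. SNR is defined as band-signal power over noise power, in dB.
Axis warp defaults to zero: calibration drift belongs to the
augmentation stage, keeping responsibilities separate.

What the generator does **not** emulate: real EV/lipoprotein chemistry
(13 origins with overlapping band sets and biological covariance),
cosmic-ray spikes, detector etaloning, multiplicative/Poisson noise,
or between-donor variability. Passing tests on this data therefore
show that the architecture, losses, augmentation and training loop do
what they claim under controlled conditions — not that the method
reaches any particular accuracy on clinical spectra.

## Reduced-scale study

The end-to-end checks run a deliberately small configuration chosen to
finish in minutes on one CPU: 3 classes × 2 labs × 33 spectra = 198
spectra, model length 256, latent 16 with a 4-dimensional frequency
block, conv channels (8, 16, 32), 15 phase-1 epochs at learning rate
10⁻³ with batch 16. The raised learning rate and smaller batch are the
scaled-down counterparts of the full protocol: ~10³ optimizer steps
instead of ~3×10⁴, where the full-scale rate would sit far from
convergence (the full-scale values remain the defaults). Under these
conditions the pipeline reaches 100 % held-out accuracy on all probe
seeds and a residual-divergence ratio around 10.

## Evaluation

* **Sensitivity** is the micro true-positive rate, 100·trace/total of
  the confusion matrix — the overall correct-classification rate.
  **Selectivity** is the macro-averaged one-vs-rest true-negative
  rate TN/(TN+FP). Both are reported to one decimal.
* **Residual Gaussianity**: pooled residual (original − reconstruction)
  and pooled original samples are each standardized; each empirical
  distribution is histogrammed on 64 equal bins over ±5σ and compared
  to a standard Gaussian discretized on the same bins by discrete KL
  divergence, normalized by ln 64 to make the statistic scale-free.
  The reported ratio div_original/div_residual exceeds 1 when the
  removed component is closer to noise than the spectra are to
  Gaussian; the statistic is invariant to affine intensity rescaling.
  With fewer than 1000 pooled samples the histogram is unstable and
  the operation refuses to run.
* **Latent projection** is scikit-learn t-SNE (seeded, PCA
  initialization, default perplexity 30) on latent means —
  visualization plumbing, not part of the model.
* **Robustness sweep** re-evaluates classification on clean, clipped,
  and clipped+noise+distorted versions of the test set, mirroring the
  training corruptions at evaluation time.

## Known limitations

* The synthetic classes are far more separable than real biological
  origins; absolute accuracies here say nothing about clinical data.
* The decoder reconstructs the clipped range only; it does not
  extrapolate spectral regions that were never acquired.
* The decoded axis is quartic but not guaranteed monotone; decoding
  exposes a validity flag rather than silently reordering.
* Early-stopping selection in phase 2 uses a very small validation set
  at reduced scale; its noise is mitigated by a long patience and
  best-state restoration, not eliminated.
* The autodiff engine is single-threaded float64 numpy: exactly
  reproducible, but not suited to training at many times the scale
  used here.
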