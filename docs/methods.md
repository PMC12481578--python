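# Methods

`sersquant` implements a three-stage computational framework for
quantifying a target biomarker from surface-enhanced Raman spectroscopy
(SERS) spectra measured in a complex biological medium: spectral
preprocessing with a denoising autoencoder, neural quantification models
with SERS-specific layers, and context-level model explanation (CRIME).
The model task is serotonin quantification (0–9 μM) in lyophilized urine,
with epinephrine and dopamine as co-spiked confounders.

## Spectral model and preprocessing

A spectrum is intensity versus Raman shift on a uniform 937-point grid
(spacing 1700/841 cm⁻¹ ≈ 2.02 cm⁻¹). The grid is placed so that exactly
842 points fall in the 300–2000 cm⁻¹ analysis window, with a point at
exactly 300.0 cm⁻¹; 49 points sit below 300 and 46 above 2000 cm⁻¹, a
typical 785 nm acquisition window. Crop bounds are applied with a 1e-9
relative tolerance so grid points that land on a bound up to float
rounding are kept.

Baseline correction uses asymmetric least squares (ALS): the baseline z
minimizes Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)², iteratively reweighted with wᵢ = p
where y > z and 1−p elsewhere, starting from unit weights. Defaults are
λ = 1000, p = 0.1, 10 iterations. The pentadiagonal system is solved
sparsely; the test suite checks it against an independent dense solve to
1e-8. Normalization is per-spectrum min–max to [0, 1]; a constant
spectrum maps to zeros with a warning rather than an error so degenerate
inputs cannot crash a batch run. The Savitzky–Golay benchmark filter
(window 33 points, 5th-order polynomial, 2nd derivative,
polynomial-extension edges) differentiates per sample index, not per
cm⁻¹.

The fixed processing order is crop → ALS → (optional background overlay)
→ normalize.

## Synthetic study data

No public spectra exist for this design, so the package generates them.
Every stage of the framework is exercised on synthetic mixtures built to
have the statistical structure the method targets:

* **References.** Each analyte is a sum of Lorentzian bands at plausible
  positions (serotonin's indole ring breathing near 759 cm⁻¹; catechol
  bands for dopamine and epinephrine; a shared catechol band at 1480 and a
  shared aromatic band at 1600 cm⁻¹). Band positions are configuration,
  not physics: the pipeline only requires distinguishable, partially
  overlapping references (pairwise cosine < 0.9).
* **Response.** Signal amplitude follows a saturating Langmuir form
  a_max·c/(k_half+c) (defaults a_max = 10, k_half = 10 μM) — the
  calibration-curve behaviour that motivates a logistic output layer. A
  helper provides an effectively linear response for
  parameter-recovery fixtures.
* **Measurement variation.** A per-measurement lognormal scale factor
  (σ = 0.1) multiplies the entire measurement — signal, baseline drift
  and noise alike — so min–max normalization cancels it exactly; this is
  the modelling rationale for normalizing at all. Additive Gaussian noise
  (σ = 0.05 on the unit-reference scale) and a fixed low-order polynomial
  drift complete the instrument model.
* **Urine background.** Urine adds a background template (urea C–N
  stretch at 1003 cm⁻¹, creatinine bands, broad humps overlapping the
  analyte regions; base amplitude 5 on the unit-reference scale). Its
  intensity varies at two levels: a per-sample "endogenous" level
  (lognormal, σ = 0.4, fixed across a sample's replicates) and a
  per-measurement level (lognormal, σ = 0.5), and each band additionally
  carries its own lognormal shape jitter (σ = 0.4).
  These three scales are what makes raw-spectrum quantification genuinely
  hard: the background corrupts the normalization anchor differently for
  every sample, and held-out samples have background levels never seen in
  training.
* **Confound.** In the design's manifest, every serotonin-absent sample
  carries epinephrine, dopamine, or blank background instead — so a model
  can learn "other-transmitter present ⇒ no serotonin", the shortcut the
  explanation stage is designed to expose.

Noise defaults were calibrated so that quantification from raw urine
spectra is substantially degraded while quantification after denoising
succeeds — the qualitative performance gap the framework exists to
demonstrate. A competitive-Langmuir mode (shared saturation denominator)
exists but is off by default; no electromagnetic or binding-kinetics
modelling is attempted.

## Neural-network engine

No deep-learning framework is part of the dependency set; the package
ships a compact reverse-mode autodiff engine on numpy (`sersquant.nn`)
with dense and 1-D convolutional layers, layer normalization, multi-head
self-attention, dropout, Adam and Nadam. Convolution uses the
cross-correlation convention (no kernel flip) with length-preserving
zero padding; gradients are computed as BLAS matrix products. All
gradients are verified against central finite differences in the test
suite. Weight initialization is fan-based uniform (Glorot) from a
seed-derived generator, so every model is a pure function of its seed.

## Denoising autoencoder

"Biological noise" is the signal contributed by everything in the medium
that is not the target analyte. Training pairs are built from clean
water-medium spectra: the noisy input is the clean spectrum plus a
randomly chosen blank-urine background measurement, overlaid after
baseline correction and before normalization; the target is the
normalized clean spectrum (noisy-input → clean-target is the denoising
objective). An optional lognormal per-overlay background gain exists for
training across wider background-level ranges; the default is unit gain,
since the blank pool's own measurement spread already covers the
per-sample level variation and a wider gain range was found to dilute
reconstruction precision. Pairs split 80:20 with the test count rounded
up (364 → 291/73).

The architecture is dense 937 → 400 → 200 (rectified) → 400 (rectified)
→ 937 through a sigmoid, trained with MSE under Nadam (lr 0.001), batch
32 for 128 epochs. Quality is
reported as held-out reconstruction MSE next to the identity baseline
(MSE between noisy inputs and clean targets): a useful denoiser must beat
leaving spectra untouched.

## Quantification models

All models map an 842-point normalized spectrum to serotonin
concentration (μM):

* **Core CNN** — a convolution (kernel 25, 8 filters) whose output passes
  through tanh and a rectifier in parallel, concatenated on the channel
  axis (the paired activation lets one feature map express both saturating
  and one-sided responses); average pooling ×4; a "half-peak" rectified
  convolution of kernel 13 (about half the nominal 25-point peak width);
  average pooling ×2; a 32-unit rectified dense layer and a scalar head.
* **CNN_L / CNN_3PL** — the core CNN with a linear or a learnable
  three-parameter-logistic output, upper/(1+exp(−steepness·(z−midpoint))),
  the standard saturating calibration-curve shape. The upper asymptote is
  initialized at 10 μM, above the maximum training concentration; the
  steepness starts at 2 per unit pre-activation so the whole 0–10 μM
  range is reachable from a modest pre-activation span, which speeds
  convergence under the MAE loss.
* **sCNN** — a multiscale block (kernels 8/25/50, 8 filters each,
  concatenated to 24 channels) and a per-region learnable scaling layer
  applied at full resolution, then pooling ×4 and the core CNN with the
  3PL head. Scaling regions are explicit configuration; a helper proposes
  regions where all pure-compound references fall below 5% of their
  maxima.
* **ViT** — patches of 25 points (937 → 38 patches, zero-padded to a
  multiple of 25), embedded to 64 dimensions with learned positional
  embeddings; 6 pre-norm transformer blocks with 6-head self-attention
  (per-head dimension 10, output projection 60 → 64), GELU MLPs and
  dropout 0.1; mean-pooled tokens feed a linear head.

Training follows the ensemble protocol: Adam (lr 0.001), MAE loss, batch
64, early stopping with best-validation checkpointing; members whose
final training MAE exceeds 1 μM are dropped; among survivors the lowest
validation MAE is selected, and ensemble-average predictions are also
available. The full protocol is 100 members × 256 epochs; desk-scale
runs use 5 members × 64 epochs. If every member is dropped the result is
an explicit no-convergence outcome, not an exception at training time.

MAE, MSE and mean percentage error (MPE) are reported; MPE is undefined
at zero truth and is averaged over entries with truth ≥ 0.5 μM (floor
configurable) since the design contains 0 μM samples.

Split rules: samples D and E are test-only; sample F's spectra go to
validation; remaining "repeat" spectra are shuffled and split with
validation count = ceil(0.1·n), the only rounding consistent with the
printed 218/46/54 partition of 318 urine spectra.

## CRIME explanations

Per-instance LIME: the spectrum is cut into contiguous 25-point segments
(about half a peak width); perturbed neighbours switch random segment
subsets "off" by replacing them with the spectrum's global baseline level
(its minimum); a ridge surrogate is fit with exponential kernel weights
on the fraction of switched-off segments; per-segment min/max values
across the perturbation sample are recorded as perturbation limits.

All explanations are flattened to [weights ‖ lower limits ‖ upper
limits] with per-column min–max normalization, embedded in the
2-dimensional latent space of a small VAE (encoder 64→32, β = 0.1,
reconstruction error summed per sample), and K-means-clustered into
contexts. The number of contexts is an explicit parameter (the study
design uses 6); an automatic mode scans k ∈ [2, 10] and maximizes
silhouette as a programmatic stand-in for visual inspection.

Each context is summarized by the mean of its member explanations. Its
segments become 3-D points (mean spectral intensity, normalized absolute
weight, position z-score), K-means-clustered into 15 groups; groups are
ranked by mean |weight| × mean intensity and the top five become the
context's peak regions. Ranking uses absolute weights; signed weights
stay in the report. Finally the mean context spectrum and each analyte
reference are multiplied elementwise by the context's weight profile
(each position inherits its segment's normalized absolute weight) and
compared by cosine similarity; the ranked matches name the context's
likely rationale — target signal, confounder, or artifact.

## Benchmarks and robustness

PLSR, random forest, SVM and XGBoost baselines are tuned by grid search
with 3-fold cross-validation (scikit-learn / xgboost); grids are modest
documented defaults. Perturbation testing adds Gaussian noise with σ =
level × the spectrum's maximum intensity, either everywhere or only
inside selected regions (the CRIME top regions, by default), at levels
5/10/20/30%, against a 0.5 μM MAE cutoff; level 0 reproduces the
unperturbed evaluation exactly.

## Numerical and design choices

* Spacing uniformity is enforced at 1e-9 relative tolerance; crop bounds
  likewise.
* ALS weights start at 1; the solver is exact per iteration (sparse
  Cholesky via spsolve), so results match a dense solve to solver
  tolerance.
* The DAE test MSE is computed against clean targets (the denoising
  objective), not noisy ones.
* Region-scaling regions are half-open [a, b) index intervals; overlap is
  rejected at construction.
* K-means uses 10 restarts with a fixed seed; VAE training consumes its
  own seeded generator for init, shuffling and reparametrization noise,
  so latent coordinates are reproducible bit-for-bit.
* Desk-scale problem sizes (ensemble 5 × 64 epochs, DAE 128 epochs, LIME
  256 perturbations) are the package's default demonstration scale; all
  are configurable up to the full protocol.

## What the synthetic fixtures do and do not show

Passing tests on the synthetic design demonstrate that the pipeline's
machinery is correct and that its qualitative claims hold under the
modelled conditions: additive, shape-varying biological background;
scale jitter; a saturating response; a serotonin-absence confound. They
do not demonstrate performance on real SERS measurements — real urine
backgrounds are far richer than an eight-band template, competitive
adsorption between analytes is not modelled (a stub exists, off by
default), and the printed error magnitudes of the original study are not
reproducible without its unreleased spectra. The explanation stage
inherits LIME's usual caveat: it explains a surrogate of the model, not
the model itself.
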