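# sersquant

Explainable deep-learning quantification of biomarkers from
surface-enhanced Raman spectroscopy (SERS) spectra.

SERS promises fast, inexpensive biomarker assays, but spectra measured in
biological media are corrupted by *biological noise* — signal from
everything in the sample that is not the target analyte — and models
trained on such spectra may quantify a confounder instead of the target.
`sersquant` implements a three-stage framework around a model task,
serotonin quantification (0–9 μM) in lyophilized urine spiked with
epinephrine and dopamine:

1. **Preprocessing & denoising** — asymmetric least-squares baseline
   correction (λ = 1000, p = 0.1, n = 10), cropping to 300–2000 cm⁻¹
   (842 points), per-spectrum min–max normalization, and a denoising
   autoencoder (dense 937→400→200→400→937, sigmoid output, MSE/Nadam)
   trained to reconstruct clean water-medium spectra from
   urine-background-corrupted inputs.
2. **Quantification** — 1-D CNNs with SERS-specific layers and a vision
   transformer, trained as ensembles (Adam, MAE loss, members above
   1 μM training MAE dropped, selection by validation MAE). The
   CNN_3PL variant ends in a learnable three-parameter logistic
   activation,

       ŷ = upper / (1 + exp(−steepness · (z − midpoint))),

   the standard saturating calibration-curve shape; the sCNN adds
   multiscale convolutions (kernels 8/25/50 × 8 filters) and learnable
   per-region scaling.
3. **Explanation (CRIME)** — LIME explanations for every instance are
   flattened (weights + perturbation limits), embedded in the 2-D latent
   space of a variational autoencoder, and K-means-clustered into
   *contexts* — consistent prediction rationales. Each context's top peak
   regions are scored, and its weighted mean spectrum is matched to
   analyte references by cosine similarity, S_cos = A·B/(‖A‖‖B‖), naming
   the rationale: target signal, confounder, or artifact.

Because the original spectra are not public, the package ships a
first-class synthetic-data module that reproduces the study design
(sample manifest, spectrum counts 318 urine + 364 water, the
218/46/54 train/validation/test split, saturating responses, intensity
jitter, urine background, and the serotonin-absence confound). A small
numpy autodiff engine (`sersquant.nn`) backs all neural components —
finite-difference-verified, seeded, with no deep-learning framework
dependency.

## Worked example

```python
from sersquant.pipeline import RunConfig, prepare_datasets
from sersquant.quantify import TrainProtocol, evaluate, train_ensemble

cfg = RunConfig(master_seed=3, n_scale=0.5, dae_epochs=48)
data = prepare_datasets(cfg)          # simulate -> ALS -> DAE -> denoise
dae = data["denoiser"]
print(f"DAE held-out MSE {dae.test_mse:.4f} vs identity {dae.identity_mse:.4f}")

for name in ("raw", "denoised"):
    ds = data[name]
    train, val, test = ds.split("train"), ds.split("validation"), ds.split("test")
    ens = train_ensemble("cnn_3pl", train, val,
                         TrainProtocol(ensemble_size=3, epochs=48,
                                       drop_threshold=5.0), seed=5)
    rep = evaluate(ens.predict_selected(test.intensity_matrix()), test.targets)
    print(f"{name} test MAE {rep.mae:.2f} uM, MPE {rep.mpe:.1f}%")
```

prints, at this half-design demo scale (about 80 s on one CPU):

```
DAE held-out MSE 0.0015 vs identity 0.0108
raw test MAE 1.79 uM, MPE 36.6%
denoised test MAE 1.53 uM, MPE 38.7%
```

The first line says the autoencoder reconstructs clean spectra about 7×
more accurately than leaving the noisy input untouched; the next two
compare quantification on raw versus denoised spectra for held-out
samples whose concentration combinations were never seen in training.
At the full design scale with the 5-member ensemble protocol the gap
widens (seed 1: raw 0.91 μM vs denoised 0.43 μM — see the acceptance
script below).
`examples/explain_contexts.py` continues this run through CRIME and
prints, per context, the membership count and the best-matching analyte
with its cosine score — on the confounded design at full scale, some
contexts match serotonin (the true signal) and others match dopamine or
epinephrine, exposing the shortcut the model learned for
serotonin-absent samples.

The `sersquant` console script offers thin wrappers:
`sersquant simulate`, `sersquant preprocess`, `sersquant run`.

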