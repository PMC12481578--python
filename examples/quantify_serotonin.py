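"""Train a small quantification ensemble and evaluate serotonin recovery.

Runs the ensemble protocol at demo scale (3 members, 24 epochs) on a
reduced version of the study design, using denoised urine spectra, and
reports MAE / MSE / MPE on the held-out test samples (unseen
concentration combinations).
"""

from sersquant.pipeline import RunConfig, prepare_datasets
from sersquant.quantify import TrainProtocol, evaluate, train_ensemble

cfg = RunConfig(master_seed=3, n_scale=0.5, dae_epochs=48)
data = prepare_datasets(cfg)
ds = data["denoised"]
train, val, test = ds.split("train"), ds.split("validation"), ds.split("test")
print(f"split: {len(train)} train / {len(val)} validation / {len(test)} test")

proto = TrainProtocol(ensemble_size=3, epochs=48, drop_threshold=5.0)
result = train_ensemble("cnn_3pl", train, val, proto, seed=5)
print(f"{len(result.survivor_indices)}/{proto.ensemble_size} members survived "
      "the training-MAE drop rule")

report = evaluate(result.predict_selected(test.intensity_matrix()), test.targets)
print(f"selected model test: MAE {report.mae:.2f} uM, MSE {report.mse:.2f}, "
      f"MPE {report.mpe:.1f}%")
# MAE is in concentration units; MPE is computed over targets >= 0.5 uM.
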