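"""End-to-end orchestration: simulate -> preprocess -> denoise -> quantify
-> explain -> benchmark, driven by one config and one master seed.

Each stage receives a seed derived deterministically from the master seed
and the stage name, so stages are independently reproducible; per-stage
outputs, a metrics summary (JSON) and a line-delimited log with timings
and seeds are written to the run directory.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .benchmark import BenchmarkGrid, PerturbationPlan, perturbation_test, run_benchmarks
from .crime import crime_analysis
from .denoiser import DAEConfig, build_noisy_pairs, train_dae
from .preprocess import ALSParams, als_baseline, minmax_normalize
from .quantify import TrainProtocol, evaluate, train_ensemble
from .spectra import (
    CROP_LO,
    CROP_HI,
    LabelledDataset,
    Spectrum,
    SpectrumState,
    split_dataset,
    study_manifest,
)
from .synth import BandLibrary, ResponseModel, default_band_library, make_dataset, make_reference

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "prepare_datasets"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(
        np.random.SeedSequence(
            [int(master_seed), zlib.crc32(stage.encode())]
        ).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    out_dir: str = "run"
    master_seed: int = 0
    model_kind: str = "cnn_3pl"
    als: ALSParams = field(default_factory=ALSParams)
    crop: tuple[float, float] = (CROP_LO, CROP_HI)
    response: ResponseModel = field(default_factory=ResponseModel)
    dae_epochs: int = 128
    protocol: TrainProtocol = field(
        default_factory=lambda: TrainProtocol(ensemble_size=5, epochs=64)
    )
    crime_contexts: int | str = 6
    crime_samples: int = 256
    run_benchmarks: bool = True
    run_perturbation: bool = True
    #: scale factor on per-sample spectrum counts (smoke runs use < 1)
    n_scale: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        for key, val in raw.items():
            if key == "als":
                kw["als"] = ALSParams(**val)
            elif key == "response":
                kw["response"] = ResponseModel(**val)
            elif key == "protocol":
                kw["protocol"] = TrainProtocol(**val)
            elif key == "crop":
                kw["crop"] = tuple(val)
            else:
                kw[key] = val
        return cls(**kw)


def _baseline_all(ds: LabelledDataset, als: ALSParams) -> np.ndarray:
    return np.stack([als_baseline(s.intensities, als)[1] for s in ds.spectra])


def _plot_latent(latent: np.ndarray, labels: np.ndarray, path: Path) -> None:
    """Latent-plane scatter for visual inspection of the context count."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(latent[:, 0], latent[:, 1], c=labels, cmap="tab10", s=12)
    ax.set_xlabel("latent z1")
    ax.set_ylabel("latent z2")
    ax.set_title("explanation contexts")
    fig.colorbar(sc, ax=ax, label="context")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def prepare_datasets(config: RunConfig, lib: BandLibrary | None = None):
    """Simulate the study design and build raw and denoised urine datasets.

    Returns a dict with the split datasets ("raw"/"denoised", each
    train/validation/test), the trained denoiser, and the reference
    spectra used for explanation matching.
    """
    import math
    from dataclasses import replace as dc_replace

    lib = lib or default_band_library()
    seed_sim = stage_seed(config.master_seed, "simulate")

    def scaled(manifest):
        if config.n_scale == 1.0:
            return manifest
        return [
            dc_replace(r, n_spectra=max(2, math.ceil(r.n_spectra * config.n_scale)))
            for r in manifest
        ]

    urine_manifest = scaled(study_manifest("urine"))
    urine = make_dataset(urine_manifest, config.response, lib, seed=seed_sim)
    water = make_dataset(scaled(study_manifest("water")), config.response, lib,
                         seed=seed_sim + 1)

    urine_b = _baseline_all(urine, config.als)
    water_b = _baseline_all(water, config.als)
    grid = urine.spectra[0].wavenumbers
    lo, hi = config.crop
    tol = 1e-9 * max(abs(lo), abs(hi), 1.0)
    mask = (grid >= lo - tol) & (grid <= hi + tol)

    # denoiser: clean water spectra + blank-urine background pool (sample U)
    u_idx = np.flatnonzero(urine.sample_ids == "U")
    backgrounds = [Spectrum(grid, urine_b[i], SpectrumState.BASELINED) for i in u_idx]
    cleans = [Spectrum(grid, row, SpectrumState.BASELINED) for row in water_b]
    pairs = build_noisy_pairs(cleans, backgrounds, seed=stage_seed(config.master_seed, "dae"))
    dae = train_dae(pairs, DAEConfig(input_dim=grid.size, epochs=config.dae_epochs),
                    seed=stage_seed(config.master_seed, "dae"))

    norm = np.stack([minmax_normalize(r) for r in urine_b])
    den = dae.reconstruct(norm)

    def build(Xmat: np.ndarray) -> LabelledDataset:
        specs = [
            Spectrum(grid[mask], row[mask], SpectrumState.NORMALIZED)
            for row in Xmat
        ]
        ds = LabelledDataset(specs, urine.targets, urine.sample_ids)
        return split_dataset(ds, urine_manifest, 0.1,
                             seed=stage_seed(config.master_seed, "split"))

    refs = [
        (a, Spectrum(grid[mask], make_reference(a, lib).intensities[mask],
                     SpectrumState.NORMALIZED))
        for a in ("serotonin", "dopamine", "epinephrine")
    ]
    return {
        "raw": build(norm),
        "denoised": build(den),
        "denoiser": dae,
        "references": refs,
        "grid": grid,
        "mask": mask,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full framework; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    metrics: dict = {"schema": 1, "master_seed": config.master_seed}

    def log(stage: str, **info):
        rec = {"stage": stage, "time": round(time.time() - t_start, 2), **info}
        with open(log_path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")

    t_start = time.time()
    data = prepare_datasets(config)
    dae = data["denoiser"]
    metrics["dae_test_mse"] = dae.test_mse
    metrics["dae_identity_mse"] = dae.identity_mse
    log("prepare", dae_test_mse=dae.test_mse, seed=stage_seed(config.master_seed, "simulate"))

    results = {}
    for name in ("raw", "denoised"):
        ds = data[name]
        tr, va, te = ds.split("train"), ds.split("validation"), ds.split("test")
        ens = train_ensemble(
            config.model_kind, tr, va, config.protocol,
            seed=stage_seed(config.master_seed, f"quant-{name}"),
        )
        if not ens.converged:
            metrics[f"{name}_converged"] = False
            log(f"quantify-{name}", converged=False)
            continue
        pred = ens.predict_selected(te.intensity_matrix())
        rep = evaluate(pred, te.targets)
        metrics[f"{name}_test_mae"] = rep.mae
        metrics[f"{name}_test_mse"] = rep.mse
        metrics[f"{name}_test_mpe"] = rep.mpe
        results[name] = (ens, te)
        log(f"quantify-{name}", test_mae=rep.mae,
            seed=stage_seed(config.master_seed, f"quant-{name}"))

    if "denoised" in results:
        ens, te = results["denoised"]
        X_all = data["denoised"].intensity_matrix()
        reports, latent, labels = crime_analysis(
            ens.selected, X_all, data["references"],
            n_samples=config.crime_samples, k=config.crime_contexts,
            seed=stage_seed(config.master_seed, "crime"),
        )
        np.savetxt(out / "latent.csv", np.column_stack([latent, labels]),
                   delimiter=",", header="z1,z2,context", comments="")
        _plot_latent(latent, labels, out / "latent.png")
        ctx_summary = [
            {
                "context": r.context_id,
                "n_members": int(r.member_indices.size),
                "top_match": r.reference_matches[0][0],
                "top_cosine": round(r.reference_matches[0][1], 4),
                "top_regions": [[int(a), int(b)] for a, b, _ in r.top_regions],
            }
            for r in reports
        ]
        metrics["contexts"] = ctx_summary
        log("crime", n_contexts=len(reports))

        if config.run_perturbation:
            plan_u = PerturbationPlan(mode="universal",
                                      seed=stage_seed(config.master_seed, "perturb"))
            regions = tuple(
                (int(a), int(b)) for a, b, _ in reports[0].top_regions
            )
            plan_l = PerturbationPlan(mode="localized", regions=regions,
                                      seed=stage_seed(config.master_seed, "perturb"))
            tab_u = perturbation_test(ens.selected, te, plan_u)
            tab_l = perturbation_test(ens.selected, te, plan_l)
            tab_u.to_csv(out / "perturbation_universal.csv", index=False)
            tab_l.to_csv(out / "perturbation_localized.csv", index=False)
            metrics["perturbation_universal"] = tab_u.to_dict("records")
            metrics["perturbation_localized"] = tab_l.to_dict("records")
            log("perturbation")

    if config.run_benchmarks and "denoised" in results:
        ds = data["denoised"]
        tr, va, te = ds.split("train"), ds.split("validation"), ds.split("test")
        bench = run_benchmarks(tr, te, BenchmarkGrid(),
                               seed=stage_seed(config.master_seed, "benchmark"))
        bench.to_csv(out / "benchmarks.csv", index=False)
        metrics["benchmarks"] = bench[["family", "mae"]].to_dict("records")
        log("benchmark")

    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    log("done")
    return out
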