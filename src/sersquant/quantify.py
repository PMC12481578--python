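"""Neural quantification models for serotonin concentration regression.

Four architectures are provided:

* ``cnn_linear`` — the core 1-D CNN with a linear output;
* ``cnn_3pl``    — the core CNN with a learnable three-parameter-logistic
  (3PL) output activation, the saturating calibration-curve shape;
* ``scnn``       — multiscale convolutions (kernels 8/25/50, 8 filters
  each) and a learnable per-region scaling layer in front of the core
  CNN, with the 3PL output;
* ``vit``        — a 1-D vision transformer (patch 25, hidden 64,
  6 blocks, 6-head attention, GELU, dropout 0.1).

The core CNN applies a paired tanh/rectifier activation to a shared
convolution (both nonlinearities of one feature map, concatenated on the
channel axis), then a "half-peak" rectified convolution of kernel 13 —
roughly half the nominal 25-point peak width — before pooling and a dense
head.

Training follows an ensemble protocol: many seeds, members whose training
MAE exceeds a drop threshold are discarded, and the member with the lowest
validation MAE is selected; ensemble-average predictions are also kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .nn import (
    Activation,
    Adam,
    Conv1D,
    Dense,
    Dropout,
    LayerNorm,
    Module,
    MultiHeadSelfAttention,
    Sequential,
    Tensor,
    concat,
    conv1d_same,
)
from .spectra import LabelledDataset

__all__ = [
    "ThreePLSpec",
    "three_pl",
    "ThreePLHead",
    "MultiscaleLayer",
    "RegionScalingSpec",
    "RegionScalingLayer",
    "TrainProtocol",
    "EvalReport",
    "QuantModel",
    "build_model",
    "train_model",
    "train_ensemble",
    "EnsembleResult",
    "evaluate",
    "propose_irrelevant_regions",
]

MODEL_KINDS = ("cnn_linear", "cnn_3pl", "scnn", "vit")


# --------------------------------------------------------------------------
# custom layers
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ThreePLSpec:
    """Three-parameter logistic: upper asymptote (uM), midpoint and
    steepness.  Initialized with the upper bound above the maximum
    training concentration so the whole 0-9 uM range is reachable."""

    upper: float = 10.0
    midpoint: float = 0.0
    steepness: float = 2.0

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")


def three_pl(z, spec: ThreePLSpec = ThreePLSpec()):
    """upper / (1 + exp(-steepness * (z - midpoint))); bounded in
    (0, upper), monotone increasing."""
    z = np.asarray(z, dtype=float)
    return spec.upper / (1.0 + np.exp(-spec.steepness * (z - spec.midpoint)))


class ThreePLHead(Module):
    """Learnable 3PL output activation applied to a scalar pre-activation."""

    def __init__(self, spec: ThreePLSpec = ThreePLSpec()):
        self.upper = Tensor(float(spec.upper), requires_grad=True)
        self.midpoint = Tensor(float(spec.midpoint), requires_grad=True)
        self.steepness = Tensor(float(spec.steepness), requires_grad=True)

    def forward(self, z: Tensor) -> Tensor:
        return self.upper / (1.0 + (-(self.steepness * (z - self.midpoint))).exp())


class MultiscaleLayer(Module):
    """Three parallel length-preserving convolutions (kernels 8/25/50,
    8 filters each) concatenated on the channel axis -> 24 channels."""

    KERNELS = (8, 25, 50)
    FILTERS = 8

    def __init__(self, n_in: int, rng: np.random.Generator):
        self.convs = [Conv1D(k, n_in, self.FILTERS, rng) for k in self.KERNELS]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] < max(self.KERNELS):
            raise ValueError("input shorter than the largest kernel")
        return concat([c(x) for c in self.convs], axis=-1)


@dataclass(frozen=True)
class RegionScalingSpec:
    """Non-overlapping half-open index regions [a_j, b_j) with a learnable
    scale s_j each; positions outside every region pass unchanged."""

    regions: tuple[tuple[int, int], ...]
    scale_init: tuple[float, ...] | float = 1.0

    def __post_init__(self) -> None:
        spans = sorted(self.regions)
        for (a, b) in spans:
            if not a < b:
                raise ValueError(f"empty region ({a}, {b})")
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValueError("regions overlap")

    def scales(self) -> np.ndarray:
        if isinstance(self.scale_init, (int, float)):
            return np.full(len(self.regions), float(self.scale_init))
        if len(self.scale_init) != len(self.regions):
            raise ValueError("scale_init length mismatch")
        return np.asarray(self.scale_init, dtype=float)


class RegionScalingLayer(Module):
    """Elementwise scaling of pre-registered spectral regions,
    S_j(X) = X[a_j:b_j] * s_j, reassembled to full length."""

    def __init__(self, spec: RegionScalingSpec, length: int):
        for a, b in spec.regions:
            if not (0 <= a < b <= length):
                raise ValueError(f"region ({a}, {b}) outside spectrum length {length}")
        self.spec = spec
        self.length = length
        self.scales = Tensor(spec.scales(), requires_grad=True)
        masks = np.zeros((len(spec.regions), length))
        outside = np.ones(length)
        for j, (a, b) in enumerate(spec.regions):
            masks[j, a:b] = 1.0
            outside[a:b] = 0.0
        self._masks = masks
        self._outside = outside

    def forward(self, x: Tensor) -> Tensor:
        # profile (L,): s_j inside region j, 1 outside all regions
        profile = (self.scales @ Tensor(self._masks)) + Tensor(self._outside)
        if len(x.shape) == 3:
            profile = profile.reshape(1, self.length, 1)
        return x * profile


class _AvgPool(Module):
    """Average pooling by factor p along the length axis (tail cropped)."""

    def __init__(self, p: int):
        self.p = p

    def parameters(self):
        return []

    def forward(self, x: Tensor) -> Tensor:
        N, L, C = x.shape
        Lc = (L // self.p) * self.p
        return x[:, :Lc, :].reshape(N, Lc // self.p, self.p, C).mean(axis=2)


class _PairedTanhReLU(Module):
    """Apply tanh and a rectifier to the same convolution output and
    concatenate the two on the channel axis."""

    def parameters(self):
        return []

    def forward(self, x: Tensor) -> Tensor:
        return concat([x.tanh(), x.relu()], axis=-1)


# --------------------------------------------------------------------------
# model assembly
# --------------------------------------------------------------------------
class QuantModel(Module):
    """A quantification model: (N, L) spectra -> (N,) serotonin uM."""

    def __init__(self, kind: str, input_dim: int, seed: int = 0,
                 regions: RegionScalingSpec | None = None):
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}")
        self.kind = kind
        self.input_dim = input_dim
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
        self._mods: list[Module] = []

        if kind == "vit":
            self._build_vit(input_dim, rng)
            return

        if kind == "scnn":
            self.multiscale = MultiscaleLayer(1, rng)
            if regions is None:
                regions = RegionScalingSpec(regions=((0, input_dim),))
            self.region_scaling = RegionScalingLayer(regions, input_dim)
            c_in = 24
        else:
            self.multiscale = None
            self.region_scaling = None
            c_in = 1

        self.conv1 = Conv1D(25, c_in, 8, rng)
        self.pair = _PairedTanhReLU()
        self.pool1 = _AvgPool(4)
        self.half_peak = Conv1D(13, 16, 8, rng)  # half-peak rectified conv
        self.pool2 = _AvgPool(2)
        flat = (input_dim // 4 // 2) * 8
        self.fc1 = Dense(flat, 32, rng)
        self.fc2 = Dense(32, 1, rng)
        self.head = ThreePLHead() if kind in ("cnn_3pl", "scnn") else None

    # --- ViT -------------------------------------------------------------
    def _build_vit(self, input_dim: int, rng: np.random.Generator,
                   patch: int = 25, dim: int = 64, depth: int = 6,
                   heads: int = 6, head_dim: int = 10, drop: float = 0.1):
        self.patch = patch
        self.n_patches = math.ceil(input_dim / patch)
        self.embed = Dense(patch, dim, rng)
        self.pos = Tensor(rng.normal(0, 0.02, size=(self.n_patches, dim)),
                          requires_grad=True)
        self.blocks = []
        for _ in range(depth):
            self.blocks.append(
                (
                    LayerNorm(dim),
                    MultiHeadSelfAttention(dim, heads, head_dim, rng),
                    LayerNorm(dim),
                    Dense(dim, 2 * dim, rng),
                    Dense(2 * dim, dim, rng),
                    Dropout(drop, rng),
                )
            )
        self.final_ln = LayerNorm(dim)
        self.vit_head = Dense(dim, 1, rng)

    def parameters(self):
        if self.kind == "vit":
            out = self.embed.parameters() + [self.pos]
            for ln1, attn, ln2, fc1, fc2, _ in self.blocks:
                for m in (ln1, attn, ln2, fc1, fc2):
                    out.extend(m.parameters())
            out.extend(self.final_ln.parameters())
            out.extend(self.vit_head.parameters())
            return out
        out = []
        if self.multiscale is not None:
            out.extend(self.multiscale.parameters())
            out.extend(self.region_scaling.parameters())
        for m in (self.conv1, self.half_peak, self.fc1, self.fc2):
            out.extend(m.parameters())
        if self.head is not None:
            out.extend(self.head.parameters())
        return out

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        x = Tensor._lift(x)
        N, L = x.shape
        if L != self.input_dim:
            raise ValueError(f"expected input dim {self.input_dim}, got {L}")
        if self.kind == "vit":
            return self._forward_vit(x, training)
        h = x.reshape(N, L, 1)
        if self.multiscale is not None:
            # full-resolution multiscale features and region scaling, then
            # pool before the core convolutions
            h = self.multiscale(h)
            h = self.region_scaling(h)
            h = self.pool1(h)
            h = self.pair(self.conv1(h))
        else:
            h = self.pair(self.conv1(h))
            h = self.pool1(h)
        h = self.half_peak(h).relu()
        h = self.pool2(h)
        h = h.reshape(N, (self.input_dim // 4 // 2) * 8)
        h = self.fc1(h).relu()
        z = self.fc2(h).reshape(N)
        return self.head(z) if self.head is not None else z

    def _forward_vit(self, x: Tensor, training: bool) -> Tensor:
        N, L = x.shape
        T, P = self.n_patches, self.patch
        pad = T * P - L
        if pad:
            x = concat([x, Tensor(np.zeros((N, pad)))], axis=-1)
        tok = x.reshape(N, T, P)
        h = self.embed(tok) + self.pos
        for ln1, attn, ln2, fc1, fc2, drop in self.blocks:
            h = h + drop(attn(ln1(h)), training=training)
            m = fc2(fc1(ln2(h)).gelu())
            h = h + drop(m, training=training)
        h = self.final_ln(h).mean(axis=1)
        return self.vit_head(h).reshape(N)

    def predict(self, X: np.ndarray, chunk: int = 128) -> np.ndarray:
        """Inference without graph construction, in memory-bounded chunks."""
        from .nn.autograd import no_grad

        X = np.atleast_2d(np.asarray(X, float))
        outs = []
        with no_grad():
            for start in range(0, X.shape[0], chunk):
                outs.append(self.forward(Tensor(X[start : start + chunk])).data)
        return np.concatenate(outs)


def build_model(kind: str, input_dim: int, seed: int = 0,
                regions: RegionScalingSpec | None = None) -> QuantModel:
    """Construct one of the four quantification architectures."""
    return QuantModel(kind, input_dim, seed=seed, regions=regions)


# --------------------------------------------------------------------------
# training protocol
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class TrainProtocol:
    """Ensemble training protocol: Adam(1e-3), MAE loss, batch 64,
    256 epochs with early-stopping patience 64; 100 members, members with
    training MAE above 1 uM dropped, selection by minimum validation MAE."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 256
    early_stop_patience: int = 64
    ensemble_size: int = 100
    drop_threshold: float = 1.0
    mpe_floor: float = 0.5


@dataclass
class EvalReport:
    mae: float
    mse: float
    mpe: float | None  # None when no truth entry reaches the MPE floor


def evaluate(pred: np.ndarray, truth: np.ndarray, mpe_floor: float = 0.5) -> EvalReport:
    """MAE (uM), MSE (uM^2) and mean percentage error.

    MPE is undefined at zero truth; it is averaged over entries with
    truth >= ``mpe_floor`` (default 0.5 uM) and reported as None when no
    entry qualifies.
    """
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be equal-length, nonempty")
    err = np.abs(pred - truth)
    mask = truth >= mpe_floor
    mpe = float(np.mean(err[mask] / truth[mask]) * 100.0) if mask.any() else None
    return EvalReport(mae=float(err.mean()), mse=float(np.mean(err**2)), mpe=mpe)


def _mae_loss(pred: Tensor, y: np.ndarray) -> Tensor:
    return (pred - Tensor(y)).abs().mean()


def train_model(
    model: QuantModel,
    train: LabelledDataset,
    validation: LabelledDataset,
    protocol: TrainProtocol = TrainProtocol(),
    seed: int = 0,
) -> dict:
    """Train one model with early stopping and best-validation checkpointing.

    Returns a history dict with per-epoch train/validation MAE; the model
    is left holding the checkpoint weights that minimized validation MAE.
    """
    X = train.intensity_matrix()
    y = train.targets
    Xv = validation.intensity_matrix()
    yv = validation.targets
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA7C4]))
    opt = Adam(model.parameters(), lr=protocol.learning_rate)
    best_val = np.inf
    best_state = model.state()
    since_best = 0
    hist: dict = {"train_mae": [], "val_mae": []}
    n = X.shape[0]
    for epoch in range(protocol.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, protocol.batch_size):
            idx = perm[start : start + protocol.batch_size]
            opt.zero_grad()
            loss = _mae_loss(model.forward(Tensor(X[idx]), training=True), y[idx])
            loss.backward()
            opt.step()
        train_mae = float(np.mean(np.abs(model.predict(X) - y)))
        val_mae = float(np.mean(np.abs(model.predict(Xv) - yv)))
        hist["train_mae"].append(train_mae)
        hist["val_mae"].append(val_mae)
        if val_mae < best_val:
            best_val = val_mae
            best_state = model.state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= protocol.early_stop_patience:
                break
    model.load_state(best_state)
    hist["best_val_mae"] = best_val
    hist["final_train_mae"] = float(np.mean(np.abs(model.predict(X) - y)))
    return hist


@dataclass
class EnsembleResult:
    """Outcome of the ensemble protocol.

    ``converged`` is False when every member exceeded the training-MAE
    drop threshold (the "no-convergence" outcome); then ``selected`` is
    None and predictions are unavailable.
    """

    members: list[QuantModel]
    histories: list[dict]
    survivor_indices: list[int]
    selected: QuantModel | None
    selected_index: int | None
    converged: bool

    def predict_selected(self, X: np.ndarray) -> np.ndarray:
        if not self.converged:
            raise RuntimeError("ensemble did not converge; no selected model")
        return self.selected.predict(X)

    def predict_ensemble(self, X: np.ndarray) -> np.ndarray:
        if not self.converged:
            raise RuntimeError("ensemble did not converge")
        preds = [self.members[i].predict(X) for i in self.survivor_indices]
        return np.mean(preds, axis=0)


def train_ensemble(
    model_kind: str,
    train: LabelledDataset,
    validation: LabelledDataset,
    protocol: TrainProtocol = TrainProtocol(),
    seed: int = 0,
    regions: RegionScalingSpec | None = None,
) -> EnsembleResult:
    """Train an ensemble of one architecture under distinct derived seeds.

    Members whose final training MAE exceeds ``protocol.drop_threshold``
    are dropped; among survivors the member with the lowest validation MAE
    is selected.  Deterministic under a fixed master seed.
    """
    if len(train) == 0 or len(validation) == 0:
        raise ValueError("train and validation sets must be nonempty")
    members: list[QuantModel] = []
    histories: list[dict] = []
    input_dim = len(train.spectra[0])
    for j in range(protocol.ensemble_size):
        member_seed = int(
            np.random.SeedSequence([seed, j]).generate_state(1)[0] % (2**31)
        )
        model = build_model(model_kind, input_dim, seed=member_seed, regions=regions)
        hist = train_model(model, train, validation, protocol, seed=member_seed)
        members.append(model)
        histories.append(hist)
    survivors = [
        j
        for j, h in enumerate(histories)
        if h["final_train_mae"] <= protocol.drop_threshold
    ]
    if not survivors:
        return EnsembleResult(members, histories, [], None, None, False)
    best = min(survivors, key=lambda j: histories[j]["best_val_mae"])
    return EnsembleResult(members, histories, survivors, members[best], best, True)


def propose_irrelevant_regions(
    references: Sequence[np.ndarray], fraction: float = 0.05, min_width: int = 10
) -> RegionScalingSpec:
    """Propose scaling regions where every reference spectrum is weak.

    A position is flagged when all pure-compound reference intensities fall
    below ``fraction`` of their own maximum; runs of at least ``min_width``
    flagged points become regions.
    """
    refs = np.stack([np.asarray(r, float) for r in references])
    thresh = fraction * refs.max(axis=1, keepdims=True)
    weak = np.all(refs <= thresh, axis=0)
    regions: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(np.append(weak, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_width:
                regions.append((start, i))
            start = None
    if not regions:
        regions = [(0, refs.shape[1])]
    return RegionScalingSpec(regions=tuple(regions))
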