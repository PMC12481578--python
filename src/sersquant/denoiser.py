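"""Denoising autoencoder for removing urine background from SERS spectra.

"Biological noise" here is the SERS signal and background contributed by
everything in the medium that is not the target analyte.  The autoencoder
is trained on pairs built from clean water-medium spectra: the noisy input
is the clean spectrum plus a randomly chosen blank urine background
measurement (overlaid after baseline correction, before normalization);
the target is the normalized clean spectrum.  The decoder ends in a
sigmoid, so reconstructions live in [0, 1] like the normalized inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Dense, Module, Nadam, Tensor
from .preprocess import minmax_normalize, overlay_noise
from .spectra import Spectrum, SpectrumState

__all__ = [
    "DAEConfig",
    "NoisyPairs",
    "TrainedDenoiser",
    "build_noisy_pairs",
    "train_dae",
    "denoise",
]


@dataclass(frozen=True)
class DAEConfig:
    """Architecture and training settings of the denoising autoencoder.

    The encoder is two rectified dense layers (2x200 = 400 units, then a
    200-dimensional code); the decoder mirrors it and reconstructs the
    full spectrum through a sigmoid.  Loss is MSE under a Nadam-type
    optimizer, 128 epochs at batch size 32, with an 80:20 train/test
    split of the pairs.
    """

    input_dim: int = 937
    encoder_widths: tuple[int, ...] = (400, 200)
    decoder_widths: tuple[int, ...] = (400,)
    epochs: int = 128
    batch_size: int = 32
    learning_rate: float = 1e-3
    train_fraction: float = 0.8


@dataclass
class NoisyPairs:
    """Normalized (noisy, clean) spectrum pairs with a train/test split."""

    noisy: np.ndarray  # (n, d)
    clean: np.ndarray  # (n, d)
    train_idx: np.ndarray
    test_idx: np.ndarray
    wavenumbers: np.ndarray

    def __len__(self) -> int:
        return self.noisy.shape[0]


def build_noisy_pairs(
    clean: list[Spectrum],
    backgrounds: list[Spectrum],
    seed: int = 0,
    train_fraction: float = 0.8,
    gain_sigma: float = 0.0,
) -> NoisyPairs:
    """Overlay a random background on each clean spectrum and normalize both.

    Inputs must be baseline-corrected and share a grid.  The test count is
    ``ceil((1 - train_fraction) * n)`` (364 pairs -> 291 train / 73 test).

    ``gain_sigma`` optionally draws a lognormal background gain per
    overlay (0 = plain unit-gain overlay, the default); the blank pool's
    own measurement-to-measurement spread already covers a range of
    background levels.
    """
    if not backgrounds:
        raise ValueError("background pool is empty")
    if not clean:
        raise ValueError("no clean spectra")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDAE]))
    picks = rng.integers(0, len(backgrounds), size=len(clean))
    gains = np.exp(rng.normal(0.0, gain_sigma, size=len(clean)))
    noisy_rows, clean_rows = [], []
    for s, k, g in zip(clean, picks, gains):
        noisy = overlay_noise(s, backgrounds[int(k)], gain=float(g))
        noisy_rows.append(minmax_normalize(noisy.intensities))
        clean_rows.append(minmax_normalize(s.intensities))
    n = len(clean)
    n_test = math.ceil((1.0 - train_fraction) * n)
    perm = rng.permutation(n)
    return NoisyPairs(
        noisy=np.stack(noisy_rows),
        clean=np.stack(clean_rows),
        train_idx=np.sort(perm[n_test:]),
        test_idx=np.sort(perm[:n_test]),
        wavenumbers=clean[0].wavenumbers.copy(),
    )


class _DAENet(Module):
    def __init__(self, config: DAEConfig, rng: np.random.Generator):
        widths = (
            list(config.encoder_widths)
            + list(config.decoder_widths)
            + [config.input_dim]
        )
        self.layers = []
        prev = config.input_dim
        for w in widths:
            self.layers.append(Dense(prev, w, rng))
            prev = w

    def parameters(self):
        out = []
        for l in self.layers:
            out.extend(l.parameters())
        return out

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for l in self.layers[:-1]:
            h = l(h).relu()
        return self.layers[-1](h).sigmoid()


@dataclass
class TrainedDenoiser:
    """A trained denoising autoencoder plus its held-out reconstruction MSE."""

    net: _DAENet
    config: DAEConfig
    test_mse: float
    identity_mse: float  # MSE of leaving the noisy input untouched
    history: list[float]

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        from .nn.autograd import no_grad

        with no_grad():
            return self.net(Tensor(np.atleast_2d(np.asarray(X, float)))).data


def train_dae(
    pairs: NoisyPairs, config: DAEConfig | None = None, seed: int = 0
) -> TrainedDenoiser:
    """Train the autoencoder on noisy -> clean pairs (MSE loss, Nadam).

    Records the held-out test MSE and, for reference, the identity
    baseline (MSE between noisy inputs and clean targets on the same
    pairs): a useful denoiser must beat leaving spectra untouched.
    """
    config = config or DAEConfig(input_dim=pairs.noisy.shape[1])
    if pairs.noisy.shape[1] != config.input_dim:
        raise ValueError(
            f"pair dimension {pairs.noisy.shape[1]} != config input_dim {config.input_dim}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDAE2]))
    net = _DAENet(config, rng)
    opt = Nadam(net.parameters(), lr=config.learning_rate)
    Xtr, Ytr = pairs.noisy[pairs.train_idx], pairs.clean[pairs.train_idx]
    history: list[float] = []
    n = Xtr.shape[0]
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            opt.zero_grad()
            out = net(Tensor(Xtr[idx]))
            loss = ((out - Tensor(Ytr[idx])) ** 2).mean()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * idx.size
        history.append(epoch_loss / n)
    Xte, Yte = pairs.noisy[pairs.test_idx], pairs.clean[pairs.test_idx]
    recon = net(Tensor(Xte)).data
    test_mse = float(np.mean((recon - Yte) ** 2))
    identity_mse = float(np.mean((Xte - Yte) ** 2))
    return TrainedDenoiser(net, config, test_mse, identity_mse, history)


def denoise(model: TrainedDenoiser, s: Spectrum) -> Spectrum:
    """Run one normalized spectrum through the denoiser."""
    if s.state not in (SpectrumState.NORMALIZED, SpectrumState.DENOISED):
        raise ValueError("spectrum must be normalized before denoising")
    if len(s) != model.config.input_dim:
        raise ValueError(
            f"spectrum length {len(s)} != denoiser input_dim {model.config.input_dim}"
        )
    out = model.reconstruct(s.intensities[None, :])[0]
    return Spectrum(s.wavenumbers, out, SpectrumState.DENOISED)
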