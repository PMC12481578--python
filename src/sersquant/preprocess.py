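"""Spectral preprocessing: ALS baseline correction, min-max normalization,
Savitzky-Golay derivative filtering and the noise-overlay construction used
to build denoiser training pairs.

The canonical processing order for every spectrum is fixed:
crop -> ALS baseline -> (optional background overlay) -> min-max normalize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from scipy.signal import savgol_filter

from .spectra import Spectrum, SpectrumState

__all__ = [
    "ALSParams",
    "SGParams",
    "als_baseline",
    "minmax_normalize",
    "sg_derivative",
    "overlay_noise",
    "preprocess_spectrum",
]


@dataclass(frozen=True)
class ALSParams:
    """Asymmetric least-squares baseline parameters.

    lam is the second-difference smoothness weight (lambda), p the
    asymmetry (weight on points above the baseline) and n_iter the number
    of reweighting iterations.
    """

    lam: float = 1000.0
    p: float = 0.1
    n_iter: int = 10

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay derivative filter parameters (points, not cm^-1)."""

    window: int = 33
    polyorder: int = 5
    deriv_order: int = 2

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.polyorder >= self.window:
            raise ValueError("polyorder must be < window")


def als_baseline(
    y: np.ndarray, params: ALSParams = ALSParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate a baseline by asymmetric least squares.

    The baseline z minimizes  sum_i w_i (y_i - z_i)^2 + lam * sum (D2 z)^2
    where D2 is the second-difference operator.  Weights start at 1 and are
    reset each iteration to p where y > z and 1-p elsewhere, so with
    p < 0.5 the baseline hugs the lower envelope and peaks stay positive
    in the corrected signal.

    Returns ``(baseline, corrected)`` with ``corrected = y - baseline``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("y must be 1-D with length >= 3")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    n = y.size
    d2 = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = params.lam * (d2.T @ d2)
    w = np.ones(n)
    z = y
    for _ in range(params.n_iter):
        W = sp.diags(w, format="csc")
        z = spsolve((W + penalty).tocsc(), w * y)
        w = np.where(y > z, params.p, 1.0 - params.p)
    return z, y - z


def minmax_normalize(y: np.ndarray) -> np.ndarray:
    """Scale a spectrum to [0, 1] by its own minimum and maximum.

    A constant input has no scale; it maps to all zeros with a warning
    rather than failing, so degenerate spectra do not crash batch runs.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 1:
        raise ValueError("empty input")
    lo, hi = y.min(), y.max()
    if hi == lo:
        warnings.warn("constant spectrum: min-max normalization returns zeros")
        return np.zeros_like(y)
    return (y - lo) / (hi - lo)


def sg_derivative(y: np.ndarray, params: SGParams = SGParams()) -> np.ndarray:
    """Savitzky-Golay smoothed derivative (per-sample-index differentiation).

    Edges are handled by polynomial-fit extension so the output length
    equals the input length (the models need a fixed dimension).
    """
    y = np.asarray(y, dtype=float)
    if y.size < params.window:
        raise ValueError("input shorter than filter window")
    return savgol_filter(
        y, params.window, params.polyorder, deriv=params.deriv_order, mode="interp"
    )


def overlay_noise(clean: Spectrum, background: Spectrum, gain: float = 1.0) -> Spectrum:
    """Overlay a background measurement onto a clean spectrum (additive).

    Both spectra must be baseline-corrected and share one grid; the overlay
    happens before normalization so intensities are scale-coherent.  The
    background gain defaults to 1.0 (no rescaling).
    """
    if clean.state is not SpectrumState.BASELINED:
        raise ValueError("clean spectrum must be baselined")
    if background.state is not SpectrumState.BASELINED:
        raise ValueError("background spectrum must be baselined")
    if not np.array_equal(clean.wavenumbers, background.wavenumbers):
        raise ValueError("wavenumber grids differ")
    return Spectrum(
        clean.wavenumbers,
        clean.intensities + gain * background.intensities,
        SpectrumState.BASELINED,
    )


def preprocess_spectrum(
    s: Spectrum,
    als: ALSParams = ALSParams(),
    normalize: bool = True,
) -> Spectrum:
    """ALS-correct and optionally normalize one spectrum."""
    _, corrected = als_baseline(s.intensities, als)
    out = Spectrum(s.wavenumbers, corrected, SpectrumState.BASELINED)
    if normalize:
        out = Spectrum(
            out.wavenumbers, minmax_normalize(out.intensities), SpectrumState.NORMALIZED
        )
    return out
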