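"""Synthetic SERS mixture spectra with the statistical structure of the
study design.

Real SERS spectra of neurotransmitter mixtures are not publicly deposited,
so every downstream stage is exercised on generated data that emulates the
features the framework is built to handle:

* peak spectra of the three analytes (serotonin, dopamine, epinephrine)
  built from Lorentzian/Gaussian bands, with one band unique to each
  analyte and shared aromatic bands creating realistic overlap;
* a saturating concentration -> intensity response (Langmuir-type
  ``a_max * c / (k_half + c)``), the behaviour that motivates a logistic
  calibration output layer;
* per-measurement multiplicative intensity jitter (lognormal), the
  hot-spot variability SERS is known for;
* an additive urine background ("biological noise") for urine-medium
  samples, plus polynomial baseline drift and additive Gaussian noise;
* the design's confounder: serotonin-absent samples carry nonzero
  dopamine/epinephrine or background only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .spectra import (
    LabelledDataset,
    Medium,
    SampleManifest,
    Spectrum,
    SpectrumState,
    default_grid,
)

__all__ = [
    "Band",
    "BandLibrary",
    "ResponseModel",
    "default_band_library",
    "make_reference",
    "make_mixture",
    "make_dataset",
]

ANALYTES = ("serotonin", "dopamine", "epinephrine")
BACKGROUND = "urine_background"


@dataclass(frozen=True)
class Band:
    """One vibrational band: center (cm^-1), FWHM (cm^-1), relative
    amplitude, and line shape."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "lorentzian"  # lorentzian | gaussian | pseudo_voigt

    def profile(self, w: np.ndarray) -> np.ndarray:
        x = (w - self.center) / (self.fwhm / 2.0)
        lor = 1.0 / (1.0 + x * x)
        if self.shape == "lorentzian":
            line = lor
        elif self.shape == "gaussian":
            line = np.exp(-np.log(2.0) * x * x)
        elif self.shape == "pseudo_voigt":
            line = 0.5 * lor + 0.5 * np.exp(-np.log(2.0) * x * x)
        else:
            raise ValueError(f"unknown band shape {self.shape!r}")
        return self.amplitude * line


@dataclass(frozen=True)
class BandLibrary:
    """Band lists per analyte plus the urine background template bands."""

    bands: Mapping[str, tuple[Band, ...]]

    def __post_init__(self) -> None:
        for name, bb in self.bands.items():
            if name != BACKGROUND and len(bb) < 4:
                raise ValueError(f"analyte {name!r} needs >= 4 bands")

    def __contains__(self, analyte: str) -> bool:
        return analyte in self.bands


def default_band_library() -> BandLibrary:
    """Plausible, overlapping band positions for the three analytes.

    Positions echo the indole bands of serotonin (759 cm^-1 ring
    breathing), the catechol bands of dopamine and epinephrine, a shared
    catechol band at 1480 cm^-1 and a shared aromatic band at 1600 cm^-1.
    The urine background is dominated by the urea C-N stretch near
    1003 cm^-1 with broad underlying humps.  Positions are configurable;
    the pipeline only needs distinguishable, partially overlapping
    references.
    """
    L, G = "lorentzian", "gaussian"
    return BandLibrary(
        {
            "serotonin": (
                Band(759, 18, 1.00, L),
                Band(1134, 16, 0.45, L),
                Band(1237, 18, 0.50, L),
                Band(1358, 20, 0.60, L),
                Band(1547, 20, 0.55, L),
                Band(1600, 22, 0.30, L),
            ),
            "dopamine": (
                Band(791, 18, 0.80, L),
                Band(1269, 18, 0.70, L),
                Band(1334, 20, 1.00, L),
                Band(1480, 22, 0.60, L),
                Band(1600, 22, 0.30, L),
            ),
            "epinephrine": (
                Band(713, 18, 0.70, L),
                Band(860, 18, 0.50, L),
                Band(1448, 20, 1.00, L),
                Band(1480, 22, 0.60, L),
                Band(1600, 22, 0.30, L),
            ),
            BACKGROUND: (
                Band(680, 25, 0.50, L),
                Band(760, 60, 0.45, G),  # broad hump over the indole region
                Band(846, 25, 0.40, L),
                Band(1003, 14, 1.00, L),
                Band(1250, 120, 0.35, G),
                Band(1340, 55, 0.30, G),  # overlaps the catechol bands
                Band(1450, 100, 0.30, G),
                Band(1650, 90, 0.25, G),
            ),
        }
    )


@dataclass(frozen=True)
class ResponseModel:
    """Concentration -> signal response and the measurement noise model.

    ``amplitude(c) = a_max * c / (k_half + c)`` is monotone increasing and
    bounded by ``a_max``; ``k_half`` (uM) is the half-saturation
    concentration.  ``scale_jitter_sigma`` is the lognormal sigma of the
    per-measurement multiplicative intensity scale; ``noise_sigma`` the
    additive Gaussian noise scale (absolute, on the unit-peak reference
    scale); ``baseline_coeffs`` a low-order polynomial drift evaluated on
    the normalized grid position in [0, 1]; ``background_amplitude``
    scales the urine template added to urine-medium spectra.
    """

    a_max: float = 10.0
    k_half: float = 10.0
    scale_jitter_sigma: float = 0.1
    noise_sigma: float = 0.05
    baseline_coeffs: tuple[float, ...] = (0.4, 0.3)
    background_amplitude: float = 5.0
    background_jitter_sigma: float = 0.5
    background_band_jitter_sigma: float = 0.4
    background_sample_sigma: float = 0.4
    competitive: bool = False

    def amplitude(self, c: float, total_c: float | None = None) -> float:
        """Signal amplitude at concentration ``c`` (uM).

        In competitive mode the half-saturation term sees the summed
        concentration of all analytes (simple competitive Langmuir).
        """
        if c < 0:
            raise ValueError("concentration must be >= 0")
        denom_c = total_c if (self.competitive and total_c is not None) else c
        return self.a_max * c / (self.k_half + denom_c)

    @staticmethod
    def linear(slope: float = 1.0, **kw) -> "ResponseModel":
        """A response that is linear to machine precision over 0-9 uM
        (huge k_half), for saturation-free fixtures."""
        big = 1e9
        return ResponseModel(a_max=slope * big, k_half=big, **kw)


def _clean_profile(analyte: str, lib: BandLibrary, w: np.ndarray) -> np.ndarray:
    bands = lib.bands.get(analyte)
    if not bands:
        raise ValueError(f"unknown analyte {analyte!r}")
    y = np.zeros_like(w)
    for b in bands:
        y += b.profile(w)
    return y


def make_reference(
    analyte: str, lib: BandLibrary | None = None, wavenumbers: np.ndarray | None = None
) -> Spectrum:
    """Noise-free unit-peak reference spectrum of one analyte, normalized."""
    lib = lib or default_band_library()
    w = default_grid() if wavenumbers is None else np.asarray(wavenumbers, float)
    y = _clean_profile(analyte, lib, w)
    if y.max() <= 0:
        raise ValueError(f"analyte {analyte!r} has no signal on the grid")
    return Spectrum(w, y / y.max(), SpectrumState.NORMALIZED)


def make_mixture(
    conc_epi: float,
    conc_da: float,
    conc_5ht: float,
    medium: str | Medium = Medium.WATER,
    model: ResponseModel | None = None,
    lib: BandLibrary | None = None,
    seed: int = 0,
    wavenumbers: np.ndarray | None = None,
    background_level: float = 1.0,
) -> Spectrum:
    """One raw mixture spectrum at the given spiked concentrations (uM).

    ``background_level`` multiplies the urine background; it models the
    sample-to-sample variation of endogenous urine composition (each
    sample carries its own level, constant across its replicates).
    """
    model = model or ResponseModel()
    lib = lib or default_band_library()
    medium = Medium(medium)
    w = default_grid() if wavenumbers is None else np.asarray(wavenumbers, float)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))

    concs = {
        "epinephrine": float(conc_epi),
        "dopamine": float(conc_da),
        "serotonin": float(conc_5ht),
    }
    if min(concs.values()) < 0:
        raise ValueError("concentrations must be >= 0")
    total_c = sum(concs.values())

    signal = np.zeros_like(w)
    for analyte, c in concs.items():
        if c > 0:
            ref = _clean_profile(analyte, lib, w)
            ref = ref / ref.max()
            signal += model.amplitude(c, total_c) * ref

    if medium is Medium.URINE:
        # background shape varies measurement to measurement: each band
        # carries its own lognormal scale, like fluctuating metabolite
        # levels, on top of an overall background scale
        bands = lib.bands[BACKGROUND]
        band_scales = np.exp(
            rng.normal(0.0, model.background_band_jitter_sigma, size=len(bands))
        )
        bg = np.zeros_like(w)
        for band, bs in zip(bands, band_scales):
            bg += bs * band.profile(w)
        template_max = _clean_profile(BACKGROUND, lib, w).max()
        bg = bg / template_max
        bg_scale = (
            model.background_amplitude
            * float(background_level)
            * float(np.exp(rng.normal(0.0, model.background_jitter_sigma)))
        )
        signal = signal + bg_scale * bg

    # the per-measurement intensity scale multiplies the whole measurement
    # (signal, baseline and noise alike), so per-spectrum min-max
    # normalization cancels it exactly — the reason normalization is part
    # of the processing chain
    jitter = float(np.exp(rng.normal(0.0, model.scale_jitter_sigma)))
    x = np.linspace(0.0, 1.0, w.size)
    if model.baseline_coeffs:
        drift = np.polynomial.polynomial.polyval(x, model.baseline_coeffs)
    else:
        drift = np.zeros_like(w)
    noise = rng.normal(0.0, model.noise_sigma, size=w.size) if model.noise_sigma > 0 else 0.0
    y = jitter * (signal + drift + noise)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities generated")
    return Spectrum(w, y, SpectrumState.RAW)


def make_dataset(
    manifest: Iterable[SampleManifest],
    model: ResponseModel | None = None,
    lib: BandLibrary | None = None,
    seed: int = 0,
    wavenumbers: np.ndarray | None = None,
) -> LabelledDataset:
    """Generate all replicate spectra of a manifest; targets are the
    serotonin concentrations.  Per-spectrum seeds are derived from the
    master seed by counter, so the dataset is reproducible spectrum by
    spectrum."""
    model = model or ResponseModel()
    spectra: list[Spectrum] = []
    targets: list[float] = []
    ids: list[str] = []
    counter = 0
    for row_idx, row in enumerate(manifest):
        # each sample carries its own endogenous background level, fixed
        # across its replicate measurements
        row_rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 0x5A17, row_idx])
        )
        bg_level = float(
            np.exp(row_rng.normal(0.0, model.background_sample_sigma))
        )
        for _ in range(row.n_spectra):
            ss = np.random.SeedSequence([int(seed), counter])
            sub_seed = int(ss.generate_state(1)[0] % (2**31))
            spectra.append(
                make_mixture(
                    row.conc_epi,
                    row.conc_da,
                    row.conc_5ht,
                    row.medium,
                    model,
                    lib,
                    seed=sub_seed,
                    wavenumbers=wavenumbers,
                    background_level=bg_level,
                )
            )
            targets.append(row.conc_5ht)
            ids.append(row.sample_id)
            counter += 1
    return LabelledDataset(spectra, np.asarray(targets), np.asarray(ids, object))
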