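"""Baseline-correct and normalize a synthetic SERS spectrum.

Generates one urine-medium mixture spectrum, removes its baseline with
asymmetric least squares (lambda=1000, p=0.1, 10 iterations), crops to the
300-2000 cm^-1 analysis window and min-max normalizes.
"""

import numpy as np

from sersquant.preprocess import ALSParams, als_baseline, minmax_normalize
from sersquant.spectra import crop_range, Spectrum, SpectrumState
from sersquant.synth import make_mixture

spectrum = make_mixture(conc_epi=2.0, conc_da=1.0, conc_5ht=3.0,
                        medium="urine", seed=7)
print(f"raw spectrum: {len(spectrum)} points, "
      f"max intensity {spectrum.intensities.max():.2f} (arb. units)")

baseline, corrected = als_baseline(spectrum.intensities, ALSParams())
print(f"ALS baseline spans {baseline.min():.2f} .. {baseline.max():.2f}; "
      f"corrected signal peaks at {corrected.max():.2f}")

cropped = crop_range(
    Spectrum(spectrum.wavenumbers, corrected, SpectrumState.BASELINED)
)
normalized = minmax_normalize(cropped.intensities)
print(f"cropped to {len(cropped)} points in [300, 2000] cm^-1; "
      f"normalized range [{normalized.min():.0f}, {normalized.max():.0f}]")
# The 842-point, unit-range vector is what the quantification models consume.
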