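"""Core domain types for SERS spectra and the study's dataset design.

A SERS measurement is a 1-D spectrum: intensity versus Raman shift
(wavenumber, cm^-1).  The study design couples each spectrum to a sample
with known spiked neurotransmitter concentrations (epinephrine, dopamine,
serotonin, in uM) measured either in water or in a lyophilized-urine
medium.  Serotonin is the regression target throughout.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumState",
    "Spectrum",
    "SampleManifest",
    "LabelledDataset",
    "Medium",
    "SplitRole",
    "SplitAssignment",
    "default_grid",
    "study_manifest",
    "read_spectra",
    "write_spectra",
    "crop_range",
    "split_dataset",
    "CROP_LO",
    "CROP_HI",
]

#: Raman-shift window retained for analysis (cm^-1).
CROP_LO = 300.0
CROP_HI = 2000.0

#: Grid spacing chosen so that exactly 842 of the 937 acquisition points
#: fall inside [300, 2000] cm^-1, with a point at exactly 300.0.
GRID_STEP = 1700.0 / 841.0
GRID_N = 937
_GRID_BELOW = 49  # points below 300 cm^-1 (grid starts near 201 cm^-1)


class SpectrumState(str, enum.Enum):
    """Processing state a spectrum can be in."""

    RAW = "raw"
    BASELINED = "baselined"
    NORMALIZED = "normalized"
    SG_DERIVATIVE = "sg_derivative"
    DENOISED = "denoised"


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum on a strictly increasing, uniform wavenumber grid.

    Parameters
    ----------
    wavenumbers
        Raman shifts in cm^-1, strictly increasing, uniformly spaced.
    intensities
        Intensities; arbitrary units when raw, in [0, 1] once normalized.
    state
        Processing state flag (see :class:`SpectrumState`).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    state: SpectrumState = SpectrumState.RAW

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)
        if w.ndim != 1 or y.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if w.size != y.size:
            raise ValueError(
                f"length mismatch: {w.size} wavenumbers vs {y.size} intensities"
            )
        if w.size >= 2:
            d = np.diff(w)
            if np.any(d <= 0):
                raise ValueError("wavenumbers must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
                raise ValueError("wavenumber spacing must be uniform")
        if self.state is SpectrumState.NORMALIZED:
            if y.size and (y.min() < -1e-12 or y.max() > 1 + 1e-12):
                raise ValueError("normalized intensities must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_intensities(
        self, y: np.ndarray, state: SpectrumState | None = None
    ) -> "Spectrum":
        return Spectrum(self.wavenumbers, np.asarray(y, float), state or self.state)


class SplitRole(str, enum.Enum):
    REPEAT = "repeat"
    HELD_OUT_VALIDATION = "held_out_validation"
    HELD_OUT_TEST = "held_out_test"


class Medium(str, enum.Enum):
    WATER = "water"
    URINE = "urine"


@dataclass(frozen=True)
class SampleManifest:
    """One sample row of the dataset design: spiked concentrations (uM),
    medium, number of replicate spectra and its role in the data split."""

    sample_id: str
    conc_epi: float
    conc_da: float
    conc_5ht: float
    medium: Medium
    n_spectra: int
    split_role: SplitRole = SplitRole.REPEAT

    def __post_init__(self) -> None:
        for name in ("conc_epi", "conc_da", "conc_5ht"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_spectra < 0:
            raise ValueError("n_spectra must be >= 0")


class SplitAssignment(str, enum.Enum):
    TRAIN = "train"
    VALIDATION = "validation"
    TEST = "test"


@dataclass
class LabelledDataset:
    """Parallel arrays of spectra, serotonin targets (uM) and sample ids."""

    spectra: list[Spectrum]
    targets: np.ndarray
    sample_ids: np.ndarray
    split_assignment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n = len(self.spectra)
        if self.targets.size != n or self.sample_ids.size != n:
            raise ValueError("spectra, targets and sample_ids must be parallel")
        if self.split_assignment is not None:
            self.split_assignment = np.asarray(self.split_assignment, dtype=object)
            if self.split_assignment.size != n:
                raise ValueError("split_assignment length mismatch")

    def __len__(self) -> int:
        return len(self.spectra)

    def intensity_matrix(self) -> np.ndarray:
        """Stack intensities into an (n_spectra, n_points) matrix."""
        return np.stack([s.intensities for s in self.spectra])

    def subset(self, idx: np.ndarray | Sequence[int]) -> "LabelledDataset":
        idx = np.asarray(idx, dtype=int)
        return LabelledDataset(
            [self.spectra[i] for i in idx],
            self.targets[idx],
            self.sample_ids[idx],
            None if self.split_assignment is None else self.split_assignment[idx],
        )

    def split(self, which: SplitAssignment | str) -> "LabelledDataset":
        if self.split_assignment is None:
            raise ValueError("dataset has no split assignment")
        which = SplitAssignment(which)
        idx = np.flatnonzero([a == which for a in self.split_assignment])
        return self.subset(idx)


def default_grid() -> np.ndarray:
    """The 937-point acquisition grid (cm^-1).

    Spacing is 1700/841 cm^-1 so that exactly 842 points fall in the
    analysis window [300, 2000] cm^-1, with a grid point at exactly 300.0.
    """
    k = np.arange(GRID_N) - _GRID_BELOW
    return CROP_LO + k * GRID_STEP


# Per-sample design: (epi, da, 5-HT in uM, water n, urine n).  Sample U is
# the blank background; only its urine measurements enter the dataset (its
# water blanks are not consumed by any stage and are omitted here).
_STUDY_DESIGN = {
    "A": (2, 0, 0, 25, 22),
    "B": (0, 2, 0, 17, 21),
    "C": (0, 0, 2, 22, 22),
    "D": (3, 0, 7, 0, 26),
    "E": (0, 8, 3, 0, 28),
    "F": (7, 3, 0, 0, 21),
    "G": (3, 2, 7, 99, 26),
    "H": (1, 1, 9, 38, 22),
    "I": (2, 8, 3, 37, 22),
    "J": (6, 9, 1, 93, 23),
    "K": (7, 3, 2, 11, 23),
    "L": (9, 6, 4, 11, 21),
    "M": (3, 3, 3, 11, 0),
    "U": (0, 0, 0, 0, 41),
}

_ROLES = {
    "D": SplitRole.HELD_OUT_TEST,
    "E": SplitRole.HELD_OUT_TEST,
    "F": SplitRole.HELD_OUT_VALIDATION,
}


def study_manifest(medium: str | Medium | None = None) -> list[SampleManifest]:
    """The study's sample design as a list of manifest rows.

    Parameters
    ----------
    medium
        Restrict to ``"water"`` or ``"urine"`` rows; ``None`` returns both.
        Held-out roles (D, E -> test; F -> validation) apply to urine rows;
        all water rows are repeats.
    """
    if medium is not None:
        medium = Medium(medium)
    rows: list[SampleManifest] = []
    for sid, (epi, da, ht5, n_water, n_urine) in _STUDY_DESIGN.items():
        for med, n in ((Medium.WATER, n_water), (Medium.URINE, n_urine)):
            if n == 0:
                continue
            if medium is not None and med is not medium:
                continue
            role = _ROLES.get(sid, SplitRole.REPEAT) if med is Medium.URINE else SplitRole.REPEAT
            rows.append(
                SampleManifest(sid, float(epi), float(da), float(ht5), med, n, role)
            )
    return rows


def read_spectra(path: str | Path, format: str = "delimited_table") -> list[Spectrum]:
    """Read spectra from a delimited table or a matrix container.

    The delimited table has a header ``wavenumber,<id1>,<id2>,...`` and one
    row per grid point.  The matrix container is an ``.npz`` with arrays
    ``wavenumbers`` (m,) and ``intensities`` (n, m).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited_table":
        df = pd.read_csv(path)
        try:
            mat = df.to_numpy(dtype=float)
        except (ValueError, TypeError):
            for col in df.columns:
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna()
                if bad.any():
                    row = int(bad.idxmax())
                    raise ValueError(
                        f"malformed numeric field in {path.name} at row {row}, "
                        f"column {col!r}: {df[col][row]!r}"
                    ) from None
            raise
        w = mat[:, 0]
        order = np.argsort(w, kind="stable")
        w = w[order]
        if np.any(np.diff(w) == 0):
            raise ValueError(f"duplicate wavenumbers in {path.name}")
        return [
            Spectrum(w, mat[order, j], SpectrumState.RAW) for j in range(1, mat.shape[1])
        ]
    elif format == "matrix_container":
        with np.load(path) as z:
            w = np.asarray(z["wavenumbers"], float)
            mat = np.asarray(z["intensities"], float)
        order = np.argsort(w, kind="stable")
        w = w[order]
        if np.any(np.diff(w) == 0):
            raise ValueError(f"duplicate wavenumbers in {path.name}")
        return [Spectrum(w, row[order], SpectrumState.RAW) for row in mat]
    raise ValueError(f"unknown format {format!r}")


def write_spectra(
    path: str | Path, spectra: Sequence[Spectrum], format: str = "delimited_table"
) -> None:
    """Write spectra sharing one grid; inverse of :func:`read_spectra`."""
    path = Path(path)
    w = spectra[0].wavenumbers
    for s in spectra[1:]:
        if not np.array_equal(s.wavenumbers, w):
            raise ValueError("all spectra must share one wavenumber grid")
    mat = np.stack([s.intensities for s in spectra])
    if format == "delimited_table":
        cols = {"wavenumber": w}
        for j, s in enumerate(spectra):
            cols[f"s{j}"] = mat[j]
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    elif format == "matrix_container":
        np.savez(path, wavenumbers=w, intensities=mat)
    else:
        raise ValueError(f"unknown format {format!r}")


def crop_range(s: Spectrum, lo: float = CROP_LO, hi: float = CROP_HI) -> Spectrum:
    """Restrict a spectrum to the closed wavenumber interval [lo, hi].

    Bounds are applied with a 1e-9 relative tolerance so grid points that
    land on a bound up to floating-point rounding are kept.
    """
    if lo >= hi:
        raise ValueError("require lo < hi")
    tol = 1e-9 * max(abs(lo), abs(hi), 1.0)
    mask = (s.wavenumbers >= lo - tol) & (s.wavenumbers <= hi + tol)
    if not mask.any():
        raise ValueError(f"no grid points in [{lo}, {hi}]")
    return Spectrum(s.wavenumbers[mask], s.intensities[mask], s.state)


def split_dataset(
    ds: LabelledDataset,
    manifest: Iterable[SampleManifest],
    val_fraction: float = 0.1,
    seed: int = 0,
) -> LabelledDataset:
    """Assign train/validation/test roles following the study's split rules.

    Held-out test samples go to the test set and held-out validation
    samples to the validation set, in full.  The remaining "repeat"
    spectra are shuffled (seeded) and split, with a validation count of
    ``ceil(val_fraction * n_repeat)`` — the rounding that reproduces the
    printed 218/46/54 partition of the 318 urine spectra.
    """
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must be in (0, 1)")
    roles: dict[str, SplitRole] = {}
    for row in manifest:
        prev = roles.get(row.sample_id)
        if prev is not None and prev is not row.split_role:
            # water/urine rows of one sample may differ; prefer held-out role
            if row.split_role is not SplitRole.REPEAT:
                roles[row.sample_id] = row.split_role
        else:
            roles[row.sample_id] = row.split_role
    unknown = set(ds.sample_ids) - set(roles)
    if unknown:
        raise ValueError(f"sample ids not in manifest: {sorted(unknown)}")

    n = len(ds)
    assignment = np.empty(n, dtype=object)
    repeat_idx = []
    for i, sid in enumerate(ds.sample_ids):
        role = roles[sid]
        if role is SplitRole.HELD_OUT_TEST:
            assignment[i] = SplitAssignment.TEST
        elif role is SplitRole.HELD_OUT_VALIDATION:
            assignment[i] = SplitAssignment.VALIDATION
        else:
            repeat_idx.append(i)
    repeat_idx = np.asarray(repeat_idx, dtype=int)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(repeat_idx.size)
    n_val = math.ceil(val_fraction * repeat_idx.size)
    val_pick = repeat_idx[perm[:n_val]]
    train_pick = repeat_idx[perm[n_val:]]
    assignment[val_pick] = SplitAssignment.VALIDATION
    assignment[train_pick] = SplitAssignment.TRAIN
    return LabelledDataset(ds.spectra, ds.targets, ds.sample_ids, assignment)
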