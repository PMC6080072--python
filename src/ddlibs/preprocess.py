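"""Replicate averaging and per-spectrum normalization.

Five normalization schemes are provided, each dividing a spectrum by one
per-spectrum scalar:

========== ==================================================
mean            mean intensity
vector_norm     Euclidean norm
area            trapezoidal integral over the wavelength axis
height          maximum intensity
reference_line  intensity at a fixed emission line (e.g. C I 247.86 nm)
========== ==================================================

All five are homogeneous of degree zero: scaling a spectrum by any
positive factor leaves the normalized result unchanged, which is what
cancels shot-to-shot laser-energy fluctuation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import Spectrum, SpectraDataset

__all__ = [
    "NormalizationMethod",
    "NORMALIZATION_NAMES",
    "CARBON_REFERENCE_NM",
    "average_replicates",
    "normalize",
]

NORMALIZATION_NAMES = ("mean", "vector_norm", "area", "height", "reference_line")

#: Default reference emission line: the C I line commonly used in LIBS work.
CARBON_REFERENCE_NM = 247.86


@dataclass(frozen=True)
class NormalizationMethod:
    """A named normalization scheme.

    ``reference_wavelength`` is required exactly when ``name`` is
    ``"reference_line"``.
    """

    name: str
    reference_wavelength: float | None = None

    def __post_init__(self) -> None:
        if self.name not in NORMALIZATION_NAMES:
            raise ValueError(
                f"unknown normalization {self.name!r}; "
                f"choose from {NORMALIZATION_NAMES}"
            )
        if self.name == "reference_line" and self.reference_wavelength is None:
            raise ValueError("reference_line normalization needs a wavelength")
        if self.name != "reference_line" and self.reference_wavelength is not None:
            raise ValueError(
                f"reference_wavelength is only valid for reference_line, "
                f"not {self.name!r}"
            )


def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spectra on identical axes."""
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    axis = spectra[0].wavelengths
    for i, s in enumerate(spectra[1:], start=1):
        if s.wavelengths.shape != axis.shape or not np.array_equal(
            s.wavelengths, axis
        ):
            raise ValueError(f"replicate {i} has a different wavelength axis")
    mean = np.mean([s.intensities for s in spectra], axis=0)
    return Spectrum(axis.copy(), mean)


def _reference_index(wavelengths: np.ndarray, target: float) -> int:
    idx = int(np.argmin(np.abs(wavelengths - target)))
    # tolerance: half the local grid step
    if idx == 0:
        step = wavelengths[1] - wavelengths[0] if wavelengths.size > 1 else np.inf
    elif idx == wavelengths.size - 1:
        step = wavelengths[-1] - wavelengths[-2]
    else:
        step = min(
            wavelengths[idx] - wavelengths[idx - 1],
            wavelengths[idx + 1] - wavelengths[idx],
        )
    if abs(wavelengths[idx] - target) > step / 2 + 1e-12:
        raise ValueError(
            f"reference line {target} nm not on axis "
            f"(nearest grid point {wavelengths[idx]} nm)"
        )
    return idx


def _divisors(ds: SpectraDataset, method: NormalizationMethod) -> np.ndarray:
    x = ds.intensities
    if method.name == "mean":
        return x.mean(axis=1)
    if method.name == "vector_norm":
        return np.linalg.norm(x, axis=1)
    if method.name == "area":
        return np.trapezoid(x, ds.wavelengths, axis=1)
    if method.name == "height":
        return x.max(axis=1)
    idx = _reference_index(ds.wavelengths, method.reference_wavelength)
    return x[:, idx]


def normalize(ds: SpectraDataset, method: NormalizationMethod) -> SpectraDataset:
    """Divide each spectrum by its per-spectrum scalar; concentrations pass
    through untouched."""
    if not np.all(np.isfinite(ds.intensities)):
        raise ValueError("non-finite intensities")
    div = _divisors(ds, method)
    bad = np.flatnonzero(div <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive {method.name} divisor for sample "
            f"{ds.sample_ids[bad[0]]!r}"
        )
    return ds.with_intensities(ds.intensities / div[:, None])
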