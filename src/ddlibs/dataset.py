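"""Spectral dataset containers and tabular I/O.

Spectra are stored as a shared, strictly increasing wavelength axis (nm)
plus an ``n_samples x n_wavelengths`` intensity matrix.  Reference analyte
concentrations (g/100 g) ride along as an optional per-sample vector.

Two plain-text dialects are supported:

* ``wide``  -- first column is the wavelength, one further column per sample.
* ``long``  -- three columns ``(sample_id, wavelength, intensity)``.

Files are UTF-8 CSV with ``.`` decimal separator; lines starting with ``#``
are comments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraDataset",
    "SpectraParseError",
    "read_spectra_table",
    "write_spectra_table",
    "read_concentration_table",
    "write_concentration_table",
    "extract_region",
    "split_dataset",
]


class SpectraParseError(ValueError):
    """Raised when a spectra table fails validation."""


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum: one wavelength axis and one intensity vector."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1-D")
        if wl.shape != it.shape:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {it.size} intensities"
            )
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(it)):
            raise ValueError("non-finite values in spectrum")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass
class SpectraDataset:
    """Sample x wavelength intensity matrix with a shared axis.

    ``concentrations`` may be ``None`` for prediction-only sets.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    concentrations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelength axis must be 1-D")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if self.intensities.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"matrix has {self.intensities.shape[1]} columns but axis has "
                f"{self.wavelengths.size} wavelengths"
            )
        n = self.intensities.shape[0]
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:03d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if self.concentrations is not None:
            c = np.asarray(self.concentrations, dtype=float)
            if c.shape != (n,):
                raise ValueError("concentrations length does not match samples")
            if np.any(c < 0):
                raise ValueError("concentrations must be non-negative")
            self.concentrations = c

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.intensities[i])

    def take(self, indices: Sequence[int]) -> "SpectraDataset":
        """Row subset preserving the given order."""
        idx = np.asarray(indices, dtype=int)
        conc = None if self.concentrations is None else self.concentrations[idx]
        return SpectraDataset(
            wavelengths=self.wavelengths.copy(),
            intensities=self.intensities[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            concentrations=conc,
        )

    def with_intensities(self, matrix: np.ndarray) -> "SpectraDataset":
        conc = None if self.concentrations is None else self.concentrations.copy()
        return SpectraDataset(
            wavelengths=self.wavelengths.copy(),
            intensities=np.asarray(matrix, dtype=float),
            sample_ids=list(self.sample_ids),
            concentrations=conc,
        )

    def equals(self, other: "SpectraDataset", atol: float = 0.0) -> bool:
        if self.sample_ids != other.sample_ids:
            return False
        if not np.allclose(self.wavelengths, other.wavelengths, atol=atol, rtol=0):
            return False
        if not np.allclose(self.intensities, other.intensities, atol=atol, rtol=0):
            return False
        a, b = self.concentrations, other.concentrations
        if (a is None) != (b is None):
            return False
        if a is not None and not np.allclose(a, b, atol=atol, rtol=0):
            return False
        return True


def _read_csv(source) -> pd.DataFrame:
    try:
        return pd.read_csv(source, comment="#", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise SpectraParseError(f"could not parse table: {exc}") from exc


def read_spectra_table(
    source: str | Path | io.TextIOBase,
    layout: str = "wide",
    concentrations: str | Path | None = None,
) -> SpectraDataset:
    """Read a spectra table in ``wide`` or ``long`` layout.

    ``concentrations`` optionally points at a two-column table
    ``(sample_id, concentration_g_per_100g)`` keyed by sample id.
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"unknown layout {layout!r}")
    df = _read_csv(source)
    if df.isna().any().any():
        row = int(df[df.isna().any(axis=1)].index[0])
        raise SpectraParseError(f"missing or non-numeric cell in data row {row}")

    if layout == "wide":
        wl_col = df.columns[0]
        try:
            wl = df[wl_col].astype(float).to_numpy()
        except ValueError as exc:
            raise SpectraParseError(f"non-numeric wavelength: {exc}") from exc
        sample_ids = [str(c) for c in df.columns[1:]]
        try:
            mat = df[df.columns[1:]].astype(float).to_numpy().T
        except ValueError as exc:
            raise SpectraParseError(f"non-numeric intensity: {exc}") from exc
        order = np.argsort(wl, kind="stable")
        wl = wl[order]
        dup = np.flatnonzero(np.diff(wl) == 0)
        if dup.size:
            raise SpectraParseError(f"duplicated wavelength {wl[dup[0]]!r}")
        if mat.size:
            mat = mat[:, order]
        else:
            mat = np.empty((0, wl.size))
            sample_ids = []
    else:
        if df.shape[1] != 3:
            raise SpectraParseError(
                f"long layout needs 3 columns, found {df.shape[1]}"
            )
        sid_col, wl_col, it_col = df.columns
        sids = df[sid_col].astype(str)
        try:
            wls = df[wl_col].astype(float)
            its = df[it_col].astype(float)
        except ValueError as exc:
            raise SpectraParseError(f"non-numeric cell: {exc}") from exc
        dup_mask = df.duplicated(subset=[sid_col, wl_col], keep=False)
        if dup_mask.any():
            r = df[dup_mask].iloc[0]
            raise SpectraParseError(
                f"duplicate (sample, wavelength) pair ({r[sid_col]}, {r[wl_col]})"
            )
        sample_ids = list(dict.fromkeys(sids))  # first-appearance order
        wl = np.unique(wls.to_numpy())
        pivot = df.pivot_table(
            index=sid_col, columns=wl_col, values=it_col, aggfunc="first"
        )
        if pivot.isna().any().any():
            missing = pivot.columns[pivot.isna().any(axis=0)][0]
            raise SpectraParseError(
                f"ragged long table: wavelength {missing} missing for some samples"
            )
        pivot = pivot.reindex(index=sample_ids, columns=wl)
        mat = pivot.to_numpy(dtype=float)

    ds = SpectraDataset(wavelengths=wl, intensities=mat, sample_ids=sample_ids)
    if concentrations is not None:
        conc_map = read_concentration_table(concentrations)
        missing = [s for s in ds.sample_ids if s not in conc_map]
        if missing:
            raise SpectraParseError(
                f"no concentration for sample(s) {missing[:3]}"
            )
        ds.concentrations = np.array([conc_map[s] for s in ds.sample_ids])
        ds.__post_init__()
    return ds


def write_spectra_table(
    ds: SpectraDataset, target: str | Path | io.TextIOBase, layout: str = "wide"
) -> None:
    """Write a dataset so that :func:`read_spectra_table` round-trips it."""
    if layout == "wide":
        data = {"wavelength_nm": ds.wavelengths}
        for i, sid in enumerate(ds.sample_ids):
            data[sid] = ds.intensities[i]
        pd.DataFrame(data).to_csv(target, index=False)
    elif layout == "long":
        n, p = ds.intensities.shape
        pd.DataFrame(
            {
                "sample_id": np.repeat(ds.sample_ids, p),
                "wavelength_nm": np.tile(ds.wavelengths, n),
                "intensity": ds.intensities.ravel(),
            }
        ).to_csv(target, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_concentration_table(source: str | Path | io.TextIOBase) -> dict[str, float]:
    df = _read_csv(source)
    if df.shape[1] < 2:
        raise SpectraParseError("concentration table needs 2 columns")
    sid, conc = df.columns[0], df.columns[1]
    try:
        values = df[conc].astype(float)
    except ValueError as exc:
        raise SpectraParseError(f"non-numeric concentration: {exc}") from exc
    ids = df[sid].astype(str)
    if ids.duplicated().any():
        raise SpectraParseError(
            f"duplicate sample id {ids[ids.duplicated()].iloc[0]!r}"
        )
    return dict(zip(ids, values))


def write_concentration_table(
    ds: SpectraDataset, target: str | Path | io.TextIOBase
) -> None:
    if ds.concentrations is None:
        raise ValueError("dataset carries no concentrations")
    pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "concentration_g_per_100g": ds.concentrations,
        }
    ).to_csv(target, index=False)


def extract_region(ds: SpectraDataset, lo: float, hi: float) -> SpectraDataset:
    """Keep columns with ``lo <= wavelength <= hi`` (closed interval)."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    mask = (ds.wavelengths >= lo) & (ds.wavelengths <= hi)
    if not mask.any():
        raise ValueError(
            f"window [{lo}, {hi}] nm selects no columns on axis "
            f"[{ds.wavelengths[0]}, {ds.wavelengths[-1]}] nm"
        )
    conc = None if ds.concentrations is None else ds.concentrations.copy()
    return SpectraDataset(
        wavelengths=ds.wavelengths[mask],
        intensities=ds.intensities[:, mask].copy(),
        sample_ids=list(ds.sample_ids),
        concentrations=conc,
    )


def split_dataset(
    ds: SpectraDataset, n_first: int, seed: int
) -> tuple[SpectraDataset, SpectraDataset]:
    """Disjoint, exhaustive random split into ``n_first`` and the rest.

    Within each part the parent's sample order is preserved, so downstream
    cross-validation folds are reproducible.
    """
    n = ds.n_samples
    if not 0 < n_first < n:
        raise ValueError(f"n_first must be in (0, {n}), got {n_first}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=n_first, replace=False)
    in_first = np.zeros(n, dtype=bool)
    in_first[chosen] = True
    first = ds.take(np.flatnonzero(in_first))
    second = ds.take(np.flatnonzero(~in_first))
    return first, second
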