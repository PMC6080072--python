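"""Synthetic LIBS-like spectrum generator.

Emulates the statistical structure the calibration method targets: a
concentration-dependent potassium doublet (766.57 / 769.95 nm) on a
512-point grid over 751.90-774.86 nm, degraded by per-sample peak shift,
peak broadening, multiplicative laser-energy fluctuation, a sloped
baseline, additive noise, and optional concentration-independent
interferent lines.  Peak amplitude saturates as ``c / (1 + s c)`` to mimic
self-absorption, so intensity tracks concentration "accordingly but not
linearly".

All randomness flows through a single seed; a fixed seed yields a
bit-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
import yaml

from .dataset import Spectrum, SpectraDataset

__all__ = [
    "SimulationConfig",
    "profile_value",
    "simulate_spectrum",
    "simulate_dataset",
    "stressed_config",
    "clean_config",
]

GRID_LO_NM = 751.90
GRID_HI_NM = 774.86
GRID_POINTS = 512
PEAK_CENTERS_NM = (766.57, 769.95)
CONCENTRATION_RANGE = (0.415, 0.815)  # g / 100 g


def profile_value(offset: float, fwhm: float, kind: str = "lorentzian"):
    """Unit-amplitude line profile at ``offset`` nm from the center.

    Lorentzian ``1 / (1 + (2 x / fwhm)^2)`` or Gaussian
    ``exp(-4 ln2 (x / fwhm)^2)``; both reach 0.5 at ``offset = fwhm / 2``.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    x = np.asarray(offset, dtype=float)
    if kind == "lorentzian":
        return 1.0 / (1.0 + (2.0 * x / fwhm) ** 2)
    if kind == "gaussian":
        return np.exp(-4.0 * np.log(2.0) * (x / fwhm) ** 2)
    raise ValueError(f"unknown profile kind {kind!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults mirror the potassium study
    geometry with every degradation switched off."""

    grid_lo: float = GRID_LO_NM
    grid_hi: float = GRID_HI_NM
    n_points: int = GRID_POINTS
    peak_centers: tuple[float, ...] = PEAK_CENTERS_NM
    peak_fwhms: tuple[float, ...] = (0.25, 0.25)
    peak_amplitudes: tuple[float, ...] = (1000.0, 600.0)  # counts per g/100 g
    self_absorption: float = 0.0  # saturation constant s >= 0
    shift_sd: float = 0.0  # nm, shared across analyte peaks
    independent_shifts: bool = False
    broadening_sd: float = 0.0  # nm
    energy_fluctuation_sd: float = 0.0  # relative
    conserve_line_area: bool = False  # amplitude ~ 1/width under broadening
    baseline_level: float = 0.0  # counts
    baseline_level_sd: float = 0.0  # relative per-sample continuum jitter
    baseline_slope: float = 0.0  # counts per nm, about the grid midpoint
    noise_sd: float = 0.0  # counts
    interferents: tuple[tuple[float, float, float], ...] = ()  # (nm, counts, nm)
    interferent_amplitude_sd: float = 0.0  # relative per-sample jitter
    concentration_lo: float = CONCENTRATION_RANGE[0]
    concentration_hi: float = CONCENTRATION_RANGE[1]
    profile: str = "lorentzian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2 or not self.grid_lo < self.grid_hi:
            raise ValueError("grid must have >= 2 strictly increasing points")
        if len(self.peak_centers) != len(self.peak_fwhms) or len(
            self.peak_centers
        ) != len(self.peak_amplitudes):
            raise ValueError("peak centers/fwhms/amplitudes disagree in length")
        if any(f <= 0 for f in self.peak_fwhms):
            raise ValueError("peak FWHMs must be > 0")
        for name in ("self_absorption", "shift_sd", "broadening_sd",
                     "energy_fluctuation_sd", "noise_sd",
                     "interferent_amplitude_sd", "baseline_level_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.concentration_lo <= self.concentration_hi:
            raise ValueError("concentration range inverted")
        if self.profile not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown profile {self.profile!r}")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.grid_lo, self.grid_hi, self.n_points)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["peak_centers"] = list(d["peak_centers"])
        d["peak_fwhms"] = list(d["peak_fwhms"])
        d["peak_amplitudes"] = list(d["peak_amplitudes"])
        d["interferents"] = [list(t) for t in d["interferents"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("peak_centers", "peak_fwhms", "peak_amplitudes"):
            if key in d:
                d[key] = tuple(d[key])
        if "interferents" in d:
            d["interferents"] = tuple(tuple(t) for t in d["interferents"])
        return cls(**d)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float
) -> float:
    """Normal draw re-sampled (then clipped) to stay above ``lower``."""
    if sd == 0:
        return max(mean, lower)
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > lower:
            return v
    return lower + abs(rng.normal(0.0, sd))


def simulate_spectrum(
    concentration: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> Spectrum:
    """One spectrum at the given concentration; deterministic given the
    generator state."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    wl = cfg.wavelengths
    intensity = np.zeros_like(wl)

    shared_shift = rng.normal(0.0, cfg.shift_sd) if cfg.shift_sd else 0.0
    energy = _truncated_normal(rng, 1.0, cfg.energy_fluctuation_sd, 0.0)
    sat = concentration / (1.0 + cfg.self_absorption * concentration)

    for center, fwhm, amp in zip(
        cfg.peak_centers, cfg.peak_fwhms, cfg.peak_amplitudes
    ):
        shift = (
            rng.normal(0.0, cfg.shift_sd)
            if (cfg.independent_shifts and cfg.shift_sd)
            else shared_shift
        )
        width = _truncated_normal(rng, fwhm, cfg.broadening_sd, fwhm * 0.05)
        # Stark-type broadening redistributes the line but conserves its
        # integrated intensity, so the amplitude drops as the line widens
        amp_eff = amp * (fwhm / width) if cfg.conserve_line_area else amp
        intensity += (
            energy
            * amp_eff
            * sat
            * profile_value(wl - (center + shift), width, cfg.profile)
        )
    for center, amp, fwhm in cfg.interferents:
        # matrix lines: concentration-independent, but they ride the same
        # plasma, so they share the spectral shift; their strength varies
        # sample to sample (texture/brand differences) when jitter is on
        amp_i = amp * _truncated_normal(rng, 1.0, cfg.interferent_amplitude_sd, 0.0)
        intensity += energy * amp_i * profile_value(
            wl - (center + shared_shift), fwhm, cfg.profile
        )

    # continuum background is plasma emission too, so it scales with the
    # same shot energy; its level also varies with sample texture when
    # baseline jitter is on.  Only detector noise stays additive
    mid = 0.5 * (cfg.grid_lo + cfg.grid_hi)
    level = cfg.baseline_level * _truncated_normal(
        rng, 1.0, cfg.baseline_level_sd, 0.0
    )
    intensity += energy * (level + cfg.baseline_slope * (wl - mid))
    if cfg.noise_sd:
        intensity += rng.normal(0.0, cfg.noise_sd, size=wl.size)
    return Spectrum(wl, intensity)


def simulate_dataset(
    n_samples: int,
    cfg: SimulationConfig,
    concentrations: Sequence[float] | None = None,
) -> SpectraDataset:
    """Simulate ``n_samples`` spectra; concentrations drawn uniformly over
    the configured range unless given explicitly."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    if concentrations is None:
        conc = rng.uniform(cfg.concentration_lo, cfg.concentration_hi, n_samples)
    else:
        conc = np.asarray(concentrations, dtype=float)
        if conc.size != n_samples:
            raise ValueError("concentrations length does not match n_samples")
    rows = [simulate_spectrum(c, cfg, rng).intensities for c in conc]
    return SpectraDataset(
        wavelengths=cfg.wavelengths,
        intensities=np.vstack(rows),
        sample_ids=[f"S{i + 1:03d}" for i in range(n_samples)],
        concentrations=conc,
    )


def clean_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Noiseless linear regime: proportional analyte peaks over a fixed,
    concentration-independent background.

    The background (baseline plus interferent lines) matters: without it a
    perfectly proportional spectrum is erased by any degree-0 normalization,
    since every normalized spectrum collapses to the same shape.
    """
    base = SimulationConfig(
        baseline_level=50.0,
        baseline_slope=0.5,
        interferents=((752.8, 200.0, 0.3), (772.5, 120.0, 0.3)),
        seed=seed,
    )
    return replace(base, **overrides)


def stressed_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The degraded regime: shift 0.05 nm, broadening 0.05 nm, 10 % energy
    fluctuation, saturation, baseline, noise and two interferent lines."""
    base = SimulationConfig(
        peak_fwhms=(0.15, 0.15),  # near the instrument resolution limit
        shift_sd=0.05,
        broadening_sd=0.05,
        energy_fluctuation_sd=0.10,
        self_absorption=0.2,
        conserve_line_area=True,
        baseline_level=150.0,
        baseline_slope=0.5,
        noise_sd=0.25,  # post replicate-averaging detector noise
        interferents=((752.8, 200.0, 0.3), (772.5, 120.0, 0.3)),
        seed=seed,
    )
    return replace(base, **overrides)
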