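"""Spectra on a wavenumber grid: Gaussian broadening, normalization, overlap.

The x-axis is wavenumber (cm⁻¹) throughout; intensities are densities per
wavenumber, so a unit-area-normalized spectrum has units cm and the
overlap integral of two such spectra has units cm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "StickSpectrum",
    "broaden",
    "normalize_unit_area",
    "spectral_overlap",
    "read_spectrum",
    "write_spectrum",
    "read_sticks",
    "fwhm_to_sigma",
]

#: FWHM = 2·sqrt(2 ln 2)·sigma for a Gaussian line shape
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / _FWHM_PER_SIGMA


@dataclass(frozen=True)
class Spectrum:
    """Intensity per wavenumber on a strictly increasing grid (cm⁻¹)."""

    grid: np.ndarray
    intensity: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.grid.ndim != 1 or self.grid.shape != self.intensity.shape:
            raise ValueError("grid and intensity must be 1-D arrays of equal length")
        if self.grid.size < 2:
            raise ValueError("a spectrum needs at least two grid points")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.normalized and abs(self.area - 1.0) > 1e-9:
            raise ValueError("spectrum flagged normalized but area != 1")

    @property
    def area(self) -> float:
        """Trapezoid area under the spectrum."""
        return float(np.trapezoid(self.intensity, self.grid))


@dataclass(frozen=True)
class StickSpectrum:
    """Vertical-transition stick list: positions (cm⁻¹) and non-negative strengths."""

    positions: np.ndarray
    strengths: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "strengths", np.asarray(self.strengths, dtype=float))
        if self.positions.shape != self.strengths.shape or self.positions.ndim != 1:
            raise ValueError("positions and strengths must be 1-D arrays of equal length")
        if np.any(self.strengths < 0):
            raise ValueError("stick strengths must be non-negative")


def broaden(sticks: StickSpectrum, fwhm: float, grid: Sequence[float]) -> Spectrum:
    """Convolve a stick spectrum with Gaussians of the given FWHM.

    Each stick contributes a normalized Gaussian scaled by its strength,
    so the area per stick equals the stick strength.  The grid must span
    every stick by at least 3·FWHM on both sides.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    grid = np.asarray(grid, dtype=float)
    lo, hi = grid[0], grid[-1]
    uncovered = [
        float(p)
        for p in sticks.positions
        if p - 3.0 * fwhm < lo or p + 3.0 * fwhm > hi
    ]
    if uncovered:
        raise ValueError(
            f"grid [{lo}, {hi}] cm^-1 does not cover sticks +/- 3 FWHM: {uncovered}"
        )
    sigma = fwhm_to_sigma(fwhm)
    x = grid[:, None] - sticks.positions[None, :]
    profiles = np.exp(-0.5 * (x / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
    return Spectrum(grid=grid, intensity=profiles @ sticks.strengths)


def normalize_unit_area(spec: Spectrum) -> Spectrum:
    """Scale intensities so the trapezoid area is 1; idempotent."""
    area = spec.area
    if area <= 0:
        raise ValueError("cannot normalize a zero-area spectrum")
    return Spectrum(grid=spec.grid, intensity=spec.intensity / area, normalized=True)


def spectral_overlap(emission: Spectrum, absorption: Spectrum) -> float:
    """Overlap integral J = ∫ I_em(ν̃) I_abs(ν̃) dν̃ of unit-area spectra, in cm.

    Both spectra are interpolated linearly onto the union grid restricted
    to the shared wavenumber range and the pointwise product is integrated
    with the trapezoid rule.  Unnormalized inputs are normalized
    internally (logged).  Disjoint ranges give 0 with a warning.
    """
    specs = []
    for name, s in (("emission", emission), ("absorption", absorption)):
        if not s.normalized:
            logger.info("normalizing %s spectrum to unit area for the overlap", name)
            s = normalize_unit_area(s)
        specs.append(s)
    emission, absorption = specs
    lo = max(emission.grid[0], absorption.grid[0])
    hi = min(emission.grid[-1], absorption.grid[-1])
    if lo >= hi:
        logger.warning("spectra cover disjoint wavenumber ranges; overlap is 0")
        return 0.0
    union = np.union1d(emission.grid, absorption.grid)
    union = union[(union >= lo) & (union <= hi)]
    ie = np.interp(union, emission.grid, emission.intensity)
    ia = np.interp(union, absorption.grid, absorption.intensity)
    return float(np.trapezoid(ie * ia, union))


def read_spectrum(path: str | Path, normalized: bool = False) -> Spectrum:
    """Read a two-column (wavenumber_cm-1, intensity) CSV/TSV with '#' comments."""
    df = pd.read_csv(path, comment="#", sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavenumber, intensity)")
    return Spectrum(
        grid=df.iloc[:, 0].to_numpy(float),
        intensity=df.iloc[:, 1].to_numpy(float),
        normalized=normalized,
    )


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"wavenumber_cm-1": spec.grid, "intensity": spec.intensity}).to_csv(
        path, index=False
    )


def read_sticks(path: str | Path) -> StickSpectrum:
    """Read a two-column (position_cm-1, strength) CSV with '#' comments."""
    df = pd.read_csv(path, comment="#", sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (position, strength)")
    return StickSpectrum(
        positions=df.iloc[:, 0].to_numpy(float),
        strengths=df.iloc[:, 1].to_numpy(float),
    )
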