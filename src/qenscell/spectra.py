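"""Containers for measured or simulated S(Q, omega) data.

An :class:`EnergyGrid` is the shared energy-transfer axis (meV).  A
:class:`QENSSpectrum` holds one detector group's intensity slice with
per-point uncertainties; a :class:`SpectrumSet` collects all Q slices of
one sample/pressure condition together with the instrument resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import FWHM_TO_SIGMA

__all__ = [
    "EnergyGrid",
    "ResolutionModel",
    "QENSSpectrum",
    "SpectrumSet",
    "normalize_spectrum",
]


@dataclass(frozen=True)
class EnergyGrid:
    """Strictly increasing energy-transfer axis in meV containing 0."""

    energies: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "energies", e)
        if e.ndim != 1 or e.size < 32:
            raise ValueError("energy grid needs at least 32 points")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if not (e[0] <= 0.0 <= e[-1]):
            raise ValueError("energy grid must contain 0 within its range")

    def __len__(self) -> int:
        return self.energies.size

    @property
    def step(self) -> float:
        """Mean bin width in meV."""
        return float((self.energies[-1] - self.energies[0]) / (len(self) - 1))

    def is_uniform(self, rtol: float = 1e-8) -> bool:
        d = np.diff(self.energies)
        return bool(np.all(np.abs(d - d[0]) <= rtol * abs(d[0])))

    @classmethod
    def linspace(cls, e_min: float, e_max: float, n: int) -> "EnergyGrid":
        return cls(np.linspace(e_min, e_max, n))


@dataclass(frozen=True)
class ResolutionModel:
    """Instrument energy resolution: analytic Gaussian or tabulated curve.

    Parameters
    ----------
    kind : {"gaussian", "tabulated"}
    fwhm_meV : float, optional
        Full width at half maximum of the Gaussian, meV.
    table : (n, 2) array, optional
        Columns (energy meV, density 1/meV); must be non-negative and
        integrate to 1 (trapezoid) within 1e-6.
    """

    kind: str
    fwhm_meV: float | None = None
    table: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "gaussian":
            if self.fwhm_meV is None or self.fwhm_meV <= 0:
                raise ValueError("gaussian resolution requires fwhm_meV > 0")
        elif self.kind == "tabulated":
            t = np.asarray(self.table, dtype=float)
            if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 3:
                raise ValueError("tabulated resolution needs an (n, 2) table")
            if np.any(t[:, 1] < 0):
                raise ValueError("tabulated resolution must be non-negative")
            area = np.trapezoid(t[:, 1], t[:, 0])
            if abs(area - 1.0) > 1e-6:
                raise ValueError(
                    f"tabulated resolution must integrate to 1 (got {area:.8f})"
                )
            object.__setattr__(self, "table", t)
        else:
            raise ValueError(f"unknown resolution kind {self.kind!r}")

    @property
    def sigma_meV(self) -> float:
        """Gaussian standard deviation in meV (gaussian kind only)."""
        if self.kind != "gaussian":
            raise ValueError("sigma_meV is defined for gaussian resolution only")
        return self.fwhm_meV * FWHM_TO_SIGMA

    def profile(self, grid: EnergyGrid) -> np.ndarray:
        """Resolution line shape R(omega) sampled on *grid*, unit analytic area."""
        w = grid.energies
        if self.kind == "gaussian":
            s = self.sigma_meV
            return np.exp(-0.5 * (w / s) ** 2) / (s * np.sqrt(2.0 * np.pi))
        return np.interp(w, self.table[:, 0], self.table[:, 1], left=0.0, right=0.0)

    @classmethod
    def gaussian(cls, fwhm_meV: float) -> "ResolutionModel":
        return cls(kind="gaussian", fwhm_meV=fwhm_meV)

    @classmethod
    def tabulated(cls, energy_meV, density) -> "ResolutionModel":
        return cls(kind="tabulated", table=np.column_stack([energy_meV, density]))


@dataclass(frozen=True)
class QENSSpectrum:
    """One detector group's S(Q, omega) slice with uncertainties."""

    q: float
    grid: EnergyGrid
    intensity: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        i = np.asarray(self.intensity, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "sigma", s)
        if self.q <= 0:
            raise ValueError("q must be positive")
        if i.shape != s.shape or i.size != len(self.grid):
            raise ValueError("intensity, sigma and grid must have equal length")
        if np.any(s <= 0):
            raise ValueError("sigma must be positive everywhere")
        if np.any(i < 0):
            raise ValueError("intensity must be non-negative")

    @property
    def area(self) -> float:
        """Trapezoidal area over the measured window."""
        return float(np.trapezoid(self.intensity, self.grid.energies))


@dataclass(frozen=True)
class SpectrumSet:
    """All Q slices of one sample/condition plus instrument metadata."""

    spectra: tuple[QENSSpectrum, ...]
    resolution: ResolutionModel
    label: str = ""

    def __post_init__(self) -> None:
        sp = tuple(self.spectra)
        object.__setattr__(self, "spectra", sp)
        if not sp:
            raise ValueError("SpectrumSet needs at least one spectrum")
        q = np.array([s.q for s in sp])
        if not np.all(np.diff(q) > 0):
            raise ValueError("q values must be unique and increasing")
        g0 = sp[0].grid.energies
        for s in sp[1:]:
            if not np.array_equal(s.grid.energies, g0):
                raise ValueError("all spectra must share one energy grid")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def q_values(self) -> np.ndarray:
        return np.array([s.q for s in self.spectra])

    @property
    def grid(self) -> EnergyGrid:
        return self.spectra[0].grid

    def normalized(self) -> "SpectrumSet":
        """Return a copy with every spectrum area-normalized."""
        return replace(
            self, spectra=tuple(normalize_spectrum(s) for s in self.spectra)
        )


def normalize_spectrum(spectrum: QENSSpectrum) -> QENSSpectrum:
    """Scale a spectrum to unit trapezoidal area over its measured window.

    Uncertainties are scaled by the same factor, so relative errors are
    preserved.  Idempotent and invariant under input rescaling.
    """
    a = spectrum.area
    if a <= 0:
        raise ValueError("cannot normalize a spectrum with non-positive area")
    return replace(
        spectrum, intensity=spectrum.intensity / a, sigma=spectrum.sigma / a
    )
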