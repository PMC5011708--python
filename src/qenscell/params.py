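"""Parameter vectors for the four-component cell model.

The model splits the scattering signal of a live-cell sample into an
elastic fraction (motions too slow for the instrument), bulk-like water,
surface-bound hydration water and a broad "proteome" component covering
fast internal motions of cellular biomolecules.  The four population
fractions are constrained to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .constants import WATER_OH_RADIUS_A

__all__ = ["WaterComponentParams", "CellModelParams", "FRACTION_SUM_TOL"]

FRACTION_SUM_TOL = 1e-9


@dataclass(frozen=True)
class WaterComponentParams:
    """Jump-diffusion + free-rotation description of one water population.

    Parameters
    ----------
    d_t : float
        Translational diffusion coefficient, cm^2/s.
    tau_ps : float
        Residence time between diffusive jumps, ps.  0 means pure
        Fickian diffusion (linear HWHM in Q^2).
    d_r : float
        Isotropic rotational diffusion coefficient, 1/ps.
    radius_A : float
        Rotation radius, Angstrom; defaults to the water O-H distance.
    """

    d_t: float
    tau_ps: float = 0.0
    d_r: float = 0.0
    radius_A: float = WATER_OH_RADIUS_A

    def __post_init__(self) -> None:
        if self.d_t < 0 or self.tau_ps < 0 or self.d_r < 0:
            raise ValueError("d_t, tau_ps and d_r must be non-negative")
        if self.radius_A <= 0:
            raise ValueError("radius_A must be positive")


@dataclass(frozen=True)
class CellModelParams:
    """Full parameter vector of the four-component cell model.

    ``background`` maps a Q value (rounded to 6 decimals) to a flat,
    energy-independent offset for that slice; Q values absent from the
    mapping get zero background.
    """

    p_elastic: float
    p_bulk: float
    p_hyd: float
    p_proteome: float
    bulk: WaterComponentParams
    hyd: WaterComponentParams
    gamma_proteome_meV: float
    background: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fr = (self.p_elastic, self.p_bulk, self.p_hyd, self.p_proteome)
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > FRACTION_SUM_TOL:
            raise ValueError(
                f"fractions must sum to 1 within {FRACTION_SUM_TOL} (got {sum(fr)!r})"
            )
        if self.gamma_proteome_meV <= 0:
            raise ValueError("gamma_proteome_meV must be positive")
        bg = {round(float(q), 6): float(b) for q, b in dict(self.background).items()}
        if any(b < 0 for b in bg.values()):
            raise ValueError("backgrounds must be non-negative")
        object.__setattr__(self, "background", bg)

    def background_at(self, q: float) -> float:
        return self.background.get(round(float(q), 6), 0.0)

    @property
    def fractions(self) -> np.ndarray:
        """(p_elastic, p_bulk, p_hyd, p_proteome)."""
        return np.array([self.p_elastic, self.p_bulk, self.p_hyd, self.p_proteome])

    def replace(self, **kwargs) -> "CellModelParams":
        return replace(self, **kwargs)

    @classmethod
    def from_fractions(
        cls,
        p_elastic: float,
        p_hyd: float,
        p_proteome: float,
        bulk: WaterComponentParams,
        hyd: WaterComponentParams,
        gamma_proteome_meV: float,
        background: Mapping[float, float] | None = None,
    ) -> "CellModelParams":
        """Build params with p_bulk derived from the sum-to-one constraint."""
        p_bulk = 1.0 - (p_elastic + p_hyd + p_proteome)
        return cls(
            p_elastic=p_elastic,
            p_bulk=p_bulk,
            p_hyd=p_hyd,
            p_proteome=p_proteome,
            bulk=bulk,
            hyd=hyd,
            gamma_proteome_meV=gamma_proteome_meV,
            background=background or {},
        )

    def to_dict(self) -> dict:
        """Flat dict with the field names used in parameter tables."""
        return {
            "p_elastic": self.p_elastic,
            "p_hyd": self.p_hyd,
            "p_bulk": self.p_bulk,
            "p_proteome": self.p_proteome,
            "D_Tbulk": self.bulk.d_t,
            "tau_bulk": self.bulk.tau_ps,
            "D_Rbulk": self.bulk.d_r,
            "D_Thyd": self.hyd.d_t,
            "tau_hyd": self.hyd.tau_ps,
            "D_Rhyd": self.hyd.d_r,
            "Gamma_proteome": self.gamma_proteome_meV,
        }
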