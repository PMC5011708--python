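"""Forward model: the four-component structure factor on an energy grid.

Every quasi-elastic component is a sum of Lorentzians.  Resolution
broadening by a Gaussian instrument line is evaluated analytically as a
Voigt profile; the elastic term is exactly ``p_elastic * R(omega)``
because a delta function convolved with the resolution is the
resolution itself.

Line widths (HWHM) are built from three motional ingredients:

* jump diffusion of the water centre of mass,
  ``Gamma_T(Q) = hbar * D * Q^2 / (1 + D * Q^2 * tau)``;
* isotropic rotational diffusion of the O-H vector, a series of lines
  with widths ``hbar * l * (l + 1) * D_R`` and spherical-Bessel weights
  ``(2l + 1) * j_l(Q a)^2``;
* the Q-independent proteome Lorentzian of width ``Gamma_proteome``.

A Lorentzian convolved with a Lorentzian is a Lorentzian whose HWHM is
the sum of the two widths, so the translational (x) rotational
convolution is exact and costs nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import spherical_jn, voigt_profile

from .constants import HBAR_MEV_PS, d_cm2s_to_A2ps
from .params import CellModelParams, WaterComponentParams
from .spectra import EnergyGrid, ResolutionModel

__all__ = [
    "lorentzian",
    "jump_diffusion_hwhm",
    "rotational_weights",
    "water_component_lines",
    "water_component_spectrum",
    "composite_model",
    "DeltaComponent",
    "ROTATION_TAIL_TOL",
    "ROTATION_L_CAP",
]

#: discard rotational series tail once its total weight drops below this
ROTATION_TAIL_TOL = 1e-4
#: hard cap on the rotational series order
ROTATION_L_CAP = 10


@dataclass(frozen=True)
class DeltaComponent:
    """Marker for a motionless water component (d_t = d_r = 0).

    Such a component is a delta function in energy and belongs in the
    elastic channel; returning a zero-width Lorentzian would be
    numerically meaningless.
    """

    weight: float = 1.0


def lorentzian(grid: EnergyGrid, hwhm_meV: float, center: float = 0.0) -> np.ndarray:
    """Unit-area Lorentzian (1/pi) * G / ((w - center)^2 + G^2) on *grid*."""
    if hwhm_meV <= 0:
        raise ValueError("hwhm_meV must be positive")
    w = grid.energies - center
    return hwhm_meV / (np.pi * (w * w + hwhm_meV * hwhm_meV))


def jump_diffusion_hwhm(d_t: float, tau_ps: float, q) -> np.ndarray | float:
    """Singwi-Sjolander jump-diffusion HWHM in meV.

    Gamma(Q) = hbar * D * Q^2 / (1 + D * Q^2 * tau), with ``d_t`` in
    cm^2/s, ``tau_ps`` in ps and ``q`` in 1/Angstrom.  For tau = 0 this
    is Fickian diffusion (Gamma linear in Q^2); for tau > 0 the width
    saturates at the plateau hbar / tau as Q grows.
    """
    if d_t < 0 or tau_ps < 0:
        raise ValueError("d_t and tau_ps must be non-negative")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    dq2 = d_cm2s_to_A2ps(d_t) * q * q
    out = HBAR_MEV_PS * dq2 / (1.0 + dq2 * tau_ps)
    return float(out) if out.ndim == 0 else out


def rotational_weights(q: float, radius_A: float, l_max: int) -> np.ndarray:
    """Isotropic-rotator structure-factor weights (2l+1) j_l(Q a)^2, l=0..l_max.

    The weights are non-negative and sum to 1 over the infinite series
    (spherical-Bessel closure), so truncation error is directly the
    missing tail weight.
    """
    if q < 0 or radius_A <= 0 or l_max < 0:
        raise ValueError("require q >= 0, radius_A > 0, l_max >= 0")
    x = q * radius_A
    l = np.arange(l_max + 1)
    jl = spherical_jn(l, x)
    return (2 * l + 1) * jl * jl


def _adaptive_l_max(q: float, radius_A: float) -> int:
    """Smallest order whose discarded tail weight is below ROTATION_TAIL_TOL."""
    w = rotational_weights(q, radius_A, ROTATION_L_CAP)
    tail = 1.0 - np.cumsum(w)
    idx = np.nonzero(tail < ROTATION_TAIL_TOL)[0]
    return int(idx[0]) if idx.size else ROTATION_L_CAP


def water_component_lines(
    params: WaterComponentParams, q: float, l_max: int | None = None
) -> tuple[np.ndarray, np.ndarray] | DeltaComponent:
    """Lorentzian decomposition (weights, HWHMs in meV) of one water component.

    Each rotational order l contributes a line of width
    ``Gamma_T(Q) + hbar * l * (l+1) * D_R`` with weight ``(2l+1) j_l(Qa)^2``;
    weights are renormalized to sum to 1 after truncation.  Returns a
    :class:`DeltaComponent` when the component carries no motion at all.
    """
    if params.d_t == 0 and params.d_r == 0:
        return DeltaComponent()
    gamma_t = jump_diffusion_hwhm(params.d_t, params.tau_ps, q)
    if params.d_r == 0:
        return np.array([1.0]), np.array([gamma_t])
    if l_max is None:
        l_max = _adaptive_l_max(q, params.radius_A)
    w = rotational_weights(q, params.radius_A, l_max)
    w = w / w.sum()
    l = np.arange(l_max + 1)
    widths = gamma_t + HBAR_MEV_PS * l * (l + 1) * params.d_r
    return w, widths


def water_component_spectrum(
    params: WaterComponentParams,
    q: float,
    grid: EnergyGrid,
    l_max: int | None = None,
) -> np.ndarray | DeltaComponent:
    """Unresolved spectrum of one water population (unit analytic area).

    The l = 0 term is the pure translational Lorentzian; higher orders
    add rotation-broadened lines via exact Lorentzian width addition.
    """
    lines = water_component_lines(params, q, l_max)
    if isinstance(lines, DeltaComponent):
        return lines
    weights, widths = lines
    out = np.zeros(len(grid))
    for wgt, gam in zip(weights, widths):
        if gam == 0.0:
            # q = 0 or a zero-width l=0 line: treat as elastic within
            # this component is impossible here (d_t>0 implies gam>0 for q>0);
            # guard against q == 0 exactly
            raise ValueError("zero-width line; evaluate at q > 0")
        out += wgt * lorentzian(grid, gam)
    return out


def _resolved_lines(
    weights: np.ndarray,
    widths: np.ndarray,
    grid: EnergyGrid,
    resolution: ResolutionModel,
) -> np.ndarray:
    """Sum of Lorentzians convolved with the instrument resolution."""
    w = grid.energies
    if resolution.kind == "gaussian":
        s = resolution.sigma_meV
        out = np.zeros(w.size)
        for wgt, gam in zip(weights, widths):
            out += wgt * voigt_profile(w, s, gam)
        return out
    # tabulated resolution: FFT convolution on a uniform grid
    if not grid.is_uniform(1e-6):
        raise ValueError("tabulated-resolution convolution needs a uniform grid")
    from scipy.signal import fftconvolve

    r = resolution.profile(grid)
    unresolved = np.zeros(w.size)
    for wgt, gam in zip(weights, widths):
        unresolved += wgt * lorentzian(grid, gam)
    return fftconvolve(unresolved, r, mode="same") * grid.step


def composite_model(
    params: CellModelParams,
    q: float,
    grid: EnergyGrid,
    resolution: ResolutionModel,
) -> np.ndarray:
    """Four-component cell model at one Q, resolution-convolved, plus background.

    ``p_elastic * R(w) + [p_bulk S_bulk + p_hyd S_hyd + p_proteome S_prot] (x) R + B(q)``

    With unit-area resolution and backgrounds excluded, the analytic
    area of the returned curve is 1 (fractions sum to 1).
    """
    r_profile = resolution.profile(grid)
    elastic_weight = params.p_elastic
    weights: list[float] = []
    widths: list[float] = []

    for frac, comp in ((params.p_bulk, params.bulk), (params.p_hyd, params.hyd)):
        if frac == 0.0:
            continue
        lines = water_component_lines(comp, q)
        if isinstance(lines, DeltaComponent):
            elastic_weight += frac  # motionless water is elastic
            continue
        wgt, gam = lines
        keep = gam > 0
        elastic_weight += frac * float(wgt[~keep].sum())
        weights.extend(frac * wgt[keep])
        widths.extend(gam[keep])

    if params.p_proteome > 0:
        weights.append(params.p_proteome)
        widths.append(params.gamma_proteome_meV)

    out = elastic_weight * r_profile
    if weights:
        out = out + _resolved_lines(
            np.asarray(weights), np.asarray(widths), grid, resolution
        )
    return out + params.background_at(q)
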