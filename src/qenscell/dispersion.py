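"""Dispersion curves Gamma(Q^2) and jump-diffusion parameter extraction.

For unrestricted Brownian motion the Lorentzian HWHM grows linearly
with Q^2 and the slope is hbar * D_T.  Confined or jumpy translation
bends the curve towards a plateau Gamma_inf = hbar / tau; fitting
Gamma(Q) = hbar * D * Q^2 / (1 + D * Q^2 * tau) yields both the
low-Q diffusion coefficient and the residence time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .constants import HBAR_MEV_PS, CM2S_TO_A2PS
from .modelfree import ModelFreeResult
from .spectra import SpectrumSet

__all__ = [
    "DispersionCurve",
    "extract_dispersion",
    "JumpDiffusionModel",
    "JumpDiffusionResults",
    "fit_jump_diffusion",
]


@dataclass(frozen=True)
class DispersionCurve:
    """HWHM vs Q^2 points with uncertainties for one motional component."""

    q2: np.ndarray
    hwhm: np.ndarray
    hwhm_err: np.ndarray
    component_label: str = ""

    def __post_init__(self) -> None:
        q2 = np.asarray(self.q2, dtype=float)
        g = np.asarray(self.hwhm, dtype=float)
        e = np.asarray(self.hwhm_err, dtype=float)
        if not (q2.shape == g.shape == e.shape):
            raise ValueError("q2, hwhm and hwhm_err must have equal length")
        if not np.all(np.diff(q2) > 0):
            raise ValueError("q2 must be strictly increasing")
        if np.any(g < 0):
            raise ValueError("hwhm must be non-negative")
        object.__setattr__(self, "q2", q2)
        object.__setattr__(self, "hwhm", g)
        object.__setattr__(self, "hwhm_err", e)

    def __len__(self) -> int:
        return self.q2.size


def extract_dispersion(
    spectrum_set: SpectrumSet,
    fits: Sequence[ModelFreeResult],
    component_index: int,
    label: str = "",
) -> DispersionCurve:
    """Assemble (Q^2, Gamma, sigma_Gamma) for one model-free width across Q.

    Failed per-Q fits are omitted with a warning; Q order is preserved.
    Components are indexed in the ascending-width order that
    :func:`~qenscell.modelfree.fit_model_free` reports.
    """
    if len(fits) != len(spectrum_set):
        raise ValueError("need one model-free fit per spectrum")
    q2, g, e = [], [], []
    for s, fit in zip(spectrum_set.spectra, fits):
        if not fit.success or component_index >= fit.n_lorentzians or not np.isfinite(
            fit.widths_meV[component_index]
        ):
            warnings.warn(f"omitting failed model-free fit at q={s.q}", stacklevel=2)
            continue
        q2.append(s.q**2)
        g.append(fit.widths_meV[component_index])
        e.append(fit.width_err[component_index])
    return DispersionCurve(
        q2=np.array(q2), hwhm=np.array(g), hwhm_err=np.array(e),
        component_label=label or f"component_{component_index}",
    )


@dataclass(frozen=True)
class JumpDiffusionResults:
    """Jump-diffusion fit of a dispersion curve.

    ``tau_fixed`` is True when the curvature test found no significant
    deviation from linearity and the residence time was pinned at 0.
    """

    d_t: float  # cm^2/s
    tau_ps: float
    d_t_err: float
    tau_err: float
    tau_fixed: bool
    chi2_reduced: float
    curvature_p_value: float

    def summary(self) -> str:
        tau_note = " (pinned: no significant curvature)" if self.tau_fixed else ""
        return (
            "Jump-diffusion fit\n"
            f"  D_T  = {self.d_t:.4e} +- {self.d_t_err:.2e} cm^2/s\n"
            f"  tau  = {self.tau_ps:.4g} +- {self.tau_err:.2g} ps{tau_note}\n"
            f"  chi2_reduced = {self.chi2_reduced:.4g}"
            f"   curvature p = {self.curvature_p_value:.3g}"
        )

    def hwhm_at(self, q) -> np.ndarray:
        from .lineshapes import jump_diffusion_hwhm

        return jump_diffusion_hwhm(self.d_t, self.tau_ps, q)


class JumpDiffusionModel:
    """Weighted jump-diffusion model of one dispersion curve.

    The residence time is freed only when an F-test on the chi-square
    improvement of the jump model over the purely linear (Fickian)
    model is significant at ``alpha`` — with a short Q range the
    high-Q plateau may simply not be visible, and a free tau would then
    be unconstrained.
    """

    def __init__(self, curve: DispersionCurve, alpha: float = 0.05) -> None:
        if len(curve) < 3:
            raise ValueError("need at least 3 dispersion points")
        if np.all(curve.hwhm == 0):
            raise ValueError("all widths are zero")
        self.curve = curve
        self.alpha = alpha
        e = curve.hwhm_err
        self.weights = 1.0 / e**2 if np.all(e > 0) else np.ones(len(curve))

    def _linear_fit(self) -> tuple[float, float, float]:
        """Weighted Gamma = hbar * D * Q^2; returns (D [A^2/ps], err, chi2)."""
        x, y, w = self.curve.q2, self.curve.hwhm, self.weights
        sxx = np.sum(w * x * x)
        slope = np.sum(w * x * y) / sxx
        chi2 = float(np.sum(w * (y - slope * x) ** 2))
        dof = max(len(self.curve) - 1, 1)
        slope_err = np.sqrt(max(chi2 / dof, 0.0) / sxx)
        return slope / HBAR_MEV_PS, slope_err / HBAR_MEV_PS, chi2

    def fit(self, force_tau_free: bool | None = None) -> JumpDiffusionResults:
        """Fit the curve; ``force_tau_free`` overrides the curvature test."""
        x, y, w = self.curve.q2, self.curve.hwhm, self.weights
        sw = np.sqrt(w)
        d_lin, d_lin_err, chi2_lin = self._linear_fit()

        def fun(p):
            d, tau = p
            dq2 = d * x
            return sw * (HBAR_MEV_PS * dq2 / (1.0 + dq2 * tau) - y)

        tau0 = 1.0
        res = least_squares(
            fun, [max(d_lin, 1e-12), tau0], bounds=([0.0, 0.0], [np.inf, 100.0]),
            method="trf", ftol=1e-15, xtol=1e-15, gtol=1e-15, x_scale="jac",
        )
        chi2_jump = float(2.0 * res.cost)
        n = len(self.curve)

        if force_tau_free is None:
            dof_jump = max(n - 2, 1)
            denom = chi2_jump / dof_jump
            if chi2_lin < 1e-20:
                # the linear model already reproduces the curve to machine
                # precision: no curvature information at all
                p_curv = 1.0
                denom = np.inf
            if denom <= 0:
                p_curv = 0.0  # jump model exact: curvature maximally significant
            else:
                f_stat = (chi2_lin - chi2_jump) / denom
                p_curv = float(f_dist.sf(max(f_stat, 0.0), 1, dof_jump))
            tau_free = p_curv < self.alpha
        else:
            tau_free = force_tau_free
            p_curv = np.nan

        if not tau_free:
            return JumpDiffusionResults(
                d_t=d_lin / CM2S_TO_A2PS, tau_ps=0.0,
                d_t_err=d_lin_err / CM2S_TO_A2PS, tau_err=0.0, tau_fixed=True,
                chi2_reduced=chi2_lin / max(n - 1, 1),
                curvature_p_value=p_curv,
            )

        dof = max(n - 2, 1)
        chi2_red = chi2_jump / dof
        jtj = res.jac.T @ res.jac
        cov = np.linalg.pinv(jtj) * max(chi2_red, 0.0)
        se = np.sqrt(np.abs(np.diag(cov)))
        return JumpDiffusionResults(
            d_t=res.x[0] / CM2S_TO_A2PS, tau_ps=float(res.x[1]),
            d_t_err=se[0] / CM2S_TO_A2PS, tau_err=float(se[1]), tau_fixed=False,
            chi2_reduced=chi2_red, curvature_p_value=p_curv,
        )


def fit_jump_diffusion(
    curve: DispersionCurve, force_tau_free: bool | None = None
) -> JumpDiffusionResults:
    """Functional wrapper around :class:`JumpDiffusionModel`."""
    return JumpDiffusionModel(curve).fit(force_tau_free=force_tau_free)
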