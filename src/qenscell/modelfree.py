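"""Model-free per-Q fits: elastic line + a few Lorentzians + background.

This is the assumption-light first pass of a QENS analysis: each Q
slice is fitted independently with an elastic term and 1-4
resolution-convolved Lorentzians of free width and amplitude.  The
widths, plotted against Q^2, produce the dispersion curves from which
jump-diffusion parameters are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .lineshapes import _resolved_lines
from .spectra import QENSSpectrum, ResolutionModel

__all__ = ["ModelFreeResult", "fit_model_free"]

_WIDTH_BOUNDS = (1e-4, 5.0)  # meV


@dataclass(frozen=True)
class ModelFreeResult:
    """Per-Q model-free fit: widths sorted ascending with their amplitudes."""

    q: float
    widths_meV: np.ndarray
    width_err: np.ndarray
    amplitudes: np.ndarray
    amplitude_err: np.ndarray
    elastic_amplitude: float
    background: float
    chi2_reduced: float
    success: bool
    message: str = ""

    @property
    def n_lorentzians(self) -> int:
        return self.widths_meV.size


def fit_model_free(
    spectrum: QENSSpectrum,
    resolution: ResolutionModel,
    n_lorentzians: int,
    *,
    seed: int = 0,
    n_starts: int = 5,
) -> ModelFreeResult:
    """Weighted fit of elastic + n Lorentzians (each resolution-convolved) + flat background.

    Widths are initialized log-spaced between the resolution width and
    a quarter of the energy window, then jittered across seeded
    multi-starts; the best-chi2 solution is kept.  Non-convergence is
    reported through ``success=False``, never as an exception.
    """
    if not 1 <= n_lorentzians <= 4:
        raise ValueError("n_lorentzians must be between 1 and 4")
    grid = spectrum.grid
    w = grid.energies
    r_profile = resolution.profile(grid)
    y, sig = spectrum.intensity, spectrum.sigma
    area = spectrum.area
    n = n_lorentzians

    # parameter vector: [a_el, a_1..a_n, log(G_1)..log(G_n), bg]
    if resolution.kind == "gaussian":
        g_lo = max(resolution.fwhm_meV / 4.0, _WIDTH_BOUNDS[0])
    else:
        g_lo = _WIDTH_BOUNDS[0] * 10
    g_hi = min((w[-1] - w[0]) / 4.0, _WIDTH_BOUNDS[1])
    g_init = np.geomspace(g_lo * 2, g_hi / 2, n) if n > 1 else np.array(
        [np.sqrt(g_lo * g_hi)]
    )

    def unpack(x):
        a_el = x[0]
        amps = x[1 : 1 + n]
        gammas = np.exp(x[1 + n : 1 + 2 * n])
        bg = x[-1]
        return a_el, amps, gammas, bg

    def fun(x):
        a_el, amps, gammas, bg = unpack(x)
        m = a_el * r_profile + _resolved_lines(amps, gammas, grid, resolution) + bg
        return (m - y) / sig

    lo = np.concatenate([[0.0], np.zeros(n), np.full(n, np.log(_WIDTH_BOUNDS[0])), [0.0]])
    hi = np.concatenate(
        [[np.inf], np.full(n, np.inf), np.full(n, np.log(_WIDTH_BOUNDS[1])), [np.inf]]
    )
    x0 = np.concatenate(
        [[0.1 * area], np.full(n, 0.9 * area / n), np.log(g_init), [0.0]]
    )

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        xs = x0.copy()
        if start > 0:
            xs[1 + n : 1 + 2 * n] += rng.uniform(-0.7, 0.7, n)
            xs[: 1 + n] *= np.exp(rng.uniform(-0.3, 0.3, 1 + n))
            xs = np.clip(xs, lo, hi)
        try:
            res = least_squares(
                fun, xs, bounds=(lo, hi), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-12, x_scale="jac",
            )
        except Exception as exc:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None or not np.isfinite(best.cost):
        nan = np.full(n, np.nan)
        return ModelFreeResult(
            q=spectrum.q, widths_meV=nan, width_err=nan, amplitudes=nan,
            amplitude_err=nan, elastic_amplitude=np.nan, background=np.nan,
            chi2_reduced=np.nan, success=False, message="optimizer failed",
        )

    a_el, amps, gammas, bg = unpack(best.x)
    n_free = best.x.size
    dof = max(y.size - n_free, 1)
    chi2_red = float(2.0 * best.cost / dof)

    jtj = best.jac.T @ best.jac
    cov = np.linalg.pinv(jtj) * max(chi2_red, 0.0)
    se = np.sqrt(np.abs(np.diag(cov)))
    amp_err = se[1 : 1 + n]
    gam_err = gammas * se[1 + n : 1 + 2 * n]  # delta method for log-width

    order = np.argsort(gammas)
    return ModelFreeResult(
        q=spectrum.q,
        widths_meV=gammas[order],
        width_err=gam_err[order],
        amplitudes=amps[order],
        amplitude_err=amp_err[order],
        elastic_amplitude=float(a_el),
        background=float(bg),
        chi2_reduced=chi2_red,
        success=bool(best.status > 0),
        message=str(best.message),
    )
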