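"""Global fit of the four-component cell model to a multi-Q spectrum set.

The public surface follows the Model/Results idiom: build a
:class:`CellSpectrumModel` from a :class:`~qenscell.spectra.SpectrumSet`,
call :meth:`~CellSpectrumModel.fit`, and read estimates, standard
errors and diagnostics off the returned :class:`CellModelResults`.

All Q slices are fitted simultaneously by weighted least squares.  The
population fractions, both water-dynamics parameter sets and the
proteome width are shared across Q; one flat background is free per Q
slice.  The sum-to-one fraction constraint is enforced by fitting
p_elastic, p_hyd and p_proteome and deriving p_bulk.  Because the data
are area-normalized per spectrum, the model curve is normalized over
the same window with the same trapezoid rule before comparison, making
the fit a pure line-shape/proportion problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import WATER_OH_RADIUS_A
from .lineshapes import DeltaComponent, _resolved_lines, water_component_lines
from .params import CellModelParams, WaterComponentParams
from .spectra import ResolutionModel, SpectrumSet

__all__ = ["CellSpectrumModel", "CellModelResults", "SHARED_PARAM_NAMES"]

#: shared (Q-independent) parameter names, in canonical order
SHARED_PARAM_NAMES = (
    "p_elastic",
    "p_hyd",
    "p_proteome",
    "D_Tbulk",
    "tau_bulk",
    "D_Rbulk",
    "D_Thyd",
    "tau_hyd",
    "D_Rhyd",
    "Gamma_proteome",
)

# internal optimizer units: value_external = value_internal * scale
_SCALES = {"D_Tbulk": 1e-5, "D_Thyd": 1e-7}

_DEFAULT_INIT = {
    "p_elastic": 0.02,
    "p_hyd": 0.12,
    "p_proteome": 0.21,
    "D_Tbulk": 2.3e-5,  # pure-water value at ambient conditions
    "tau_bulk": 1.0,
    "D_Rbulk": 0.10,
    "D_Thyd": 5.0e-7,
    "tau_hyd": 0.0,
    "D_Rhyd": 0.05,
    "Gamma_proteome": 0.4,
}

_DEFAULT_BOUNDS = {
    "p_elastic": (0.0, 1.0),
    "p_hyd": (0.0, 1.0),
    "p_proteome": (0.0, 1.0),
    "D_Tbulk": (0.5e-5, 5e-5),
    "tau_bulk": (0.0, 10.0),
    "D_Rbulk": (0.0, 1.0),
    "D_Thyd": (0.5e-7, 50e-7),
    "tau_hyd": (0.0, 10.0),
    "D_Rhyd": (0.0, 1.0),
    "Gamma_proteome": (0.05, 2.0),
}


def _as_value_dict(init) -> dict[str, float]:
    if init is None:
        return dict(_DEFAULT_INIT)
    if isinstance(init, CellModelParams):
        d = init.to_dict()
        return {k: d[k] for k in SHARED_PARAM_NAMES}
    out = dict(_DEFAULT_INIT)
    unknown = set(init) - set(SHARED_PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    out.update(init)
    return out


class CellSpectrumModel:
    """Four-component whole-cell QENS model bound to one spectrum set.

    Parameters
    ----------
    data : SpectrumSet
        Measured or simulated spectra.  They are area-normalized on
        construction (idempotent if already normalized).
    tau_hyd_free : bool
        Free the hydration-water residence time.  Off by default: over
        a 0.2-1.1 1/A window the hydration plateau is not reached, so
        tau_hyd is not identifiable and is pinned at 0.
    rotation_radius_A : float
        Rotation radius used for both water populations.
    """

    def __init__(
        self,
        data: SpectrumSet,
        *,
        tau_hyd_free: bool = False,
        rotation_radius_A: float = WATER_OH_RADIUS_A,
    ) -> None:
        self.data = data.normalized()
        self.resolution = data.resolution
        self.tau_hyd_free = tau_hyd_free
        self.radius = rotation_radius_A
        self._grid = self.data.grid
        self._energies = self._grid.energies
        self._r_profile = self.resolution.profile(self._grid)
        self._bg_names = tuple(f"bg_{i:02d}" for i in range(len(self.data)))
        self.param_names = SHARED_PARAM_NAMES + self._bg_names
        self.n_obs = len(self.data) * len(self._grid)

    @classmethod
    def from_file(cls, path, resolution, **kwargs) -> "CellSpectrumModel":
        """Construct from a spectra TSV file; see :func:`qenscell.io.read_spectrum_set`."""
        from .io import read_spectrum_set

        return cls(read_spectrum_set(path, resolution), **kwargs)

    # ---------------------------------------------------------------- model
    def _slice_lines(self, vals: Mapping[str, float], q: float):
        """(elastic_weight, line_weights, line_hwhms) for one Q slice."""
        p_el = vals["p_elastic"]
        p_hyd = vals["p_hyd"]
        p_prot = vals["p_proteome"]
        p_bulk = 1.0 - (p_el + p_hyd + p_prot)
        elastic = p_el
        weights: list[float] = []
        widths: list[float] = []
        comps = (
            (p_bulk, vals["D_Tbulk"], vals["tau_bulk"], vals["D_Rbulk"]),
            (p_hyd, vals["D_Thyd"], vals["tau_hyd"], vals["D_Rhyd"]),
        )
        for frac, d_t, tau, d_r in comps:
            if frac == 0.0:
                continue
            lines = water_component_lines(
                WaterComponentParams(d_t=d_t, tau_ps=tau, d_r=d_r, radius_A=self.radius),
                q,
            )
            if isinstance(lines, DeltaComponent):
                elastic += frac
                continue
            wgt, gam = lines
            keep = gam > 0
            elastic += frac * float(wgt[~keep].sum())
            weights.extend(frac * wgt[keep])
            widths.extend(gam[keep])
        weights.append(p_prot)
        widths.append(vals["Gamma_proteome"])
        return elastic, np.asarray(weights), np.asarray(widths)

    def _predict_slice(self, vals: Mapping[str, float], i: int) -> np.ndarray:
        """Normalized model curve for slice *i* (matches normalized data)."""
        q = self.data.spectra[i].q
        elastic, weights, widths = self._slice_lines(vals, q)
        y = elastic * self._r_profile
        y = y + _resolved_lines(weights, widths, self._grid, self.resolution)
        y = y + vals[self._bg_names[i]]
        area = np.trapezoid(y, self._energies)
        if not np.isfinite(area) or area <= 0:
            return np.full(y.size, np.inf)
        return y / area

    def predict(self, params: CellModelParams) -> list[np.ndarray]:
        """Normalized model curves for every slice at the given parameters."""
        vals = _as_value_dict(params)
        for i, s in enumerate(self.data.spectra):
            vals[self._bg_names[i]] = params.background_at(s.q)
        return [self._predict_slice(vals, i) for i in range(len(self.data))]

    def _residuals(
        self, vals: Mapping[str, float], sigmas: Sequence[np.ndarray] | None = None
    ) -> np.ndarray:
        out = []
        for i, s in enumerate(self.data.spectra):
            sig = s.sigma if sigmas is None else sigmas[i]
            out.append((self._predict_slice(vals, i) - s.intensity) / sig)
        return np.concatenate(out)

    def _pearson_sigmas(self, vals: Mapping[str, float]) -> list[np.ndarray]:
        """Model-based (expected-count) uncertainties per slice.

        For counting data reduced as counts/area with sigma =
        sqrt(counts)/area, the per-bin ratio intensity/sigma^2 equals
        the area factor, so the count scale can be recovered from the
        data and the Poisson sigma re-evaluated at the *model*
        intensity.  This removes the classic low-count bias of
        weighting by observed counts.
        """
        out = []
        for i, s in enumerate(self.data.spectra):
            mask = s.intensity > 0
            area = float(np.median(s.intensity[mask] / s.sigma[mask] ** 2))
            m = np.maximum(self._predict_slice(vals, i), 0.0)
            out.append(np.sqrt(np.maximum(m * area, 1.0)) / area)
        return out

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        init: CellModelParams | Mapping[str, float] | None = None,
        fixed: Mapping[str, float] | Iterable[str] | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        seed: int = 0,
        n_starts: int = 3,
        jitter: float = 0.2,
        weighting: str = "data",
    ) -> "CellModelResults":
        """Weighted global least squares with seeded multi-start.

        Parameters
        ----------
        init : CellModelParams or mapping, optional
            Starting values for the shared parameters; defaults are
            physically motivated (see module docstring).
        fixed : mapping name -> value, or iterable of names, optional
            Parameters held at the given value (or at their init value).
        bounds : mapping name -> (lo, hi), optional
            Overrides of the default box bounds.
        seed : int
            Seed for the multi-start jitter; results are bit-for-bit
            reproducible for a fixed seed.
        n_starts : int
            Number of starts; the first is unjittered, the rest draw a
            log-uniform factor in [1 - jitter, 1 + jitter] per parameter.
        weighting : {"data", "pearson"}
            "data" weights each point by its stated uncertainty.
            "pearson" additionally re-derives Poisson uncertainties
            from the fitted model intensities and refits (two warm-start
            passes); preferred for low-count data, where weighting by
            observed counts biases widths downward.
        """
        if weighting not in ("data", "pearson"):
            raise ValueError("weighting must be 'data' or 'pearson'")
        init_vals = _as_value_dict(init)
        bg_init = {n: 0.0 for n in self._bg_names}
        if isinstance(init, CellModelParams):
            for i, s in enumerate(self.data.spectra):
                bg_init[self._bg_names[i]] = init.background_at(s.q)
        all_init = {**init_vals, **bg_init}

        fixed_vals: dict[str, float] = {}
        if fixed is not None:
            if isinstance(fixed, Mapping):
                fixed_vals = {k: float(v) for k, v in fixed.items()}
            else:
                fixed_vals = {k: all_init[k] for k in fixed}
        if not self.tau_hyd_free and "tau_hyd" not in fixed_vals:
            fixed_vals["tau_hyd"] = all_init["tau_hyd"]
        unknown = set(fixed_vals) - set(self.param_names)
        if unknown:
            raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")
        all_init.update(fixed_vals)

        bound_map = {**_DEFAULT_BOUNDS, **(dict(bounds) if bounds else {})}
        for n in self._bg_names:
            bound_map.setdefault(n, (0.0, np.inf))

        free = [n for n in self.param_names if n not in fixed_vals]
        scales = np.array([_SCALES.get(n, 1.0) for n in free])
        lo = np.array([bound_map[n][0] for n in free]) / scales
        hi = np.array([bound_map[n][1] for n in free]) / scales
        x0 = np.array([all_init[n] for n in free]) / scales
        x0 = np.clip(x0, lo, hi)

        vals = dict(all_init)
        sigmas: list[np.ndarray] | None = None

        def fun(x: np.ndarray) -> np.ndarray:
            for n, xi, sc in zip(free, x, scales):
                vals[n] = xi * sc
            return self._residuals(vals, sigmas)

        def solve(xs: np.ndarray):
            return least_squares(
                fun, xs, bounds=(lo, hi), method="trf",
                ftol=1e-10, xtol=1e-10, gtol=1e-10, x_scale="jac",
            )

        rng = np.random.default_rng(seed)
        best = None
        nfev = 0
        if free:
            for start in range(max(1, n_starts)):
                if start == 0:
                    xs = x0
                else:
                    f = np.exp(
                        rng.uniform(np.log(1.0 - jitter), np.log(1.0 + jitter), x0.size)
                    )
                    xs = np.clip(np.where(x0 != 0.0, x0 * f, x0), lo, hi)
                res = solve(xs)
                nfev += res.nfev
                if best is None or res.cost < best.cost:
                    best = res
            if weighting == "pearson":
                for _ in range(2):
                    for n, xi, sc in zip(free, best.x, scales):
                        vals[n] = xi * sc
                    sigmas = self._pearson_sigmas(vals)
                    best = solve(best.x)
                    nfev += best.nfev
            x_opt = best.x
            for n, xi, sc in zip(free, x_opt, scales):
                vals[n] = xi * sc
        else:
            # everything held fixed: pure evaluation, no optimization
            if weighting == "pearson":
                sigmas = self._pearson_sigmas(vals)
            x_opt = np.empty(0)

            class _Eval:
                pass

            best = _Eval()
            r0 = self._residuals(vals, sigmas)
            best.cost = 0.5 * float(r0 @ r0)
            best.x = x_opt
            best.jac = np.empty((r0.size, 0))
            best.status = 1
            best.message = "all parameters fixed; residuals evaluated"

        n_free = len(free)
        dof = max(self.n_obs - n_free, 1)
        chi2_reduced = float(2.0 * best.cost / dof)

        # curvature-based covariance in internal units
        stderr: dict[str, float] = {n: 0.0 for n in fixed_vals}
        cov = None
        cov_ok = True
        if n_free:
            jtj = best.jac.T @ best.jac
            try:
                cov = np.linalg.inv(jtj) * max(chi2_reduced, 0.0)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(jtj) * max(chi2_reduced, 0.0)
                cov_ok = False
            d = np.diag(cov)
            if np.any(d < 0):
                cov_ok = False
            se = np.sqrt(np.abs(d)) * scales
            stderr.update(dict(zip(free, se)))

        # derived p_bulk and its propagated error
        p_bulk = 1.0 - (vals["p_elastic"] + vals["p_hyd"] + vals["p_proteome"])
        if cov is not None:
            e = np.zeros(n_free)
            for j, n in enumerate(free):
                if n in ("p_elastic", "p_hyd", "p_proteome"):
                    e[j] = -scales[j]
            stderr["p_bulk"] = float(np.sqrt(max(e @ cov @ e, 0.0)))
        else:
            stderr["p_bulk"] = 0.0

        pinned = [
            n
            for n, xi, l_, h_ in zip(free, x_opt, lo, hi)
            if np.isfinite(h_) and (abs(xi - l_) < 1e-10 or abs(xi - h_) < 1e-10)
            or (not np.isfinite(h_) and abs(xi - l_) < 1e-10)
        ]
        pinned_shared = [n for n in pinned if n in SHARED_PARAM_NAMES]
        if pinned_shared:
            # backgrounds resting at their natural lower bound of 0 are
            # expected; a shared parameter on a bound is worth a warning
            warnings.warn(f"bound-pinned parameters: {pinned_shared}", stacklevel=2)

        background = {
            s.q: vals[self._bg_names[i]] for i, s in enumerate(self.data.spectra)
        }
        # p_bulk is derived; if the free fractions overshoot 1 the optimum
        # is unphysical — clip at 0 and renormalize so the result is valid
        fr = np.array([vals["p_elastic"], max(p_bulk, 0.0), vals["p_hyd"], vals["p_proteome"]])
        if p_bulk < 0:
            warnings.warn("derived p_bulk < 0; fractions renormalized", stacklevel=2)
            fr = fr / fr.sum()
        params = CellModelParams(
            p_elastic=fr[0],
            p_bulk=fr[1],
            p_hyd=fr[2],
            p_proteome=fr[3],
            bulk=WaterComponentParams(
                d_t=vals["D_Tbulk"], tau_ps=vals["tau_bulk"], d_r=vals["D_Rbulk"],
                radius_A=self.radius,
            ),
            hyd=WaterComponentParams(
                d_t=vals["D_Thyd"], tau_ps=vals["tau_hyd"], d_r=vals["D_Rhyd"],
                radius_A=self.radius,
            ),
            gamma_proteome_meV=vals["Gamma_proteome"],
            background=background,
        )

        per_q_residuals = {}
        r = self._residuals(vals, sigmas)
        ne = len(self._grid)
        for i, s in enumerate(self.data.spectra):
            per_q_residuals[s.q] = r[i * ne : (i + 1) * ne]

        return CellModelResults(
            model=self,
            params=params,
            bse=stderr,
            chi2_reduced=chi2_reduced,
            n_evaluations=nfev,
            fixed_mask={n: (n in fixed_vals) for n in self.param_names},
            seed=seed,
            per_q_residuals=per_q_residuals,
            pinned=tuple(pinned),
            cov_available=cov_ok,
            success=bool(best.status > 0),
            message=best.message,
        )


@dataclass
class CellModelResults:
    """Estimates, uncertainties and diagnostics of one global fit."""

    model: CellSpectrumModel
    params: CellModelParams
    bse: dict[str, float]
    chi2_reduced: float
    n_evaluations: int
    fixed_mask: dict[str, bool]
    seed: int
    per_q_residuals: dict[float, np.ndarray]
    pinned: tuple[str, ...] = ()
    cov_available: bool = True
    success: bool = True
    message: str = ""

    #: parameter names reported in tables (shared + derived p_bulk)
    REPORT_NAMES = (
        "p_elastic",
        "p_hyd",
        "p_bulk",
        "p_proteome",
        "D_Tbulk",
        "tau_bulk",
        "D_Rbulk",
        "D_Thyd",
        "tau_hyd",
        "D_Rhyd",
        "Gamma_proteome",
    )

    def value(self, name: str) -> float:
        return self.params.to_dict()[name]

    def stderr(self, name: str) -> float:
        return self.bse.get(name, float("nan"))

    def to_series(self):
        """Parameter point estimates as a pandas Series."""
        import pandas as pd

        d = self.params.to_dict()
        return pd.Series({n: d[n] for n in self.REPORT_NAMES})

    def to_frame(self):
        """DataFrame with value / stderr / fixed columns, one row per parameter."""
        import pandas as pd

        d = self.params.to_dict()
        rows = {
            n: dict(
                value=d[n],
                stderr=self.bse.get(n, np.nan),
                fixed=self.fixed_mask.get(n, False),
            )
            for n in self.REPORT_NAMES
        }
        return pd.DataFrame.from_dict(rows, orient="index")

    def derived(self) -> dict:
        """Derived quantities: rotational correlation times 1/(2 D_R), ps."""
        d = self.params.to_dict()
        out = dict(d)
        for comp, key in (("bulk", "D_Rbulk"), ("hyd", "D_Rhyd")):
            dr = d[key]
            out[f"tau_rot_{comp}_ps"] = (1.0 / (2.0 * dr)) if dr > 0 else None
        out["chi2_reduced"] = self.chi2_reduced
        return out

    def compare(self, other: "CellModelResults", labels=("A", "B")):
        """Cross-condition comparison table (this result is the reference).

        Relative change is 100 * (x_A - x_B) / x_A, flagged NaN when the
        reference is 0; a change is marked significant when it exceeds
        the combined standard error of the two estimates.
        """
        import pandas as pd

        da, db = self.params.to_dict(), other.params.to_dict()
        rows = []
        for n in self.REPORT_NAMES:
            a, b = da[n], db[n]
            sa = self.bse.get(n, np.nan)
            sb = other.bse.get(n, np.nan)
            delta = a - b
            rel = 100.0 * delta / a if a != 0 else np.nan
            comb = np.sqrt(np.nan_to_num(sa) ** 2 + np.nan_to_num(sb) ** 2)
            rows.append(
                dict(
                    parameter=n,
                    **{f"value_{labels[0]}": a, f"value_{labels[1]}": b},
                    abs_change=delta,
                    rel_change_pct=rel,
                    significant=bool(abs(delta) > comb) if comb > 0 else False,
                )
            )
        return pd.DataFrame(rows).set_index("parameter")

    def summary(self) -> str:
        """Plain-text fit report."""
        lines = [
            "Four-component cell model — global fit",
            f"  data: {len(self.model.data)} Q slices x {len(self.model.data.grid)} bins"
            f"  ({self.model.data.label or 'unlabelled'})",
            f"  chi2_reduced = {self.chi2_reduced:.4g}   nfev = {self.n_evaluations}"
            f"   seed = {self.seed}",
            "",
            f"  {'parameter':<16}{'value':>12}{'stderr':>12}  flags",
        ]
        d = self.params.to_dict()
        for n in self.REPORT_NAMES:
            flags = []
            if self.fixed_mask.get(n, False):
                flags.append("fixed")
            if n == "p_bulk":
                flags.append("derived")
            if n in self.pinned:
                flags.append("at-bound")
            lines.append(
                f"  {n:<16}{d[n]:>12.4g}{self.bse.get(n, float('nan')):>12.3g}"
                f"  {','.join(flags)}"
            )
        if not self.cov_available:
            lines.append("  [warning] curvature singular; stderr unreliable")
        return "\n".join(lines)


def derived_quantities(result: CellModelResults) -> dict:
    """Functional alias for :meth:`CellModelResults.derived`."""
    return result.derived()
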