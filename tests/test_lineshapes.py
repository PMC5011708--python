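"""Forward-model line shapes: Lorentzians, jump diffusion, rotation, Voigt."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import spherical_jn

from qenscell import (
    CellModelParams,
    EnergyGrid,
    ResolutionModel,
    WaterComponentParams,
    composite_model,
    jump_diffusion_hwhm,
    lorentzian,
    rotational_weights,
    water_component_spectrum,
)
from qenscell.constants import HBAR_MEV_PS
from qenscell.lineshapes import DeltaComponent, _resolved_lines

WIDE = EnergyGrid(np.linspace(-50, 50, 20001))


def _numeric_lorentz_gauss_conv(gamma, sigma, eval_grid):
    """Brute-force convolution oracle: exact Lorentzian samples x Gaussian kernel."""
    h = min(gamma, sigma) / 40.0
    half = 8.0 * sigma
    kern_t = np.arange(-half, half + h / 2, h)
    kern = np.exp(-0.5 * (kern_t / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    out = np.empty(eval_grid.size)
    for i, w in enumerate(eval_grid):
        t = w - kern_t
        lor = gamma / (np.pi * (t * t + gamma * gamma))
        out[i] = np.trapezoid(lor * kern, kern_t)
    return out


class TestLorentzian:
    def test_peak_and_hwhm(self):
        grid = EnergyGrid(np.linspace(-1, 1, 2001))
        y = lorentzian(grid, 0.1)
        i0 = np.argmin(np.abs(grid.energies))
        assert y[i0] == pytest.approx(1 / (np.pi * 0.1), rel=1e-12)
        ih = np.argmin(np.abs(grid.energies - 0.1))
        assert y[ih] == pytest.approx(y[i0] / 2, rel=1e-12)

    def test_area_approaches_one_on_wide_grid(self):
        # a +-w window captures (2/pi) arctan(w/Gamma) of a Lorentzian:
        # 98.73% at +-50*Gamma, inside 1% of unity at +-100*Gamma
        grid50 = EnergyGrid(np.linspace(-5, 5, 40001))
        area50 = np.trapezoid(lorentzian(grid50, 0.1), grid50.energies)
        assert area50 == pytest.approx(2 / np.pi * np.arctan(50), abs=1e-6)
        grid100 = EnergyGrid(np.linspace(-10, 10, 80001))
        area100 = np.trapezoid(lorentzian(grid100, 0.1), grid100.energies)
        assert area100 == pytest.approx(1.0, abs=0.01)

    def test_rejects_nonpositive_width(self):
        grid = EnergyGrid(np.linspace(-1, 1, 101))
        with pytest.raises(ValueError):
            lorentzian(grid, 0.0)

    def test_width_addition_matches_fft_convolution(self):
        # Lorentz(a) x Lorentz(b) = Lorentz(a+b): check vs FFT convolution
        from scipy.signal import fftconvolve

        grid = np.linspace(-200, 200, 2**17 + 1)
        h = grid[1] - grid[0]
        for a, b in [(0.05, 0.05), (0.1, 0.4), (0.3, 0.05)]:
            la = a / (np.pi * (grid**2 + a**2))
            lb = b / (np.pi * (grid**2 + b**2))
            conv = fftconvolve(la, lb, mode="same") * h
            direct = (a + b) / (np.pi * (grid**2 + (a + b) ** 2))
            sel = np.abs(grid) < 2.0
            err = np.max(np.abs(conv[sel] - direct[sel])) / direct.max()
            assert err < 1e-6


class TestJumpDiffusion:
    def test_zero_q_gives_zero_width(self):
        assert jump_diffusion_hwhm(2e-5, 1.0, 0.0) == 0.0

    def test_reference_value(self):
        # D=0.198 A^2/ps, tau=1.05 ps, Q=0.5: 0.6582*0.0495/(1+0.0495*1.05)
        got = jump_diffusion_hwhm(1.98e-5, 1.05, 0.5)
        assert got == pytest.approx(0.030971735893486, rel=1e-12)

    def test_high_q_plateau_is_hbar_over_tau(self):
        assert jump_diffusion_hwhm(1.98e-5, 1.05, 100.0) == pytest.approx(
            HBAR_MEV_PS / 1.05, rel=1e-3
        )

    def test_low_q_slope_is_d(self):
        q = 0.01
        d_a2ps = 0.198
        assert jump_diffusion_hwhm(1.98e-5, 1.05, q) / (
            HBAR_MEV_PS * q**2
        ) == pytest.approx(d_a2ps, rel=1e-3)

    def test_monotone_in_q(self):
        q = np.linspace(0, 5, 200)
        g = jump_diffusion_hwhm(1.98e-5, 1.05, q)
        assert np.all(np.diff(g) >= 0)

    def test_depends_only_on_dq2(self):
        # doubling Q^2 with D halved leaves the widths unchanged
        q = np.linspace(0.2, 1.1, 10)
        a = jump_diffusion_hwhm(1.98e-5, 1.05, q)
        b = jump_diffusion_hwhm(0.99e-5, 1.05, q * np.sqrt(2.0))
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            jump_diffusion_hwhm(-1e-5, 1.0, 0.5)
        with pytest.raises(ValueError):
            jump_diffusion_hwhm(1e-5, 1.0, -0.5)


class TestRotationalWeights:
    def test_q_zero_is_pure_elastic(self):
        w = rotational_weights(0.0, 0.98, 5)
        assert w[0] == 1.0
        assert np.all(w[1:] == 0.0)

    def test_partial_sum_near_one_at_instrument_q(self):
        # oracle: closure sum to l=50
        w50 = rotational_weights(1.0, 0.98, 50)
        assert w50.sum() == pytest.approx(1.0, abs=1e-10)
        assert rotational_weights(1.0, 0.98, 5).sum() >= 0.9999

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(min_value=0.0, max_value=2.0))
    def test_closure_property(self, x):
        # sum_{l<=50} (2l+1) j_l(x)^2 = 1 for any argument in [0, 2]
        l = np.arange(51)
        s = np.sum((2 * l + 1) * spherical_jn(l, x) ** 2)
        assert s == pytest.approx(1.0, abs=1e-8)

    def test_weights_nonnegative_and_partial_sums_monotone(self):
        w = rotational_weights(1.1, 0.98, 10)
        assert np.all(w >= 0)
        assert np.all(np.diff(np.cumsum(w)) >= 0)


class TestWaterComponent:
    def test_rotation_off_reduces_to_single_lorentzian(self):
        grid = EnergyGrid(np.linspace(-1.5, 1.5, 301))
        p = WaterComponentParams(d_t=1.98e-5, tau_ps=1.05, d_r=0.0)
        y = water_component_spectrum(p, 0.7, grid)
        gam = jump_diffusion_hwhm(p.d_t, p.tau_ps, 0.7)
        np.testing.assert_allclose(y, lorentzian(grid, gam), rtol=1e-12)

    def test_unit_area(self):
        p = WaterComponentParams(d_t=1.98e-5, tau_ps=1.05, d_r=0.11)
        y = water_component_spectrum(p, 0.7, WIDE)
        assert np.trapezoid(y, WIDE.energies) == pytest.approx(1.0, abs=0.01)

    def test_matches_fft_convolution_of_translation_and_rotation(self):
        # trans Lorentzian (x) [w0 delta + sum_l w_l rot-Lorentzians] via FFT
        from scipy.signal import fftconvolve

        grid = np.linspace(-100, 100, 2**17 + 1)
        h = grid[1] - grid[0]
        egrid = EnergyGrid(grid)
        p = WaterComponentParams(d_t=1.98e-5, tau_ps=1.05, d_r=0.11)
        q = 0.9
        analytic = water_component_spectrum(p, q, egrid, l_max=6)
        gam_t = jump_diffusion_hwhm(p.d_t, p.tau_ps, q)
        trans = gam_t / (np.pi * (grid**2 + gam_t**2))
        w = rotational_weights(q, p.radius_A, 6)
        w = w / w.sum()
        rot = np.zeros_like(grid)
        rot[np.argmin(np.abs(grid))] = w[0] / h  # discrete delta
        for l in range(1, 7):
            g = HBAR_MEV_PS * l * (l + 1) * p.d_r
            rot += w[l] * g / (np.pi * (grid**2 + g**2))
        conv = fftconvolve(trans, rot, mode="same") * h
        sel = np.abs(grid) < 2.0
        err = np.max(np.abs(conv[sel] - analytic[sel])) / analytic.max()
        assert err < 1e-6

    def test_motionless_component_is_flagged_delta(self):
        grid = EnergyGrid(np.linspace(-1, 1, 101))
        p = WaterComponentParams(d_t=0.0, tau_ps=0.0, d_r=0.0)
        assert isinstance(water_component_spectrum(p, 0.7, grid), DeltaComponent)


class TestCompositeModel:
    def _params(self, **over):
        base = dict(
            p_elastic=1.0, p_bulk=0.0, p_hyd=0.0, p_proteome=0.0,
            bulk=WaterComponentParams(d_t=1.98e-5, tau_ps=1.05, d_r=0.11),
            hyd=WaterComponentParams(d_t=5.17e-7, d_r=0.06),
            gamma_proteome_meV=0.431,
        )
        base.update(over)
        return CellModelParams(**base)

    def test_pure_elastic_returns_resolution_profile(self):
        grid = EnergyGrid(np.linspace(-1.5, 1.5, 301))
        res = ResolutionModel.gaussian(0.010)
        y = composite_model(self._params(), 0.5, grid, res)
        np.testing.assert_array_equal(y, res.profile(grid))

    def test_proteome_voigt_matches_numeric_convolution(self):
        grid = EnergyGrid(np.linspace(-1.5, 1.5, 301))
        res = ResolutionModel.gaussian(0.010)
        p = self._params(p_elastic=0.0, p_proteome=1.0, gamma_proteome_meV=0.363)
        y = composite_model(p, 0.5, grid, res)
        oracle = _numeric_lorentz_gauss_conv(0.363, res.sigma_meV, grid.energies)
        assert np.max(np.abs(y - oracle)) / oracle.max() < 1e-6

    def test_voigt_vs_numeric_convolution_across_width_range(self):
        # log-uniform (Gamma, FWHM) pairs in [1e-3, 1] meV, seeded
        rng = np.random.default_rng(7)
        pairs = 10 ** rng.uniform(-3, 0, size=(6, 2))
        for gamma, fwhm in pairs:
            res = ResolutionModel.gaussian(fwhm)
            span = 10 * (gamma + fwhm)
            grid = np.linspace(-span, span, 801)
            egrid = EnergyGrid(grid)
            y = _resolved_lines(np.array([1.0]), np.array([gamma]), egrid, res)
            oracle = _numeric_lorentz_gauss_conv(gamma, res.sigma_meV, grid)
            assert np.max(np.abs(y - oracle)) / oracle.max() < 1e-6

    def test_unit_area_of_background_free_model(self):
        res = ResolutionModel.gaussian(0.010)
        p = self._params(p_elastic=0.01, p_bulk=0.66, p_hyd=0.10, p_proteome=0.23)
        y = composite_model(p, 0.7, WIDE, res)
        assert np.trapezoid(y, WIDE.energies) == pytest.approx(1.0, abs=0.01)

    def test_tabulated_resolution_agrees_with_gaussian(self):
        grid = EnergyGrid(np.linspace(-1.5, 1.5, 1501))
        gauss = ResolutionModel.gaussian(0.010)
        t = np.linspace(-0.2, 0.2, 4001)
        dens = np.exp(-0.5 * (t / gauss.sigma_meV) ** 2)
        dens /= np.trapezoid(dens, t)
        tab = ResolutionModel.tabulated(t, dens)
        p = self._params(p_elastic=0.2, p_proteome=0.8, p_bulk=0.0, p_hyd=0.0)
        yg = composite_model(p, 0.5, grid, gauss)
        yt = composite_model(p, 0.5, grid, tab)
        assert np.max(np.abs(yg - yt)) / yg.max() < 1e-3

    def test_fraction_constraint_validated(self):
        with pytest.raises(ValueError):
            self._params(p_elastic=0.5, p_bulk=0.6)

    def test_background_offset_added(self):
        grid = EnergyGrid(np.linspace(-1.5, 1.5, 301))
        res = ResolutionModel.gaussian(0.010)
        p0 = self._params()
        pb = self._params(background={0.5: 0.25})
        y0 = composite_model(p0, 0.5, grid, res)
        yb = composite_model(pb, 0.5, grid, res)
        np.testing.assert_allclose(yb - y0, 0.25, rtol=1e-12)
        # other Q values fall back to zero background
        np.testing.assert_array_equal(
            composite_model(pb, 0.7, grid, res), composite_model(p0, 0.7, grid, res)
        )
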