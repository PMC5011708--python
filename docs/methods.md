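# Methods

## The model

`qenscell` analyses quasi-elastic neutron scattering (QENS) spectra of
live, hydrogen-rich cell samples.  The measured dynamic structure
factor S(Q, ω) — intensity versus momentum-transfer modulus Q (Å⁻¹)
and energy transfer ω (meV) — is decomposed into four motional
populations plus a flat background, all convolved with the instrument
resolution R(ω):

    S(Q, ω) = p_el · R(ω)
            + [ p_bulk · S_bulk(Q, ω) + p_hyd · S_hyd(Q, ω)
              + p_prot · L(ω; Γ_prot) ] ⊗ R(ω)  +  B(Q)

with the fraction constraint p_el + p_bulk + p_hyd + p_prot = 1.

* **Elastic fraction** p_el: scatterers whose motions are slower than
  the instrument can resolve; a delta function in ω, realized exactly
  as p_el·R(ω) (never as a finite-width numerical spike).
* **Bulk-like water** and **hydration water** each follow a
  jump-diffusion translation convolved with free isotropic rotation.
  Translation gives a Lorentzian of half width
  Γ_T(Q) = ħ·D_T·Q² / (1 + D_T·Q²·τ) (Singwi–Sjölander), where D_T is
  the low-Q diffusion coefficient and τ the residence time between
  jumps; Γ_T saturates at ħ/τ at high Q.  Rotation adds the
  isotropic-rotator (Sears) series: lines of width ħ·l(l+1)·D_R with
  weights (2l+1)·j_l²(Q·a), a the rotation radius.  Because a
  Lorentzian convolved with a Lorentzian is a Lorentzian of summed
  widths, the translation⊗rotation convolution is evaluated
  analytically — no numerical convolution is ever performed for it.
* **Proteome component**: one broad Lorentzian of Q-independent width
  Γ_prot, standing for the fast internal motions of cellular
  biomolecules (dominated by proteins).
* **Background** B(Q): one flat, energy-independent offset per Q slice.

For a Gaussian resolution each resolution-broadened Lorentzian is a
Voigt profile (`scipy.special.voigt_profile`); for a tabulated
resolution curve the quasi-elastic sum is convolved by FFT on the
(uniform) energy grid.

The model is symmetric in ω: at room temperature over a ±1.5 meV
window the detailed-balance asymmetry is negligible and is not
modelled, and the Debye–Waller factor drops out because every spectrum
is area-normalized.

## Parameters, units, defaults

| parameter | meaning | unit | default / bounds |
|---|---|---|---|
| p_el, p_bulk, p_hyd, p_prot | population fractions | – | each in [0, 1], sum = 1 |
| D_Tbulk | bulk-water translational diffusion | cm²/s | init 2.3e-5 (pure water); bounds [0.5, 5]×10⁻⁵ |
| τ_bulk | bulk-water residence time | ps | init 1.0; bounds [0, 10] |
| D_Rbulk, D_Rhyd | rotational diffusion | ps⁻¹ | bounds [0, 1] |
| D_Thyd | hydration-water diffusion | cm²/s | init 5e-7; bounds [0.5, 50]×10⁻⁷ |
| τ_hyd | hydration residence time | ps | fixed at 0 by default (not identifiable below Q ≈ 1.1 Å⁻¹); freeable |
| Γ_prot | proteome Lorentzian HWHM | meV | init 0.4; bounds [0.05, 2] |
| a | water rotation radius | Å | 0.98 (O–H distance), same for both water populations, configurable |

Internally widths are meV, times ps, lengths Å; ħ = 0.6582119569
meV·ps; diffusion coefficients cross the API in cm²/s
(1×10⁻⁵ cm²/s = 0.1 Å²/ps).  The rotational series is truncated
adaptively once the discarded tail weight falls below 1e-4 (l ≤ 5
suffices for Q·a ≤ 1.1; hard cap l = 10), and the kept weights are
renormalized so each component keeps exactly unit area.

## Fitting

**Global fit** (`CellSpectrumModel.fit`): all Q slices are fitted
simultaneously by trust-region-reflective weighted least squares
(`scipy.optimize.least_squares`, ftol = xtol = gtol = 1e-10, numerical
Jacobians).  Shared across Q: the three free fractions (p_bulk is
derived from the sum constraint, being the largest and least
degenerate), both water parameter sets, Γ_prot.  Per Q: the flat
background.  Internally D_Tbulk and D_Thyd are scaled to order-one
units.  Multi-start: the first start is the nominal init, subsequent
starts multiply every free parameter by a seeded log-uniform factor in
[0.8, 1.2]; the best-χ² solution wins, so the objective never
increases across starts and results are bit-for-bit reproducible for a
fixed seed.  Standard errors come from the curvature (J^T J)⁻¹ of the
weighted problem at the optimum, scaled by reduced χ²; a singular
curvature is flagged and pseudo-inverted.  Parameters resting on a
bound are flagged and warned about.

**Per-spectrum normalization.**  The data are area-normalized over the
measured window, so the fit compares the *area-normalized* model curve
(background included, same trapezoid rule, same window) to the data.
This makes the fit a pure line-shape/proportion problem — exactly the
information the normalization preserves — and makes noiseless parameter
recovery exact even though the broad proteome Lorentzian has ~18% of
its area outside a ±1.5 meV window.

**Weighting.**  Default weights are 1/σ² with the uncertainties stated
in the data (`weighting="data"`).  For low-count counting data this
classic Neyman weighting biases widths low: tail bins with ~30 counts
that fluctuate downward get overweighted.  `weighting="pearson"`
therefore re-derives Poisson uncertainties from the *fitted* model
intensities (the count scale is recovered per spectrum from the
intensity/σ² ratio) and refits twice from a warm start.  In replicate
studies this removes a ~3% downward bias on Γ_prot at 10⁵ counts per
spectrum; it is the recommended mode for counting data.

**Model-free path** (`fit_model_free`): each slice independently gets
elastic + 1–4 resolution-convolved Lorentzians + flat background, with
log-parameterized widths, seeded multi-start, and widths reported in
ascending order.  Non-convergence yields a flagged result, not an
exception.  `extract_dispersion` assembles Γ(Q²) curves per component,
omitting failed slices with a warning.

**Jump-diffusion fit** (`fit_jump_diffusion`): weighted fit of the
dispersion relation to a Γ(Q²) curve.  The residence time is freed
only when an F-test (jump vs. purely linear model) is significant at
the 5% level; otherwise τ is pinned at 0 and flagged — with a short Q
range the plateau may simply not be visible, and a free τ would be
unconstrained.  Degenerate inputs (fewer than 3 points, all-zero
widths) are rejected.

**Derived quantities**: rotational correlation times 1/(2·D_R) for
both water populations (undefined when D_R = 0), and cross-condition
comparison tables with relative changes 100·(x_A − x_B)/x_A (flagged
undefined when the reference is 0) and a significance flag comparing
|Δ| with the combined standard error.  Note that 1/(2·D_R) at
D_R = 0.11 ps⁻¹ is 4.545 ps; the literature for these samples quotes
"4.7 ps" for the same definition, a discrepancy we reproduce rather
than hide — the package always computes 1/(2·D_R) literally.

## Synthetic data

The generator emulates a cold-neutron disk-chopper time-of-flight
setup at 10 Å incident wavelength: 19 detector groups at
Q = 0.20…1.10 Å⁻¹ (step 0.05), a ±1.5 meV window with 301 bins, and a
Gaussian resolution of 10 μeV FWHM.  The exact detector grouping of
the original experiment is not public; 19 equally spaced groups is a
convention, and the grouping is configurable.  Scenario presets carry
the published whole-cell parameter values for *T. barophilus* and
*T. kodakarensis* at 0.1 and 40 MPa as generating truth, with τ_hyd = 0
and zero backgrounds; printed fraction columns that sum to 1.00–1.03
are renormalized to sum exactly to 1 (the divisor is retrievable via
`scenario_fraction_scale`).

Counting noise: each slice is scaled to an expected total count
(default 10⁵, comparable to a several-hour measurement per pressure
point), integer counts are drawn per bin from a seeded Poisson
generator, σ = sqrt(max(counts, 1)), and the slice is then
area-normalized.  Noiseless generation returns the forward model
bit-for-bit with a nominal uniform σ = 1e-4.

What the generator does **not** emulate: sample-container scattering,
absorption and self-shielding, multiple scattering, detector
efficiency, the kinematic Q–ω coupling of a real time-of-flight
instrument, detailed balance, or any temperature dependence.  Passing
recovery tests therefore demonstrate that the estimator is unbiased
and well-conditioned *under the stated model*, not that the model is
complete for real reduced data.

## Problem sizes used in the test suite

Full-instrument recovery checks (the acceptance tests) run on the
complete 19 × 301-point preset.  Replicate-based property checks run
scaled down with 3–8 replicates — the estimator-consistency study on a
9-Q, 201-bin layout (five Q groups proved too few to identify τ_bulk
without small-sample bias), the noise-scaling study on a 5-Q, 151-bin
layout — enough to detect gross bias while keeping the whole suite at
desk scale.

## Known limitations

* When the true background is exactly zero it sits on the
  non-negativity bound of the per-Q background parameters; their
  estimates are then half-normal (upward-biased) and absorb a little
  Lorentzian tail intensity, leaving a residual sub-sigma downward
  bias (~1% at 10⁵ counts/spectrum) on Γ_prot and D_Tbulk.  The effect
  vanishes when backgrounds are held at their known value, and is
  immaterial for real data with genuinely nonzero backgrounds.  Full
  Poisson maximum likelihood (deviance residuals) was evaluated and
  gives estimates identical to the Pearson-weighted fit here, so it is
  not the weighting.
* The fraction/width decomposition is degenerate at very low counts;
  the hydration rotational rate D_Rhyd is the softest direction
  (its line is broad and weak), and at 10⁵ counts per spectrum its
  statistical error is of the same order as its value.
* The elastic fraction trades against the narrowest hydration line
  within the resolution width; with a 10 μeV resolution and 10 μeV
  binning this is benign for synthetic data but would matter for real
  spectra with vanadium-shaped resolution wings.
* Curvature-based errors assume a locally quadratic objective;
  bound-pinned parameters (flagged) violate this.
* The per-Q model-free decomposition identifies components by width
  ordering; when two true widths cross or merge, dispersion curves
  must be relabelled by the caller.
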