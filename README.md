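# qenscell

Four-component analysis of quasi-elastic neutron scattering (QENS)
spectra of live cells.

QENS measures the dynamic structure factor S(Q, ω) — scattering
intensity versus momentum transfer Q and energy transfer ω — whose
quasi-elastic broadening encodes diffusive molecular motion on
picosecond time scales.  In a living cell the incoherent signal is
dominated by hydrogen, and a whole-cell spectrum can be decomposed
into four populations:

    S(Q, ω) = p_el·R(ω) + [ p_bulk·S_bulk + p_hyd·S_hyd + p_prot·L(ω; Γ_prot) ] ⊗ R + B(Q),
    p_el + p_bulk + p_hyd + p_prot = 1

an elastic fraction (unresolved motion), bulk-like water, surface-bound
hydration water — each water population a Singwi–Sjölander jump
diffusion, Γ_T(Q) = ħ·D_T·Q²/(1 + D_T·Q²·τ), convolved analytically
with free isotropic rotation (Sears expansion, widths ħ·l(l+1)·D_R,
weights (2l+1)·j_l²(Qa)) — and one broad Q-independent "proteome"
Lorentzian for the internal dynamics of cellular biomolecules.  All
components are convolved with the instrument resolution R (a Gaussian
becomes a Voigt profile per Lorentzian line).

The package is aimed at neutron spectroscopists and biophysicists who
want this decomposition as a reusable, testable library instead of a
one-off beamline script.  It provides:

* the forward model (`qenscell.lineshapes`, `qenscell.params`);
* a statsmodels-style global fit over all Q slices,
  `CellSpectrumModel(...).fit() -> CellModelResults`, with shared
  dynamics parameters, per-Q backgrounds, multi-start seeding,
  curvature standard errors and comparison tables;
* the model-free path: per-Q Lorentzian fits (`fit_model_free`),
  Γ(Q²) dispersion curves (`extract_dispersion`) and jump-diffusion
  fits with an F-test on curvature (`fit_jump_diffusion`);
* a synthetic-data generator for an IN5-like time-of-flight
  configuration (10 μeV resolution, Q = 0.2–1.1 Å⁻¹) with seeded
  Poisson counting noise and scenario presets carrying the published
  whole-cell parameters of *Thermococcus barophilus* (a piezophile)
  and *Thermococcus kodakarensis* at 0.1 and 40 MPa;
* a CLI: `qenscell simulate | fit | dispersion | compare | report`.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Simulate the piezophile at ambient pressure with counting noise, fit
it, and read off the water dynamics:

```python
import qenscell as qc

truth = qc.scenario("Tb_0.1MPa")                  # published generating values
sset = qc.generate(truth, qc.preset_in5(),
                   qc.NoiseModel("poisson", counts_per_spectrum=1e5, seed=1),
                   label="Tb_0.1MPa")
result = qc.CellSpectrumModel(sset).fit(seed=1, weighting="pearson")
print(result.summary())
```

```
Four-component cell model — global fit
  data: 19 Q slices x 301 bins  (Tb_0.1MPa)
  chi2_reduced = 0.9965   nfev = 65   seed = 1

  parameter              value      stderr  flags
  p_elastic             0.0149     0.00211
  p_hyd                 0.0927     0.00216
  p_bulk                0.6651     0.00172  derived
  p_proteome            0.2273     0.00161
  D_Tbulk            1.985e-05    9.53e-08
  tau_bulk                1.14       0.089
  D_Rbulk               0.1032     0.00647
  D_Thyd             5.663e-07    3.49e-08
  tau_hyd                    0           0  fixed
  D_Rhyd                0.0956      0.0328
  Gamma_proteome        0.4298     0.00489
```

Reading the table: about two thirds of the scattering hydrogens move
like bulk water (D_Tbulk ≈ 2.0×10⁻⁵ cm²/s, the free-water value), a
~10% hydration-water population diffuses roughly 40× slower
(D_Thyd ≈ 5×10⁻⁷ cm²/s), and the proteome line width Γ_proteome sits
near 0.43 meV.  χ²_red ≈ 1 says the fit is statistically consistent
with the counting noise.  Comparing the fitted 0.1 MPa and 40 MPa
conditions (`result.compare(other)`) shows the signature effect: the
hydration-water diffusion coefficient of the piezophile drops by ~35%
under 40 MPa while its bulk-water diffusion stays put.

The same workflow from the shell:

```sh
qenscell simulate Tb_0.1MPa --counts 100000 --seed 1 -o tb01.tsv
qenscell fit tb01.tsv --resolution-fwhm 0.010 -o fit_tb01
qenscell dispersion tb01.tsv --resolution-fwhm 0.010 -o disp_tb01
qenscell compare fit_tb01 fit_tb40 -o comparison.csv
```

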