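# rnpquant

Quantification pipeline for comparing CRISPR–Cas9 ribonucleoprotein (RNP)
delivery modalities. It answers, in absolute numbers, the questions a
delivery experiment poses: *how many Cas9 RNPs reached each nucleus, what
fraction of them is DNA-bound, what dose is needed for half-maximal
editing, and how fast are breaks made and repaired* — for electroporation
versus packaged (enveloped-delivery-vehicle) delivery.

The package implements four analysis stages plus seeded simulators that
stand in for the microscope and the droplet reader, so every stage is
testable without instrument data:

1. **FCS copy-number quantification** — fluorescence correlation
   spectroscopy measures the autocorrelation G(τ) of intensity
   fluctuations as labeled RNPs diffuse through a calibrated confocal
   volume. Models provided:

   - free 3D diffusion: `G(τ) = (1/N)·[(1+τ/τ_d)·√(1+s²τ/τ_d)]⁻¹`
   - anomalous diffusion with exponent α and offset G(∞)
   - a two-component mixture of a fast free fraction `F_fast` and a slow,
     anomalously diffusing DNA-bound fraction `1−F_fast`

   The structure factor `s = 0.17` is fixed in all fits. Calibration with
   a dye standard (Alexa Fluor 594, D(25 °C) = 3.88×10⁻⁶ cm²/s,
   temperature-corrected by Stokes–Einstein) yields the effective volume
   `V_eff = π^{3/2}ω₁³/s`, and accepted fits convert to nuclear
   concentration `C = N/(N_A·V_eff)` and copies per nucleus
   `N_nucleus = C·V_nuc·N_A` (V_nuc = 690 μm³ for HeLa).

2. **Fit QC** — measurements with τ_diff1 < 0.5 ms (free RNA),
   τ_diff1 > 10 ms (aggregation), α < 0.3, χ² > 30, or no identifiable
   second component are rejected; conditions need ≥ 20 accepted cells.

3. **Dose–response and kinetics** — four-parameter logistic (4PL) fits of
   editing versus dose give EC50/EC90 and fold-reductions between
   modalities; linear regression maps dose to nuclear concentration;
   editing time courses yield half-maximal times and %-per-hour rates.

4. **ddPCR double-strand-break quantification** — two-channel droplet
   data (HEX reference amplicon, FAM cut-site amplicon) thresholded
   against untreated wells, Poisson-corrected per channel
   (λ = −ln(1−positives/n)), give `%DSB = 100·(1 − [FAM]/[HEX])`.

## Worked example

```python
import rnpquant as rq

# dye standard: literature D(25°C) corrected to the imaging temperature
d37 = rq.temp_correct_diffusion(3.88e-6, 37.0)   # 5.196e-06 cm^2/s

# calibration: dwell time of the dye standard -> waist -> volume
omega1 = rq.lateral_waist(d37, 2.0e-5)            # 2.040e-05 cm (0.204 um)
v_eff = rq.effective_volume(omega1, 0.17)         # 2.776e-16 l  (0.278 fl)

# a two-component nuclear fit returning N = 8.2 molecules in V_eff:
c = rq.concentration_from_n(8.2, v_eff)           # 4.905e-08 M (49.0 nM)
n_nuc = rq.molecules_per_nucleus(3.2e-9)          # 1329.7 -> ~1300 copies
frac = rq.per_cell_fraction(rq.molecules_per_nucleus(39e-9), 15e7)
                                                  # 1.08e-04 (~0.01% of dose)

# dose arithmetic between delivery modalities
rq.fold_change(2.4e6, 5.7e4)                      # 42.1-fold dose reduction
```

A nuclear concentration of 3.2 nM — the electroporation dose producing
half-maximal editing with an efficient guide — corresponds to ~1300 Cas9
RNPs per nucleus, which is only ~0.01% of the electroporated dose;
packaged delivery reaches the same editing with ~42-fold less Cas9.

The same pipeline is scriptable from the shell (`rnpquant --help`):
`calibrate`, `correlate`, `fit`, `quantify`, `dose`, `ddpcr`,
`simulate-fcs`, `simulate-ddpcr`, `make-fixtures`, and
`reproduce-paper`, which prints the worked-example chain above as a
pass/fail table.

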