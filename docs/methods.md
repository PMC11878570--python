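# Methods

## Autocorrelation models

FCS measures the normalized autocorrelation of fluorescence fluctuations
produced by molecules crossing a 3D Gaussian detection volume with
lateral 1/e² waist ω₁ and axial waist ω_z = ω₁/s. Three models are
implemented (`rnpquant.models`):

- **Free diffusion**: G(τ) = (1/N)·[(1+τ/τ_d)·√(1+s²τ/τ_d)]⁻¹, where N
  is the mean number of molecules in the effective volume and τ_d the
  dwell time.
- **Anomalous diffusion**: the same kernel with τ/τ_d replaced by
  (τ/τ_d)^α, plus an additive offset G(∞). α < 1 describes subdiffusion
  from crowding and transient binding in nuclei. An alternative
  "printed" exponent placement — raising the whole parenthesized factors
  to α — is selectable (`placement="printed"`) because both conventions
  appear in the literature; the standard placement is the default and is
  the form the two-component model uses for its slow term.
- **Two-component**: G(τ) = (1/N)·[F_fast·g_free(τ; τ_diff1) +
  (1−F_fast)·g_anom(τ; τ_diff2, α)], a fast freely diffusing fraction
  plus a slow anomalously diffusing (DNA-bound) fraction. A
  `literal_product` form multiplying the two terms is retained for
  fidelity comparisons only: its zero-lag limit F(1−F)/N contradicts the
  meaning of N as a molecule count, so the additive mixture is the
  default.

The structure factor is fixed at s = 0.17 in every fit — it is a
property of the optical train measured once from a dye standard, and
letting it float would trade off against τ_d.

Physical constants: Avogadro's number uses the CODATA value
6.02214076×10²³ mol⁻¹ (some sources print 6.023×10²³; the difference,
<0.02%, is far below every tolerance here). Water viscosity is pinned at
η(25 °C) = 8.90×10⁻⁴ Pa·s and η(37 °C) = 6.913×10⁻⁴ Pa·s and
interpolated with an Arrhenius form η = A·exp(B/T) between 0 and 60 °C;
only the two pinned temperatures matter in practice.

## Calibration

Dye-standard curves are fitted with the free-diffusion model, dwell
times averaged, and the volume derived as ω₁ = √(4·D·τ_d),
V_eff = π^{3/2}ω₁³/s. Literature diffusion coefficients tabulated at
25 °C are corrected with D(T) = D(25 °C)·T/η(T)·2.985×10⁻⁶ Pa·s/K,
which is exactly the Stokes–Einstein proportionality D ∝ T/η with the
prefactor chosen so the relation is the identity at 25 °C. For Alexa
Fluor 594 (3.88×10⁻⁶ cm²/s) this gives 5.20×10⁻⁶ cm²/s at 37 °C. A
V_eff outside 0.25–0.4 fl sets a warning flag — values outside that
band indicate a mis-adjusted correction collar for this optical
configuration. Calibration requires ≥3 usable curves; curves whose fit
fails or whose amplitudes are non-finite are excluded with a logged
reason.

## Correlator

Photon-count series are correlated with the symmetric normalization
G(kΔt) = ⟨F(t)F(t+kΔt)⟩/(⟨F⟩₁⟨F⟩₂) − 1, where the two means run over
the two shifted segments; this suppresses bias from slow drift. Lag zero
is excluded (shot-noise dominated); curves start at one bin time. The
multi-tau estimator computes the first 2m lags (m = 16) at native
resolution, then repeatedly sums adjacent bin pairs and evaluates lags
m+1…2m per octave, producing a quasi-logarithmic grid. On native lags it
is bit-identical to the direct O(N·K) estimator; on coarsened lags it
differs only by binning (second-order in bin width over correlation
time). Long measurements are split into 10 equal sub-traces — mirroring
the ten-trace acquisition convention — correlated separately, and
averaged; the per-lag standard error of the mean supplies fit weights.
When segments are identical the SEM is floored at 10⁻¹⁵ so the
strictly-positive-error invariant of curve containers holds.

## Fitting and QC

Weighted least squares (lmfit, Levenberg–Marquardt) with weights 1/g_se
when per-lag errors exist, otherwise unweighted. Initialization: N from
the inverse early-plateau amplitude, τ_diff1 from the half-fall lag of
the plateau, τ_diff2 = 5×τ_diff1, F_fast = 0.5, α = 0.8, plus two
seeded log-normal jittered restarts; the best-χ² converged start wins.
The ordering τ_diff1 < τ_diff2 is enforced structurally by fitting
δ > 0 with τ_diff2 = τ_diff1(1+δ), preventing label switching. Bounds:
N ∈ (10⁻³, 10⁴), τ ∈ (10⁻⁶, 1) s, α ∈ (0.05, 1.5).

χ² is by default *reduced* — Σ[(g_obs−g_fit)/g_se]²/(n_lags−n_params) —
so the χ² > 30 rejection rule is comparable across lag grids; a raw
(unreduced) mode exists because the original rule's normalization is not
fixed by convention, and the configured mode is recorded with every run.

Model selection compares one- versus two-component χ²; ties within 10⁻⁹
relative go to the one-component model (parsimony). A two-component fit
whose mixture is degenerate (F_fast outside (0.01, 0.99) or
τ_diff2/τ_diff1 < 1.05) is not counted as having a second component.

QC rules (all configurable; defaults): τ_diff1 < 0.5 ms → `free_rna`
(uncomplexed labeled guide diffuses faster than the RNP);
τ_diff1 > 10 ms → `aggregation`; α < 0.3 → `low_alpha`; χ² > 30 →
`high_chi2`; a selected fit without a second component where one was
required → `no_second_component`. Reasons are exhaustive (every failing
rule is listed), and the filter is a pure function. Conditions with
fewer than 20 accepted curves are flagged `insufficient_n`.

## Nuclear quantification

C = N/(N_A·V_eff); N_nucleus = C·V_nuc·N_A with V_nuc = 6.90×10⁻¹³ l
(690 μm³, HeLa). The DNA-bound concentration defaults to
C_bound = (1−F_fast)·C, since the slow component is the bound
population; the alternative C/F_fast form is implemented behind
`mode="literal"` but flagged whenever it exceeds C, which a
sub-population concentration cannot. Summaries print two significant
figures (16 000, 1300, 1200); data files keep full precision.

## Dose–response and kinetics

The 4PL response = bottom + (top−bottom)/(1+(EC50/x)^hill) is fitted on
log10(dose) for conditioning, with bottom ≥ 0 and top ≤ 100 because
responses are percentages. EC-levels invert in closed form:
x = EC50·(level/(100−level))^(1/hill); with hill = 1, EC90 = 9·EC50.
Flat responses raise a non-identifiability error rather than returning
an arbitrary EC50. Fold-changes are simple EC50 ratios.

Half-maximal editing time fits a 4PL in time and returns the closed-form
crossing of the fitted curve at half its fitted plateau (top/2) — the
plateau, not 100%, defines "maximal" — falling back to linear
interpolation of the observed course at half its maximum when the
sigmoid is not identifiable (too few points, no transition, or a
crossing outside the sampled range). Editing rates are finite
differences over a window with interpolated endpoints.

## ddPCR

Channel thresholds come from untreated reference wells: a deterministic
1-D two-means split per channel, threshold at the midpoint between the
negative cluster's upper edge (mean + k·SD, k = 5) and the positive
cluster's lower edge (mean − k·SD). A channel without two separated
modes falls back to mean + k·SD with a warning. Concentrations use
Poisson statistics λ = −ln(1−positives/n) — the droplet-reader
convention — and %DSB = 100·(1−λ_FAM/λ_HEX), clamped to [0, 100] with a
warning when noise makes FAM exceed HEX. The `raw_counts` mode using
positive fractions directly is kept for sensitivity analysis; it is
biased low at high occupancy (≈38% observed at λ = 1 for a true 50%
fraction) because multi-copy droplets saturate, and the tests assert
that bias. A saturated channel (all droplets positive) is bounded with a
half-droplet correction. Droplet-resampling bootstrap confidence
intervals are provided.

## Synthetic data

The generators define the conditions every recovery test runs under:

- **Brownian-dynamics photon traces**: particles in a periodic box of
  half-width 3ω_z per axis (axial detection falls to e⁻¹⁸ at the
  boundary), particle count Poisson-drawn from concentration × box
  volume so amplitude statistics are realistic, Gaussian detection
  profile exp(−2r²/ω₁²−2z²/ω_z²), per-bin expected counts scaled by
  molecular brightness (default 3×10⁴ counts/s/molecule), realized
  counts Poisson-distributed. Defaults: ω₁ = 0.204 μm, s = 0.17
  (V_eff ≈ 0.28 fl), 0.2 ms bins. Subdiffusion is approximated by
  independent Gaussian increments with variance rescaled so the
  cumulative MSD ∝ t^α — not true fractional Brownian motion, whose
  increment correlations this ignores; the analytic generator is the
  primary path for anomalous-fit tests. The displacement stream is
  drawn chunk-wise by a vectorized RNG and consumed by a compiled
  (numba) kernel; everything derives from the config seed.
- **Analytic ACF curves**: model evaluation on a log-spaced grid
  (10⁻⁵–1 s, 40 points/decade) with seeded multiplicative Gaussian
  noise whose relative scale grows 1×→3× across the grid, mimicking the
  larger correlator variance at long lags; the known per-lag noise scale
  is returned as g_se.
- **Droplets**: template copies per droplet Poisson(λ_HEX); each copy's
  cut-site amplicon survives independently with probability 1−f, so
  λ_FAM = λ_HEX(1−f) exactly and the Poisson-mode estimator is unbiased
  at any occupancy. Amplitude clusters default to 1000±100 (negative)
  and 8000±300 (positive).
- **Dose tables**: 4PL plus additive Gaussian noise in percentage
  points, clamped to [0, 100].
- **Time courses**: closed-form two-compartment chain uncut→cut→indel
  with rates k_cut, k_repair per hour; as k_repair→∞ indels approach the
  saturating exponential with half-max at ln2/k_cut.

What the simulators do **not** emulate — detector afterpulsing, dead
time, triplet blinking, optical aberrations, cell-to-cell volume
variability, droplet rain between clusters, PCR efficiency gradients —
bounds what passing tests show: they validate the estimators against
their own generating models at realistic sizes and noise, not against
instrument systematics.

## Problem sizes and numerical choices

The end-to-end particle check uses a single 60-s trace at ⟨N⟩ = 5
(≈6700 particles, 3×10⁵ bins), recovering concentration within a few
percent; recovery studies use 50 curves per occupancy level
N ∈ {2, 5, 20} at 2% noise, 100 dose-curve replicates at 3-point noise,
and 20 000 droplets per well — sizes at which the acceptance margins are
comfortably resolved on a single CPU in minutes. Fold-change
re-estimation regenerates dose tables at 1-point replicate noise (three
technical replicates), matching the tight replicate scatter typical of
flow-cytometry dose curves. Seeds flow from a single integer; identical
(config, seed) runs are byte-identical, including output tables, which
carry the tool version and a hash of the resolved configuration.

## Known limitations

- The approximate subdiffusion generator reproduces the ACF shape but
  not increment memory; anomalous-exponent recovery is therefore tested
  on analytic curves.
- The χ² > 30 rule's effect depends on the configured χ² mode and on
  realistic g_se estimates; with unweighted fits the statistic is
  scale-dependent and the cutoff should be reconsidered.
- Thresholding assumes two amplitude clusters; heavy droplet rain would
  need the fallback or manual thresholds.
- Time-course summaries assume a single rise to plateau; multiphasic
  courses only use the interpolation fallback sensibly.
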