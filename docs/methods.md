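# Methods

This note records the models, algorithms and numerical choices behind
`nirpls`, in the order data flows through the pipeline.

## Data model

A `SpectrumSet` holds a strictly decreasing wavenumber grid (instrument
order), an intensity matrix with one spectrum per row, per-row sample
labels (replicates share a label) and the known amorphous content in
w/w% (NaN for unknowns). Intensities are percent transmittance
(%T ∈ (0, 100]) or absorbance. The nominal instrument resolution (2, 4
or 8 cm⁻¹) is metadata distinct from the grid step: files sampled at
1 cm⁻¹ can carry any nominal resolution, and no stage assumes a
particular step.

All modeling is done in absorbance, A = 2 − log₁₀(%T). The instrument
reports transmittance, but Beer–Lambert additivity holds in absorbance,
where a binary mixture spectrum is exactly linear in the mass fraction;
converting on load makes the latent-variable model interpretable and
the noiseless problem exactly rank-limited. (The alternative — modeling
%T directly — merely shifts curvature into the regression and is not
exposed as an option.)

Wavenumber intervals are half-open, [hi, lo), except the final interval
of a partition, which is closed. This makes k equal-width subintervals
an exact partition of a shared-endpoint grid: slicing and
concatenating is the identity, with no duplicated or dropped boundary
points.

## Pretreatment operators

* **SNV** — per spectrum, subtract the mean and divide by the sample SD
  (n−1); output moments are exactly 0/1. Undefined for constant
  spectra (error).
* **MSC** — per spectrum, least-squares fit x ≈ a + b·ref and return
  (x − a)/b. The reference is the mean *calibration* spectrum at that
  point of the chain, learned at fit time and replayed unchanged on
  validation and unknown spectra; applying an unfitted MSC chain is an
  error. MSC is idempotent with respect to its reference.
* **Savitzky–Golay derivatives** — window 15 points, polynomial order
  2 by default (no values are prescribed by the study design; these are
  conventional for 1 cm⁻¹-sampled NIR). Interior points use the
  standard convolution; edge points are re-fit with a shrinking
  one-sided window that never drops below polyorder+1 points, so the
  output length equals the input length and iPLS interval widths stay
  intact. Derivatives are taken with respect to grid index.
* **Wavelet denoising** — 'db4', decomposition level min(5, maximum for
  the length), soft universal threshold σ̂·√(2 ln n) with σ̂ estimated
  as MAD(finest detail)/0.6745, applied to detail coefficients only
  (VisuShrink). Signal extension mode is 'smooth' (linear), so linear
  trends pass through untouched. These are declared defaults, not
  reconstructions of unstated settings.

Chains are applied in exactly the named order ("SNV+WT" = SNV first).
Every operator is row-wise, hence permutation-equivariant over samples.
A fitted chain serializes to YAML (step list plus MSC reference) so a
calibrated pipeline is reproducible. After a non-trivial chain the
intensities are unbounded and are tagged absorbance-mode regardless of
input mode.

## PLS regression (NIPALS)

Univariate-response NIPALS with mean centering and no per-channel
scaling (channels share physical units; autoscaling would amplify
noise-dominated channels). Per component: w = X'y/‖X'y‖, t = Xw,
p = X't/t't, q = y't/t't, then rank-one deflation of X and y.
Components are nested, so one fit at the maximum count provides every
smaller model; regression vectors come from b_k = W_k(P_k'W_k)⁻¹q_k.
The per-component explained X-variance is ‖t p'‖²/‖X_c‖², the exact
bookkeeping of each deflation step (contributions plus the residual sum
of squares account for 100%).

Requesting more components than the centered-X rank is an error; the
internal cross-validation loop instead stops at the attainable count
and reuses the largest model for higher counts.

**Cross-validation** is leave-one-*sample*-out: all replicate spectra
of a physical sample are held out together, so replicate correlation
cannot leak into the error estimate. RMSECV(k) is the root mean square
over all held-out predictions with k components.

**Component selection** is parsimonious: the smallest k whose RMSECV is
within 2% (relative) of the curve minimum. The default component cap is
10, bounded by the smallest training fold minus one.

## iPLS band selection

The span is split into 12 equal-width subintervals numbered from the
high-wavenumber end (so 10,000–4,000 cm⁻¹ gives 500 cm⁻¹ intervals,
with interval 3 = 9000–8500, 8 = 6500–6000, 12 = 4500–4000). Each
interval gets its own cross-validated component count and RMSECV. The
benchmark is the *full-spectrum* RMSECV at exactly 3 components —
deliberately component-starved, so smooth global nuisance structure
(scatter, baseline drift) that a local model handles cheaply penalizes
the full-spectrum model. Intervals with RMSECV below the baseline are
concatenated in wavenumber order; an empty selection is an explicit
error.

Numerical choice: the strict comparison carries an absolute tolerance
of 1e-9·max(1, SD(y)). On noiseless data both sides are ~1e-14 (pure
rounding error) and the sign of their difference is meaningless; the
tolerance makes selection deterministic there while being vacuous at
any realistic noise level.

## Figures of merit

R² = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)²; RMSE = √(Σ(yᵢ−ŷᵢ)²/n) (reported as
RMSEC/RMSECV/RMSEP depending on the prediction source);
RSD% = 100·√(Σ(ŷᵢ−ȳ)²/(n−1))/ȳ; LOD = 3.3σ/s and LOQ = 10σ/s, so
LOQ/LOD = 10/3.3 identically. σ is taken as the SD of the predicted
contents of the replicate spectra of the blank (lowest-content)
calibration sample, and s is the slope of the predicted-vs-reference
calibration line; "SD of predicted content values" does not pin down
the sample, and the blank is the conventional choice for a detection
limit (the residual SD of the calibration curve is a documented
alternative a caller can compute directly). Report tables round to 4
decimals, half-up.

The precision/repeatability/stability protocols are not specified
beyond "assessed at the 45% level"; they are defined here as three
replicate-measurement regimes of one 45 w/w% sample — back-to-back
rescans of one loading (precision), independently re-packed loadings
(repeatability), and scans spread over a session (stability) — which
the simulator realizes as noise regimes of increasing scope (see
below).

## Pipeline

Stage order: absorbance conversion → full-spectrum RMSECV curve and
3-component baseline → iPLS selection/reconstruction → per-chain fit,
CV and component choice over the grid {raw, SNV, MSC, SG1st, SG2nd} ×
{±WT} → winner by smallest RMSECV (ties: fewer components, then lower
LOD) → calibration curve and LOD/LOQ → validation predictions and
RSDs. Validation data never influences selection; re-running with the
same configuration and inputs yields byte-identical JSON reports. The
CLI (`simulate`, `fit`, `predict`, `validate`, `report`) is a thin
wrapper over the library and exits 0/1/2 for ok/data error/usage
error.

## Synthetic data generator

The generator emulates the study conditions: 21 calibration mixtures at
the published contents (0–100 w/w%), 6 validation mixtures
(≈5/15/25/35/45/70%), three averaged spectra per sample (63 calibration
spectra), grid 10,000–4,000 cm⁻¹ at 1 cm⁻¹ step, nominal resolutions
2/4/8 cm⁻¹.

*Bands.* Each solid form is a sum of Gaussian absorbance bands.
Centers follow published NIR band assignments for the two forms of
indomethacin — the carboxylic-acid O–H/C–O and C–H/C=O combination
bands near 4600 cm⁻¹, crystalline hydrogen-bond bands (4528, 4333,
4188 cm⁻¹, split pairs 4468/4464 and 4093/4076 cm⁻¹), amorphous
combinations (4659, 4611, 4166, 4073 cm⁻¹) and backbone overtones near
8532, 8432 and 5940 cm⁻¹ — supplemented with field-standard band
regions (C–H combinations near 7100–7700, free-vs-bonded O–H first
overtone near 6900/6750, C–H first overtones 5800–6150, C=O second
overtone ≈5200 cm⁻¹) so that every subinterval from 9000 to 4000 cm⁻¹
carries form-discriminating signal and nothing above 9000 cm⁻¹ does.
Depths and widths are free parameters (true intensities are not
published) chosen once: amorphous bands broader, crystalline bands
sharper, crystalline-only bands vanishing with amorphous fraction (the
hydrogen-bond mechanism). Instrument resolution enters as an analytic
Gaussian convolution (SDs add in quadrature, peak area conserved), so
higher resolution sharpens but never heightens peaks.

*Mixing.* A(f) = (f/100)·A_am + (1−f/100)·A_cr exactly, then
%T = 100·10⁻ᴬ — nonlinear in f, as observed for real transmission
peaks.

*Noise* (defaults in parentheses; chosen once as plausible for a
high-S/N FT-NIR transmission accessory): per-point additive detector
noise in %T (SD 0.05), a per-spectrum absorbance gain 1+N(0, 0.01)
with a wavelength-dependent tilt component (SD 0.01), a constant
baseline offset (mean 0.03 AU, SD 0.005), linear tilt (SD 0.004) and
quadratic bow (SD 0.004). The smooth wavelength-dependent terms are
structural, not cosmetic: they require several latent components to
model over the full spectrum but are locally near-affine, which is why
the 3-component full-spectrum baseline loses to local interval models —
the behaviour the band-selection stage exists to exploit. Replicate
regimes: precision = additive noise only; repeatability = the full
model; stability = additive plus baseline drift without repacking gain.
Generation is a pure function of (design, bands, noise model, seed).

*What the simulator does not capture*: real particle-size distributions
(Kubelka–Munk/radiative-transfer effects), instrument line-shape
asymmetry, water/temperature interferences, band shifts with
composition, and the true band intensities of indomethacin. Passing
end-to-end tests therefore demonstrate that the pipeline recovers
composition under the assumed noise structure, not that any particular
accuracy will be achieved on real instrument data.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on an 8 cm⁻¹-step grid (751 points) for
speed; the end-to-end recovery checks and the acceptance script use the
full study geometry (63 spectra × 6001 points, three resolutions). A
full three-resolution study runs in well under a minute on one CPU.

## Known limitations

* Univariate response only (binary mixtures); PLS2/multi-analyte is out
  of scope.
* The iPLS stage evaluates single intervals only (no synergy/moving
  window variants).
* LOD/LOQ depend on the σ convention above; with noiseless synthetic
  replicates σ = 0 and the limits collapse to zero.
* The JCAMP-DX reader covers AFFN `(X++(Y..Y))` tables with a linear
  abscissa only.
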