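# Methods

This note documents the quantitative model behind `fretassay`, the
defaults it ships, the synthetic-data generator that stands in for
instrument data, and the numerical choices that were genuinely open.

## Assay model

The assay is a steady-state, sensitized-emission FRET measurement in
multi-well plates. A donor-dye protein conjugate (emission peak
≈ 520 nm) is mixed with an acceptor-dye conjugate (≈ 570 nm); complex
formation brings the dyes within Förster distance, quenching the donor
and producing sensitized acceptor emission. Two excitation scans are
taken per well: the donor band (470 nm) and the acceptor band
(530 nm by default; some protocols quote 540 nm — the configured value
in `AnalysisWindows.acceptor_ex_nm` is authoritative).

### Cross-talk correction

The 570-nm signal under 470-nm excitation is a sum of three parts:
unquenched donor bleed-through, directly excited acceptor, and the
sensitized emission of interest. Two plate-wide ratio factors, measured
once per plate from dedicated calibration wells and applied plate-wide
(per-well recalibration is not attempted; the factors are
concentration-independent ratios), separate them:

* `a` — mean over a donor-only concentration series of
  I(570)/I(520) at 470-nm excitation;
* `b` — mean over an acceptor-only series of I₄₇₀(570)/I₅₃₀(570).

Both are reported with the population rms across the series. The
corrected signal is `F_FRET = F_DA − a·F_D − b·F_A`, where `F_D` is
measured in the *mixture* (the remaining unquenched donor scales the
bleed-through). Negative `F_FRET` values (zero-acceptor wells, noise)
are deliberately retained for fitting and clipped only at presentation:
truncation at zero would bias the K_d fit upward.

### Peak readout

"Intensity at 520/570 nm" is implemented as the mean intensity over
peak ± 2 nm (`peak_halfwidth_nm`, configurable; 0 gives the interpolated
point value). A small window makes the readout robust to 1–2 nm grid
offsets. All integrals are trapezoidal with linearly interpolated window
endpoints; wavelength grids are never resampled implicitly — operating
on mismatched grids is an error, because silent interpolation hides
acquisition mistakes.

### Spectral FRET efficiency

The published symbolic form of the efficiency estimator used with this
assay exists only as an untranscribed figure; the reconstruction here
follows the standard sensitized-emission method and is kept behind a
single function (`fret.fret_efficiency`) so it can be swapped:

    S  = ∫₅₆₀⁶¹⁰ [ f_mix − (f_mix(520)/f_D(520))·f_D − f_A,470 ] dλ
    E% = 100 · (A^A / A^D) · S / ∫₅₆₀⁶¹⁰ f_A,exA dλ

`f_D`, `f_A,470`, `f_A,exA` are donor-only and acceptor-only reference
scans at the mixture's conjugate concentrations; `A^D`, `A^A` are donor
and acceptor absorbances at 470 nm. Scaling the donor reference to the
mixture's own 520-nm peak is the spectral generalization of the `a`
factor. The estimator is homogeneous of degree zero under a common
rescaling of all four spectra (gain invariance). Published per-A/D
efficiency tables for this assay are strongly non-monotone in A/D and are
*not* used as a correctness oracle; the only efficiency oracle used is
the generator round-trip.

### Binding model

One-to-one binding with ligand depletion: for totals A, D and constant
K_d, `[DA]` is the physical root of `[DA]² − (A+D+K_d)[DA] + AD = 0`,
evaluated in the cancellation-free form `2AD/(s + sqrt(s² − 4AD))`,
`s = A+D+K_d`. The signal model is `F_FRET = F_FRETmax·[DA]/D`. The
hyperbolic (excess-ligand) approximation is wrong by design here: with
K_d ≈ 18 nM and D = 100 nM, complexation depletes a large fraction of
the titrant at the low end of the series.

Fitting: unweighted nonlinear least squares (inverse-variance weighting
available by passing per-point sigmas), multi-start on K_d (5 seeds
log-spaced over kd₀/10…kd₀·10 around the half-maximum estimate, because
the saturation tail is flat enough to trap single-start optimizers),
bounds K_d ∈ (10⁻³, 10⁶) nM and F_FRETmax ∈ (0, 100·max observation),
with bound hits reported. Standard errors come from the Jacobian
covariance. Adjusted R² uses n = number of per-concentration mean points
and p = 2, matching how such fits are usually reported. Whether a
published ± on K_d is a fit standard error or a replicate spread is
often unstated, so both are available: the fit SE always, and a
percentile bootstrap (case resampling of replicate-level points,
stratified within concentration so every resample keeps the full
titration design) on request.

### Screening

Inhibition efficiency is `100·(F_control − F_x)/F_control`. It is
computed per replicate (replicate i of the inhibitor condition paired
with control replicate i) and averaged; the value computed from the two
condition means is reported alongside, since the two differ slightly
whenever control replicates scatter — this mirrors the small discrepancy
one sees between worked single-value examples and replicate-averaged
published tables. The first-order rms is
`100·(f_x/f_c)·sqrt((rms_c/f_c)² + (rms_x/f_x)²)`. Negative inhibition
(enhancers) is reported as-is with a flag. Significance versus control
uses Student's equal-variance t-test by default ("student t-test" being
the convention in this assay's literature; Welch available), two-sided,
stars ** p<0.005 and * p<0.05, no multiple-testing correction by default
(Holm optional). IC50 fitting is deliberately excluded — the report
presents per-dose inhibition only. Dose–response curves are summarized
by per-dose inhibitor rankings.

### Degree of labeling

`F/P = A_max/(ε_dye·l·[protein])` with `A_max` the maximum absorbance
within ±5 nm of the dye's nominal maximum (tolerating small
conjugation-induced shifts) and `[protein] = (A280 − cf·A_max)/(ε₂₈₀·l)`
where `cf` is the dye's 280-nm correction factor. Default dye constants
(Alexa-488-like: ε = 71,000 M⁻¹cm⁻¹, cf = 0.11; Alexa-555-like:
ε = 150,000 M⁻¹cm⁻¹, cf = 0.08) are vendor-documented values shipped as
editable configuration, never hard-coded in the computation. A/D ratios
are computed from first principles as
`(acceptor conc·F/P_acc)/(donor conc·F/P_don)`; published A/D sequences
for this assay are internally inconsistent with proportionality and are
not reproduced verbatim.

## Synthetic-data generator

The generator emulates the plate experiment well enough that every
estimator in the pipeline can be validated by parameter recovery.

* **Bands.** Split Gaussians (two half-Gaussians sharing the peak;
  FWHM 35 nm donor-like, 40 nm acceptor-like; red half widened by 15%).
  A split Gaussian was chosen over a skew-normal because it places the
  mode exactly at `peak_nm` with exact unit amplitude and degenerates to
  an exactly symmetric band at zero asymmetry — properties the recovery
  tests rely on; the qualitative shape is equivalent.
* **Readout tie.** Band shapes are calibrated through the *same* ±2 nm
  windowed readout the pipeline uses: the donor shape is constructed so
  its 570:520 readout ratio equals the target `a` exactly, the acceptor
  emission under 470-nm excitation is exactly `b` times its
  acceptor-band-excitation emission, and the sensitized contribution has
  a 570-nm readout of exactly `F_FRETmax·[DA]/D`. Without this tie,
  recovery would only hold up to second-order window-curvature factors
  (~0.2%); with it, noiseless recovery is exact to solver tolerance,
  which is the property the validation suite asserts.
* **Idealizations.** The acceptor emission shape is constructed to have
  a zero 520-nm readout (the real dye's blue tail is a few permille
  there), and the donor dye is treated as not excited in the acceptor
  band. Both make the cross-talk bookkeeping exactly invertible;
  relaxing them perturbs recovered quantities at the sub-percent level.
* **Equilibria.** Titration wells use the ligand-depletion quadratic.
  Inhibitor wells solve the coupled equilibria D+A⇌DA (K_d), D+I⇌DI
  (K_i) by damped fixed-point iteration on free donor (relative
  tolerance 10⁻¹²), validated in tests against an independent bracketed
  root-finder. Donor quenching is modeled as
  `F_D(mix) = F_D(free)·(1 − e_complex·[DA]/D)` with per-complex
  transfer efficiency `e_complex = 0.6` by default (only its
  monotone-quenching character matters to the pipeline; no estimator
  consumes it).
* **Efficiency tie.** In screen mode the sensitized amplitude is set so
  the pipeline's efficiency estimator returns `target_efficiency_pct`
  (default 53.51%) for the uninhibited control, and scales with
  `[DA]/[DA]₀` thereafter; the implied per-condition true efficiencies
  and inhibitions are recorded in the ledger sidecar.
* **Noise and replicates.** Per-wavelength multiplicative log-normal
  noise with mean 1 (CV default 2%) applied to signal plus a constant
  background (50 RFU); blanks measure the background. Replicates are
  3 samples × 3 reads = 9 measurements per condition, emitted as nine
  wells sharing an identical condition record (the plate format keys
  spectra by well and excitation); grouping is by identical condition.
* **Defaults as study design.** Donor 100 nM; acceptor series
  0, 25, 50, 100, 150, 200, 300, 400, 600, 800, 1200, 1600 nM
  (12 points to 1.6 µM); K_d = 17.93 nM; F_FRETmax = 6330 RFU;
  a = 0.129; b = 0.101; F/P 1.48 (donor) and 3.14 (acceptor); donor-only
  calibration at 100–300 nM (3 points) and acceptor-only at 100–500 nM
  (5 points); ε₄₇₀ = 60,000 (donor) and 12,000 M⁻¹cm⁻¹ (acceptor) with
  0.5 cm effective path for the absorbance ratio. Where the assay
  literature states no value (band widths, background, ε₄₇₀,
  `e_complex`, inhibitor K_i values), defaults were chosen once for
  physical plausibility and are ordinary configurable parameters.
* **What the generator does not emulate.** Photobleaching, inner-filter
  effects, detector saturation, spatial plate gradients, wavelength-
  correlated noise, and real dye spectra digitized from data sheets.
  Passing recovery tests therefore demonstrates estimator correctness
  under the stated model, not robustness to instrument artifacts absent
  from it.

## Degenerate inputs and edge policies

* Grid mismatch, non-increasing grids, duplicated scan points, and
  layout/spectra inconsistencies are hard errors at I/O time.
* Ratio factors with non-positive denominators raise degenerate-input
  errors; factors ≥ 1 are computed but flagged with a warning.
* All-zero titrations raise a degenerate-data error; saturated
  (constant) titrations either fail to fit or return an unbounded K_d
  standard error / a bound hit — both are honest "unidentifiable"
  signals.
* Efficiencies are clipped to [0, 100]% only via the presentation-time
  accessor; all arithmetic uses unclipped values.
* t-tests on two zero-variance groups return p = 1 (equal means) or
  p = 0 (distinct means), the analytic limits.

## Problem sizes used in validation

The validation suite runs the full plate pipeline at the study design
(12 concentrations × 9 replicate wells plus calibration wells, ~120
wells × 2 excitations × 301 wavelengths). Monte-Carlo checks use 200
repetitions for estimator bias, 100 simulated experiments × 150
resamples for bootstrap coverage, and 1000 null draws for t-test
calibration — sizes at which the checked statistics are stable to well
within the asserted tolerances.
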