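# Methods

## Model

The package estimates resting oxygen extraction (OEF₀) by reconciling two
expressions for the maximum BOLD signal M. The calibration expression
(`oxymodel.m_calib`) maps the measured peak fractional BOLD and CBF
responses to a breath-hold stimulus — together with the arterial O₂
content at baseline (room air, PaO₂ 127 mmHg) and at the breath-hold peak
(104 mmHg) — onto M, for an assumed OEF₀. The capillary oxygen-diffusion
expression (`oxymodel.m_diffusion`) maps resting physiology (OEF₀, CBF₀,
CaO₂, [Hb]) onto M directly. Both are monotone-in-OEF₀ curves that cross
once in the physiologic range; `solve_oef_grid` evaluates both on the
1000-point OEF grid (0.001…1.000, step 0.001) and keeps the minimiser of
|M_calib − M_diffusion|. Solutions on a grid boundary, voxels without a
vasodilatory response (fractional CBF change ≤ 0), and voxels whose data
admit no positive-M candidate are flagged invalid rather than raised.

Two numerical conventions matter:

* **Units inside the diffusion expression.** The oxygen delivery product
  OEF₀·CBF₀·CaO₂ is expressed in µmol/mL tissue/min: CBF in
  mL blood/mL tissue/min (printed value / 100, tissue density 1 g/mL) and
  CaO₂ converted from mL O₂/dL at 44.64 µmol per mL O₂ (ideal gas,
  22.4 L/mol; configurable as `ModelConstants.o2_umol_per_ml`). Under this
  convention the grey-matter operating point (OEF 0.37, CBF 54 mL/100 g/min,
  Hb 15 g/dL, TE 30 ms, A·ρ/K = 8.85) gives M = 0.0998, i.e. ~10% — the
  healthy grey-matter scale.
* **Negative-response regime.** Because of dissolved O₂, CaO₂/(φ·[Hb]) can
  slightly exceed 1, so the deoxyhaemoglobin term crosses zero near
  OEF ≈ 0.008 and the calibration expression's braced denominator changes
  sign at low OEF with strong vasodilation. There the model predicts a
  *negative* BOLD response with a still-positive M. `m_calib` therefore
  returns the algebraic value wherever it is defined (NaN only for a zero
  denominator or a negative bracket under the non-integer exponent β), and
  the grid solver admits only candidates with M > 0. This preserves the
  exact forward/inverse round trip over the whole grid and removes a
  spurious near-zero crossing next to the dissolved-O₂ floor.

CMRO₂ uses the Fick principle, CMRO₂ = CaO₂·OEF₀·CBF₀, reported in
µmol O₂/100 g/min with the same mL-to-µmol factor.

## Pipeline

Stages and their defaults (all configurable through `PipelineOptions`):

1. **Echo splitting.** Perfusion from echo 1 by surround subtraction
   (each volume vs the mean of its two opposite-condition neighbours,
   signed control − tag; one-sided at the series ends, so output length
   equals input length); BOLD from echo 2 by surround averaging.
   Tag/control parity is configurable (`AcquisitionSpec.tag_first`,
   default tag-first).
2. **Smoothing.** Slice-wise 2-D Gaussian, σ = 0.5 px, reflective
   boundaries (slice means preserved).
3. **High-pass.** Gaussian-weighted running-line detrending with
   σ = FWHM/2.355 where FWHM = 100 s, converted to samples at the TR; the
   local linear fit is subtracted and the series mean restored exactly.
   A linear drift is removed to numerical precision; a 50 s oscillation
   passes at ≥ 98% amplitude.
4. **Masks.** Brain = voxels above 10% of the robust (99th-percentile)
   maximum of the mean BOLD image. Grey matter = mean perfusion between
   the 85th and 99th percentiles over brain voxels (linear-interpolation
   percentiles; the top percentile rejects macrovascular voxels). The
   boundary comparisons carry a 1e-9 relative slack so global intensity
   rescaling cannot flip boundary ties.
5. **Global regressor.** Mean in-mask BOLD and perfusion series are
   z-scored, combined 2:1 (BOLD:ASL), and affinely rescaled to [0, 1], so
   a regression slope equals the peak response.
6. **Delay and regression.** Integer-lag cross-correlation of each
   voxel's concatenated z-scored BOLD+ASL series against the shifted
   regressor, lags −5…+5 (±22 s); ties prefer the smallest |lag|, then
   the negative one. Voxels with peak correlation < 0.2 are flagged.
   OLS on [intercept, shifted regressor] yields baselines and fractional
   changes; non-positive baselines invalidate the voxel.
7. **Calibration.** Single-PLD pCASL quantification against the PD image:
   CBF = 6000·λ·ΔM·exp(PLD/T1b) / (2·α_eff·M0·T1b·(1 − exp(−τ/T1b))) with
   λ = 0.9 mL/g, combined labeling/background-suppression efficiency
   0.72, blood T₁ = 1.65 s — community consensus defaults, all
   configurable. The paper-protocol acquisition (TR 4.4 s, TE 10/30 ms,
   τ = PLD = 1.5 s) is the `AcquisitionSpec` default.

The arterial state uses the group-mean PaO₂ values (127 mmHg baseline,
104 mmHg breath-hold) rather than per-subject gas traces; [Hb] comes from
the subject's venous T₁ (below) or is supplied directly. Motion correction
and anatomical registration are out of scope: input is assumed realigned.

## Venous oximetry (TRUST / inversion recovery)

Venous T₁ is fitted with the long-TR magnitude model
S = |a + b·exp(−TI/T₁)| on the first 40 points of the repeat-averaged
TI ladder (60 × 150 ms), with multi-start nonlinear least squares (the
magnitude model has a cusp at the null). Voxel selection is two-step: the
five most intense candidates at the second inversion time, then the
smallest relative RMS deviation from the mono-exponential. T₁ maps to
haematocrit via T₁ = 1/(0.83·Hct + 0.28) and on to [Hb] via
Hct = 0.0485·[Hb](mmol/L) + 0.0083, converted to g/dL with the
haemoglobin monomer molar mass 16,114 g/mol (configurable).

TRUST difference signals (two brightest voxels, three repeats averaged)
are fitted with S = S₀·exp(−eTE/T₂) at eTEs 0/40/80/160 ms. T₂ inverts to
the venous saturation Yv through an Hct-dependent oximetry calibration,
1/T₂ = A(Hct) + B(Hct)·(1−Yv) + C(Hct)·(1−Yv)², implemented as a
pluggable coefficient table whose default is the bovine-blood calibration
for a CPMG inter-echo spacing of 10 ms; inversion is by bisection
(|ΔYv| < 1e-6), with out-of-range T₂ clamped under a warning. Global
OEF = (Ya − Yv)/Ya with Ya = 0.98.

## Synthetic sessions

`synthdata` forward-generates complete sessions from known truth. The
breath-hold paradigm is 10 holds × 20 s with 30 s recovery, 24 s lead-in
(total 8 min 44 s), sampled at TR 4.4 s; the haemodynamic response is a
boxcar convolved with a single-exponential kernel (τ = 8 s — the response
model is a package choice, configurable). PaO₂ follows the same
normalised respiratory driver as CBF, matching the single
baseline/breath-hold PaO₂ pair used in estimation.

The default phantom is an elliptical brain (22×22×4) with a white-matter
bulk (CBF 22), a wide interior grey-matter annulus (CBF 54, fractional
CBF response 0.12) and one bright vessel column in the white-matter core
(4× grey-matter perfusion) that the upper mask percentile must reject.
ASL signals invert the CBF quantification equation exactly (so
calibration round-trips); BOLD baselines are 500 au on an M0 of 1000 au.
Noise is additive white Gaussian per echo, with defaults chosen to give a
grey-matter ASL tSNR ≈ 4 after surround subtraction and BOLD tSNR ≈ 80 —
representative of 3 T dual-excitation pCASL. Population draws use
OEF ~ N(0.37, 0.04), CBF ~ N(54, 10), Hb ~ N(14, 1) (healthy-adult
grey-matter statistics), and session-level variation models perfusion
drift (×N(1, 0.03)) and variable breath-hold performance (peak fractional
CBF ± 0.02) — the latter affects BOLD and ASL together, which is why it
largely cancels in OEF.

**Response linearisation.** By default each voxel's BOLD time course is
the shared regressor scaled by the exact model-derived peak amplitude
("linearized"). The fully nonlinear evaluation of the calibration
expression at every time point ("exact" mode) deviates from this shape by
up to ~15% at mid-regressor values; since the estimator measures peak
responses by linear regression, only the linearised generator makes the
noiseless simulator/estimator pair exactly adjoint (OEF to one grid step,
CBF₀ to < 0.3%). The exact mode is retained for sensitivity studies.

**What the simulator does not emulate:** motion, physiological noise
beyond white Gaussian, arterial transit and slice-timing effects, partial
volume beyond the smoothing-induced mixing at compartment borders, and
per-subject PaO₂ trajectories. Passing tests therefore demonstrate
correctness of the estimator against its own generative assumptions and
robustness at realistic SNR — not accuracy on in-vivo data.

## Statistics

ICC is the two-way mixed-effects, absolute-agreement, single-measure
coefficient computed from ANOVA mean squares, with the standard F-based
95% CI (Satterthwaite degrees of freedom). Bland–Altman reports
mean ± 1.96·SD limits, switching to median and 2.5/97.5 percentiles when
a Shapiro–Wilk test (p < 0.05 on either variable) indicates
non-normality. The between-measurement CV is |A−B|/(√2·mean)·100 per
subject (two-point SD over the mean), reported mean ± SD across subjects.
Paired comparisons use a two-tailed sign-flip permutation test on the
paired differences — the ROI-level analogue of a voxelwise permutation
t-test; cluster-enhanced voxelwise inference is deliberately out of
scope. All 2ⁿ sign assignments are enumerated for n ≤ 14 (exact p);
larger n uses seeded Monte-Carlo with the observed assignment included.

## Problem sizes and reproducibility

Simulated studies use the 22×22×4 phantom (≈1260 brain, ≈200 grey-matter
voxels) and the full 120-volume paradigm; the repeatability study runs 20
subjects × 2 sessions at the stated tSNR. These sizes give stable
statistics while keeping a full acceptance run near ten seconds. The
two-condition sensitivity analysis is run noiseless: it isolates the
method's *systematic* ability to recover a 3.4% OEF contrast, which at
single-ROI scale would otherwise be dominated by measurement noise (noise
robustness is assessed separately by the repeatability study). Every
stochastic output is fully determined by (seed, configuration); seeds are
recorded in simulator output sidecars.

## Known limitations

* The diffusion expression assumes PmO₂ = 0 and a fixed A·ρ/K; neither is
  estimated from data. Regimes with concurrently long capillary transit
  and elevated mitochondrial O₂ tension are outside the model.
* The method requires a vasodilatory reserve; voxels without a positive
  CBF response are flagged invalid by design.
* Estimates in white matter and near large vessels are unreliable (low
  perfusion SNR, macrovascular contamination); the perfusion-percentile
  mask confines reporting to grey matter.
* The T₂–Yv calibration table is a bovine-blood default; substitute a
  different table via `T2YvCalibration` where appropriate.
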