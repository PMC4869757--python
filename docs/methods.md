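# Methods

This note documents the models, numerical choices and design decisions
behind `petmrcorr`, and what the synthetic phantoms do and do not show
about real patient data.

## Grids, containers, resampling

All images live on axis-aligned regular lattices (`ImageGrid`: shape,
spacing in mm/voxel, world origin at the center of voxel (0,0,0)).  Voxel
indices are 0-based and world coordinates are voxel-center based, which
removes any half-voxel ambiguity; maps and masks are only compared on
identical grids, and resampling is the explicit bridge between grids.
Oblique affines are rejected — the analysis needs no oblique support, and a
silent mis-read would corrupt every downstream sample.

Resampling uses B-spline interpolation of degree 0, 1 or 3 (default 3) via
`scipy.ndimage.map_coordinates`.  Target voxels outside the source field of
view come back NaN rather than extrapolated.  Invalid (non-finite) source
voxels are zero-filled for the spline evaluation, but a conservatively
dilated invalidity indicator (dilation = spline support half-width) is
carried through linear interpolation and any touched target voxel is
flagged NaN, so no value is ever synthesised across an invalid voxel.
Degree-3 splines reproduce cubic polynomials exactly in the interior; the
recursive prefilter's boundary handling (mirror) perturbs values within
roughly a dozen voxels of the volume edge (error ∝ 0.268^distance), which
the tests respect by checking polynomial reproduction away from edges.

4D NIfTI carries no reliable frame timing, so dynamic series store frame
starts/durations (seconds) in a JSON sidecar written and read together with
the volume.

## Wash-in summary maps

`mean_activity_map` implements rectangle integration over a window
(default 0–240 s): each frame contributes its value times the length of its
overlap with the window, and the sum is divided by the window length.  The
value-times-overlap convention is the one consistent with frame-averaged
PET data; frames partially overlapping the window edges are pro-rated by
overlap length, which removes the discretization bias of whole-frame
inclusion/exclusion.  Coverage is enforced: a total gap larger than one
frame duration raises an error naming the missing interval.  The map is
linear in the series and window-additive to 1e-9, both tested.

DCE enhancement is the series minus the per-voxel mean of the first
`n_baseline` frames.  The bolus arrival is an acquisition-driven config
parameter, not auto-detected.  ΔS̄_DCE applies the same rectangle mean to
the enhancement series over the 0–4 min post-injection window.

ADC from two b-values is the exact monoexponential inversion
ln(S_low/S_high)/(b₂−b₁); voxels with non-positive signal or
S_high > S_low (negative ADC) are flagged invalid rather than raising,
and equal signals give ADC 0.

## Extended Tofts modelling

The tissue model is C_t(t) = v_p·C_p(t) + K^trans ∫₀ᵗ C_p(τ)
e^{−k_ep(t−τ)} dτ with k_ep = K^trans/v_e (units: K^trans in min⁻¹, v_e and
v_p dimensionless, v_e+v_p ≤ 1).  The convolution is evaluated on a uniform
time grid refined 10× relative to the frame spacing, with the exponential
kernel integrated analytically per step assuming piecewise-linear C_p; the
resulting constant-coefficient recursion runs through `scipy.signal.lfilter`
(stable for any k_ep, no overflow, exact for the piecewise-linear input).
Against the constant-AIF closed form the error is ~1e-13 relative, far
inside the 0.1 % budget.

**AIF.** No functional form is prescribed by the emulated protocol, so the
default is a biexponential decay gated by a brief exponential bolus rise,
C_p(t) = (a₁e^{−m₁s} + a₂e^{−m₂s})(1−e^{−rs}) with s = (t−t₀)/60 min, zero
before the bolus arrival t₀.  `fit_aif` estimates all six parameters from
the carotid enhancement curve by Levenberg–Marquardt with log-transformed
positive parameters and a small multistart over (m₁, m₂) inits; it requires
at least three pre-bolus samples and a peak exceeding the pre-bolus level
by three standard deviations, otherwise it raises and asks for a manual t₀.
A `constant` form exists for closed-form checks.

**Fitting target.** The emulated analysis fits signal-time curves whose
relation to concentration is an approximately constant factor at low
enhancement; the fit therefore works on baseline-subtracted enhancement
with one global enhancement-per-concentration scale that is absorbed into
the AIF amplitude.  Every downstream statistic is a rank correlation and
hence invariant to this monotone scale.  The enhancement→concentration
conversion via native T1 (below) is provided as an optional path, off by
default.

**Bounds and initialization.** K^trans = e^a, v_e = σ(b),
v_p = σ(c)·(1−v_e) turn the box constraints (and v_e+v_p ≤ 1) into an
unconstrained problem with smooth gradients, so Levenberg–Marquardt runs
without clipping and its convergence flag is honest.  Initialization is
(0.1 min⁻¹, 0.2, 0.02); when the residual exceeds a noise-scaled threshold
(0.0025·n·peak², i.e. the RSS of ~5 % peak noise) two further starts are
tried and the best kept.  An all-zero curve short-circuits to
(0, 0, 0, converged) — v_e is unidentifiable without exchange, and an
undefined k_ep (K^trans > 0 with v_e = 0) is rejected.  Noiseless recovery
across a 5×5×5 grid spanning the physical ranges at 2.9 s sampling is
~1e-12 relative; with 5 % peak Gaussian noise the median K^trans error over
100 repeats stays under 10 %.

Regional fits average the enhancement curves over each 3×3×4 block's GTV
voxels first and fit once per block — the regional-level counterpart of the
voxel fits, matching how the regional analysis is defined.

**T1 mapping.** DESPOT1 linearization of the SPGR equation
S = M₀ sin α(1−E₁)/(1−E₁cos α), E₁ = e^{−TR/T1}: with two flip angles the
slope of S/sin α vs S/tan α gives E₁ exactly, so noiseless recovery over
200–3000 ms is at machine precision; voxels with E₁ outside (0,1) are
flagged invalid instead of raising.  The concentration conversion inverts
the SPGR equation per frame under fast-exchange linear relaxivity
R₁(t) = 1/T1 + r₁C(t), flagging frame-voxels outside the monotone branch.

## Normalization

SUV = activity[kBq/mL] / (injected[kBq]/weight[g]) assuming 1 g/mL tissue;
the injected activity is taken as already decay-corrected to scan start by
the caller (the package does no half-life arithmetic — the acquisition
protocol, not the analysis, owns that convention).  TBR divides by the
arithmetic mean of the background-muscle ROI (median available via
argument; the choice is recorded in the map name).  Both transforms are
strictly monotone per voxel, so all Spearman coefficients are exactly
invariant — tested as exact equality.

## Correlation analysis

`spearman` is the Pearson correlation of average ranks (ties get their mean
rank).  A constant vector raises rather than contributing a silent zero to
a cohort median.  The implementation is cross-checked against an
independent brute-force oracle (explicit sort-based ranking plus the
Pearson formula) and against `scipy.stats.spearmanr` to 1e-12 on
tie-containing data, and satisfies monotone invariance and antisymmetry as
property tests.

Voxel samples are the paired values at GTV voxels where both maps are
valid; dropped voxels are counted and reported.  Regional samples are means
over non-overlapping 3×3×4-voxel blocks tiling the GTV bounding box from
its minimal corner; a block is kept iff ≥ 50 % of its voxels lie in the GTV
and a kept region averages only its GTV voxels (both knobs exposed in
`RegionSpec`, since the anchoring and partial-block policy of the emulated
analysis are unstated).  On the 2.8×2.8×2.0 mm³ PET grid a block spans
8.4×8.4×8 mm³.  Patients with fewer than ten sub-regions are excluded from
the regional level but still contribute at the voxel level.  Pairs
involving a modality a patient lacks are simply absent — no imputation —
and cohort tables report per-pair median, (min, max) and N, with
zero-contributor pairs absent rather than zero.

## The phantom generator

The generator's central promise is exact control of the population Spearman
structure.  One latent Gaussian field per modality is drawn white, mixed to
Pearson ρ_P = 2 sin(π ρ_S/6) (the Gaussian-copula inverse of the Spearman
map), smoothed with a single shared periodic Gaussian kernel, and
standardized.  A shared linear filter applied to jointly stationary fields
preserves the pointwise cross-correlation exactly, and the periodic
boundary keeps the fields stationary to the edge.  Strictly monotone
marginal transforms (Gaussian CDF, then affine into the modality range)
convert latents into SUV 1–15, TBR 0.8–3, ADC 0.6–2.0×10⁻³ mm²/s,
K^trans 0.01–0.6 min⁻¹, v_e 0.05–0.6, v_p 0.01–0.1 (so v_e+v_p ≤ 0.7 < 1
everywhere), and a perfusion surrogate 2–10 kBq/mL.  Because ranks are
untouched by monotone maps, the noise-free maps inherit the latent sample
Spearman *exactly* — the property the pipeline-recovery tests assert.

Latent-to-map wiring: `fdg`→FDG, `fmiso`→late FMISO, `perfusion`→ the
FMISO wash-in series (Ā_FMISO is exactly linear in the surrogate, as the
frame values are exact frame averages of P·(1−e^{−t/τ}), τ = 60 s),
`dce`→ the Tofts truth triple driving the forward-simulated DCE series
(2.9 s frames, 300 s duration, 10 baseline frames, bolus at 29 s, global
enhancement scale 10 per mM over a baseline signal of 100), `adc`→ADC.
Carotid voxels carry v_p = 1 so the DCE series contains the AIF itself for
the per-patient AIF fit.  Mean DCE enhancement is monotone in the `dce`
latent (all three Tofts parameters increase with it), so ΔS̄_DCE also
inherits the latent ranks exactly in the noiseless case.

Geometry: ellipsoidal GTV of semi-axes (21, 21, 17) mm ≈ 31 cm³ — the
scale of the emulated cohort's median tumor — centered on a
36×36×26-voxel grid at 2.8×2.8×2.0 mm³ (~2000 GTV voxels, ~56
sub-regions), with a muscle box and a carotid column placed disjointly.
The default target matrix uses the emulated cohort's median coefficients
for its four flagship pairs (FDG/FMISO 0.56, FDG/Ā_FMISO 0.55,
Ā_FMISO/ΔS̄_DCE 0.46, ADC/FDG −0.39) and moderate plausible values
elsewhere, chosen once so the matched Pearson matrix is positive definite
(minimum eigenvalue ≈ 0.36).

Noise is added after the marginal transforms, per modality: additive
Gaussian for post-reconstruction PET maps and dynamic series, Rician for MR
magnitude maps.  The emulated protocol publishes no noise magnitudes, so
the defaults (SUV σ 0.3, TBR σ 0.08, ADC σ 5×10⁻⁵ mm²/s, DCE frame σ 2
signal units, wash-in frame σ 0.3 kBq/mL) are config placeholders at
PET/MR-plausible relative levels — small enough that rank-correlation
attenuation stays ≈ 1 %, which is what "calibrated noise" means here.  All
randomness flows from one seed through spawned generators, so a fixed seed
reproduces datasets bit-exactly.

**What the phantom does not emulate:** anatomy beyond ellipsoids,
PET reconstruction physics (sinograms, attenuation, scatter,
partial-volume), registration error between modalities, patient motion,
and ADC geometric distortion.  Passing tests therefore demonstrate the
correctness and calibration of the *analysis*, not the physiological
truth of any particular patient correlation; in real data, registration
and distortion push measured coefficients toward zero in ways the phantom
deliberately omits.

## Problem sizes and determinism

Default study conditions: 8 synthetic patients per cohort (the dynamic-
protocol group size), ~2000 GTV voxels each, 104 DCE frames at 2.9 s,
17 wash-in frames at 15 s.  The seed-averaged recovery checks use 20
cohort replicates; the kinetic recovery checks use a 5×5×5 parameter grid
at 90 frames.  Every stochastic step takes an explicit seed and the
pipeline writes a manifest (config hash, version, per-output checksums,
warnings) so identical configs reproduce identical outputs, which the
tests assert at the byte level.

## Known limitations

- Voxelwise Tofts fitting is a per-voxel Python loop over Levenberg–
  Marquardt fits (~4 ms/voxel); it is deliberately kept simple and is
  switched off by default in cohort runs (`AnalysisSettings.fit_dce`),
  where ΔS̄_DCE carries the DCE information into the correlation matrix.
- The AIF fit assumes the carotid curve starts pre-bolus and has a single
  bolus; no dispersion or recirculation term is modelled.
- `m₂` (slow washout) is weakly identified on a 4–5 min acquisition; the
  multistart mitigates but cannot remove this.
- Regional coefficients on smooth phantoms track voxel coefficients to
  within sampling noise; the phantom cannot reproduce regional-vs-voxel
  differences caused by registration error, since it simulates none.
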