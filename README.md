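# petmrcorr

Multi-parametric PET/MR correlation analysis of head-and-neck tumors,
re-built as a tested, reusable pipeline and exercised end to end on
synthetic multi-modal phantoms with known ground truth.

## The scientific problem

Functional imaging of head-and-neck cancer produces several candidate maps
for biologically adapted radiotherapy: FDG-PET (glucose metabolism),
FMISO-PET (hypoxia, both late-static and early wash-in), ADC maps from
diffusion-weighted MRI (cellularity), and DCE-MRI derived perfusion/
permeability parameters.  Whether these maps are complementary or partly
redundant is assessed by correlating every available pair, per patient,
inside the gross tumor volume (GTV).  This package implements that
analysis for physicists and image analysts who want to run it, test it, or
stress it on simulated data:

- **Wash-in summary maps.** Dynamic FMISO activity is integrated per voxel
  over 0–4 min post injection with the rectangle method and divided by the
  window length, giving the mean-activity map Ā_FMISO; DCE signal is
  baseline-subtracted and averaged over the same window, giving ΔS̄_DCE.
- **Kinetic modelling.** DCE enhancement curves are fitted voxelwise and
  per 3×3×4-voxel region with the extended Tofts model,
  C_t(t) = v_p·C_p(t) + K^trans ∫₀ᵗ C_p(τ)·e^{−k_ep(t−τ)} dτ,
  k_ep = K^trans/v_e, using Levenberg–Marquardt least squares and a
  per-patient arterial input function fitted to the common-carotid curve.
  Dual-flip-angle (DESPOT1) T1 mapping and an optional
  enhancement→concentration conversion are included.
- **Normalization.** FDG activity → SUV (activity / injected dose per gram);
  FMISO activity → TBR (division by the mean signal of a background neck
  muscle).  Both are strictly monotone, so they provably change no rank
  correlation.
- **Correlation.** Tie-corrected Spearman coefficients r per map pair and
  patient, at the voxel level (samples on the 2.8×2.8×2.0 mm³ PET grid) and
  the regional level (means over non-overlapping 3×3×4-voxel sub-regions,
  8.4×8.4×8 mm³).  Patients with fewer than ten sub-regions are excluded
  from the regional level.  Cohort tables report the median, range and N
  per pair.
- **Phantoms.** A Gaussian-copula generator produces cohorts of synthetic
  patients whose maps have any requested inter-modality Spearman structure
  (Pearson ρ_P = 2·sin(π·ρ_S/6) on latent fields, monotone marginals into
  modality ranges, forward-simulated DCE and wash-in series, PET/MR-style
  noise), so every stage has a known ground truth.

## Worked example

```python
from petmrcorr import RunConfig, run_analysis

results, summary, manifest = run_analysis(
    RunConfig(output_dir="results/analysis", seed=0, n_patients=8))
print(summary[summary.pair == "FDG/FMISO"].to_string(index=False))
```

prints (seed 0, the default eight-patient phantom cohort):

```
     pair    level  median_r    min_r    max_r  n_patients
FDG/FMISO regional  0.534860 0.365003 0.674163           8
FDG/FMISO    voxel  0.526755 0.456390 0.584369           8
```

i.e. across the eight synthetic patients the FDG/FMISO rank correlation has
a cohort median of ~0.53 at both analysis levels, scattered around the
configured population target of 0.56 — the generator controls the
population Spearman exactly, and the residual spread is finite-sample
variation within each GTV (~2000 voxels, ~56 sub-regions).  The same run
writes `per_patient_correlations.csv`, `cohort_summary.csv` and the square
median matrix (voxel level in the upper triangle, regional in the lower)
under `results/analysis/`.

The numbered scripts under `analysis/` run the same steps as a narrative:
`01_generate_phantom_cohort.py` writes the phantoms to `scratch/phantoms/`,
`02_run_correlation_analysis.py` produces the tables above, and
`03_kinetics_validation.py` checks the kinetic stack against closed-form
oracles (noiseless Tofts recovery errors ~1e-12, T1 recovery ~1e-10 ms).

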