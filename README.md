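# dtialps

A tested Python pipeline for **DTI-ALPS** — diffusion-tensor-image analysis
along the perivascular space — from raw diffusion-weighted volumes to
longitudinal group statistics, with synthetic data generators so that every
stage can be exercised and validated without patient imaging.

## The problem and who this is for

The glymphatic system clears interstitial waste from the brain through
perivascular channels. At the level of the lateral-ventricle body, medullary
veins and their perivascular spaces run along the left–right image axis
(*x*), perpendicular both to the adjacent projection fibers (running
inferior–superior, *z*) and to the association fibers of the superior
longitudinal fasciculus (anterior–posterior, *y*). The ALPS index exploits
this geometry: water movement along the perivascular space elevates the
*x*-axis diffusivity in both fiber bundles relative to their fiber-transverse
diffusivities,

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

where Dxx/Dyy/Dzz are the *diagonal elements* of the diffusion tensor in the
image frame (not eigenvalues), averaged over small circular ROIs (5 mm
diameter by default) placed in the projection- and association-fiber areas of
each hemisphere. An index near 1 means no detectable perivascular component;
larger values indicate more x-axis (perivascular) diffusion.

The package targets neuroimaging researchers studying glymphatic function
longitudinally — for example in rehabilitation trials where ischemic-stroke
patients receive high-frequency (HF, excitatory, infarcted-hemisphere M1) or
low-frequency (LF, inhibitory, intact-hemisphere M1) repetitive transcranial
magnetic stimulation, and ALPS is measured at baseline (BL) and follow-up
(FU). The per-day change rate

```
rate = ((FU − BL) / BL) / interval_days × 100   [% per day]
```

is compared between arms, correlated against upper-limb motor scores
(WMFT, FMA, …), and adjusted for age, sex, BMI and days since stroke onset.

What is inside:

- `dtialps.gradients` / `dtialps.phantom` — deterministic diffusion gradient
  schemes and a forward DWI simulator over phantoms with known ground-truth
  tensors arranged in the bilateral ALPS geometry (Gaussian/Rician noise).
- `dtialps.tensor` — per-voxel log-linear tensor fitting (OLS or one-pass
  reweighted WLS), FA / MD / directionally-encoded color-FA and axis
  diffusivity maps.
- `dtialps.alps` — ROI masks, ROI-mean diffusivities, the ALPS index per
  hemisphere and total-cerebral, and the group→stimulated-hemisphere mapping.
- `dtialps.cohort` — synthetic two-arm longitudinal cohorts with prescribed
  group effects and a Gaussian copula linking ALPS change rates to clinical
  improvements.
- `dtialps.stats` — the full analysis chain: Shapiro-gated t / Mann-Whitney
  baseline contrasts, chi-square, paired t, Wilcoxon signed rank (exact
  tie-aware null up to n = 25), Spearman correlations, covariate-adjusted
  OLS, Benjamini–Hochberg FDR, and a one-call `run_full_analysis`.
- `dtialps.io` / `dtialps.cli` — NIfTI-1 + FSL bval/bvec IO, cohort CSV,
  ROI-spec YAML, JSON/markdown reports, and a `dtialps` command with
  `simulate-phantom`, `fit-tensor`, `compute-alps`, `simulate-cohort`,
  `analyze` and `report` subcommands.

## Worked example

```python
from dtialps import (alps_phantom_spec, analytic_alps, make_gradient_table,
                     simulate_dwi, fit_tensor, compute_scalar_maps,
                     extract_roi_means, phantom_roi_specs, compute_alps,
                     map_hemispheres, CohortSpec, generate_cohort,
                     run_full_analysis)

# 1. imaging chain: 20-direction b=1000 phantom with analytic ALPS 1.35
gtab = make_gradient_table(20, 1000.0, 1)
spec = alps_phantom_spec(target_alps=1.35, noise_model="rician", snr=30.0,
                         seed=42)
dwi, truth = simulate_dwi(spec, gtab)
maps = compute_scalar_maps(fit_tensor(dwi, "wls"))
res = compute_alps(extract_roi_means(maps, phantom_roi_specs(spec)),
                   map_hemispheres("HF", infarct_side="left"))
print(f"analytic ALPS      : {analytic_alps(spec, 'left'):.4f}")
print(f"left / right ALPS  : {res.alps['left']:.4f} / {res.alps['right']:.4f}")

# 2. statistics chain: moment-matched synthetic trial cohort (17 HF / 18 LF)
df = generate_cohort(CohortSpec(seed=1, empirical=True))
report = run_full_analysis(df, correlation_scope="pooled")
t3 = report.table3["non_stimulated"]
print(f"non-stim change-rate contrast: t = {t3.statistic:.2f}, "
      f"p = {t3.p_raw:.3f}, p_FDR = {t3.p_fdr:.3f}")
```

prints

```
analytic ALPS      : 1.3500
left / right ALPS  : 1.3784 / 1.3105
non-stim change-rate contrast: t = -2.62, p = 0.013, p_FDR = 0.040
```

The noisy per-hemisphere estimates sit within ~2% of the 1.35 ground truth
at SNR 30 (they are exact to 1e−6 without noise), and the between-arm
contrast of the non-stimulated-hemisphere ALPS change rate is significant
and survives FDR over the three regional contrasts: the HF arm's index in
the hemisphere opposite the stimulated M1 declines faster than the LF arm's.

The same steps are available from the shell:

```
dtialps simulate-phantom --out-dir ph --seed 42 --noise rician --snr 30
dtialps fit-tensor --dwi ph/dwi.nii --bval ph/dwi.bval --bvec ph/dwi.bvec --out-dir maps
dtialps compute-alps --maps-dir maps --roi-spec ph/rois.yaml --out alps.csv \
        --group HF --infarct-side left
dtialps simulate-cohort --out cohort.csv --seed 1 --empirical
dtialps analyze --cohort cohort.csv --out report.json
dtialps report --analysis report.json --out report.md
```

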