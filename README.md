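# hepamap

Non-contrast liver-function mapping from multiparametric MRI, evaluated on
digital liver phantoms with known ground truth.

Liver cirrhosis impairs hepatocyte function and tissue perfusion, and does so
heterogeneously across the organ — information a single global score (e.g. a
Child-Pugh grade) cannot capture, but which matters for applications such as
liver-sparing radiotherapy planning. `hepamap` implements, end to end, the
quantitative pipeline needed to study this at the voxel level:

1. **IVIM-DWI** (intravoxel incoherent motion diffusion-weighted imaging).
   The signal over a 13-b-value scheme (b = 0…800 s/mm²) follows the
   biexponential

   S(b)/S₀ = F_p·exp(−b·D_fast) + (1 − F_p)·exp(−b·D_slow),

   separating molecular diffusion (D_slow, mm²/s) from capillary
   pseudo-diffusion (D_fast) and its signal fraction (F_p) — perfusion
   surrogates that need no contrast agent. Maps are fitted voxelwise either
   by segmented constrained least squares or by a per-voxel Bayesian
   (Metropolis-within-Gibbs) sampler under the Gaussian likelihood, which
   strongly suppresses the notorious noise amplification of the D_fast map.
2. **Dual-flip-angle T1 mapping with B1 correction.** SPGR signals at 3°/15°
   (TR 5.08 ms) determine T1 via DESPOT1-initialized nonlinear least squares;
   the transmit-field (B1) map rescales the effective flip angles. The
   pre/post-gadoxetate percent change ΔT1% = 100·(T1pre − T1post)/T1pre is a
   hepatocyte-function surrogate.
3. **Hepatic extraction fraction (HEF)** from low-temporal-resolution DCE
   series by truncated-SVD deconvolution of the tissue curve against the
   vascular input function, reading HEF off the recovered impulse retention
   function R(t) = (1 − HEF)·e^(−t/τ_fast) + HEF·e^(−t/τ_slow) as
   late-plateau over peak.
4. **Biomarker statistics**: percent difference to reference and
   intra/inter-session CVs, within-subject CV of scan–rescan pairs,
   Mann-Whitney group comparison, ROC with Youden-index cutoffs and
   stratified bootstrap CIs (n = 1000, 95%), voxelwise Pearson correlation
   with Fisher-Z pooling across subjects, and Dice overlap as registration QC.
5. **A synthetic-phantom module** that generates two-cohort studies
   (10 healthy volunteers, 12 patients with mild impairment) with known
   voxelwise ground truth for every parameter, so each estimator is
   scored against truth without any scan data.

The voxelwise fitters are scikit-learn-style estimators
(`IVIMBayesian`, `IVIMLeastSquares`, `DespotT1`, `TSVDHef`) operating on
`(n_voxels, n_measurements)` matrices with per-voxel fitted attributes
(`d_slow_`, `t1_`, `hef_`, …); the map-level functions and the pipeline
driver are thin wrappers over them.

## Worked example

Simulate a two-cohort study and run the whole pipeline (Bayesian IVIM fit at
reduced sampling, T1/ΔT1%/HEF maps for patients, group statistics):

```python
from hepamap import CohortConfig, PipelineConfig, make_cohort, run_pipeline

subjects = make_cohort(CohortConfig(shape=(32, 32, 4), noise_sd=50.0, seed=7))
report = run_pipeline(subjects, PipelineConfig(
    mcmc_iterations=2000, mcmc_burn_in=1000, voxel_fraction=0.25,
    bootstrap_samples=1000, seed=7))

for p in ("d_slow", "f_p", "d_fast"):
    gc, roc = report["group_comparison"][p], report["roc"][p]
    print(p, gc["healthy"]["median"], gc["patient"]["median"],
          gc["p_value"], roc["auc"], roc["auc_ci"], roc["cutoff"])
```

Output (healthy vs patient medians; diffusivities in ×10⁻³ mm²/s, F_p in %):

```
d_slow  healthy   1.04  patient   0.94  p=0.1213  AUC=0.700 [0.467, 0.917]  cutoff=1.06
f_p     healthy  30.91  patient  22.90  p=0.0017  AUC=0.900 [0.717, 1.000]  cutoff=26.95
d_fast  healthy  87.15  patient  45.66  p=0.0003  AUC=0.958 [0.866, 1.000]  cutoff=57.16
```

Read: the perfusion-linked parameters F_p and D_fast separate mild
impairment from healthy liver (small p, high AUC, cutoffs at ~27% and
~57×10⁻³ mm²/s), while pure diffusion D_slow does not reach significance —
the qualitative behavior expected of this protocol. The report also carries
per-patient voxelwise correlation tables (HEF vs IVIM vs T1 parameters) with
Fisher-Z pooled averages, Dice QC, provenance (config hash, seed, version)
and a deterministic digest: rerunning with the same seed reproduces it
bit-for-bit.

A command-line umbrella mirrors the library:

```sh
hepamap simulate --n-healthy 10 --n-patient 12 --seed 1 --out study/
hepamap ivim fit --dwi study/sub-011/dwi.nii.gz --bvals study/sub-011/dwi.bval \
        --mask study/sub-011/liver_mask.nii.gz --method bayes --out maps/
hepamap t1 fit --fa3 pre_fa3.nii.gz --fa15 pre_fa15.nii.gz --b1 b1.nii.gz \
        --mask mask.nii.gz --out t1_pre.nii.gz
hepamap hef --dce dce.nii.gz --times dce_times.txt --aif aif.csv \
        --mask mask.nii.gz --out hef.nii.gz
hepamap run --seed 1 --out report.json
```

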