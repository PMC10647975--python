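# Methods

This note documents the models implemented in `hepamap`, their assumptions,
the default parameters and why they were chosen, what the synthetic phantom
does and does not emulate, and the numerical decisions taken where the
design was genuinely open.

## IVIM diffusion model and fitters

The voxel signal over the 13-b acquisition (b = 0, 10, 20, 30, 40, 50, 60,
70, 80, 100, 200, 400, 800 s/mm²; per-b excitation counts 1/2/3 as in the
emulated clinical protocol) is modelled as

S(b) = S₀ [F_p e^(−b·D_fast) + (1 − F_p) e^(−b·D_slow)] + ξ,  ξ ~ N(0, σ²_y).

Diffusivities are carried in SI mm²/s internally and converted to
×10⁻³ mm²/s (and F_p to %) only in human-facing summaries. Both fitters
share the physiologic bounds D_slow ∈ [0.1, 3]×10⁻³, D_fast ∈ [3, 300]×10⁻³
mm²/s, F_p ∈ [0, 0.6].

**Segmented least squares** (the baseline): log-linear fit over
b ≥ 200 s/mm² gives D_slow and the slow amplitude S₀(1 − F_p); F_p follows
from the gap between the measured b = 0 signal and that intercept; D_fast is
a one-parameter least-squares fit of the residual fast component on a
400-point log-spaced grid with parabolic refinement. The b-threshold of
200 s/mm² is the common segmentation convention (at 200 s/mm² the fast
component has decayed by e^(−b·D_fast) ≤ e^(−0.6) even for slow
pseudo-diffusion). Voxels with non-positive signals are flagged NaN and
counted.

**Bayesian fit**: each voxel is sampled independently (no spatial prior) by
Metropolis-within-Gibbs on the transformed vector
θ = (log D_slow, log D_fast − log D_slow, logit(F_p/0.6), log S₀), which
enforces D_fast > D_slow > 0 and the F_p range by construction. Priors are
flat on the transformed scale within finite bounds; σ²_y carries a weak
conjugate inverse-gamma prior (a₀ = b₀ = 10⁻⁶) and is Gibbs-sampled each
iteration — with the chain initialized at the least-squares solution, this
makes the effective temperature track the current misfit, so the sampler
anneals into the posterior even for (nearly) noise-free data. A joint
Gaussian random-walk proposal with per-voxel scalar scale is adapted during
burn-in toward ≈ 0.3 acceptance (Robbins-Monro on the log-scale); all voxel
chains run in lockstep as vectorized numpy updates, which is what makes
500-voxel × several-thousand-iteration fits take a second rather than
minutes. Defaults are 10 000 iterations / 5 000 burn-in; the point map is
the posterior median (robust to the skewed D_fast marginals), with the mean
available. Post-burn-in samples are thinned to at most `max_kept` per voxel
before computing medians, means and central 95% intervals.

Quality flags: per-voxel acceptance rate outside [0.1, 0.6] after
adaptation, invalid input, or a posterior median piled against a prior
support bound (within 10% of a diffusivity bound, or above 95% of the F_p
ceiling) — the last identifies voxels whose true value likely lies outside
the support, where the estimate is pinned rather than informative.

Noise-free data drive σ² to the prior floor and the acceptance rate toward
zero; such voxels are flagged, and their posterior median remains at the
(correct) likelihood peak.

## Preprocessing

A 3×3 in-plane median filter (reflection at edges) is applied slicewise to
every b-volume before fitting, mirroring clinical practice for EPI noise;
it is applied before masking. In-plane resampling (down for fitting, up for
presentation, e.g. 340×218 ↔ 128×128) uses anti-aliased linear
interpolation downward (area-averaging-like, appropriate for signal) and
plain bilinear upward (appropriate for parameter maps); slice and b axes
are never resampled, and constant fields are preserved exactly.

## Dual-flip-angle T1 with B1 correction

SPGR steady state: S(α) = M₀ sin(α_eff)(1 − E₁)/(1 − cos(α_eff)E₁),
E₁ = e^(−TR/T1), α_eff = α·B1, with α ∈ {3°, 15°}, TR = 5.08 ms. The B1 map
is consumed as a dimensionless multiplicative flip-angle factor (nominal
1.0); any scanner-specific encoding must be converted upstream. The fit is
nonlinear least squares on (log T1, log M₀) by vectorized Gauss-Newton,
initialized from the DESPOT1 linearization S/sin α = E₁·(S/tan α) +
M₀(1 − E₁); for two angles and noise-free data the initialization is already
exact. Bounds 50–5000 ms; voxels with non-physical linear slope
(E₁ ∉ (0, 1)), angle-independent signal, or bound-hitting solutions are
flagged NaN and counted. Because the relative T1 error is roughly twice the
relative flip-angle error, an uncorrected 20% B1 offset biases T1 by tens of
percent — the reason the correction exists; the package's acceptance run
measures this bias and its removal.

ΔT1% = 100·(T1pre − T1post)/T1pre, computed voxelwise with NaN propagation;
it depends only on the fitted T1 values and is invariant to any common
rescaling of the signal amplitude.

## HEF by TSVD deconvolution

Tissue curves are modelled as c_a ⊛ R with a two-compartment impulse
retention function R(t) = (1 − HEF)e^(−t/τ_fast) + HEF·e^(−t/τ_slow):
a vascular washout term and a hepatocyte retention term whose amplitude is
the extraction fraction. Curves are treated as relative enhancement — no
signal-to-concentration conversion — consistent with estimating a
*fraction*. The discrete convolution operator is lower-triangular
(causality) with trapezoid weights, supporting non-uniform breath-hold time
grids via linear interpolation of the input function at the required lags.
The generator and the deconvolution stage share this exact operator, so
noise-free forward simulations are reproduced by the inverse stage to
machine precision on the constrained support.

Two numerical facts shape the estimator:

* Because the input function is zero at lag zero, the final retention
  sample only influences the tissue curve beyond the acquisition window; it
  is unconstrained by the data and the minimum-norm TSVD solution leaves it
  near zero. Recovery guarantees therefore apply to all but the final
  sample.
* On the coarse low-temporal-resolution grid (21 samples, 60 s spacing)
  heavy truncation produces strong early-time ringing that smears the peak
  of R. A truncation sweep over HEF ∈ [0.1, 0.9] at the study noise level
  (SNR 20 on the curve peak) shows worst-case mean recovery error of
  ≈ 0.31 at truncation 0.05, ≈ 0.09 at 0.10, and ≈ 0.14 at 0.15. The
  default `truncation_fraction` is therefore **0.10** (minimax across the
  sweep); noise-free data are best served by a minimal truncation (0.02),
  i.e. the regularization level should be matched to the noise.

HEF readout: HEF = (late-plateau amplitude)/(peak of R), clipped to [0, 1].
The late amplitude is obtained from the samples at t > `split_time`
(default 300 s, ≥ 5 fast time constants) by a log-linear exponential fit
extrapolated to t = 0 — the plain late-window mean would be biased low by
the slow compartment's own decay over the 20-min window (factor
≈ e^(−t̄/τ_slow) ≈ 0.77 for τ_slow = 3000 s). The extrapolation is trusted
only when the fitted tail time constant indicates genuine retention
(τ ≥ split_time); a faster-decaying tail is residual vascular washout, for
which the plain mean is used — this preserves the HEF → 0 limit. Negative
retention samples are clipped to zero after the solve and counted.

## The digital liver phantom

The phantom exists to make every stage testable against known truth. Each
subject is an ellipsoidal "liver" in a 3D grid (default 64×64×8; most tests
use 16–32 voxel grids) partitioned into four segment-like regions. One
subject-level value per parameter is drawn from the cohort distribution,
region values scatter multiplicatively around it, and fields are smoothed
within the mask (Gaussian, σ = 1.5 voxels, renormalized so there is no edge
decay).

Cohort distributions are parameterized by (median, SD) per parameter with
median-exact families chosen to respect the invariants: log-normal for the
diffusivities, logit-normal for F_p and HEF (delta-method scale), truncated
normal for T1. The IVIM medians/SDs are the study conditions of the
emulated protocol: healthy D_slow 1.02 ± 0.15 ×10⁻³ mm²/s, F_p 29.2 ± 5.1%,
D_fast 73.5 ± 25.5 ×10⁻³; patient 0.96 ± 0.13, 21.6 ± 4.0%, 36.4 ± 14.2.
T1 and HEF cohort values are literature-typical liver values at 3T: healthy
T1pre ≈ 810 ms with strong gadoxetate uptake (T1post ≈ 310 ms, ΔT1% ≈ 62%)
and HEF ≈ 0.85; cirrhotic T1pre ≈ 870 ms with reduced uptake
(T1post ≈ 530 ms) and HEF ≈ 0.55. T1post is derived per subject from a
drawn uptake fraction so T1post ≤ T1pre holds by construction. Within-liver
heterogeneity is a documented free knob: the region-to-region relative
scatter is `heterogeneity` (default 0.3) times the cohort-level CV of each
parameter, so degenerate configurations with zero group SD produce
perfectly uniform livers.

Forward simulations: DWI per Eq. above with Gaussian noise by default
(matching the model's stated error term; Rician magnitude noise available,
as magnitude MR data is properly Rician) and per-b averaging simulated as
the mean of independent noisy excitations (1/2/3 per the protocol table);
SPGR pairs through the exact SPGR expression under a smooth deterministic
polynomial B1 field spanning [0.8, 1.2] (a bowl-shaped transmit profile
typical of 3T body imaging); DCE curves through the same discrete
convolution operator used by the deconvolution stage, on a 21-point,
60-s-spaced grid to 1200 s, with a gamma-variate input function (α = 2,
β = 60 s) and τ_fast = 60 s, τ_slow = 3000 s. Healthy subjects receive only
the DWI acquisition — volunteers are not given contrast, so no SPGR/T1 or
DCE data exist for them. Per-subject seeds are spawned deterministically
from the study seed.

Not emulated: k-space/EPI distortion, motion and breathing, registration
error (inputs are co-registered by construction; Dice is computed as QC
only), coil sensitivity, partial volume, tumors. Passing tests therefore
demonstrate correctness of the estimators under the stated signal and noise
models, not robustness to acquisition artifacts.

## Statistics layer

Sample SD (n−1) throughout (small groups). Mann-Whitney U uses the exact
null distribution for n_a + n_b ≤ 12 without ties, otherwise the normal
approximation with tie correction; the method used is reported. The
significance threshold α defaults to 0.05; it is a config value because the
emulated protocol's own reporting is ambiguous between 0.05 and a stricter
0.005 table footnote. AUC is the rank statistic (ties counted half);
direction is auto-chosen so AUC ≥ 0.5 and reported. The optimal cutoff
maximizes the Youden index with ties broken toward higher specificity
(criterion configurable); cutoffs are midpoints between adjacent scores.
Bootstrap CIs are stratified percentile intervals (default n = 1000, 95%),
resampling each class separately so no resample degenerates to one class.
Voxelwise Pearson r carries a Fisher-transform CI and a strength band
(|r| 0.1–0.3 small, 0.3–0.5 medium, 0.5–1.0 large); pooling across subjects
is z̄ = mean(atanh r), r̄ = tanh z̄, which is bounded by the extremes of the
inputs. Dice = 2|A∩B|/(|A|+|B|) with the both-empty convention 1.0.
Normality testing is a reported diagnostic only; it gates nothing. No
multiple-testing correction is applied across the correlation pairs.

## Pipeline and problem sizes

`run_pipeline` drives: optional median filter → IVIM fit (method, MCMC
length and a `voxel_fraction` subsample of liver voxels are configurable) →
whole-liver summaries → patient T1/ΔT1%/HEF maps → Dice QC against a
configurable floor (default 0.8; subjects below it are excluded from the
correlation stage with a logged reason) → group comparison, ROC with
bootstrap, and single-slice voxelwise correlations (the best-covered slice
by default; whole-volume correlation is an explicit opt-in). Reports are
JSON-serializable dicts with a provenance block (config hash, seed,
version) and a sha256 digest over the rounded payload; fixed seeds
reproduce reports bit-for-bit.

The test and acceptance runs use desk-scale problem sizes chosen to keep
the full suite in the minutes range while leaving every assertion
statistically comfortable: 16–48 voxel grids, 25% voxel subsampling and
1200–2000 MCMC iterations for cohort replicates (30–50 replicates), 3000–
4000 iterations for single-stage fits, 200 repetitions per HEF level, 200
simulated studies for bootstrap coverage. The spec-scale defaults (64×64×8
grid, 10 000 iterations, full voxel coverage) remain the library defaults.

## Known limitations

* The Bayesian fitter assumes Gaussian noise; no Rician likelihood (the
  generator can produce Rician data, and at SNR ≥ 20 the Gaussian
  approximation bias is small relative to posterior spread).
* No spatial regularization across voxels (by design — voxels are fitted
  independently), no tri-exponential or kurtosis extensions.
* HEF identifiability rests on τ_slow ≫ window spacing; tails decaying
  faster than `split_time` are indistinguishable from vascular washout.
* The two-compartment retention parameterization and the late-plateau/peak
  readout are one self-consistent definition of HEF; other deconvolution
  conventions differ by a calibration, not an architecture change.
* DESPOT1-based T1 assumes ideal spoiling and a scalar B1 factor (no slice
  profile modelling); vendor in-line maps will differ systematically.
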