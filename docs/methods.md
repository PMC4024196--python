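# Methods

This note documents the models, the synthetic study conditions, the numerical
choices and the known limitations of the package. It states nothing the test
suite or the acceptance script does not itself compute.

## Signal model

The spoiled gradient-echo (FLASH) steady state is modeled per voxel, per
weighting `w ∈ {PDw, T1w, MTw}` and per echo:

* **Ernst (exact)**: `S = A sin a (1 − E1)/(1 − cos a · E1) · e^(−TE·R2*)`
  with `E1 = exp(−TR·R1)` and true flip angle `a = α_w · f_T`, where `f_T` is
  the B1⁺ transmit factor (actual/nominal flip).
* **Rational (small-angle / short-TR)**:
  `S = A a TR·R1 / (a²/2 + TR·R1 + δ/100) · e^(−TE·R2*)`,
  with the MT saturation δ in percent units entering only the MT-weighted
  acquisition. δ is the percentage of longitudinal magnetization removed per
  TR by the off-resonance pre-pulse (4 ms Gaussian, 220° nominal, 2 kHz
  off-resonance in the default protocol descriptor; the pulse itself is not
  Bloch-simulated — δ is a ground-truth input).

The simulator uses the rational model by default (`signal_model` is
configurable) so that the estimator round trip is algebraically exact; the
Ernst model is available to quantify the small-angle approximation error,
which at the protocol settings (6°/23.7 ms, 20°/18.7 ms) stays below ~5% on
R1 and grows monotonically with flip angle (tested by sweep).

## Estimators

* **R2***: unweighted OLS of log-signal on echo time over the eight
  PD-weighted echoes; slope = −R2*. Any non-positive echo sample invalidates
  the voxel (counted, masked). Noise-driven negative rates are clamped to 0
  and counted. Unweighted regression was chosen over variance-weighted
  because the estimator contract is a plain log-linear fit; at the simulated
  SNR the difference is negligible against the Monte-Carlo tolerance (2% on
  the mean at SNR 50).
* **Echo averaging**: arithmetic mean over the six echoes common to all three
  weightings (effective TE = 8.45 ms). The two late PDw echoes enter only the
  R2* fit.
* **R1 / amplitude** (dual flip angle, rational):
  `R1 = ½ (S_T1 a_T1/TR_T1 − S_PD a_PD/TR_PD) / (S_PD/a_PD − S_T1/a_T1)`,
  with B1-corrected angles; `A_app` follows by back-substitution. Voxels with
  non-positive denominator or non-positive R1 are masked. Both quantities are
  invariant to any receive-field scale common to the weightings.
* **MT saturation**:
  `δ = 100·[(A_app·a_MT/S_MT − 1)·R1·TR_MT − a_MT²/2]`. The flash-module
  default leaves the readout angle uncorrected for B1 (`mt_b1_correct=False`,
  the map being semi-quantitative); the pipeline orchestrators enable the
  correction because the transmit field is always an available input here and
  the uncorrected estimate scales as δ/f_T voxel-wise, which would corrupt
  slope recovery by up to ±20% under the default B1 range.
* **Amplitude at TE=0**: the averaged signals carry the mean decay
  `k̄ = mean_k exp(−TE_k·R2*)`, so `A_app` is the amplitude at the effective
  TE. The estimator also reports `A0 = A_app / k̄(R2*_fit)`; the zero-noise
  round trip recovers the true amplitude through `A0`. PD* itself is built
  from `A_app` — deliberately uncorrected for R2* decay, which is what the
  star denotes.
* **PD\***: a 3D polynomial (total degree 3) is fit to log-amplitude over
  white matter and divided out as the receive-field estimate, then one global
  scale per subject sets mean WM PD* to exactly 69 (% water). The polynomial
  stand-in is testable against the simulator's known receive field; it
  restores inter-regional amplitude ratios exactly when the true field is
  log-polynomial (tested) and approximately otherwise.

## VBQ, VBM and analysis masks

Tissue-weighted smoothing `q = G★(w·p)/G★(w)` uses separable discrete
Gaussian kernels (σ = FWHM/√(8 ln 2), truncated at 4σ, zero-padded; the
weight in the denominator self-corrects boundary truncation). Output is
masked where the smoothed weight falls below ε = 0.05 (configurable; no
canonical value exists). The operation is exact for within-tissue-constant
maps and is a convex combination of input values (both properties tested).
VBM modulation multiplies the GM probability by the Jacobian determinant
(default 1: the synthetic cohort lives in a common space, so spatial
normalization is the identity; the API accepts per-subject Jacobians so real
deformations can be plugged in) and smooths at 6 mm.

Cohort masks: per class, Jacobian-modulated probabilities smoothed at 3 mm
are averaged over subjects; each voxel goes to the class with maximal average
probability (ties broken GM > WM > CSF), and is excluded when neither GM nor
WM exceeds 0.20 (strict inequality — the boundary case is unobservable in
floating point anyway). GM and WM analysis masks are disjoint by
construction.

## GLM and error control

Design columns, in order: intercept, age [years, unstandardized so the age
beta reads units/year], sex (M = +½, F = −½), total intracranial volume
[mm³], scanner (2 = +½, 1 = −½); centered indicator codings make the
intercept the grand mean. The intercept is always included. Rank deficiency
(e.g. a single-sex cohort) raises with the offending column named. OLS is
vectorized over voxels with a shared pseudo-inverse; dof = n − rank.

Hypothesized directions for the age contrast: one-tailed decline for MT and
R1 (demyelination), two-tailed for R2* and PD*. FWE control uses the
permutation distribution of the volume-wise maximum statistic with
Freedman–Lane residual permutation under the reduced model (default
n_perm = 1000; adjusted p = rank of the observed score among permutation
maxima, floored at 1/(n_perm+1) and never below the uncorrected p).
Permutation was chosen over Gaussian-random-field theory because it is exact
under exchangeability and needs no smoothness estimation; Bonferroni is
provided as the cheap conservative alternative (dominance over maxT under
spatial correlation is tested). Empirical FWE under a global null is
calibrated against the binomial 95% band around α = 0.05 over 200 replicate
cohorts (16³ voxels, n = 20 — sizes chosen to make the calibration cheap
while keeping the t statistics well away from degenerate dof).

**Genu-versus-splenium rates.** Whether two regions age at different rates is
tested by regressing the per-subject difference of ROI means on age and
t-testing the age coefficient (two-tailed). A two-sample test on "per-subject
slopes" is not well defined (a slope is a cohort-level quantity), and the
paired-difference regression removes shared between-subject variance, which
is what makes the comparison powerful.

**ROI slope summaries** erode each ROI (default 2 voxels; 3 in the
full-scale validation study) before averaging fitted slopes. The 3 mm kernel
mixes values across ROI boundaries within ~2σ ≈ 2.5 voxels; eroding the
extraction core keeps the summary inside the region the preset actually
governs. Residual kernel-scale mixing is the main known bias of the recovery
studies and shrinks as structure size grows relative to the kernel.

## Synthetic study conditions

The generator's defaults are the study conditions, not tuning knobs:

* **Cohort**: n = 138; ages uniform on [19, 75] (a sparse-middle mode that
  under-samples 35–55 is available); 49/138 male; scanners split 69/69; a
  1% multiplicative amplitude gain on scanner 2 (small by design — amplitude
  scales cancel through the ratio-based estimators and the PD* calibration,
  so the scanner F-test stage faces a near-null, matching the sporadic
  scanner effects such studies report).
* **Phantom**: 48³ voxels at 1 mm isotropic (configurable); nested spheres
  (CSF shell, cortical GM ribbon, WM core) rasterized about a deliberately
  off-grid center so partial-volume fractions spread smoothly; ROI spheres of
  5–6 voxel radius — kept large relative to the 3 mm kernel, as the real
  structures are. Tissue probability maps use a linear half-voxel
  partial-volume ramp; a voxel whose center lies in a region carries that
  region's probability ≥ 0.5. TIV = voxel volume × count of voxels with
  tissue-probability sum above 0.5, after a per-subject global head-size
  scaling of the TPMs (SD 4%) that makes TIV a non-degenerate covariate.
* **Aging model**: per tissue and per ROI, `value = baseline +
  slope·(age − 46.6) + N(0, SD)`, one draw per region per subject, constant
  within the region. ROI slope presets carry the published annual rates (MT:
  genu −0.0019, splenium −0.0005 %/yr; R1: genu −0.0007, optic radiation
  −0.0016 s⁻¹/yr; R2*: pallidum +0.22, putamen +0.12, motor cortex +0.03
  s⁻¹/yr); deep-gray R2* baselines use age-matched MPM reference values
  (pallidum 28.32, putamen 20.74 s⁻¹); remaining baselines are plausible 3T
  mid-age values and are configuration, not claims. The published MT rates
  are stored verbatim in absolute percent-units of the MT map per year — the
  natural reading of their printed units — even though they are 2–3 orders
  of magnitude below typical WM MT saturation (~2 p.u.); the unit
  interpretation lives here, in configuration, not in code. Between-subject
  SDs (MT 0.02 p.u., R1 0.01 s⁻¹, R2* 0.5 s⁻¹, PD 1%) model residual
  variability after nuisance regression within a homogeneous ROI core.
* **Fields and noise**: B1⁺ is a smooth center-bright paraboloid spanning
  0.8–1.2; the receive field a smooth oblique gradient (±30%). Noise is
  additive Gaussian per echo image with SD = 1% of the mean WM first-echo
  PDw signal (the high-SNR regime of averaged multi-echo protocols; the
  log-linear and rational estimators assume this regime). A Rician mode
  exists for robustness testing; Rician bias at this SNR is < 0.5% of signal.
* **Atrophy**: optional linear GM-probability decline with age in designated
  ROIs (off by default) gives the VBM stage a detectable signal.
* **Cord**: cylinder radii from sex-specific presets (√(80.7/π) mm for men,
  √(76.6/π) mm for women, SD 0.22 mm chosen to reproduce the published
  ~7 mm² area SD), through-plane angulation uniform 0–12°, 15 slices,
  rendered at 0.5 × 0.5 × 1 mm with sharp (pixel-center) edges and a
  CSF-like rim at 25% of cord intensity; cord R2* slope preset 0.031 s⁻¹/yr
  with SD 2.0 s⁻¹ (matching the published t ≈ 2.9 at n = 138), cord MT slope
  0 (no significant cord MT aging to emulate).

What the generator does **not** emulate: k-space sampling, coil arrays,
motion, imperfect spoiling, susceptibility gradients, nonlinear (inverted-U)
lifespan trajectories, within-region texture, and real registration error
(the cohort is generated in a common space, so "normalization" is the
identity). Passing recovery tests therefore demonstrates correctness of the
estimators and statistics under the stated forward model — not robustness to
acquisition physics the model omits.

## Spinal-cord analysis choices

The 25% intensity-drop criterion is referenced, by default, to the running
mean of the accepted region (stable against single-voxel noise); a
seed-referenced variant is a flag. Growth is 4-connected (8-connected by
flag), breadth-first, deterministic. A runaway guard (default 2000 voxels at
0.25 mm² pixels ≈ 6× the expected cord area) aborts growth when cord/CSF
contrast is insufficient. The manual C2 landmark and manually measured
angulation of the original workflow are config inputs (the generator knows
truth); a centroid-drift angle estimator is provided as a convenience with no
claim of equivalence. Posterior sectors span 45° each side of the posterior
midline about the slice centroid; midline voxels are excluded so left-right
reflection exactly swaps the sectors. R1 and PD* are not extracted in the
cord (no transmit-field coverage there — the same reason the original
workflow omitted them).

## Numerical details and degenerate inputs

* Times are milliseconds in configuration, seconds internally; angles
  degrees in configuration, radians internally.
* Voxel indexing is 0-based with RAS diagonal affines; echo index is the 4th
  NIfTI axis.
* All randomness flows from explicit seeds through `numpy` `SeedSequence`
  spawning (one independent child stream per subject), so cohort generation
  is bit-reproducible and subjects are order-independent.
* Degenerate voxels (non-positive signal, inverted flip-angle ordering,
  zero variance) are masked and counted in QC sidecars, never silently
  dropped; negative R2*/δ estimates are clamped to zero and counted.
* The staged pipeline keys stage-completion markers to an MD5 hash of the
  canonical YAML config; resume only skips stages whose marker matches.

## Validation scale

The acceptance studies run at the full cohort scale (n = 138, 48³) for slope
recovery, 200 replicates at 16³/n = 20 for FWE calibration, and n = 138
cords for morphometry — sizes at which each check's Monte-Carlo error is
small against its tolerance while the full suite completes in about a minute
on one CPU.
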