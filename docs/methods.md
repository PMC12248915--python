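# Methods

This note records the models, conventions and numerical choices behind
`hpmfm`, in enough detail to reproduce or audit any stage.

## Forward model and synthetic cohort

The generator emulates a small hyperpolarized ¹³C-pyruvate study of
multifocal prostate cancer. It is first-class, tested code — the study
conditions it encodes are fixed defaults, not tuning knobs.

**Dynamics.** Longitudinal magnetizations follow the discrete two-site
exchange recursion given in the README, driven by a gamma-variate bolus
u(t) ∝ t^α·e^(−t/β), normalized so `bolus_amplitude` is the *total*
delivered magnetization (signals are therefore on a
fraction-of-delivered-polarization scale). Defaults: TR = 3 s, 20
frames, flips 15° (pyruvate) / 30° (lactate), α = 2.5, β = 4 s,
r1p = r1l = 1/25 s⁻¹ (typical published effective relaxation rates for
hyperpolarized ¹³C metabolites; the acquisition parameters mirror a
clinical abdominopelvic EPI protocol). The simulator and the fitter
share one recursion, so noiseless recovery isolates estimator error
from model error; a `substeps > 1` mode integrates the continuous-time
ODE (including the k_PL loss on pyruvate and intra-frame bolus decay)
to probe discretization bias, which is a systematic ≈20% amplitude
offset at these settings with essentially unchanged timing.

**Noise.** Additive Gaussian noise of scale `noise_sigma` on both
signal channels. The regime of interest is high SNR, where magnitude
(Rician) bias is negligible; the default 0.0074 puts the pyruvate peak
(≈0.148 for unit delivered magnetization) at SNR ≈ 20. `noise_sigma=0`
is supported and used by the round-trip tests.

**Anatomy.** Native grid 16×16×11 at 2 cm isotropic (a 2-cm EPI matrix
trimmed in z so ellipsoidal lesions fit the field of view). Each patient
carries 2–8 ellipsoidal lesions (semi-axes 8–25 mm; site labels drawn
with metastatic-prostate-cancer frequencies: bone 72%, node 11%, liver
10%, prostate 5%, soft tissue 2%). Per-patient base k_PL is lognormal
around 15 ks⁻¹ — the regime around the 17 ks⁻¹ dichotomization cutoff —
with per-lesion and per-voxel lognormal jitter for intra-tumor
heterogeneity, and per-voxel bolus-timing jitter so the mean-time map
carries real spatial structure. Overlapping lesions resolve by
last-writer-wins labeling.

**Outcomes.** Survival times come from a Weibull-baseline
proportional-hazards law: T = scale·(−ln U / e^η)^(1/shape) with
shape 1.2, PFS scale 12 months, OS scale 2.5× that, OS floored at PFS.
The linear predictor η is a user-chosen weighted sum of z-scored
generator-side ground-truth features (median/max k_PL, TMV, elongation,
serology, age); the default weights hazard on median k_PL alone, giving
downstream selection a known driver to recover. Censoring is one common
follow-up time per patient: an administrative cap at 36 months, replaced
with probability `censor_rate` (default 0.25) by an early dropout
uniform over the follow-up window. Serology is lognormal around the
cohort medians of the emulated population (PSA 13.9, LDH 208, ALP 76),
with PSA moderately coupled to TMV (both are tumor-burden surrogates);
ALP is blanked for 2 patients by default to exercise median imputation.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: B0/B1 inhomogeneity, coil sensitivity and
EPI artifacts, respiratory/cardiac motion, partial-volume mixtures
beyond resampling, treatment-timing confounding of scan dates, and any
¹H-MRI channel. Feature–outcome effect sizes in the synthetic cohorts
are cleaner than clinical reality; recovery rates here are upper bounds.

## Parametric maps

* **Inputless k_PL fit.** Signals→magnetizations by dividing by sin θ;
  the lactate state is seeded from the first measured lactate frame and
  propagated with fixed T1L = 25 s (fixing T1 is the established
  convention for this model class and keeps the per-voxel problem 1-D).
  The predicted lactate curve is linear in k_PL, so the bounded
  least-squares estimate is the normal-equation solution clipped to
  [0, 0.1] s⁻¹ — the exact minimizer a bounded 1-D search would reach;
  `solver_tolerance` guards the denominator for degenerate voxels.
  Internal computation is in s⁻¹; maps are reported in ks⁻¹.
* **Noise floor.** 3× the robust SD (1.4826·MAD) of the first frame,
  which precedes bolus arrival and so estimates the background. Voxels
  whose pyruvate peak falls below it return k_PL = 0; the mean-time map
  additionally zeroes voxels whose *summed* pyruvate is below the floor
  scaled by √n_frames. Whether sub-noise voxels should be zero-filled or
  excluded entirely is an open modeling choice; zero-filling was chosen
  and is flagged for sensitivity analysis (TMV, which counts k_PL > 0,
  is insensitive to the difference).
* **AUC** is the plain frame sum (no TR weighting); any constant factor
  cancels in min-anchored fixed-bin discretization downstream.
* **Resampling** to 5 mm isotropic uses trilinear interpolation for
  intensity maps and nearest-neighbor for the label mask
  (`nibabel.processing.resample_to_output`); world-space centroids are
  preserved within half a native voxel (tested).

## Feature bank

* **Discretization**: fixed bin width anchored at the ROI minimum,
  level(x) = ⌊(x − min)/w⌋ + 1 with the maximum clamped into the top
  bin. Default widths: 1.0 ks⁻¹ for k_PL, 0.02 signal units for AUC,
  0.1 s for MT — on this generator's scales these produce bin counts of
  order 30–50 (k_PL), 50–150 (AUC) and up to a few hundred (MT). Fixed
  width (rather than fixed count) is the more reproducible convention
  for quantitative maps.
* **First-order set (18)**: mean, median, variance, skewness,
  non-excess kurtosis (normal → 3; Pearson bound ≥ 1), energy, total
  energy (energy × voxel volume in mm³), histogram entropy and
  uniformity on the discretized levels, min/max/range, 10th/90th
  percentiles, IQR, mean absolute deviation, robust MAD (within the
  10–90 percentile window; 0 when that window is empty), RMS.
* **Shape elongation**: √(λ₂/λ₁) of the covariance of in-mask voxel
  center world coordinates, λ₁ ≥ λ₂ the two largest eigenvalues.
  Emitted once per map (identical values, per-map labels). Single-voxel
  ROIs are reported as missing (NaN).
* **Texture dialects** (fixed for reproducibility, verified against
  brute-force enumerators): GLRLM counts maximal equal-level runs along
  the 13 unique 3-D directions and sums the per-direction matrices
  before scalar computation; run percentage divides by the total
  voxel-run coverage (13 × voxel count). GLSZM counts 26-connected
  equal-level zones by size. GLDM counts, per voxel, 26-neighbors with
  the identical level (tolerance 0); its "dependence size" j includes
  the center voxel (j = dependents + 1), keeping small-dependence
  emphasis finite. Scalar sets: 16 GLRLM, 16 GLSZM, 14 GLDM.
* **Aggregation**: all lesion labels merge into one composite ROI per
  patient (consistent with reporting a single median k_PL across ROIs);
  a `per_lesion` mode with voxel-count-weighted averaging is provided
  as an alternative. TMV = (in-mask voxels with k_PL > 0) × voxel mL.
* The full vector is 196 features: 3 maps × (18 first-order + 1 shape +
  46 texture) + TMV.

## Survival statistics

* **Cox PH**: Breslow tie handling; Newton–Raphson on internally
  standardized covariates with step halving, to gradient norm 1e-8;
  covariance from the inverse observed information; likelihood-ratio
  test against the null; Wald 95% CIs for hazard ratios. Monotone
  likelihood (perfect separation) is detected as a standardized
  coefficient exceeding 30 and reported with a capped estimate and a
  warning. Constant covariates carry no partial-likelihood information
  and are reported with zero coefficient and undefined variance (the
  all-constant fit degrades to the null model) — this keeps degenerate
  leave-one-out cohorts well-defined. An optional ridge penalty
  stabilizes collinear fits.
* **Harrell's C**: a pair is usable iff the two times differ strictly
  and the earlier time is an observed event; tied risks count ½. Tied
  event times are not usable (simulated times are continuous, so this
  choice is inert in practice but is fixed and oracle-tested). Note the
  C of a fitted univariate predictor is *usually* ≥ ½ but not
  guaranteed on pure-noise data: the ML sign and the concordance sign
  can disagree marginally in finite censored samples.
* **Kaplan–Meier** via lifelines; median = smallest t with S(t) ≤ 0.5,
  "NR" when never reached. Dichotomization convention: "low" group is
  score ≤ threshold.
* **ALP imputation**: missing values take the cohort median of the
  observed values.

## Selection chain and MPS

* Adjusted concordance = 0.8·C_PFS + 0.2·C_OS of each feature's
  univariate Cox linear predictor (the self-orienting Cox-fit C, not
  the raw feature C); constant features are excluded. Serology (PSA,
  LDH, imputed ALP) joins the metabolic features before ranking.
* Retention keeps ⌈0.20 × column count⌉ features; ties break by name
  so results are column-order invariant.
* Clustering: distance 1 − |Pearson r| across patients, average-linkage
  agglomerative dendrogram (the standard default for
  correlation-distance trees) cut to 4 branches; each branch's top
  scorer is selected; the leaf-ordered correlation matrix is emitted as
  the correlogram table.
* MPS = Σ βᵢ·xᵢ from the multivariate Cox fit of the representatives
  plus age on the PFS endpoint (PFS is privileged as the more mature
  endpoint; OS metrics are computed from the same score by a univariate
  fit). Threshold = cohort median score. Collinear representative sets
  (condition number > 1e8 after standardization) trigger a flagged
  ridge-stabilized refit (λ = 0.01).
* Leave-one-out stability: n refits of the same model, each with one
  patient withheld; normalized SD = SD across refits / |full-cohort
  coefficient| (defined as 0 when the spread is exactly 0).
* The correlogram correlates features against *observed* PFS/OS
  durations including censored ones — a documented approximation;
  censored durations understate event times.

## Pipeline

Strict dataclass configuration (unknown keys rejected by name) that
round-trips through YAML; a SHA-256 config hash and per-stage counts go
to the run manifest. Stages simulate → maps → features → survival →
select run in order, each writing standard formats (NIfTI, CSV with
fixed float formatting, JSON with sorted keys) so identical configs
reproduce identical bytes; `resume=True` reloads cached stage outputs.
The univariate report fits both endpoints per chosen feature (defaults:
k_PL max/median/kurtosis, TMV, PSA, LDH, ALP) and dichotomizes median
k_PL at the cohort median unless a fixed cutoff is configured.

## Problem sizes and determinism

Default cohorts are 16 patients (the emulated study size); the
selection-recovery experiment uses 20 seeded cohorts of 100 patients
with 1–3 lesions each — scaled-up cohorts carry fewer lesions per
patient purely as a problem-size choice. All randomness flows from
`numpy.random.default_rng` seeded per spec/config; derived seeds stay
below 2³¹.

## Known limitations

* The inputless fit inherits the two-site model's assumptions: fixed
  T1L, no bolus re-circulation, no alanine/bicarbonate channels, no B1
  correction.
* Feature values after 5-mm resampling are partial-volume diluted at
  lesion rims (imaged median k_PL sits below the generator's truth);
  cross-patient ranking, which is what the survival link uses, is
  preserved (rank correlation ≈ 0.97 at study settings).
* At n = 16 the MPS coefficients are unstable by construction — that is
  what the leave-one-out normalized SDs quantify — so the multivariate
  model is hypothesis-generating, not a validated classifier.
* The printed 316-feature count of radiomics toolchains with different
  class configurations is not reproduced; the documented 196-name set
  is this package's contract.
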