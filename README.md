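# hpmfm — multiparametric features of metabolism from hyperpolarized ¹³C MRI

`hpmfm` implements an end-to-end analysis pipeline for dynamic
hyperpolarized [1-¹³C]pyruvate MRI of multifocal cancer (the motivating
setting is advanced/metastatic prostate cancer): kinetic parametric
mapping, radiomic-style feature extraction from the metabolic maps, and
survival-linked feature selection culminating in a composite risk score.
It is aimed at imaging scientists who want to prototype and stress-test
this kind of multivariate metabolic-biomarker analysis before real
patient data are in hand: a first-class synthetic-cohort generator
emulates the full data structure (dynamic series, lesion masks, clinical
table with censored outcomes), so every stage is testable and every
reported number is reproducible from a seed.

## The model and the statistics

**Kinetics.** Pyruvate→lactate conversion is modeled as two-site
exchange. Per frame *i* (repetition time TR, flip angles θ_P, θ_L), the
longitudinal magnetizations follow

    P[i+1] = P[i]·cos θ_P·e^(−TR·r1p) + U[i]
    L[i+1] = L[i]·cos θ_L·e^(−TR/T1L) + k_PL·TR·(P[i]·cos θ_P + P[i+1])/2

with U[i] the bolus delivered during the frame and signals
S_X = M_X·sin θ_X. The *inputless* fit inverts the lactate recursion
using the **measured** pyruvate signal as the source term — no arterial
input function — and returns the k_PL ≥ 0 minimizing the squared
lactate-signal residual (the prediction is linear in k_PL, so the
bounded least-squares solution is exact). k_PL is reported in
ks⁻¹ = 10⁻³ s⁻¹. Two further maps summarize delivery: the pyruvate
signal summed over time (AUC) and the mean pyruvate time
MT = Σ tᵢ·S_P(i) / Σ S_P(i), the bolus center of mass.

**Features.** The three maps are resampled to 5 mm isotropic voxels and
reduced over the lesion mask to 196 named features per patient
(`<map>_original_<class>_<Feature>`): an 18-feature first-order set per
map, shape elongation √(λ₂/λ₁) from the ROI's principal axes, the
GLDM/GLRLM/GLSZM texture scalar families on fixed-bin-width discretized
levels, and the total metabolic volume (TMV, mL of lesion with
measurable k_PL).

**Survival link.** Cox proportional-hazards regression (Breslow ties,
Newton–Raphson, likelihood-ratio tests), Harrell's concordance index,
and Kaplan–Meier curves with median survival ("NR" when never reached).
The multivariate chain ranks every feature by the adjusted concordance
0.8·C_PFS + 0.2·C_OS, retains the top 20%, clusters the survivors under
the distance 1 − |Pearson r| (average linkage, 4 branches), selects each
cluster's top scorer, and fits an age-adjusted Cox model on the four
representatives. The resulting linear score — the **Metabolic Prognostic
Score (MPS)**, lower = more favorable — is dichotomized at its cohort
median, and leave-one-out refits report per-coefficient stability.

## Worked example

`examples/` contains one narrative script per capability. The shortest
(`examples/01_simulate_and_fit_kpl.py`) simulates a voxel at
k_PL = 17 ks⁻¹ (TR 3 s, 15°/30° flips) and inverts it:

```
pyruvate peak signal : 0.1478 (arb. units)
lactate  peak signal : 0.0475
true k_PL            : 17.000 ks^-1
fitted k_PL          : 17.000000 ks^-1
noisy fits (n=100)   : mean 16.95 ks^-1, SD 0.85 (bias -0.30%)
```

Noiseless recovery is exact because the fitter inverts the same frame
recursion the simulator uses; at peak SNR ≈ 20 the per-voxel estimates
scatter (SD 0.85 ks⁻¹) but stay nearly unbiased. The full chain
(`examples/04_feature_selection_and_mps.py`, 40 synthetic patients whose
progression hazard is driven by true median k_PL) ends with:

```
cluster representatives: ['kPL_original_glszm_LargeAreaLowGrayLevelEmphasis',
 'kPL_original_firstorder_InterquartileRange',
 'kPL_original_gldm_SmallDependenceEmphasis',
 'kPL_original_gldm_DependenceNonUniformityNormalized']
MPS C-index: PFS 0.807, OS 0.738
  PFS median, low vs high MPS: 18.434 vs 4.365 months
  OS median, low vs high MPS: NR vs 13.941 months
```

All four representatives are k_PL-family features — the selection chain
found the planted driver — and the median split separates outcomes
(the low-MPS group's median OS is never reached within follow-up).

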