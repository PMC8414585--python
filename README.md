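# mrkit

Bidirectional two-sample Mendelian randomization (MR) for a circulating
biomarker against binary disease outcomes, built around the GDF-15 /
neurodegeneration study design: does genetically proxied growth
differentiation factor 15 (GDF-15, in SD units, 1 SD ≈ 625 pg/ml) alter the
risk of Alzheimer's disease (AD), Parkinson's disease (PD), or amyotrophic
lateral sclerosis (ALS) — and vice versa?

The package is for genetic epidemiologists who have GWAS summary statistics
(per-variant effect, SE, alleles, frequency) for an exposure and an outcome
and want the complete summary-data MR workflow as tested, scriptable Python:
instrument selection, allele harmonization, estimation, sensitivity
diagnostics, and power.

## The model

Each genetic instrument k contributes an exposure association X_k (SE σX_k)
and an outcome association Y_k (SE σY_k) on a common effect allele. The
per-instrument causal estimate is the Wald ratio Y_k/X_k with first-order
SE σY_k/|X_k|. The primary pooled estimator is fixed-effect IVW,

    β̂ = Σ X_k Y_k σY_k⁻² / Σ X_k² σY_k⁻² ,   σ̂ = (Σ X_k² σY_k⁻²)^{-1/2},

the zero-intercept weighted regression of Y on X. When instruments are in
linkage disequilibrium, the generalized form uses Ω_jk = σY_j σY_k r_jk:
β̂ = (XᵀΩ⁻¹X)⁻¹XᵀΩ⁻¹Y. Sensitivity estimators are the weighted median
(consistent if >50% of the weight is valid) and MR–Egger regression, whose
intercept measures directional pleiotropy (t test with k−2 df) under the
InSIDE assumption. Heterogeneity is Cochran's Q on the ratio scale with
I² = max(0, 100·(Q−df)/Q), plus leave-one-out re-estimation. Binary-outcome
power uses the normal approximation z = √(N·R²·K(1−K))·|ln OR|, invertible
for the smallest detectable OR at a target power.

## Worked example

The `analysis/` scripts run the whole design on synthetic GWAS fixtures
with known ground truth (generated by `mrkit.simulate`, five instruments
explaining 21.5% of exposure variance, exposure GWAS n = 5,440, disease
GWAS of 21,982 cases / 41,944 controls):

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_run_mr.py
```

prints, among the six bidirectional pairs (Bonferroni threshold 0.05/6):

```
gdf15_to_ad: OR 1.144 (1.103-1.185), p=2.81e-13  <- family-wise significant
gdf15_to_pd: OR 1.017 (0.983-1.053), p=0.335
ad_to_gdf15: beta 0.021 (-0.013, 0.055), p=0.221
```

i.e. the pipeline recovers the simulated causal effect (true OR 1.14 per SD
of exposure) in the forward AD pair, reports null pairs as null, and
expresses reverse analyses as SD change in biomarker per unit log-OR of
disease liability. `analysis/03_power_bounds.py` prints each design's
detectable-OR interval at 80% power, e.g. `PD: 80% power outside
(0.966, 1.035)`, and `analysis/04_calibration.py` verifies frequentist
calibration over replicated simulations (null rejection 0.044, CI coverage
0.956, Egger intercept mean 0.052 against a true directional pleiotropy of
0.05).

A CLI wraps the same library: `mrkit run --plan plan.yaml --out report/`,
`mrkit simulate directional_pleiotropy --out fixtures/`, and
`mrkit power --n-cases 33674 --n-controls 449056 --r2 0.215`.

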