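# Methods

## Setting

Two-sample summary-data Mendelian randomization: genetic variants robustly
associated with an exposure (circulating GDF-15, inverse-normal transformed,
1 SD ≈ 625.0 pg/ml) serve as instruments for its causal effect on binary
disease outcomes, with exposure and outcome associations drawn from
different GWAS. The package also runs the reverse direction (disease
liability → biomarker), where the estimate is the SD change in biomarker per
unit log-OR of disease.

## Instrument selection and harmonization

Instruments are variants with exposure p below genome-wide significance
(default 5×10⁻⁸, strict `<`; a flag switches to `≤` since published
descriptions use both). Harmonization aligns each outcome record onto the
exposure's effect allele by rsID: identical codings are copied, swapped
codings negate the outcome beta, and strand-complement codings are resolved
before alignment. Palindromic variants (A/T, C/G) cannot be resolved from
labels; they are retained only when the exposure EAF and the *label-aligned*
outcome EAF (1−eaf when labels are swapped) fall on the same side of 0.5 and
both lie outside [limit, 1−limit], default limit 0.42. Expressing the
outcome EAF for the aligned allele makes the rule invariant under relabeling
the outcome record, which a raw-value comparison is not. Discordant or
near-0.5 palindromes, and palindromes missing either EAF, are dropped as
`palindromic_ambiguous` rather than frequency-corrected — a deliberately
conservative choice for five-instrument panels, where one silently
mis-oriented variant can dominate.

## Estimators

* **Wald ratio** per instrument: θ_k = Y_k/X_k, SE σY_k/|X_k| (first-order
  only; no second-order delta term).
* **Fixed-effect IVW** (primary): the precision-weighted combination of
  ratios, identical to zero-intercept WLS of Y on X with weights σY⁻².
  A multiplicative random-effects scale max(1, √(Q/(k−1))) is available but
  off by default; the fixed-effect form is the reference definition here.
* **Correlated-instrument IVW**: origin-constrained GLS with
  Ω_jk = σY_j σY_k r_jk from a supplied LD r-matrix. With an identity matrix
  it reduces to IVW exactly (a tested identity). Condition numbers above
  1e12 raise a singularity error suggesting pruning of |r| = 1 pairs.
* **MR–Egger**: instruments are oriented so X_k ≥ 0 (X and Y negated
  jointly), then Y is regressed on X with a free intercept, weights σY⁻².
  SEs carry the multiplicative residual scale max(1, √(RSS_w/(k−2))); the
  intercept test uses Student's t with k−2 df (k is small in practice), the
  slope a normal approximation.
* **Weighted median**: ratio weights are the inverse first-order Wald
  variances X_k²/σY_k². Sorted ratios are interpolated at standardized
  mid-point cumulative weight 0.5; ties break by (θ, rsID) for
  reproducibility. The SE is a parametric bootstrap (resampling each X_k,
  Y_k from normals at their observed values; default 10,000 draws, seed 1,
  recorded in the run manifest).

95% CIs are β ± 1.96σ throughout, matching the reporting convention of the
field; p-values are two-sided normal except the Egger intercept. Binary
outcomes are reported as OR = exp(β) per SD of exposure.

## Sensitivity diagnostics

Cochran's Q uses IVW weights on the ratio scale, which makes Q exactly the
weighted residual sum of squares of the IVW regression (an identity used as
a test oracle). I² = max(0, 100·(Q−df)/Q), the Higgins convention floored at
zero. Leave-one-out refits the primary estimator (correlation-adjusted when
an LD matrix is present, with the matching sub-matrix) k times, flagging
rows whose CI excludes the full-panel point estimate.

## Power

For a binary outcome GWAS of size N with case fraction K and instruments
explaining R² of exposure variance, the two-sided Wald test of the causal
log-OR has approximate non-centrality z = √(N·R²·K(1−K))·|ln OR|, giving
power Φ(z − z_{1−α/2}) and the closed-form detectable bound
ln OR = (z_{1−α/2} + z_power)/√(N·R²·K(1−K)); the lower bound is the exact
reciprocal. With the three disease GWAS dimensions (AD 21,982/41,944; PD
33,674/449,056; ALS 20,806/59,804) and R² = 0.215 this yields upper bounds
of 1.052, 1.035, and 1.050. Published figures derived from the mRnd web
calculator can differ by a few tenths of a percent on the OR scale
(≈ 1.057 has been reported for the AD design), consistent with an
additional binary-trait attenuation term or a different sample-size choice
in the web tool's input; this implementation keeps the transparent
closed form above rather than matching any specific web-tool variant.

## Synthetic data generator

Summary statistics are simulated directly — no individual-level genotypes —
because the analysis consumes only summary data and direct simulation keeps
replicate suites at seconds. Per study: MAFs uniform on (0.1, 0.4); true
exposure effects positive and of comparable magnitude (relative spread
uniform on 0.75–1.25, as sentinel variants at a locus tend to be), scaled so
Σ 2f(1−f)b² equals the explained-variance target (default 0.215 — exactly,
a construction constraint tests rely on). Observed effects add Gaussian
noise with the large-sample SEs 1/√(2f(1−f)N_exp) (continuous exposure) and
1/√(2f(1−f)N·K(1−K)) (binary outcome). The true outcome effect is
causal·b_k + α_k with α_k ~ N(pleiotropy_mean, pleiotropy_sd²) independent
of b_k, so InSIDE holds by construction. `ld_block_r` correlates the
sampling noise with a uniform within-block r and returns the matching
r-matrix. All randomness flows from one seeded generator per study;
replicate suites derive child seeds deterministically from a base seed.

Default dimensions mirror the motivating design: 5 instruments, exposure
GWAS n = 5,440, outcome 21,982 cases / 41,944 controls. The narrow relative
effect spread guarantees (not merely makes likely) that all five exposure
associations are genome-wide significant at these dimensions, so the
selection → harmonization → estimation chain is exercised end to end.

What the generator does **not** emulate: sample overlap between the two
GWAS, winner's curse in instrument discovery, allele-frequency differences
between cohorts, strand mislabeling, and non-collider confounding
structures. Calibration results on these fixtures therefore demonstrate
correctness of the estimators under their own assumptions, not robustness
to those real-data pathologies.

Scenario catalogue (fixed once): `null` (β = 0), `causal` (β = ln 1.14, the
effect size of the motivating finding), `balanced_pleiotropy`
(pleiotropy_sd = 0.002 — deliberately small against the outcome sampling
noise, since the fixed-effect IVW test retains nominal size only in that
regime), `directional_pleiotropy` (mean 0.05 ≈ the magnitude reported in
this literature, sd 0.01), `correlated_instruments` (within-block r = 0.3).

## Numerical choices

* Delimited I/O writes floats at 17 significant digits and parses with
  correctly-rounded conversion, so write→read round-trips are bit-exact.
* Correlation matrices must be symmetric (asymmetries < 1e-6 are averaged),
  unit-diagonal within 1e-6, and PSD within an 1e-8 eigenvalue tolerance.
* A zero exposure effect makes the Wald ratio undefined and raises a named
  error rather than propagating an infinity.
* Underflowing simulated p-values are clipped to 1e-300 to stay inside the
  (0, 1] contract.
* Replicate seeds are drawn as 32-bit states reduced mod 2³¹.

## Analysis problem sizes

The shipped calibration suites use 1,000 null replicates and 500 each for
the causal and directional-pleiotropy scenarios — enough for Monte-Carlo
SEs of ~0.007 on a 5% rejection rate and ~0.003 on the Egger intercept
mean, so the nominal-size, coverage, and unbiasedness checks are sharp at
the tolerances asserted, while a full run stays in the tens of seconds.

## Known limitations

* No MR-PRESSO, mode-based, multivariable, or Steiger extensions.
* No LD clumping or reference-panel computation: the r-matrix is an input.
* The power formula is the transparent normal approximation; see above for
  its relation to web-calculator variants.
* Harmonization matches by rsID only; coordinates are carried as metadata
  (no liftover, no proxy lookup).
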