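# Methods

## Model and derivation

Mortality is modelled with a Gompertz proportional-hazards (PH) form: the
hazard of death `t` years after baseline for a subject aged `CA` with
biomarker vector `x` is

    h(t) = rate · exp(β_age·CA + Σ_i β_i·x_i + shape·t),

i.e. an exponential baseline trend in follow-up time multiplied by a
log-linear term in baseline age and biomarkers. Two nested fits drive the
clock: an age-only model (parameters rate₁, shape₁, β₁) and an
age-plus-biomarkers model (rate₂, shape₂, β₂, β₂ᵢ) fitted with β₂
constrained to β₁. Biological age is the age at which the age-only model's
hazard equals the full model's hazard at t = 0, giving the linear clock

    BioAge = CA + Σ_i (β₂ᵢ/β₁)·x_i + constant.

The two models' empirical hazards differ subject to subject; a
bias-correction factor γ = h₁/h₂ absorbs the discrepancy into the
constant, estimated as the training-cohort mean of
(1/β₁)·log(h₁ⱼ/h₂ⱼ · rate₂/rate₁) with both hazards evaluated at t = 0.
Under the shared-β₁ constraint this collapses algebraically to
−(1/β₁)·Σᵢ β₂ᵢ·mean(xᵢ), which makes the training mean of
BioAgeDiff = BioAge − CA exactly zero; the implementation satisfies that
identity to 1e-10 relative and the test suite enforces it. A
ratio-of-means variant of γ (single scalar mean(h₁)/mean(h₂)) is exposed
via `derive_clock(..., gamma="ratio-of-means")`; it changes only the
constant, by a Jensen-gap amount, and the per-subject mean-of-logs form is
the default. All logarithms are natural.

## Fitting

The right-censored log-likelihood Σ event·log h(tᵢ) − H(tᵢ) (H the
integrated hazard, `(rate·e^lp/shape)(e^{shape·t}−1)` with a series
evaluation below |shape·t| = 1e-5 so the shape→0 exponential limit is
continuous) is maximized with L-BFGS on analytic gradients. Choices that
matter:

- **Parameterization.** The optimizer works on log(rate), so positivity is
  structural. Shape is unconstrained; negative shapes (declining hazard)
  are legal both in fitting and simulation.
- **Initialization.** shape = 0.08 and β_age = 0.08 (a typical adult
  Gompertz slope, a robust basin), biomarker coefficients 0, and log-rate
  at its conditional maximum given those values (the exponential-fit
  rate).
- **Convergence.** The objective is averaged per subject; a fit is flagged
  converged when the scaled score's max-norm is ≤ 1e-4 (typically ~1e-9
  after the polishing pass). A stalled optimizer returns
  `converged=False` with diagnostics rather than raising.
- **Constrained variants.** `fixed_beta_age=v` pins the age coefficient at
  exactly `v` and re-estimates *all* remaining parameters — rate, shape
  and biomarker coefficients. Whether the clock protocol refits rate₂ and
  shape₂ under the constraint is an interpretive choice; this package
  refits them, since holding them at their unconstrained values would
  leave the model at a non-stationary point of the constrained
  likelihood. `fixed_shape=0` with `include_age=False` reduces to the
  exponential model, whose MLE rate equals events/person-time (tested to
  1e-6 relative).
- **Degenerate inputs.** Zero events raise; a rank-deficient biomarker
  matrix (condition number > 1e10) warns and proceeds, since L-BFGS
  tolerates flat directions.

Biomarkers enter on their native scales so clock coefficients keep
clinical units (years per mg/dL, etc.); standardization is confined to the
selection module, whose supports are thereby unit-invariant.

## Synthetic cohorts

The simulator draws ages uniformly on a range (default 40–80), biomarkers
from per-marker normal/lognormal specs (optionally with a linear age
trend, off by default so coefficient recovery is unconfounded), and event
times by inverse-transform sampling of the Gompertz PH hazard:
T = (1/shape)·log(1 + shape·E/(rate·e^lp)) with E ~ Exp(1). For negative
shapes the survival function plateaus; draws landing in the never-dying
tail are resampled, so times are conditioned on the event occurring.
Censoring is an administrative horizon (default 20 years) plus optional
exponential dropout. Everything is reproducible bit-for-bit from one
integer seed.

`make_light_truth(beta1)` builds the recovery experiment: three biomarkers
whose generating coefficients are the published clock ratios (8.3313,
0.8270, 5.7305 years per unit) times β₁ = 0.09/yr, shape 0.09/yr,
marginals chosen to approximate routine clinical ranges — creatinine
N(0.9, 0.3) mg/dL, glucose N(5.5, 1.5) mmol/L, log CRP N(0.3, 1.0) — and
the baseline rate calibrated deterministically (fixed-seed Monte Carlo +
root finding on log-rate) so ~35% of subjects die within the horizon.

What the simulator does *not* emulate: biomarker–biomarker and
age–biomarker correlation (unless requested), measurement error,
non-proportional hazards, cohort heterogeneity beyond the modelled
covariates, and competing risks. Passing tests therefore demonstrate the
estimator and derivation machinery, not robustness to real-data
violations of the PH or Gompertz assumptions.

## A known, quantified limitation

The recovery experiment exposes an intrinsic property of the two-model
protocol: the age-only model is misspecified whenever biomarkers carry
real hazard variance, and its β₁ is attenuated relative to the full
model's age coefficient (here ≈ 0.083 vs 0.090 at n = 500,000 — the
linear-predictor SD contributed by the biomarkers is ≈ 0.57). Since β₁ is
the denominator of every clock coefficient, derived ratios run a few
percent high (≈ +6–8% under these conditions), on top of sampling noise
(relative SE at n = 20,000 and ~7,000 events: ≈ 5% for the
creatinine-analogue, ≈ 11% for the glucose-analogue, ≈ 2% for the
log-CRP-analogue). The effect shrinks with shorter follow-up and smaller
biomarker effects, and is invisible in the constant (the γ correction
absorbs level bias exactly). The package reports what the protocol
produces; it does not re-scale coefficients toward the generating truth.

## Selection

`lasso_cox_select` standardizes candidates, fits a pure-L1 elastic-net Cox
path, and scores each penalty by k-fold cross-validated Harrell C-index
with folds stratified by event status and shuffled deterministically from
the seed. Penalty rules: the C-index maximizer, the parsimonious
one-standard-deviation rule (largest penalty within one SD of the
maximum), or an exact user-fixed value. Ties in the partial likelihood use
Breslow handling. An empty support at the chosen penalty warns and
returns no biomarkers. `stability_subsample` refits at a single penalty on
`frac`-subsamples without replacement and reports per-biomarker selection
frequencies.

## Evaluation battery

- **C-index**: Harrell's concordance (ties at 0.5), cross-checked in the
  tests against an O(n²) pairwise oracle.
- **Horizon AUC** (default 10 years): outcome is death by the horizon;
  subjects censored earlier without an event carry no label and are
  excluded (simple-exclusion convention — configurable in principle, and
  an acknowledged place where conventions differ; IPCW weighting is out
  of scope). Both the fitted-probability AUC of a univariate logistic
  model and the rank AUC are reported; they coincide when the logistic
  slope is positive.
- **KM quantile curves**: product-limit curves for the top/bottom
  age-gap quantiles (threshold ties are included in the high-risk group,
  making "top 25%" a closed upper set), Greenwood log-log 95% bands,
  optional age strata (defaults 45–54/55–64/65–74/75–85).
- **Cox HR per year of age gap**: partial-likelihood fit (Breslow ties)
  with optional age/sex adjustment, Wald 95% CI.
- **PCA age**: biomarkers standardized, first five principal-component
  scores regressed on age by least squares, fitted value returned. Fewer
  biomarkers than components → all components, with a warning.
- **Mahalanobis distance**: Cholesky solve against a reference
  mean/covariance (cohort or designated subsample); a singular covariance
  is ridge-regularized with a warning.

## Panel decomposition and risk score

A panel definition assigns disjoint biomarker subsets (e.g.
cardiometabolic/inflammatory/neurological/oncological); each panel's Diff
is Σ coefficient·(x − cohort mean), so panel Diffs are mean-zero and sum
(with unassigned terms) to the centered total. The risk score counts the
panels in which a subject sits at or above the top-quantile threshold
(default top 25%), an integer 0..n_panels; ties count as high-risk so the
rule is deterministic.

## Problem sizes in the test suite

Simulation-based tests use the smallest sizes at which their statistical
assertions are stable: n = 20,000 for coefficient recovery and panel
independence, n = 50,000 for distributional fidelity (KS at the 1%
critical value), n = 100,000 for empirical hazard-ratio checks, n ≤ 5,000
for selection, and ≤ 200 subjects wherever an O(n²) oracle runs. The full
suite completes in well under a minute on one CPU.
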