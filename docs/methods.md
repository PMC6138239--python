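# Methods

## The model

Serum concentration after a single oral dose is described by the Bateman
(one-compartment, first-order absorption and elimination) curve

    c(t) = D·K·ka / [(Cl/F)·(ka − K)] · (e^(−K·t) − e^(−ka·t)),

with dose `D` (mg), absorption and elimination rate constants `ka`, `K`
(h⁻¹), and apparent oral clearance `Cl/F` (L/h, clearance over
bioavailability; equal to `D / AUC₀₋∞` in this model).  With `ka > K` the
`(ka − K)` denominator keeps concentrations non-negative.  Derived
quantities follow in closed form: `t_max = ln(ka/K)/(ka − K)`,
`C_max = c(t_max)`, half-lives `ln 2 / K` and `ln 2 / ka`, apparent volume
`V/F = (Cl/F)/K`.

Under repeated dosing every `τ` hours (default 24 h, once daily), each
exponential acquires its geometric accumulation factor `1/(1 − e^(−k·τ))`,
giving the steady-state trough `c_min,ss` (profile at `t = τ`), the peak
`c_max,ss` at

    t_max,ss = ln[ka(1 − e^(−Kτ)) / (K(1 − e^(−kaτ)))] / (ka − K),

and the interval average `c_avg,ss = D/[(Cl/F)·τ]`.  An explicit n-dose
superposition sum (`superposition_oracle`) provides an independent check of
these closed forms; the tests require agreement to 1e-8 relative at 30
doses.  Note that `t_max,ss` is slightly smaller than the single-dose
`t_max`; the package exposes both and never conflates them.

A second parameterization expresses clearance as a multiple of the
patient's baseline creatinine clearance, `Cl/F = r · CrCl` with `r`
dimensionless and CrCl in L/h.  This is the form used for renal dose
individualization: predicted steady-state peaks over a grid of CrCl values
and dose levels.

### The ka = K boundary

The Bateman denominator vanishes at `ka = K`.  Within `|ka − K| < 1e-6` the
implementation switches to a second-order series in `(ka − K)·t`
(`c → D·K·ka·t·e^(−Kt)/(Cl/F) · (1 − dt/2 + (dt)²/6)`), so the two branches
agree to ~1e-8 relative at the switch and optimizers can traverse the
boundary.  The steady-state forms use a zeroth-order limit switched at
1e-9, where the neglected term is below 1e-7 relative.

## Estimation

Population parameters are estimated by maximizing a Laplace-approximate
marginal likelihood.  Patient-level random intercepts act additively on the
natural scale of `Cl/F` (or the ratio `r`) and `ka`, with an unstructured
2×2 covariance and additive Gaussian residual error:

    y_ij = c(t_ij; K, ka + b_ka,i, Cl/F + b_cl,i) + ε_ij.

For each patient the mode of the penalized least-squares problem is found
by damped Gauss-Newton with analytic Jacobians (vectorized across
patients), and the random-effect integral is replaced by the Gaussian
volume at the mode with the Gauss-Newton Hessian `JᵀJ/σ² + Ψ⁻¹`.  The seven
population parameters are optimized on transformed scales (log for positive
quantities, atanh for the correlation) by L-BFGS-B, followed by a short
Nelder-Mead polish: the likelihood ridge between `ka` and clearance is
flat, and finite-difference gradients alone stop a fraction of a percent
short of the optimum.  Fits are deterministic given the data; reordering or
relabeling patients perturbs results only at optimizer-reproducibility
level (~1e-5 relative).

Initial values are deterministic: `K` from the terminal slope of pooled
dose-normalized log concentrations (t ≥ 8 h), `ka` by the method of
residuals, clearance from dose over the extrapolated trapezoidal AUC, all
polished by one pooled nonlinear least squares.

Pre-dose records with concentration zero are excluded by default: under
the additive-error model the prediction there is exactly zero and the
records carry no information (toggle `include_baseline_zeros`).  Rows
flagged below the limit of quantification (0.02 mg/L) are excluded from
fitting.

The covariance of the fixed effects comes from the observed information
(central-difference Hessian at the optimum, chain-ruled to the natural
scale).  Variance components that collapse onto a boundary — e.g. the
random-effect SDs on noise-free data — contribute no curvature and are
treated as fixed when inverting; a missing-curvature fixed effect is an
error.  AIC and BIC use `p = 7` parameters and `n` = number of
concentration observations; model comparison is smaller-is-better.  Because
the parameter count entering published information criteria is not
standardized across software, only the comparison logic — not specific
AIC/BIC values — is treated as reproducible.

Empirical Bayes estimates (BLUPs) are the per-patient posterior modes at
the fitted population parameters.  They shrink individual least-squares
estimates toward the population mean; with two correlated random effects
the shrinkage path is not exactly coordinate-wise, so the tests allow a
small margin when asserting betweenness.

Standard errors for derived quantities use the delta method: `se² = gᵀΣg`
with `g` the central-difference gradient of the transform on the
natural-scale fixed effects and `Σ` their covariance, and Wald intervals
from normal quantiles.  Parametric bootstrap agreement (within 5% at
coefficient CV < 0.2) is part of the acceptance suite.

## Renal function

eGFR uses the creatinine equation
`141 · min(Cr/a, 1)^b · max(Cr/a, 1)^(−1.209) · 0.993^age · c · k` with
creatinine in μmol/L, sex-specific constants `a` = 79.6/61.9,
`b` = −0.411/−0.329, `c` = 1/1.018 (male/female), and `k` = 1.159 with the
ethnicity adjustment.  The `min/max` kernel is read as the ratio `Cr/a` —
the standard CKD-EPI structure; any other reading degenerates for plausible
creatinine values.

Creatinine clearance uses the Cockcroft-Gault equation with μmol/L
constants 1.23 (male) / 1.04 (female) and a BMI-dependent weight: total
body weight below BMI 18.5, ideal body weight (metric Devine: 50/45.5 kg +
0.906 kg/cm above 152.4 cm, floored at the base) for BMI 18.5-22.9, and
adjusted body weight `IBW + 0.4·(TBW − IBW)` at BMI ≥ 23 (unrounded BMI;
23.0 exactly triggers the ABW rule).  The Devine formula and the
1.23/1.04 constants are this package's documented choices where the source
analysis names the quantities without defining them.

Clearance unit conversion is the exact factor 1 L/h = 1000/60 mL/min.

## Trough diagnostics

The fitted single-dose model implies per-dose steady-state bands: 95%
confidence intervals for the *mean* `c_min,ss`, `c_avg,ss`, `c_max,ss`
(delta method).  These are mean-response intervals, not prediction
intervals — individual troughs legitimately fall outside them, so the
classification rule keys on repetition: a patient is Group 1 when strictly
more than one trough exceeds the upper limit of the `c_min,ss` interval
(boundary equality counts as inside, conservative toward Group 2).  In the
motivating cohort this label tracks creatinine clearance below about
32 mL/min, where the one-compartment model under-predicts accumulation.

A visit is flagged as a suspected protocol violation (dose taken before
the pre-dose blood draw) when one or two of a patient's troughs lie inside
the `c_max,ss` interval while all others lie inside the `c_min,ss` interval
(closed-interval membership).  Flags are labels; no observation is ever
altered or removed.

Group comparisons use the Wilcoxon rank-sum test with `W` defined as the
Mann-Whitney count of `(x_i > y_j)` pairs (ties ½) for the first-listed
sample.  The p-value is exact — full permutation distribution via the
standard recurrence — when `n_x·n_y ≤ 400` and there are no cross-sample
ties, otherwise a tie-corrected normal approximation.  The shift estimate
is Hodges-Lehmann (median of pairwise differences) with an exact
order-statistic confidence interval.

The exploratory trough model regresses log concentration on dose, CrCl and
BMI with a patient random intercept (REML, statsmodels MixedLM), starting
from all two-way interactions and removing non-significant terms backward —
interactions first, one per step, largest Wald p first, main effects kept
while a surviving interaction contains them.

## Synthetic trials

The generator emulates the three-cohort dose-escalation design: 6 patients
per cohort at 250/500/1000 mg once daily, first-dose sampling at 0, 2, 4,
6, 8, 24 h, and six trough visits over four weeks; limit of quantification
0.02 mg/L (censored values reported at the limit with a flag).  Defaults
are the published population estimates: `K` 0.119 h⁻¹, `ka` 0.65 h⁻¹,
`Cl/F` 29.6 L/h, between-patient SDs 11.56 L/h and 0.395 h⁻¹ with
correlation 0.785, residual SD 0.095 mg/L, and baseline CrCl uniform on
18-49 mL/min (the study reports only the range and median, so the uniform
is a documented choice).  Covariates are drawn to match the cohort
summaries (median age 66 y, median BMI 38 kg/m², BMI truncated at 23 so the
adjusted-body-weight rule always applies, as observed), and serum
creatinine is back-solved so Cockcroft-Gault reproduces the drawn CrCl.

Random effects are a truncated bivariate normal on the natural scale
(redraw until both individual parameters are positive), mirroring the
fitting assumption.  The truncation is a deliberate deviation from pure
normality and biases the realized clearance moments slightly (mean +~4%,
SD −~8% at the default parameters), because rejecting negative-`ka` draws
preferentially removes low-clearance draws under the strong positive
correlation.

Two planted mechanisms give the downstream diagnostics known answers:

* **Breakdown** — patients with CrCl below 32 mL/min have troughs
  multiplied by a patient-level factor drawn log-uniformly on [1.5, 4].
  This is phenomenological, not kinetic: the motivating study reports the
  model failure but proposes no generative mechanism, so the factor exists
  solely to give the classifier a detectable planted signal.
* **Protocol violations** — with probability 0.05 per visit a trough is
  replaced by the individual steady-state peak plus noise and recorded in
  the truth sidecar.

The truth log (individual parameters, breakdown factors, violation visits)
is written to a separate JSON sidecar and never appears in the
analysis-facing CSVs.

What the generator does *not* emulate: nonlinear or time-varying
elimination, absorption lag, within-patient kinetic changes over the four
weeks, dropout, or assay-specific error structure.  Passing tests therefore
demonstrate that the estimation and classification machinery recovers known
structure under the model's own assumptions — not that the model is correct
for real patients.

## Problem sizes and tolerances

* Parameter recovery: 50 simulated 18-patient cohorts; fixed-effect bias
  < 15%, Cl/F Wald-CI coverage in [85%, 99%].  Larger single-cohort checks
  use ~100 patients (10% fixed-effect, 25% random-effect tolerance,
  reflecting n and the Laplace approximation).
* Superposition cross-check: 100 random parameter sets, 30 doses, 1e-8
  relative.
* Rank-sum exactness: full enumeration for all sample splits up to total
  size 10.
* Values quoted from the published analysis are asserted at 1% relative
  (estimates are printed to 2-3 significant figures); the CrCl-model dose
  predictions at 1.5% because that model's own rate constants are
  unpublished and the plain-model values stand in.
* Inner mode convergence: gradient norm below 1e-9·(1+|objective|); outer
  convergence by L-BFGS-B (ftol 1e-12) plus Nelder-Mead polish
  (xatol 1e-6).

## Known limitations

* The Laplace approximation uses the Gauss-Newton Hessian at the mode;
  with large residual curvature its likelihood differs from adaptive
  quadrature.  At this design's residual error the parameter-recovery
  experiments bound the practical consequence.
* Natural-scale random effects can imply non-positive individual
  parameters; the fit constrains the per-patient modes to the positive
  region and the generator truncates, so extreme tails are not faithfully
  normal.
* Mean-response bands are narrower than prediction bands; users reading
  the classification output should not interpret band exceedance by a
  single observation as model failure (the rule requires repetition for
  this reason).
* The exact rank-sum path requires tie-free data; ties always route to the
  tie-corrected normal approximation regardless of sample size.
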