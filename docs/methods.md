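# Methods

## Model

Individuals are cross-classified by survey period (wave year, 7 levels)
and birth cohort (15 unequal-width historical groups). For respondent
*i* in period *j* and cohort *k*,

    y_ijk = x_i'β + p_0j + c_0k + (p_4j + c_4k)·rural_i + e_ijk,

where x_i holds an intercept, grand-mean-centered age, the square of
centered age, centered 0/1 covariate dummies (female, rural *hukou*,
party member, married, four education levels against illiteracy,
employed), and age-by-covariate interactions built as products of the
centered columns. The random terms are independent normals:
p_0j ~ N(0, σ²_p0), c_0k ~ N(0, σ²_c0), p_4j ~ N(0, σ²_p4),
c_4k ~ N(0, σ²_c4), e ~ N(0, σ²_e). Random slopes multiply the *raw*
rural indicator (the fixed *hukou* term stays centered), and slopes are
independent of intercepts within a classification — no covariance term
is estimated, matching the model's level-2 specification of separate
normal deviations.

Identification of the three collinear time scales rests on (a) the
nonlinear (quadratic) age profile at level 1 and (b) the unequal-width
cohort grouping plus shrinkage of the period/cohort deviations toward
zero. This is a constrained solution to the age-period-cohort problem,
not a free lunch; the synthetic generator draws data from exactly this
model, so recovery results certify the estimator, not the
identification strategy on arbitrary real data.

### Centering conventions

Age and each dummy are centered at their grand means; the age-squared
column is the square of centered age and the interaction columns are
products of centered columns, and neither is re-centered afterwards.
The intercept is therefore the conditional predicted outcome at the
covariate means up to the small β₂·E[(a−ā)²] term. Whether the original
analysis additionally centered the age-squared column is not
determinable from its near-zero baseline-model coefficient; the
generator and the design builder share one convention, so simulations
are exact-model either way. Predictions are always reported on the
original age scale, so the choice of offsets cannot change any curve.

## Estimation

Writing Z for the horizontal stack of the active indicator blocks and
D for the diagonal of variance ratios γ_b = σ²_b/σ²_e, the marginal
covariance is V = σ²_e(I + Z D Z'). All likelihood quantities reduce by
the Woodbury identity to the cross-products X'X, Z'Z, Z'X, X'y, Z'y,
y'y, computed once per design; each evaluation then costs O(q³) in the
number of random-effect levels q (≤ 44), never O(n³). β is profiled out
by GLS and σ²_e analytically, leaving a ≤ 4-dimensional problem in
log γ, solved by Nelder-Mead (two fixed starts, log 0.05 and log 0.5;
relative log-likelihood tolerance ~1e-8). Non-negativity is enforced by
the log parameterization with a floor at log γ = −30; estimates below
log γ = −15 are reported as exact zeros with a boundary flag.

REML is the default for variance components. The Model 1→5 ladder is
fitted under ML because the models differ in fixed effects and REML
likelihoods are not comparable across fixed-effect sets. BIC is
−2·loglik + k·ln(n) with k = fixed effects + estimated variance
components and n = individuals (software packages differ here; this
convention is stated so ladders are comparable within this package).

Standard errors: fixed effects from σ̂²_e(X'W⁻¹X)⁻¹ with two-sided
normal p-values; variance components from a central finite-difference
Hessian of the (RE)ML log-likelihood on the variance scale, with
one-sided Wald z p-values (the convention of common mixed-model
software output). Boundary components get NaN standard errors — a Wald
test is meaningless at the boundary. A likelihood-ratio alternative can
be formed from `marginal_loglik` directly; it is not wired into the
summary because the reference output it mirrors uses Wald-type tests.

BLUPs are conditional means û = G Z'V⁻¹(y − Xβ̂) with prediction
variances G − G Z'V⁻¹Z G + G Z'V⁻¹X (X'V⁻¹X)⁻¹ X'V⁻¹Z G; the star
codes attached to period/cohort curves are two-sided normal tests of
û against its prediction standard error.

### Degenerate inputs

With a single period (or cohort), the group indicator is collinear with
the intercept: under ML the variance is driven to the zero boundary and
β̂ equals OLS; under REML the fixed-effect determinant correction
absorbs the one-group ridge exactly and the profile is flat in that
variance — the optimizer then returns an arbitrary point on the ridge,
which is why the degenerate-case contract is stated under ML.
σ²_e = 0 is rejected (singular model).

## Synthetic generator

The generator emulates a seven-wave repeated cross-sectional survey
(2005, 2006, 2008, 2010–2013) with per-wave sizes proportional to the
published wave totals (total 62,755; `scale_wave_sizes` rescales them
to any total). Defaults are the study conditions: full-model fixed
effects (intercept 3.5017, age −0.0225, age² 0.00029, rural −0.0722,
married 0.1182, employed 0.1887, age×hukou −0.0025, ...), variance
components σ²_p0 = 0.10, σ²_c0 = 0.015, σ²_p4 = 0.0046,
σ²_c4 = 0.0032, and σ²_e = 1.0645. The residual variance is not
published directly; it is derived by inverting the baseline model's
intra-class correlation: σ²_e = (σ²_p0+σ²_c0)(1−ICC)/ICC with
ICC = .1004 and the baseline variances .1038/.0150.

Birth years are drawn by sampling a cohort group with probability equal
to the mass of a normal age structure (mean 46.22, SD 15.48) over the
ages the group implies at that wave, then uniformly within the group's
admissible years (minimum respondent age 15); covariates are drawn
independently from the published marginal proportions. The latent
outcome is built through the same design builder the fitting side uses,
so parameter-recovery simulations are exact-model. Discretization onto
the 1–5 scale uses fixed cut points (1.55, 2.64, 3.28, 4.37), the
latent-outcome quantiles of the default configuration at the observed
cumulative category shares; the default pipeline runs on the latent
continuous outcome, with discretization available for robustness
exercises.

What the generator does **not** emulate: multistage cluster sampling,
survey weights, nonresponse, covariate-cohort dependence (education is
independent of cohort here, unlike reality), and ordinal measurement
error beyond simple thresholding. Passing recovery tests therefore show
the estimator is correct for the assumed model, not that the model is
correct for any particular survey.

## Derived curves and classification

Conditional predicted values put every centered covariate at 0 (the
grand mean) unless a profile overrides it with a raw value. Disparity
curves are computed literally as urban-profile prediction minus
rural-profile prediction (positive = urban advantage), which for the
age axis equals −(π̂₄ + β̂_age×hukou·(a−ā)) and for the period/cohort
axes subtracts the random-slope BLUPs.

A linear-in-age group gap main + interaction·(a−ā) is classified as
"cumulative" when |gap| grows over the requested age range, "leveler"
when it shrinks, "leveler-with-reversal" when its zero crossing
(ā + main/(−interaction), reported to 0.1 year) lies inside the range,
and "constant" with no interaction. The classification range is a
parameter because it changes labels near the edges: the published
urban-rural coefficients put the zero-gap age near 17, so classifying
from the adult span (~30 up) calls that gap cumulative, while a range
reaching down to the mid-teens would report a technical reversal at an
age where the gap is negligible.

## Problem sizes in the test suite

The dense-covariance likelihood/BLUP oracle runs at n ≤ 300 (the oracle
is O(n³)). The recovery study uses 100 replicates of the seven-wave
design at n = 10,000 with the default (published-scale) parameters,
checking mean estimates against truth within two Monte-Carlo standard
errors and BIC preference for the full model; the classification check
fits one n = 40,000 replicate. These sizes are the package's chosen
simulation scale; the estimator itself handles the full 62,755-row
design in under a minute.

## Known limitations

- Two crossed classifications only; no three-way crossing, no nesting.
- Gaussian outcome only; the ordinal outcome is handled by treating the
  scale as continuous (or by thresholding in the generator), not by a
  cumulative-link model.
- No intercept-slope covariance within a classification.
- No sampling weights; list-wise deletion is the only missing-data
  strategy.
- Wald z tests on variance components are poorly calibrated near the
  boundary; treat "+" codes on small variance components with caution.
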