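# apchealth

Hierarchical age–period–cohort analysis of self-rated health with
cross-classified random effects, built around the urban–rural (*hukou*)
health-disparity question in Chinese repeated cross-sectional survey
data.

## The problem

Self-rated health (SRH, a 1–5 ordinal scale treated approximately as
continuous) varies along three exactly collinear time dimensions —
age, survey period, and birth cohort (period = age + cohort) — so their
effects cannot be separated in an ordinary regression. The hierarchical
APC cross-classified random effects model (HAPC-CCREM) breaks the
deadlock by treating individuals (level 1) as cross-classified by survey
period *j* and birth cohort *k* (level 2), with unequal-width,
historically defined cohort groups aiding identification:

Level 1:

    Health_ijk = α_0jk + β₁·age_i + β₂·age_i² + β₃·gender_i
               + β_4jk·hukou_i + β₅·party_i + β₆·marital_i
               + β₇·education_i + β₈·work_i
               + Σ_m β_m·age_i·x_mi + e_ijk

Level 2:

    α_0jk = π₀ + p_0j + c_0k
    β_4jk = π₄ + p_4j + c_4k

with p_0j ~ N(0, σ²_p0), c_0k ~ N(0, σ²_c0) the random period and cohort
intercepts and p_4j, c_4k random *hukou* slopes, so the urban–rural
health gap itself varies over periods and cohorts. All fixed-effect
covariates are grand-mean centered, making π₀ the conditional predicted
SRH at the covariate means. Estimation is by profiled (restricted)
maximum likelihood over the variance components; the package reports
fixed effects with Wald tests, variance components with one-sided Wald z
tests, BLUPs (shrinkage predictions) of every random effect, the
intra-class correlation (σ²_p0+σ²_c0)/(σ²_p0+σ²_c0+σ²_e), and BIC.

The package covers the whole workflow:

- `synthetic_cgss` — generates seven-wave survey data (2005–2013
  structure, realistic covariate margins and wave sizes) with exactly
  the model's statistical structure, so every downstream stage is
  testable without restricted-access survey data;
- `survey_prep` — validation, the 15-group historical cohort scheme
  (warlord-dogfight through further-reform cohorts), dummy coding,
  centering, and design-matrix construction;
- `ccrem` — the cross-classified mixed model (ML/REML), via a Woodbury
  reduction that never forms the n×n covariance;
- `apc_effects` — net age/period/cohort curves, urban–rural disparity
  curves, quadratic turning points, gap-crossing ages, and
  cumulative-advantage vs age-as-leveler classification;
- `report` / `cli` — the stepwise Model 1→5 ladder, a combined
  coefficient table, printed-table consistency checks, and an
  `apchealth` command-line interface.

## Worked example

```python
import apchealth as ap

cfg = ap.GeneratorConfig(wave_sizes=ap.scale_wave_sizes(20000), seed=2)
table = ap.assign_cohorts(ap.generate_survey(cfg))

spec = ap.model_ladder(method="reml")[-1]          # full model (M5)
fit = ap.fit_ccrem(ap.build_design(table, spec), spec)

print(f"ICC = {fit.icc:.4f}")
print(fit.varcomps.round(4))
tp = ap.turning_point(fit.beta["age"], fit.beta["age2"],
                      fit.centering_offsets["age"])
print(f"age trajectory minimum at {tp:.1f} years")
pat = ap.classify_age_pattern(fit.beta["marital"], fit.beta["age_x_marital"],
                              fit.centering_offsets["age"], (30, 95))
print(f"marital gap: {pat.label} (zero-gap age {pat.crossing_age})")
```

prints

```
ICC = 0.1338
                     estimate      se  pvalue  boundary
sigma2_period          0.1612  0.0936  0.0425     False
sigma2_cohort          0.0046  0.0024  0.0281     False
sigma2_period_slope    0.0064  0.0045  0.0777     False
sigma2_cohort_slope    0.0065  0.0040  0.0527     False
sigma2_resid           1.0732  0.0107  0.0000     False
age trajectory minimum at 85.0 years
marital gap: leveler-with-reversal (zero-gap age 92.4)
```

On this replicate, 13.4% of the outcome variance sits at the
period/cohort level; the quadratic age profile declines until age 85
then turns; and the married/unmarried health gap narrows with age and
reverses late in life — the age-as-leveler pattern — while the
urban–rural gap widens with age (cumulative disadvantage). Single
replicates are noisy at this scale; the test suite's recovery study
averages 100 replicates.

The same pipeline is available from the shell:

```sh
apchealth simulate --config cfg.yaml --out data.csv --seed 42
apchealth fit --data data.csv --method reml --out fit.json
apchealth effects --fit fit.json --axis cohort --out cohort_curve.tsv
apchealth run --config cfg.yaml --out report_dir/   # full Model 1→5 ladder
```

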