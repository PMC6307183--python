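"""Synthetic repeated cross-sectional survey generator.

Emulates the structure of a seven-wave Chinese social survey (2005-2013):
per-wave sample sizes, covariate margins, a quadratic age profile, crossed
period x cohort random intercepts, random urban/rural (*hukou*) slopes in
both classifications, and a latent continuous self-rated-health outcome
that can optionally be discretized onto the 1-5 ordinal scale.

The latent outcome for respondent i in wave j and cohort k is

    y_ijk = x_i' beta + p0_j + c0_k + (p4_j + c4_k) * rural_i + e_ijk,

where x_i is exactly the fixed-effects design the model-fitting side
builds (intercept, centered age, squared centered age, centered dummies
and age interactions), so parameter-recovery simulations are exact-model.
Covariates are drawn independently from configurable margins; birth years
are drawn uniformly within a cohort group after the group is sampled with
probability proportional to a normal age structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .survey_prep import (
    CATEGORY_LEVELS,
    SURVEY_COLUMNS,
    CohortScheme,
    ModelSpec,
    assign_cohorts,
    build_design,
    default_cohort_scheme,
)

__all__ = [
    "GeneratorConfig",
    "default_table1_margins",
    "default_fixed_effects",
    "generate_survey",
    "scale_wave_sizes",
    "SRH_CUT_POINTS",
]

logger = logging.getLogger("apchealth.synthetic")

#: Survey wave calendar years and their sample sizes (per-wave totals of
#: the seven-wave 2005-2013 design; total 62,755).
DEFAULT_WAVE_YEARS = (2005, 2006, 2008, 2010, 2011, 2012, 2013)
DEFAULT_WAVE_SIZES = (10332, 10139, 5628, 11145, 5218, 10555, 9738)

#: Overall age distribution used to weight cohort groups (mean and SD of
#: respondent age across all waves).
AGE_MEAN = 46.22
AGE_SD = 15.48

#: Cut points mapping the latent continuous outcome to the 1-5 ordinal
#: scale.  Fixed once as the latent-outcome quantiles of the default
#: configuration at the observed cumulative shares .037 / .204 / .393 /
#: .751, so that discretization reproduces the observed marginal SRH
#: distribution (3.7 / 16.7 / 18.9 / 35.8 / 24.8 percent).
SRH_CUT_POINTS = (1.55, 2.64, 3.28, 4.37)


def default_table1_margins() -> dict[str, dict[str, float]]:
    """Marginal covariate proportions of the pooled seven-wave sample.

    Each map is keyed by category level (reference level first) and is
    renormalized to sum exactly to 1.
    """
    raw = {
        "gender": {"male": 0.483, "female": 0.517},
        "hukou": {"urban": 0.469, "rural": 0.531},
        "party": {"nonmember": 0.895, "member": 0.105},
        "marital": {"single": 0.192, "married": 0.808},
        "education": {"illiteracy": 0.128, "primary": 0.234,
                      "junior": 0.301, "senior": 0.202, "college": 0.135},
        "work": {"unemployed": 0.344, "employed": 0.656},
    }
    out = {}
    for col, m in raw.items():
        total = sum(m.values())
        out[col] = {k: v / total for k, v in m.items()}
    return out


def default_fixed_effects() -> dict[str, float]:
    """Fixed-effect coefficients of the full model (SRH points per unit).

    The intercept is the conditional predicted SRH at the covariate grand
    means; all other coefficients apply to grand-mean-centered columns.
    """
    return {
        "intercept": 3.5017,
        "age": -0.0225,
        "age2": 0.00029,
        "gender": -0.1159,
        "hukou": -0.0722,
        "party": 0.0487,
        "marital": 0.1182,
        "edu_primary": 0.1377,
        "edu_junior": 0.3084,
        "edu_senior": 0.3699,
        "edu_college": 0.4028,
        "work": 0.1887,
        "age_x_gender": -0.0010,
        "age_x_hukou": -0.0025,
        "age_x_marital": -0.0038,
        "age_x_work": 0.0021,
    }


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated survey.

    Defaults reproduce the seven-wave 2005-2013 structure: wave sizes,
    covariate margins, full-model fixed effects, period intercept variance
    .10, cohort intercept variance .015, hukou slope variances .0046
    (period) and .0032 (cohort) and residual variance 1.0645 (obtained by
    inverting the baseline model's intra-class correlation of .1004 from
    its period + cohort variances), all in squared SRH points.
    """

    wave_years: tuple[int, ...] = DEFAULT_WAVE_YEARS
    wave_sizes: tuple[int, ...] = DEFAULT_WAVE_SIZES
    cohort_scheme: CohortScheme = field(default_factory=default_cohort_scheme)
    fixed_effects: dict[str, float] = field(default_factory=default_fixed_effects)
    sigma2_period: float = 0.10
    sigma2_cohort: float = 0.015
    sigma2_period_slope: float = 0.0046
    sigma2_cohort_slope: float = 0.0032
    sigma2_resid: float = 1.0645
    covariate_margins: dict[str, dict[str, float]] = field(
        default_factory=default_table1_margins)
    birth_year_range: tuple[int, int] = (1915, 1996)
    min_age: int = 15
    seed: int = 0
    discretize: bool = False

    def validate(self) -> None:
        if len(self.wave_years) != len(self.wave_sizes):
            raise ValueError("wave_years and wave_sizes must have equal length")
        if any(s < 1 for s in self.wave_sizes):
            raise ValueError("all wave_sizes must be >= 1")
        for name in ("sigma2_period", "sigma2_cohort", "sigma2_period_slope",
                     "sigma2_cohort_slope", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.birth_year_range
        if lo < 1890 or hi > max(self.wave_years):
            raise ValueError("birth_year_range must lie within "
                             "[1890, max(wave_years)]")
        if hi > self.cohort_scheme.max_year:
            raise ValueError("birth_year_range exceeds the cohort scheme")
        if hi >= min(self.wave_years):
            raise ValueError("latest birth year would produce non-positive "
                             "ages in the earliest wave")
        for col, m in self.covariate_margins.items():
            if abs(sum(m.values()) - 1.0) > 1e-9:
                raise ValueError(f"covariate margins for {col!r} must sum to 1")
            levels = CATEGORY_LEVELS.get(col)
            if levels is not None and set(m) != set(levels):
                raise ValueError(
                    f"margins for {col!r} must cover levels {list(levels)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort_scheme"] = [list(iv) for iv in self.cohort_scheme.intervals]
        d["wave_years"] = list(self.wave_years)
        d["wave_sizes"] = list(self.wave_sizes)
        d["birth_year_range"] = list(self.birth_year_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "cohort_scheme" in d:
            ivs = tuple(
                (lab, None if s is None else int(s), int(e))
                for lab, s, e in d["cohort_scheme"]
            )
            d["cohort_scheme"] = CohortScheme(ivs)
        for key in ("wave_years", "wave_sizes", "birth_year_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def scale_wave_sizes(total: int,
                     sizes: tuple[int, ...] = DEFAULT_WAVE_SIZES
                     ) -> tuple[int, ...]:
    """Scale per-wave sample sizes proportionally to a new overall total."""
    sizes = np.asarray(sizes, dtype=float)
    raw = sizes / sizes.sum() * total
    out = np.floor(raw).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    short = total - out.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    out[order[:short]] += 1
    return tuple(int(x) for x in np.maximum(out, 1))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _cohort_weights(config: GeneratorConfig, wave: int) -> np.ndarray:
    """Probability of each cohort group in a given wave.

    Mass of a normal age structure (mean 46.22, SD 15.48) over the ages
    the group's admissible birth years imply at that wave; groups with no
    admissible birth year (too young or outside the configured range) get
    zero weight.
    """
    lo_r, hi_r = config.birth_year_range
    hi_r = min(hi_r, wave - config.min_age)
    w = []
    for label, start, end in config.cohort_scheme.intervals:
        lo = max(start if start is not None else lo_r, lo_r)
        hi = min(end, hi_r)
        if lo > hi:
            w.append(0.0)
            continue
        age_lo, age_hi = wave - hi, wave - lo   # inclusive age range
        mass = stats.norm.cdf(age_hi + 0.5, AGE_MEAN, AGE_SD) \
            - stats.norm.cdf(age_lo - 0.5, AGE_MEAN, AGE_SD)
        w.append(max(mass, 0.0))
    w = np.asarray(w)
    if w.sum() <= 0:
        raise ValueError(f"no admissible cohort group in wave {wave}")
    return w / w.sum()


def _admissible_years(config: GeneratorConfig, wave: int,
                      group_idx: int) -> tuple[int, int]:
    lo_r, hi_r = config.birth_year_range
    label, start, end = config.cohort_scheme.intervals[group_idx]
    lo = max(start if start is not None else lo_r, lo_r)
    hi = min(end, hi_r, wave - config.min_age)
    return lo, hi


def generate_survey(config: GeneratorConfig | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Generate one survey table under ``config`` (a pure function of it).

    Returns a DataFrame with columns srh, age, birth_year, wave, gender,
    hukou, party, marital, education, work.  ``seed`` overrides
    ``config.seed`` when given.
    """
    if config is None:
        config = GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    scheme = config.cohort_scheme

    frames = []
    for wave, size in zip(config.wave_years, config.wave_sizes):
        weights = _cohort_weights(config, wave)
        groups = rng.choice(len(scheme), size=size, p=weights)
        birth = np.empty(size, dtype=int)
        for g in np.unique(groups):
            lo, hi = _admissible_years(config, wave, g)
            sel = groups == g
            birth[sel] = rng.integers(lo, hi + 1, size=sel.sum())
        row = {
            "wave": np.full(size, wave, dtype=int),
            "birth_year": birth,
            "age": wave - birth,
        }
        for col, margins in config.covariate_margins.items():
            levels = list(CATEGORY_LEVELS[col])
            p = np.array([margins[lv] for lv in levels])
            row[col] = np.asarray(levels, dtype=object)[
                rng.choice(len(levels), size=size, p=p)]
        frames.append(pd.DataFrame(row))
    df = pd.concat(frames, ignore_index=True)

    # Latent outcome via the same design the fitting side builds.
    df["srh"] = 0.0   # placeholder so the design builder has an outcome
    df = assign_cohorts(df, scheme)
    spec = _generating_spec(config)
    design = build_design(df, spec, scheme)

    beta = np.zeros(len(design.column_names))
    unknown = set(config.fixed_effects) - set(design.column_names)
    if unknown:
        raise ValueError(f"fixed_effects refer to unknown design column(s): "
                         f"{sorted(unknown)}")
    for i, name in enumerate(design.column_names):
        beta[i] = config.fixed_effects.get(name, 0.0)

    y = design.X @ beta
    sds = np.sqrt([config.sigma2_period, config.sigma2_cohort,
                   config.sigma2_period_slope, config.sigma2_cohort_slope])
    y = y + design.Z_p @ rng.normal(0.0, sds[0], design.Z_p.shape[1])
    y = y + design.Z_c @ rng.normal(0.0, sds[1], design.Z_c.shape[1])
    if design.Z_ps is not None:
        y = y + design.Z_ps @ rng.normal(0.0, sds[2], design.Z_ps.shape[1])
    if design.Z_cs is not None:
        y = y + design.Z_cs @ rng.normal(0.0, sds[3], design.Z_cs.shape[1])
    y = y + rng.normal(0.0, np.sqrt(config.sigma2_resid), len(df))

    empty = [lab for lab in scheme.labels if lab not in set(df["cohort"])]
    if empty:
        logger.warning("cohort group(s) with no respondents: %s", empty)

    if config.discretize:
        df["srh"] = 1 + np.searchsorted(SRH_CUT_POINTS, y).astype(int)
    else:
        df["srh"] = y
    return df.drop(columns=["cohort"])[SURVEY_COLUMNS]


def _generating_spec(config: GeneratorConfig) -> ModelSpec:
    """Model specification implied by the configured coefficients."""
    keys = set(config.fixed_effects)
    fixed = []
    for term in ("age", "age2", "gender", "hukou", "party", "marital", "work"):
        if term in keys:
            fixed.append(term)
    if keys & {"edu_primary", "edu_junior", "edu_senior", "edu_college"}:
        fixed.append("education")
    interactions = [k.removeprefix("age_x_") for k in keys
                    if k.startswith("age_x_")]
    order = ["gender", "hukou", "party", "marital", "work"]
    interactions = [t for t in order if t in interactions]
    # keep canonical fixed-term ordering
    canon = ["age", "age2", "gender", "hukou", "party", "marital",
             "education", "work"]
    fixed = [t for t in canon if t in fixed]
    need_slopes = "hukou" in fixed
    return ModelSpec(
        fixed=fixed or ["age"],
        interactions=interactions,
        period_intercept=True,
        cohort_intercept=True,
        period_hukou_slope=need_slopes and config.sigma2_period_slope >= 0,
        cohort_hukou_slope=need_slopes and config.sigma2_cohort_slope >= 0,
    )
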