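"""Derived age / period / cohort effect and disparity curves.

Converts a fitted cross-classified mixed model into conditional predicted
self-rated-health trajectories: the quadratic age profile, period and
cohort curves built from the shrinkage (BLUP) estimates, urban-minus-rural
disparity curves on each axis, quadratic turning points, group-gap
crossing ages, and the cumulative-advantage versus age-as-leveler
classification of how a group gap moves with age.

The "conditional predicted value" convention puts every centered
covariate at its grand mean (centered value 0) unless a profile overrides
it with a raw value on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ccrem import FittedCcrem, significance_codes

__all__ = [
    "EffectCurve",
    "DisparityCurve",
    "AgePattern",
    "predict_srh",
    "age_curve",
    "period_curve",
    "cohort_curve",
    "disparity_curve",
    "turning_point",
    "crossing_age",
    "classify_age_pattern",
]


@dataclass
class EffectCurve:
    """Conditional predicted SRH over a grid on one temporal axis."""

    axis: str                       # "age" | "period" | "cohort"
    grid: list
    values: np.ndarray
    sig_codes: list[str] | None = None
    profile: dict | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")


@dataclass
class DisparityCurve:
    """Urban-minus-rural predicted SRH difference over a grid.

    Positive values mean an urban health advantage.
    """

    axis: str
    grid: list
    difference: np.ndarray
    classification: str | None = None
    crossing_age: float | None = None


def _profile_value(fit: FittedCcrem, col: str, profile: dict) -> float:
    """Centered value of a covariate column under a raw-scale profile."""
    offset = fit.centering_offsets.get(col, 0.0)
    if profile and col in profile:
        return float(profile[col]) - offset
    return 0.0


def predict_srh(fit: FittedCcrem, age: float | None = None,
                profile: dict | None = None,
                period: int | None = None,
                cohort: str | None = None) -> float:
    """Conditional predicted SRH for one covariate/temporal configuration.

    ``profile`` maps dummy column names (e.g. ``hukou``, ``marital``,
    ``edu_college``) to raw 0/1 values; unspecified covariates sit at
    their grand means.  ``age`` defaults to the sample mean age.  Period
    and cohort add the corresponding BLUPs (intercept, and hukou slope
    weighted by the profile's rural value) when given; otherwise the
    random effects are at their zero means.
    """
    profile = profile or {}
    unknown = set(profile) - set(fit.column_names) - {"age"}
    if unknown:
        raise ValueError(f"profile refers to unknown column(s): "
                         f"{sorted(unknown)}")
    mean_age = fit.centering_offsets.get("age", 0.0)
    a = (float(age) - mean_age) if age is not None else 0.0

    val = 0.0
    for col, b in fit.beta.items():
        if col == "intercept":
            x = 1.0
        elif col == "age":
            x = a
        elif col == "age2":
            x = a * a
        elif col.startswith("age_x_"):
            x = a * _profile_value(fit, col.removeprefix("age_x_"), profile)
        else:
            x = _profile_value(fit, col, profile)
        val += float(b) * x

    # raw rural indicator for the random hukou-slope contribution
    rural = float(profile.get("hukou", fit.centering_offsets.get("hukou", 0.0)))
    if period is not None:
        if "period" not in fit.blups:
            raise ValueError("fit has no period BLUPs")
        val += float(fit.blups["period"][period])
        if "period_slope" in fit.blups:
            val += rural * float(fit.blups["period_slope"][period])
    if cohort is not None:
        if "cohort" not in fit.blups:
            raise ValueError("fit has no cohort BLUPs")
        val += float(fit.blups["cohort"][cohort])
        if "cohort_slope" in fit.blups:
            val += rural * float(fit.blups["cohort_slope"][cohort])
    return val


def age_curve(fit: FittedCcrem, ages=None,
              profile: dict | None = None) -> EffectCurve:
    """Net age effect: predicted SRH over an age grid, random effects at 0."""
    if ages is None:
        lo, hi = fit.age_range
        ages = np.arange(np.floor(lo), np.ceil(hi) + 1)
    ages = np.asarray(ages, dtype=float)
    if ages.ndim != 1 or len(ages) == 0 or np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be a non-empty strictly increasing grid")
    vals = np.array([predict_srh(fit, age=a, profile=profile) for a in ages])
    return EffectCurve(axis="age", grid=list(ages), values=vals,
                       profile=profile)


def _blup_curve(fit: FittedCcrem, axis: str,
                profile: dict | None) -> EffectCurve:
    key = "period" if axis == "period" else "cohort"
    if key not in fit.blups:
        raise ValueError(f"fit has no {key} BLUPs")
    labels = list(fit.blups[key].index)
    vals = np.array([
        predict_srh(fit, profile=profile,
                    **({"period": lab} if axis == "period" else {"cohort": lab}))
        for lab in labels
    ])
    se = fit.blup_se[key].to_numpy()
    blup = fit.blups[key].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, blup / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    codes = [significance_codes(pi) if np.isfinite(pi) else "" for pi in p]
    return EffectCurve(axis=axis, grid=labels, values=vals, sig_codes=codes,
                       profile=profile)


def period_curve(fit: FittedCcrem, profile: dict | None = None) -> EffectCurve:
    """Net period effect: intercept plus each wave's BLUP, with star codes."""
    return _blup_curve(fit, "period", profile)


def cohort_curve(fit: FittedCcrem, profile: dict | None = None) -> EffectCurve:
    """Net cohort effect: intercept plus each cohort's BLUP, with star codes."""
    return _blup_curve(fit, "cohort", profile)


def disparity_curve(fit: FittedCcrem, axis: str, ages=None,
                    profile: dict | None = None) -> DisparityCurve:
    """Urban-minus-rural predicted SRH gap along one temporal axis.

    Constructed as the pointwise difference of two full prediction calls
    (urban profile minus rural profile).  The period/cohort axes require
    random hukou slopes on that classification.
    """
    profile = dict(profile or {})
    urban = {**profile, "hukou": 0.0}
    rural = {**profile, "hukou": 1.0}

    if axis == "age":
        if ages is None:
            lo, hi = fit.age_range
            ages = np.arange(np.floor(lo), np.ceil(hi) + 1)
        grid = list(np.asarray(ages, dtype=float))
        diff = np.array([
            predict_srh(fit, age=a, profile=urban)
            - predict_srh(fit, age=a, profile=rural)
            for a in grid
        ])
        label, cross = None, None
        if "hukou" in fit.beta.index:
            main = -float(fit.beta["hukou"])
            inter = -float(fit.beta.get("age_x_hukou", 0.0))
            pat = classify_age_pattern(main, inter,
                                       fit.centering_offsets.get("age", 0.0),
                                       (grid[0], grid[-1]))
            label, cross = pat.label, pat.crossing_age
        return DisparityCurve(axis="age", grid=grid, difference=diff,
                              classification=label, crossing_age=cross)

    if axis not in ("period", "cohort"):
        raise ValueError("axis must be 'age', 'period' or 'cohort'")
    key = f"{axis}_slope"
    if key not in fit.blups:
        raise ValueError(
            f"fit has no random hukou slope on the {axis} classification; "
            "fit a model with random hukou slopes (Model 4 or 5)"
        )
    labels = list(fit.blups[key].index)
    kw = "period" if axis == "period" else "cohort"
    diff = np.array([
        predict_srh(fit, profile=urban, **{kw: lab})
        - predict_srh(fit, profile=rural, **{kw: lab})
        for lab in labels
    ])
    return DisparityCurve(axis=axis, grid=labels, difference=diff)


def turning_point(beta1: float, beta2: float,
                  mean_age: float) -> float | None:
    """Age minimizing the quadratic profile b1*(a-abar) + b2*(a-abar)^2.

    Returns ``mean_age - beta1 / (2 beta2)`` when the curve is convex
    (beta2 > 0), else None (no interior minimum).
    """
    if beta2 <= 0:
        return None
    return float(mean_age - beta1 / (2.0 * beta2))


def crossing_age(main_effect: float, interaction: float,
                 mean_age: float) -> float | None:
    """Age at which a group gap main + interaction*(a - abar) changes sign."""
    if interaction == 0:
        return None
    return float(mean_age + main_effect / (-interaction))


@dataclass
class AgePattern:
    """How a group health gap evolves with age."""

    label: str                      # cumulative | leveler |
                                    # leveler-with-reversal | constant
    crossing_age: float | None = None


def classify_age_pattern(main_effect: float, interaction: float,
                         mean_age: float,
                         age_range: tuple[float, float]) -> AgePattern:
    """Classify a linear-in-age group gap against the two ageing theories.

    The gap is main + interaction * (age - mean_age).  "cumulative"
    (cumulative advantage/disadvantage): |gap| grows over the age range;
    "leveler": |gap| shrinks; "leveler-with-reversal": the gap crosses
    zero inside the range (it shrinks, vanishes, then reopens with the
    opposite sign); "constant": no interaction.
    """
    lo, hi = age_range
    if lo >= hi:
        raise ValueError("age_range must be an increasing interval")
    if interaction == 0:
        return AgePattern("constant")
    cross = crossing_age(main_effect, interaction, mean_age)
    gap_lo = main_effect + interaction * (lo - mean_age)
    gap_hi = main_effect + interaction * (hi - mean_age)
    if cross is not None and lo < cross < hi:
        return AgePattern("leveler-with-reversal", round(cross, 1))
    if abs(gap_hi) > abs(gap_lo):
        return AgePattern("cumulative")
    return AgePattern("leveler")
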