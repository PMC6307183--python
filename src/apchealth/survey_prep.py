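"""Survey-table preparation: cohort assignment, encoding, centering, design.

Turns a person-level repeated cross-sectional survey table (self-rated
health plus demographics over several survey waves) into the numeric
design matrices a cross-classified mixed model needs: grand-mean-centered
fixed-effect columns, age interactions, and period/cohort indicator
blocks for the random part.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortScheme",
    "ModelSpec",
    "DesignMatrices",
    "default_cohort_scheme",
    "assign_cohort",
    "assign_cohorts",
    "read_survey",
    "write_survey",
    "validate_table",
    "center_fixed_effects",
    "build_design",
]

# Canonical column layout of a survey table (CSV header order).
SURVEY_COLUMNS = [
    "srh", "age", "birth_year", "wave",
    "gender", "hukou", "party", "marital", "education", "work",
]

# Category levels; the first level of each is the reference category of the
# corresponding dummy (male, urban, non-member, unmarried, illiterate,
# not working).
CATEGORY_LEVELS = {
    "gender": ("male", "female"),
    "hukou": ("urban", "rural"),
    "party": ("nonmember", "member"),
    "marital": ("single", "married"),
    "education": ("illiteracy", "primary", "junior", "senior", "college"),
    "work": ("unemployed", "employed"),
}

# Dummy column names produced by the encoder, keyed by source column.
DUMMY_COLUMNS = {
    "gender": ["gender"],
    "hukou": ["hukou"],
    "party": ["party"],
    "marital": ["marital"],
    "education": ["edu_primary", "edu_junior", "edu_senior", "edu_college"],
    "work": ["work"],
}


# ---------------------------------------------------------------------------
# Cohort scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortScheme:
    """Ordered, contiguous, unequal-width birth-year intervals.

    ``intervals`` is a tuple of ``(label, start, end)`` with inclusive
    bounds; the first interval is open on the left (``start`` is None).
    """

    intervals: tuple[tuple[str, int | None, int], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("cohort scheme must contain at least one interval")
        prev_end = None
        for label, start, end in self.intervals:
            if start is not None and start > end:
                raise ValueError(f"interval {label!r} has start > end")
            if prev_end is not None:
                if start is None or start != prev_end + 1:
                    raise ValueError(
                        f"intervals must be contiguous; {label!r} starts at "
                        f"{start} after an interval ending {prev_end}"
                    )
            prev_end = end

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _, _ in self.intervals]

    @property
    def max_year(self) -> int:
        return self.intervals[-1][2]

    def __len__(self) -> int:
        return len(self.intervals)


#: The 15 historically defined Chinese birth-cohort groups, from the
#: pre-1925 warlord era through the 1990-1996 "further reform" years.
_DEFAULT_INTERVALS = (
    ("warlord dogfight", None, 1924),
    ("early country struggle", 1925, 1929),
    ("later country struggle", 1930, 1934),
    ("early anti-Japanese war", 1935, 1939),
    ("later anti-Japanese war", 1940, 1944),
    ("liberation war", 1945, 1949),
    ("economic recovery", 1950, 1955),
    ("great leap", 1956, 1958),
    ("famine", 1959, 1961),
    ("baby boomer", 1962, 1965),
    ("early cultural revolution", 1966, 1970),
    ("later cultural revolution", 1971, 1976),
    ("early reform", 1977, 1984),
    ("city reform", 1985, 1989),
    ("further reform", 1990, 1996),
)


def default_cohort_scheme() -> CohortScheme:
    """The 15-group historical cohort scheme used throughout the pipeline."""
    return CohortScheme(_DEFAULT_INTERVALS)


def assign_cohort(birth_year: int, scheme: CohortScheme | None = None) -> str:
    """Map a single birth year to its cohort label.

    Years at or below the first named bound fall in the open first group;
    years beyond the scheme's last year are rejected.
    """
    if scheme is None:
        scheme = default_cohort_scheme()
    if not float(birth_year).is_integer():
        raise ValueError(f"birth_year must be an integer, got {birth_year!r}")
    by = int(birth_year)
    if by > scheme.max_year:
        raise ValueError(
            f"birth year {by} is beyond the cohort scheme's last interval "
            f"(ends {scheme.max_year})"
        )
    for label, start, end in scheme.intervals:
        if (start is None or by >= start) and by <= end:
            return label
    # unreachable for contiguous schemes
    raise ValueError(f"birth year {by} not covered by the cohort scheme")


def assign_cohorts(table: pd.DataFrame,
                   scheme: CohortScheme | None = None) -> pd.DataFrame:
    """Return a copy of ``table`` with a ``cohort`` label column added."""
    if scheme is None:
        scheme = default_cohort_scheme()
    by = table["birth_year"].to_numpy()
    if not np.all(np.equal(np.mod(by, 1), 0)):
        raise ValueError("birth_year column must be integer-valued")
    by = by.astype(int)
    if by.max() > scheme.max_year:
        bad = by[by > scheme.max_year][0]
        raise ValueError(
            f"birth year {bad} is beyond the cohort scheme's last interval "
            f"(ends {scheme.max_year})"
        )
    edges = [iv[2] for iv in scheme.intervals]  # inclusive right edges
    idx = np.searchsorted(edges, by, side="left")
    labels = np.asarray(scheme.labels, dtype=object)
    out = table.copy()
    out["cohort"] = labels[idx]
    return out


# ---------------------------------------------------------------------------
# I/O and validation
# ---------------------------------------------------------------------------

def read_survey(path) -> pd.DataFrame:
    """Read a survey CSV with the canonical header."""
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey file is missing columns: {missing}")
    return df


def write_survey(table: pd.DataFrame, path) -> None:
    """Write a survey table as CSV with the canonical column order."""
    cols = [c for c in SURVEY_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def validate_table(table: pd.DataFrame,
                   wave_years: Sequence[int] | None = None,
                   drop_incomplete: bool = False) -> pd.DataFrame:
    """Check the structural invariants of a survey table.

    age must equal wave - birth_year exactly and (optionally) waves must
    belong to a declared set.  An ordinal (integer-valued) outcome must
    lie on the 1-5 scale; a latent continuous outcome is unbounded and is
    only required to be finite.  Incomplete rows are either dropped
    (list-wise deletion) or rejected.
    """
    df = table.copy()
    if drop_incomplete:
        df = df.dropna(subset=[c for c in SURVEY_COLUMNS if c in df.columns])
    elif df[[c for c in SURVEY_COLUMNS if c in df.columns]].isna().any().any():
        raise ValueError(
            "table contains missing values; pass drop_incomplete=True for "
            "list-wise deletion"
        )
    mismatch = df["age"].to_numpy() != (df["wave"] - df["birth_year"]).to_numpy()
    if mismatch.any():
        i = int(np.flatnonzero(mismatch)[0])
        raise ValueError(
            f"age != wave - birth_year at row {df.index[i]} "
            f"(age={df['age'].iloc[i]}, wave={df['wave'].iloc[i]}, "
            f"birth_year={df['birth_year'].iloc[i]})"
        )
    srh = df["srh"].to_numpy(dtype=float)
    if not np.all(np.isfinite(srh)):
        raise ValueError("srh values must be finite")
    if np.all(srh == np.round(srh)) and ((srh < 1).any() or (srh > 5).any()):
        raise ValueError("ordinal srh values must lie in [1, 5]")
    if wave_years is not None:
        bad = set(df["wave"].unique()) - set(wave_years)
        if bad:
            raise ValueError(f"unexpected wave years: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# Encoding and centering
# ---------------------------------------------------------------------------

def _encode_dummies(table: pd.DataFrame) -> pd.DataFrame:
    """Raw 0/1 dummy frame (reference categories per CATEGORY_LEVELS)."""
    out = pd.DataFrame(index=table.index)
    out["age"] = table["age"].astype(float)
    for col, levels in CATEGORY_LEVELS.items():
        if col not in table.columns:
            continue
        vals = table[col].astype(str)
        unseen = set(vals.unique()) - set(levels)
        if unseen:
            raise ValueError(
                f"column {col!r} contains unseen category level(s): "
                f"{sorted(unseen)}; expected one of {list(levels)}"
            )
        if col == "education":
            for level, name in zip(levels[1:], DUMMY_COLUMNS[col]):
                out[name] = (vals == level).astype(float)
        else:
            out[DUMMY_COLUMNS[col][0]] = (vals == levels[1]).astype(float)
    return out


def center_fixed_effects(columns: pd.DataFrame,
                         terms: Sequence[str] | None = None
                         ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Grand-mean center the requested numeric columns.

    Returns the centered columns and the offset (mean) subtracted from
    each, so predictions can be mapped back to the original scale.  A
    constant column cannot be centered (it would vanish) and is rejected.
    """
    if terms is None:
        terms = list(columns.columns)
    missing = [t for t in terms if t not in columns.columns]
    if missing:
        raise ValueError(f"unknown term(s): {missing}")
    centered = pd.DataFrame(index=columns.index)
    offsets: dict[str, float] = {}
    for t in terms:
        x = columns[t].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(
                f"column {t!r} is constant and cannot be centered "
                "(confounded with the intercept)"
            )
        m = float(x.mean())
        centered[t] = x - m
        offsets[t] = m
    return centered, offsets


# ---------------------------------------------------------------------------
# Model specification and design construction
# ---------------------------------------------------------------------------

#: Canonical ordering of fixed-effect terms (before interactions).
FIXED_TERM_ORDER = [
    "age", "age2", "gender", "hukou", "party", "marital", "education", "work",
]


@dataclass
class ModelSpec:
    """Which fixed terms, age interactions and random terms a model has.

    ``fixed`` uses term names ("education" expands to its four dummies);
    ``interactions`` lists covariates whose centered dummy is multiplied by
    centered age.  Random *hukou* slopes require hukou among the fixed terms.
    """

    fixed: list[str] = field(default_factory=lambda: ["age", "age2"])
    interactions: list[str] = field(default_factory=list)
    period_intercept: bool = True
    cohort_intercept: bool = True
    period_hukou_slope: bool = False
    cohort_hukou_slope: bool = False
    method: str = "reml"

    def __post_init__(self) -> None:
        unknown = [t for t in self.fixed if t not in FIXED_TERM_ORDER]
        if unknown:
            raise ValueError(f"unknown fixed term(s): {unknown}")
        bad = [t for t in self.interactions
               if t not in ("gender", "hukou", "party", "marital", "work",
                            "education")]
        if bad:
            raise ValueError(f"cannot interact age with: {bad}")
        if (self.period_hukou_slope or self.cohort_hukou_slope) \
                and "hukou" not in self.fixed:
            raise ValueError("random hukou slopes require 'hukou' among the "
                             "fixed terms")
        if self.method not in ("ml", "reml"):
            raise ValueError("method must be 'ml' or 'reml'")

    # JSON form used by the CLI: {"fixed": [...], "interactions": [...],
    # "random": {...}, "method": ...}
    def to_dict(self) -> dict:
        return {
            "fixed": list(self.fixed),
            "interactions": list(self.interactions),
            "random": {
                "period_intercept": self.period_intercept,
                "cohort_intercept": self.cohort_intercept,
                "period_hukou_slope": self.period_hukou_slope,
                "cohort_hukou_slope": self.cohort_hukou_slope,
            },
            "method": self.method,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        rnd = d.get("random", {})
        return cls(
            fixed=list(d.get("fixed", ["age", "age2"])),
            interactions=list(d.get("interactions", [])),
            period_intercept=bool(rnd.get("period_intercept", True)),
            cohort_intercept=bool(rnd.get("cohort_intercept", True)),
            period_hukou_slope=bool(rnd.get("period_hukou_slope", False)),
            cohort_hukou_slope=bool(rnd.get("cohort_hukou_slope", False)),
            method=d.get("method", "reml"),
        )


@dataclass
class DesignMatrices:
    """Numeric design for the cross-classified mixed model.

    X holds the intercept plus grand-mean-centered fixed-effect columns
    (age-squared and interactions are built from the centered inputs);
    Z_p / Z_c are one-hot period / cohort indicators, and Z_ps / Z_cs are
    those indicators multiplied by the raw rural (0/1) dummy when random
    hukou slopes are requested.
    """

    y: np.ndarray
    X: np.ndarray
    column_names: list[str]
    Z_p: np.ndarray | None
    Z_c: np.ndarray | None
    Z_ps: np.ndarray | None
    Z_cs: np.ndarray | None
    period_labels: list[int]
    cohort_labels: list[str]
    centering_offsets: dict[str, float]
    age_range: tuple[float, float]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(table: pd.DataFrame, spec: ModelSpec,
                 scheme: CohortScheme | None = None) -> DesignMatrices:
    """Build y, X and the random-effect indicator blocks for ``spec``.

    The table must already carry a ``cohort`` label column (see
    :func:`assign_cohorts`).  Fixed columns appear in the canonical order;
    each dummy and age is centered at its grand mean, age-squared is the
    square of centered age, and interaction columns are products of
    centered age with the centered dummy.
    """
    if "cohort" not in table.columns:
        raise ValueError("table has no 'cohort' column; run assign_cohorts first")
    if scheme is None:
        scheme = default_cohort_scheme()

    raw = _encode_dummies(table)

    # Expand term list in canonical order.
    fixed = [t for t in FIXED_TERM_ORDER if t in spec.fixed]
    base_cols: list[str] = []
    for t in fixed:
        if t == "age2":
            continue
        base_cols.extend(DUMMY_COLUMNS.get(t, [t]))
    centered, offsets = center_fixed_effects(raw, base_cols)

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(table))}
    for t in fixed:
        if t == "age2":
            if "age" not in fixed:
                raise ValueError("age2 requires age among the fixed terms")
            cols["age2"] = centered["age"].to_numpy() ** 2
        else:
            for c in DUMMY_COLUMNS.get(t, [t]):
                cols[c] = centered[c].to_numpy()
    for t in spec.interactions:
        for c in DUMMY_COLUMNS.get(t, [t]):
            if c not in centered.columns:
                raise ValueError(
                    f"interaction term {t!r} requires {c!r} among the fixed terms"
                )
            cols[f"age_x_{c}" if t == "education" else f"age_x_{t}"] = \
                centered["age"].to_numpy() * centered[c].to_numpy()

    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    y = table["srh"].to_numpy(dtype=float)

    # Random-effect indicator blocks.
    waves = sorted(int(w) for w in pd.unique(table["wave"]))
    wave_idx = pd.Categorical(table["wave"], categories=waves).codes
    Z_p = np.zeros((len(table), len(waves)))
    Z_p[np.arange(len(table)), wave_idx] = 1.0

    present = set(table["cohort"].unique())
    cohort_labels = [lab for lab in scheme.labels if lab in present]
    stray = present - set(scheme.labels)
    if stray:
        raise ValueError(f"cohort labels not in scheme: {sorted(stray)}")
    coh_idx = pd.Categorical(table["cohort"], categories=cohort_labels).codes
    Z_c = np.zeros((len(table), len(cohort_labels)))
    Z_c[np.arange(len(table)), coh_idx] = 1.0

    Z_ps = Z_cs = None
    if spec.period_hukou_slope or spec.cohort_hukou_slope:
        rural = raw["hukou"].to_numpy()[:, None]
        if spec.period_hukou_slope:
            Z_ps = Z_p * rural
        if spec.cohort_hukou_slope:
            Z_cs = Z_c * rural

    age = table["age"].to_numpy(dtype=float)
    return DesignMatrices(
        y=y, X=X, column_names=names,
        Z_p=Z_p if spec.period_intercept else None,
        Z_c=Z_c if spec.cohort_intercept else None,
        Z_ps=Z_ps, Z_cs=Z_cs,
        period_labels=waves, cohort_labels=cohort_labels,
        centering_offsets=offsets,
        age_range=(float(age.min()), float(age.max())),
    )
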