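"""Stepwise model ladder, summary tables and printed-table checks.

Runs the five-model stepwise sequence (base quadratic-age model with
crossed random intercepts, plus covariates, plus age interactions, plus
random *hukou* slopes), renders a combined coefficient table in the style
of a published regression table (estimate + star codes, variance
components, ICC, BIC), and recomputes the arithmetic of the published
descriptive tables (category counts, percentages, per-wave totals) as
consistency checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import pandas as pd

from .apc_effects import age_curve, cohort_curve, disparity_curve, period_curve
from .ccrem import FittedCcrem, fit_ccrem, significance_codes
from .survey_prep import (
    CohortScheme,
    ModelSpec,
    assign_cohorts,
    build_design,
    default_cohort_scheme,
)

__all__ = [
    "model_ladder",
    "run_ladder",
    "LadderReport",
    "consistency_checks",
    "TABLE1_COUNTS",
    "TABLE2_PERIOD_TOTALS",
    "VALID_SAMPLE_SIZE",
]

logger = logging.getLogger("apchealth.report")

# ---------------------------------------------------------------------------
# Printed descriptive-table fixtures (category counts of the pooled
# seven-wave sample and per-wave totals), used by consistency_checks.
# ---------------------------------------------------------------------------

VALID_SAMPLE_SIZE = 62_755

TABLE1_COUNTS = {
    "srh": {"very poor": 2332, "poor": 10484, "fair": 11883,
            "good": 22470, "very good": 15586},
    "gender": {"male": 30330, "female": 32425},
    "hukou": {"urban": 29401, "rural": 33354},
    "party": {"member": 6608, "nonmember": 56147},
    "marital": {"married": 50703, "single": 12052},
    "education": {"illiteracy": 8029, "primary": 14680, "junior": 18919,
                  "senior": 12675, "college": 8452},
    "work": {"employed": 41154, "unemployed": 21601},
}

TABLE1_PERCENTAGES = {
    "srh": {"very poor": 3.7, "poor": 16.7, "fair": 18.9,
            "good": 35.8, "very good": 24.8},
    "gender": {"male": 48.3, "female": 51.7},
    "hukou": {"urban": 46.9, "rural": 53.1},
    "party": {"member": 10.5, "nonmember": 89.5},
    "marital": {"married": 80.8, "single": 19.2},
    "education": {"illiteracy": 12.8, "primary": 23.4, "junior": 30.1,
                  "senior": 20.2, "college": 13.5},
    "work": {"employed": 65.6, "unemployed": 34.4},
}

TABLE2_PERIOD_TOTALS = {2005: 10332, 2006: 10139, 2008: 5628, 2010: 11145,
                        2011: 5218, 2012: 10555, 2013: 9738}


# ---------------------------------------------------------------------------
# Model ladder
# ---------------------------------------------------------------------------

_COVARIATES = ["gender", "hukou", "party", "marital", "education", "work"]
_INTERACTIONS = ["gender", "hukou", "marital", "work"]


def model_ladder(method: str = "ml") -> list[ModelSpec]:
    """The stepwise five-model sequence M1..M5.

    M1: age + age^2 with crossed random period/cohort intercepts;
    M2: M1 + all covariates; M3: M2 + age interactions (education and
    party excluded by default); M4: M2 + random hukou slopes;
    M5: M3 + random hukou slopes.  The default estimation method is ML so
    that the BIC ladder compares models with different fixed effects.
    """
    base = ["age", "age2"]
    m1 = ModelSpec(fixed=list(base), method=method)
    m2 = ModelSpec(fixed=base + _COVARIATES, method=method)
    m3 = ModelSpec(fixed=base + _COVARIATES,
                   interactions=list(_INTERACTIONS), method=method)
    m4 = ModelSpec(fixed=base + _COVARIATES,
                   period_hukou_slope=True, cohort_hukou_slope=True,
                   method=method)
    m5 = ModelSpec(fixed=base + _COVARIATES,
                   interactions=list(_INTERACTIONS),
                   period_hukou_slope=True, cohort_hukou_slope=True,
                   method=method)
    return [m1, m2, m3, m4, m5]


@dataclass
class LadderReport:
    """Fits and the combined summary table for a model ladder."""

    fits: list[FittedCcrem]
    table: pd.DataFrame          # formatted estimate+stars strings

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


_VC_LABELS = {
    "sigma2_period": "period intercept",
    "sigma2_cohort": "cohort intercept",
    "sigma2_period_slope": "period hukou slope",
    "sigma2_cohort_slope": "cohort hukou slope",
    "sigma2_resid": "residual",
}


def _fmt(est: float, p: float) -> str:
    return f"{est:.4f}{significance_codes(p)}"


def summary_table(fits: list[FittedCcrem],
                  names: list[str] | None = None) -> pd.DataFrame:
    """Combined coefficient / variance-component / fit-index table.

    One column per model; coefficient cells show the estimate to four
    decimals with star codes, matching the layout of a published stepwise
    regression table.
    """
    if names is None:
        names = [f"Model {i + 1}" for i in range(len(fits))]
    row_order: list[str] = []
    for fit in fits:
        for c in fit.column_names:
            if c not in row_order:
                row_order.append(c)
    vc_rows = [k for k in _VC_LABELS
               if any(k in f.varcomps.index for f in fits)]
    index = row_order + [f"vc:{k}" for k in vc_rows] + ["ICC", "BIC", "n"]
    out = pd.DataFrame(index=index, columns=names, dtype=object)
    for name, fit in zip(names, fits):
        for c in fit.column_names:
            out.loc[c, name] = _fmt(fit.beta[c], fit.pvalues[c])
        for k in vc_rows:
            if k in fit.varcomps.index:
                row = fit.varcomps.loc[k]
                out.loc[f"vc:{k}", name] = _fmt(row["estimate"], row["pvalue"])
        out.loc["ICC", name] = f"{fit.icc:.4f}"
        out.loc["BIC", name] = f"{fit.bic:.1f}"
        out.loc["n", name] = str(fit.n)
    out.index = [
        _VC_LABELS[i[3:]] if isinstance(i, str) and i.startswith("vc:") else i
        for i in out.index
    ]
    return out.fillna("")


def run_ladder(table: pd.DataFrame,
               ladder: list[ModelSpec] | None = None,
               scheme: CohortScheme | None = None) -> LadderReport:
    """Fit every model of the ladder on a prepared survey table.

    The table must carry the survey columns; cohort labels are assigned
    here if absent.  Any individual fit failure aborts with the failing
    model named.
    """
    if ladder is None:
        ladder = model_ladder()
    if scheme is None:
        scheme = default_cohort_scheme()
    if "cohort" not in table.columns:
        table = assign_cohorts(table, scheme)
    fits = []
    for i, spec in enumerate(ladder, start=1):
        logger.info("fitting model %d/%d (%s)", i, len(ladder), spec.method)
        try:
            design = build_design(table, spec, scheme)
            fit = fit_ccrem(design, spec)
        except Exception as exc:
            raise RuntimeError(f"model {i} of the ladder failed: {exc}") from exc
        logger.info("model %d: loglik=%.2f bic=%.1f icc=%.4f converged=%s",
                    i, fit.loglik, fit.bic, fit.icc, fit.converged)
        fits.append(fit)
    return LadderReport(fits=fits, table=summary_table(fits))


# ---------------------------------------------------------------------------
# Printed-table consistency checks
# ---------------------------------------------------------------------------

def consistency_checks(table1_counts: dict | None = None,
                       table2_totals: dict | None = None,
                       total: int = VALID_SAMPLE_SIZE) -> pd.DataFrame:
    """Recompute the printed descriptive-table arithmetic.

    Verifies that every category breakdown and the per-wave totals sum to
    the valid sample size and that percentages recompute to one decimal.
    Returns a frame of (check, expected, actual, passed); failures are
    reported, not raised.
    """
    t1 = table1_counts if table1_counts is not None else TABLE1_COUNTS
    t2 = table2_totals if table2_totals is not None else TABLE2_PERIOD_TOTALS
    rows = []
    for var, counts in t1.items():
        s = sum(counts.values())
        rows.append({"check": f"{var} counts sum", "expected": total,
                     "actual": s, "passed": s == total})
        pcts = TABLE1_PERCENTAGES.get(var, {})
        for level, count in counts.items():
            if level not in pcts:
                continue
            pct = round(100.0 * count / total, 1)
            rows.append({
                "check": f"{var}:{level} percentage",
                "expected": pcts[level], "actual": pct,
                "passed": abs(pct - pcts[level]) < 0.05 + 1e-12,
            })
    s2 = sum(t2.values())
    rows.append({"check": "period totals sum", "expected": total,
                 "actual": s2, "passed": s2 == total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-pipeline report directory (used by the CLI `run` command)
# ---------------------------------------------------------------------------

def write_report(outdir, report: LadderReport) -> None:
    """Write table, per-model fit JSONs, curve TSVs and checks to a directory."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_tsv(out / "table3.tsv")
    for i, fit in enumerate(report.fits, start=1):
        (out / f"fit_m{i}.json").write_text(
            json.dumps(fit.to_dict(), sort_keys=True, indent=1) + "\n")
    curves = out / "curves"
    curves.mkdir(exist_ok=True)
    full = report.fits[-1]
    _write_curve(curves / "age.tsv", age_curve(full))
    _write_curve(curves / "period.tsv", period_curve(full))
    _write_curve(curves / "cohort.tsv", cohort_curve(full))
    for axis in ("age", "period", "cohort"):
        try:
            disp = disparity_curve(full, axis)
        except ValueError:
            continue
        df = pd.DataFrame({"axis": axis, "point": disp.grid,
                           "value": disp.difference, "sig_code": ""})
        df.to_csv(curves / f"disparity_{axis}.tsv", sep="\t", index=False)
    consistency_checks().to_csv(out / "checks.tsv", sep="\t", index=False)


def _write_curve(path, curve) -> None:
    df = pd.DataFrame({
        "axis": curve.axis,
        "point": curve.grid,
        "value": curve.values,
        "sig_code": curve.sig_codes if curve.sig_codes is not None else "",
    })
    df.to_csv(path, sep="\t", index=False)
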