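import numpy as np
import pytest

import apchealth as ap


@pytest.fixture(scope="session")
def small_table():
    """~1,200 respondents over the seven waves, latent outcome."""
    cfg = ap.GeneratorConfig(wave_sizes=ap.scale_wave_sizes(1200), seed=42)
    return ap.assign_cohorts(ap.generate_survey(cfg))


@pytest.fixture(scope="session")
def m5_spec():
    return ap.model_ladder(method="reml")[-1]


@pytest.fixture(scope="session")
def m5_design(small_table, m5_spec):
    return ap.build_design(small_table, m5_spec)


@pytest.fixture(scope="session")
def m5_fit(m5_design, m5_spec):
    return ap.fit_ccrem(m5_design, m5_spec)


# ---------------------------------------------------------------------------
# Dense-matrix likelihood / BLUP oracle: forms the full n x n marginal
# covariance explicitly.  Used only to cross-check the Woodbury-based
# implementation on small instances.
# ---------------------------------------------------------------------------

def dense_blocks(design):
    return [(name, Z) for name, Z in [
        ("sigma2_period", design.Z_p),
        ("sigma2_cohort", design.Z_c),
        ("sigma2_period_slope", design.Z_ps),
        ("sigma2_cohort_slope", design.Z_cs),
    ] if Z is not None]


def dense_V(design, varcomps):
    V = varcomps["sigma2_resid"] * np.eye(design.n)
    for name, Z in dense_blocks(design):
        V += varcomps[name] * (Z @ Z.T)
    return V


def dense_loglik(design, varcomps, method="reml"):
    X, y = design.X, design.y
    n, p = X.shape
    V = dense_V(design, varcomps)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, logdetV = np.linalg.slogdet(V)
    quad = r @ Vi @ r
    log2pi = np.log(2 * np.pi)
    if method == "ml":
        return -0.5 * (n * log2pi + logdetV + quad)
    _, logdetA = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - p) * log2pi + logdetV + logdetA + quad)


def dense_blups(design, varcomps):
    """Closed-form conditional means G Z' V^-1 (y - X beta_gls)."""
    X, y = design.X, design.y
    V = dense_V(design, varcomps)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    out = {}
    key = {"sigma2_period": "period", "sigma2_cohort": "cohort",
           "sigma2_period_slope": "period_slope",
           "sigma2_cohort_slope": "cohort_slope"}
    for name, Z in dense_blocks(design):
        out[key[name]] = varcomps[name] * (Z.T @ (Vi @ r))
    return out
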