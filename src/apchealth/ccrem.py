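"""Cross-classified linear mixed model (HAPC-CCREM) estimation.

Individuals (level 1) are cross-classified by survey period and birth
cohort (level 2).  The outcome is modelled as

    y = X beta + Z_p u_p + Z_c u_c + Z_ps u_ps + Z_cs u_cs + e,

with independent normal random intercepts for period and cohort, optional
independent random *hukou* (urban/rural) slopes in each classification,
and i.i.d. residuals.  Estimation maximizes the marginal (restricted)
likelihood over variance components; the fixed effects are profiled out by
generalized least squares.

The implementation never forms the n-by-n marginal covariance: writing
V = sigma2_e * (I + Z D Z'), all likelihood quantities reduce via the
Woodbury identity to cross-products X'X, Z'Z, Z'X, ... computed once, so
each likelihood evaluation costs O(q^3) in the (small) number of random
effect levels q.  The residual variance is profiled analytically and the
optimizer works on the log variance ratios log(sigma2_b / sigma2_e).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .survey_prep import DesignMatrices, ModelSpec

__all__ = [
    "VARIANCE_COMPONENTS",
    "FittedCcrem",
    "marginal_loglik",
    "predict_blups",
    "fit_ccrem",
    "compute_icc",
    "compute_bic",
    "significance_codes",
]

logger = logging.getLogger("apchealth.ccrem")

#: Names of the variance components, in reporting order.
VARIANCE_COMPONENTS = [
    "sigma2_period", "sigma2_cohort",
    "sigma2_period_slope", "sigma2_cohort_slope",
    "sigma2_resid",
]

# Log variance ratios below this are treated as the zero boundary.
_LOG_RATIO_FLOOR = -30.0
_BOUNDARY_LOG_RATIO = -15.0


def _blocks(design: DesignMatrices) -> list[tuple[str, np.ndarray]]:
    """Active random-effect blocks (name, indicator matrix), fixed order."""
    out = []
    for name, Z in [
        ("sigma2_period", design.Z_p),
        ("sigma2_cohort", design.Z_c),
        ("sigma2_period_slope", design.Z_ps),
        ("sigma2_cohort_slope", design.Z_cs),
    ]:
        if Z is not None:
            out.append((name, Z))
    return out


class _CrossProducts:
    """Sufficient statistics for all likelihood evaluations."""

    def __init__(self, design: DesignMatrices):
        X, y = design.X, design.y
        Xy = np.column_stack([X, y])
        self.C = Xy.T @ Xy
        blocks = _blocks(design)
        self.block_names = [b[0] for b in blocks]
        self.block_sizes = [b[1].shape[1] for b in blocks]
        if blocks:
            Z = np.hstack([b[1] for b in blocks])
        else:
            Z = np.zeros((X.shape[0], 0))
        self.ZtZ = Z.T @ Z
        self.ZtXy = Z.T @ Xy
        self.n = X.shape[0]
        self.p = X.shape[1]
        self.q = Z.shape[1]

    def expand(self, per_block: np.ndarray) -> np.ndarray:
        """Repeat one value per block across that block's columns."""
        return np.repeat(per_block, self.block_sizes)


def _whitened(cp: _CrossProducts, gamma: np.ndarray):
    """Core Woodbury reduction at variance ratios ``gamma`` (per block).

    Returns (G, logdetW, M_cho, s) where G = [X y]' W^-1 [X y] for
    W = I + Z diag(d) Z', logdetW = log|W|, and M_cho is the Cholesky
    factorization of M = I + D^1/2 Z'Z D^1/2 (s = sqrt of expanded d).
    """
    d = cp.expand(gamma)
    s = np.sqrt(d)
    M = np.eye(cp.q) + (s[:, None] * cp.ZtZ) * s[None, :]
    L = cho_factor(M, lower=True)
    logdetW = 2.0 * np.log(np.diag(L[0])).sum()
    B = s[:, None] * cp.ZtXy            # D^1/2 Z' [X y]
    G = cp.C - B.T @ cho_solve(L, B)
    return G, logdetW, L, s


def _gls(G: np.ndarray, p: int):
    """GLS beta, whitened RSS and X'W^-1X from the reduced cross-product."""
    A = G[:p, :p]
    b = G[:p, p]
    yy = G[p, p]
    cA = cho_factor(A, lower=True)
    beta = cho_solve(cA, b)
    rss = float(yy - b @ beta)
    logdetA = 2.0 * np.log(np.diag(cA[0])).sum()
    return beta, max(rss, 1e-300), A, cA, logdetA


def _profiled_loglik(cp: _CrossProducts, log_gamma: np.ndarray, method: str):
    """(RE)ML log-likelihood with beta and sigma2_e profiled out."""
    gamma = np.exp(np.clip(log_gamma, _LOG_RATIO_FLOOR, 30.0))
    if cp.q:
        G, logdetW, _, _ = _whitened(cp, gamma)
    else:
        G, logdetW = cp.C, 0.0
    beta, rss, _, _, logdetA = _gls(G, cp.p)
    n, p = cp.n, cp.p
    log2pi = np.log(2.0 * np.pi)
    if method == "ml":
        s2 = rss / n
        ll = -0.5 * (n * log2pi + n * np.log(s2) + logdetW + n)
    else:
        s2 = rss / (n - p)
        ll = -0.5 * ((n - p) * log2pi + (n - p) * np.log(s2)
                     + logdetW + logdetA + (n - p))
    return float(ll), float(s2), beta


def marginal_loglik(design: DesignMatrices, varcomps: dict[str, float],
                    method: str = "reml") -> float:
    """Marginal Gaussian (restricted) log-likelihood at fixed variances.

    ``varcomps`` maps component names (see :data:`VARIANCE_COMPONENTS`) to
    variances; it must cover ``sigma2_resid`` (> 0) and every random block
    present in the design.  beta is profiled out by GLS; REML adds the
    fixed-effect determinant correction.
    """
    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")
    s2e = float(varcomps.get("sigma2_resid", 0.0))
    if s2e <= 0.0:
        raise ValueError("sigma2_resid must be strictly positive "
                         "(a zero-variance model is singular)")
    cp = _CrossProducts(design)
    gamma = np.empty(len(cp.block_names))
    for i, name in enumerate(cp.block_names):
        if name not in varcomps:
            raise ValueError(f"varcomps is missing {name!r}")
        v = float(varcomps[name])
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
        gamma[i] = v / s2e
    if cp.q:
        G, logdetW, _, _ = _whitened(cp, gamma)
    else:
        G, logdetW = cp.C, 0.0
    beta, rss, _, _, logdetA = _gls(G, cp.p)
    n, p = cp.n, cp.p
    log2pi = np.log(2.0 * np.pi)
    ll = -0.5 * (n * log2pi + n * np.log(s2e) + logdetW + rss / s2e)
    if method == "reml":
        ll += 0.5 * p * log2pi - 0.5 * (logdetA - p * np.log(s2e))
    return float(ll)


_BLOCK_KEYS = {"sigma2_period": "period", "sigma2_cohort": "cohort",
               "sigma2_period_slope": "period_slope",
               "sigma2_cohort_slope": "cohort_slope"}


def predict_blups(design: DesignMatrices, varcomps: dict[str, float],
                  ) -> dict[str, pd.Series]:
    """Conditional means (BLUPs) of the random effects at fixed variances.

    beta is set to its GLS value under the given variance components;
    the returned predictions shrink each group's residual mean toward 0
    by the usual ratio of between to total variance.
    """
    s2e = float(varcomps.get("sigma2_resid", 0.0))
    if s2e <= 0.0:
        raise ValueError("sigma2_resid must be strictly positive")
    cp = _CrossProducts(design)
    if not cp.q:
        return {}
    gamma = np.array([float(varcomps[name]) / s2e
                      for name in cp.block_names])
    if (gamma < 0).any():
        raise ValueError("variance components must be non-negative")
    G, _, L, s = _whitened(cp, gamma)
    beta, _, _, _, _ = _gls(G, cp.p)
    d = cp.expand(gamma)
    t = cp.ZtXy[:, cp.p] - cp.ZtXy[:, :cp.p] @ beta
    u = d * (t - cp.ZtZ @ (s * cho_solve(L, s * t)))
    out = {}
    offset = 0
    for name, size in zip(cp.block_names, cp.block_sizes):
        labels = design.period_labels if name.startswith("sigma2_period") \
            else design.cohort_labels
        out[_BLOCK_KEYS[name]] = pd.Series(u[offset:offset + size],
                                           index=labels)
        offset += size
    return out


# ---------------------------------------------------------------------------
# Fitted-model container
# ---------------------------------------------------------------------------

@dataclass
class FittedCcrem:
    """Estimates from a fitted cross-classified mixed model.

    ``varcomps`` has one row per component with columns estimate / se /
    pvalue / boundary; variance p-values are one-sided Wald z tests on the
    variance scale and are NaN at a boundary (zero-variance) estimate.
    ``blups`` maps "period" / "cohort" / "period_slope" / "cohort_slope"
    to shrinkage predictions keyed by wave year or cohort label.
    """

    beta: pd.Series
    se: pd.Series
    pvalues: pd.Series
    varcomps: pd.DataFrame
    blups: dict[str, pd.Series]
    blup_se: dict[str, pd.Series]
    loglik: float
    bic: float
    icc: float
    n: int
    n_params: int
    method: str
    converged: bool
    n_iter: int
    column_names: list[str] = field(default_factory=list)
    centering_offsets: dict[str, float] = field(default_factory=dict)
    period_labels: list[int] = field(default_factory=list)
    cohort_labels: list[str] = field(default_factory=list)
    age_range: tuple[float, float] = (0.0, 0.0)

    @property
    def varcomp_estimates(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.varcomps["estimate"].items()}

    # ---- JSON round trip (used by the CLI) -------------------------------
    def to_dict(self) -> dict:
        return {
            "beta": {k: float(v) for k, v in self.beta.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "varcomps": {
                name: {
                    "estimate": float(row["estimate"]),
                    "se": float(row["se"]),
                    "pvalue": float(row["pvalue"]),
                    "boundary": bool(row["boundary"]),
                }
                for name, row in self.varcomps.iterrows()
            },
            "blups": {k: {str(i): float(v) for i, v in s.items()}
                      for k, s in self.blups.items()},
            "blup_se": {k: {str(i): float(v) for i, v in s.items()}
                        for k, s in self.blup_se.items()},
            "loglik": self.loglik, "bic": self.bic, "icc": self.icc,
            "n": self.n, "n_params": self.n_params, "method": self.method,
            "converged": self.converged, "n_iter": self.n_iter,
            "column_names": self.column_names,
            "centering_offsets": self.centering_offsets,
            "period_labels": self.period_labels,
            "cohort_labels": self.cohort_labels,
            "age_range": list(self.age_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedCcrem":
        vc = pd.DataFrame.from_dict(d["varcomps"], orient="index")
        blups = {}
        blup_se = {}
        for k, s in d["blups"].items():
            keys = list(s)
            if k.startswith("period"):
                idx = [int(i) for i in keys]
            else:
                idx = keys
            blups[k] = pd.Series([s[i] for i in keys], index=idx, dtype=float)
            se_map = d["blup_se"][k]
            blup_se[k] = pd.Series([se_map[i] for i in keys], index=idx,
                                   dtype=float)
        return cls(
            beta=pd.Series(d["beta"], dtype=float),
            se=pd.Series(d["se"], dtype=float),
            pvalues=pd.Series(d["pvalues"], dtype=float),
            varcomps=vc, blups=blups, blup_se=blup_se,
            loglik=d["loglik"], bic=d["bic"], icc=d["icc"],
            n=d["n"], n_params=d["n_params"], method=d["method"],
            converged=d["converged"], n_iter=d["n_iter"],
            column_names=list(d["column_names"]),
            centering_offsets=dict(d["centering_offsets"]),
            period_labels=[int(x) for x in d["period_labels"]],
            cohort_labels=list(d["cohort_labels"]),
            age_range=tuple(d["age_range"]),
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_ccrem(design: DesignMatrices, spec: ModelSpec | None = None,
              method: str | None = None) -> FittedCcrem:
    """Fit the cross-classified mixed model by (RE)ML.

    Variance components maximize the profiled (restricted) likelihood
    under non-negativity (log-ratio parameterization with a floor), beta
    is the GLS estimate at the optimum, and BLUPs are the conditional
    means of the random effects.  A variance estimate at the zero
    boundary is reported with a flag, not an error.
    """
    if method is None:
        method = spec.method if spec is not None else "reml"
    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")
    if spec is not None:
        wanted = {
            "sigma2_period": spec.period_intercept,
            "sigma2_cohort": spec.cohort_intercept,
            "sigma2_period_slope": spec.period_hukou_slope,
            "sigma2_cohort_slope": spec.cohort_hukou_slope,
        }
        have = {name for name, _ in _blocks(design)}
        for name, on in wanted.items():
            if on and name not in have:
                raise ValueError(
                    f"spec requests {name} but the design has no such block; "
                    "rebuild the design with matching random flags"
                )

    cp = _CrossProducts(design)
    k = len(cp.block_names)
    n_iter = 0
    converged = True
    if k:
        def objective(x):
            return -_profiled_loglik(cp, x, method)[0]

        best = None
        for start in (np.full(k, np.log(0.05)), np.full(k, np.log(0.5))):
            res = optimize.minimize(
                objective, start, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9,
                         "maxiter": 4000, "maxfev": 4000},
            )
            n_iter += res.nit
            if best is None or res.fun < best.fun:
                best = res
        if not best.success:
            logger.warning("variance-component optimizer did not report "
                           "convergence: %s", best.message)
            converged = False
        log_gamma = np.clip(best.x, _LOG_RATIO_FLOOR, 30.0)
    else:
        log_gamma = np.zeros(0)

    ll, s2e, _ = _profiled_loglik(cp, log_gamma, method)
    gamma = np.exp(log_gamma)
    boundary = log_gamma <= _BOUNDARY_LOG_RATIO
    gamma = np.where(boundary, 0.0, gamma)

    # Final quantities at the optimum.
    if cp.q:
        G, logdetW, L, s = _whitened(cp, gamma)
    else:
        G, logdetW, L, s = cp.C, 0.0, None, None
    beta, rss, A, cA, _ = _gls(G, cp.p)

    se_beta = np.sqrt(s2e * np.diag(cho_solve(cA, np.eye(cp.p))))
    z = beta / se_beta
    p_beta = 2.0 * stats.norm.sf(np.abs(z))

    # BLUPs and their prediction standard errors.
    blups: dict[str, pd.Series] = {}
    blup_se: dict[str, pd.Series] = {}
    if cp.q:
        d = cp.expand(gamma)
        t = cp.ZtXy[:, cp.p] - cp.ZtXy[:, :cp.p] @ beta      # Z' r
        ZtWinv_r = t - cp.ZtZ @ (s * cho_solve(L, s * t))
        u = d * ZtWinv_r
        # var(u_hat - u) = s2e * [D - D (Z'W^-1 Z) D + D Z'W^-1X A^-1 X'W^-1Z D]
        ZtWinvZ = cp.ZtZ - cp.ZtZ @ (s[:, None] * cho_solve(L, s[:, None] * cp.ZtZ))
        ZtWinvX = cp.ZtXy[:, :cp.p] - cp.ZtZ @ (s[:, None] * cho_solve(L, s[:, None] * cp.ZtXy[:, :cp.p]))
        mid = ZtWinvX @ cho_solve(cA, ZtWinvX.T)
        pred_var = s2e * (d - np.einsum("i,ij,j->i", d, ZtWinvZ, d)
                          + np.einsum("i,ij,j->i", d, mid, d))
        pred_se = np.sqrt(np.maximum(pred_var, 0.0))
        offset = 0
        for name, size in zip(cp.block_names, cp.block_sizes):
            labels = design.period_labels if name.startswith("sigma2_period") \
                else design.cohort_labels
            key = _BLOCK_KEYS[name]
            blups[key] = pd.Series(u[offset:offset + size], index=labels)
            blup_se[key] = pd.Series(pred_se[offset:offset + size],
                                     index=labels)
            offset += size

    # Variance-component table with Wald z tests on the variance scale.
    est = {name: float(g * s2e) for name, g in zip(cp.block_names, gamma)}
    est["sigma2_resid"] = float(s2e)
    names = [n_ for n_ in VARIANCE_COMPONENTS if n_ in est]
    vse, vp = _varcomp_wald(design, est, names, method,
                            dict(zip(cp.block_names, boundary)))
    vc = pd.DataFrame({
        "estimate": [est[n_] for n_ in names],
        "se": [vse[n_] for n_ in names],
        "pvalue": [vp[n_] for n_ in names],
        "boundary": [bool(dict(zip(cp.block_names, boundary)).get(n_, False))
                     for n_ in names],
    }, index=names)

    n_params = cp.p + len(names)
    bic = compute_bic(ll, cp.n, n_params)
    icc = compute_icc(est) if ("sigma2_period" in est or
                               "sigma2_cohort" in est) else 0.0

    return FittedCcrem(
        beta=pd.Series(beta, index=design.column_names),
        se=pd.Series(se_beta, index=design.column_names),
        pvalues=pd.Series(p_beta, index=design.column_names),
        varcomps=vc, blups=blups, blup_se=blup_se,
        loglik=float(ll), bic=float(bic), icc=float(icc),
        n=cp.n, n_params=n_params, method=method,
        converged=converged, n_iter=int(n_iter),
        column_names=list(design.column_names),
        centering_offsets=dict(design.centering_offsets),
        period_labels=list(design.period_labels),
        cohort_labels=list(design.cohort_labels),
        age_range=design.age_range,
    )


def _varcomp_wald(design, est, names, method, boundary_map):
    """One-sided Wald z tests from a finite-difference observed information.

    The Hessian of the (RE)ML log-likelihood is taken with respect to the
    variance components on the variance scale; components at the zero
    boundary get NaN standard errors and p-values.
    """
    free = [n_ for n_ in names if not boundary_map.get(n_, False)]
    se = {n_: float("nan") for n_ in names}
    pv = {n_: float("nan") for n_ in names}
    if not free:
        return se, pv
    x0 = np.array([est[n_] for n_ in free])

    def f(x):
        vc = dict(est)
        vc.update({n_: max(xi, 1e-12) for n_, xi in zip(free, x)})
        return marginal_loglik(design, vc, method)

    m = len(free)
    h = np.maximum(1e-5, 1e-3 * np.abs(x0))
    H = np.empty((m, m))
    f0 = f(x0)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-H)
        dvar = np.diag(cov)
        for n_, v in zip(free, dvar):
            if v > 0:
                se[n_] = float(np.sqrt(v))
                pv[n_] = float(stats.norm.sf(est[n_] / se[n_]))
    except np.linalg.LinAlgError:   # pragma: no cover - pathological designs
        pass
    return se, pv


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def compute_icc(varcomps: dict[str, float],
                include_slopes: bool = False) -> float:
    """Intra-class correlation: share of variance from period + cohort.

    By default only the random intercept variances enter the numerator;
    ``include_slopes=True`` also counts the random hukou-slope variances.
    """
    s2e = float(varcomps.get("sigma2_resid", 0.0))
    if s2e <= 0:
        raise ValueError("sigma2_resid must be strictly positive")
    num = float(varcomps.get("sigma2_period", 0.0)) \
        + float(varcomps.get("sigma2_cohort", 0.0))
    if include_slopes:
        num += float(varcomps.get("sigma2_period_slope", 0.0)) \
            + float(varcomps.get("sigma2_cohort_slope", 0.0))
    return num / (num + s2e)


def compute_bic(loglik: float, n: int, n_params: int) -> float:
    """Bayesian information criterion, -2 loglik + k ln(n).

    ``n_params`` counts fixed effects plus estimated variance components;
    ``n`` is the number of individuals.
    """
    if n_params < 1 or n <= n_params:
        raise ValueError("require n > n_params >= 1")
    return -2.0 * float(loglik) + n_params * float(np.log(n))


def significance_codes(p: float) -> str:
    """Conventional star codes: *** <.001, ** <.01, * <.05, + <= .1."""
    if np.isnan(p):
        return ""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p <= 0.1:
        return "+"
    return ""
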