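import numpy as np
import pandas as pd
import pytest

import apchealth as ap
from apchealth.ccrem import marginal_loglik, predict_blups
from conftest import dense_loglik

VC_FULL = {"sigma2_period": 0.08, "sigma2_cohort": 0.02,
           "sigma2_period_slope": 0.005, "sigma2_cohort_slope": 0.003,
           "sigma2_resid": 1.1}


@pytest.fixture(scope="module")
def tiny_design(small_table, m5_spec):
    sub = small_table.sample(n=220, random_state=0).reset_index(drop=True)
    return ap.build_design(sub, m5_spec)


class TestMarginalLoglik:
    @pytest.mark.parametrize("method", ["ml", "reml"])
    @pytest.mark.parametrize("vc", [
        VC_FULL,
        {"sigma2_period": 0.3, "sigma2_cohort": 1e-4,
         "sigma2_period_slope": 0.0, "sigma2_cohort_slope": 0.2,
         "sigma2_resid": 0.7},
    ])
    def test_matches_dense_oracle(self, tiny_design, method, vc):
        ours = marginal_loglik(tiny_design, vc, method)
        oracle = dense_loglik(tiny_design, vc, method)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_reduces_to_ols_loglik_without_random_effects(self, tiny_design):
        """All random variances zero: the marginal likelihood is the
        ordinary least squares Gaussian likelihood."""
        s2 = 0.9
        vc = {k: 0.0 for k in VC_FULL}
        vc["sigma2_resid"] = s2
        X, y = tiny_design.X, tiny_design.y
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(np.sum((y - X @ beta) ** 2))
        n = len(y)
        ols = -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + rss / s2)
        assert marginal_loglik(tiny_design, vc, "ml") == pytest.approx(
            ols, abs=1e-8)

    def test_zero_residual_variance_rejected(self, tiny_design):
        vc = {k: 0.0 for k in VC_FULL}
        with pytest.raises(ValueError, match="sigma2_resid"):
            marginal_loglik(tiny_design, vc, "ml")

    def test_variance_ratio_profile_invariant_to_scale(self, small_table):
        """On pure-noise data, doubling sigma2_e with matched outcome
        scaling leaves the ML profile over the variance ratio unchanged."""
        rng = np.random.default_rng(3)
        sub = small_table.sample(n=300, random_state=1).reset_index(drop=True)
        sub["srh"] = rng.normal(3.5, 1.0, len(sub)).clip(1, 5)
        spec = ap.ModelSpec(fixed=["age", "age2"], cohort_intercept=False)
        d1 = ap.build_design(sub, spec)
        sub2 = sub.copy()
        sub2["srh"] = np.sqrt(2) * sub["srh"]
        d2 = ap.build_design(sub2, spec)
        ratios = np.linspace(0.001, 0.5, 60)

        def profile(design, s2e):
            return [marginal_loglik(
                design, {"sigma2_period": g * s2e, "sigma2_resid": s2e},
                "ml") for g in ratios]

        p1 = profile(d1, 1.0)
        p2 = profile(d2, 2.0)
        assert np.argmax(p1) == np.argmax(p2)


class TestFit:
    def test_optimum_beats_dense_grid_search(self, small_table):
        """Brute-force grid over variance ratios with the dense-covariance
        oracle never finds a better (restricted) likelihood."""
        sub = small_table.sample(n=250, random_state=2).reset_index(drop=True)
        spec = ap.ModelSpec(fixed=["age", "age2", "gender", "hukou"])
        design = ap.build_design(sub, spec)
        fit = ap.fit_ccrem(design, spec)
        s2_grid = np.array([0.7, 0.9, 1.0, 1.1, 1.3]) \
            * fit.varcomp_estimates["sigma2_resid"]
        ratio_grid = [0.0, 0.001, 0.005, 0.02, 0.05, 0.1, 0.2, 0.5]
        best = -np.inf
        for s2 in s2_grid:
            for gp in ratio_grid:
                for gc in ratio_grid:
                    vc = {"sigma2_period": gp * s2, "sigma2_cohort": gc * s2,
                          "sigma2_resid": s2}
                    best = max(best, dense_loglik(design, vc, "reml"))
        assert fit.loglik >= best - 1e-4

    def test_degenerate_single_period_single_cohort(self):
        """One period and one cohort: both variances hit the zero boundary
        and the fixed effects equal ordinary least squares."""
        cfg = ap.GeneratorConfig(
            wave_years=(2010,), wave_sizes=(400,),
            birth_year_range=(1966, 1970), seed=29,
        )
        df = ap.assign_cohorts(ap.generate_survey(cfg))
        # ML: under REML the one-group variance is absorbed exactly by the
        # intercept correction and the profile is flat rather than maximized
        # at zero.
        spec = ap.ModelSpec(fixed=["age", "age2"], method="ml")
        design = ap.build_design(df, spec)
        fit = ap.fit_ccrem(design, spec)
        assert fit.varcomps.loc["sigma2_period", "boundary"]
        assert fit.varcomps.loc["sigma2_cohort", "boundary"]
        ols = np.linalg.lstsq(design.X, design.y, rcond=None)[0]
        assert np.allclose(fit.beta.to_numpy(), ols, atol=1e-6)

    def test_row_permutation_invariance(self, small_table, m5_spec):
        sub = small_table.sample(n=600, random_state=3).reset_index(drop=True)
        perm = sub.sample(frac=1.0, random_state=4).reset_index(drop=True)
        f1 = ap.fit_ccrem(ap.build_design(sub, m5_spec), m5_spec)
        f2 = ap.fit_ccrem(ap.build_design(perm, m5_spec), m5_spec)
        assert np.allclose(f1.beta.to_numpy(), f2.beta.to_numpy(), atol=1e-8)
        assert np.allclose(f1.varcomps["estimate"].to_numpy(),
                           f2.varcomps["estimate"].to_numpy(), atol=1e-7)

    def test_reml_and_ml_converge_with_sample_size(self):
        """REML and ML variance components agree asymptotically: their gap
        at n = 20,000 is far below the gap at n = 500."""
        gaps = {}
        for n in (500, 20000):
            cfg = ap.GeneratorConfig(wave_sizes=ap.scale_wave_sizes(n),
                                     seed=31)
            df = ap.assign_cohorts(ap.generate_survey(cfg))
            spec = ap.model_ladder()[1]
            design = ap.build_design(df, spec)
            est = {}
            for method in ("reml", "ml"):
                est[method] = ap.fit_ccrem(design, method=method) \
                    .varcomp_estimates
            gaps[n] = sum(
                abs(est["reml"][k] - est["ml"][k])
                for k in ("sigma2_period", "sigma2_cohort", "sigma2_resid")
            )
        assert gaps[20000] < 0.5 * gaps[500]

    def test_mismatched_spec_and_design_rejected(self, small_table):
        spec_plain = ap.ModelSpec(fixed=["age", "age2", "hukou"])
        spec_slopes = ap.ModelSpec(fixed=["age", "age2", "hukou"],
                                   period_hukou_slope=True,
                                   cohort_hukou_slope=True)
        design = ap.build_design(small_table, spec_plain)
        with pytest.raises(ValueError, match="sigma2_period_slope"):
            ap.fit_ccrem(design, spec_slopes)


class TestBlups:
    def test_blups_shrink_to_zero_as_variance_vanishes(self, tiny_design):
        vc = dict(VC_FULL)
        vc["sigma2_period"] = 1e-10
        u = predict_blups(tiny_design, vc)["period"]
        assert np.abs(u.to_numpy()).max() < 1e-6

    def test_blups_approach_group_residual_means_for_huge_variance(self):
        """With one observation per period and a huge period variance the
        shrinkage disappears: BLUPs equal the raw period residuals."""
        cfg = ap.GeneratorConfig(
            wave_years=tuple(range(2000, 2012)), wave_sizes=(1,) * 12,
            birth_year_range=(1940, 1970), seed=37,
            fixed_effects={"intercept": 3.5, "age": -0.02},
        )
        df = ap.assign_cohorts(ap.generate_survey(cfg))
        spec = ap.ModelSpec(fixed=["age"], cohort_intercept=False)
        design = ap.build_design(df, spec)
        vc = {"sigma2_period": 1e6, "sigma2_resid": 1.0}
        u = predict_blups(design, vc)["period"]
        # GLS residuals per period at the same variances
        from conftest import dense_V
        V = dense_V(design, vc)
        Vi = np.linalg.inv(V)
        X, y = design.X, design.y
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        resid = y - X @ beta
        assert np.allclose(u.to_numpy(), design.Z_p.T @ resid, atol=1e-3)

    def test_blup_sums_near_zero(self, m5_fit):
        for key, u in m5_fit.blups.items():
            scale = max(np.abs(u.to_numpy()).max(), 1e-12)
            assert abs(u.sum()) / len(u) < 0.5 * scale


class TestSummaries:
    def test_icc_zero_and_derived_value(self):
        assert ap.compute_icc({"sigma2_period": 0, "sigma2_cohort": 0,
                               "sigma2_resid": 1.0}) == 0.0
        icc = ap.compute_icc({"sigma2_period": 0.1038,
                              "sigma2_cohort": 0.0150,
                              "sigma2_resid": 1.0645})
        assert round(icc, 4) == 0.1004

    def test_icc_monotone_decreasing_in_residual_variance(self):
        iccs = [ap.compute_icc({"sigma2_period": 0.1, "sigma2_cohort": 0.02,
                                "sigma2_resid": s}) for s in (0.5, 1.0, 2.0)]
        assert iccs[0] > iccs[1] > iccs[2]

    def test_icc_scale_invariant(self):
        vc = {"sigma2_period": 0.1, "sigma2_cohort": 0.02,
              "sigma2_resid": 1.3}
        scaled = {k: 7.5 * v for k, v in vc.items()}
        assert ap.compute_icc(vc) == pytest.approx(ap.compute_icc(scaled))

    def test_icc_with_slopes_option(self):
        vc = {"sigma2_period": 0.1, "sigma2_cohort": 0.02,
              "sigma2_period_slope": 0.01, "sigma2_cohort_slope": 0.01,
              "sigma2_resid": 1.0}
        assert ap.compute_icc(vc, include_slopes=True) > ap.compute_icc(vc)

    def test_bic_closed_form_and_difference_identity(self):
        assert ap.compute_bic(0.0, np.e, 1) == pytest.approx(1.0)
        assert ap.compute_bic(0.0, 100, 1) == pytest.approx(np.log(100))
        d = ap.compute_bic(-50.0, 1000, 5) - ap.compute_bic(-40.0, 1000, 3)
        assert d == pytest.approx(-2 * (-10.0) + 2 * np.log(1000))

    @pytest.mark.parametrize("p,code", [
        (0.0005, "***"), (0.001, "**"), (0.009, "**"), (0.01, "*"),
        (0.049, "*"), (0.05, "+"), (0.1, "+"), (0.10001, ""), (0.5, ""),
    ])
    def test_significance_codes(self, p, code):
        assert ap.significance_codes(p) == code

    def test_fit_json_round_trip(self, m5_fit):
        import json
        d = m5_fit.to_dict()
        again = ap.FittedCcrem.from_dict(d)
        assert json.dumps(again.to_dict(), sort_keys=True) == \
            json.dumps(d, sort_keys=True)
        assert np.allclose(again.beta.to_numpy(), m5_fit.beta.to_numpy())
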