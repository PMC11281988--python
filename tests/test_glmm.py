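import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lifespace import glmm
from lifespace.glmm import (
    build_day_design,
    center_grand_mean,
    coefficient_table,
    distribution_specific_variance,
    fit_poisson_glmm,
    format_report,
    icc,
    make_design,
    r2_nakagawa,
    wald_ci,
)


class TestCentering:
    def test_simple_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out, means = center_grand_mean(df)
        assert list(out["a"]) == [-1.0, 0.0, 1.0]
        assert means["a"] == 2.0

    def test_mean_zero_after_centering(self):
        rng = np.random.default_rng(31)
        df = pd.DataFrame({"a": rng.normal(37.0, 4.0, 500)})
        out, _ = center_grand_mean(df)
        assert abs(out["a"].mean()) < 1e-12

    def test_idempotent(self):
        df = pd.DataFrame({"a": [5.0, 7.0, 9.0]})
        once, _ = center_grand_mean(df)
        twice, _ = center_grand_mean(once)
        assert np.allclose(once["a"], twice["a"])

    def test_constant_column_warns(self):
        df = pd.DataFrame({"a": [3.0, 3.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            out, _ = center_grand_mean(df)
        assert (out["a"] == 0.0).all()


def _person_frame(pid: str, **overrides) -> dict:
    base = dict(
        person_id=pid,
        age=80.0,
        sex_female=1,
        cohabiting=1,
        education="high",
        ksk12=44.0,
        psk12=58.0,
        health_literacy=41.0,
        social_network_satisfaction=9.0,
        active_driving=1,
    )
    base.update(overrides)
    return base


def _env_frame(pid: str, **overrides) -> dict:
    base = dict(
        person_id=pid,
        intersection_density=90,
        green_share_pct=20.0,
        pt_reach_count=4,
        health_reach_count=2,
        sidewalk_quality=2.0,
        utilization_score=2.8,
        subjective_access=2.6,
    )
    base.update(overrides)
    return base


def _mobility_frame(pids, days=7, toh=319.4) -> pd.DataFrame:
    rows = []
    for pid in pids:
        for d in range(days):
            rows.append(
                dict(
                    person_id=pid,
                    mobility_date=f"2022-07-{d + 1:02d}",
                    toh_min=toh + d,
                    chull_km2=2.6,
                    valid=True,
                )
            )
    return pd.DataFrame(rows)


class TestBuildDayDesign:
    def test_two_persons_seven_days(self):
        persons = pd.DataFrame([_person_frame("a", age=78.0), _person_frame("b", age=85.0)])
        env = pd.DataFrame([_env_frame("a"), _env_frame("b", green_share_pct=30.0)])
        design = build_day_design(_mobility_frame(["a", "b"]), persons, env)
        assert design.n_obs == 14
        assert design.n_groups == 2
        assert design.terms[0] == "intercept"
        assert design.terms[-1] == "counter"

    def test_response_rounding(self):
        persons = pd.DataFrame([_person_frame("a", age=78.0), _person_frame("b", age=85.0)])
        env = pd.DataFrame([_env_frame("a"), _env_frame("b", green_share_pct=30.0)])
        design = build_day_design(
            _mobility_frame(["a", "b"], days=1, toh=319.4), persons, env
        )
        assert list(design.y) == [319, 319]

    def test_missing_covariate_drops_person(self):
        persons = pd.DataFrame(
            [
                _person_frame("a", age=78.0),
                _person_frame("b", age=85.0),
                _person_frame("c", age=82.0, health_literacy=np.nan),
            ]
        )
        env = pd.DataFrame(
            [_env_frame("a"), _env_frame("b", green_share_pct=30.0), _env_frame("c")]
        )
        design = build_day_design(_mobility_frame(["a", "b", "c"]), persons, env)
        assert design.n_obs == 14
        assert design.n_dropped_persons == 1
        assert "c" not in design.group_ids

    def test_invalid_days_excluded_and_counter_bounds(self):
        mob = _mobility_frame(["a", "b"])
        mob.loc[mob.index[:3], "valid"] = False
        persons = pd.DataFrame([_person_frame("a", age=78.0), _person_frame("b", age=85.0)])
        env = pd.DataFrame([_env_frame("a"), _env_frame("b", green_share_pct=30.0)])
        design = build_day_design(mob, persons, env)
        assert design.n_obs == 11
        ctr = design.X[:, design.terms.index("counter")] + design.centered_means["counter"]
        assert set(np.round(ctr).astype(int)) <= {1, 2, 3, 4, 5, 6, 7}

    def test_continuous_columns_centered(self):
        persons = pd.DataFrame([_person_frame("a", age=78.0), _person_frame("b", age=85.0)])
        env = pd.DataFrame([_env_frame("a"), _env_frame("b", green_share_pct=30.0)])
        design = build_day_design(_mobility_frame(["a", "b"]), persons, env)
        for term in ("age", "green_share_pct", "counter", "ksk12"):
            col = design.X[:, design.terms.index(term)]
            assert abs(col.mean()) < 1e-9
        # binaries left as 0/1
        sex = design.X[:, design.terms.index("sex_female")]
        assert set(sex) <= {0.0, 1.0}

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(32)
        df = pd.DataFrame(
            {
                "person_id": np.repeat(["a", "b", "c"], 5),
                "y": rng.poisson(10, 15),
                "x1": rng.normal(0, 1, 15),
            }
        )
        df["x2"] = 2.0 * df["x1"]
        design = make_design(df, "y", ["x1", "x2"])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_poisson_glmm(design)


def _sim_design(
    n_persons=100,
    days=7,
    beta=(2.0, 0.5),
    tau=0.5,
    seed=0,
    counter_beta=0.0,
):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n_persons)
    b = rng.normal(0, math.sqrt(tau), n_persons)
    rows = []
    for i in range(n_persons):
        for d in range(1, days + 1):
            eta = beta[0] + beta[1] * x[i] + counter_beta * d + b[i]
            rows.append(
                dict(person_id=f"g{i:03d}", y=rng.poisson(math.exp(eta)), x1=x[i], counter=d)
            )
    df = pd.DataFrame(rows)
    cols = ["x1", "counter"] if counter_beta or days > 1 else ["x1"]
    return make_design(df, "y", cols)


class TestFitPoissonGlmm:
    def test_intercept_only_matches_log_mean(self):
        rng = np.random.default_rng(33)
        y = rng.poisson(10.0, 2000)
        df = pd.DataFrame({"person_id": [f"g{i}" for i in range(len(y))], "y": y})
        design = make_design(df, "y", [])
        fit = fit_poisson_glmm(design, tau00_fixed=0.0)
        # closed-form MLE: beta0 = ln(mean)
        assert fit.beta[0] == pytest.approx(math.log(y.mean()), abs=1e-8)
        assert abs(fit.beta[0] - math.log(10.0)) < 3 * fit.se[0]

    def test_matches_ordinary_poisson_glm(self):
        # one observation per person, tau fixed at 0: must equal plain GLM
        rng = np.random.default_rng(34)
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n), rng.normal(0, 1, n)])
        y = rng.poisson(np.exp(X @ np.array([1.5, 0.4, -0.2])))
        df = pd.DataFrame(
            {"person_id": [f"g{i}" for i in range(n)], "y": y, "x1": X[:, 1], "x2": X[:, 2]}
        )
        design = make_design(df, "y", ["x1", "x2"])
        fit = fit_poisson_glmm(design, tau00_fixed=0.0)
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.allclose(fit.beta, glm.params, atol=1e-6)
        assert np.allclose(fit.se, glm.bse, atol=1e-6)

    def test_zero_tau_data_recovers_boundary(self):
        design = _sim_design(n_persons=150, tau=0.0, seed=35)
        fit = fit_poisson_glmm(design)
        assert fit.tau00 < 0.02

    def test_recovers_moderate_tau(self):
        design = _sim_design(n_persons=300, tau=0.8, seed=36)
        fit = fit_poisson_glmm(design)
        assert fit.converged
        assert 0.5 < fit.tau00 < 1.2
        assert abs(fit.beta[design.terms.index("x1")] - 0.5) < 3 * fit.se[1]

    def test_loglik_at_optimum_beats_truth(self):
        design = _sim_design(n_persons=80, tau=0.5, seed=37)
        fit = fit_poisson_glmm(design)
        beta_true = np.zeros(len(design.terms))
        beta_true[design.terms.index("intercept")] = 2.0
        beta_true[design.terms.index("x1")] = 0.5
        ll_true, _ = glmm.laplace_loglik(design, beta_true, 0.5)
        assert fit.loglik >= ll_true - 1e-6

    def test_invariant_to_row_order_and_relabeling(self):
        rng = np.random.default_rng(38)
        design = _sim_design(n_persons=60, tau=0.4, seed=38)
        fit1 = fit_poisson_glmm(design)

        df = pd.DataFrame(
            {
                "person_id": [design.group_ids[c] for c in design.group_codes],
                "y": design.y,
                "x1": design.X[:, 1],
                "counter": design.X[:, 2],
            }
        )
        perm = rng.permutation(len(df))
        df2 = df.iloc[perm].reset_index(drop=True)
        df2["person_id"] = "zz_" + df2["person_id"]
        fit2 = fit_poisson_glmm(make_design(df2, "y", ["x1", "counter"]))
        assert np.allclose(fit1.beta, fit2.beta, atol=1e-6)
        assert fit1.tau00 == pytest.approx(fit2.tau00, abs=1e-6)

    def test_single_group_rejected(self):
        df = pd.DataFrame({"person_id": ["a"] * 10, "y": np.arange(10)})
        with pytest.raises(ValueError, match=">= 2 persons"):
            fit_poisson_glmm(make_design(df, "y", []))


class TestVarianceDecomposition:
    def test_sigma2d_closed_form_at_lambda_one(self):
        design = _sim_design(n_persons=50, seed=39)
        fit = fit_poisson_glmm(design)
        fit.beta[0] = 0.0  # lambda_bar = exp(0 + tau/2)
        fit.tau00 = 0.0
        assert distribution_specific_variance(fit, design) == pytest.approx(math.log(2.0))

    def test_sigma2d_vanishes_for_large_lambda(self):
        design = _sim_design(n_persons=50, seed=40)
        fit = fit_poisson_glmm(design)
        fit.tau00 = 0.0
        fit.beta[0] = 20.0
        assert distribution_specific_variance(fit, design) < 1e-8

    def test_sigma2d_strictly_decreasing_in_lambda(self):
        design = _sim_design(n_persons=50, seed=41)
        fit = fit_poisson_glmm(design)
        fit.tau00 = 0.0
        values = []
        for b0 in (0.0, 1.0, 2.0, 4.0):
            fit.beta[0] = b0
            values.append(distribution_specific_variance(fit, design))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_icc_published_arithmetic(self):
        assert round(icc(3.44, 0.13), 2) == 0.96

    def test_icc_edges(self):
        assert icc(0.0, 1.0) == 0.0
        assert icc(2.0, 2.0) == 0.5
        with pytest.raises(ValueError):
            icc(0.0, 0.0)
        with pytest.raises(ValueError):
            icc(-1.0, 1.0)

    def test_r2_marginal_zero_without_fixed_effects(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame(
            {"person_id": np.repeat([f"g{i}" for i in range(40)], 5),
             "y": rng.poisson(8.0, 200)}
        )
        fit = fit_poisson_glmm(make_design(df, "y", []))
        assert fit.r2_marginal == pytest.approx(0.0, abs=1e-12)

    def test_r2_conditional_at_least_marginal(self):
        design = _sim_design(n_persons=80, tau=0.6, seed=43)
        fit = fit_poisson_glmm(design)
        assert fit.r2_conditional >= fit.r2_marginal

    def test_large_tau_weak_fixed_effects(self):
        design = _sim_design(n_persons=120, beta=(2.0, 0.01), tau=2.0, seed=44)
        fit = fit_poisson_glmm(design)
        assert fit.r2_conditional > 0.9
        assert fit.r2_marginal < 0.1


class TestReporting:
    def test_z_identity_and_row_count(self):
        design = _sim_design(n_persons=60, tau=0.3, seed=45)
        fit = fit_poisson_glmm(design)
        table = coefficient_table(fit)
        assert len(table) == len(design.terms)
        np.testing.assert_allclose(fit.z, fit.beta / fit.se, rtol=1e-9)

    def test_wald_p_at_196(self):
        from scipy import stats

        assert 2 * stats.norm.sf(1.96) == pytest.approx(0.05, abs=1e-3)

    def test_report_text_contains_random_effects_block(self):
        design = _sim_design(n_persons=60, tau=0.3, seed=46)
        fit = fit_poisson_glmm(design)
        text = format_report(fit)
        for token in ("tau00", "ICC", "N persons", "Marginal R2"):
            assert token in text

    def test_wald_ci_brackets_estimate(self):
        design = _sim_design(n_persons=60, tau=0.3, seed=47)
        fit = fit_poisson_glmm(design)
        ci = wald_ci(fit)
        assert (ci["lower"] < ci["beta"]).all()
        assert (ci["upper"] > ci["beta"]).all()
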