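import numpy as np
import pandas as pd
import pytest

from exhazard import (
    ModelError,
    ModelSpec,
    NotEstimableError,
    RerEstimate,
    era_stratified_rer,
    fit_excess_model,
    lr_test,
    neg_log_likelihood,
    rer_contrast,
    make_toy_lifetable,
    simulate_cohort,
    expand_cohort,
    SimulationConfig,
)
from exhazard.excess_model import FittedModel
from tests.conftest import make_intervals

INTERCEPT_ONLY = ModelSpec(followup_bands=(0.0,), covariates=(), interactions=())
SEX_ONLY = ModelSpec(followup_bands=(0.0,), covariates=("sex",), interactions=())


class TestLikelihood:
    def test_single_censored_interval(self):
        df = make_intervals([1.0], [0], [0.1])
        nll = neg_log_likelihood([np.log(0.1)], df, INTERCEPT_ONLY)
        assert nll == pytest.approx(0.2, abs=1e-12)

    def test_single_death_interval(self):
        df = make_intervals([1.0], [1], [0.0])
        nll = neg_log_likelihood([0.0], df, INTERCEPT_ONLY)
        assert nll == pytest.approx(1.0, abs=1e-12)

    def test_gradient_and_hessian_match_finite_differences(self):
        rng = np.random.default_rng(3)
        df = make_intervals(
            rng.uniform(0.1, 2.0, 10),
            rng.integers(0, 2, 10),
            rng.uniform(0.0, 0.2, 10),
            sex=["female" if i % 2 else "male" for i in range(10)],
        )
        theta = np.array([-1.3, 0.4])
        nll, grad, hess = neg_log_likelihood(theta, df, SEX_ONLY, derivs=True)
        h = 1e-6
        for k in range(2):
            e = np.zeros(2)
            e[k] = h
            fd = (
                neg_log_likelihood(theta + e, df, SEX_ONLY)
                - neg_log_likelihood(theta - e, df, SEX_ONLY)
            ) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-5)
            for j in range(2):
                _, gp, _ = neg_log_likelihood(theta + e, df, SEX_ONLY, derivs=True)
                _, gm, _ = neg_log_likelihood(theta - e, df, SEX_ONLY, derivs=True)
                fd2 = (gp[j] - gm[j]) / (2 * h)
                assert hess[k, j] == pytest.approx(fd2, rel=1e-4, abs=1e-7)

    def test_wrong_parameter_count(self):
        df = make_intervals([1.0], [0], [0.1])
        with pytest.raises(ModelError, match="parameters"):
            neg_log_likelihood([0.0, 0.0], df, INTERCEPT_ONLY)


class TestClosedFormFits:
    def test_intercept_only_zero_expected(self):
        # D=5, PY=100, lambda*=0: alpha-hat = log(D/PY) exactly
        df = make_intervals([10.0] * 10, [1] * 5 + [0] * 5, [0.0] * 10)
        fit = fit_excess_model(df, INTERCEPT_ONLY)
        assert fit.converged
        assert fit.params.iloc[0] == pytest.approx(np.log(0.05), abs=1e-8)

    def test_intercept_only_constant_expected(self):
        # stationarity D/(lambda*+mu) = PY  =>  mu-hat = D/PY - lambda*
        df = make_intervals([10.0] * 10, [1] * 5 + [0] * 5, [0.01] * 10)
        fit = fit_excess_model(df, INTERCEPT_ONLY)
        assert np.exp(fit.params.iloc[0]) == pytest.approx(0.04, abs=1e-8)

    def test_saturated_poisson_reduction(self):
        # lambda* = 0 and a saturated sex model: rates are O/PY per cell
        df = make_intervals(
            [5.0, 5.0, 4.0, 4.0, 2.0],
            [1, 0, 1, 1, 0],
            [0.0] * 5,
            sex=["male", "male", "female", "female", "female"],
        )
        fit = fit_excess_model(df, SEX_ONLY)
        mu_male = np.exp(fit.params["base[0,inf)"])
        mu_female = np.exp(
            fit.params["base[0,inf)"] + fit.params["sex[female]"]
        )
        assert mu_male == pytest.approx(1 / 10.0, rel=1e-7)
        assert mu_female == pytest.approx(2 / 10.0, rel=1e-7)

    def test_poisson_glm_oracle(self):
        # with zero expected hazard the model is Poisson regression with a
        # log-exposure offset; statsmodels is the independent oracle
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n = 60
        sex = ["female" if u < 0.5 else "male" for u in rng.random(n)]
        df = make_intervals(
            rng.uniform(0.5, 3.0, n),
            rng.integers(0, 2, n),
            [0.0] * n,
            sex=sex,
        )
        fit = fit_excess_model(df, SEX_ONLY)
        X = np.column_stack(
            [np.ones(n), np.asarray(sex) == "female"]
        ).astype(float)
        glm = sm.GLM(
            df["death"].to_numpy(),
            X,
            family=sm.families.Poisson(),
            offset=np.log(df["duration"].to_numpy()),
        ).fit()
        assert fit.params["base[0,inf)"] == pytest.approx(glm.params[0], abs=1e-6)
        assert fit.params["sex[female]"] == pytest.approx(glm.params[1], abs=1e-6)
        se = np.sqrt(np.diag(fit.covariance.to_numpy()))
        assert se == pytest.approx(glm.bse, rel=1e-4)

    def test_requires_a_death(self):
        df = make_intervals([1.0] * 4, [0] * 4, [0.1] * 4)
        with pytest.raises(ModelError, match="death"):
            fit_excess_model(df, INTERCEPT_ONLY)


@pytest.fixture(scope="module")
def small_sim():
    table = make_toy_lifetable()
    cfg = SimulationConfig(
        n_candidates=4000,
        seed=42,
        true_rer={"0-12": 1.0, "13-24": 1.0, "25-44": 1.4, "45-59": 1.0,
                  ">=60": 1.0},
    )
    res = simulate_cohort(cfg, table)
    pt = expand_cohort(res.cohort, table)
    return pt


LEAN_SPEC = ModelSpec(covariates=("sex", "age_category"))


class TestContrasts:
    def test_zero_coefficients_give_unit_rer(self):
        names = ["base[0,inf)", "sex[female]", "sex[female]:age_category[45-59]"]
        fit = FittedModel(
            params=pd.Series(0.0, index=names),
            covariance=pd.DataFrame(0.0, index=names, columns=names),
            loglik=0.0, n_intervals=1, n_deaths=1, converged=True, n_iter=1,
            spec=LEAN_SPEC, n_base=1, aliased=[],
        )
        est = rer_contrast(fit, age_category="45-59")
        assert (est.rer, est.ci_lo, est.ci_hi) == (1.0, 1.0, 1.0)

    def test_sex_relabelling_inverts_rer(self, small_sim):
        fit = fit_excess_model(small_sim, LEAN_SPEC)
        est = rer_contrast(fit, age_category="45-59")

        # swapping the labels makes the "female" contrast compare the
        # original males with the original females: RER' = 1/RER with
        # swapped, inverted CI bounds
        swapped = small_sim.assign(
            sex=small_sim["sex"].map({"female": "male", "male": "female"})
        )
        fit_sw = fit_excess_model(swapped, LEAN_SPEC)
        est_sw = rer_contrast(fit_sw, age_category="45-59")
        assert est_sw.rer == pytest.approx(1.0 / est.rer, rel=1e-6)
        assert est_sw.ci_lo == pytest.approx(1.0 / est.ci_hi, rel=1e-6)
        assert est_sw.ci_hi == pytest.approx(1.0 / est.ci_lo, rel=1e-6)

    def test_unknown_age_category_rejected(self, small_sim):
        fit = fit_excess_model(small_sim, LEAN_SPEC)
        with pytest.raises(ModelError, match="age category"):
            rer_contrast(fit, age_category="90-120")

    def test_single_sex_not_estimable(self, small_sim):
        males = small_sim[small_sim["sex"] == "male"]
        fit = fit_excess_model(males, LEAN_SPEC)
        with pytest.raises(NotEstimableError):
            rer_contrast(fit, age_category="45-59")

    def test_rer_recovers_simulated_truth(self, small_sim):
        # loose 3-sigma recovery check at modest n; tight calibrated
        # recovery is exercised at larger n in the acceptance suite
        fit = fit_excess_model(small_sim, LEAN_SPEC)
        est = rer_contrast(fit, age_category="25-44")
        assert abs(np.log(est.rer) - np.log(1.4)) < 3 * est.se_log


class TestLrTest:
    def test_identical_specs_give_zero(self, small_sim):
        f1 = fit_excess_model(small_sim, LEAN_SPEC)
        f2 = fit_excess_model(small_sim, LEAN_SPEC)
        stat, df, p = lr_test(f1, f2)
        assert abs(stat) < 1e-6
        assert df == 0
        assert p == 1.0

    def test_statistic_is_twice_loglik_difference(self, small_sim):
        full = fit_excess_model(small_sim, ModelSpec(
            covariates=("sex", "age_category", "race")))
        red = fit_excess_model(small_sim, LEAN_SPEC)
        stat, df, p = lr_test(full, red)
        assert stat == pytest.approx(2 * (full.loglik - red.loglik), abs=1e-10)
        assert df == 2  # Black, other
        assert 0.0 <= p <= 1.0
        assert stat >= -1e-6

    def test_non_nested_rejected(self, small_sim):
        f_race = fit_excess_model(
            small_sim, ModelSpec(covariates=("sex", "race"), interactions=())
        )
        f_age = fit_excess_model(small_sim, LEAN_SPEC)
        with pytest.raises(ModelError, match="nested"):
            lr_test(f_age, f_race)

    def test_reference_level_invariance(self, small_sim):
        """The LR statistic does not depend on the chosen reference levels."""
        full_a = fit_excess_model(
            small_sim, ModelSpec(covariates=("sex", "age_category", "race"))
        )
        red_a = fit_excess_model(small_sim, LEAN_SPEC)
        stat_a = 2 * (full_a.loglik - red_a.loglik)

        refs = {"sex": "female", "race": "other", "age_category": ">=60"}
        full_b = fit_excess_model(
            small_sim,
            ModelSpec(covariates=("sex", "age_category", "race"),
                      references=refs),
        )
        red_b = fit_excess_model(
            small_sim,
            ModelSpec(covariates=("sex", "age_category"), references=refs),
        )
        stat_b = 2 * (full_b.loglik - red_b.loglik)
        assert stat_a == pytest.approx(stat_b, abs=1e-5)


class TestEraStratified:
    def test_single_era_partition_matches_unstratified(self, small_sim):
        part = ((1988, 2019),)
        strat = era_stratified_rer(small_sim, LEAN_SPEC, era_partition=part)
        fit = fit_excess_model(small_sim, LEAN_SPEC.without_era())
        for _, row in strat.iterrows():
            est = rer_contrast(fit, age_category=row["age_category"])
            assert row["rer"] == pytest.approx(est.rer, rel=1e-9)
            assert row["ci_lo"] == pytest.approx(est.ci_lo, rel=1e-9)

    def test_candidate_order_invariance(self, small_sim):
        part = ((1988, 1998), (1999, 2008), (2009, 2019))
        a = era_stratified_rer(small_sim, LEAN_SPEC, era_partition=part)
        rng = np.random.default_rng(0)
        perm = small_sim.sample(frac=1.0, random_state=1)
        b = era_stratified_rer(perm, LEAN_SPEC, era_partition=part)
        merged = a.merge(b, on=["era", "age_category"], suffixes=("_a", "_b"))
        assert np.allclose(
            merged["rer_a"].astype(float),
            merged["rer_b"].astype(float),
            rtol=1e-8, equal_nan=True,
        )

    def test_empty_era_reported_not_dropped(self, small_sim):
        sub = small_sim[small_sim["listing_year"] >= 1999]
        part = ((1988, 1998), (1999, 2019))
        strat = era_stratified_rer(sub, LEAN_SPEC, era_partition=part)
        first = strat[strat["era"] == "1988-1998"]
        assert len(first) == 1
        assert not first["estimable"].iloc[0]
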