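import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import optimize, stats

from ecdna.errors import FitError
from ecdna.simulate import (
    CohortSimConfig,
    CoxSimConfig,
    fixture_tables,
    gen_cohort,
    gen_cox_cohort,
)
from ecdna.survival import (
    ContingencyTable2x2,
    aft_fit,
    chi2_2x2,
    cox_fit,
    cox_partial_loglik,
    design_matrix,
    fisher_exact_2x2,
    km_estimate,
    load_cohort,
    mediation_baron_kenny,
    percentage_change,
    select_ridge_lambda,
)


@pytest.fixture(scope="module")
def cox_cohort():
    return gen_cox_cohort(CoxSimConfig(seed=0))


@pytest.fixture(scope="module")
def cohort():
    return gen_cohort(CohortSimConfig(seed=0))


class TestDesignMatrix:
    frame = pd.DataFrame(
        {
            "time_days": [1.0, 2.0, 3.0, 4.0, np.nan],
            "event": [1, 0, 1, 1, 1],
            "age": [5.0, 6.0, np.nan, 8.0, 9.0],
            "subgroup": ["SHH", "G3", "G3", "G3", "SHH"],
        }
    )

    def test_dummy_coding_reference_is_largest_group(self):
        X = design_matrix(self.frame, ["age", "subgroup"])
        # rows 2 (NaN age) and 4 (NaN time) dropped; G3 is the largest group
        assert list(X.index) == [0, 1, 3]
        assert "subgroup_SHH" in X.columns and "subgroup_G3" not in X.columns
        assert X.subgroup_SHH.tolist() == [1.0, 0.0, 0.0]

    def test_explicit_reference_level(self):
        X = design_matrix(self.frame, ["subgroup"], reference_levels={"subgroup": "SHH"})
        assert "subgroup_G3" in X.columns and "subgroup_SHH" not in X.columns


class TestKaplanMeier:
    def test_single_group_hand_example(self):
        # times 1,2,3 all events: S = 2/3, 1/3, 0
        est, logrank = km_estimate([1, 2, 3], [1, 1, 1])
        km = next(iter(est.values()))
        assert logrank is None
        assert km.survival[km.times == 1][0] == pytest.approx(2 / 3)
        assert km.survival[km.times == 2][0] == pytest.approx(1 / 3)
        assert km.survival[km.times == 3][0] == pytest.approx(0.0)

    def test_censoring_hand_example(self):
        # events at 1 and 3, censored at 2: S(1)=3/4, S(3)=3/4 * 1/2
        est, _ = km_estimate([1, 2, 3, 4], [1, 0, 1, 0])
        km = next(iter(est.values()))
        assert km.survival[km.times == 3][0] == pytest.approx(3 / 8)

    def test_two_group_logrank_matches_scipy(self, cox_cohort):
        frame, _ = cox_cohort
        est, (chi2, p) = km_estimate(frame.time_days, frame.event, frame.x)
        assert set(est) == {"0", "1"}
        res = stats.logrank(
            stats.CensoredData(
                frame.time_days[frame.x == 0][frame.event[frame.x == 0] == 1],
                right=frame.time_days[frame.x == 0][frame.event[frame.x == 0] == 0],
            ),
            stats.CensoredData(
                frame.time_days[frame.x == 1][frame.event[frame.x == 1] == 1],
                right=frame.time_days[frame.x == 1][frame.event[frame.x == 1] == 0],
            ),
        )
        assert p == pytest.approx(res.pvalue, rel=1e-6)
        assert p < 1e-10  # a true HR of 2.5 is detected


class TestCoxFit:
    def test_recovers_true_log_hazard_ratio(self, cox_cohort):
        frame, truth = cox_cohort
        fit = cox_fit(frame[["x"]], frame.time_days, frame.event)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(truth["log_hr"], abs=0.15)
        assert fit.ci_lower[0] < np.exp(truth["log_hr"]) < fit.ci_upper[0]

    def test_matches_lifelines_efron(self, cox_cohort):
        frame, _ = cox_cohort
        fit = cox_fit(frame[["x"]], frame.time_days, frame.event)
        cph = CoxPHFitter()
        cph.fit(frame, duration_col="time_days", event_col="event")
        assert fit.beta[0] == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit.se[0] == pytest.approx(cph.standard_errors_["x"], abs=1e-5)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_matches_generic_optimizer(self, cox_cohort):
        frame, _ = cox_cohort
        X = frame[["x"]].to_numpy(dtype=float)
        t = frame.time_days.to_numpy()
        e = frame.event.to_numpy()
        fit = cox_fit(frame[["x"]], t, e)
        res = optimize.minimize(
            lambda b: -cox_partial_loglik(b, X, t, e),
            x0=np.zeros(1),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12},
        )
        assert fit.beta[0] == pytest.approx(res.x[0], abs=1e-5)

    def test_efron_hand_example_two_tied_deaths(self):
        """Three subjects, two tied deaths at t=1, one at-risk survivor.

        Efron log-likelihood at beta:
            eta1 + eta2 - log(w1+w2+w3) - log(w1/2 + w2/2 + w3)
        """
        X = np.array([[1.0], [0.0], [0.0]])
        t = np.array([1.0, 1.0, 2.0])
        e = np.array([1, 1, 0])
        for b in (0.0, 0.5, -1.2):
            w = np.exp(X[:, 0] * b)
            expected = (
                X[0, 0] * b + X[1, 0] * b
                - np.log(w.sum())
                - np.log(w[0] / 2 + w[1] / 2 + w[2])
            )
            got = cox_partial_loglik(np.array([b]), X, t, e)
            assert got == pytest.approx(expected)

    def test_breslow_duplication_invariance(self):
        rng = np.random.default_rng(5)
        n = 80
        X = rng.normal(size=(n, 1))
        t = rng.exponential(1.0, size=n)
        e = rng.random(n) < 0.7
        fit1 = cox_fit(X, t, e.astype(int), ties="breslow")
        X2 = np.vstack([X, X])
        t2 = np.concatenate([t, t])
        e2 = np.concatenate([e, e]).astype(int)
        fit2 = cox_fit(X2, t2, e2, ties="breslow")
        assert fit2.beta[0] == pytest.approx(fit1.beta[0], abs=1e-8)

    def test_ridge_shrinks_monotonically(self, cox_cohort):
        frame, _ = cox_cohort
        norms = [
            abs(cox_fit(frame[["x"]], frame.time_days, frame.event, ridge_lambda=lam).beta[0])
            for lam in (0.0, 1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 0.1 * norms[0]

    def test_separated_data_needs_ridge(self):
        # perfect separation: the covariate is a step in event time
        t = np.arange(1.0, 21.0)
        e = np.ones(20, dtype=int)
        X = (t > 10).astype(float).reshape(-1, 1)
        unpen = cox_fit(X, t, e, ridge_lambda=0.0)
        pen = cox_fit(X, t, e, ridge_lambda=1.0)
        assert pen.converged and np.isfinite(pen.beta[0])
        assert abs(pen.beta[0]) < abs(unpen.beta[0])

    def test_no_events_raises(self):
        with pytest.raises(FitError):
            cox_fit(np.ones((5, 1)), np.arange(1.0, 6.0), np.zeros(5, dtype=int))

    def test_invalid_args(self):
        X = np.ones((5, 1))
        t = np.arange(1.0, 6.0)
        e = np.array([1, 0, 1, 0, 1])
        with pytest.raises(ValueError):
            cox_fit(X, t, e, ridge_lambda=-1.0)
        with pytest.raises(ValueError):
            cox_fit(X, t, e, ties="exact")


class TestRidgeSelection:
    def test_collinear_covariates_select_positive_lambda(self):
        rng = np.random.default_rng(2)
        n = 150
        z = rng.normal(size=n)
        X = pd.DataFrame(
            {
                "a": z + rng.normal(scale=0.01, size=n),
                "b": z + rng.normal(scale=0.01, size=n),
            }
        )
        t = np.exp(-0.5 * z + rng.normal(scale=0.5, size=n))
        e = np.ones(n, dtype=int)
        lam, table = select_ridge_lambda(X, t, e, seed=1)
        assert lam in table["lambda"].tolist()
        fit = cox_fit(X, t, e, ridge_lambda=lam)
        assert np.isfinite(fit.beta).all()
        assert table.cv_loglik.notna().all()

    def test_ties_go_to_smallest_lambda(self, cox_cohort):
        frame, _ = cox_cohort
        lam, _ = select_ridge_lambda(
            frame[["x"]].iloc[:100],
            frame.time_days.iloc[:100],
            frame.event.iloc[:100],
            lambda_grid=(0.01, 0.01, 0.01),
        )
        assert lam == 0.01

    def test_deterministic_given_seed(self, cox_cohort):
        frame, _ = cox_cohort
        sub = frame.iloc[:120]
        a = select_ridge_lambda(sub[["x"]], sub.time_days, sub.event, seed=7)
        b = select_ridge_lambda(sub[["x"]], sub.time_days, sub.event, seed=7)
        assert a[0] == b[0] and a[1].equals(b[1])


class TestAFT:
    def test_recovers_generating_coefficients(self, cohort):
        frame, truth = cohort
        fit = aft_fit(frame[["tp53", "ecDNA"]], frame.time_days, frame.event)
        assert fit.beta["ecDNA"] == pytest.approx(truth["beta_m"], abs=0.15)
        assert fit.beta["tp53"] == pytest.approx(truth["beta_e"], abs=0.2)
        assert fit.sigma == pytest.approx(truth["sigma"], abs=0.1)

    def test_percentage_change(self):
        assert percentage_change(0.0) == 0.0
        assert percentage_change(np.log(2.0)) == pytest.approx(100.0)
        assert percentage_change(-np.log(2.0)) == pytest.approx(-50.0)

    def test_no_events_raises(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 0.0]})
        with pytest.raises(FitError):
            aft_fit(X, [1.0, 2.0, 3.0], [0, 0, 0])


class TestMediation:
    def test_strong_mediator_attenuates_exposure_effect(self, cohort):
        frame, truth = cohort
        res = mediation_baron_kenny(frame, exposure="tp53", mediator="ecDNA")
        # the mediator carries most of the exposure-outcome association
        assert res.mediator_model_coef == pytest.approx(truth["a1"], abs=0.8)
        assert abs(res.direct_effect) < abs(res.total_effect)
        assert res.attenuation > 0.5
        assert res.mediator_effect == pytest.approx(truth["beta_m"], abs=0.2)
        assert res.total_pct_change == pytest.approx(
            percentage_change(res.total_effect)
        )

    def test_independent_mediator_no_attenuation(self):
        rng = np.random.default_rng(4)
        n = 800
        e = (rng.random(n) < 0.4).astype(int)
        m = (rng.random(n) < 0.3).astype(int)  # independent of e
        log_t = 7.0 - 0.8 * e + 0.6 * rng.normal(size=n)
        t_event = np.exp(log_t)
        t_cens = rng.uniform(0, 4000, n)
        frame = pd.DataFrame(
            {
                "tp53": e,
                "ecDNA": m,
                "time_days": np.minimum(t_event, t_cens),
                "event": (t_event <= t_cens).astype(int),
            }
        )
        res = mediation_baron_kenny(frame, exposure="tp53", mediator="ecDNA")
        assert abs(res.attenuation) < 0.15

    def test_degenerate_inputs_rejected(self):
        base = pd.DataFrame(
            {
                "e": [0, 1, 0, 1],
                "m": [0, 1, 0, 1],
                "time_days": [1.0, 2.0, 3.0, 4.0],
                "event": [1, 1, 1, 1],
            }
        )
        with pytest.raises(ValueError, match="collinear"):
            mediation_baron_kenny(base, exposure="e", mediator="m")
        const = base.assign(m=0)
        with pytest.raises(ValueError, match="constant"):
            mediation_baron_kenny(const, exposure="e", mediator="m")


class TestAssociationTests:
    def test_chi2_matches_r_style_value(self):
        tables = fixture_tables()
        chi2, p, dof = chi2_2x2(tables["shh_vs_rest_ecdna"])
        assert dof == 1
        assert round(chi2, 2) == 7.66
        assert p == pytest.approx(0.0056, abs=5e-4)

    def test_chi2_without_yates_matches_hand_formula(self):
        tbl = ContingencyTable2x2(10, 20, 30, 40)
        chi2, _, _ = chi2_2x2(tbl, yates=False)
        n = 100
        expected = n * (10 * 40 - 20 * 30) ** 2 / (30 * 70 * 40 * 60)
        assert chi2 == pytest.approx(expected)

    def test_fisher_matches_enumeration_oracle(self):
        tbl = fixture_tables()["tp53_vs_ecdna_shh"]
        odds, p = fisher_exact_2x2(tbl)
        # independent oracle: enumerate all same-margin tables
        a, b, c, d = tbl.a, tbl.b, tbl.c, tbl.d
        total, row1, col1 = a + b + c + d, a + b, a + c
        k = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
        pmf = stats.hypergeom.pmf(k, total, col1, row1)
        obs = stats.hypergeom.pmf(a, total, col1, row1)
        expected = pmf[pmf <= obs * (1 + 1e-9)].sum()
        assert p == pytest.approx(expected, rel=1e-9)
        assert odds == pytest.approx((a * d) / (b * c))

    def test_fisher_midp_less_than_standard(self):
        tbl = fixture_tables()["tp53_vs_ecdna_shh"]
        _, p_std = fisher_exact_2x2(tbl)
        _, p_mid = fisher_exact_2x2(tbl, midp=True)
        assert p_mid < p_std
        # mid-p subtracts half the observed table's probability class
        assert p_mid == pytest.approx(1.3e-7, rel=0.05)

    def test_bad_tables_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)
        with pytest.raises(ValueError):
            chi2_2x2(ContingencyTable2x2(0, 0, 3, 4))


class TestLoadCohort:
    def test_round_trip_and_missing_columns(self, tmp_path, cohort):
        frame, _ = cohort
        p = tmp_path / "cohort.csv"
        frame.to_csv(p, index=False)
        back = load_cohort(p)
        assert back.shape == frame.shape
        frame.drop(columns=["subgroup"]).to_csv(p, index=False)
        with pytest.raises(ValueError, match="subgroup"):
            load_cohort(p)
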