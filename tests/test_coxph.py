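"""The internal Cox fitter against lifelines and simulation ground truth."""

import numpy as np
import pandas as pd
import pytest

from crprog.coxph import fit_coxph, null_partial_loglik, breslow_baseline
from crprog.othercause import combine_cif_with_cox, fit_cox_other_cause
from crprog.nonparametric import aalen_cif, nelson_aalen_cause_specific


def _sim(n, beta, seed, p_covs=1):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p_covs))
    lam = 0.1 * np.exp(X @ np.atleast_1d(beta))
    t = rng.exponential(1.0 / lam)
    c = rng.exponential(15.0, n)
    obs = np.minimum(t, c)
    return X, obs, t <= c


class TestAgainstLifelines:
    def test_coefficients_loglik_and_se_match(self):
        lifelines = pytest.importorskip("lifelines")
        X, t, e = _sim(500, [0.5, -0.3], seed=1, p_covs=2)
        mine = fit_coxph(X, t, e)
        df = pd.DataFrame({"t": t, "e": e.astype(int), "x0": X[:, 0], "x1": X[:, 1]})
        ref = lifelines.CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(mine.beta, ref.params_.values, atol=1e-6)
        assert mine.loglik == pytest.approx(ref.log_likelihood_, abs=1e-6)
        np.testing.assert_allclose(mine.se, ref.standard_errors_.values, atol=1e-5)

    def test_breslow_baseline_reproduces_na_when_beta_zero(self):
        # with a zero covariate the baseline is the Nelson-Aalen estimate
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 200)
        e = rng.random(200) < 0.5
        z = np.zeros((200, 1))
        bt, binc = breslow_baseline(np.array([0.0]), z, t, e)
        ev = np.where(e, 1, 0)
        nt, ninc = nelson_aalen_cause_specific(t, ev, cause=1)
        np.testing.assert_allclose(bt, nt)
        np.testing.assert_allclose(binc, ninc, atol=1e-12)


class TestRecovery:
    def test_null_model_loglik(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 100)
        e = rng.random(100) < 0.4
        ll0 = null_partial_loglik(t, e)
        res = fit_coxph(rng.standard_normal((100, 1)) * 1e-14, t, e)
        assert res.loglik == pytest.approx(ll0, abs=1e-6)

    def test_recovers_simulated_log_hazard_ratio(self):
        X, t, e = _sim(4000, [np.log(2.0)], seed=4)
        res = fit_coxph(X, t, e)
        assert res.beta[0] == pytest.approx(np.log(2.0), abs=3 * res.se[0])

    def test_monotone_likelihood_capped(self):
        # all events in one stratum: infinite MLE, finite capped estimate
        t = np.concatenate([np.ones(20) * 2.0, np.arange(1, 21)])
        e = np.concatenate([np.zeros(20, bool), np.ones(20, bool)])
        z = np.concatenate([np.zeros(20), np.ones(20)])[:, None]
        res = fit_coxph(z, t, e)
        assert res.capped
        assert np.isfinite(res.beta[0])


class TestOtherCauseModel:
    def test_null_age_effect_within_3se(self):
        from crprog import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(
            n_subjects=2000, lambda_oth_le80=0.05, lambda_oth_gt80=0.05
        )
        co = simulate_cohort(cfg, seed=5)
        t, e = co.arrays()
        fit = fit_cox_other_cause(t, e, co.df["age_bin"].to_numpy())
        assert abs(fit.log_hr) < 3 * fit.se

    def test_recovers_age_hazard_ratio(self, cohort_n5000):
        t, e = cohort_n5000.arrays()
        fit = fit_cox_other_cause(t, e, cohort_n5000.df["age_bin"].to_numpy())
        # generated other-cause hazards: 0.10 vs 0.02 per year
        assert fit.log_hr == pytest.approx(np.log(5.0), abs=3 * fit.se)

    def test_no_other_cause_events_rejected(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 0, 1])
        with pytest.raises(ValueError):
            fit_cox_other_cause(t, e, np.array([0, 1, 0]))

    def test_no_metastatic_deaths_equals_all_deaths_fit(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(8, 300)
        e = np.where(rng.random(300) < 0.5, 2, 0)  # other-cause or censored
        z = (rng.random(300) < 0.3).astype(int)
        fit = fit_cox_other_cause(t, e, z)
        res = fit_coxph(z.astype(float)[:, None], t, e > 0)
        assert fit.log_hr == pytest.approx(res.beta[0], abs=1e-10)


class TestCombineCifWithCox:
    def test_reduces_to_aalen_cif_when_pooled(self, toy_competing_df):
        """With beta=0 and the group's own other-cause increments, the
        product-integral composition is algebraically the Aalen-Johansen
        estimate."""
        from crprog.othercause import CoxFit

        t = toy_competing_df["time"].to_numpy()
        e = toy_competing_df["event"].to_numpy()
        mt, minc = nelson_aalen_cause_specific(t, e, cause=1)
        ot, oinc = nelson_aalen_cause_specific(t, e, cause=2)
        cox = CoxFit(
            log_hr=0.0, se=0.0, loglik=0.0, loglik_null=0.0, df=1, n_events=1,
            baseline_times=ot, baseline_increments=oinc,
        )
        combined = combine_cif_with_cox(mt, minc, cox, age_bin=0)
        ref = aalen_cif(t, e, cause=1)
        for tau in (1.0, 2.0, 3.0, 4.0, 5.0):
            assert combined.cif_at(tau) == pytest.approx(ref.cif_at(tau), abs=1e-12)

    def test_two_event_hand_product_integral(self):
        """Met increment 0.2 at t=1, other increment 0.1 at t=2 (HR=e),
        met increment 0.5 at t=3, checked against a hand calculation."""
        from crprog.othercause import CoxFit

        cox = CoxFit(
            log_hr=1.0, se=0.0, loglik=0.0, loglik_null=0.0, df=1, n_events=1,
            baseline_times=np.array([2.0]), baseline_increments=np.array([0.1]),
        )
        curve = combine_cif_with_cox(
            np.array([1.0, 3.0]), np.array([0.2, 0.5]), cox, age_bin=1
        )
        s1 = 1.0  # S(1-)
        f1 = s1 * 0.2
        s2 = s1 * (1 - 0.2)  # S(2-)
        s3 = s2 * (1 - 0.1 * np.e)  # S(3-)
        f3 = f1 + s3 * 0.5
        assert curve.cif_at(1.0) == pytest.approx(f1)
        assert curve.cif_at(2.5) == pytest.approx(f1)
        assert curve.cif_at(3.0) == pytest.approx(f3)

    def test_elderly_have_lower_metastatic_cif(self, cohort_n2000):
        t, e = cohort_n2000.arrays()
        fit = fit_cox_other_cause(t, e, cohort_n2000.df["age_bin"].to_numpy())
        assert fit.log_hr > 0
        mask = cohort_n2000.df["lbtd_bin"].to_numpy() == 3
        mt, minc = nelson_aalen_cause_specific(t[mask], e[mask], cause=1)
        young = combine_cif_with_cox(mt, minc, fit, age_bin=0)
        old = combine_cif_with_cox(mt, minc, fit, age_bin=1)
        for tau in (2.0, 5.0, 10.0):
            assert old.cif_at(tau) < young.cif_at(tau)
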