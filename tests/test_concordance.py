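"""Fixed-horizon competing-risks concordance against exhaustive enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crprog import SimulationConfig, bootstrap_cindex, cr_cindex, model_risk_scores, simulate_cohort
from crprog.imputation import MIConfig

from _oracles import brute_cindex


class TestExactCases:
    def test_perfectly_ordered_risks_give_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 1, 1, 1])
        risk = np.array([0.9, 0.7, 0.5, 0.3, 0.1])  # earlier death = higher risk
        res = cr_cindex(risk, t, e, tau=10.0)
        assert res.cindex == 1.0

    def test_all_tied_risks_give_half(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 2, 1])
        res = cr_cindex(np.full(4, 0.3), t, e, tau=10.0)
        assert res.cindex == 0.5
        assert res.tied == res.comparable

    def test_five_subject_hand_example(self):
        # two cause events, one competing, two censored
        t = np.array([1.0, 4.0, 2.0, 1.5, 6.0])
        e = np.array([1, 1, 2, 0, 0])
        risk = np.array([0.8, 0.4, 0.6, 0.1, 0.2])
        res = cr_cindex(risk, t, e, tau=5.0)
        c, comparable, concordant, tied = brute_cindex(risk, t, e, 5.0)
        assert res.cindex == pytest.approx(c)
        assert (res.comparable, res.concordant, res.tied) == (comparable, concordant, tied)

    def test_no_events_by_tau_rejected(self):
        with pytest.raises(ValueError):
            cr_cindex(np.array([0.1, 0.2]), np.array([5.0, 6.0]), np.array([1, 0]), tau=1.0)

    def test_tau_beyond_last_time_same_pairs(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(3, 40)
        e = rng.integers(0, 3, 40)
        risk = rng.random(40)
        last = t.max()
        a = cr_cindex(risk, t, e, tau=last)
        b = cr_cindex(risk, t, e, tau=last * 10)
        assert a.cindex == b.cindex and a.comparable == b.comparable


class TestBruteForceEquality:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        t = rng.integers(1, 10, n).astype(float)
        e = rng.integers(0, 3, n)
        risk = rng.choice([0.1, 0.25, 0.5, 0.75], n)  # ties likely
        if not ((e == 1) & (t <= 6.0)).any():
            pytest.skip("no cause events drawn")
        res = cr_cindex(risk, t, e, tau=6.0)
        c, comparable, *_ = brute_cindex(risk, t, e, 6.0)
        assert res.cindex == pytest.approx(c, abs=1e-14)
        assert res.comparable == comparable

    def test_harrell_c_on_single_cause_uncensored(self):
        rng = np.random.default_rng(7)
        n = 40
        t = rng.permutation(n).astype(float) + 1
        e = np.ones(n, dtype=int)
        risk = rng.random(n)
        res = cr_cindex(risk, t, e, tau=float(n + 1))
        c, *_ = brute_cindex(risk, t, e, float(n + 1))
        assert res.cindex == pytest.approx(c, abs=1e-14)


class TestInvariances:
    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        t = rng.exponential(3, n)
        e = rng.integers(0, 3, n)
        risk = rng.random(n)
        if not ((e == 1) & (t <= 4.0)).any():
            return
        a = cr_cindex(risk, t, e, tau=4.0).cindex
        b = cr_cindex(np.exp(3 * risk) + 1, t, e, tau=4.0).cindex
        assert a == pytest.approx(b, abs=1e-14)

    def test_risk_reversal_antisymmetry(self):
        rng = np.random.default_rng(9)
        n = 30
        t = rng.exponential(3, n)
        e = rng.integers(0, 3, n)
        risk = rng.random(n)
        a = cr_cindex(risk, t, e, tau=5.0)
        b = cr_cindex(-risk, t, e, tau=5.0)
        assert a.cindex + b.cindex == pytest.approx(1.0, abs=1e-14)


class TestModelRiskScores:
    def test_c3s_model_discriminates_better(self):
        cfg = SimulationConfig(n_subjects=3000, p_missing_c3s_by_bin=(0.0,) * 6)
        co = simulate_cohort(cfg, seed=21)
        t, e = co.arrays()
        for tau in (2.0, 5.0, 10.0):
            c_full = cr_cindex(model_risk_scores(co.df, "lbtd_c3s", tau), t, e, tau).cindex
            c_lbtd = cr_cindex(model_risk_scores(co.df, "lbtd", tau), t, e, tau).cindex
            assert c_full > c_lbtd

    def test_true_cif_risks_stable_across_horizons(self, cohort_n2000, default_config):
        from crprog import true_group_cif

        df = cohort_n2000.df
        t, e = cohort_n2000.arrays()
        cs = []
        for tau in (2.0, 5.0, 10.0):
            risks = np.array([
                true_group_cif(default_config, b, tau, c3s=c3)
                for b, c3 in zip(df["lbtd_bin"], df["c3s_true"])
            ])
            cs.append(cr_cindex(risks, t, e, tau).cindex)
        assert max(cs) - min(cs) < 0.08

    def test_bootstrap_ci_brackets_point(self):
        cfg = SimulationConfig(n_subjects=600, p_missing_c3s_by_bin=(0.0,) * 6)
        co = simulate_cohort(cfg, seed=22)
        results = bootstrap_cindex(co, "lbtd_c3s", taus=(5.0,),
                                   config=MIConfig(m=1, b=60), seed=5)
        (r,) = results
        assert r.ci[0] <= r.cindex <= r.ci[1]
        assert 0.5 < r.cindex <= 1.0
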