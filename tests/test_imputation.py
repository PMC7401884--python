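"""Multiple imputation of chromosome-3 status and the pooled MI bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crprog import (
    MIConfig,
    SimulationConfig,
    fit_imputation_model,
    impute_c3s,
    mi_bootstrap_ci,
    pool_cif,
    simulate_cohort,
)
from crprog.nonparametric import group_cif_at


class TestImputationModel:
    def test_fitted_bin_effects_rise_with_prevalence(self, cohort_n5000):
        model = fit_imputation_model(cohort_n5000)
        coefs = dict(zip(model.columns, model.params))
        bins = [coefs[f"lbtd_bin{b}"] for b in range(2, 7)]
        # generating monosomy prevalence rises steeply with bin; the fitted
        # dummy coefficients should rise overall (noise tolerated between
        # neighbours)
        assert bins[-1] > bins[0]
        assert np.mean(np.diff([0.0] + bins)) > 0

    def test_all_observed_cohort_still_fits(self):
        cfg = SimulationConfig(n_subjects=400, p_missing_c3s_by_bin=(0.0,) * 6)
        co = simulate_cohort(cfg, seed=3)
        model = fit_imputation_model(co)
        assert model.n_complete == co.n

    def test_single_bin_cohort_degenerates_gracefully(self):
        cfg = SimulationConfig(
            n_subjects=300,
            lbtd_log_mean=np.log(8.0),
            lbtd_log_sd=0.05,
            lbtd_range=(6.0, 9.9),
        )
        co = simulate_cohort(cfg, seed=4)
        assert set(co.df["lbtd_bin"]) == {1}
        model = fit_imputation_model(co)
        p = model.predict_p(co.df[co.df["m3"].isna()])
        assert np.all((p > 0) & (p < 1))

    def test_no_complete_cases_rejected(self):
        cfg = SimulationConfig(n_subjects=50, p_missing_c3s_by_bin=(1.0,) * 6)
        co = simulate_cohort(cfg, seed=5)
        with pytest.raises(ValueError):
            fit_imputation_model(co)


class TestImputeC3S:
    def test_observed_values_never_altered(self, cohort_n2000, desk_config):
        ens = impute_c3s(cohort_n2000, config=desk_config, seed=1)
        observed = cohort_n2000.df["m3"].to_numpy()
        mask = ~np.isnan(observed)
        for i in range(ens.m):
            np.testing.assert_array_equal(ens.m3_draws[i][mask], observed[mask])

    def test_every_dataset_complete(self, cohort_n2000, desk_config):
        ens = impute_c3s(cohort_n2000, config=desk_config, seed=1)
        for ds in ens.datasets():
            assert not ds["m3"].isna().any()

    def test_deterministic_given_seed(self, cohort_n2000, desk_config):
        a = impute_c3s(cohort_n2000, config=desk_config, seed=9)
        b = impute_c3s(cohort_n2000, config=desk_config, seed=9)
        for i in range(a.m):
            np.testing.assert_array_equal(a.m3_draws[i], b.m3_draws[i])

    def test_no_missing_data_identity(self):
        cfg = SimulationConfig(n_subjects=200, p_missing_c3s_by_bin=(0.0,) * 6)
        co = simulate_cohort(cfg, seed=6)
        ens = impute_c3s(co, config=MIConfig(m=5, b=10), seed=1)
        base = co.df["m3"].to_numpy().astype(np.int64)
        for i in range(ens.m):
            np.testing.assert_array_equal(ens.m3_draws[i], base)

    def test_mar_prevalence_recovery_within_3se(self):
        """Under MAR-given-LBTD missingness the pooled imputed monosomy
        prevalence per bin should track the generating prevalence."""
        cfg = SimulationConfig(n_subjects=5000)
        co = simulate_cohort(cfg, seed=7)
        ens = impute_c3s(co, config=MIConfig(m=11, b=1), seed=2)
        bins = co.df["lbtd_bin"].to_numpy()
        for b in range(1, 7):
            mask = bins == b
            pooled = np.mean([d[mask].mean() for d in ens.m3_draws])
            p = cfg.p_m3_by_bin[b - 1]
            se = np.sqrt(p * (1 - p) / mask.sum())
            assert pooled == pytest.approx(p, abs=3.5 * se)


class TestPooling:
    def test_mean_pooling(self):
        assert pool_cif([0.2, 0.4]) == pytest.approx(0.3)
        assert pool_cif([0.7] * 11) == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_cif([])

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_permutation_invariant(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert pool_cif(shuffled) == pytest.approx(pool_cif(values), abs=1e-12)


def _group_cif5(df):
    bins = df["lbtd_bin"].to_numpy(dtype=np.int64)
    m3 = df["m3"].to_numpy(dtype=float)
    codes = (bins - 1) * 2 + m3.astype(np.int64)
    return group_cif_at(
        df["time"].to_numpy(float), df["event"].to_numpy(np.int64), codes, 12, 5.0, 1
    )


class TestMIBootstrap:
    def test_ci_brackets_point_estimate(self):
        cfg = SimulationConfig(n_subjects=800)
        co = simulate_cohort(cfg, seed=8)
        res = mi_bootstrap_ci(
            co, _group_cif5, config=MIConfig(m=5, b=100), seed=3,
            columns=["time", "event", "lbtd_bin", "m3"],
        )
        ok = np.isfinite(res.point)
        # cells with a handful of subjects can put the point estimate at a
        # percentile edge; the overwhelming majority must bracket
        inside = (res.lower[ok] <= res.point[ok] + 1e-9) & (
            res.point[ok] <= res.upper[ok] + 1e-9
        )
        assert inside.mean() > 0.9
        assert np.all(res.lower[ok] >= 0) and np.all(res.upper[ok] <= 1)
        assert np.all(res.lower[ok] <= res.upper[ok] + 1e-12)

    def test_reduces_to_plain_bootstrap_without_missingness(self):
        cfg = SimulationConfig(n_subjects=300, p_missing_c3s_by_bin=(0.0,) * 6)
        co = simulate_cohort(cfg, seed=9)
        res = mi_bootstrap_ci(
            co, _group_cif5, config=MIConfig(m=1, b=150), seed=4,
            columns=["time", "event", "lbtd_bin", "m3"],
        )
        assert res.n_boot == 150

    def test_vanishing_missingness_converges_to_complete_data(self):
        cfg = SimulationConfig(n_subjects=600, p_missing_c3s_by_bin=(0.0,) * 6)
        co = simulate_cohort(cfg, seed=10)
        ens = impute_c3s(co, config=MIConfig(m=7, b=1), seed=5)
        pooled = np.mean([_group_cif5(ds) for ds in ens.datasets()], axis=0)
        complete = _group_cif5(co.df)
        np.testing.assert_allclose(pooled, complete, atol=1e-10)
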