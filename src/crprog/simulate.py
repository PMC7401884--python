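"""Synthetic choroidal-melanoma cohorts with known ground truth.

The generator emulates the statistical structure the prognostic analysis
assumes: a right-skewed LBTD distribution on 2.4-28 mm (log-normal,
median 12 mm, truncated), monosomy-3 prevalence rising with tumour diameter,
diameter-dependent missingness of chromosome-3 status (small tumours are the
least likely to be typed, a missing-at-random mechanism given LBTD),
constant cause-specific hazards of metastatic and other-cause death per
(LBTD bin, C3S) and age cell, independent exponential censoring, and an
administrative follow-up horizon.

Constant hazards keep the ground-truth cumulative incidence in closed form,

    F_met(t) = lm / (lm + lo) * (1 - exp(-(lm + lo) t)),

which serves as the exact oracle for estimator-recovery and coverage tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, bin_lbtd

__all__ = ["SimulationConfig", "ConfigError", "simulate_cohort", "true_cif", "true_group_cif"]


class ConfigError(ValueError):
    """A simulation-configuration field is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are calibrated qualitatively to a large UK ocular-oncology
    referral cohort: LBTD log-normal with median 12 mm and interquartile
    range about 9.6-14.8 mm truncated to [2.4, 28]; roughly 10% of patients
    older than 80 at treatment; monosomy-3 prevalence rising from ~22% in
    the smallest tumours to ~79% in the largest; chromosome-3 typing missing
    most often for small tumours; metastatic-death hazards increasing with
    diameter and sharply higher for monosomy 3; other-cause mortality much
    higher over age 80.
    """

    n_subjects: int = 4000
    # LBTD: log-normal(log 12, 0.32) truncated to [2.4, 28] mm
    lbtd_log_mean: float = math.log(12.0)
    lbtd_log_sd: float = 0.32
    lbtd_range: tuple[float, float] = (2.4, 28.0)
    # age: normal(62, 14) truncated to [20, 99] years
    age_mean: float = 62.0
    age_sd: float = 14.0
    age_range: tuple[float, float] = (20.0, 99.0)
    # monosomy-3 prevalence and missingness per LBTD bin (1..6)
    p_m3_by_bin: tuple[float, ...] = (0.22, 0.29, 0.45, 0.57, 0.64, 0.79)
    p_missing_c3s_by_bin: tuple[float, ...] = (0.85, 0.78, 0.72, 0.65, 0.58, 0.50)
    # cause-specific hazards (per year)
    lambda_met_d3: tuple[float, ...] = (0.002, 0.004, 0.007, 0.012, 0.020, 0.022)
    lambda_met_m3: tuple[float, ...] = (0.030, 0.055, 0.090, 0.130, 0.180, 0.220)
    lambda_oth_le80: float = 0.02
    lambda_oth_gt80: float = 0.10
    censor_rate: float = 0.04
    admin_horizon: float = 25.0
    #: log-odds shift of missingness for deceased subjects (0 = MAR given LBTD)
    missing_outcome_log_or: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        for name in ("p_m3_by_bin", "p_missing_c3s_by_bin"):
            probs = getattr(self, name)
            if len(probs) != 6 or any(not 0.0 <= p <= 1.0 for p in probs):
                raise ConfigError(f"{name} must be 6 probabilities in [0, 1]")
        for name in ("lambda_met_d3", "lambda_met_m3"):
            lams = getattr(self, name)
            if len(lams) != 6 or any(l < 0 for l in lams):
                raise ConfigError(f"{name} must be 6 nonnegative hazards")
        for name in ("lambda_oth_le80", "lambda_oth_gt80", "censor_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.admin_horizon <= 0:
            raise ConfigError("admin_horizon must be positive")
        if not self.lbtd_range[0] < self.lbtd_range[1]:
            raise ConfigError("lbtd_range must be increasing")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigError("age_range must be increasing")

    def with_(self, **overrides) -> "SimulationConfig":
        """A copy with the given fields replaced."""
        return replace(self, **overrides)

    # -- population quantities used by the ground-truth oracle --------------

    def p_age_gt80(self) -> float:
        """P(age > 80) under the truncated-normal age distribution."""
        lo, hi = self.age_range
        a, b = (lo - self.age_mean) / self.age_sd, (hi - self.age_mean) / self.age_sd
        return float(
            stats.truncnorm.sf(80.0, a, b, loc=self.age_mean, scale=self.age_sd)
        )

    def p_lbtd_bin(self) -> np.ndarray:
        """P(LBTD bin) under the truncated log-normal diameter distribution."""
        lo, hi = self.lbtd_range
        a = (math.log(lo) - self.lbtd_log_mean) / self.lbtd_log_sd
        b = (math.log(hi) - self.lbtd_log_mean) / self.lbtd_log_sd
        edges = np.log(np.array([lo, 10.0, 12.0, 14.0, 16.0, 18.0, hi]))
        cdf = stats.truncnorm.cdf(edges, a, b, loc=self.lbtd_log_mean, scale=self.lbtd_log_sd)
        return np.diff(cdf)

    def hazards(self, lbtd_bin: int, c3s: str, age_bin: int) -> tuple[float, float]:
        """(metastatic, other-cause) hazards for one cell."""
        if not 1 <= lbtd_bin <= 6:
            raise ConfigError("lbtd_bin must be in 1..6")
        lam_met = (self.lambda_met_m3 if c3s == "M3" else self.lambda_met_d3)[lbtd_bin - 1]
        lam_oth = self.lambda_oth_gt80 if age_bin == 1 else self.lambda_oth_le80
        return lam_met, lam_oth


def _truncnorm(rng, n, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> Cohort:
    """Draw one cohort; bit-identical for the same seed.

    The returned cohort keeps the latent (pre-masking) chromosome-3 status in
    a ``c3s_true`` column for oracle-based recovery tests; the observed
    ``c3s`` column has values masked per the missingness model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects

    lbtd = np.exp(_truncnorm(rng, n, config.lbtd_log_mean, config.lbtd_log_sd,
                             math.log(config.lbtd_range[0]), math.log(config.lbtd_range[1])))
    age = _truncnorm(rng, n, config.age_mean, config.age_sd, *config.age_range)
    bins = bin_lbtd(lbtd)
    age_bin = (age > 80.0).astype(np.int64)

    p_m3 = np.asarray(config.p_m3_by_bin)[bins - 1]
    m3 = (rng.random(n) < p_m3).astype(np.int64)

    lam_met = np.where(
        m3 == 1,
        np.asarray(config.lambda_met_m3)[bins - 1],
        np.asarray(config.lambda_met_d3)[bins - 1],
    )
    lam_oth = np.where(age_bin == 1, config.lambda_oth_gt80, config.lambda_oth_le80)

    t_met = rng.exponential(np.where(lam_met > 0, 1.0 / np.maximum(lam_met, 1e-300), np.inf))
    t_met = np.where(lam_met > 0, t_met, np.inf)
    t_oth = rng.exponential(np.where(lam_oth > 0, 1.0 / np.maximum(lam_oth, 1e-300), np.inf))
    t_oth = np.where(lam_oth > 0, t_oth, np.inf)
    t_cens = (
        rng.exponential(1.0 / config.censor_rate, size=n)
        if config.censor_rate > 0
        else np.full(n, np.inf)
    )
    t_cens = np.minimum(t_cens, config.admin_horizon)

    t_event = np.minimum(t_met, t_oth)
    observed = np.minimum(t_event, t_cens)
    observed = np.maximum(observed, 1e-6)  # registry times are strictly positive
    event = np.where(t_event <= t_cens, np.where(t_met <= t_oth, 1, 2), 0)

    # cause-of-death categories exercising the registry coding rule:
    # metastatic deaths certified definite (cat 1) or probable (cat 2);
    # other deaths spread over possible-metastatic/other-malignancy/
    # non-cancerous/unknown (cats 3-6).
    outcome = np.full(n, "alive", dtype=object)
    met_mask = event == 1
    outcome[met_mask] = rng.choice([1, 2], p=[0.8, 0.2], size=int(met_mask.sum()))
    oth_mask = event == 2
    outcome[oth_mask] = rng.choice(
        [3, 4, 5, 6], p=[0.05, 0.40, 0.45, 0.10], size=int(oth_mask.sum())
    )

    # missingness of chromosome-3 typing: depends on LBTD bin (MAR given an
    # observed covariate); optional outcome-dependent shift for sensitivity
    # analyses.
    p_miss = np.asarray(config.p_missing_c3s_by_bin)[bins - 1]
    if config.missing_outcome_log_or != 0.0:
        logit = np.log(p_miss / (1.0 - p_miss)) + config.missing_outcome_log_or * (event > 0)
        p_miss = 1.0 / (1.0 + np.exp(-logit))
    missing = rng.random(n) < p_miss
    c3s_true = np.where(m3 == 1, "M3", "D3")
    c3s_obs = c3s_true.astype(object)
    c3s_obs[missing] = ""

    # covariates with no effect on the generated hazards (noise factors for
    # the selection suite), plus thickness loosely correlated with diameter.
    raw = pd.DataFrame(
        {
            "id": [f"sim{i}" for i in range(n)],
            "lbtd_mm": lbtd,
            "age_years": age,
            "sex": rng.choice(["male", "female"], size=n),
            "c3s": c3s_obs,
            "c3s_true": c3s_true,
            "chr8q": rng.choice(["normal", "gain"], p=[0.6, 0.4], size=n),
            "ciliary_body": rng.random(n) < 0.12,
            "extraocular": rng.random(n) < 0.05,
            "thickness_mm": np.clip(0.35 * lbtd + rng.normal(0, 1.2, n) + 1.0, 0.5, 18.0),
            "closed_loops": rng.random(n) < 0.3,
            "epithelioid": rng.random(n) < 0.35,
            "mitotic_count": rng.poisson(4.0, n),
            "followup_years": observed,
            "outcome": outcome,
        }
    )
    cohort = Cohort.from_dataframe(raw, provenance={"source": "simulate_cohort",
                                                    "seed": config.seed if seed is None else seed})
    return cohort


def true_cif(
    config: SimulationConfig,
    cell: tuple[int, str, int],
    t,
    cause: str = "met",
):
    """Exact cumulative incidence for one (lbtd_bin, c3s, age_bin) cell.

    Censoring is non-informative and is ignored (it does not change the
    estimand).  ``cause`` is ``"met"`` or ``"oth"``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    lbtd_bin, c3s, age_bin = cell
    lam_met, lam_oth = config.hazards(lbtd_bin, c3s, age_bin)
    lam = lam_met + lam_oth
    target = lam_met if cause == "met" else lam_oth
    with np.errstate(invalid="ignore"):
        out = np.where(lam > 0, target / np.maximum(lam, 1e-300) * (-np.expm1(-lam * t)), 0.0)
    return float(out) if out.ndim == 0 else out


def true_group_cif(
    config: SimulationConfig,
    lbtd_bin: int,
    t,
    c3s: str | None = None,
    age_bin: int | None = None,
    cause: str = "met",
):
    """Ground-truth CIF for a group, marginalising unspecified dimensions.

    Subjects are i.i.d., so the marginal CIF over chromosome-3 status and/or
    age is the mixture of cell CIFs weighted by the population cell
    probabilities implied by the config.
    """
    p80 = config.p_age_gt80()
    age_levels = [(age_bin, 1.0)] if age_bin is not None else [(0, 1.0 - p80), (1, p80)]
    if c3s is not None:
        c3s_levels = [(c3s, 1.0)]
    else:
        pm3 = config.p_m3_by_bin[lbtd_bin - 1]
        c3s_levels = [("D3", 1.0 - pm3), ("M3", pm3)]
    total = 0.0
    for cs, w_c in c3s_levels:
        for ab, w_a in age_levels:
            total = total + w_c * w_a * true_cif(config, (lbtd_bin, cs, ab), t, cause)
    return total
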