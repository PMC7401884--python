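# crprog — competing-risks prognostication for choroidal melanoma

`crprog` implements parsimonious models for estimating the absolute risk of
metastatic death in patients with choroidal (uveal) melanoma, for settings
where a full multivariable prognosticator is not available.  It is aimed at
biostatisticians and ocular-oncology researchers who need competing-risks
absolute risks — not Kaplan–Meier "1 − survival", which exaggerates
metastatic mortality in frail populations — stratified by the two most
informative predictors: largest basal tumour diameter (LBTD, six ordered
bins from `<10.1` to `18.1–28.0` mm) and chromosome 3 status (disomy D3 vs
monosomy M3), with patient age (≤80 vs >80 years) driving the competing
risk of death from other causes.

## The model

For group *k* (6 LBTD bins, or 12 LBTD × C3S cells), the absolute risk of
metastatic death is the Aalen–Johansen estimator

```
F̂_k(t) = Σ_{u ≤ t}  Ŝ_k(u−) · Y_k(u)⁻¹ · ΔN_k(u)
```

where `N_k` counts metastatic deaths, `Y_k` is the at-risk count and
`Ŝ_k(u−)` the left-hand limit of the group's Kaplan–Meier all-cause
survival; no independence assumption is made about the competing risk.
Death from other causes is modelled by a Cox model with the single binary
covariate age > 80, and age-specific risks are obtained by a discrete
product-integral combining the group's metastatic hazard increments with
the age-scaled other-cause baseline hazard.

Chromosome 3 is untyped for most patients (small tumours are typed least
often and skew toward D3, so complete-case analysis would be biased).
Missing status is completed by approximate Bayesian multiple imputation —
a logistic model for P(M3 | LBTD bin, event type, log follow-up time) with
posterior-normal coefficient draws — and per-dataset estimates are pooled
by their arithmetic mean over the *M* imputed datasets
(`F̄_k(t) = M⁻¹ Σᵢ F̂_k⁽ⁱ⁾(t)`, default M = 101; desk profile M = 11).
95% confidence intervals use the pooled-sample MI bootstrap: B resamples
per imputed dataset (default B = 2000; desk 200), all M·B estimates pooled,
CI = (2.5th, 97.5th) percentiles.  Discrimination is measured by the
fixed-horizon competing-risks C-index at 2, 5 and 10 years, and risk
factors are ranked by the rescaled AIC (LR χ² − 2·Δdf) under backward
selection.

Because the underlying individual-level hospital cohort is not publicly
deposited, the package ships a synthetic-cohort generator with the same
statistical structure (diameter-dependent monosomy prevalence and
missingness, constant cause-specific hazards per cell) whose closed-form
cumulative incidences serve as ground truth for the test suite.

## Worked example

```python
from crprog import MetastaticRiskModel, MIConfig, SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_subjects=2000), seed=7)
model = MetastaticRiskModel(cohort, mi_config=MIConfig.desk(seed=7))
results = model.fit(seed=7)

risk, lo, hi = results.risk_at(4, 10.0, c3s="M3", age_bin=0)
print(f"10-year risk, M3, 14.1-16.0 mm, age <81: {100*risk:.0f}% "
      f"(95% CI {100*lo:.0f}-{100*hi:.0f}%)")
risk, lo, hi = results.risk_at(4, 10.0, c3s="D3", age_bin=0)
print(f"10-year risk, D3, 14.1-16.0 mm, age <81: {100*risk:.1f}% "
      f"(95% CI {100*lo:.1f}-{100*hi:.1f}%)")
for r in results.concordance():
    print(f"C-index at {r.tau:.0f} y: {r.cindex:.2f}")
print(f"other-cause HR (age >80): {results.cox_other_cause.hazard_ratio:.1f}")
```

prints (for this seed):

```
10-year risk, M3, 14.1-16.0 mm, age <81: 63% (95% CI 52-74%)
10-year risk, D3, 14.1-16.0 mm, age <81: 10.8% (95% CI 3.3-18.9%)
C-index at 2 y: 0.88
C-index at 5 y: 0.87
C-index at 10 y: 0.87
other-cause HR (age >80): 4.5
```

i.e. a monosomy-3 tumour of 14–16 mm carries roughly six times the 10-year
metastatic mortality of a disomy-3 tumour of the same size; the 12-group
model ranks patients with C ≈ 0.87; and patients over 80 die of other
causes at ~4.5 times the rate of younger patients, which *lowers* their
absolute risk of metastatic death.

A thin CLI wraps the same pipeline:

```bash
crprog simulate --seed 1 --n 2000 --out cohort.csv
crprog all --cohort cohort.csv -m 11 -b 200 --seed 1 --out-dir out/
```

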