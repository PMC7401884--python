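# Methods

## Estimands and estimators

The quantity of clinical interest is the absolute risk (cumulative
incidence) of metastatic death by *t* years after treatment, in the
presence of the competing risk of death from other causes.  For a patient
group *k* it is estimated nonparametrically by the Aalen–Johansen form

F̂ₖ(t) = Σ_{u≤t} Ŝₖ(u−) · Yₖ(u)⁻¹ · ΔNₖ(u),

with Ŝₖ the group's Kaplan–Meier estimate of *all-cause* survival (left
limits), Yₖ the at-risk count just before *u*, and Nₖ the counting process
of metastatic deaths.  Computed jointly for both causes on the shared grid
of death times, the decomposition satisfies
F̂_met(t) + F̂_oth(t) + Ŝ(t) = 1 exactly (to floating-point rounding) at
every death time; the test suite asserts this to 1e−12.  No independence
assumption between the two causes is required.

Groups are the six LBTD bins (edges 10, 12, 14, 16, 18 mm, right-closed;
raw unrounded diameters are binned) or the twelve LBTD × chromosome-3
cells.  Cause of death follows the registry rule: only "definite" or
"probable" metastatic uveal melanoma counts as metastatic death; "possible"
metastatic disease, other malignancies, non-cancerous and unknown causes
count as other-cause death; survivors are censored.  Unknown cause is
grouped with other-cause death because metastatic attribution requires a
positive certification.

### Other-cause mortality and age-specific risks

Death from other causes is modelled semiparametrically: a Cox proportional
hazards model with the single binary covariate "age at treatment > 80
years" (exactly 80 counts as the younger group — ages are registry whole
years, hence the "<81 yr"/">80 yr" labels).  Age-specific metastatic risks
for a group combine the group's cause-specific Nelson–Aalen increments
ΔΛ_met,k with the age-scaled Breslow baseline increments of the Cox model
through a discrete product-integral:

S(u) = Π_{v≤u} (1 − ΔΛ_met,k(v) − e^{βz} ΔΛ_oth,0(v)),
F(t) = Σ_{u≤t} S(u−) ΔΛ_met,k(u).

With β = 0 and the group's own other-cause increments this reduces
algebraically to the group's Aalen–Johansen estimate (a unit test pins the
identity).  The composition is isolated in one function
(`combine_cif_with_cox`) so alternative readings can be swapped; it is the
reason elderly patients show *lower* absolute metastatic risk in every
table: their other-cause hazard (fitted HR ≈ 5 under the default generator)
removes them from risk earlier.

Ties: deaths of different causes at the same time share the same at-risk
set and left-limit survival; censorings at a death time are removed after
the death.  In the product-integral, if a merged increment sum exceeds 1
(possible only in degenerate tiny strata) both increments are scaled
proportionally so each survival factor stays in [0, 1].

### Cox fitting

Cox partial-likelihood fits use an internal Newton–Raphson solver with
Breslow tie handling (event times in both real registries and the
generator are continuous, so ties are rare and Breslow ≈ Efron; the solver
is verified against an Efron-ties reference on tie-free data to 1e−6).
Convergence: Newton step with step-halving, stopping when the step or the
relative likelihood change falls below 1e−9/1e−10 of the likelihood scale;
coefficients are capped at |β| ≤ 15 and flagged when a monotone likelihood
(no events in a stratum) would push them to infinity.  The solver exists
in-package because the MI bootstrap and the selection simulations refit
Cox models tens of thousands of times and need millisecond fits.

## Missing chromosome-3 status

Typing is missing for most patients and the mechanism depends on tumour
size (small tumours are typed least often), so complete-case analysis
would understate risk.  Imputation model: logistic regression of P(M3) on
an intercept, five LBTD-bin dummies, indicators of metastatic and of
other-cause death, and log follow-up time, fitted on complete cases.
Outcome variables must enter an imputation model used for survival
analysis; the chosen covariate set is the natural sufficient summary of
the analysis model.  "Approximate Bayesian" proper imputation: each of the
M datasets uses a fresh coefficient vector drawn from N(β̂, Σ̂) (covariance
eigen-decomposed with negative eigenvalues clipped), then draws each
missing status Bernoulli.  Observed statuses are never altered (asserted
per dataset).  Quasi-separation or degenerate designs (single bin, all
statuses equal) fall back to a ridge-penalised fit (α = 1, covariance from
the penalised information) with a warning.

Point estimates pool per-dataset estimates by their arithmetic mean
(M = 101 at full scale; the desk profile M = 11 is the package default for
fits and tests).  Confidence intervals use the pooled-sample MI bootstrap:
B subject-level resamples within each imputed dataset (B = 2000 full
scale, 200 desk), all M·B estimates pooled into one empirical distribution,
CI = 2.5/97.5 percentiles.  Rubin's rules are deliberately not used — the
percentile pooling *is* the interval.  Resamples where a cell is empty
return NaN for that cell and are excluded from its percentile (counted and
logged); a cell with no events contributes a legitimate 0.

## Factor ranking and backward selection

A factor's importance for a cause-specific hazard is its rescaled AIC:
LR χ² − 2·Δdf comparing the full Cox model with the model without the
factor.  Positive values mean the factor earns its degrees of freedom;
negative values signal overfitting risk (for a pure-noise 1-df factor the
value averages E[χ²₁] − 2 = −1, which the tests confirm by simulation).
The reported ranking uses single-deletion values from the full model;
retention uses sequential backward deletion (remove the most negative,
refit, repeat until all remaining are positive) — both single and
sequential retention rules are implemented, sequential being the default.
With missing chromosome-3 status, selection runs within each imputed
dataset and averages the values.  Codings: LBTD as the six-level factor
(5 df), thickness and mitotic count continuous, all other factors binary.
Constant or collinear design columns are dropped with a warning.

## Concordance

Discrimination uses the fixed-horizon competing-risks C-index at τ ∈
{2, 5, 10} years.  Pair (i, j) is comparable when i dies of metastasis at
Tᵢ ≤ τ and j is known metastasis-free at Tᵢ: either Tⱼ > Tᵢ, or j died of
a competing cause (event-free for metastasis at every horizon).  Subjects
censored at or before Tᵢ are not comparable; no IPCW weighting is applied
(the plain estimator is pinned by an exhaustive-pair oracle; a weighted
variant is a possible future flag, out of scope here).  Tied risks count
½.  Risk scores are model-based: a subject's group CIF at τ, pooled over
imputed datasets when status is missing.  The index is invariant to
strictly monotone transforms of the scores and maps C → 1−C when all risks
are negated; both properties are tested exactly.

## Prognostic tables

Three panels (D3, M3, unknown status) × six LBTD rows × {2, 5, 10} years ×
two age columns.  The unknown panel is the LBTD-only model's *marginal*
estimate, not an average of the D3/M3 panels, matching the two-model
framing (with C3S / without C3S).  Cells with no subjects are reported
unavailable ("—"), never fabricated.  Rendered percentages use one decimal
below 10% and two significant figures above, with crude summary
percentages rounded half-up in integer arithmetic so x.x5 cases are exact.

## Synthetic cohort generator

The generator reproduces the structure the analysis assumes, with defaults
chosen to resemble a large UK referral cohort qualitatively:

| parameter | default | rationale |
|---|---|---|
| LBTD | log-normal(log 12, 0.32) truncated to [2.4, 28] mm | median 12 mm, IQR ≈ 9.6–14.8 mm |
| age | normal(62, 14) truncated to [20, 99] y | ~10% of patients > 80 y |
| P(M3) per bin | 0.22 → 0.79 rising | monosomy prevalence rises with diameter |
| P(untyped) per bin | 0.85 → 0.50 falling | small tumours least often typed (MAR given LBTD) |
| λ_met per (bin, C3S), /y | D3 0.002–0.022; M3 0.030–0.220 | 10-y cell risks spanning ~1–80% |
| λ_oth, /y | 0.02 (≤80 y), 0.10 (>80 y) | sharply higher elderly background mortality |
| censoring | exp(0.04) ∧ 25 y admin horizon | long but finite follow-up |

Hazards are constant per cell so the ground truth is closed form:
F_met(t) = λ_m/(λ_m+λ_o) · (1 − e^{−(λ_m+λ_o)t}); marginal group truths are
exact mixtures over the population cell probabilities.  Missingness
depends only on the observed LBTD bin (missing at random); an optional
log-odds shift for deceased subjects enables MNAR sensitivity analyses.
Metastatic deaths are certified definite/probable (80/20) and other-cause
deaths spread over the four non-metastatic categories, exercising the
registry coding rule.

What the generator does **not** emulate: calendar-time referral drift,
non-constant (e.g. accelerating-then-plateauing) cause-specific hazards,
measurement error in diameter, correlation between typing availability and
treatment era, or informative censoring.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated structure, not
fidelity of any particular fitted number to a real cohort.

## Test-suite problem sizes and tolerances

Simulation-backed checks use: estimator consistency at n = 5000 with the
Monte-Carlo SE estimated from 40 independent replicates (deviation < 3 MC
SE per cell and horizon); MI validity at n = 4000 with 40% flat MAR
missingness, M = 11 (pooled vs complete-data CIFs within 3 binomial SEs);
bootstrap coverage over 200 replicates at n = 400, M = 5, B = 100,
counting cells chosen *ex ante* from the generating model (expected
metastatic deaths by 5 y ≥ 3 — percentile intervals are not meaningful
below that), requiring pooled coverage in [0.90, 0.99]; selection recovery
over 50 replicates at n = 5000 (true factors in the top two in ≥ 95%);
and exhaustive enumeration of all event/censor patterns for cohorts of up
to 8 subjects (plus tied-time patterns) against a hand-evaluation oracle.
Unknown-panel betweenness is asserted within 3 binomial SEs of the bin
size, since the marginal and status-specific estimators share no exact
finite-sample mixture identity.

## Known limitations

* The composition of the other-cause Cox model with the group CIFs is one
  faithful reading of "a Cox model for the competing risks"; the exact
  published mechanism is not spelled out, which is why it lives behind a
  single swappable operation.
* The imputation model's covariates beyond (LBTD bin, event type, log
  time) are a design decision; richer models (e.g. interactions) may be
  needed for cohorts with stronger missingness mechanisms.
* Percentile bootstrap intervals undercover in cells with very few
  events; such cells should be (and are) reported unavailable rather than
  trusted.
* TNM staging, IPCW-weighted concordance and non-constant-hazard
  generators are out of scope.
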