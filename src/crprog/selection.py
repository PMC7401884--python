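"""Backward selection and rescaled-AIC ranking of risk factors.

Candidate predictors of the cause-specific hazard (metastatic or other-cause
death) are ranked by the rescaled Akaike Information Criterion of their
removal from the full Cox model:

    rescaled AIC = LR chi-square - 2 * delta-df

where LR = 2*(loglik_full - loglik_reduced).  A positive value means the
factor carries more information than its degrees of freedom cost; a negative
value signals overfitting risk.  Backward selection repeatedly removes the
factor whose deletion has the most negative value until every remaining
factor is positive.

Factor codings: LBTD enters as the six-level bin factor (5 df), tumour
thickness and mitotic count as continuous, everything else binary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coxph import fit_coxph, null_partial_loglik

__all__ = [
    "FactorFit",
    "FactorRanking",
    "AVAILABLE_FACTORS",
    "fit_cause_specific_cox",
    "rescaled_aic",
    "backward_select",
    "backward_select_mi",
]


def _binary(col, true_value=None):
    def build(df):
        x = df[col]
        if true_value is not None:
            v = (x == true_value).astype(float).to_numpy()
        else:
            v = x.astype(float).to_numpy()
        return v[:, None], [col]

    return build


def _continuous(col):
    def build(df):
        return df[col].to_numpy(dtype=float)[:, None], [col]

    return build


def _lbtd(df):
    bins = df["lbtd_bin"].to_numpy()
    cols = [(bins == b).astype(float) for b in range(2, 7)]
    return np.column_stack(cols), [f"lbtd_bin{b}" for b in range(2, 7)]


def _c3s(df):
    m3 = df["m3"].to_numpy(dtype=float)
    if np.isnan(m3).any():
        raise ValueError(
            "c3s factor has missing values; use backward_select_mi on an "
            "imputation ensemble"
        )
    return m3[:, None], ["m3"]


#: factor name -> design-column builder
AVAILABLE_FACTORS = {
    "lbtd": _lbtd,
    "c3s": _c3s,
    "age": _binary("age_bin"),
    "sex": _binary("sex", "male"),
    "ciliary_body": _binary("ciliary_body"),
    "extraocular": _binary("extraocular"),
    "chr8q": _binary("chr8q", "gain"),
    "closed_loops": _binary("closed_loops"),
    "epithelioid": _binary("epithelioid"),
    "thickness": _continuous("thickness_mm"),
    "mitotic_count": _continuous("mitotic_count"),
}


@dataclass
class FactorFit:
    """One cause-specific Cox fit over a set of factors."""

    loglik: float
    loglik_null: float
    df: int
    factors: tuple[str, ...]
    coefficients: dict
    cause: int


def _build_design(df: pd.DataFrame, factors):
    blocks, names, spans = [], [], {}
    start = 0
    for f in factors:
        if f not in AVAILABLE_FACTORS:
            raise KeyError(f"unknown factor {f!r}")
        X_f, cols = AVAILABLE_FACTORS[f](df)
        blocks.append(X_f)
        names.extend(cols)
        spans[f] = slice(start, start + X_f.shape[1])
        start += X_f.shape[1]
    X = np.column_stack(blocks) if blocks else np.empty((len(df), 0))
    # drop constant or linearly dependent columns (duplicated factors etc.)
    keep = []
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            warnings.warn(f"dropping constant design column {names[j]!r}", stacklevel=3)
            continue
        cand = keep + [j]
        if np.linalg.matrix_rank(X[:, cand]) < len(cand):
            warnings.warn(f"dropping collinear design column {names[j]!r}", stacklevel=3)
            continue
        keep.append(j)
    return X[:, keep], [names[j] for j in keep]


def fit_cause_specific_cox(df: pd.DataFrame, factors, cause: int = 1) -> FactorFit:
    """Partial-likelihood fit of the listed factors for one cause.

    Events of the competing cause are treated as censoring.  Collinear or
    constant factor columns are dropped with a warning.
    """
    time = df["time"].to_numpy(dtype=float)
    event = (df["event"].to_numpy() == cause)
    if not event.any():
        raise ValueError(f"no events of cause {cause}")
    X, names = _build_design(df, list(factors))
    if X.shape[1] == 0:
        ll0 = null_partial_loglik(time, event)
        return FactorFit(loglik=ll0, loglik_null=ll0, df=0,
                         factors=tuple(factors), coefficients={}, cause=cause)
    res = fit_coxph(X, time, event)
    return FactorFit(
        loglik=res.loglik,
        loglik_null=res.loglik_null,
        df=res.df,
        factors=tuple(factors),
        coefficients=dict(zip(names, res.beta)),
        cause=cause,
    )


def rescaled_aic(full_fit: FactorFit, reduced_fit: FactorFit) -> float:
    """LR chi-square minus twice the df difference between nested fits."""
    if reduced_fit.df > full_fit.df or not set(reduced_fit.factors) <= set(full_fit.factors):
        raise ValueError("reduced fit is not nested in full fit")
    lr = 2.0 * (full_fit.loglik - reduced_fit.loglik)
    ddf = full_fit.df - reduced_fit.df
    return float(lr - 2.0 * ddf)


@dataclass
class FactorRanking:
    """Risk factors ranked by rescaled AIC (descending), with the retained
    subset after backward selection."""

    entries: list  # (factor, rescaled_aic, delta_df)
    retained: list
    cause: int
    mode: str = "sequential"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["factor", "rescaled_aic", "df"])


def _drop_one_values(df, factors, cause, full=None):
    full = full or fit_cause_specific_cox(df, factors, cause)
    values = {}
    for f in factors:
        reduced = fit_cause_specific_cox(df, [g for g in factors if g != f], cause)
        values[f] = (rescaled_aic(full, reduced), full.df - reduced.df)
    return values, full


def backward_select(
    df: pd.DataFrame, factors, cause: int = 1, mode: str = "sequential"
) -> FactorRanking:
    """Rank factors by rescaled AIC and select the informative subset.

    The reported ranking uses single-deletion values from the full model
    (one value per factor, as in a factor-importance table).  With
    ``mode="sequential"`` (default) factors are then removed one at a time —
    most negative value first, recomputing after each removal — until all
    remaining factors have positive values; ``mode="single"`` retains
    exactly the factors with positive full-model values.
    """
    factors = list(factors)
    if not factors:
        raise ValueError("at least one factor required")
    values, _ = _drop_one_values(df, factors, cause)
    entries = sorted(
        [(f, v, ddf) for f, (v, ddf) in values.items()], key=lambda e: -e[1]
    )
    if mode == "single":
        retained = [f for f, v, _ in entries if v > 0]
    elif mode == "sequential":
        current = list(factors)
        current_values = {f: v for f, (v, _) in values.items()}
        while current:
            worst = min(current, key=lambda f: current_values[f])
            if current_values[worst] > 0:
                break
            current.remove(worst)
            if not current:
                break
            new_values, _ = _drop_one_values(df, current, cause)
            current_values = {f: v for f, (v, _) in new_values.items()}
        retained = current
    else:
        raise ValueError("mode must be 'sequential' or 'single'")
    return FactorRanking(entries=entries, retained=retained, cause=cause, mode=mode)


def backward_select_mi(ensemble, factors, cause: int = 1, mode: str = "sequential") -> FactorRanking:
    """Selection with missing chromosome-3 status: run the single-deletion
    ranking within each imputed dataset and average the rescaled AIC values
    across datasets; the sequential-removal rule is then applied to the
    averaged values."""
    factors = list(factors)
    acc = {f: [] for f in factors}
    ddfs = {}
    for ds in ensemble.datasets():
        values, _ = _drop_one_values(ds, factors, cause)
        for f, (v, ddf) in values.items():
            acc[f].append(v)
            ddfs[f] = ddf
    entries = sorted(
        [(f, float(np.mean(acc[f])), ddfs[f]) for f in factors], key=lambda e: -e[1]
    )
    retained = [f for f, v, _ in entries if v > 0]
    return FactorRanking(entries=entries, retained=retained, cause=cause, mode=f"mi-{mode}")
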