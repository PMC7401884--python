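"""Competing-risks concordance index at fixed horizons.

The C-index measures how well predicted risks rank metastatic-death times.
At horizon tau, a pair (i, j) is comparable when subject i dies of the cause
of interest at T_i <= tau and subject j is known to be event-free from that
cause at T_i: either j is still under observation after T_i, or j died of a
competing cause (which makes j event-free for the cause at every horizon).
Subjects censored at or before T_i are not comparable (no inverse-
probability-of-censoring weighting is applied).  The pair is concordant when
risk_i > risk_j; exactly tied risks count one half:

    C = (concordant + ties/2) / comparable

On single-cause data with no censoring this reduces to Harrell's C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imputation import MIConfig, impute_c3s, mi_bootstrap_ci
from .nonparametric import group_cif_at

__all__ = ["CIndexResult", "cr_cindex", "model_risk_scores", "bootstrap_cindex"]


@dataclass
class CIndexResult:
    tau: float
    cindex: float
    comparable: int
    concordant: int
    tied: int
    ci: tuple[float, float] | None = None


def cr_cindex(risk, time, event, tau: float, cause: int = 1) -> CIndexResult:
    """Fixed-horizon competing-risks concordance of one risk score.

    ``risk`` is one predicted probability (or any monotone score) per
    subject; higher scores should mean earlier events of the cause.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=np.int64)
    if tau <= 0:
        raise ValueError("tau must be positive")
    cases = np.flatnonzero((event == cause) & (time <= tau))
    if cases.size == 0:
        raise ValueError("no comparable pairs: no events of the cause by tau")
    competing = event == (2 if cause == 1 else 1)
    # comparable[c, j]: j still under observation after T_c, or j had a
    # competing event (event-free for the cause at all horizons)
    comp = (time[None, :] > time[cases, None]) | competing[None, :]
    comp[np.arange(cases.size), cases] = False
    diff = risk[cases, None] - risk[None, :]
    concordant = int(np.sum(comp & (diff > 0)))
    tied = int(np.sum(comp & (diff == 0)))
    comparable = int(comp.sum())
    if comparable == 0:
        raise ValueError("no comparable pairs")
    c = (concordant + 0.5 * tied) / comparable
    return CIndexResult(tau=float(tau), cindex=float(c), comparable=comparable,
                        concordant=concordant, tied=tied)


def _group_codes(df, model: str) -> tuple[np.ndarray, int]:
    bins = df["lbtd_bin"].to_numpy(dtype=np.int64)
    if model == "lbtd":
        return bins - 1, 6
    if model == "lbtd_c3s":
        m3 = df["m3"].to_numpy(dtype=float)
        if np.isnan(m3).any():
            raise ValueError("lbtd_c3s risk scores need completed chromosome-3 status")
        return (bins - 1) * 2 + m3.astype(np.int64), 12
    raise ValueError("model must be 'lbtd' or 'lbtd_c3s'")


def model_risk_scores(df, model: str, tau: float, cause: int = 1) -> np.ndarray:
    """Per-subject risk score = the subject's group CIF at the horizon.

    Groups are the 6 LBTD bins (``model="lbtd"``) or the 12 LBTD x C3S cells
    (``model="lbtd_c3s"``, requiring completed chromosome-3 status).
    """
    codes, n_groups = _group_codes(df, model)
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=np.int64)
    cifs = group_cif_at(time, event, codes, n_groups, tau, cause)
    return cifs[codes]


def bootstrap_cindex(
    cohort,
    model: str,
    taus=(2.0, 5.0, 10.0),
    config: MIConfig | None = None,
    seed: int | None = None,
    cause: int = 1,
) -> list[CIndexResult]:
    """C-index per horizon with pooled-sample MI bootstrap percentile CIs.

    Risks are re-estimated inside every resample from that resample's group
    CIFs; with missing chromosome-3 status the estimates pool over imputed
    datasets exactly as the absolute-risk CIs do.  Degenerate resamples (no
    comparable pairs) contribute NaN and are excluded from the percentiles.
    """
    config = config or MIConfig.desk()
    taus = [float(t) for t in taus]

    def estimator(df):
        out = np.empty(len(taus))
        time = df["time"].to_numpy(dtype=float)
        event = df["event"].to_numpy(dtype=np.int64)
        for k, tau in enumerate(taus):
            try:
                risks = model_risk_scores(df, model, tau, cause)
                out[k] = cr_cindex(risks, time, event, tau, cause).cindex
            except ValueError:
                out[k] = np.nan
        return out

    cols = ["time", "event", "lbtd_bin", "m3"]
    needs_mi = model == "lbtd_c3s" and cohort.df["m3"].isna().any()
    ensemble = impute_c3s(cohort, config=config, seed=seed) if needs_mi else None
    if ensemble is None:
        # no imputation needed: a single "completed" dataset suffices
        one = config.with_(m=1)
        res = mi_bootstrap_ci(cohort, estimator, config=one, seed=seed,
                              ensemble=_identity_ensemble(cohort), columns=cols)
    else:
        res = mi_bootstrap_ci(cohort, estimator, config=config, seed=seed,
                              ensemble=ensemble, columns=cols)
    results = []
    for k, tau in enumerate(taus):
        results.append(
            CIndexResult(
                tau=tau,
                cindex=float(res.point[k]),
                comparable=-1,
                concordant=-1,
                tied=-1,
                ci=(float(res.lower[k]), float(res.upper[k])),
            )
        )
    return results


def _identity_ensemble(cohort):
    from .imputation import MIEnsemble

    m3 = cohort.df["m3"].to_numpy(dtype=float)
    filled = np.nan_to_num(m3, nan=0.0).astype(np.int64)
    ens = MIEnsemble(cohort=cohort, m3_draws=[filled], model=None)
    return ens
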