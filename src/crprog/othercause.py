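"""Other-cause mortality model and its composition with group CIFs.

Death from causes other than metastatic melanoma is modelled semi-
parametrically: a Cox proportional-hazards model with the single binary
covariate "age at treatment > 80 years", whose Breslow baseline hazard is
shared across all tumour groups.  Age-specific absolute risks of metastatic
death are then obtained by a discrete product-integral that combines a
group's cause-specific metastatic hazard increments with the age-scaled
other-cause increments:

    S(u)   = prod_{v <= u} (1 - dL_met,k(v) - exp(b*z) dL_oth,0(v))
    F_k(t) = sum_{u <= t} S(u-) dL_met,k(u)

With b = 0 and the other-cause increments taken from the same group, this
reduces exactly to the group's Aalen-Johansen CIF.  A higher other-cause
hazard (age > 80) yields a pointwise lower metastatic CIF: elderly patients
are more likely to die of something else first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .coxph import fit_coxph, breslow_baseline
from .nonparametric import CIFCurve

__all__ = ["CoxFit", "fit_cox_other_cause", "combine_cif_with_cox"]


@dataclass
class CoxFit:
    """Cox model for other-cause death with binary age (>80 yr).

    ``baseline_times`` / ``baseline_increments`` hold the Breslow baseline
    cumulative-hazard increments for the reference group (age <= 80).
    """

    log_hr: float
    se: float
    loglik: float
    loglik_null: float
    df: int
    n_events: int
    baseline_times: np.ndarray
    baseline_increments: np.ndarray
    capped: bool = False

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.log_hr))


def fit_cox_other_cause(time, event, age_bin) -> CoxFit:
    """Fit the other-cause Cox model, censoring metastatic deaths.

    Raises if there are no other-cause deaths; warns (and the coefficient is
    capped) when one age stratum has no events, which makes the partial
    likelihood monotone.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=np.int64)
    z = np.asarray(age_bin, dtype=float)
    oth = event == 2
    if not oth.any():
        raise ValueError("no other-cause deaths: other-cause model not identifiable")
    for stratum in (0.0, 1.0):
        if not oth[z == stratum].any():
            warnings.warn(
                "no other-cause events in one age stratum; "
                "age coefficient capped (monotone likelihood)",
                stacklevel=2,
            )
    res = fit_coxph(z[:, None], time, oth)
    bt, binc = breslow_baseline(res.beta, z[:, None], time, oth)
    return CoxFit(
        log_hr=float(res.beta[0]),
        se=float(res.se[0]),
        loglik=res.loglik,
        loglik_null=res.loglik_null,
        df=res.df,
        n_events=res.n_events,
        baseline_times=bt,
        baseline_increments=binc,
        capped=res.capped,
    )


def combine_cif_with_cox(
    met_times: np.ndarray,
    met_increments: np.ndarray,
    cox: CoxFit,
    age_bin: int,
    group=None,
) -> CIFCurve:
    """Age-specific metastatic CIF from group hazard increments + Cox model.

    The two increment processes are merged onto a common grid; at each time
    the overall-survival factor is ``1 - dL_met - dL_oth``.  If the summed
    increment exceeds 1 (possible only in pathological tiny strata) both
    increments are scaled down proportionally so the factor stays in [0, 1].
    """
    met_times = np.asarray(met_times, dtype=float)
    met_increments = np.asarray(met_increments, dtype=float)
    mult = float(np.exp(cox.log_hr * age_bin))
    grid = np.union1d(met_times, cox.baseline_times)
    dm = np.zeros(grid.size)
    dm[np.searchsorted(grid, met_times)] = met_increments
    do = np.zeros(grid.size)
    do[np.searchsorted(grid, cox.baseline_times)] = cox.baseline_increments * mult
    total = dm + do
    over = total > 1.0
    if over.any():
        scale = np.where(over, 1.0 / total, 1.0)
        dm = dm * scale
        do = do * scale
    factor = 1.0 - dm - do
    if np.any(factor < -1e-12):
        raise ValueError("negative survival factor after clipping (pathological input)")
    s_left = np.concatenate(([1.0], np.cumprod(np.clip(factor, 0.0, 1.0))[:-1]))
    values = np.cumsum(s_left * dm)
    return CIFCurve(times=grid, values=values, cause=1, n=0, group=group)
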