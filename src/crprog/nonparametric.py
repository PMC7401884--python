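"""Nonparametric competing-risks estimation.

The absolute risk (cumulative incidence) of metastatic death in group ``k``
is estimated by the Aalen-Johansen form

    F_k(t) = sum_{u <= t}  S_k(u-) * dN_k(u) / Y_k(u)

where ``N_k`` counts metastatic deaths in the group, ``Y_k(u)`` is the number
still at risk just before ``u``, and ``S_k(u-)`` is the left-hand limit of
the group's Kaplan-Meier estimate of all-cause survival.  No independence
assumption is made about the competing risk of death from other causes.

Both curve objects are right-continuous step functions.  Event codes follow
:mod:`crprog.cohort`: 0 censored, 1 metastatic death, 2 other-cause death.
Ties: deaths of different causes at the same time share the same at-risk set
and left-limit survival; censorings at a death time are removed after the
death (standard convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurvivalCurve",
    "CIFCurve",
    "km_all_cause",
    "aalen_cif",
    "competing_cifs",
    "nelson_aalen_cause_specific",
    "cif_at",
    "group_cif_at",
    "eval_cif",
]


def _step_lookup(times: np.ndarray, values: np.ndarray, t, start: float, side: str):
    idx = np.searchsorted(times, np.asarray(t, dtype=float), side=side) - 1
    vals = np.concatenate(([start], values))[idx + 1]
    return float(vals) if np.isscalar(t) else vals


@dataclass
class SurvivalCurve:
    """Right-continuous Kaplan-Meier step function for one group.

    ``times`` are the distinct death times, ``survival`` the value just after
    each, ``at_risk`` the number at risk just before each.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_deaths: np.ndarray
    n: int
    group: object = None

    def survival_at(self, t):
        """S(t), right-continuous."""
        return _step_lookup(self.times, self.survival, t, 1.0, "right")

    def left_limit(self, t):
        """S(t-), the value just before t."""
        return _step_lookup(self.times, self.survival, t, 1.0, "left")


@dataclass
class CIFCurve:
    """Right-continuous cumulative-incidence step function for one cause."""

    times: np.ndarray
    values: np.ndarray
    cause: int
    n: int
    group: object = None

    def cif_at(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("t must be nonnegative")
        return _step_lookup(self.times, self.values, t, 0.0, "right")


def _check_group(time: np.ndarray, event: np.ndarray):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=np.int64)
    if time.size == 0:
        raise ValueError("empty group")
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("times must be positive and finite")
    return time, event


def _death_table(time: np.ndarray, event: np.ndarray):
    """Distinct death times with at-risk counts and per-cause death counts."""
    n = time.size
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    death_mask = e_sorted > 0
    td = t_sorted[death_mask]
    ed = e_sorted[death_mask]
    u = np.unique(td)
    at_risk = n - np.searchsorted(t_sorted, u, side="left")
    pos = np.searchsorted(u, td)
    d_all = np.bincount(pos, minlength=u.size)
    d_met = np.bincount(pos[ed == 1], minlength=u.size)
    d_oth = np.bincount(pos[ed == 2], minlength=u.size)
    return u, at_risk, d_all, d_met, d_oth


def km_all_cause(time, event, group=None) -> SurvivalCurve:
    """Kaplan-Meier estimate of all-cause survival (any death is an event)."""
    time, event = _check_group(time, event)
    u, y, d_all, _, _ = _death_table(time, event)
    surv = np.cumprod(1.0 - d_all / y)
    return SurvivalCurve(times=u, survival=surv, at_risk=y, n_deaths=d_all,
                         n=time.size, group=group)


def competing_cifs(time, event, group=None) -> tuple[SurvivalCurve, dict[int, CIFCurve]]:
    """All-cause KM plus the CIF of each cause, on a shared time grid.

    Computed jointly so the algebraic identity
    ``F_met(t) + F_oth(t) + S(t) = 1`` holds exactly (to rounding) at every
    death time.
    """
    time, event = _check_group(time, event)
    u, y, d_all, d_met, d_oth = _death_table(time, event)
    surv = np.cumprod(1.0 - d_all / y)
    s_left = np.concatenate(([1.0], surv[:-1]))
    km = SurvivalCurve(times=u, survival=surv, at_risk=y, n_deaths=d_all,
                       n=time.size, group=group)
    cifs = {
        1: CIFCurve(times=u, values=np.cumsum(s_left * d_met / y), cause=1,
                    n=time.size, group=group),
        2: CIFCurve(times=u, values=np.cumsum(s_left * d_oth / y), cause=2,
                    n=time.size, group=group),
    }
    return km, cifs


def aalen_cif(time, event, cause: int = 1, group=None) -> CIFCurve:
    """Aalen-Johansen cumulative incidence of one cause for one group.

    A group with no events of the cause yields a valid all-zero curve.
    """
    _, cifs = competing_cifs(time, event, group=group)
    if cause not in cifs:
        raise ValueError(f"unknown cause code {cause}")
    return cifs[cause]


def nelson_aalen_cause_specific(time, event, cause: int = 1):
    """Cause-specific Nelson-Aalen hazard increments dL(u) = dN_cause(u)/Y(u).

    Returns ``(times, increments)`` at the distinct event times of the cause
    (empty arrays when the cause never occurs).
    """
    time, event = _check_group(time, event)
    u, y, _, d_met, d_oth = _death_table(time, event)
    d_c = d_met if cause == 1 else d_oth
    keep = d_c > 0
    return u[keep], (d_c / y)[keep]


def eval_cif(curve: CIFCurve, t):
    """Right-continuous lookup of a CIF curve; 0 before the first event."""
    return curve.cif_at(t)


# ---------------------------------------------------------------------------
# Fast scalar kernels for bootstrap/simulation loops
# ---------------------------------------------------------------------------


def cif_at(time: np.ndarray, event: np.ndarray, tau: float, cause: int = 1) -> float:
    """Aalen-Johansen CIF of ``cause`` at a single horizon, minimal-overhead.

    Equivalent to ``aalen_cif(time, event, cause).cif_at(tau)``; an empty
    group or a group with no deaths by ``tau`` returns 0.0.
    """
    n = time.size
    if n == 0:
        return 0.0
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    death = (e > 0) & (t <= tau)
    if not death.any():
        return 0.0
    td = t[death]
    ed = e[death]
    u = np.unique(td)
    pos = np.searchsorted(u, td)
    d_all = np.bincount(pos, minlength=u.size).astype(float)
    d_c = np.bincount(pos[ed == cause], minlength=u.size).astype(float)
    y = (n - np.searchsorted(t, u, side="left")).astype(float)
    surv = np.cumprod(1.0 - d_all / y)
    s_left = np.concatenate(([1.0], surv[:-1]))
    return float(np.sum(s_left * d_c / y))


def group_cif_at(
    time: np.ndarray,
    event: np.ndarray,
    group_codes: np.ndarray,
    n_groups: int,
    tau: float,
    cause: int = 1,
) -> np.ndarray:
    """Per-group ``cif_at`` for integer group codes 0..n_groups-1.

    Groups with no members contribute 0.0 (they are logged by callers that
    need to distinguish empty cells).
    """
    out = np.zeros(n_groups, dtype=float)
    for g in range(n_groups):
        mask = group_codes == g
        if mask.any():
            out[g] = cif_at(time[mask], event[mask], tau, cause)
    return out
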