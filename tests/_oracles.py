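"""Brute-force reference implementations used only as test oracles.

Everything here is written as plainly as possible (explicit loops over
subjects and time points, no shared code with the package) so it can serve
as an independent check of the vectorised estimators.
"""

import numpy as np
from scipy import integrate


def brute_km(times, events, t_eval):
    """Product-limit all-cause survival at t_eval, by definition."""
    distinct = sorted({t for t, e in zip(times, events) if e > 0 and t <= t_eval})
    s = 1.0
    for u in distinct:
        at_risk = sum(1 for t in times if t >= u)
        deaths = sum(1 for t, e in zip(times, events) if t == u and e > 0)
        s *= 1.0 - deaths / at_risk
    return s


def brute_cif(times, events, cause, t_eval):
    """Aalen-Johansen cumulative incidence at t_eval, by definition:
    sum over event times u <= t_eval of S(u-) * d_cause(u) / Y(u)."""
    distinct = sorted({t for t, e in zip(times, events) if e > 0 and t <= t_eval})
    total = 0.0
    for u in distinct:
        # left limit of KM: survival just before u
        s_left = 1.0
        for v in distinct:
            if v >= u:
                break
            at_risk_v = sum(1 for t in times if t >= v)
            deaths_v = sum(1 for t, e in zip(times, events) if t == v and e > 0)
            s_left *= 1.0 - deaths_v / at_risk_v
        at_risk = sum(1 for t in times if t >= u)
        d_c = sum(1 for t, e in zip(times, events) if t == u and e == cause)
        total += s_left * d_c / at_risk
    return total


def brute_decomposition(times, events):
    """Stepwise hand evaluation of the competing-risks decomposition.

    Walks the distinct death times in order keeping a running survival,
    exactly as one would by hand: returns a list of
    (u, S(u), F_cause1(u), F_cause2(u)).
    """
    out = []
    s = 1.0
    f1 = f2 = 0.0
    for u in sorted({t for t, e in zip(times, events) if e > 0}):
        at_risk = sum(1 for t in times if t >= u)
        d1 = sum(1 for t, e in zip(times, events) if t == u and e == 1)
        d2 = sum(1 for t, e in zip(times, events) if t == u and e == 2)
        f1 += s * d1 / at_risk
        f2 += s * d2 / at_risk
        s *= 1.0 - (d1 + d2) / at_risk
        out.append((u, s, f1, f2))
    return out


def brute_cindex(risks, times, events, tau, cause=1):
    """Fixed-horizon competing-risks concordance by exhaustive pair
    enumeration.  Pair (i, j): i dies of the cause by tau; j survives past
    T_i or died of the competing cause."""
    competing = 2 if cause == 1 else 1
    concordant = tied = comparable = 0
    n = len(times)
    for i in range(n):
        if events[i] != cause or times[i] > tau:
            continue
        for j in range(n):
            if j == i:
                continue
            if times[j] > times[i] or events[j] == competing:
                comparable += 1
                if risks[i] > risks[j]:
                    concordant += 1
                elif risks[i] == risks[j]:
                    tied += 1
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return (concordant + 0.5 * tied) / comparable, comparable, concordant, tied


def integrate_true_cif(lam_met, lam_oth, t):
    """Numerically integrate int_0^t S(u) lam_met du for constant hazards."""
    val, _ = integrate.quad(
        lambda u: np.exp(-(lam_met + lam_oth) * u) * lam_met, 0.0, t
    )
    return val


def enumerate_small_cohorts(max_n=8, tie_n=(4, 5)):
    """Yield (times, events) covering all censor/cause patterns.

    For n up to ``max_n``: distinct times 1..n with every assignment of
    {censored, cause 1, cause 2}.  For n in ``tie_n``: every multiset of
    times drawn from {1, 2, 3} (ties included) with every event assignment.
    """
    from itertools import combinations_with_replacement, product

    for n in range(1, max_n + 1):
        times = list(range(1, n + 1))
        for events in product((0, 1, 2), repeat=n):
            yield times, list(events)
    for n in tie_n:
        for times in combinations_with_replacement((1, 2, 3), n):
            if len(set(times)) == len(times):
                continue  # distinct patterns already covered
            for events in product((0, 1, 2), repeat=n):
                yield list(times), list(events)
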