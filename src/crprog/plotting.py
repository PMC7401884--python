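"""Cumulative-incidence plots (matplotlib)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_cif_curves"]


def plot_cif_curves(curves, labels=None, ax=None, xmax=None, title=None):
    """Step plot of one or more cumulative-incidence curves.

    Parameters
    ----------
    curves : iterable of CIFCurve
    labels : optional legend labels, one per curve
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    curves = list(curves)
    labels = labels or [str(c.group) if c.group is not None else f"curve {i}"
                        for i, c in enumerate(curves)]
    for curve, label in zip(curves, labels):
        t = np.concatenate(([0.0], curve.times))
        v = np.concatenate(([0.0], curve.values))
        ax.step(t, v, where="post", label=label)
    ax.set_xlabel("years after treatment")
    ax.set_ylabel("absolute risk (cumulative incidence)")
    ax.set_ylim(0, 1)
    if xmax is not None:
        ax.set_xlim(0, xmax)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
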