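"""Assembly and rendering of the prognostic risk tables.

The clinical deliverable is a paper-form table of absolute risks of
metastatic death with 95% CIs: six LBTD rows; three panels (disomy 3,
monosomy 3, unknown chromosome-3 status); columns for horizons 2, 5 and 10
years crossed with the two age groups.  The D3/M3 panels come from the 12
LBTD x C3S groups (with multiple imputation completing missing statuses and
arithmetic-mean pooling across imputed datasets); the unknown panel is the
LBTD-only model's marginal estimate over chromosome-3 status, not an
average of the other two panels.  Age columns are produced by combining
each group's metastatic hazard increments with the shared age-scaled
other-cause Cox hazard.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import LBTD_BIN_LABELS, AGE_BIN_LABELS, Cohort
from .imputation import MIConfig, MIBootstrapResult, impute_c3s, mi_bootstrap_ci
from .nonparametric import nelson_aalen_cause_specific
from .othercause import combine_cif_with_cox, fit_cox_other_cause

__all__ = ["PrognosticTable", "build_prognostic_table", "render_table", "format_risk"]

PANELS = ("D3", "M3", "unknown")
HORIZONS = (2.0, 5.0, 10.0)
#: cells with fewer subjects than this are reported as unavailable
MIN_CELL_N = 1


@dataclass
class PrognosticTable:
    """Absolute risks of metastatic death (fractions in [0, 1]).

    Arrays are indexed ``[panel, lbtd_bin-1, age_bin, horizon]`` with panels
    (D3, M3, unknown), age 0 = "<81 yr", 1 = ">80 yr" and horizons 2/5/10
    years.  ``available`` marks cells whose group had at least one subject
    in every imputed dataset.  ``n_by_panel_bin`` holds pooled group sizes.
    """

    risk: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    available: np.ndarray
    n_by_panel_bin: np.ndarray
    horizons: tuple[float, ...] = HORIZONS
    meta: dict = field(default_factory=dict)

    def cell(self, panel: str, lbtd_bin: int, age_bin: int, horizon: float):
        p = PANELS.index(panel)
        h = self.horizons.index(float(horizon))
        return (
            float(self.risk[p, lbtd_bin - 1, age_bin, h]),
            float(self.lower[p, lbtd_bin - 1, age_bin, h]),
            float(self.upper[p, lbtd_bin - 1, age_bin, h]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p, panel in enumerate(PANELS):
            for b in range(6):
                for a in range(2):
                    for h, tau in enumerate(self.horizons):
                        rows.append(
                            {
                                "panel": panel,
                                "lbtd": LBTD_BIN_LABELS[b],
                                "age": AGE_BIN_LABELS[a],
                                "horizon_years": tau,
                                "risk_pct": 100.0 * self.risk[p, b, a, h],
                                "lower_pct": 100.0 * self.lower[p, b, a, h],
                                "upper_pct": 100.0 * self.upper[p, b, a, h],
                                "available": bool(self.available[p, b]),
                            }
                        )
        return pd.DataFrame(rows)


def format_risk(pct: float) -> str:
    """Render a risk percentage: one decimal below 10%, two significant
    figures (whole percent) at 10% and above."""
    if not np.isfinite(pct):
        return "—"
    if pct < 9.95:
        return f"{pct:.1f}"
    return f"{pct:.0f}"


def _group_met_increments(df, mask):
    sub_t = df["time"].to_numpy(dtype=float)[mask]
    sub_e = df["event"].to_numpy(dtype=np.int64)[mask]
    if sub_t.size == 0:
        return None
    return nelson_aalen_cause_specific(sub_t, sub_e, cause=1)


def _table_values(df: pd.DataFrame, horizons=HORIZONS) -> np.ndarray:
    """Flat [panel, bin, age, horizon] risk array for one completed cohort.

    Empty groups yield NaN cells (never fabricated values).
    """
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=np.int64)
    age = df["age_bin"].to_numpy(dtype=np.int64)
    bins = df["lbtd_bin"].to_numpy(dtype=np.int64)
    m3 = df["m3"].to_numpy(dtype=float)
    try:
        cox = fit_cox_other_cause(time, event, age)
    except ValueError:
        return np.full(len(PANELS) * 6 * 2 * len(horizons), np.nan)
    out = np.full((len(PANELS), 6, 2, len(horizons)), np.nan)
    taus = np.asarray(horizons)
    for p, panel in enumerate(PANELS):
        for b in range(1, 7):
            if panel == "unknown":
                mask = bins == b
            else:
                mask = (bins == b) & (m3 == (1.0 if panel == "M3" else 0.0))
            inc = _group_met_increments(df, mask)
            if inc is None:
                continue
            for a in (0, 1):
                curve = combine_cif_with_cox(inc[0], inc[1], cox, a)
                out[p, b - 1, a, :] = curve.cif_at(taus)
    return out.ravel()


def build_prognostic_table(
    cohort: Cohort,
    config: MIConfig | None = None,
    seed: int | None = None,
    with_ci: bool = True,
) -> PrognosticTable:
    """Build the three-panel prognostic table from a coded cohort.

    Point estimates pool the per-imputed-dataset estimates; CIs come from
    the pooled-sample MI bootstrap.  Cells whose group is empty are flagged
    unavailable (NaN), never fabricated.
    """
    config = config or MIConfig.desk()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = (len(PANELS), 6, 2, len(HORIZONS))
    ensemble = impute_c3s(cohort, config=config, seed=int(rng.integers(2**31)))

    if with_ci:
        res: MIBootstrapResult = mi_bootstrap_ci(
            cohort, _table_values, config=config,
            seed=int(rng.integers(2**31)), ensemble=ensemble,
            columns=["time", "event", "age_bin", "lbtd_bin", "m3"],
        )
        point, lower, upper = (a.reshape(shape) for a in (res.point, res.lower, res.upper))
    else:
        points = np.vstack([_table_values(ds) for ds in ensemble.datasets()])
        point = points.mean(axis=0).reshape(shape)
        lower = np.full(shape, np.nan)
        upper = np.full(shape, np.nan)

    # pooled average group sizes (constant across datasets except for the
    # imputed D3/M3 split)
    n_pb = np.zeros((len(PANELS), 6))
    for i, ds in enumerate(ensemble.datasets()):
        bins = ds["lbtd_bin"].to_numpy()
        m3 = ds["m3"].to_numpy(dtype=float)
        for b in range(1, 7):
            n_pb[0, b - 1] += ((bins == b) & (m3 == 0.0)).sum()
            n_pb[1, b - 1] += ((bins == b) & (m3 == 1.0)).sum()
            n_pb[2, b - 1] += (bins == b).sum()
    n_pb /= ensemble.m
    available = n_pb >= MIN_CELL_N

    return PrognosticTable(
        risk=point,
        lower=lower,
        upper=upper,
        available=available,
        n_by_panel_bin=n_pb,
        meta={"m": ensemble.m, "b": config.b if with_ci else 0,
              "n": cohort.n, "n_missing_c3s": cohort.n_missing_c3s},
    )


def render_table(table: PrognosticTable, fmt: str = "markdown") -> str:
    """Render the table as ``"markdown"`` (paper-form layout, CI in
    parentheses) or ``"csv"`` (tidy, exact values; round-trips through
    pandas)."""
    if fmt == "csv":
        buf = io.StringIO()
        table.to_dataframe().to_csv(buf, index=False)
        return buf.getvalue()
    if fmt != "markdown":
        raise ValueError(f"unknown format {fmt!r}")
    panel_titles = {
        "D3": "Disomy-3 Melanoma",
        "M3": "Monosomy-3 Melanoma",
        "unknown": "Unknown Chromosome 3 Status",
    }
    lines = ["# Absolute Risk of Metastatic Death (%, 95% CI)", ""]
    header = (
        "| LBTD, mm | "
        + " | ".join(
            f"{AGE_BIN_LABELS[a]}, {int(tau)} y" for a in (0, 1) for tau in table.horizons
        )
        + " |"
    )
    for p, panel in enumerate(PANELS):
        lines.append(f"## {panel_titles[panel]}")
        lines.append(header)
        lines.append("|" + "---|" * 7)
        for b in range(6):
            cells = [LBTD_BIN_LABELS[b]]
            for a in (0, 1):
                for h in range(len(table.horizons)):
                    if not table.available[p, b] or not np.isfinite(table.risk[p, b, a, h]):
                        cells.append("—")
                        continue
                    r = format_risk(100.0 * table.risk[p, b, a, h])
                    lo, hi = table.lower[p, b, a, h], table.upper[p, b, a, h]
                    if np.isfinite(lo) and np.isfinite(hi):
                        cells.append(f"{r} ({format_risk(100 * lo)}, {format_risk(100 * hi)})")
                    else:
                        cells.append(r)
            lines.append("| " + " | ".join(cells) + " |")
        lines.append("")
    return "\n".join(lines)
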