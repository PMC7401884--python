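"""Model / Results objects tying the estimation pipeline together.

``MetastaticRiskModel`` is built from a cohort (DataFrame, CSV or
:class:`~crprog.cohort.Cohort`); ``fit()`` runs imputation of missing
chromosome-3 status, groupwise Aalen-Johansen estimation combined with the
other-cause Cox model, and (optionally) the pooled-sample MI bootstrap, and
returns a :class:`MetastaticRiskResults` carrying the prognostic table,
the other-cause fit, discrimination measures and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, summarize_cohort
from .concordance import CIndexResult, bootstrap_cindex, cr_cindex, model_risk_scores
from .imputation import MIConfig, impute_c3s
from .nonparametric import CIFCurve, nelson_aalen_cause_specific
from .othercause import CoxFit, combine_cif_with_cox, fit_cox_other_cause
from .selection import FactorRanking, backward_select, backward_select_mi
from .tables import PrognosticTable, build_prognostic_table, render_table

__all__ = ["MetastaticRiskModel", "MetastaticRiskResults"]


class MetastaticRiskModel:
    """Parsimonious competing-risks model of metastatic death.

    Parameters
    ----------
    cohort : Cohort, DataFrame or path-like
        Per-patient table (see :mod:`crprog.cohort` for the schema).
    include_c3s : bool
        If True (default), risks are stratified by the 12 LBTD x C3S groups
        with multiple imputation of missing statuses; if False, by the 6
        LBTD-only groups.
    mi_config : MIConfig
        Imputation/bootstrap profile; defaults to the desk-scale profile
        (M=11, B=200).
    """

    def __init__(self, cohort, include_c3s: bool = True, mi_config: MIConfig | None = None):
        if isinstance(cohort, Cohort):
            self.cohort = cohort
        elif isinstance(cohort, pd.DataFrame):
            self.cohort = Cohort.from_dataframe(cohort)
        else:
            self.cohort = Cohort.from_csv(cohort)
        self.include_c3s = include_c3s
        self.mi_config = mi_config or MIConfig.desk()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "MetastaticRiskModel":
        return cls(df, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MetastaticRiskModel":
        return cls(Cohort.from_csv(path), **kwargs)

    def fit(self, seed: int | None = None, compute_ci: bool = True) -> "MetastaticRiskResults":
        """Run the estimation pipeline and return the results object."""
        rng = np.random.default_rng(self.mi_config.seed if seed is None else seed)
        cohort = self.cohort
        time, event = cohort.arrays()
        age = cohort.df["age_bin"].to_numpy(dtype=np.int64)
        cox = fit_cox_other_cause(time, event, age)
        ensemble = impute_c3s(cohort, config=self.mi_config, seed=int(rng.integers(2**31)))
        table = build_prognostic_table(
            cohort, config=self.mi_config, seed=int(rng.integers(2**31)),
            with_ci=compute_ci,
        )
        return MetastaticRiskResults(
            model=self, cox_other_cause=cox, ensemble=ensemble, table=table,
            seed=seed,
        )


@dataclass
class MetastaticRiskResults:
    """Fitted absolute risks, other-cause model and diagnostics."""

    model: MetastaticRiskModel
    cox_other_cause: CoxFit
    ensemble: object
    table: PrognosticTable
    seed: int | None = None
    _rankings: dict = field(default_factory=dict, repr=False)

    @property
    def cohort(self) -> Cohort:
        return self.model.cohort

    def risk_at(self, lbtd_bin: int, horizon: float, c3s: str | None = None,
                age_bin: int = 0) -> tuple[float, float, float]:
        """Pooled absolute risk (and CI bounds) for one table cell.

        ``c3s=None`` reads the unknown-status (LBTD-only) panel.
        """
        panel = c3s if c3s in ("D3", "M3") else "unknown"
        return self.table.cell(panel, lbtd_bin, age_bin, horizon)

    def cumulative_incidence(self, lbtd_bin: int, c3s: str | None = None,
                             age_bin: int = 0) -> CIFCurve:
        """Pooled metastatic-CIF step curve for one group.

        Per-imputed-dataset curves (group hazard increments combined with
        the age-scaled other-cause hazard) are averaged on the union grid.
        """
        grids, curves = [], []
        for ds in self.ensemble.datasets():
            bins = ds["lbtd_bin"].to_numpy()
            mask = bins == lbtd_bin
            if c3s in ("D3", "M3"):
                mask &= ds["m3"].to_numpy(dtype=float) == (1.0 if c3s == "M3" else 0.0)
            t = ds["time"].to_numpy(dtype=float)[mask]
            e = ds["event"].to_numpy(dtype=np.int64)[mask]
            if t.size == 0:
                continue
            mt, minc = nelson_aalen_cause_specific(t, e, cause=1)
            curve = combine_cif_with_cox(mt, minc, self.cox_other_cause, age_bin)
            grids.append(curve.times)
            curves.append(curve)
        if not curves:
            raise ValueError("empty group")
        grid = np.unique(np.concatenate(grids)) if grids else np.array([])
        vals = np.mean([c.cif_at(grid) for c in curves], axis=0)
        return CIFCurve(times=grid, values=vals, cause=1,
                        n=0, group=(lbtd_bin, c3s, age_bin))

    def concordance(self, taus=(2.0, 5.0, 10.0), bootstrap: bool = False,
                    seed: int | None = None) -> list[CIndexResult]:
        """Metastatic-death C-index of the fitted model at each horizon."""
        model_kind = "lbtd_c3s" if self.model.include_c3s else "lbtd"
        if bootstrap:
            return bootstrap_cindex(self.cohort, model_kind, taus,
                                    config=self.model.mi_config, seed=seed)
        results = []
        df = self.cohort.df
        time, event = self.cohort.arrays()
        needs_mi = model_kind == "lbtd_c3s" and df["m3"].isna().any()
        for tau in taus:
            if needs_mi:
                risks = np.mean(
                    [model_risk_scores(ds, model_kind, tau) for ds in self.ensemble.datasets()],
                    axis=0,
                )
            else:
                risks = model_risk_scores(df, model_kind, tau)
            results.append(cr_cindex(risks, time, event, tau))
        return results

    def rank_factors(self, factors=("lbtd", "c3s", "sex", "ciliary_body", "chr8q"),
                     cause: int = 1) -> FactorRanking:
        """Rescaled-AIC factor ranking for a cause (cached per argument set)."""
        key = (tuple(factors), cause)
        if key not in self._rankings:
            if "c3s" in factors and self.cohort.df["m3"].isna().any():
                self._rankings[key] = backward_select_mi(self.ensemble, factors, cause)
            else:
                self._rankings[key] = backward_select(self.cohort.df, factors, cause)
        return self._rankings[key]

    def summary(self) -> str:
        """Human-readable fit summary."""
        c = self.cohort
        time, event = c.arrays()
        n_met = int((event == 1).sum())
        n_oth = int((event == 2).sum())
        cox = self.cox_other_cause
        lines = [
            "Competing-risks model of metastatic death from choroidal melanoma",
            "=" * 66,
            f"subjects: {c.n}   metastatic deaths: {n_met}   "
            f"other-cause deaths: {n_oth}",
            f"chromosome 3 untyped: {c.n_missing_c3s} "
            f"({100.0 * c.n_missing_c3s / c.n:.1f}%)   "
            f"imputations M={self.ensemble.m}",
            f"risk groups: {'LBTD x C3S (12)' if self.model.include_c3s else 'LBTD only (6)'}",
            "",
            "Other-cause mortality (Cox, age > 80 yr):",
            f"  log HR = {cox.log_hr:.3f} (SE {cox.se:.3f}), "
            f"HR = {cox.hazard_ratio:.2f}, events = {cox.n_events}",
            "",
            render_table(self.table, "markdown"),
        ]
        return "\n".join(lines)

    def summarize_cohort(self):
        return summarize_cohort(self.cohort)
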