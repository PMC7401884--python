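"""Cohort data model, CSV I/O and covariate/outcome codings.

The analyses in this package operate on per-patient records of choroidal
melanoma: largest basal tumour diameter (LBTD, mm), age at treatment,
chromosome 3 status (disomy D3 / monosomy M3, frequently untyped), a handful
of further anatomic/histologic/genetic covariates, follow-up time in years
and a six-level cause-of-death category.  This module holds the codings the
prognostic models rely on:

* LBTD recoded into the six ordered diameter bins used by the risk tables
  (``<10.1`` up to ``18.1-28.0`` mm);
* age dichotomised at 80 years (``<81 yr`` / ``>80 yr``), the split that best
  separates non-metastatic from metastatic mortality;
* cause of death collapsed to a competing-risks event code: definite or
  probable metastatic uveal melanoma counts as metastatic death, every other
  recorded cause (including "possible" metastatic disease and unknown causes)
  as death from other causes, and survivors are censored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LBTD_BIN_EDGES",
    "LBTD_BIN_LABELS",
    "AGE_BIN_LABELS",
    "EVENT_CENSORED",
    "EVENT_METASTATIC",
    "EVENT_OTHER",
    "CAUSE_CATEGORIES",
    "CohortSchemaError",
    "SubjectRecord",
    "Cohort",
    "Table1Summary",
    "bin_lbtd",
    "bin_age",
    "code_cause_of_death",
    "load_cohort",
    "summarize_cohort",
]

#: Right-closed upper edges separating the six LBTD bins (mm).
LBTD_BIN_EDGES: tuple[float, ...] = (10.0, 12.0, 14.0, 16.0, 18.0)
#: Printed labels of the six bins, matching the prognostic tables.
LBTD_BIN_LABELS: tuple[str, ...] = (
    "<10.1",
    "10.1-12.0",
    "12.1-14.0",
    "14.1-16.0",
    "16.1-18.0",
    "18.1-28.0",
)
#: LBTD range typical of referral cohorts; values outside trigger a warning.
LBTD_TYPICAL_RANGE: tuple[float, float] = (2.4, 28.0)

AGE_THRESHOLD = 80.0
AGE_BIN_LABELS: tuple[str, str] = ("<81 yr", ">80 yr")

EVENT_CENSORED = 0
EVENT_METASTATIC = 1
EVENT_OTHER = 2
EVENT_LABELS = {
    EVENT_CENSORED: "censored",
    EVENT_METASTATIC: "metastatic_death",
    EVENT_OTHER: "other_death",
}

#: Six-level cause-of-death registry coding.
CAUSE_CATEGORIES: Mapping[int, str] = {
    1: "definite_metastatic_um",
    2: "probable_metastatic_um",
    3: "possible_metastatic_um",
    4: "other_malignancy",
    5: "non_cancerous",
    6: "unknown",
}
_CAUSE_BY_NAME = {v: k for k, v in CAUSE_CATEGORIES.items()}

_C3S_ALIASES = {
    "d3": "D3",
    "disomy": "D3",
    "disomy3": "D3",
    "disomy 3": "D3",
    "m3": "M3",
    "monosomy": "M3",
    "monosomy3": "M3",
    "monosomy 3": "M3",
}
_MISSING_TOKENS = {"", "na", "nan", "none", "missing", "unknown", "?"}

REQUIRED_COLUMNS = ("lbtd_mm", "age_years", "sex", "c3s", "followup_years", "outcome")
OPTIONAL_COLUMNS = (
    "id",
    "chr8q",
    "ciliary_body",
    "extraocular",
    "thickness_mm",
    "closed_loops",
    "epithelioid",
    "mitotic_count",
    "c3s_true",
)
_CODED_COLUMNS = ("lbtd_bin", "lbtd_label", "age_bin", "event", "time", "m3")


class CohortSchemaError(ValueError):
    """Input table does not have the columns or types the cohort schema needs."""


def bin_lbtd(lbtd_mm):
    """Map LBTD in mm to its six-level ordinal bin (1..6).

    Edges are right-closed: ``<=10.0`` -> 1, ``(10,12]`` -> 2, ...,
    ``>18.0`` -> 6, so a tumour of exactly 12.0 mm falls in the
    ``10.1-12.0`` bin.  Raw (unrounded) diameters are binned.
    """
    x = np.asarray(lbtd_mm, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("lbtd_mm must be positive and finite")
    lo, hi = LBTD_TYPICAL_RANGE
    if np.any((x < lo) | (x > hi)):
        warnings.warn(
            f"LBTD outside the typical {lo}-{hi} mm range", stacklevel=2
        )
    bins = 1 + np.searchsorted(LBTD_BIN_EDGES, x, side="left")
    return int(bins) if np.isscalar(lbtd_mm) else bins.astype(np.int64)


def lbtd_bin_label(bins):
    """Printed label of an LBTD bin index (1..6)."""
    b = np.asarray(bins)
    if np.any((b < 1) | (b > 6)):
        raise ValueError("lbtd_bin must be in 1..6")
    labels = np.asarray(LBTD_BIN_LABELS, dtype=object)[b - 1]
    return str(labels) if np.isscalar(bins) else labels


def bin_age(age_years):
    """Dichotomise age at treatment at 80 years: 0 = ``<81 yr``, 1 = ``>80 yr``.

    Exactly 80 years counts as the younger group (ages are recorded in whole
    years in the source registries, so the groups read "<81" and ">80").
    """
    x = np.asarray(age_years, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("age_years must be positive and finite")
    bins = (x > AGE_THRESHOLD).astype(np.int64)
    return int(bins) if np.isscalar(age_years) else bins


def code_cause_of_death(category) -> int:
    """Collapse the six-level cause-of-death category to the event code.

    Categories 1 (definite metastatic uveal melanoma) and 2 (probable) are
    attributed to the melanoma; categories 3-6 (possible metastatic, other
    malignancy, non-cancerous, unknown) count as death from other causes;
    ``"alive"`` is censored.
    """
    if category is None or (isinstance(category, float) and np.isnan(category)):
        raise ValueError("cause-of-death category is missing")
    if isinstance(category, str):
        token = category.strip().lower()
        if token in {"alive", "censored"}:
            return EVENT_CENSORED
        if token in _CAUSE_BY_NAME:
            return EVENT_METASTATIC if _CAUSE_BY_NAME[token] <= 2 else EVENT_OTHER
        try:
            category = int(token)
        except ValueError:
            raise ValueError(f"unknown cause-of-death category: {category!r}") from None
    cat = int(category)
    if cat == 0:
        return EVENT_CENSORED
    if cat in (1, 2):
        return EVENT_METASTATIC
    if cat in (3, 4, 5, 6):
        return EVENT_OTHER
    raise ValueError(f"unknown cause-of-death category: {category!r}")


def _normalize_c3s(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    token = str(value).strip()
    if token.lower() in _MISSING_TOKENS:
        return None
    norm = _C3S_ALIASES.get(token.lower(), token.upper())
    if norm not in ("D3", "M3"):
        raise ValueError(f"unknown chromosome-3 status: {value!r}")
    return norm


@dataclass
class SubjectRecord:
    """One patient: measurements, covariates, follow-up and outcome."""

    id: str
    lbtd_mm: float
    age_years: float
    sex: str
    c3s: str | None  # "D3", "M3" or None when untyped
    followup_years: float
    outcome: object  # "alive" or cause category 1..6
    chr8q: str | None = None
    ciliary_body: bool | None = None
    extraocular: bool | None = None
    thickness_mm: float | None = None
    closed_loops: bool | None = None
    epithelioid: bool | None = None
    mitotic_count: int | None = None

    def validate(self) -> None:
        if not np.isfinite(self.lbtd_mm) or self.lbtd_mm <= 0:
            raise ValueError("lbtd_mm must be positive")
        if not np.isfinite(self.age_years) or self.age_years <= 0:
            raise ValueError("age_years must be positive")
        if not np.isfinite(self.followup_years) or self.followup_years <= 0:
            raise ValueError("followup_years must be positive")
        code_cause_of_death(self.outcome)
        _normalize_c3s(self.c3s)


@dataclass
class Cohort:
    """An ordered, coded collection of subjects plus provenance metadata.

    ``df`` holds both the raw columns and the derived codings
    (``lbtd_bin``, ``age_bin``, ``event``, ``time``, ``m3``), one row per
    subject.  ``m3`` is 1.0 for monosomy 3, 0.0 for disomy 3, NaN when
    chromosome 3 was not typed.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.df) == 0:
            raise ValueError("cohort must be nonempty")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def n_missing_c3s(self) -> int:
        return int(self.df["m3"].isna().sum())

    @classmethod
    def from_dataframe(cls, raw: pd.DataFrame, provenance: dict | None = None) -> "Cohort":
        """Validate and code a raw per-patient table.

        Rows with non-numeric or non-positive LBTD, age or follow-up time, or
        with an unrecognised outcome, are rejected and logged with their row
        index; the remaining rows are coded in order.
        """
        missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
        if missing:
            raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
        known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS) | set(_CODED_COLUMNS)
        unknown = [c for c in raw.columns if c not in known]
        if unknown:
            warnings.warn(f"ignoring unknown column(s): {', '.join(unknown)}", stacklevel=2)

        df = raw.loc[:, [c for c in raw.columns if c in known and c not in _CODED_COLUMNS]].copy()
        df = df.reset_index(drop=True)
        n0 = len(df)

        lbtd = pd.to_numeric(df["lbtd_mm"], errors="coerce")
        age = pd.to_numeric(df["age_years"], errors="coerce")
        fu = pd.to_numeric(df["followup_years"], errors="coerce")
        event = np.full(n0, -1, dtype=np.int64)
        for i, val in enumerate(df["outcome"].tolist()):
            try:
                event[i] = code_cause_of_death(val)
            except ValueError:
                event[i] = -1
        c3s_norm = np.empty(n0, dtype=object)
        for i, val in enumerate(df["c3s"].tolist()):
            try:
                c3s_norm[i] = _normalize_c3s(val)
            except ValueError:
                c3s_norm[i] = None
                event[i] = event[i]  # c3s errors tolerated: treated as untyped
                logger.warning("row %d: unrecognised c3s value treated as missing", i)

        ok = (
            lbtd.notna()
            & (lbtd > 0)
            & age.notna()
            & (age > 0)
            & fu.notna()
            & (fu > 0)
            & (event >= 0)
        ).to_numpy()
        rejected = np.flatnonzero(~ok)
        for i in rejected:
            logger.warning("row %d rejected: invalid lbtd/age/followup/outcome", i)
        if not ok.any():
            raise ValueError("no valid rows in cohort table")

        df = df.loc[ok].reset_index(drop=True)
        lbtd = lbtd.to_numpy()[ok]
        age = age.to_numpy()[ok]
        fu = fu.to_numpy()[ok]
        event = event[ok]
        c3s_norm = c3s_norm[ok]

        if "id" not in df.columns:
            df["id"] = [f"s{i}" for i in range(len(df))]
        df["lbtd_mm"] = lbtd
        df["age_years"] = age
        df["followup_years"] = fu
        df["c3s"] = pd.array([v if v is not None else pd.NA for v in c3s_norm], dtype="string")
        df["lbtd_bin"] = bin_lbtd(lbtd)
        df["lbtd_label"] = lbtd_bin_label(df["lbtd_bin"].to_numpy())
        df["age_bin"] = bin_age(age)
        df["event"] = event
        df["time"] = fu
        df["m3"] = np.where(c3s_norm == "M3", 1.0, np.where(c3s_norm == "D3", 0.0, np.nan))

        prov = dict(provenance or {})
        prov.setdefault("coding_version", "lbtd6-age80-cause2")
        prov["n_input_rows"] = n0
        prov["n_rejected_rows"] = int(len(rejected))
        return cls(df=df, provenance=prov)

    @classmethod
    def from_csv(cls, path, **read_kwargs) -> "Cohort":
        raw = pd.read_csv(path, na_values=["NA", ""], keep_default_na=True, **read_kwargs)
        return cls.from_dataframe(raw, provenance={"source": str(path)})

    def to_csv(self, path) -> None:
        """Write the raw columns back out (round-trips through ``from_csv``)."""
        cols = [c for c in ("id",) + REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in self.df.columns]
        out = self.df.loc[:, list(dict.fromkeys(cols))]
        out.to_csv(path, index=False)

    # -- convenience accessors used throughout the estimation modules --------

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(time, event) as float/int numpy arrays."""
        return (
            self.df["time"].to_numpy(dtype=float),
            self.df["event"].to_numpy(dtype=np.int64),
        )


def load_cohort(path, schema_config: dict | None = None) -> Cohort:
    """Load a cohort CSV, validating and coding every row.

    Unknown columns are ignored with a warning; rows violating invariants
    (non-positive follow-up, unparseable numbers, unknown outcome codes) are
    rejected and logged with their index.
    """
    del schema_config  # single coding scheme in this release
    return Cohort.from_csv(path)


# ---------------------------------------------------------------------------
# Crude summary (chromosome-3 status and age panels)
# ---------------------------------------------------------------------------


@dataclass
class Table1Summary:
    """Crude event counts by LBTD bin: metastatic deaths per chromosome-3
    column (untyped / D3 / M3) and non-metastatic deaths per age column.

    Percentages are crude ``100*n/N`` rounded to one decimal, matching how
    such cohort tables are printed; column totals give N only.
    """

    by_c3s: pd.DataFrame
    by_age: pd.DataFrame

    def to_markdown(self) -> str:
        lines = ["| LBTD (mm) | " + " | ".join(
            f"{col} N | {col} met. deaths (%)" for col in ("Unknown", "D3", "M3")
        ) + " |"]
        lines.append("|" + "---|" * 7)
        for label, row in self.by_c3s.iterrows():
            cells = [str(label)]
            for col in ("unknown", "D3", "M3"):
                n = row[f"{col}_n"]
                cells.append(f"{int(n)}" if pd.notna(n) else "—")
                d, p = row.get(f"{col}_deaths"), row.get(f"{col}_pct")
                cells.append(f"{int(d)} ({p})" if pd.notna(d) else "—")
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines)


def _crude_pct(deaths: float, n: float) -> float:
    """100*d/n rounded half-up to one decimal (the convention of printed
    cohort tables), computed in integer arithmetic so x.x5 cases are exact."""
    if n <= 0:
        return np.nan
    d, nn = int(deaths), int(n)
    return ((2000 * d + nn) // (2 * nn)) / 10.0


def summarize_cohort(cohort: Cohort) -> Table1Summary:
    """Crude counts/percentages per LBTD bin, by chromosome-3 status and age.

    For each LBTD bin and chromosome-3 column (untyped, D3, M3): number of
    subjects N and metastatic deaths n with crude percentage.  For each LBTD
    bin and age column: N and non-metastatic deaths with percentage.  A
    ``Total`` row carries the column Ns.
    """
    df = cohort.df
    if len(df) == 0:
        raise ValueError("empty cohort")

    rows_c3s, rows_age = [], []
    for b in range(1, 7):
        sub = df[df["lbtd_bin"] == b]
        row_c = {"lbtd_bin": b}
        for key, mask in (
            ("unknown", sub["m3"].isna()),
            ("D3", sub["m3"] == 0.0),
            ("M3", sub["m3"] == 1.0),
        ):
            cell = sub[mask]
            n = len(cell)
            d = int((cell["event"] == EVENT_METASTATIC).sum())
            row_c[f"{key}_n"] = n
            row_c[f"{key}_deaths"] = d if n > 0 else np.nan
            row_c[f"{key}_pct"] = _crude_pct(d, n)
        rows_c3s.append(row_c)

        row_a = {"lbtd_bin": b}
        for key, mask in (("le80", sub["age_bin"] == 0), ("gt80", sub["age_bin"] == 1)):
            cell = sub[mask]
            n = len(cell)
            d = int((cell["event"] == EVENT_OTHER).sum())
            row_a[f"{key}_n"] = n
            row_a[f"{key}_deaths"] = d if n > 0 else np.nan
            row_a[f"{key}_pct"] = _crude_pct(d, n)
        rows_age.append(row_a)

    by_c3s = pd.DataFrame(rows_c3s).set_index(
        pd.Index(LBTD_BIN_LABELS, name="lbtd")
    )
    by_age = pd.DataFrame(rows_age).set_index(pd.Index(LBTD_BIN_LABELS, name="lbtd"))

    totals_c = {f"{k}_n": by_c3s[f"{k}_n"].sum() for k in ("unknown", "D3", "M3")}
    totals_a = {f"{k}_n": by_age[f"{k}_n"].sum() for k in ("le80", "gt80")}
    by_c3s.loc["Total"] = {**totals_c}
    by_age.loc["Total"] = {**totals_a}
    return Table1Summary(by_c3s=by_c3s, by_age=by_age)
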