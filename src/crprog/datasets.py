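"""Published crude counts from the Liverpool choroidal-melanoma cohort.

The individual-level Liverpool/Glasgow cohort (8348 patients, 1993-2018) is
not publicly deposited; what is public are the crude per-cell counts of its
summary table: subjects (N) and metastatic deaths per LBTD bin within each
chromosome-3 column (untyped / disomy 3 / monosomy 3), and subjects and
non-metastatic deaths per LBTD bin within each age column.  Those printed
counts are reproduced here verbatim so the crude-percentage arithmetic can
be recomputed and checked, and so a count-matched surrogate cohort can be
constructed.  The D3/M3 column totals (511/433) are reproduced exactly as
printed even though they cover only a subset of the 4174 typed patients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import LBTD_BIN_LABELS, Cohort

__all__ = ["LIVERPOOL_TABLE1", "table1_counts", "cohort_from_table1_counts"]

# per LBTD bin: (N, metastatic deaths) for unknown/D3/M3 columns and
# (N, non-metastatic deaths) for the two age columns
LIVERPOOL_TABLE1 = {
    "unknown": [(1067, 69), (721, 96), (591, 160), (405, 173), (227, 121), (219, 136)],
    "D3": [(144, 0), (128, 4), (98, 3), (71, 4), (48, 7), (22, 3)],
    "M3": [(41, 11), (52, 11), (80, 21), (94, 36), (85, 49), (81, 52)],
    "le80": [(673, 46), (433, 28), (410, 37), (264, 14), (147, 7), (122, 3)],
    "gt80": [(579, 141), (468, 111), (359, 75), (306, 69), (213, 39), (200, 27)],
}


def table1_counts() -> pd.DataFrame:
    """The printed counts as a tidy DataFrame (one row per bin x column)."""
    rows = []
    for col, cells in LIVERPOOL_TABLE1.items():
        for b, (n, d) in enumerate(cells, start=1):
            rows.append({"column": col, "lbtd_bin": b, "lbtd": LBTD_BIN_LABELS[b - 1],
                         "n": n, "deaths": d})
    return pd.DataFrame(rows)


# representative diameters, one per bin, used to place surrogate subjects
_BIN_MIDPOINTS = (8.0, 11.0, 13.0, 15.0, 17.0, 20.0)


def cohort_from_table1_counts(panel: str = "c3s") -> Cohort:
    """A count-matched surrogate cohort for one panel of the printed table.

    Synthetic subjects (this is NOT the real cohort): each (bin, column)
    cell contributes exactly N subjects of whom the printed number die —
    of metastasis (cause 1) in the chromosome-3 panel, of a non-melanoma
    cause (cause 5) in the age panel; everyone else is censored.  Times and
    remaining covariates are placeholders — only the crude counts are
    meaningful, which is all the crude summary uses.
    """
    if panel == "c3s":
        columns = {"unknown": ("", 60.0, 1), "D3": ("D3", 60.0, 1), "M3": ("M3", 60.0, 1)}
    elif panel == "age":
        columns = {"le80": ("", 60.0, 5), "gt80": ("", 85.0, 5)}
    else:
        raise ValueError("panel must be 'c3s' or 'age'")
    recs = []
    for col, (c3s, age, cause) in columns.items():
        for b, (n, d) in enumerate(LIVERPOOL_TABLE1[col], start=1):
            for i in range(n):
                recs.append(
                    {
                        "lbtd_mm": _BIN_MIDPOINTS[b - 1],
                        "age_years": age,
                        "sex": "female",
                        "c3s": c3s,
                        "followup_years": 5.0,
                        "outcome": cause if i < d else "alive",
                    }
                )
    raw = pd.DataFrame(recs)
    return Cohort.from_dataframe(
        raw, provenance={"source": f"table1-count-matched-surrogate-{panel}"}
    )
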