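"""End-to-end analysis pipeline: cohort in, tables/rankings/C-indices out.

Deterministic given the seed; every output is a text artifact (CSV or
markdown) plus a JSON run manifest recording seeds, MI settings and
versions.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, load_cohort, summarize_cohort
from .imputation import MIConfig
from .model import MetastaticRiskModel
from .simulate import SimulationConfig, simulate_cohort
from .tables import render_table

__all__ = ["run_pipeline"]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(
    out_dir,
    cohort_path=None,
    sim_config: SimulationConfig | None = None,
    mi_config: MIConfig | None = None,
    seed: int = 0,
    factors=("lbtd", "c3s", "sex", "ciliary_body", "chr8q"),
    with_ci: bool = True,
) -> dict:
    """Run load/simulate -> summary -> selection -> tables -> C-indices.

    Either ``cohort_path`` (CSV) or ``sim_config`` must be given.  Returns
    the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    mi_config = mi_config or MIConfig.desk()

    if (cohort_path is None) == (sim_config is None):
        raise ValueError("give exactly one of cohort_path or sim_config")
    if cohort_path is not None:
        cohort = _stage("load")(load_cohort)(cohort_path)
    else:
        cohort = _stage("simulate")(simulate_cohort)(sim_config, seed=int(rng.integers(2**31)))
        cohort.to_csv(out / "cohort.csv")

    summary = _stage("summarize")(summarize_cohort)(cohort)
    summary.by_c3s.to_csv(out / "summary_by_c3s.csv")
    summary.by_age.to_csv(out / "summary_by_age.csv")

    model = MetastaticRiskModel(cohort, include_c3s=True, mi_config=mi_config)
    results = _stage("fit")(model.fit)(seed=int(rng.integers(2**31)), compute_ci=with_ci)

    ranking = _stage("select")(results.rank_factors)(factors)
    ranking.to_frame().to_csv(out / "factor_ranking.csv", index=False)

    (out / "prognostic_table.md").write_text(render_table(results.table, "markdown"))
    (out / "prognostic_table.csv").write_text(render_table(results.table, "csv"))

    cidx_rows = []
    for kind in ("lbtd_c3s", "lbtd"):
        sub_model = MetastaticRiskModel(cohort, include_c3s=(kind == "lbtd_c3s"),
                                        mi_config=mi_config)
        sub_res = sub_model.fit(seed=int(rng.integers(2**31)), compute_ci=False)
        for r in _stage("cindex")(sub_res.concordance)():
            cidx_rows.append({"model": kind, "tau": r.tau, "cindex": r.cindex})
    pd.DataFrame(cidx_rows).to_csv(out / "cindex.csv", index=False)

    manifest = {
        "crprog_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "m": mi_config.m,
        "b": mi_config.b,
        "n_subjects": cohort.n,
        "n_missing_c3s": cohort.n_missing_c3s,
        "source": cohort.provenance.get("source"),
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
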