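"""Method comparison on a region: tuning grids, normalized R², rankings.

Normalized R² is each method's R² divided by the lead-variant-only R² for
the same region, so the lead-only row is 1 by construction.  When an
outcome is supplied, the IVW MR estimate is attached per row together
with an "instability-suspect" flag: a row whose MR standard error is less
than half the lead-only SE, or whose point estimate is more than two
combined SEs from the lead-only estimate, warrants suspicion of numerical
instability rather than genuine precision gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cisiv import pruning
from cisiv.cojo import CojoConfig, cojo_select
from cisiv.data_model import (
    AlignedRegion,
    RegionSumstats,
    SelectionResult,
    filter_by_p,
    preprune_r2,
)
from cisiv.mr import mr_with_selection
from cisiv.pca import pca_select
from cisiv.pruning import PruneConfig
from cisiv.strength import strength_summary
from cisiv.susie import SusieConfig, susie_select

DEFAULT_GRIDS = {
    "prune_standard": [round(0.02 * i, 2) for i in range(41)],   # 0..0.8
    "prune_modified": [round(0.02 * i, 2) for i in range(41)],
    "cojo": [round(0.1 * i, 1) for i in range(1, 10)],           # 0.1..0.9
    "pca": [round(0.90 + 0.01 * i, 2) for i in range(10)]
    + [round(0.99 + 0.001 * i, 3) for i in range(10)],           # 90%..99.9%
}

SE_RATIO_FLAG = 0.5
SHIFT_SD_FLAG = 2.0


@dataclass
class ComparisonReport:
    region_label: str
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)


def compare_methods(
    region: AlignedRegion,
    outcome: RegionSumstats | None = None,
    grids: dict | None = None,
    seed: int | None = None,
    region_label: str = "region",
    methods=("lead_only", "prune_standard", "prune_modified", "cojo", "susie", "pca"),
) -> ComparisonReport:
    """Run every selector across its tuning grid on one region."""
    grids = dict(DEFAULT_GRIDS, **(grids or {}))
    filtered = filter_by_p(region)
    if not len(filtered):
        raise ValueError("no variant passes the p filter; lead-only R² is 0")
    lead = filtered.lead_id()
    _, leadF, lead_r2, lead_adj = strength_summary(filtered, [lead])
    if lead_r2 == 0:
        raise ValueError("lead-only R² is 0; report aborted")
    lead_sel = SelectionResult("lead_only", {}, (lead,), 1, leadF, lead_r2, lead_adj)

    rows = []

    def add(label: str, sel: SelectionResult, src_region: AlignedRegion):
        row = {
            "method": label,
            "tuning": ";".join(f"{k}={v}" for k, v in sel.tuning.items()),
            "J": sel.J,
            "F": sel.F,
            "r2": sel.r2,
            "adj_r2": sel.adj_r2,
            "norm_r2": sel.r2 / lead_r2,
            "selected_ids": ";".join(sel.selected_ids),
        }
        if outcome is not None and sel.J > 0:
            res = mr_with_selection(src_region, outcome, sel)
            row.update(mr_estimate=res.estimate, mr_se=res.se,
                       mr_ci_low=res.ci_low, mr_ci_high=res.ci_high,
                       mr_pval=res.pval, stabilized=res.stabilized)
        rows.append(row)

    add("lead_only", lead_sel, filtered)
    for method in methods:
        if method == "lead_only":
            continue
        for tv in grids.get(method, []):
            if method == "prune_standard":
                sel = pruning.prune_standard(filtered, PruneConfig(tv, "standard", seed=seed))
            elif method == "prune_modified":
                sel = pruning.prune_modified(filtered, PruneConfig(tv, "modified", seed=seed))
            elif method == "cojo":
                sel = cojo_select(region, CojoConfig(collinearity_threshold=tv))
            elif method == "pca":
                sel = pca_select(preprune_r2(filtered, 0.95, seed=seed), tv)
            else:
                continue
            src = region if method == "cojo" else filtered
            add(f"{method}@{tv:g}", sel, src)
        if method == "susie":
            sel = susie_select(filtered, SusieConfig(seed=seed))
            if sel.J == 0:
                sel = SelectionResult("lead_only", {"fallback": "lead"},
                                      (lead,), 1, leadF, lead_r2, lead_adj)
            add("susie", sel, filtered)

    table = pd.DataFrame(rows)
    # dense ranks on normalized R², rank 1 = best; ties share the better rank
    table["rank"] = table["norm_r2"].rank(method="dense", ascending=False).astype(int)
    if outcome is not None and "mr_se" in table.columns:
        lead_row = table.loc[table["method"] == "lead_only"].iloc[0]
        shift = np.abs(table["mr_estimate"] - lead_row["mr_estimate"])
        comb = np.sqrt(table["mr_se"] ** 2 + lead_row["mr_se"] ** 2)
        table["instability_suspect"] = (
            (table["mr_se"] < SE_RATIO_FLAG * lead_row["mr_se"])
            | (shift > SHIFT_SD_FLAG * comb)
        ).fillna(False)
    return ComparisonReport(region_label, table,
                            meta={"lead_r2": lead_r2, "seed": seed})


def rank_methods(reports) -> pd.DataFrame:
    """Distribution of per-region method ranks (min/quartiles/max)."""
    reports = list(reports)
    if not reports:
        raise ValueError("at least one report is required")
    frames = [r.table[["method", "rank"]].assign(region=r.region_label)
              for r in reports]
    allranks = pd.concat(frames)
    return (
        allranks.groupby("method", sort=False)["rank"]
        .agg(min="min",
             q1=lambda s: float(np.percentile(s, 25)),
             median="median",
             q3=lambda s: float(np.percentile(s, 75)),
             max="max")
        .reset_index()
    )
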