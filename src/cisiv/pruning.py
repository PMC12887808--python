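"""Standard and modified LD-pruning for instrument selection.

Standard pruning iterates: select the remaining variant with the smallest
marginal p, then exclude every remaining variant whose pairwise r² with it
exceeds the threshold.  The modified variant adds two gates before a
candidate is retained: it must strictly increase the adjusted R² of the
selected set, and must not make the selected-set LD submatrix singular.
A candidate rejected by a gate is removed from further consideration but
does not trigger r²-exclusion of its neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cisiv.data_model import AlignedRegion, SelectionResult, selection_order
from cisiv.strength import adjusted_r2, is_singular, strength_summary

#: float-equality guard for the adjusted-R² improvement test
ADJ_R2_TOL = 1e-12


@dataclass
class PruneConfig:
    """Tuning for LD-pruning; thresholds 0–0.8 (step 0.02) are customary."""

    r2_threshold: float
    mode: str = "standard"  # "standard" | "modified"
    seed: int | None = None
    deterministic_ties: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must lie in [0, 1]")
        if self.mode not in ("standard", "modified"):
            raise ValueError(f"unknown pruning mode: {self.mode!r}")


def _empty_result(method: str, cfg: PruneConfig) -> SelectionResult:
    return SelectionResult(
        method=method,
        tuning={"r2_threshold": cfg.r2_threshold},
        selected_ids=(),
        J=0,
        F=0.0,
        r2=0.0,
        adj_r2=0.0,
        seed=cfg.seed,
    )


def prune_standard(region: AlignedRegion, cfg: PruneConfig) -> SelectionResult:
    """Classic p-ranked LD-pruning at ``cfg.r2_threshold``."""
    if len(region) == 0:
        return _empty_result("prune_standard", cfg)
    order = selection_order(region, seed=cfg.seed,
                            deterministic_ties=cfg.deterministic_ties)
    idx = {v: i for i, v in enumerate(region.ids)}
    r2 = region.ld.r ** 2
    remaining = list(order)
    selected: list[str] = []
    while remaining:
        pick = remaining.pop(0)
        selected.append(pick)
        i = idx[pick]
        remaining = [v for v in remaining if r2[i, idx[v]] <= cfg.r2_threshold]
    J, F, r2v, adj = strength_summary(region, selected)
    return SelectionResult(
        method="prune_standard",
        tuning={"r2_threshold": cfg.r2_threshold},
        selected_ids=tuple(selected),
        J=J,
        F=F,
        r2=r2v,
        adj_r2=adj,
        seed=cfg.seed,
        sequence=tuple(selected),
    )


def prune_modified(region: AlignedRegion, cfg: PruneConfig) -> SelectionResult:
    """LD-pruning with adjusted-R² and singularity gating.

    The first candidate (the lead variant) is always retained: from an
    empty set any genuinely associated variant increases adjusted R².
    """
    if len(region) == 0:
        return _empty_result("prune_modified", cfg)
    order = selection_order(region, seed=cfg.seed,
                            deterministic_ties=cfg.deterministic_ties)
    idx = {v: i for i, v in enumerate(region.ids)}
    r2 = region.ld.r ** 2
    n = region.n
    remaining = list(order)
    selected: list[str] = []
    adj_trace: list[float] = []
    current_adj = 0.0  # adjusted R² of the empty set (J = 0 ⇒ R² = 0)
    while remaining:
        cand = remaining.pop(0)
        tentative = selected + [cand]
        if is_singular(region.ld.submatrix(tentative)):
            continue  # rejected: drop candidate only, neighbours stay
        Jt, Ft, r2t, adjt = strength_summary(region, tentative)
        # first pick (the lead) is always retained; afterwards require a
        # strict adjusted-R² improvement
        if selected and adjt <= current_adj + ADJ_R2_TOL:
            continue
        selected = tentative
        current_adj = adjt
        adj_trace.append(adjt)
        i = idx[cand]
        remaining = [v for v in remaining if r2[i, idx[v]] <= cfg.r2_threshold]
    J, F, r2v, adj = strength_summary(region, selected)
    return SelectionResult(
        method="prune_modified",
        tuning={"r2_threshold": cfg.r2_threshold},
        selected_ids=tuple(selected),
        J=J,
        F=F,
        r2=r2v,
        adj_r2=adj,
        seed=cfg.seed,
        sequence=tuple(selected),
        notes={"adj_r2_trace": tuple(adj_trace)},
    )
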