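"""Forward-backward stepwise conditional selection (COJO-style).

Variants enter by smallest *conditional* p-value (conditioned on the
variants already selected) subject to a collinearity gate: a candidate
whose variance explained by the selected set — r_csᵀ R_ss⁻¹ r_cs — exceeds
the collinearity threshold has its conditional p set to 1 and cannot
enter.  After each addition, joint-model p-values of all selected variants
are recomputed and the weakest is removed if it no longer clears the
cutoff.  Iteration stops when no variant is added or removed.

All p-comparisons are carried out on the |z| scale (the identical
ordering, immune to floating-point underflow of extreme p-values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from cisiv.data_model import AlignedRegion, LDMatrix, SelectionResult
from cisiv.strength import joint_from_marginal, stabilize_ld, strength_summary


@dataclass
class CojoConfig:
    """Stepwise-selection tuning; collinearity grid 0.1–0.9 is customary."""

    p_cutoff: float = 0.001
    collinearity_threshold: float = 0.5
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must lie in (0, 1)")
        if not 0 < self.collinearity_threshold < 1:
            raise ValueError("collinearity_threshold must lie in (0, 1)")


class ConvergenceError(RuntimeError):
    """Stepwise selection oscillated past ``max_iter`` outer iterations."""


def collinearity_r2(candidate, selected, ld: LDMatrix) -> float:
    """Variance of ``candidate`` explained by ``selected`` in LD space.

    Equals r_csᵀ R_ss⁻¹ r_cs, the R² of regressing the candidate variant
    on the selected variants; detects linear-combination collinearity that
    pairwise r² misses.
    """
    selected = list(selected)
    if candidate in selected:
        raise ValueError("candidate is already in the selected set")
    if not selected:
        raise ValueError("selected set must be non-empty")
    ci = ld.indices([candidate])[0]
    si = ld.indices(selected)
    r_cs = ld.r[ci, si]
    R_ss = np.asarray(stabilize_ld(ld.r[np.ix_(si, si)]), float)
    val = float(r_cs @ linalg.solve(R_ss, r_cs, assume_a="pos"))
    return float(np.clip(val, 0.0, 1.0 + 1e-6))


def conditional_assoc(region: AlignedRegion, selected, candidate):
    """Candidate's effect conditioned on ``selected``: (beta, se, p).

    Fits the joint model on selected ∪ {candidate}; the p-value is
    two-sided standard-normal on the candidate's joint coefficient.  With
    an empty conditioning set this returns the marginal beta/se/p.
    """
    selected = list(selected)
    if not selected:
        sub = region.restrict([candidate])
        b, s = float(sub.beta[0]), float(sub.se[0])
        return b, s, 2 * float(stats.norm.sf(abs(b / s)))
    ja = joint_from_marginal(region, selected + [candidate])
    b = float(ja.gamma[-1])
    s = float(np.sqrt(ja.sigma[-1, -1]))
    return b, s, 2 * float(stats.norm.sf(abs(b / s)))


def _joint_abs_z(region: AlignedRegion, ids) -> np.ndarray:
    ja = joint_from_marginal(region, ids)
    return np.abs(ja.gamma) / np.sqrt(np.diag(ja.sigma))


def cojo_select(region: AlignedRegion, cfg: CojoConfig | None = None) -> SelectionResult:
    """Run the full forward-backward stepwise selection on a region.

    The region should be unfiltered: the p cutoff acts internally.
    """
    cfg = cfg or CojoConfig()
    # |z| threshold equivalent to the two-sided normal p cutoff
    z_cut = float(stats.norm.isf(cfg.p_cutoff / 2))

    def empty() -> SelectionResult:
        return SelectionResult(
            method="cojo",
            tuning={
                "p_cutoff": cfg.p_cutoff,
                "collinearity_threshold": cfg.collinearity_threshold,
            },
            selected_ids=(),
            J=0,
            F=0.0,
            r2=0.0,
            adj_r2=0.0,
        )

    if len(region) == 0:
        return empty()
    absz = np.abs(region.z)
    lead = int(np.argmax(absz))
    if absz[lead] < z_cut:
        return empty()

    ids = list(region.ids)
    index = {v: i for i, v in enumerate(ids)}
    n = region.n
    z = region.z
    bcorr = z / np.sqrt(z**2 + n - 2)  # implied marginal correlations
    R = region.ld.r

    selected = [ids[lead]]
    barred: set = set()
    removed_once: set = set()

    for _ in range(cfg.max_iter):
        changed = False
        # forward step: conditional |z| of every eligible candidate at once,
        # via the Schur complement of the selected-set LD block
        sel_idx = np.array([index[v] for v in selected])
        cand_idx = np.array(
            [i for i, v in enumerate(ids) if v not in selected and v not in barred]
        )
        if cand_idx.size:
            Rss = np.asarray(stabilize_ld(R[np.ix_(sel_idx, sel_idx)]), float)
            A = linalg.inv(Rss)
            bs = bcorr[sel_idx]
            q_sel = float(bs @ A @ bs)
            Rcs = R[np.ix_(cand_idx, sel_idx)]
            RcsA = Rcs @ A
            colin = np.einsum("ij,ij->i", RcsA, Rcs)  # collinearity R² per candidate
            eligible = colin <= cfg.collinearity_threshold
            resid = bcorr[cand_idx] - Rcs @ (A @ bs)
            s = np.maximum(1.0 - colin, 1e-12)  # residual variance of candidate LD
            q_new = np.clip(q_sel + resid**2 / s, 0.0, 1.0 - 1e-12)
            J_new = len(selected) + 1
            with np.errstate(divide="ignore", invalid="ignore"):
                z_cond = np.sqrt(
                    np.maximum(resid**2 / s, 0.0) * (n - J_new - 1) / (1.0 - q_new)
                )
            z_cond = np.where(eligible, z_cond, 0.0)  # gated: conditional p = 1
            best = int(np.argmax(z_cond))
            if z_cond[best] > z_cut:
                selected.append(ids[cand_idx[best]])
                changed = True
        # backward step: drop the weakest selected variant if non-significant
        if len(selected) > 1:
            zj = _joint_abs_z(region, selected)
            weakest = int(np.argmin(zj))
            if zj[weakest] < z_cut:
                victim = selected.pop(weakest)
                if victim in removed_once:
                    barred.add(victim)  # oscillation guard: no re-entry
                removed_once.add(victim)
                changed = True
        if not changed:
            break
    else:
        raise ConvergenceError(
            f"stepwise selection did not settle in {cfg.max_iter} iterations; "
            f"current set: {selected}"
        )

    J, F, r2, adj = strength_summary(region, selected)
    return SelectionResult(
        method="cojo",
        tuning={
            "p_cutoff": cfg.p_cutoff,
            "collinearity_threshold": cfg.collinearity_threshold,
        },
        selected_ids=tuple(selected),
        J=J,
        F=F,
        r2=r2,
        adj_r2=adj,
        sequence=tuple(selected),
    )
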