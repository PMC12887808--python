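"""Fixed-effects inverse-variance-weighted MR with correlated instruments.

The estimator generalizes textbook IVW to instruments in LD: with γ the
variant-exposure associations, Γ the variant-outcome associations and
Ω_ij = se_Y,i·se_Y,j·ρ_ij the LD-scaled outcome covariance,

    θ̂ = (γᵀΩ⁻¹γ)⁻¹ γᵀΩ⁻¹Γ,      se(θ̂) = √((γᵀΩ⁻¹γ)⁻¹).

When Ω is numerically singular its diagonal is shifted by
ε = −λ_min + 1e-8 and the result is flagged, so reports can surface the
recommended lead-variant-only comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from cisiv.data_model import AlignedRegion, RegionSumstats, SelectionResult
from cisiv.pca import transform_to_pcs
from cisiv.strength import EIG_FLOOR, is_singular

Z975 = 1.959964


@dataclass
class MRInput:
    gamma_x: np.ndarray
    se_x: np.ndarray
    gamma_y: np.ndarray
    se_y: np.ndarray
    rho: np.ndarray
    omega: np.ndarray | None = None  # direct outcome covariance (PC basis)

    def __post_init__(self) -> None:
        gx = np.atleast_1d(np.asarray(self.gamma_x, float))
        J = gx.size
        if J == 0:
            raise ValueError("at least one instrument is required")
        for name in ("se_x", "gamma_y", "se_y"):
            v = np.atleast_1d(np.asarray(getattr(self, name), float))
            if v.size != J:
                raise ValueError(f"{name} has length {v.size}, expected {J}")
            setattr(self, name, v)
        self.gamma_x = gx
        self.rho = np.atleast_2d(np.asarray(self.rho, float))
        if self.rho.shape != (J, J):
            raise ValueError("rho dimension does not match instruments")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def J(self) -> int:
        return self.gamma_x.size


@dataclass
class MRResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    J: int
    stabilized: bool


def ivw_correlated(inp: MRInput) -> MRResult:
    """Fixed-effects IVW accounting for instrument correlation."""
    if inp.J == 0:
        raise ValueError("at least one instrument is required")
    omega = inp.omega if inp.omega is not None else (
        np.outer(inp.se_y, inp.se_y) * inp.rho
    )
    stabilized = False
    if is_singular(omega):
        lmin = float(np.linalg.eigvalsh(omega)[0])
        omega = omega + (-lmin + EIG_FLOOR) * np.eye(inp.J)
        stabilized = True
    wi_g = linalg.solve(omega, inp.gamma_x, assume_a="pos")
    denom = float(inp.gamma_x @ wi_g)
    est = float(wi_g @ inp.gamma_y) / denom
    se = float(np.sqrt(1.0 / denom))
    p = 2 * float(stats.norm.sf(abs(est) / se))
    return MRResult(
        estimate=est,
        se=se,
        ci_low=est - Z975 * se,
        ci_high=est + Z975 * se,
        pval=p,
        J=inp.J,
        stabilized=stabilized,
    )


def mr_with_selection(region_x: AlignedRegion, outcome: RegionSumstats,
                      sel: SelectionResult) -> MRResult:
    """IVW MR using a selection result (variant set or PC basis).

    ``outcome`` must be harmonized to the same coded alleles as
    ``region_x``.  For PC selections, both exposure and outcome
    associations are projected onto the basis and Ω is the transformed
    outcome covariance.
    """
    if sel.method == "pca":
        if sel.pc_basis is None:
            raise ValueError("PCA selection carries no basis")
        t = transform_to_pcs(region_x, sel.pc_basis, outcome=outcome)
        k = sel.pc_basis.k
        inp = MRInput(
            gamma_x=t["beta"],
            se_x=np.sqrt(np.diag(t["cov"])),
            gamma_y=t["beta_out"],
            se_y=np.sqrt(np.diag(t["cov_out"])),
            rho=np.eye(k),
            omega=t["cov_out"],
        )
        return ivw_correlated(inp)
    ids = list(sel.selected_ids)
    if not ids:
        raise ValueError("selection is empty; no instruments to use")
    missing = [v for v in ids if v not in set(outcome.ids)]
    if missing:
        raise KeyError(f"selected variant(s) missing from outcome: {missing}")
    sub = region_x.restrict(ids)
    tab = outcome.table.set_index("variant_id").loc[ids]
    inp = MRInput(
        gamma_x=sub.beta,
        se_x=sub.se,
        gamma_y=tab["beta"].to_numpy(float),
        se_y=tab["se"].to_numpy(float),
        rho=sub.ld.r,
    )
    return ivw_correlated(inp)
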