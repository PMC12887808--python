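"""Principal-component instruments from the z-weighted LD matrix.

Instead of selecting individual variants, the region is transformed into a
small orthogonal basis: the LD matrix is weighted entrywise by
z_i·z_j = (β̂_i/SE_i)(β̂_j/SE_j) to up-weight strongly associated variants,
eigendecomposed, and the top components retained until a pre-specified
fraction of the weighted matrix's variance (trace) is explained.  Summary
statistics are then re-expressed in the PC basis and used directly for
strength and MR calculations with J = k instruments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from cisiv.data_model import AlignedRegion, RegionSumstats, SelectionResult
from cisiv.strength import adjusted_r2, r2_from_f, stabilize_ld


@dataclass
class PCBasis:
    loadings: np.ndarray        # J x k, orthonormal columns
    eigenvalues: np.ndarray     # length k, non-increasing, >= 0
    variance_fraction: float
    source_ids: tuple

    def __post_init__(self) -> None:
        L = np.asarray(self.loadings, float)
        if not np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8):
            raise ValueError("loadings are not orthonormal")
        ev = np.asarray(self.eigenvalues, float)
        if np.any(np.diff(ev) > 1e-12) or np.any(ev < -1e-8):
            raise ValueError("eigenvalues must be non-increasing and non-negative")

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def weighted_ld(region: AlignedRegion) -> np.ndarray:
    """W with W_ij = z_i·z_j·r_ij; symmetric PSD (Schur product theorem)."""
    z = region.z
    return np.outer(z, z) * region.ld.r


def pc_basis(W: np.ndarray, variance_threshold: float, ids) -> PCBasis:
    """Retain the minimal k PCs whose eigenvalue fraction meets the threshold.

    Negative numerical eigenvalues are clipped to 0 before the fraction is
    computed; the denominator is the trace of W after clipping.  Each
    eigenvector's sign is fixed so its largest-magnitude loading is
    positive.
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    W = np.asarray(W, float)
    ev, vec = linalg.eigh(W)
    ev, vec = ev[::-1].copy(), vec[:, ::-1].copy()
    ev = np.clip(ev, 0.0, None)
    total = ev.sum()
    if total <= 0:
        raise ValueError("weighted LD matrix has no signal to decompose")
    frac = np.cumsum(ev) / total
    k = int(np.searchsorted(frac, variance_threshold - 1e-12)) + 1
    k = min(k, len(ev))
    L = vec[:, :k]
    for j in range(k):  # deterministic sign convention
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return PCBasis(
        loadings=L,
        eigenvalues=ev[:k],
        variance_fraction=float(frac[k - 1]),
        source_ids=tuple(ids),
    )


def transform_to_pcs(region: AlignedRegion, basis: PCBasis,
                     outcome: RegionSumstats | None = None) -> dict:
    """Re-express associations in the PC basis.

    Returns a dict with keys ``beta`` (Lᵀβ̂), ``cov`` (LᵀSRSL),
    ``corr_y`` (Lᵀb, correlations of the trait with the PC scores),
    ``pc_cov`` (LᵀRL, covariance of the PC scores) and, when ``outcome``
    is given, ``beta_out``/``cov_out`` transformed the same way.
    """
    if list(basis.source_ids) != list(region.ids):
        raise ValueError("basis was not built from this region's variants")
    L = basis.loadings
    S = region.se
    R = region.ld.r
    z = region.z
    n = region.n
    b = z / np.sqrt(z**2 + n - 2)
    out = {
        "beta": L.T @ region.beta,
        "cov": L.T @ (S[:, None] * R * S[None, :]) @ L,
        "corr_y": L.T @ b,
        "pc_cov": L.T @ R @ L,
        "n": n,
    }
    if outcome is not None:
        tab = outcome.table.set_index("variant_id").loc[list(region.ids)]
        beta_y = tab["beta"].to_numpy(float)
        se_y = tab["se"].to_numpy(float)
        out["beta_out"] = L.T @ beta_y
        out["cov_out"] = L.T @ (se_y[:, None] * R * se_y[None, :]) @ L
    return out


def pc_strength(region: AlignedRegion, basis: PCBasis) -> tuple[int, float, float, float]:
    """(k, F, R², adjusted R²) of the PC-instrument system.

    R² is the multiple correlation of the trait with the k PC scores:
    (Lᵀb)ᵀ(LᵀRL)⁻¹(Lᵀb); with all PCs retained and invertible LD this
    equals the full-variant-set R².
    """
    t = transform_to_pcs(region, basis)
    C = np.asarray(stabilize_ld(t["pc_cov"]), float)
    # pc_cov is not a correlation matrix; apply the same eigenvalue floor
    ev = np.linalg.eigvalsh(C)
    if ev[0] < 1e-10 * max(1.0, ev[-1]):
        C = C + (1e-10 * max(1.0, ev[-1]) - ev[0]) * np.eye(C.shape[0])
    q = float(np.clip(t["corr_y"] @ linalg.solve(C, t["corr_y"], assume_a="pos"),
                      0.0, 1.0 - 1e-12))
    k = basis.k
    n = region.n
    F = (n - k - 1) / k * q / (1 - q)
    return k, F, r2_from_f(F, n, k), adjusted_r2(q, n, k)


def pca_select(region: AlignedRegion, variance_threshold: float) -> SelectionResult:
    """Build the PC basis at ``variance_threshold`` and score its strength."""
    W = weighted_ld(region)
    basis = pc_basis(W, variance_threshold, region.ids)
    k, F, r2, adj = pc_strength(region, basis)
    return SelectionResult(
        method="pca",
        tuning={"variance_threshold": variance_threshold},
        selected_ids=(),
        J=k,
        F=F,
        r2=r2,
        adj_r2=adj,
        pc_basis=basis,
    )
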