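"""Instrument strength for correlated variants from summary statistics.

Reconstructs the multivariable (joint) effect vector γ̂ and its covariance
Σγ̂ for a subset of variants from marginal estimates plus the LD matrix,
then derives the joint F-statistic and the variance explained

    R² = J·F̂ / (N − J − 1 + J·F̂),
    R²_adj = 1 − (1 − R²)(N − 1)/(N − J − 1).

The reconstruction works on the correlation scale: the marginal t-statistic
z_j maps exactly to the sample correlation b_j = z_j/√(z_j² + N − 2), the
joint R² is the multiple-correlation identity bᵀR⁻¹b, and Σγ̂ carries the
joint residual variance (1 − R²).  On data where the LD matrix and the
marginal estimates come from the same sample, this chain reproduces the
individual-level multivariable OLS R² exactly, and for J = 1 it reduces to
the familiar z²/(N − 2 + z²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from cisiv.data_model import AlignedRegion, LDMatrix

#: smallest eigenvalue guaranteed after stabilization
EIG_FLOOR = 1e-8


@dataclass
class JointAssoc:
    """Joint (multivariable) effects γ̂ with covariance Σγ̂ for a variant set."""

    ids: tuple
    gamma: np.ndarray
    sigma: np.ndarray
    n: int
    r2: float  # joint variance explained of this subset

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, float)
        s = np.asarray(self.sigma, float)
        if s.shape != (g.size, g.size) or len(self.ids) != g.size:
            raise ValueError("inconsistent JointAssoc dimensions")
        if not np.allclose(s, s.T, atol=1e-8):
            raise ValueError("sigma is not symmetric")
        if np.any(np.diag(s) <= 0):
            raise ValueError("sigma diagonal must be strictly positive")


def _as_matrix(r) -> np.ndarray:
    return r.r if isinstance(r, LDMatrix) else np.asarray(r, float)


def stabilize_ld(r):
    """Shift the diagonal so every eigenvalue is at least 1e-8.

    If λ_min > 1e-8 the matrix is returned unchanged; otherwise
    ε = −λ_min + 1e-8 is added to each diagonal entry.  Off-diagonal
    entries are never touched, so the operation is idempotent.
    """
    m = _as_matrix(r)
    if m.size == 0:
        return r
    lmin = float(np.linalg.eigvalsh(m)[0])
    if lmin > EIG_FLOOR:
        return r
    eps = -lmin + EIG_FLOOR
    out = m + eps * np.eye(m.shape[0])
    if isinstance(r, LDMatrix):
        out = LDMatrix.__new__(LDMatrix)  # bypass unit-diagonal validation
        object.__setattr__(out, "ids", r.ids)
        object.__setattr__(out, "r", m + eps * np.eye(m.shape[0]))
        object.__setattr__(out, "_index", {v: i for i, v in enumerate(r.ids)})
        return out
    return out


def is_singular(r) -> bool:
    """True when λ_min < 1e-8 · max(1, λ_max) (relative tolerance)."""
    m = _as_matrix(r)
    if m.size == 0:
        return False
    ev = np.linalg.eigvalsh(m)
    return bool(ev[0] < EIG_FLOOR * max(1.0, ev[-1]))


def _solve_stabilized(m: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    m = _as_matrix(stabilize_ld(m))
    return linalg.solve(m, rhs, assume_a="pos")


def joint_from_marginal(region: AlignedRegion, subset) -> JointAssoc:
    """Joint effects and covariance for ``subset`` from marginal stats + LD.

    With z the marginal z-scores of the subset, R its LD submatrix
    (stabilized before inversion when needed) and N = region sample size:

    * b = z/√(z² + N − 2) are the implied marginal correlations,
    * a = R⁻¹b the standardized joint coefficients, R² = bᵀa,
    * γ̂_j = c_j·a_j with scale c_j = se_j·√(N − 2)/√(1 − b_j²)
      (the per-allele/per-unit conversion implied by the marginal SE),
    * Σγ̂ = (1 − R²)/(N − J − 1) · C R⁻¹ C.

    For J = 1 this gives γ̂ = beta and Σγ̂ = se² exactly.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    sub = region.restrict(subset)
    n = sub.n
    J = len(subset)
    if n <= J + 1:
        raise ValueError(f"sample size N={n} too small for J={J} instruments")
    z = sub.z
    b = z / np.sqrt(z**2 + n - 2)
    R = _as_matrix(stabilize_ld(sub.ld))
    a = linalg.solve(R, b, assume_a="pos")
    r2 = float(np.clip(b @ a, 0.0, 1.0 - 1e-12))
    c = sub.se * np.sqrt(n - 2) / np.sqrt(1.0 - b**2)
    gamma = c * a
    Rinv = linalg.inv(R)
    sigma = (1.0 - r2) / (n - J - 1) * (c[:, None] * Rinv * c[None, :])
    sigma = (sigma + sigma.T) / 2
    return JointAssoc(tuple(subset), gamma, sigma, n, r2)


def f_statistic(ja: JointAssoc) -> float:
    """Joint F-statistic  F̂ = γ̂ᵀΣγ̂⁻¹γ̂ / J  (non-negative).

    With Σγ̂ carrying the joint residual variance this is the classic
    overall regression F with (J, N − J − 1) degrees of freedom; for
    J = 1 it equals z².
    """
    J = len(ja.ids)
    if ja.n <= J:
        raise ValueError(f"N={ja.n} must exceed J={J}")
    w = float(ja.gamma @ _solve_stabilized(ja.sigma, ja.gamma))
    return max(w, 0.0) / J


def r2_from_f(F: float, N: int, J: int) -> float:
    """Variance explained  R² = J·F/(N − J − 1 + J·F)  in [0, 1)."""
    if N <= J + 1:
        raise ValueError(f"N={N} must exceed J+1={J + 1}")
    if F < 0:
        raise ValueError("F must be non-negative")
    return J * F / (N - J - 1 + J * F)


def adjusted_r2(r2: float, N: int, J: int) -> float:
    """Adjusted R² = 1 − (1 − R²)(N − 1)/(N − J − 1); may be negative."""
    if J == 0:
        return r2
    if N <= J + 1:
        raise ValueError(f"N={N} must exceed J+1={J + 1}")
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    return 1.0 - (1.0 - r2) * (N - 1) / (N - J - 1)


def strength_summary(region: AlignedRegion, subset) -> tuple[int, float, float, float]:
    """(J, F, R², adjusted R²) for a variant subset; zeros when empty."""
    subset = list(subset)
    if not subset:
        return 0, 0.0, 0.0, 0.0
    ja = joint_from_marginal(region, subset)
    J = len(subset)
    F = f_statistic(ja)
    r2 = r2_from_f(F, ja.n, J)
    return J, F, r2, adjusted_r2(r2, ja.n, J)
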