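"""Joint-effect reconstruction and the F / R² / adjusted-R² chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisiv import synthetic as syn
from cisiv.strength import (
    adjusted_r2,
    f_statistic,
    is_singular,
    joint_from_marginal,
    r2_from_f,
    stabilize_ld,
    strength_summary,
)
from tests.conftest import make_region


class TestSingleVariant:
    def test_identity_case_gamma_sigma(self):
        reg = make_region([0.2], [0.02], np.eye(1), n=10_000)
        ja = joint_from_marginal(reg, ["v1"])
        assert ja.gamma[0] == pytest.approx(0.2, rel=1e-12)
        assert ja.sigma[0, 0] == pytest.approx(0.02**2, rel=1e-12)

    def test_f_equals_z_squared(self):
        reg = make_region([0.2], [0.02], np.eye(1), n=10_000)
        F = f_statistic(joint_from_marginal(reg, ["v1"]))
        assert F == pytest.approx(100.0, rel=1e-9)

    def test_r2_equals_single_variant_formula(self):
        # R² = z²/(N-2+z²) through the whole chain
        n, z = 10_000, 10.0
        reg = make_region([z * 0.02], [0.02], np.eye(1), n=n)
        _, _, r2, _ = strength_summary(reg, ["v1"])
        assert r2 == pytest.approx(z**2 / (n - 2 + z**2), rel=1e-9)


class TestOrthogonalCase:
    def test_gamma_equals_marginals_sigma_diagonal(self):
        reg = make_region([0.05, -0.03], [0.01, 0.012], np.eye(2), n=50_000)
        ja = joint_from_marginal(reg, ["v1", "v2"])
        assert np.allclose(ja.gamma, [0.05, -0.03], rtol=1e-12)
        assert ja.sigma[0, 1] == pytest.approx(0.0, abs=1e-15)
        # small effects: covariance close to the marginal se²
        assert np.allclose(np.diag(ja.sigma), [0.01**2, 0.012**2], rtol=0.01)


class TestIndividualLevelOracle:
    def test_joint_matches_multivariable_ols(self):
        """γ̂, Σγ̂ and R² from summary stats match an individual-level
        multivariable regression on the same sample."""
        panel = syn.simulate_panel(20_000, 6, block_sizes=[6],
                                   within_block_rho=0.6, seed=9, mode="gaussian")
        rng = np.random.default_rng(10)
        g = panel.genotypes
        y = 0.1 * g[:, 0] + 0.07 * g[:, 3] + rng.normal(0, 1, panel.n)
        trait = syn.SimulatedTrait(y, (panel.ids[0], panel.ids[3]), (0.1, 0.07),
                                   1.0, 0.0, (0, 3))
        region = syn.sumstats_from_panel(panel, trait)
        subset = list(panel.ids[:4])
        ja = joint_from_marginal(region, subset)
        # OLS with intercept
        X = np.column_stack([np.ones(panel.n), g[:, :4]])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        s2 = resid @ resid / (panel.n - 5)
        cov = s2 * np.linalg.inv(X.T @ X)
        assert np.allclose(ja.gamma, coef[1:], rtol=0.02)
        assert np.allclose(ja.sigma, cov[1:, 1:], rtol=0.03, atol=1e-8)
        # R² via the chain vs OLS coefficient of determination
        _, _, r2, _ = strength_summary(region, subset)
        tss = ((y - y.mean()) ** 2).sum()
        r2_ols = 1 - (resid @ resid) / tss
        assert r2 == pytest.approx(r2_ols, abs=0.01)


class TestFormulas:
    def test_r2_from_f_values(self):
        assert r2_from_f(0.0, 1000, 3) == 0.0
        assert r2_from_f(1000.0, 1002, 1) == pytest.approx(0.5)

    def test_r2_from_f_monotone_in_f(self):
        vals = [r2_from_f(f, 5000, 4) for f in (0.1, 1, 10, 100, 1e6)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1

    def test_r2_domain_errors(self):
        with pytest.raises(ValueError):
            r2_from_f(1.0, 4, 3)
        with pytest.raises(ValueError, match="sample size"):
            joint_from_marginal(
                make_region([0.1, 0.1], [0.05, 0.05], np.eye(2), n=3),
                ["v1", "v2"])

    def test_adjusted_r2_values(self):
        assert adjusted_r2(0.5, 101, 1) == pytest.approx(1 - 0.5 * 100 / 99)
        assert adjusted_r2(0.0, 50, 1) < 0
        assert adjusted_r2(0.3, 1000, 0) == 0.3  # J=0 bookkeeping identity

    @given(r2=st.floats(0, 0.99), j=st.integers(1, 20))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_adjusted_r2_below_r2_and_decreasing_in_j(self, r2, j):
        n = 1000
        adj = adjusted_r2(r2, n, j)
        assert adj <= r2 + 1e-15
        assert adjusted_r2(r2, n, j + 1) <= adj + 1e-15


class TestStabilization:
    def test_identity_unchanged(self):
        m = np.eye(3)
        assert stabilize_ld(m) is m

    def test_rank_one_shifted(self):
        m = np.ones((2, 2))
        out = stabilize_ld(m)
        ev = np.linalg.eigvalsh(out)
        assert ev[0] == pytest.approx(1e-8, rel=1e-3)
        assert ev[1] == pytest.approx(2 + 1e-8, rel=1e-9)
        assert out[0, 1] == 1.0  # off-diagonal untouched

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_floor_and_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(4, 6))
        m = np.corrcoef(A)  # may be near-singular
        out = np.asarray(stabilize_ld(m), float)
        assert np.linalg.eigvalsh(out)[0] >= 1e-8 * (1 - 1e-9)
        again = np.asarray(stabilize_ld(out), float)
        assert np.allclose(out, again, atol=1e-14)
        offdiag = ~np.eye(4, dtype=bool)
        assert np.allclose(out[offdiag], m[offdiag])

    def test_is_singular(self):
        assert not is_singular(np.eye(2))
        assert is_singular(np.ones((2, 2)))
        # third variant an exact average of two others in correlation space
        r13 = r23 = 0.9
        r12 = 2 * r13**2 - 1
        m = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1.0]])
        assert is_singular(m)
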