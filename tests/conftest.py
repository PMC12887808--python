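"""Shared fixtures: hand-built toy regions and seeded simulation replicates."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cisiv import synthetic as syn
from cisiv.data_model import AlignedRegion, LDMatrix, RegionSumstats


def make_region(beta, se, R, n=10_000, ids=None, eaf=None) -> AlignedRegion:
    """Build an AlignedRegion directly from effect/SE vectors and an LD matrix."""
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    J = beta.size
    if ids is None:
        ids = [f"v{i + 1}" for i in range(J)]
    z = beta / se
    pval = np.maximum(2 * stats.t.sf(np.abs(z), n - 2), 1e-300)
    tab = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "1",
            "pos": np.arange(J) + 1,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": 0.3 if eaf is None else eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )
    return AlignedRegion(RegionSumstats(tab), LDMatrix(np.asarray(ids, dtype=object), np.asarray(R, float)))


@pytest.fixture(scope="session")
def one_causal_rep():
    """One seeded small-profile replicate of the single-causal design."""
    panel = syn.simulate_panel(5_000, 300, seed=101)
    trait = syn.simulate_trait(panel, "one_causal", seed=102)
    region = syn.sumstats_from_panel(panel, trait)
    return panel, trait, region


@pytest.fixture(scope="session")
def two_causal_rep():
    """One seeded small-profile replicate of the two-causal design (rho = 0.5)."""
    panel = syn.simulate_panel(5_000, 300, seed=201)
    trait = syn.simulate_trait(panel, "two_causal", seed=202)
    region = syn.sumstats_from_panel(panel, trait)
    return panel, trait, region


@pytest.fixture(scope="session")
def scenario_reports():
    """Reduced-scale runs of the main simulation study, both scenarios.

    12 replicates at n = 5,000 / J = 300 with one tuning value per method;
    medians are compared against the analytic 40% / 30% benchmarks with
    Monte-Carlo-sized windows.
    """
    tunings = {"prune_modified": [0.4], "cojo": [0.5], "pca": [0.999]}
    one = syn.run_main_scenarios("one_causal", reps=12, n=5_000, J=300,
                                 tunings=tunings, seed=31)
    two = syn.run_main_scenarios("two_causal", reps=12, n=5_000, J=300,
                                 tunings=tunings, seed=32)
    return {"one_causal": one, "two_causal": two}
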