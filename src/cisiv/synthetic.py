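"""Synthetic genotype panels, traits and summary statistics.

Emulates the statistical structure of a dense cis region: a few hundred
to ~1,600 variants in blocks of strong local LD, one or two causal
variants explaining a known fraction of trait variance, and marginal
association estimates computed per variant exactly as a GWAS would.

Genotypes are drawn from a latent multivariate normal with AR(1)
correlation inside LD blocks (adjacent-variant correlation
``within_block_rho``, decaying geometrically with distance, independent
across blocks), thresholded into {0,1,2} dosages at Hardy-Weinberg
cut-points for a per-variant MAF drawn uniformly from (0.05, 0.5), then
column-standardized.  A ``gaussian`` mode skips thresholding for
exact-correlation tests.

Trait models (standardized genotypes G, heritability h² = 0.40 by
default):

* one causal variant:  X = √h²·G_c + ε,  ε ~ N(0, 1 − h²)
* two causal variants (correlation ρ ≈ 0.5):
  X = β(G_c1 + G_c2) + ε with β = √(h²/(2 + 2ρ)), so the pair jointly
  explains h² and each variant marginally explains h²(1 + ρ)/2
  (30% at h² = 0.40, ρ = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cisiv import pruning, susie
from cisiv.cojo import CojoConfig, cojo_select
from cisiv.data_model import (
    AlignedRegion,
    LDMatrix,
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

#: study-scale profile (region size of the motivating cis locus)
FULL_PROFILE = {"n": 20_000, "J": 1_620, "reps": 100}
#: reduced profile for fast runs
SMALL_PROFILE = {"n": 5_000, "J": 300, "reps": 50}

DEFAULT_H2 = 0.40
DEFAULT_RHO_CAUSAL = 0.5
DEFAULT_WITHIN_BLOCK_RHO = 0.9


@dataclass
class GenotypePanel:
    genotypes: np.ndarray        # n x J, column-standardized
    ids: tuple
    maf: np.ndarray
    block_sizes: tuple
    within_block_rho: float
    seed: int | None

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def J(self) -> int:
        return self.genotypes.shape[1]

    def corr_with(self, col: int) -> np.ndarray:
        """Empirical correlation of column ``col`` with every column."""
        g = self.genotypes
        return g.T @ g[:, col] / self.n


@dataclass
class SimulatedTrait:
    values: np.ndarray
    causal_ids: tuple
    effect_sizes: tuple
    residual_variance: float
    true_r2: float                # in-replicate OLS R² on the causal set
    causal_indices: tuple = ()


@dataclass
class ScenarioReport:
    scenario: str
    reps: int
    table: pd.DataFrame
    replicate_table: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def _default_block_sizes(J: int, rng: np.random.Generator) -> tuple:
    sizes: list[int] = []
    while sum(sizes) < J:
        sizes.append(int(rng.integers(20, 81)))
    sizes[-1] -= sum(sizes) - J
    if sizes[-1] == 0:
        sizes.pop()
    return tuple(sizes)


def simulate_panel(
    n: int,
    J: int,
    block_sizes=None,
    within_block_rho: float = DEFAULT_WITHIN_BLOCK_RHO,
    seed: int | None = None,
    mode: str = "genotype",
    maf_range: tuple = (0.05, 0.5),
) -> GenotypePanel:
    """Draw a standardized genotype panel with block-AR(1) LD."""
    if n < 100 or J < 2:
        raise ValueError("need n >= 100 and J >= 2")
    rng = np.random.default_rng(seed)
    if block_sizes is None:
        block_sizes = _default_block_sizes(J, rng)
    block_sizes = tuple(int(b) for b in block_sizes)
    if sum(block_sizes) != J:
        raise ValueError(f"block sizes sum to {sum(block_sizes)}, expected {J}")

    # latent AR(1) within blocks via the causal recursion (exact Cholesky);
    # variants are rows here so the recursion runs on contiguous memory
    latent = rng.standard_normal((J, n))
    rho = within_block_rho
    innov = np.sqrt(1 - rho**2)
    col = 0
    for b in block_sizes:
        for j in range(1, b):
            latent[col + j] *= innov
            latent[col + j] += rho * latent[col + j - 1]
        col += b

    maf = rng.uniform(*maf_range, size=J)
    if mode == "gaussian":
        g = latent
    elif mode == "genotype":
        q1 = stats.norm.ppf((1 - maf) ** 2)[:, None]
        q2 = stats.norm.ppf(1 - maf**2)[:, None]
        g = (latent >= q1).astype(float)
        g += latent >= q2
        degenerate = np.flatnonzero(g.std(axis=1) == 0)
        for j in degenerate:  # vanishingly rare at n >= 100, maf >= 0.05
            while g[j].std() == 0:
                maf[j] = rng.uniform(0.2, 0.5)
                g[j] = (latent[j] >= stats.norm.ppf((1 - maf[j]) ** 2)).astype(float)
                g[j] += latent[j] >= stats.norm.ppf(1 - maf[j] ** 2)
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    g -= g.mean(axis=1, keepdims=True)
    g /= g.std(axis=1, keepdims=True)
    g = g.T  # n x J view, column-contiguous
    ids = tuple(f"rs{j + 1}" for j in range(J))
    return GenotypePanel(g, ids, maf, block_sizes, rho, seed)


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    X1 = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid**2).sum()) / tss


def find_correlated_pair(panel: GenotypePanel, first: int,
                         rho_causal: float, tol: float = 0.05) -> int | None:
    """Partner of ``first`` with empirical correlation closest to the target."""
    corr = panel.corr_with(first)
    corr[first] = np.inf
    dev = np.abs(corr - rho_causal)
    j = int(np.argmin(dev))
    return j if dev[j] <= tol else None


def simulate_trait(
    panel: GenotypePanel,
    scenario: str = "one_causal",
    h2: float = DEFAULT_H2,
    rho_causal: float = DEFAULT_RHO_CAUSAL,
    seed: int | None = None,
) -> SimulatedTrait:
    """Simulate a trait with known variance explained by its causal set."""
    if not 0 <= h2 < 1:
        raise ValueError("h2 must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    g = panel.genotypes
    n = panel.n
    if scenario == "one_causal":
        c1 = int(rng.integers(panel.J))
        beta = np.sqrt(h2)
        genetic = beta * g[:, c1]
        causal = (c1,)
        effects = (beta,)
    elif scenario == "two_causal":
        order = rng.permutation(panel.J)
        c1 = c2 = None
        for cand in order:
            partner = find_correlated_pair(panel, int(cand), rho_causal)
            if partner is not None:
                c1, c2 = int(cand), partner
                break
        if c1 is None:
            raise ValueError(
                "no variant pair with the requested correlation; "
                "increase J or adjust the block structure"
            )
        beta = np.sqrt(h2 / (2 + 2 * rho_causal))
        genetic = beta * (g[:, c1] + g[:, c2])
        causal = (c1, c2)
        effects = (beta, beta)
    else:
        raise ValueError(f"unknown scenario: {scenario!r}")
    resid_var = 1.0 - h2
    y = genetic + rng.normal(0.0, np.sqrt(resid_var), size=n)
    true_r2 = _ols_r2(g[:, list(causal)], y)
    return SimulatedTrait(
        values=y,
        causal_ids=tuple(panel.ids[c] for c in causal),
        effect_sizes=effects,
        residual_variance=resid_var,
        true_r2=true_r2,
        causal_indices=causal,
    )


def sumstats_from_panel(panel: GenotypePanel, trait: SimulatedTrait,
                        keep: np.ndarray | None = None) -> AlignedRegion:
    """Per-variant univariable regressions + empirical LD, as an AlignedRegion.

    ``keep`` optionally restricts to a boolean mask or index array of
    variants (used by the proxy-removal study).
    """
    g = panel.genotypes
    ids = np.asarray(panel.ids, dtype=object)
    maf = panel.maf
    if keep is not None:
        g = g[:, keep]
        ids = ids[keep]
        maf = maf[keep]
    n, J = g.shape
    y = trait.values - trait.values.mean()
    var_y = float(y @ y) / n
    beta = g.T @ y / n  # columns are standardized (ddof=0)
    resid_var = np.maximum(var_y - beta**2, 1e-300)
    se = np.sqrt(resid_var / (n - 2))
    tstat = beta / se
    pval = np.maximum(2 * stats.t.sf(np.abs(tstat), n - 2), 1e-300)
    table = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "1",
            "pos": (np.flatnonzero(keep) + 1 if keep is not None
                    and np.asarray(keep).dtype == bool else np.arange(J) + 1),
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )
    ld = g.T @ g / n
    ld = np.clip((ld + ld.T) / 2, -1.0, 1.0)
    np.fill_diagonal(ld, 1.0)
    return AlignedRegion(RegionSumstats(table), LDMatrix(ids, ld))


# ---------------------------------------------------------------------------
# scenario runners


DEFAULT_TUNINGS = {
    "prune_modified": [0.1, 0.2, 0.4],
    "cojo": [0.1, 0.5, 0.9],
    "pca": [0.99, 0.995, 0.999],
}


def _child_seeds(seed: int | None, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(k)]


def _run_methods_once(region: AlignedRegion, methods, tunings, seed: int):
    """One replicate's (method, tuning) -> (J, R²) rows; NaN on failure."""
    rows = []
    filtered = filter_by_p(region)
    lead_r2 = np.nan
    if len(filtered):
        _, _, lead_r2, _ = strength_summary(filtered, [filtered.lead_id()])
    for method in methods:
        tune_values = tunings.get(method, [None])
        for tv in tune_values:
            label = method if tv is None else f"{method}@{tv:g}"
            try:
                if method == "lead_only":
                    J, r2 = (1, lead_r2) if len(filtered) else (0, np.nan)
                elif method == "prune_standard":
                    res = pruning.prune_standard(
                        filtered, PruneConfig(tv, "standard", seed=seed))
                    J, r2 = res.J, res.r2
                elif method == "prune_modified":
                    res = pruning.prune_modified(
                        filtered, PruneConfig(tv, "modified", seed=seed))
                    J, r2 = res.J, res.r2
                elif method == "cojo":
                    res = cojo_select(region, CojoConfig(collinearity_threshold=tv))
                    J, r2 = res.J, res.r2
                elif method == "susie":
                    res = susie_select(filtered, SusieConfig(seed=seed))
                    if res.J == 0 and len(filtered):  # fallback to the lead
                        J, r2 = 1, lead_r2
                    else:
                        J, r2 = res.J, res.r2
                elif method == "pca":
                    pruned = preprune_r2(filtered, 0.95, seed=seed)
                    res = pca_select(pruned, tv)
                    J, r2 = res.J, res.r2
                else:
                    raise ValueError(f"unknown method: {method!r}")
            except Exception:  # NA policy: record, do not abort the study
                J, r2 = np.nan, np.nan
            rows.append({"method": label, "J": J, "r2": r2,
                         "norm_r2": r2 / lead_r2 if lead_r2 else np.nan})
    return rows


def run_main_scenarios(
    scenario: str = "one_causal",
    reps: int = 100,
    n: int = 20_000,
    J: int = 1_620,
    methods=("lead_only", "prune_modified", "cojo", "susie", "pca"),
    tunings: dict | None = None,
    seed: int | None = None,
    h2: float = DEFAULT_H2,
) -> ScenarioReport:
    """Replicate the main simulation study for one scenario.

    Per replicate: fresh panel, trait and summary statistics; every method
    at every tuning value; medians of J and R² (and of the per-replicate
    normalized R²) across replicates.
    """
    tunings = dict(DEFAULT_TUNINGS, **(tunings or {}))
    seeds = _child_seeds(seed, 3 * reps)
    rows = []
    true_r2s = []
    for rep in range(reps):
        s_panel, s_trait, s_sel = seeds[3 * rep: 3 * rep + 3]
        panel = simulate_panel(n, J, seed=s_panel)
        trait = simulate_trait(panel, scenario, h2=h2, seed=s_trait)
        region = sumstats_from_panel(panel, trait)
        true_r2s.append(trait.true_r2)
        for row in _run_methods_once(region, methods, tunings, s_sel):
            rows.append({"rep": rep, **row})
    per_rep = pd.DataFrame(rows)
    table = (
        per_rep.groupby("method", sort=False)
        .agg(
            median_J=("J", "median"),
            median_r2=("r2", "median"),
            median_norm_r2=("norm_r2", "median"),
            n_failed=("r2", lambda s: int(s.isna().sum())),
        )
        .reset_index()
    )
    return ScenarioReport(
        scenario=scenario,
        reps=reps,
        table=table,
        replicate_table=per_rep,
        meta={"n": n, "J": J, "h2": h2,
              "median_true_r2": float(np.median(true_r2s))},
    )


def run_extended_I(
    reps: int = 100,
    n: int = 20_000,
    J: int = 1_620,
    proxy_thresholds=(0.95, 0.8, 0.4),
    methods=("lead_only", "prune_modified", "cojo", "susie", "pca"),
    tunings: dict | None = None,
    seed: int | None = None,
    h2: float = DEFAULT_H2,
) -> ScenarioReport:
    """Proxy-removal study: the causal variant and its r²-proxies are
    dropped before selection, at each threshold in ``proxy_thresholds``."""
    tunings = dict(DEFAULT_TUNINGS, **(tunings or {}))
    seeds = _child_seeds(seed, 3 * reps)
    rows = []
    for rep in range(reps):
        s_panel, s_trait, s_sel = seeds[3 * rep: 3 * rep + 3]
        panel = simulate_panel(n, J, seed=s_panel)
        trait = simulate_trait(panel, "one_causal", h2=h2, seed=s_trait)
        c1 = trait.causal_indices[0]
        corr2 = panel.corr_with(c1) ** 2
        for thr in proxy_thresholds:
            keep = corr2 <= thr
            keep[c1] = False
            if keep.sum() < 2:
                continue
            region = sumstats_from_panel(panel, trait, keep=keep)
            for row in _run_methods_once(region, methods, tunings, s_sel):
                rows.append({"rep": rep, "proxy_threshold": thr, **row})
    per_rep = pd.DataFrame(rows)
    table = (
        per_rep.groupby(["proxy_threshold", "method"], sort=False)
        .agg(median_J=("J", "median"), median_r2=("r2", "median"),
             median_norm_r2=("norm_r2", "median"))
        .reset_index()
    )
    return ScenarioReport("extended_I", reps, table, per_rep,
                          meta={"n": n, "J": J, "h2": h2})


def run_extended_II(
    reps: int = 100,
    n: int = 20_000,
    J: int = 1_620,
    theta: float = 0.3,
    delta: float = 0.3,
    methods=("lead_only", "prune_modified", "cojo", "susie", "pca"),
    tunings: dict | None = None,
    seed: int | None = None,
    h2: float = DEFAULT_H2,
) -> ScenarioReport:
    """Horizontal-pleiotropy study (two-sample MR).

    Exposure: two *independent* causal variants (different LD blocks),
    each with effect √(h²/2).  Outcome, in an independently drawn panel:
    Y = θ·X + δ·G_pleio + ε, where G_pleio is the first causal variant,
    so δ is a direct effect not mediated by the exposure.  Reports each
    method's mean MR estimate, bias relative to θ, and Monte-Carlo SE.
    """
    tunings = dict(DEFAULT_TUNINGS, **(tunings or {}))
    seeds = _child_seeds(seed, 5 * reps)
    rows = []
    for rep in range(reps):
        s_p1, s_t1, s_p2, s_e, s_sel = seeds[5 * rep: 5 * rep + 5]
        panel_x = simulate_panel(n, J, seed=s_p1)
        rng = np.random.default_rng(s_t1)
        # two causal variants in different blocks (independent)
        bounds = np.cumsum((0,) + panel_x.block_sizes)
        b1, b2 = rng.choice(len(panel_x.block_sizes), size=2, replace=False)
        c1 = int(rng.integers(bounds[b1], bounds[b1 + 1]))
        c2 = int(rng.integers(bounds[b2], bounds[b2 + 1]))
        beta = np.sqrt(h2 / 2)
        x = beta * (panel_x.genotypes[:, c1] + panel_x.genotypes[:, c2])
        x = x + rng.normal(0, np.sqrt(1 - h2), size=n)
        trait_x = SimulatedTrait(x, (panel_x.ids[c1], panel_x.ids[c2]),
                                 (beta, beta), 1 - h2,
                                 _ols_r2(panel_x.genotypes[:, [c1, c2]], x),
                                 (c1, c2))
        region_x = sumstats_from_panel(panel_x, trait_x)
        # independent outcome sample with the same LD structure
        panel_y = simulate_panel(n, J, block_sizes=panel_x.block_sizes,
                                 seed=s_p2)
        rng_y = np.random.default_rng(s_e)
        x_out = beta * (panel_y.genotypes[:, c1] + panel_y.genotypes[:, c2])
        x_out = x_out + rng_y.normal(0, np.sqrt(1 - h2), size=n)
        y_out = theta * x_out + delta * panel_y.genotypes[:, c1] + \
            rng_y.normal(0, 1.0, size=n)
        trait_y = SimulatedTrait(y_out, (panel_y.ids[c1],), (delta,), 1.0,
                                 _ols_r2(panel_y.genotypes[:, [c1, c2]], y_out),
                                 (c1,))
        outcome_region = sumstats_from_panel(panel_y, trait_y)
        outcome = outcome_region.sumstats

        filtered = filter_by_p(region_x)
        if not len(filtered):
            continue
        selections = {}
        lead = filtered.lead_id()
        _, F, r2, adj = strength_summary(filtered, [lead])
        selections["lead_only"] = SelectionResult(
            "lead_only", {}, (lead,), 1, F, r2, adj)
        for method in methods:
            if method == "lead_only":
                continue
            for tv in tunings.get(method, [None]):
                label = method if tv is None else f"{method}@{tv:g}"
                try:
                    if method == "prune_modified":
                        selections[label] = pruning.prune_modified(
                            filtered, PruneConfig(tv, "modified", seed=s_sel))
                    elif method == "cojo":
                        selections[label] = cojo_select(
                            region_x, CojoConfig(collinearity_threshold=tv))
                    elif method == "susie":
                        sel = susie_select(filtered, SusieConfig(seed=s_sel))
                        selections[label] = sel if sel.J else selections["lead_only"]
                    elif method == "pca":
                        pruned = preprune_r2(filtered, 0.95, seed=s_sel)
                        selections[label] = pca_select(pruned, tv)
                except Exception:
                    continue
        for label, sel in selections.items():
            try:
                res = mr_with_selection(
                    filtered if sel.method != "cojo" else region_x,
                    outcome, sel)
                rows.append({"rep": rep, "method": label,
                             "estimate": res.estimate, "se": res.se})
            except Exception:
                rows.append({"rep": rep, "method": label,
                             "estimate": np.nan, "se": np.nan})
    per_rep = pd.DataFrame(rows)
    table = (
        per_rep.groupby("method", sort=False)
        .agg(mean_estimate=("estimate", "mean"),
             mc_se=("estimate", lambda s: s.std(ddof=1) / np.sqrt(s.notna().sum())),
             mean_se=("se", "mean"),
             reps_used=("estimate", lambda s: int(s.notna().sum())))
        .reset_index()
    )
    table["bias"] = table["mean_estimate"] - theta
    return ScenarioReport("extended_II", reps, table, per_rep,
                          meta={"n": n, "J": J, "theta": theta, "delta": delta})
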