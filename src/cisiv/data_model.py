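"""Core data types, readers and shared pre-selection filters.

A *region* is a single cis gene locus: a table of per-variant marginal
(univariable) GWAS association estimates plus a signed LD correlation
matrix over the same variants.  All selection methods consume an
:class:`AlignedRegion`, in which the two inputs share one variant order
and every beta is expressed with respect to the LD reference's coded
allele.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("cisiv")

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class FormatError(ValueError):
    """Malformed input file (missing column, non-square matrix, ...)."""


class ValidationError(ValueError):
    """Well-formed input that violates a data invariant."""


class HarmonizationError(ValueError):
    """Allele pair irreconcilable between summary statistics and LD reference."""


@dataclass
class RegionSumstats:
    """Marginal association estimates for one cis region.

    ``table`` holds one row per variant with the canonical columns
    ``variant_id chrom pos effect_allele other_allele eaf beta se pval n``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        t = self.table.reset_index(drop=True)
        if t["variant_id"].duplicated().any():
            dup = t.loc[t["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValidationError(f"duplicate variant_id: {dup}")
        bad_se = t.index[~(t["se"] > 0)]
        if len(bad_se):
            raise ValidationError(
                f"non-positive se in row {bad_se[0] + 1} "
                f"(variant {t.loc[bad_se[0], 'variant_id']})"
            )
        if not ((t["eaf"] > 0) & (t["eaf"] < 1)).all():
            bad = t.index[~((t["eaf"] > 0) & (t["eaf"] < 1))][0]
            raise ValidationError(f"eaf outside (0,1) in row {bad + 1}")
        if not ((t["pval"] > 0) & (t["pval"] <= 1)).all():
            bad = t.index[~((t["pval"] > 0) & (t["pval"] <= 1))][0]
            raise ValidationError(f"pval outside (0,1] in row {bad + 1}")
        object.__setattr__(self, "table", t)

    @property
    def ids(self) -> np.ndarray:
        return self.table["variant_id"].to_numpy()

    @property
    def n(self) -> int:
        # min(n) is the conservative region sample size when per-variant
        # n is heterogeneous.
        return int(self.table["n"].min())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class LDMatrix:
    """Signed variant-variant correlation matrix with a variant-ID index."""

    ids: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=object)
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise FormatError(f"LD matrix is not square: shape {r.shape}")
        if r.shape[0] != len(ids):
            raise FormatError("LD matrix dimension does not match variant IDs")
        if len(ids):
            if not np.allclose(r, r.T, atol=1e-8):
                raise ValidationError("LD matrix is not symmetric (tolerance 1e-8)")
            if not np.allclose(np.diag(r), 1.0, atol=1e-8):
                raise ValidationError("LD matrix diagonal is not 1 (tolerance 1e-8)")
            if np.abs(r).max() > 1 + 1e-8:
                raise ValidationError("LD matrix has |r| > 1 + 1e-8")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "r", r)
        object.__setattr__(
            self, "_index", {v: i for i, v in enumerate(ids)}
        )

    def indices(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[v] for v in ids], dtype=int)
        except KeyError as err:  # pragma: no cover - message path
            raise KeyError(f"variant not in LD matrix: {err.args[0]}") from None

    def submatrix(self, ids) -> np.ndarray:
        idx = self.indices(ids)
        return self.r[np.ix_(idx, idx)]

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class AlignedRegion:
    """Summary statistics and LD with identical variant order, harmonized."""

    sumstats: RegionSumstats
    ld: LDMatrix
    palindromic_flagged: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if list(self.sumstats.ids) != list(self.ld.ids):
            raise ValidationError(
                "sumstats and LD variant IDs differ or are ordered differently"
            )

    @property
    def ids(self) -> np.ndarray:
        return self.sumstats.ids

    @property
    def beta(self) -> np.ndarray:
        return self.sumstats.table["beta"].to_numpy(float)

    @property
    def se(self) -> np.ndarray:
        return self.sumstats.table["se"].to_numpy(float)

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def pval(self) -> np.ndarray:
        return self.sumstats.table["pval"].to_numpy(float)

    @property
    def n(self) -> int:
        return self.sumstats.n

    def __len__(self) -> int:
        return len(self.sumstats)

    def restrict(self, ids) -> "AlignedRegion":
        """Sub-region over ``ids`` (kept in the given order)."""
        ids = list(ids)
        tab = self.sumstats.table.set_index("variant_id").loc[ids].reset_index()
        ld = LDMatrix(np.asarray(ids, dtype=object), self.ld.submatrix(ids))
        flagged = tuple(v for v in self.palindromic_flagged if v in set(ids))
        return AlignedRegion(RegionSumstats(tab), ld, flagged)

    def lead_id(self) -> str:
        """Variant with the largest |z| (equivalently the smallest p)."""
        return self.ids[int(np.argmax(np.abs(self.z)))]


@dataclass
class SelectionResult:
    """Outcome of one instrument-selection method at one tuning setting."""

    method: str
    tuning: dict
    selected_ids: tuple
    J: int
    F: float
    r2: float
    adj_r2: float
    seed: int | None = None
    pc_basis: object | None = None
    sequence: tuple = ()
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method != "pca" and self.J != len(self.selected_ids):
            raise ValidationError("J must equal the number of selected variants")


# ---------------------------------------------------------------------------
# readers / writers


def read_sumstats(path, column_map: dict | None = None) -> RegionSumstats:
    """Read a tab-delimited summary-statistics table.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"variant_id": "SNP", "beta": "BETA"}``.  Rows with missing beta or
    se are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "variant_id": str})
    if column_map:
        if column_map.get("chrom") in df.columns:
            df[column_map["chrom"]] = df[column_map["chrom"]].astype(str)
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"missing required column(s): {', '.join(missing)} "
            f"(file columns: {', '.join(df.columns)})"
        )
    df = df[CANONICAL_COLUMNS]
    n_missing = int(df["beta"].isna().sum() + df["se"].isna().sum())
    if n_missing:
        before = len(df)
        df = df.dropna(subset=["beta", "se"])
        logger.info("dropped %d row(s) with missing beta/se", before - len(df))
    return RegionSumstats(df)


def write_sumstats(ss: RegionSumstats, path) -> None:
    """Write the canonical TSV; floats at full round-trip precision."""
    ss.table.to_csv(path, sep="\t", index=False)


def read_ld(path, format: str = "square") -> LDMatrix:
    """Read an LD matrix.

    ``square``: first row is a variant-ID header, body is a whitespace-
    delimited square matrix.  ``long_pairs``: PLINK-style columns
    ``SNP_A SNP_B R``; the matrix is symmetrized by mirroring and
    unobserved pairs are set to 0 with a warning.
    """
    if format == "square":
        with open(path) as fh:
            header = fh.readline().split()
            body = [line.split() for line in fh if line.strip()]
        if any(len(row) != len(header) for row in body) or len(body) != len(header):
            raise FormatError(
                f"square LD file body is not {len(header)}x{len(header)}"
            )
        r = np.array(body, dtype=float)
        return LDMatrix(np.asarray(header, dtype=object), r)
    if format == "long_pairs":
        df = pd.read_csv(path, sep=r"\s+")
        for col in ("SNP_A", "SNP_B", "R"):
            if col not in df.columns:
                raise FormatError(f"missing required column: {col}")
        ids = list(dict.fromkeys(pd.concat([df["SNP_A"], df["SNP_B"]])))
        idx = {v: i for i, v in enumerate(ids)}
        J = len(ids)
        r = np.full((J, J), np.nan)
        np.fill_diagonal(r, 1.0)
        for a, b, val in zip(df["SNP_A"], df["SNP_B"], df["R"].astype(float)):
            r[idx[a], idx[b]] = val
            r[idx[b], idx[a]] = val
        unobserved = int(np.isnan(r[np.triu_indices(J, 1)]).sum())
        if unobserved:
            warnings.warn(
                f"{unobserved} unobserved variant pair(s) set to r = 0",
                stacklevel=2,
            )
            r = np.nan_to_num(r, nan=0.0)
        return LDMatrix(np.asarray(ids, dtype=object), r)
    raise ValueError(f"unknown LD format: {format!r}")


# ---------------------------------------------------------------------------
# harmonization and filters


def harmonize(
    ss: RegionSumstats,
    ld: LDMatrix,
    ld_coded_alleles: dict | None = None,
) -> AlignedRegion:
    """Align summary statistics to the LD reference.

    Variants are restricted to the intersection and ordered by genomic
    position (ties by variant ID).  When a variant's effect allele differs
    from the LD coded allele, beta is negated and eaf replaced by 1-eaf.
    Palindromic variants (A/T, C/G) with 0.42 < eaf < 0.58 are flagged in
    the result, not dropped.  With ``ld_coded_alleles=None`` the LD matrix
    is assumed to be coded on the sumstats effect alleles.
    """
    common = set(ss.ids) & set(ld.ids)
    tab = ss.table[ss.table["variant_id"].isin(common)].copy()
    tab = tab.sort_values(["pos", "variant_id"], kind="mergesort").reset_index(drop=True)

    flagged = []
    if ld_coded_alleles is not None:
        betas = tab["beta"].to_numpy(float).copy()
        eafs = tab["eaf"].to_numpy(float).copy()
        ea = tab["effect_allele"].to_numpy(object).copy()
        oa = tab["other_allele"].to_numpy(object).copy()
        for i, vid in enumerate(tab["variant_id"]):
            coded = ld_coded_alleles.get(vid)
            if coded is None or coded == ea[i]:
                pass
            elif coded == oa[i]:
                betas[i] = -betas[i]
                eafs[i] = 1 - eafs[i]
                ea[i], oa[i] = oa[i], ea[i]
            else:
                raise HarmonizationError(
                    f"variant {vid}: LD coded allele {coded} matches neither "
                    f"{ea[i]} nor {oa[i]}"
                )
        tab["beta"], tab["eaf"] = betas, eafs
        tab["effect_allele"], tab["other_allele"] = ea, oa
    for _, row in tab.iterrows():
        pair = frozenset({str(row["effect_allele"]).upper(), str(row["other_allele"]).upper()})
        if pair in _PALINDROMIC and 0.42 < row["eaf"] < 0.58:
            flagged.append(row["variant_id"])

    order = list(tab["variant_id"])
    sub = LDMatrix(np.asarray(order, dtype=object), ld.submatrix(order))
    return AlignedRegion(RegionSumstats(tab), sub, tuple(flagged))


def filter_by_p(region: AlignedRegion, p_threshold: float = 0.001) -> AlignedRegion:
    """Keep variants with marginal p strictly below ``p_threshold``."""
    keep = region.ids[region.pval < p_threshold]
    return region.restrict(keep)


def selection_order(region: AlignedRegion, seed: int | None = None,
                    deterministic_ties: bool = False) -> np.ndarray:
    """Variant IDs in selection priority order (strongest first).

    Ordering is by |z| descending, which is identical to marginal p
    ascending (all p share the same reference distribution) but immune to
    floating-point underflow of extreme p-values.  Exact ties are broken
    uniformly at random with ``seed``, or by position when
    ``deterministic_ties`` is set.
    """
    absz = np.abs(region.z)
    if deterministic_ties:
        jitter = np.zeros(len(absz))
    else:
        rng = np.random.default_rng(seed)
        jitter = rng.random(len(absz))
    pos = region.sumstats.table["pos"].to_numpy()
    order = np.lexsort((jitter, pos, -absz)) if deterministic_ties else np.lexsort((jitter, -absz))
    return region.ids[order]


def preprune_r2(region: AlignedRegion, r2_cap: float = 0.95,
                seed: int | None = None) -> AlignedRegion:
    """Greedy removal of extremely highly correlated variants.

    Walk variants in ascending-p order; drop any variant whose squared
    correlation with an already-kept variant exceeds ``r2_cap``.  The
    region's lead variant always survives.  Output preserves positional
    order.
    """
    if len(region) <= 1:
        return region
    order = selection_order(region, seed=seed)
    idx = {v: i for i, v in enumerate(region.ids)}
    r2 = region.ld.r ** 2
    kept: list[int] = []
    for vid in order:
        i = idx[vid]
        if all(r2[i, j] <= r2_cap for j in kept):
            kept.append(i)
    kept_ids = [v for v in region.ids if idx[v] in set(kept)]
    return region.restrict(kept_ids)
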