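"""Readers, writers, harmonization and the shared pre-selection filters."""

import numpy as np
import pandas as pd
import pytest

from cisiv.data_model import (
    FormatError,
    HarmonizationError,
    LDMatrix,
    RegionSumstats,
    ValidationError,
    filter_by_p,
    harmonize,
    preprune_r2,
    read_ld,
    read_sumstats,
    write_sumstats,
)
from tests.conftest import make_region


def _sumstats_df(**over):
    df = pd.DataFrame(
        {
            "variant_id": ["a", "b", "c"],
            "chrom": "16",
            "pos": [100, 200, 300],
            "effect_allele": ["A", "C", "T"],
            "other_allele": ["G", "T", "C"],
            "eaf": [0.2, 0.4, 0.3],
            "beta": [0.11, -0.05, 0.02],
            "se": [0.01, 0.012, 0.011],
            "pval": [1e-20, 3e-5, 0.07],
            "n": 10_708,
        }
    )
    for k, v in over.items():
        df[k] = v
    return df


class TestReaders:
    def test_sumstats_round_trip_full_precision(self, tmp_path):
        ss = RegionSumstats(_sumstats_df(beta=[0.1234567890123, -1e-7, 3.3]))
        path = tmp_path / "ss.tsv"
        write_sumstats(ss, path)
        back = read_sumstats(path)
        pd.testing.assert_frame_equal(back.table, ss.table)

    def test_column_map_round_trip(self, tmp_path):
        df = _sumstats_df().rename(columns={"variant_id": "SNP", "beta": "BETA", "se": "SE"})
        path = tmp_path / "alt.tsv"
        df.to_csv(path, sep="\t", index=False)
        ss = read_sumstats(path, column_map={"variant_id": "SNP", "beta": "BETA", "se": "SE"})
        assert list(ss.ids) == ["a", "b", "c"]
        assert ss.table["beta"].tolist() == [0.11, -0.05, 0.02]

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        _sumstats_df().drop(columns=["se"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="se"):
            read_sumstats(path)

    def test_nonpositive_se_names_the_row(self):
        with pytest.raises(ValidationError, match="row 2"):
            RegionSumstats(_sumstats_df(se=[0.01, 0.0, 0.011]))

    def test_read_ld_square(self, tmp_path):
        path = tmp_path / "ld.txt"
        path.write_text("a b\n1 0.5\n0.5 1\n")
        ld = read_ld(path, format="square")
        assert ld.r[0, 1] == 0.5 and list(ld.ids) == ["a", "b"]

    def test_read_ld_long_pairs_fills_missing_with_zero(self, tmp_path):
        path = tmp_path / "ld.ld"
        path.write_text("SNP_A SNP_B R\na b 0.3\na c 0.1\n")
        with pytest.warns(UserWarning, match="unobserved"):
            ld = read_ld(path, format="long_pairs")
        i = {v: k for k, v in enumerate(ld.ids)}
        assert ld.r[i["a"], i["b"]] == 0.3
        assert ld.r[i["b"], i["c"]] == 0.0
        assert np.allclose(np.diag(ld.r), 1)

    def test_asymmetric_square_rejected(self, tmp_path):
        path = tmp_path / "ld.txt"
        path.write_text("a b\n1 0.5\n0.4 1\n")
        with pytest.raises(ValidationError, match="symmetric"):
            read_ld(path, format="square")

    def test_r_above_one_rejected(self):
        with pytest.raises(ValidationError, match=r"\|r\|"):
            LDMatrix(np.array(["a", "b"], dtype=object), np.array([[1.0, 1.2], [1.2, 1.0]]))


class TestHarmonize:
    def _inputs(self):
        ss = RegionSumstats(_sumstats_df())
        R = np.array([[1, 0.5, 0.2], [0.5, 1, 0.1], [0.2, 0.1, 1.0]])
        ld = LDMatrix(np.array(["a", "b", "c"], dtype=object), R)
        return ss, ld

    def test_matching_allele_leaves_beta(self):
        ss, ld = self._inputs()
        reg = harmonize(ss, ld, {"a": "A", "b": "C", "c": "T"})
        assert reg.beta[0] == pytest.approx(0.11)

    def test_flip_negates_beta_and_eaf(self):
        ss, ld = self._inputs()
        reg = harmonize(ss, ld, {"a": "G", "b": "C", "c": "T"})
        assert reg.beta[0] == pytest.approx(-0.11)
        assert reg.sumstats.table["eaf"].iloc[0] == pytest.approx(0.8)

    def test_irreconcilable_allele_raises(self):
        ss, ld = self._inputs()
        with pytest.raises(HarmonizationError, match="a"):
            harmonize(ss, ld, {"a": "T"})

    def test_intersection_only(self):
        ss, _ = self._inputs()
        R = np.array([[1, 0.1], [0.1, 1]])
        ld = LDMatrix(np.array(["b", "c"], dtype=object), R)
        reg = harmonize(ss, ld)
        assert list(reg.ids) == ["b", "c"]

    def test_idempotent(self):
        ss, ld = self._inputs()
        coded = {"a": "G", "b": "C", "c": "T"}
        once = harmonize(ss, ld, coded)
        twice = harmonize(once.sumstats, once.ld, coded)
        pd.testing.assert_frame_equal(once.sumstats.table, twice.sumstats.table)

    def test_palindromic_intermediate_freq_flagged_not_dropped(self):
        df = _sumstats_df(effect_allele=["A", "C", "T"],
                          other_allele=["T", "G", "A"],
                          eaf=[0.5, 0.1, 0.3])
        ss = RegionSumstats(df)
        R = np.eye(3)
        ld = LDMatrix(np.array(["a", "b", "c"], dtype=object), R)
        reg = harmonize(ss, ld)
        assert reg.palindromic_flagged == ("a",)
        assert len(reg) == 3


class TestFilters:
    def test_filter_by_p_counts(self):
        reg = make_region([0.3, 0.05, 0.04], [0.05] * 3, np.eye(3), n=2000)
        # z = 6, 1, 0.8 -> p ~ 1e-9, 0.32, 0.42
        out = filter_by_p(reg, 0.001)
        assert list(out.ids) == ["v1"]
        assert filter_by_p(reg, 1.0).ids.tolist() == ["v1", "v2", "v3"]
        assert len(filter_by_p(reg, 1e-12)) == 0

    def test_preprune_drops_near_duplicate_keeps_stronger(self):
        R = np.array([[1, 0.995], [0.995, 1]])
        reg = make_region([0.30, 0.25], [0.03, 0.03], R, n=5000)
        out = preprune_r2(reg, 0.95)
        assert list(out.ids) == ["v1"]

    def test_preprune_noop_below_cap_and_singleton(self):
        R = np.array([[1, 0.5], [0.5, 1]])
        reg = make_region([0.3, 0.25], [0.03, 0.03], R)
        assert len(preprune_r2(reg, 0.95)) == 2
        single = make_region([0.3], [0.03], np.eye(1))
        assert list(preprune_r2(single).ids) == ["v1"]

    def test_preprune_output_respects_cap(self, two_causal_rep):
        _, _, region = two_causal_rep
        out = preprune_r2(filter_by_p(region), 0.95, seed=0)
        r2 = out.ld.r ** 2
        np.fill_diagonal(r2, 0)
        assert r2.max() <= 0.95 + 1e-12

    def test_filter_order_insensitive(self):
        rng = np.random.default_rng(5)
        J = 8
        A = rng.normal(size=(J, J))
        R = np.corrcoef(A)
        beta = rng.normal(0, 0.1, J)
        reg = make_region(beta, np.full(J, 0.02), R, n=4000)
        perm = rng.permutation(J)
        reg_p = reg.restrict(reg.ids[perm])
        a = set(preprune_r2(filter_by_p(reg, 0.5), 0.5, seed=3).ids)
        b = set(preprune_r2(filter_by_p(reg_p, 0.5), 0.5, seed=3).ids)
        assert a == b
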