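"""Readers, quantile normalization and expression summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexkit.data_io import (
    ExpressionMatrix,
    quantile_normalize,
    read_expression,
    read_gene_list,
    read_gmt,
    read_jaspar_pfm,
    read_promoter_fasta,
    summarize_gene,
)
from coexkit.errors import DataError, FormatError

from oracles import quantile_normalize_brute


# ---------------------------------------------------------------------------
# expression readers

class TestReadExpression:
    def test_tsv_identity_load(self, write_tsv):
        path = write_tsv(["A", "B"], ["s1", "s2"], [[1.0, 2.0], [3.0, 4.0]])
        m = read_expression(path)
        assert m.gene_ids == ["A", "B"]
        assert m.sample_ids == ["s1", "s2"]
        np.testing.assert_array_equal(m.values, [[1.0, 2.0], [3.0, 4.0]])

    def test_duplicate_symbols_collapse_to_max_mean_row(self, write_tsv):
        path = write_tsv(["brd4", "BRD4"], ["s1", "s2"],
                         [[5.0, 5.0], [6.0, 6.0]])
        m = read_expression(path)
        assert m.gene_ids == ["BRD4"]
        np.testing.assert_array_equal(m.values, [[6.0, 6.0]])

    def test_gct_dimension_mismatch_is_format_error(self, tmp_path):
        path = tmp_path / "bad.gct"
        path.write_text(
            "#1.2\n3\t2\nName\tDescription\ts1\ts2\n"
            "A\t-\t1\t2\nB\t-\t3\t4\n"
        )
        with pytest.raises(FormatError):
            read_expression(path, dialect="gct")

    def test_gct_round_trip(self, tmp_path):
        path = tmp_path / "ok.gct"
        path.write_text(
            "#1.2\n2\t2\nName\tDescription\ts1\ts2\n"
            "A\tdesc\t1\t2\nB\tdesc\t3\t4\n"
        )
        m = read_expression(path, dialect="gct")
        assert m.gene_ids == ["A", "B"]
        np.testing.assert_array_equal(m.values, [[1, 2], [3, 4]])

    @pytest.mark.parametrize("cell", ["", "NA", "oops"])
    def test_bad_cells_are_data_errors(self, write_tsv, cell):
        path = write_tsv(["A", "B"], ["s1", "s2"], [[1, 2], [3, cell]])
        with pytest.raises(DataError, match="B"):
            read_expression(path)

    def test_empty_matrix_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("GENE\ts1\ts2\n")
        with pytest.raises(DataError):
            read_expression(path)


class TestGeneListAndGmt:
    def test_gene_list_uppercases_and_skips_comments(self, tmp_path):
        path = tmp_path / "list.txt"
        path.write_text("# immune genes\ncd80\nCD86  # note\n\nTNFRSF8\n")
        gs = read_gene_list(path)
        assert gs.members == {"CD80", "CD86", "TNFRSF8"}

    def test_gmt_basic(self, tmp_path):
        path = tmp_path / "lib.gmt"
        path.write_text("S1\tdesc\tA\tb\nS2\tdesc\tC\t\tD\n")
        lib = read_gmt(path)
        assert [s.name for s in lib] == ["S1", "S2"]
        assert lib["S1"].members == {"A", "B"}
        assert lib["S2"].members == {"C", "D"}  # empty field dropped

    def test_gmt_too_few_fields_names_line(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S1\tdesc\tA\nS2\tdesc\n")
        with pytest.raises(FormatError, match="2"):
            read_gmt(path)

    def test_gmt_duplicate_name(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S1\td\tA\nS1\td\tB\n")
        with pytest.raises(FormatError, match="S1"):
            read_gmt(path)


class TestReadJasparPfm:
    def test_bracketed_dialect(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text(">M1 TESTTF\nA [4 0]\nC [0 4]\nG [0 0]\nT [0 0]\n")
        pfm = read_jaspar_pfm(path)
        assert pfm.name == "M1 TESTTF"
        assert pfm.length == 2
        np.testing.assert_array_equal(
            pfm.counts, [[4, 0], [0, 4], [0, 0], [0, 0]]
        )

    def test_plain_dialect_gives_identical_matrix(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text("A 4 0\nC 0 4\nG 0 0\nT 0 0\n")
        np.testing.assert_array_equal(
            read_jaspar_pfm(path).counts, [[4, 0], [0, 4], [0, 0], [0, 0]]
        )

    def test_unequal_row_lengths(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text("A 4 0\nC 0 4 1\nG 0 0\nT 0 0\n")
        with pytest.raises(FormatError):
            read_jaspar_pfm(path)

    def test_missing_base_row(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text("A 4 0\nC 0 4\nG 0 0\n")
        with pytest.raises(FormatError, match="T"):
            read_jaspar_pfm(path)

    def test_negative_count_is_data_error(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text("A 4 0\nC 0 -4\nG 0 0\nT 0 0\n")
        with pytest.raises(DataError):
            read_jaspar_pfm(path)


class TestPromoterFasta:
    def test_tss_key_in_description(self, tmp_path):
        path = tmp_path / "prom.fa"
        path.write_text(">prom tss=5\nACGTACGTAC\n")
        prom = read_promoter_fasta(path)
        assert prom.tss_offset == 5
        assert prom.sequence == "ACGTACGTAC"

    def test_argument_overrides_and_missing_key_fails(self, tmp_path):
        path = tmp_path / "prom.fa"
        path.write_text(">prom\nACGT\n")
        assert read_promoter_fasta(path, tss_offset=2).tss_offset == 2
        with pytest.raises(DataError):
            read_promoter_fasta(path)


# ---------------------------------------------------------------------------
# quantile normalization

class TestQuantileNormalize:
    def test_two_column_hand_computation(self):
        m = ExpressionMatrix(["A", "B"], ["s1", "s2"],
                             np.array([[1.0, 3.0], [2.0, 4.0]]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, [[2.0, 2.0], [3.0, 3.0]])

    def test_single_column_unchanged(self):
        m = ExpressionMatrix(["A", "B", "C"], ["s1"],
                             np.array([[3.0], [1.0], [2.0]]))
        np.testing.assert_allclose(quantile_normalize(m).values, m.values)

    def test_ties_receive_mean_of_reference_ranks(self):
        m = ExpressionMatrix(
            ["A", "B"], ["s1", "s2"], np.array([[1.0, 7.0], [1.0, 3.0]])
        )
        out = quantile_normalize(m)
        # reference = [(1+3)/2, (1+7)/2] = [2, 4]; column 1 is fully tied
        np.testing.assert_allclose(out.values[:, 0], [3.0, 3.0])
        np.testing.assert_allclose(out.values[:, 1], [4.0, 2.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_idempotent_and_columns_share_sorted_values(self, seed):
        # continuous input: the invariants hold exactly on tie-free data
        rng = np.random.default_rng(seed)
        values = rng.normal(7, 1.5, size=(6, 4))
        m = ExpressionMatrix(
            [f"g{i}" for i in range(6)], [f"s{j}" for j in range(4)],
            values,
        )
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)
        cols = np.sort(once.values, axis=0)
        for j in range(1, cols.shape[1]):
            np.testing.assert_allclose(cols[:, j], cols[:, 0], atol=1e-12)

    def test_matches_brute_force_on_distinct_values(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 5))
        m = ExpressionMatrix(
            [f"g{i}" for i in range(20)], [f"s{j}" for j in range(5)], X
        )
        expected = np.array(
            quantile_normalize_brute([list(X[:, j]) for j in range(5)])
        ).T
        np.testing.assert_allclose(quantile_normalize(m).values, expected,
                                   atol=1e-12)


# ---------------------------------------------------------------------------
# gene summaries

class TestSummarizeGene:
    def test_maximal_gene_has_rank_100(self, write_tsv):
        m = ExpressionMatrix(
            ["TOP", "MID", "LOW"], ["s1", "s2"],
            np.array([[9.0, 9.5], [5.0, 6.0], [1.0, 2.0]]),
        )
        assert summarize_gene(m, "TOP").min_percentile_rank == 100.0

    def test_constant_gene_fold_range_one(self):
        m = ExpressionMatrix(
            ["C", "X"], ["s1", "s2"], np.array([[4.0, 4.0], [1.0, 9.0]])
        )
        s = summarize_gene(m, "C")
        assert s.fold_range == 1.0
        assert s.sd_log2 == 0.0

    def test_fold_range_is_two_to_the_log2_span(self):
        m = ExpressionMatrix(
            ["Q", "X"], ["s1", "s2"], np.array([[10.0, 10.83], [7.0, 7.0]])
        )
        assert summarize_gene(m, "Q").fold_range == pytest.approx(
            2 ** 0.83, rel=1e-12
        )
        assert summarize_gene(m, "Q").fold_range == pytest.approx(1.778, abs=5e-4)

    def test_rank_invariant_under_monotone_per_sample_transform(self):
        rng = np.random.default_rng(3)
        X = rng.normal(7, 1, size=(30, 6))
        genes = [f"g{i}" for i in range(30)]
        samples = [f"s{j}" for j in range(6)]
        m1 = ExpressionMatrix(genes, samples, X)
        # strictly increasing, different per sample
        X2 = np.exp(X / 4) * np.arange(1, 7)[None, :] + np.arange(6)[None, :]
        m2 = ExpressionMatrix(genes, samples, X2)
        s1 = summarize_gene(m1, "g5")
        s2 = summarize_gene(m2, "g5")
        assert s1.min_percentile_rank == s2.min_percentile_rank

    def test_unknown_gene_raises_key_error(self, small_matrix):
        with pytest.raises(KeyError):
            summarize_gene(small_matrix, "NOPE")
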