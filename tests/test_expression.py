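import io

import numpy as np
import pandas as pd
import pytest

import coextree as ct
from coextree.expression import write_expression


def tsv(text: str) -> io.StringIO:
    return io.StringIO(text)


class TestLoadExpression:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
            index=["G1", "G2", "G3"],
            columns=["S1", "S2"],
        )
        m = ct.ExpressionMatrix(df, "tpm")
        path = tmp_path / "m.tsv"
        write_expression(m, path)
        back = ct.load_expression(path, "tpm")
        assert back.gene_ids == ["G1", "G2", "G3"]
        assert back.sample_ids == ["S1", "S2"]
        np.testing.assert_allclose(back.values, m.values)

    def test_gct_preamble_skipped(self):
        body = "#1.2\n3\t2\ngene\tS1\tS2\nG1\t1\t2\nG2\t3\t4\nG3\t5\t6\n"
        m = ct.load_expression(tsv(body), "counts")
        assert m.values.shape == (3, 2)

    def test_duplicate_gene_rejected(self):
        body = "gene\tS1\nG1\t1\nG1\t2\n"
        with pytest.raises(ValueError, match="duplicate gene"):
            ct.load_expression(tsv(body), "tpm")

    def test_non_numeric_cell_named(self):
        body = "gene\tS1\tS2\nG1\t1\tbad\n"
        with pytest.raises(ValueError, match="G1.*S2"):
            ct.load_expression(tsv(body), "tpm")

    def test_header_only_is_valid_empty_matrix(self):
        m = ct.load_expression(tsv("gene\tS1\tS2\n"), "tpm")
        assert m.n_genes == 0 and m.n_samples == 2


class TestReplaceZerosAndLog2:
    def test_zero_replaced_by_global_min_nonzero(self):
        df = pd.DataFrame([[0.0, 2.0, 8.0]], index=["G1"], columns=list("abc"))
        out = ct.replace_zeros_and_log2(ct.ExpressionMatrix(df, "tpm"))
        np.testing.assert_allclose(out.values, [[1.0, 1.0, 3.0]])
        assert out.scale == "log2"

    def test_no_zeros_is_plain_log2(self):
        df = pd.DataFrame([[1.0, 4.0], [2.0, 16.0]], index=["G1", "G2"],
                          columns=["a", "b"])
        out = ct.replace_zeros_and_log2(ct.ExpressionMatrix(df, "tpm"))
        np.testing.assert_allclose(out.values, np.log2(df.to_numpy()))

    def test_all_zero_matrix_errors(self):
        df = pd.DataFrame([[0.0, 0.0]], index=["G1"], columns=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            ct.replace_zeros_and_log2(ct.ExpressionMatrix(df, "tpm"))

    def test_monotone_within_sample(self, rng):
        vals = np.round(rng.uniform(0, 50, size=(30, 4)), 1)
        vals[rng.random(vals.shape) < 0.2] = 0.0
        df = pd.DataFrame(vals, index=[f"G{i}" for i in range(30)],
                          columns=list("abcd"))
        out = ct.replace_zeros_and_log2(ct.ExpressionMatrix(df, "tpm"))
        for j in range(4):
            nz = vals[:, j] > 0
            before = np.argsort(vals[nz, j], kind="stable")
            after = np.argsort(out.values[nz, j], kind="stable")
            assert (before == after).all()


class TestFilters:
    def make(self, rows, genes, samples=None):
        samples = samples or [f"S{j}" for j in range(len(rows[0]))]
        return ct.ExpressionMatrix(
            pd.DataFrame(rows, index=genes, columns=samples, dtype=float), "tpm"
        )

    def test_zero_sd_removes_constant_rows_only(self):
        m = self.make([[5, 5, 5], [5, 5, 6]], ["CONST", "VAR"])
        out, rep = ct.filter_zero_sd_genes(m)
        assert out.gene_ids == ["VAR"]
        assert rep.removed_zero_sd == ["CONST"]

    def test_zero_sd_all_constant_gives_empty(self):
        m = self.make([[1, 1], [2, 2]], ["G1", "G2"])
        out, rep = ct.filter_zero_sd_genes(m)
        assert out.n_genes == 0
        assert rep.removed_zero_sd == ["G1", "G2"]

    def test_suffix_and_deprecated_filters(self):
        m = self.make(
            [[1, 2], [3, 4], [5, 6]],
            ["ENSG000001.5_PAR_Y", "G7.2", "G8"],
        )
        out, rep = ct.filter_gene_ids(m, suffix="_PAR_Y", deprecated={"G7"})
        assert out.gene_ids == ["G8"]
        assert rep.removed_suffix == ["ENSG000001.5_PAR_Y"]
        assert rep.removed_deprecated == ["G7.2"]

    def test_no_matches_is_identity(self):
        m = self.make([[1, 2], [3, 4]], ["G1", "G2"])
        out, rep = ct.filter_gene_ids(m, suffix="_PAR_Y", deprecated=set())
        assert out.gene_ids == m.gene_ids
        assert rep.removed_suffix == rep.removed_deprecated == []

    def test_cell_line_samples_dropped(self):
        m = self.make([[1, 2, 3, 4, 5]], ["G1"], [f"S{j}" for j in range(5)])
        meta = {
            f"S{j}": ct.SampleMetadata(f"S{j}", "tissue", j in (1, 3))
            for j in range(5)
        }
        out, rep = ct.drop_cell_line_samples(m, meta)
        assert out.sample_ids == ["S0", "S2", "S4"]
        assert rep.removed_cell_line_samples == ["S1", "S3"]

    def test_unknown_sample_errors(self):
        m = self.make([[1, 2]], ["G1"], ["S0", "MYSTERY"])
        meta = {"S0": ct.SampleMetadata("S0", "tissue")}
        with pytest.raises(KeyError, match="MYSTERY"):
            ct.drop_cell_line_samples(m, meta)

    def test_filters_preserve_order_and_counts(self, rng):
        n = 40
        genes = [f"G{i}" for i in range(n)]
        vals = rng.uniform(1, 10, size=(n, 3))
        vals[::7] = 2.0  # constant rows
        m = self.make(vals.tolist(), genes)
        out, rep = ct.filter_zero_sd_genes(m)
        assert len(out.gene_ids) + len(rep.removed_zero_sd) == n
        kept = [g for g in genes if g not in set(rep.removed_zero_sd)]
        assert out.gene_ids == kept
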