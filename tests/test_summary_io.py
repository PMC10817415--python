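"""Reader validation and allele harmonization behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mrmediate.summary_io import (ConfigurationError, HarmonizationError,
                                  dataset_from_frame, harmonize,
                                  read_summary_stats)

COLS = ["SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE", "P", "N"]


def _rows(n=5, se=0.1):
    return [[f"rs{i}", "1", 1000 + i, "A", "G", 0.3, 0.1 * (i + 1), se,
             0.01, 1000] for i in range(n)]


def _write(tmp_path, rows, cols=COLS, sep="\t", name="stats.tsv"):
    path = tmp_path / name
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)
    return path


def _frame(records):
    return pd.DataFrame(records, columns=["snp_id", "chrom", "pos",
                                          "effect_allele", "other_allele",
                                          "eaf", "beta", "se", "pvalue", "n"])


class TestReader:
    def test_well_formed_file_read_verbatim(self, tmp_path):
        ds = read_summary_stats(_write(tmp_path, _rows(5)))
        assert len(ds) == 5
        assert list(ds.table["snp_id"]) == [f"rs{i}" for i in range(5)]

    def test_zero_se_row_dropped_and_counted(self, tmp_path):
        rows = _rows(5)
        rows[2][7] = 0.0
        ds = read_summary_stats(_write(tmp_path, rows))
        assert len(ds) == 4
        assert ds.drop_reasons["nonpositive-se"] == 1

    def test_shuffled_columns_with_map_match_ordered_parse(self, tmp_path):
        ordered = read_summary_stats(_write(tmp_path, _rows(5)))
        shuffled_cols = ["beta_col", "snp", "pv", "ea", "stderr", "oa",
                         "freq", "chrom", "bp", "nn"]
        rows = [[r[6], r[0], r[8], r[3], r[7], r[4], r[5], r[1], r[2], r[9]]
                for r in _rows(5)]
        path = _write(tmp_path, rows, cols=shuffled_cols, name="shuf.csv",
                      sep=",")
        shuffled = read_summary_stats(path, column_map={
            "snp_id": "snp", "chrom": "chrom", "pos": "bp",
            "effect_allele": "ea", "other_allele": "oa", "eaf": "freq",
            "beta": "beta_col", "se": "stderr", "pvalue": "pv", "n": "nn"})
        pd.testing.assert_frame_equal(ordered.table, shuffled.table)

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        path = _write(tmp_path, [r[:7] + r[8:] for r in _rows(3)],
                      cols=[c for c in COLS if c != "SE"])
        with pytest.raises(ConfigurationError, match="SE"):
            read_summary_stats(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ConfigurationError):
            read_summary_stats(path)

    def test_n_backfilled_from_default(self, tmp_path):
        rows = _rows(3)
        rows[1][9] = np.nan
        ds = read_summary_stats(_write(tmp_path, rows), n_default=777)
        assert ds.table.loc[1, "n"] == 777

    def test_indel_and_multiallelic_records_dropped(self, tmp_path):
        rows = _rows(4)
        rows[0][3] = "AT"   # indel
        rows[1][4] = "I"    # non-ACGT code
        ds = read_summary_stats(_write(tmp_path, rows))
        assert len(ds) == 2
        assert ds.drop_reasons["invalid-alleles"] == 2


def _pair(exp_rec, out_rec):
    exp = dataset_from_frame(_frame([exp_rec]), "exp")
    out = dataset_from_frame(_frame([out_rec]), "out")
    return exp, out


class TestHarmonize:
    def test_identical_alleles_kept(self):
        exp, out = _pair(["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.02, 1e-9, 1e4],
                         ["rs1", "1", 100, "A", "G", 0.3, 0.05, 0.02, 0.01, 1e4])
        h = harmonize(exp, out, ["rs1"])
        row = h.table.iloc[0]
        assert row.action == "kept"
        assert row.beta_out == 0.05

    def test_swapped_alleles_flip_sign_and_frequency(self):
        exp, out = _pair(["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.02, 1e-9, 1e4],
                         ["rs1", "1", 100, "G", "A", 0.3, 0.05, 0.02, 0.01, 1e4])
        h = harmonize(exp, out, ["rs1"])
        row = h.table.iloc[0]
        assert row.action == "flipped"
        assert row.beta_out == -0.05
        assert row.eaf_out == pytest.approx(0.7)

    def test_strand_flip_relabelled(self):
        exp, out = _pair(["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.02, 1e-9, 1e4],
                         ["rs1", "1", 100, "T", "C", 0.3, 0.05, 0.02, 0.01, 1e4])
        h = harmonize(exp, out, ["rs1"])
        row = h.table.iloc[0]
        assert row.action == "strand-corrected"
        assert row.beta_out == 0.05

    def test_palindromic_resolved_by_minor_allele_side(self):
        # exhaustive 2-case oracle: with eaf on opposite sides of 0.5 the
        # alignment that matches minor-allele sides is the flipped one
        exp, out = _pair(["rs1", "1", 100, "A", "T", 0.10, 0.1, 0.02, 1e-9, 1e4],
                         ["rs1", "1", 100, "A", "T", 0.92, 0.05, 0.02, 0.01, 1e4])
        h = harmonize(exp, out, ["rs1"], palindrome_eaf_window=(0.42, 0.58))
        row = h.table.iloc[0]
        assert row.action == "flipped"
        assert row.beta_out == -0.05
        assert row.eaf_out == pytest.approx(0.08)

    def test_palindromic_ambiguous_eaf_dropped(self):
        exp, out = _pair(["rs1", "1", 100, "A", "T", 0.10, 0.1, 0.02, 1e-9, 1e4],
                         ["rs1", "1", 100, "A", "T", 0.50, 0.05, 0.02, 0.01, 1e4])
        with pytest.raises(HarmonizationError, match="dropped-palindromic"):
            harmonize(exp, out, ["rs1"], palindrome_eaf_window=(0.42, 0.58))

    def test_missing_outcome_snp_logged_as_dropped(self):
        exp = dataset_from_frame(_frame(
            [["rs1", "1", 100, "A", "G", 0.3, 0.1, 0.02, 1e-9, 1e4],
             ["rs2", "1", 200, "A", "G", 0.3, 0.2, 0.02, 1e-9, 1e4]]), "exp")
        out = dataset_from_frame(_frame(
            [["rs1", "1", 100, "A", "G", 0.3, 0.05, 0.02, 0.01, 1e4]]), "out")
        h = harmonize(exp, out, ["rs1", "rs2"])
        assert h.n_snps == 1
        assert set(h.log["action"]) == {"kept", "dropped-missing"}

    def test_every_input_snp_in_log_exactly_once(self):
        exp = dataset_from_frame(_frame(
            [[f"rs{i}", "1", 100 * i, "A", "G", 0.3, 0.1, 0.02, 1e-9, 1e4]
             for i in range(6)]), "exp")
        out = dataset_from_frame(_frame(
            [[f"rs{i}", "1", 100 * i, "G", "A", 0.3, 0.05, 0.02, 0.01, 1e4]
             for i in range(0, 6, 2)]), "out")
        h = harmonize(exp, out)
        assert sorted(h.log["snp_id"]) == sorted(exp.table["snp_id"])
        assert not h.log["snp_id"].duplicated().any()

    @given(beta=st.floats(-2, 2, allow_nan=False),
           eaf=st.floats(0.05, 0.95))
    def test_double_flip_is_identity(self, beta, eaf):
        flipped_beta, flipped_eaf = -(-beta), 1.0 - (1.0 - eaf)
        assert flipped_beta == beta
        assert flipped_eaf == pytest.approx(eaf, abs=1e-15)

    def test_harmonization_idempotent(self):
        rng = np.random.default_rng(7)
        recs_e, recs_o = [], []
        alleles = [("A", "G"), ("C", "T"), ("G", "T")]
        for i in range(9):
            ea, oa = alleles[i % 3]
            swap = i % 2 == 0
            recs_e.append([f"rs{i}", "1", 100 * i, ea, oa, 0.3,
                           rng.normal(), 0.05, 1e-9, 1e4])
            recs_o.append([f"rs{i}", "1", 100 * i, oa if swap else ea,
                           ea if swap else oa, 0.7 if swap else 0.3,
                           rng.normal(), 0.05, 0.01, 1e4])
        exp = dataset_from_frame(_frame(recs_e), "exp")
        out = dataset_from_frame(_frame(recs_o), "out")
        h1 = harmonize(exp, out)
        exp2, out2 = h1.to_datasets_like(exp, out)
        h2 = harmonize(exp2, out2)
        assert (h2.log["action"] == "kept").all()
        for col in ("beta_exp", "beta_out", "eaf_out", "se_out"):
            np.testing.assert_array_equal(h1.table[col], h2.table[col])
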