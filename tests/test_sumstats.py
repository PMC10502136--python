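"""Summary-statistics I/O, harmonization, LD scores and exclusion regions."""

import numpy as np
import pandas as pd
import pytest

import pleiomix as px
from pleiomix.sumstats import (DEFAULT_EXCLUSION_REGIONS, SumStatsError,
                               compute_ld_scores)


def _write(tmp_path, rows, name="ss.tsv", header="SNP CHR BP A1 A2 Z P N"):
    path = tmp_path / name
    lines = [header.replace(" ", "\t")]
    lines += ["\t".join(str(x) for x in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadSumstats:
    def test_reads_valid_rows_in_position_order(self, tmp_path):
        path = _write(tmp_path, [
            ("rs3", 2, 500, "A", "G", 1.96, 0.05, 1000),
            ("rs1", 1, 100, "C", "T", 0.0, 1.0, 1000),
            ("rs2", 1, 900, "G", "T", -1.0, 0.3173, 1000),
        ])
        ss = px.read_sumstats(path)
        assert len(ss) == 3
        assert list(ss.df["SNP"]) == ["rs1", "rs2", "rs3"]

    def test_p_zero_row_dropped(self, tmp_path):
        path = _write(tmp_path, [
            ("rs1", 1, 100, "A", "G", 1.0, 0.3173, 1000),
            ("rs2", 1, 200, "A", "G", 99.0, 0.0, 1000),
        ])
        assert len(px.read_sumstats(path)) == 1

    def test_pz_inconsistency_dropped(self, tmp_path):
        path = _write(tmp_path, [
            ("rs1", 1, 100, "A", "G", 1.96, 0.05, 1000),   # consistent
            ("rs2", 1, 200, "A", "G", 1.96, 0.5, 1000),    # p does not match z
        ])
        assert list(px.read_sumstats(path).df["SNP"]) == ["rs1"]

    def test_missing_column_is_hard_error(self, tmp_path):
        path = _write(tmp_path, [("rs1", 1, 100, "A", "G", 1.0)],
                      header="SNP CHR BP A1 A2 Z")
        with pytest.raises(SumStatsError, match="N"):
            px.read_sumstats(path)

    def test_empty_file_is_hard_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("SNP\tCHR\tBP\tA1\tA2\tZ\tP\tN\n")
        with pytest.raises(SumStatsError):
            px.read_sumstats(path)

    def test_column_map_and_default_n(self, tmp_path):
        path = _write(tmp_path, [("rs1", 1, 100, "A", "G", 1.0, 0.3173)],
                      header="rsid chrom pos ea oa zscore pval")
        ss = px.read_sumstats(path, column_map={
            "SNP": "rsid", "CHR": "chrom", "BP": "pos", "A1": "ea",
            "A2": "oa", "Z": "zscore", "P": "pval"}, default_n=5000)
        assert ss.df.loc[0, "N"] == 5000


def _mini_panel():
    index = pd.DataFrame({
        "SNP": ["rs1", "rs2", "rs3", "rs4"],
        "CHR": [1, 1, 1, 1],
        "BP": [100, 200, 300, 400],
        "A1": ["A", "A", "A", "C"],
        "A2": ["G", "G", "G", "T"],
    })
    return px.LDPanel(index=index, blocks=[np.eye(4)])


def _table(rows):
    df = pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2", "Z", "P", "N"])
    return px.SumStats(df)


class TestHarmonize:
    def test_allele_swap_negates_z(self):
        s1 = _table([("rs1", 1, 100, "A", "G", 1.0, 0.3173, 100),
                     ("rs2", 1, 200, "A", "G", 0.5, 0.6171, 100)])
        s2 = _table([("rs1", 1, 100, "G", "A", 1.5, 0.1336, 100),
                     ("rs2", 1, 200, "A", "G", 0.5, 0.6171, 100)])
        h1, h2 = px.harmonize_pair(s1, s2, _mini_panel())
        assert h2.df.loc[h2.df["SNP"] == "rs1", "Z"].iloc[0] == -1.5
        assert h2.df.loc[h2.df["SNP"] == "rs2", "Z"].iloc[0] == 0.5

    def test_strand_complement_same_orientation_kept(self):
        # panel rs1 is A/G; T/C is its strand complement in the same orientation
        s1 = _table([("rs1", 1, 100, "T", "C", 1.0, 0.3173, 100),
                     ("rs2", 1, 200, "A", "G", 0.5, 0.6171, 100)])
        s2 = _table([("rs1", 1, 100, "A", "G", 1.0, 0.3173, 100),
                     ("rs2", 1, 200, "A", "G", 0.5, 0.6171, 100)])
        h1, _ = px.harmonize_pair(s1, s2, _mini_panel())
        assert h1.df.loc[h1.df["SNP"] == "rs1", "Z"].iloc[0] == 1.0

    def test_strand_ambiguous_dropped(self):
        s1 = _table([("rs1", 1, 100, "A", "T", 1.0, 0.3173, 100),
                     ("rs2", 1, 200, "A", "G", 0.5, 0.6171, 100),
                     ("rs3", 1, 300, "A", "G", 0.5, 0.6171, 100)])
        s2 = _table([("rs2", 1, 200, "A", "G", 0.5, 0.6171, 100),
                     ("rs3", 1, 300, "A", "G", 0.5, 0.6171, 100)])
        h1, h2 = px.harmonize_pair(s1, s2, _mini_panel())
        assert "rs1" not in set(h1.df["SNP"])

    def test_idempotent(self):
        s1 = _table([("rs1", 1, 100, "G", "A", 1.0, 0.3173, 100),
                     ("rs2", 1, 200, "A", "G", 0.5, 0.6171, 100)])
        s2 = _table([("rs1", 1, 100, "A", "G", 1.0, 0.3173, 100),
                     ("rs2", 1, 200, "A", "G", 0.5, 0.6171, 100)])
        h1, h2 = px.harmonize_pair(s1, s2, _mini_panel())
        g1, g2 = px.harmonize_pair(h1, h2, _mini_panel())
        pd.testing.assert_frame_equal(h1.df, g1.df)
        pd.testing.assert_frame_equal(h2.df, g2.df)

    def test_too_few_survivors_is_error(self):
        s1 = _table([("rs1", 1, 100, "A", "T", 1.0, 0.3173, 100),
                     ("rs2", 1, 200, "A", "G", 0.5, 0.6171, 100)])
        s2 = _table([("rs9", 1, 900, "A", "G", 0.5, 0.6171, 100),
                     ("rs2", 1, 200, "A", "G", 0.5, 0.6171, 100)])
        with pytest.raises(SumStatsError):
            px.harmonize_pair(s1, s2, _mini_panel())


class TestExclusions:
    @pytest.mark.parametrize("chrom,bp,excluded", [
        (6, 26_000_000, True),    # inside the extended MHC interval
        (6, 24_000_000, False),
        (17, 41_000_000, True),   # inside the MAPT interval
        (8, 8_000_000, True),     # inside 8p23.1
        (2, 8_000_000, False),
    ])
    def test_default_intervals(self, chrom, bp, excluded):
        ss = _table([("rs1", chrom, bp, "A", "G", 0.5, 0.6171, 100),
                     ("rs2", 22, 1, "A", "G", 0.5, 0.6171, 100)])
        mask = px.apply_exclusions(ss)
        assert mask[list(ss.df["SNP"]).index("rs1")] == (not excluded)

    def test_exact_removal_on_spanning_fixture(self):
        rows, expect = [], []
        for i, (c, s, e) in enumerate(DEFAULT_EXCLUSION_REGIONS):
            rows += [(f"in{i}", c, (s + e) // 2, "A", "G", 0.5, 0.6171, 100),
                     (f"edge{i}", c, s, "A", "G", 0.5, 0.6171, 100),
                     (f"out{i}", c, e + 1, "A", "G", 0.5, 0.6171, 100)]
            expect += [False, False, True]
        ss = _table(rows)
        order = np.argsort([r[2] for r in rows], kind="stable")
        got = px.apply_exclusions(ss)
        names = list(ss.df["SNP"])
        for name, keep in zip([r[0] for r in rows], expect):
            assert got[names.index(name)] == keep

    def test_from_file_round_trip(self, tmp_path):
        path = tmp_path / "regions.bed"
        path.write_text("chr6\t25119106\t33854733\n8\t7242715\t12483982\n")
        regions = px.ExclusionRegions.from_file(path)
        assert regions.intervals[0] == (6, 25119106, 33854733)


class TestLdScores:
    def test_identity_block_gives_one(self):
        panel = _mini_panel()
        assert np.allclose(compute_ld_scores(panel), 1.0)

    def test_two_variant_block(self):
        index = _mini_panel().index.iloc[:2]
        panel = px.LDPanel(index=index, blocks=[np.array([[1.0, 0.5], [0.5, 1.0]])])
        assert np.allclose(compute_ld_scores(panel), 1.25)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(5, 5))
        R = np.corrcoef(A)
        index = pd.DataFrame({"SNP": [f"rs{i}" for i in range(5)],
                              "CHR": 1, "BP": np.arange(1, 6) * 100,
                              "A1": "A", "A2": "G"})
        panel = px.LDPanel(index=index, blocks=[R])
        oracle = np.array([sum(R[j, k] ** 2 for k in range(5)) for j in range(5)])
        assert np.allclose(compute_ld_scores(panel), oracle)

    def test_block_crossing_chromosome_rejected(self):
        index = _mini_panel().index.copy()
        index.loc[2:, "CHR"] = 2
        with pytest.raises(ValueError, match="chromosome"):
            px.LDPanel(index=index, blocks=[np.eye(4)])
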