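import numpy as np
import pandas as pd
import pytest

from finepgs.sumstats import (
    PGSModel,
    SumStats,
    flip_orientation,
    harmonize_to_panel,
    read_pgs_model,
    read_sumstats,
    write_pgs_model,
)

from conftest import toy_sumstats_frame


def _write(df, path):
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadSumstats:
    def test_missing_required_row_dropped_and_counted(self, tmp_path):
        df = toy_sumstats_frame()
        df.loc[2, "se"] = np.nan
        ss = read_sumstats(_write(df, tmp_path / "ss.tsv"))
        assert len(ss) == 4
        assert ss.read_report.dropped == {"missing_required_field": 1}
        assert ss.read_report.n_input == ss.read_report.n_output + 1

    def test_column_map_gives_identical_table(self, tmp_path):
        df = toy_sumstats_frame()
        canonical = read_sumstats(_write(df, tmp_path / "a.tsv"))
        renamed = df.rename(columns={"chrom": "CHR", "pos": "BP", "se": "SE", "pval": "P"})
        mapped = read_sumstats(
            _write(renamed, tmp_path / "b.tsv"),
            column_map={"CHR": "chrom", "BP": "pos", "SE": "se", "P": "pval"},
        )
        pd.testing.assert_frame_equal(canonical.table, mapped.table)

    def test_unresolvable_column_is_hard_error(self, tmp_path):
        df = toy_sumstats_frame().drop(columns=["se"])
        with pytest.raises(ValueError, match="se"):
            read_sumstats(_write(df, tmp_path / "ss.tsv"))

    def test_duplicate_key_keeps_first_in_file_order(self, tmp_path):
        df = toy_sumstats_frame()
        dup = df.iloc[[1]].assign(beta=9.9)
        df = pd.concat([df, dup], ignore_index=True)
        ss = read_sumstats(_write(df, tmp_path / "ss.tsv"))
        assert len(ss) == 5
        assert ss.read_report.dropped["duplicate_key"] == 1
        kept = ss.table.query("chrom == '1' and pos == 200")
        assert kept["beta"].iloc[0] == -0.2  # first occurrence wins

    def test_duplicate_detected_on_unordered_allele_pair(self, tmp_path):
        df = toy_sumstats_frame()
        swapped = df.iloc[[0]].assign(effect_allele="A", other_allele="G", beta=9.9)
        df = pd.concat([df, swapped], ignore_index=True)
        ss = read_sumstats(_write(df, tmp_path / "ss.tsv"))
        assert ss.read_report.dropped["duplicate_key"] == 1

    def test_indels_and_invalid_rows_rejected(self, tmp_path):
        df = toy_sumstats_frame()
        df.loc[0, "effect_allele"] = "AT"   # indel
        df.loc[1, "se"] = -0.1              # invalid SE
        df.loc[3, "pval"] = 0.0             # invalid p
        ss = read_sumstats(_write(df, tmp_path / "ss.tsv"))
        assert len(ss) == 2
        assert ss.read_report.dropped == {
            "non_snp_allele": 1, "nonpositive_se": 1, "invalid_pval": 1,
        }

    def test_zero_surviving_rows_is_hard_error(self, tmp_path):
        df = toy_sumstats_frame()
        df["se"] = np.nan
        with pytest.raises(ValueError, match="no rows"):
            read_sumstats(_write(df, tmp_path / "ss.tsv"))

    def test_table_sorted_by_chrom_pos(self, tmp_path):
        df = toy_sumstats_frame().iloc[::-1]
        ss = read_sumstats(_write(df, tmp_path / "ss.tsv"))
        t = ss.table
        for chrom, grp in t.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing

    def test_roundtrip_write_read(self, tmp_path):
        ss = read_sumstats(_write(toy_sumstats_frame(), tmp_path / "a.tsv"))
        ss.table.to_csv(tmp_path / "b.tsv", sep="\t", index=False)
        back = read_sumstats(tmp_path / "b.tsv")
        pd.testing.assert_frame_equal(ss.table, back.table)


def _panel_variants():
    return pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "2", "2"],
            "pos": [100, 200, 300, 100, 250],
            "ref": ["A", "T", "C", "A", "C"],
            "alt": ["G", "C", "T", "G", "A"],
            "freq": [0.3, 0.5, 0.12, 0.7, 0.25],
        }
    )


class TestHarmonize:
    def test_effect_equals_panel_alt_unchanged(self):
        ss = SumStats(toy_sumstats_frame().iloc[[0]].reset_index(drop=True))
        out, rep = harmonize_to_panel(ss, _panel_variants())
        assert rep.n_flipped == 0
        assert out.table["beta"].iloc[0] == 0.1
        assert out.table["effect_allele"].iloc[0] == "G"

    def test_effect_equals_panel_ref_flipped(self):
        df = toy_sumstats_frame().iloc[[0]].reset_index(drop=True)
        df["effect_allele"], df["other_allele"] = "A", "G"
        df["beta"], df["freq"] = 0.3, 0.2
        out, rep = harmonize_to_panel(SumStats(df), _panel_variants())
        assert rep.n_flipped == 1
        row = out.table.iloc[0]
        assert row["beta"] == -0.3
        assert row["freq"] == pytest.approx(0.8)
        assert (row["effect_allele"], row["other_allele"]) == ("G", "A")

    def test_ambiguous_resolved_by_frequency_agreement(self):
        # C/T panel variant at 1:300 replaced with an ambiguous pair panel
        panel = pd.DataFrame({"chrom": ["1"], "pos": [300], "ref": ["A"], "alt": ["T"], "freq": [0.12]})
        df = toy_sumstats_frame().iloc[[2]].reset_index(drop=True)
        df["effect_allele"], df["other_allele"] = "T", "A"
        df["freq"] = 0.1
        out, rep = harmonize_to_panel(SumStats(df), panel)
        assert len(out) == 1 and rep.n_flipped == 0  # 0.1 close to 0.12: keep orientation
        df["freq"] = 0.49  # both orientations ~equidistant: unresolvable
        out2, rep2 = harmonize_to_panel(SumStats(df), panel)
        assert len(out2) == 0
        assert rep2.dropped["ambiguous_unresolved"] == 1

    def test_ambiguous_without_frequency_dropped(self):
        panel = pd.DataFrame({"chrom": ["1"], "pos": [300], "ref": ["A"], "alt": ["T"]})
        df = toy_sumstats_frame().iloc[[2]].reset_index(drop=True)
        df["effect_allele"], df["other_allele"] = "T", "A"
        df = df.drop(columns=["freq"])
        out, rep = harmonize_to_panel(SumStats(df), panel)
        assert len(out) == 0 and rep.dropped["ambiguous_unresolved"] == 1

    def test_irreconcilable_pair_dropped_never_kept(self):
        df = toy_sumstats_frame().iloc[[0]].reset_index(drop=True)
        df["effect_allele"], df["other_allele"] = "C", "A"  # panel has A/G
        out, rep = harmonize_to_panel(SumStats(df), _panel_variants())
        assert len(out) == 0
        assert rep.dropped["irreconcilable_alleles"] == 1

    def test_strand_complement_resolved(self):
        # reported on the opposite strand: C/T at a panel G/A site
        df = toy_sumstats_frame().iloc[[0]].reset_index(drop=True)
        df["effect_allele"], df["other_allele"] = "C", "T"  # complements of G/A
        out, rep = harmonize_to_panel(SumStats(df), _panel_variants())
        assert len(out) == 1
        row = out.table.iloc[0]
        assert (row["effect_allele"], row["other_allele"]) == ("G", "A")
        assert row["beta"] == 0.1  # orientation preserved after complementing

    def test_absent_from_panel_dropped(self):
        df = toy_sumstats_frame()
        out, rep = harmonize_to_panel(SumStats(df), _panel_variants().iloc[:2])
        assert rep.dropped["absent_from_panel"] == 3
        assert rep.n_input == rep.n_output + sum(rep.dropped.values())

    def test_flip_is_involutive(self):
        df = toy_sumstats_frame()
        mask = np.array([True, False, True, True, False])
        twice = flip_orientation(flip_orientation(df, mask), mask)
        pd.testing.assert_frame_equal(df, twice)


class TestPGSModel:
    def _model(self):
        df = toy_sumstats_frame().iloc[:3][
            ["chrom", "pos", "other_allele", "effect_allele", "beta"]
        ].reset_index(drop=True)
        df["weight_ppi"] = [0.9, 0.01, 0.5]
        df["weight"] = df["weight_ppi"] * df["beta"]
        return PGSModel(df)

    def test_roundtrip_exact(self, tmp_path):
        m = self._model()
        write_pgs_model(m, tmp_path / "m.tsv")
        back = read_pgs_model(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(m.table, back.table)

    def test_empty_model_is_hard_error(self, tmp_path):
        m = self._model()
        m.table = m.table.iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            write_pgs_model(m, tmp_path / "m.tsv")

    def test_weight_is_product_of_beta_and_ppi(self, tmp_path):
        m = self._model()
        write_pgs_model(m, tmp_path / "m.tsv")
        df = read_pgs_model(tmp_path / "m.tsv").table
        assert np.array_equal(df["weight"], df["beta"] * df["weight_ppi"])

    def test_ppi_out_of_range_rejected(self):
        df = self._model().table.copy()
        df.loc[0, "weight_ppi"] = 1.0
        with pytest.raises(ValueError, match="weight_ppi"):
            PGSModel(df)
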