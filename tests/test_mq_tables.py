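"""Table parsing, schema validation and the Perseus-style site merge."""

import numpy as np
import pandas as pd
import pytest

from redoxtmt import mq_tables as mq


def _write(df, path):
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadMqTable:
    def test_parses_hand_written_fixture(self, mod_peptide_fixture):
        df = mq.read_mq_table(mod_peptide_fixture, mq.TableKind.MOD_PEPTIDES)
        assert len(df) == 3
        assert df.loc[0, "Sequence"] == "ACDEFK"
        assert df.loc[0, "Reporter intensity 1"] == 100.0
        # 0 means "not observed" and must be preserved verbatim here
        assert df.loc[1, "Reporter intensity 10"] == 0.0

    def test_flag_mapping(self, mod_peptide_fixture):
        df = mq.read_mq_table(mod_peptide_fixture, mq.TableKind.MOD_PEPTIDES)
        assert df["Reverse"].tolist() == [False, False, True]
        assert not df["Potential contaminant"].any()

    def test_missing_required_column_names_it(self, mod_peptide_fixture, tmp_path):
        df = pd.read_csv(mod_peptide_fixture, sep="\t")
        broken = _write(df.drop(columns=["Reporter intensity 3", "Modifications"]),
                        tmp_path / "broken.txt")
        with pytest.raises(mq.SchemaError, match="Modifications"):
            mq.read_mq_table(broken, mq.TableKind.MOD_PEPTIDES)

    def test_duplicate_ids_rejected(self, mod_peptide_fixture, tmp_path):
        df = pd.read_csv(mod_peptide_fixture, sep="\t")
        df["id"] = [0, 0, 2]
        with pytest.raises(mq.IntegrityError, match="duplicate"):
            mq.read_mq_table(_write(df, tmp_path / "dup.txt"), mq.TableKind.MOD_PEPTIDES)

    def test_round_trip(self, mod_peptide_fixture, tmp_path):
        df = mq.read_mq_table(mod_peptide_fixture, mq.TableKind.MOD_PEPTIDES)
        out = tmp_path / "again.txt"
        mq.write_mq_table(df, out, mq.TableKind.MOD_PEPTIDES)
        again = mq.read_mq_table(out, mq.TableKind.MOD_PEPTIDES)
        pd.testing.assert_frame_equal(df, again)


@pytest.mark.parametrize(
    "mods,expected",
    [
        (mq.LIGHT_MOD, mq.LabelState.LIGHT),
        ("2 " + mq.LIGHT_MOD, mq.LabelState.LIGHT),
        (mq.HEAVY_MOD, mq.LabelState.HEAVY),
        (mq.LIGHT_MOD + "," + mq.HEAVY_MOD, mq.LabelState.MIXED),
        ("Unmodified", mq.LabelState.NONE),
        ("Oxidation (M)", mq.LabelState.NONE),
        ("Acetyl (Protein N-term),3 " + mq.HEAVY_MOD, mq.LabelState.HEAVY),
    ],
)
def test_label_state_parsing(mods, expected):
    assert mq.parse_label_state(mods) is expected


def _site_row(sid, protein, pos, pep_ids):
    return {
        "id": sid, "Protein": protein, "Position": pos,
        "Score diff": 12.5, "Localization prob": 0.99,
        "Mod. peptide IDs": pep_ids,
    }


@pytest.fixture
def merge_inputs():
    mod = pd.DataFrame(
        {
            "id": [7, 8, 9],
            "Sequence": ["ACDEFK", "LMNQR", "ACDEFK"],
            "Modifications": [mq.LIGHT_MOD, "Unmodified", mq.HEAVY_MOD],
            "Peptide ID": [0, 1, 0],
            "Reverse": [False] * 3,
            "Potential contaminant": [False] * 3,
        }
    )
    peptides = pd.DataFrame(
        {
            "id": [0, 1],
            "Sequence": ["ACDEFK", "LMNQR"],
            "C Count": [1, 0],
            "Start position": [151, 30],
            "End position": [156, 34],
            "Leading razor protein": ["P1", "P2"],
            "Reverse": [False, False],
            "Potential contaminant": [False, False],
        }
    )
    light = pd.DataFrame([_site_row(0, "P1", 152, "7")])
    heavy = pd.DataFrame([_site_row(0, "P1", 152, "9")])
    return mod, peptides, heavy, light


class TestMergeSiteColumns:
    def test_single_key_join_attaches_position(self, merge_inputs):
        merged = mq.merge_site_columns(*merge_inputs)
        row = merged.set_index("id").loc[7]
        assert mq.site_positions_list(row["Site positions"]) == [152]
        assert row["C count"] == 1
        assert row["Leading razor protein"] == "P1"
        assert row["Localization prob"] == 0.99

    def test_unmatched_row_kept_with_missing_site_fields(self, merge_inputs):
        merged = mq.merge_site_columns(*merge_inputs)
        row = merged.set_index("id").loc[8]
        assert mq.site_positions_list(row["Site positions"]) == []
        assert np.isnan(row["Score diff"])

    def test_row_count_conserved(self, merge_inputs):
        mod = merge_inputs[0]
        merged = mq.merge_site_columns(*merge_inputs)
        assert list(merged["id"]) == list(mod["id"])

    def test_multi_id_link_attaches_to_both_rows(self, merge_inputs):
        mod, peptides, heavy, _ = merge_inputs
        light = pd.DataFrame([_site_row(0, "P1", 152, "7;9")])
        merged = mq.merge_site_columns(mod, peptides, heavy, light).set_index("id")
        # hand enumeration: ids 7 and 9 each gain position 152; id 8 none
        assert mq.site_positions_list(merged.loc[7, "Site positions"]) == [152]
        assert mq.site_positions_list(merged.loc[9, "Site positions"]) == [152]
        assert mq.site_positions_list(merged.loc[8, "Site positions"]) == []
        assert len(merged) == 3

    def test_unknown_peptide_id_skipped_with_warning(self, merge_inputs, caplog):
        mod, peptides, heavy, _ = merge_inputs
        light = pd.DataFrame([_site_row(0, "P1", 152, "7;999")])
        with caplog.at_level("WARNING"):
            merged = mq.merge_site_columns(mod, peptides, heavy, light)
        assert "999" in caplog.text
        assert len(merged) == 3

    def test_label_state_column(self, merge_inputs):
        merged = mq.merge_site_columns(*merge_inputs).set_index("id")
        assert merged.loc[7, "Label state"] == "LIGHT"
        assert merged.loc[8, "Label state"] == "NONE"
        assert merged.loc[9, "Label state"] == "HEAVY"


def test_labeled_peptides_keep_cys_count_after_merge(small_sim):
    t = small_sim["tables"]
    merged = mq.merge_site_columns(
        t["modificationSpecificPeptides"], t["peptides"],
        t["heavy_sites"], t["light_sites"],
    )
    labeled = merged[merged["Label state"].isin(["LIGHT", "HEAVY", "MIXED"])]
    assert (labeled["C count"] >= 1).all()


def test_reporter_columns_family_separation():
    cols = ["Reporter intensity 1", "Reporter intensity 2",
            "Reporter intensity corrected 1", "Reporter intensity corrected 2",
            "Reporter intensity count 1"]
    assert mq.reporter_columns(cols, mq.RAW_FAMILY) == [
        "Reporter intensity 1", "Reporter intensity 2"]
    assert mq.reporter_columns(cols, mq.CORRECTED_FAMILY) == [
        "Reporter intensity corrected 1", "Reporter intensity corrected 2"]
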