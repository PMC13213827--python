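"""Outer-join assembly, variants, growth timeline and quality filters."""

import numpy as np
import pandas as pd
import pytest

from bioactlink.tables import (
    ConfigurationError,
    DuplicateKeyError,
    TableVariant,
    apply_quality_filters,
    build_variant,
    column_manifest,
    growth_timeline,
    merge_outputs,
)


def ligand_df(rows):
    return pd.DataFrame(rows, columns=[
        "structure_id", "het_code", "chain_id", "residue_number", "heavy_atoms",
        "mol_weight", "covalent", "skip_reasons"])


def structure_df(rows):
    return pd.DataFrame(rows, columns=[
        "structure_id", "resolution", "r_factor", "r_free", "method", "deposition_date"])


def activity_df(rows):
    return pd.DataFrame(rows, columns=[
        "structure_id", "het_code", "chain_id", "target_accession", "assay_id",
        "activity_type", "value", "units", "document_date", "identity",
        "molecule_level", "n_site_mutations", "quality", "from_seqadv",
        "best_alignment", "molecule_inchikey", "data_validity_comment"])


L1 = ("S001", "ATP", "A", 101, 31, 507.2, False, "")
L2 = ("S001", "MG", "A", 102, 1, 24.3, False, "UNSUPPORTED_ELEMENT")
S1 = ("S001", 1.8, 0.18, 0.21, "X-RAY DIFFRACTION", "2005-01-01")
A1 = ("S001", "ATP", "A", "CHEMBL25", "A1", "IC50", 100.0, "nM", "2006-05-01",
      99.0, 5, 0, "GOLD", False, True, "KEY1", "")


class TestMergeOutputs:
    def test_ligands_with_structure_no_activity(self):
        merged = merge_outputs(ligand_df([L1, L2]), structure_df([S1]), activity_df([]))
        assert len(merged) == 2
        assert set(merged["merge_ligand_structure"]) == {"both"}
        assert set(merged["merge_activity"]) == {"absent"}

    def test_disjoint_keys_sum_of_counts(self):
        lig = ligand_df([L1])
        struct = structure_df([("S999", 2.0, None, None, "NMR", "2010-01-01")])
        act = activity_df([("S888", "GTP", "B", "CHEMBL3", "A9", "Ki", 5.0, "nM",
                            "2011-01-01", 98.0, 4, 0, "GOLD", False, True, "K2", "")])
        merged = merge_outputs(lig, struct, act)
        assert len(merged) == 3
        assert (merged["merge_ligand_structure"] == "ligand_only").sum() == 1
        assert (merged["merge_ligand_structure"] == "structure_only").sum() == 1
        assert (merged["merge_activity"] == "present").sum() == 1

    def test_all_three_sources_single_row(self):
        merged = merge_outputs(ligand_df([L1]), structure_df([S1]), activity_df([A1]))
        assert len(merged) == 1
        row = merged.iloc[0]
        assert row["merge_ligand_structure"] == "both"
        assert row["merge_activity"] == "present"

    def test_duplicate_ligand_key_rejected(self):
        with pytest.raises(DuplicateKeyError):
            merge_outputs(ligand_df([L1, L1]), structure_df([S1]), activity_df([]))


class TestBuildVariant:
    def _merged(self):
        a_winner = A1
        a_loser = ("S001", "ATP", "A", "CHEMBL99", "A2", "IC50", 50.0, "nM",
                   "2007-05-01", 97.0, 5, 0, "GOLD", False, True, "KEY1", "")
        return merge_outputs(ligand_df([L1, L2]), structure_df([S1]),
                             activity_df([a_winner, a_loser]))

    def test_full_is_identity(self):
        merged = self._merged()
        assert build_variant(merged, TableVariant.FULL).equals(merged)

    def test_filtered_keeps_only_winner_rows(self):
        merged = self._merged()
        out = build_variant(merged, TableVariant.FILTERED, {("S001", "ATP"): "CHEMBL25"})
        act = out[out["merge_activity"] == "present"]
        assert set(act["target_accession"]) == {"CHEMBL25"}
        # the losing target's rows are gone but no ligand disappeared
        assert set(out["het_code"].dropna()) == {"ATP", "MG"}

    def test_seqadv_only_match_leaves_dataless_row(self):
        a_seqadv = ("S001", "ATP", "A", "CHEMBL25", "A1", "IC50", 100.0, "nM",
                    "2006-05-01", 100.0, 5, 0, "GOLD", True, True, "KEY1", "")
        merged = merge_outputs(ligand_df([L1]), structure_df([S1]), activity_df([a_seqadv]))
        out = build_variant(merged, TableVariant.FILTERED, {("S001", "ATP"): "CHEMBL25"})
        assert len(out) == 1
        assert out.iloc[0]["merge_activity"] == "absent"
        assert out.iloc[0]["het_code"] == "ATP"

    def test_filtered_subset_and_idempotent(self):
        merged = self._merged()
        winners = {("S001", "ATP"): "CHEMBL25"}
        once = build_variant(merged, TableVariant.FILTERED, winners)
        twice = build_variant(once, TableVariant.FILTERED, winners)
        key = ["structure_id", "het_code", "target_accession", "assay_id"]
        act_once = once[once["merge_activity"] == "present"][key]
        act_twice = twice[twice["merge_activity"] == "present"][key]
        assert act_once.reset_index(drop=True).equals(act_twice.reset_index(drop=True))
        full_keys = set(map(tuple, merged[merged["merge_activity"] == "present"][key]
                            .itertuples(index=False)))
        assert set(map(tuple, act_once.itertuples(index=False))) <= full_keys

    def test_missing_cascade_results_rejected(self):
        with pytest.raises(ConfigurationError):
            build_variant(self._merged(), TableVariant.FILTERED, None)

    def test_target_variant_drops_ligand_specific_columns(self):
        merged = self._merged()
        out = build_variant(merged, TableVariant.TARGET)
        assert "molecule_level" not in out.columns
        assert "n_site_mutations" not in out.columns


def _timeline_rows(dates):
    rows = []
    for i, (dep, doc) in enumerate(dates):
        rows.append({
            "structure_id": f"S{i:03d}", "het_code": "ATP",
            "deposition_date": dep, "document_date": doc,
            "merge_activity": "present",
        })
    return pd.DataFrame(rows)


class TestGrowthTimeline:
    def test_yearly_and_cumulative_counts(self):
        tl = growth_timeline(_timeline_rows([
            ("2005-01-01", "2004-01-01"),
            ("2006-01-01", "2005-01-01"),
            ("2006-06-01", "2006-01-01"),
        ]))
        assert dict(zip(tl["year"], tl["new_complexes"])) == {2005: 1, 2006: 2}
        assert dict(zip(tl["year"], tl["cumulative"])) == {2005: 1, 2006: 3}

    def test_later_date_rule(self):
        tl = growth_timeline(_timeline_rows([("2004-01-01", "2008-06-01")]))
        assert tl["year"].tolist() == [2008]

    def test_empty_input(self):
        assert len(growth_timeline(pd.DataFrame(columns=["merge_activity"]))) == 0

    def test_rows_missing_both_dates_excluded(self):
        tl = growth_timeline(_timeline_rows([(None, None), ("2005-01-01", "2003-01-01")]))
        assert tl["new_complexes"].sum() == 1


class TestQualityFilters:
    def _rows(self):
        return pd.DataFrame([
            {"resolution": 2.0, "identity": 99.0, "n_site_mutations": 1,
             "molecule_level": 5, "quality": "GOLD", "skip_reasons": "",
             "density_support": 0.9, "data_validity_comment": "",
             "molecule_inchikey": "K1", "target_accession": "CHEMBL1",
             "activity_type": "IC50", "value": 10.0, "units": "nM"},
            {"resolution": 2.4, "identity": 96.0, "n_site_mutations": 0,
             "molecule_level": 3, "quality": "SILVER", "skip_reasons": "",
             "density_support": -1.0, "data_validity_comment": "",
             "molecule_inchikey": "K2", "target_accession": "CHEMBL1",
             "activity_type": "IC50", "value": 20.0, "units": "nM"},
            {"resolution": 3.0, "identity": 85.0, "n_site_mutations": 0,
             "molecule_level": 5, "quality": "BRONZE",
             "skip_reasons": "COVALENT_LINK", "density_support": 1.1,
             "data_validity_comment": "outside typical range",
             "molecule_inchikey": "K1", "target_accession": "CHEMBL1",
             "activity_type": "IC50", "value": 10.0, "units": "nM"},
        ])

    def test_resolution_bound_is_strict(self):
        out = apply_quality_filters(self._rows(), {"resolution_max": 2.5})
        assert len(out) == 2

    def test_conjunction_of_criteria(self):
        out = apply_quality_filters(
            self._rows(), {"identity_min": 95, "site_mutations_max": 0})
        assert len(out) == 1  # identity 99 fails the mutation cap

    def test_density_range_removes_not_computable(self):
        out = apply_quality_filters(self._rows(), {"density_min": 0.0})
        assert (-1.0 not in out["density_support"].tolist())

    def test_empty_criteria_is_identity(self):
        rows = self._rows()
        assert apply_quality_filters(rows, {}).equals(rows)

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_quality_filters(self._rows(), {"not_a_criterion": 1})

    def test_duplicate_and_validity_removal(self):
        out = apply_quality_filters(
            self._rows(), {"remove_duplicates": True, "remove_data_validity": True})
        # third row is both a duplicate measurement and validity-commented
        assert len(out) == 2

    def test_monotone_and_order_independent(self):
        rows = self._rows()
        c1 = {"resolution_max": 2.5}
        c2 = {"resolution_max": 2.5, "quality_min": "SILVER"}
        assert len(apply_quality_filters(rows, c2)) <= len(apply_quality_filters(rows, c1))
        a = apply_quality_filters(apply_quality_filters(rows, c1), {"quality_min": "SILVER"})
        b = apply_quality_filters(apply_quality_filters(rows, {"quality_min": "SILVER"}), c1)
        assert a.reset_index(drop=True).equals(b.reset_index(drop=True))


def test_column_manifest_covers_merge_indicators():
    manifest = column_manifest()
    assert "merge_ligand_structure" in manifest["indicators"]
    assert "merge_activity" in manifest["indicators"]
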