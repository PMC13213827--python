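"""Structure parsing, ligand discovery and binding-site geometry."""

import numpy as np
import pytest

from bioactlink.structures import (
    Atom,
    BindingSite,
    ChainRecord,
    DegenerateLigandError,
    EmptyStructureError,
    HetGroup,
    LigandInstance,
    ResidueRecord,
    SkipReason,
    StructureFormatError,
    StructureRecord,
    extract_ligands,
    find_binding_site,
    parse_structure,
)

from conftest import ATP_ATOMS, build_pdb


class TestParseStructure:
    def test_basic_chain_and_het_group(self, atp_pdb):
        s = parse_structure(atp_pdb)
        assert len(s.chains) == 1
        assert s.chains[0].one_letter_sequence == "AGS"
        assert s.chains[0].atom_sequence == "AGS"
        assert [g.het_code for g in s.het_groups] == ["ATP"]

    def test_header_fields(self, atp_pdb):
        s = parse_structure(atp_pdb)
        assert s.resolution == pytest.approx(1.8)
        assert s.r_factor == pytest.approx(0.180)
        assert s.r_free == pytest.approx(0.210)
        assert s.experimental_method == "X-RAY DIFFRACTION"
        assert s.deposition_date.isoformat() == "2005-01-01"
        assert s.structure_id == "1ABC"

    def test_water_never_a_het_group(self, atp_pdb):
        s = parse_structure(atp_pdb)
        assert all(g.het_code != "HOH" for g in s.het_groups)

    def test_empty_text_is_format_error(self):
        with pytest.raises(StructureFormatError):
            parse_structure("")

    def test_garbage_text_is_format_error(self):
        with pytest.raises(StructureFormatError):
            parse_structure("this is not a structure\nat all\n")

    def test_no_polymer_chain_is_empty_structure_error(self):
        text = build_pdb(sequence="", het_atoms=[("C1", "C")], het_code="LIG")
        with pytest.raises(EmptyStructureError):
            parse_structure(text)

    def test_seqadv_parsed(self):
        line = "SEQADV 1ABC MET A    2  UNP  Q01ABC    LEU    2  ENGINEERED MUTATION"
        s = parse_structure(build_pdb(sequence="AMG", extra_header=[line]))
        assert len(s.seqadv_entries) == 1
        e = s.seqadv_entries[0]
        assert (e.chain_id, e.residue_number) == ("A", 2)
        assert (e.modeled_residue, e.reference_residue) == ("MET", "LEU")

    def test_roundtrip_through_fixture_writer(self):
        from bioactlink.fixtures import generate_structure, random_scenario

        spec = random_scenario(7, n_structures=3)
        for i, bp in enumerate(spec.structures):
            text, _ = generate_structure(spec, i)
            s = parse_structure(text)
            assert s.structure_id == bp.structure_id
            assert s.chains[0].one_letter_sequence == bp.sequence
            assert s.resolution == pytest.approx(bp.resolution, abs=5e-3)
            assert s.deposition_date == bp.deposition


class TestExtractLigands:
    def test_atp_descriptors(self, atp_pdb):
        ligs = extract_ligands(parse_structure(atp_pdb))
        assert len(ligs) == 1
        lig = ligs[0]
        # independent count: non-hydrogen atom records placed in the fixture
        assert lig.heavy_atom_count == len(ATP_ATOMS) == 31
        assert lig.skip_reasons == set()
        assert not lig.covalent
        assert lig.molecular_weight > 0

    def test_water_only_gives_empty_inventory(self):
        s = parse_structure(build_pdb(het_atoms=None, with_water=True))
        assert extract_ligands(s) == []

    def test_unsupported_element_flag(self):
        s = parse_structure(build_pdb(het_atoms=[("FE", "FE")], het_code="MFE"))
        (lig,) = extract_ligands(s)
        assert SkipReason.UNSUPPORTED_ELEMENT in lig.skip_reasons

    def test_covalent_link_flag(self):
        link = ("LINK         C1  LIG A 101                 CA  GLY A   2     "
                "1555   1555  1.80")
        s = parse_structure(
            build_pdb(het_atoms=[("C1", "C"), ("O1", "O")], het_code="LIG",
                      link_lines=[link])
        )
        (lig,) = extract_ligands(s)
        assert lig.covalent
        assert SkipReason.COVALENT_LINK in lig.skip_reasons

    def test_metadata_peculiarity_flags(self):
        s = parse_structure(build_pdb(
            het_atoms=[("C1", "C")], het_code="LIG",
            extra_header=["REMARK 470 MISSING ATOM",
                          "REMARK 470     LIG A 101    O1"],
        ))
        (lig,) = extract_ligands(s)
        assert SkipReason.MISSING_ATOMS_ANNOTATED in lig.skip_reasons

    def test_formula_mismatch_against_reference(self):
        s = parse_structure(build_pdb(het_atoms=[("C1", "C"), ("O1", "O")], het_code="LIG"))
        (ok,) = extract_ligands(s, reference_formulas={"LIG": "C1 O1"})
        assert SkipReason.FORMULA_MISMATCH not in ok.skip_reasons
        (bad,) = extract_ligands(s, reference_formulas={"LIG": "C2 O1"})
        assert SkipReason.FORMULA_MISMATCH in bad.skip_reasons

    def test_polymer_code_flagged_not_dropped(self):
        s = parse_structure(build_pdb(het_atoms=[("N", "N"), ("CA", "C")], het_code="ALA"))
        (lig,) = extract_ligands(s)
        assert SkipReason.POLYMER_LIGAND in lig.skip_reasons


def _toy_structure(res_positions, lig_positions):
    """One-chain record with single-atom residues and a free-floating ligand."""
    residues = [
        ResidueRecord("ALA", i + 1, [Atom("CA", "C", *pos)])
        for i, pos in enumerate(res_positions)
    ]
    chain = ChainRecord("A", residues, "A" * len(residues), "A" * len(residues))
    s = StructureRecord(
        structure_id="TOY1", chains=[chain], het_groups=[],
        seqadv_entries=[], resolution=None, r_factor=None, r_free=None,
        experimental_method=None, deposition_date=None, link_records=[],
        metadata_peculiarities=[],
    )
    lig = LigandInstance(
        structure_id="TOY1", het_code="LIG", chain_id="A", residue_number=99,
        heavy_atom_coordinates=[Atom(f"C{i+1}", "C", *p) for i, p in enumerate(lig_positions)],
        heavy_atom_count=len(lig_positions), molecular_weight=12.0 * len(lig_positions),
    )
    return s, lig


class TestBindingSite:
    def test_residue_inside_cutoff_included(self):
        s, lig = _toy_structure([(3.0, 0, 0)], [(0, 0, 0)])
        site = find_binding_site(s, lig, cutoff=3.25)
        assert site.residues == {("A", 1)}
        assert site.sequence_positions == {"A": {0}}

    def test_residue_outside_cutoff_excluded(self):
        s, lig = _toy_structure([(3.5, 0, 0)], [(0, 0, 0)])
        assert find_binding_site(s, lig, cutoff=3.25).residues == set()

    def test_any_ligand_atom_counts(self):
        # residue is near the second ligand atom only
        s, lig = _toy_structure([(10.0, 0, 0)], [(0, 0, 0), (8.0, 0, 0)])
        assert find_binding_site(s, lig, cutoff=3.25).residues == {("A", 1)}

    def test_zero_heavy_atoms_is_degenerate(self):
        s, lig = _toy_structure([(0, 0, 0)], [])
        with pytest.raises(DegenerateLigandError):
            find_binding_site(s, lig)

    def test_rigid_motion_invariance(self, rng):
        res = rng.normal(size=(12, 3)) * 4
        ligp = rng.normal(size=(4, 3)) * 2
        s, lig = _toy_structure([tuple(p) for p in res], [tuple(p) for p in ligp])
        before = find_binding_site(s, lig).residues
        # random rotation (QR of a Gaussian matrix) + translation of everything
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(size=3) * 50
        s2, lig2 = _toy_structure(
            [tuple(q @ p + t) for p in res], [tuple(q @ p + t) for p in ligp]
        )
        assert find_binding_site(s2, lig2).residues == before

    def test_never_fewer_ligands_than_het_groups(self, atp_pdb):
        s = parse_structure(atp_pdb)
        assert len(extract_ligands(s)) >= len(s.het_groups)
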