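"""Synthetic structures and bioactivity tables with planted ground truth.

Every stage of the linking pipeline is testable offline: this module
generates PDB-format complexes (idealized extended-chain backbones with
Cβ stubs, a ligand placed so that its binding site is exactly a planted
residue set), matching bioactivity tables emulating a registry extract,
and a :class:`TruthBundle` stating what the pipeline must recover —
ligand inventories and skip reasons, binding-site residues, alignment
statistics, molecule match levels, binding-site mutation counts, cascade
winners with their deciding steps, and variant-sequence handling.

A scenario is a list of per-structure blueprints, each engineered so that
one specific cascade step decides its best target.  ``random_scenario``
cycles through every deciding step plus SEQADV-decoy and variant-sequence
cases.  Generation is deterministic under the scenario seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date

import numpy as np
from rdkit import Chem

from .cascade import DUMMY_TARGET

__all__ = [
    "LigandEntry",
    "AssayBlueprint",
    "TargetBlueprint",
    "StructureBlueprint",
    "ScenarioSpec",
    "StructureTruth",
    "TruthBundle",
    "GenerationError",
    "LIGAND_LIBRARY",
    "random_scenario",
    "generate_structure",
    "generate_bioactivities",
    "generate_scenario_files",
    "SCENARIO_KINDS",
]


class GenerationError(ValueError):
    """Infeasible geometry or inconsistent blueprint."""


AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

_MONTHS = ["JAN", "FEB", "MAR", "APR", "MAY", "JUN",
           "JUL", "AUG", "SEP", "OCT", "NOV", "DEC"]

#: Cα spacing of the idealized extended chain, Å.
CA_SPACING = 3.8
#: Ligand heavy atoms sit this far (Å) above their planted site residue's Cα;
#: must be below the site cutoff while keeping neighbours outside it.
LIGAND_OFFSET = 2.8


@dataclass(frozen=True)
class LigandEntry:
    """One library compound with pre-chosen related forms for planting
    molecule match levels (5 exact / 3 enantiomer / 1 tautomer / 0 unrelated)."""

    het_code: str
    smiles: str
    enantiomer: str | None = None
    tautomer: str | None = None
    unrelated: str = "Oc1ccccc1"

    def smiles_for(self, kind: str) -> str:
        if kind == "exact":
            return self.smiles
        value = getattr(self, kind, None)
        if value is None:
            raise GenerationError(f"{self.het_code} has no {kind} form")
        return value

    def heavy_atoms(self) -> list[str]:
        mol = Chem.MolFromSmiles(self.smiles)
        return [a.GetSymbol().upper() for a in mol.GetAtoms()]


LIGAND_LIBRARY: dict[str, LigandEntry] = {
    "L01": LigandEntry(  # chiral hydroxy-ketone: supports all four levels
        "L01",
        smiles="C[C@H](O)CC(C)=O",
        enantiomer="C[C@@H](O)CC(C)=O",
        tautomer="C[C@H](O)C=C(C)O",
    ),
    "L02": LigandEntry("L02", smiles="CC(=O)Oc1ccccc1C(=O)O"),
    "L03": LigandEntry("L03", smiles="NC(=O)c1ccccc1"),
    "CVL": LigandEntry("CVL", smiles="CC=O"),  # covalent decoy
}


@dataclass
class AssayBlueprint:
    assay_id: str
    molecule_kind: str = "exact"       # exact | enantiomer | tautomer | unrelated
    n_values: int = 1                  # distinct activity values
    variant: str | None = None         # None | "match" | "undefined"
    planted_level: int = 5             # expected molecule match level (0 = unlinked)


@dataclass
class TargetBlueprint:
    accession: str
    target_type: str = "SINGLE PROTEIN"
    component_mutations: list[tuple[int, str]] = field(default_factory=list)
    # component sequence == chain sequence with these (position, new_aa) applied
    via_seqadv: bool = False           # component equals the SEQADV-reverted chain
    assays: list[AssayBlueprint] = field(default_factory=list)


@dataclass
class StructureBlueprint:
    structure_id: str
    kind: str                          # which cascade step this case exercises
    chain_length: int
    sequence: str
    ligand: str                        # LIGAND_LIBRARY key
    site_positions: list[int]          # 0-based chain indices forming the site
    targets: list[TargetBlueprint]
    seqadv: tuple[int, str] | None = None   # (position, reference_aa) header entry
    with_decoys: bool = False          # covalent + metal + water + remark-470
    resolution: float = 2.0
    r_factor: float = 0.18
    r_free: float = 0.22
    deposition: date = date(2005, 6, 15)


@dataclass
class ScenarioSpec:
    seed: int
    n_structures: int
    chain_length_range: tuple[int, int]
    structures: list[StructureBlueprint]

    def het_smiles(self) -> dict[str, str]:
        """Component-dictionary view (het code -> reference SMILES)."""
        return {e.het_code: e.smiles for e in LIGAND_LIBRARY.values()}


@dataclass
class StructureTruth:
    structure_id: str
    ligands: dict = field(default_factory=dict)       # (het,chain,resnum) -> descriptors
    site_residues: dict = field(default_factory=dict)  # primary ligand -> residue numbers
    candidates: dict = field(default_factory=dict)     # accession -> planted attributes
    assay_levels: dict = field(default_factory=dict)   # assay_id -> planted level
    assay_rows: dict = field(default_factory=dict)     # assay_id -> variant/mutation truth
    winner_binding: str | None = None
    decided_binding: str = "SINGLE"
    winner_target: str | None = None
    decided_target: str = "SINGLE"


@dataclass
class TruthBundle:
    structures: dict[str, StructureTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, set):
                return sorted(o)
            return dataclasses.asdict(o)
        return json.dumps(
            {sid: dataclasses.asdict(t) for sid, t in self.structures.items()},
            default=enc, indent=1, sort_keys=True,
        )


# --- PDB text writing -------------------------------------------------------

def _fmt_date(d: date) -> str:
    return f"{d.day:02d}-{_MONTHS[d.month - 1]}-{d.year % 100:02d}"


def _atom_line(rec, serial, name, element, res, chain, num, x, y, z):
    if len(element) == 1 and len(name) <= 3:
        name_f = f" {name:<3s}"
    else:
        name_f = f"{name:<4s}"
    return (
        f"{rec:<6s}{serial:>5d} {name_f} {res:<3s} {chain}{num:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{20.00:6.2f}          {element:>2s}"
    )


def _seqres_lines(chain: str, sequence: str) -> list[str]:
    res3 = [AA1TO3[a] for a in sequence]
    lines = []
    for i in range(0, len(res3), 13):
        chunk = " ".join(f"{r:<3s}" for r in res3[i:i + 13])
        lines.append(f"SEQRES {i // 13 + 1:>3d} {chain} {len(res3):>4d}  {chunk}")
    return lines


def _seqadv_line(pid, chain, num, modeled3, ref3, comment="ENGINEERED MUTATION"):
    return (
        f"SEQADV {pid:<4s} {modeled3:<3s} {chain} {num:>4d}  UNP  "
        f"{'Q0' + pid:<9s} {ref3:<3s} {num:>4d}  {comment}"
    )


def _link_line(name1, res1, chain1, num1, name2, res2, chain2, num2):
    n1 = f" {name1:<3s}" if len(name1) <= 3 else f"{name1:<4s}"
    n2 = f" {name2:<3s}" if len(name2) <= 3 else f"{name2:<4s}"
    return (
        f"LINK        {n1} {res1:<3s} {chain1}{num1:>4d}                "
        f"{n2} {res2:<3s} {chain2}{num2:>4d}     1555   1555  1.80"
    )


def _element_names(elements: list[str]) -> list[str]:
    counts: dict[str, int] = {}
    names = []
    for el in elements:
        counts[el] = counts.get(el, 0) + 1
        names.append(f"{el}{counts[el]}")
    return names


def generate_structure(spec: ScenarioSpec, index: int) -> tuple[str, StructureTruth]:
    """PDB text for one blueprint plus its truth fragment.

    The chain is an extended backbone (Cα every 3.8 Å along x, Cβ stubs at
    −1.5 Å in y); ligand heavy atom *k* sits 2.8 Å above the Cα of the
    *k*-th planted site residue, remaining atoms are parked far away, so
    the binding site at the default 3.25 Å cutoff is exactly the planted
    residue set.
    """
    bp = spec.structures[index]
    L = bp.chain_length
    if any(p < 0 or p >= L for p in bp.site_positions):
        raise GenerationError(f"site positions outside chain of length {L}")
    entry = LIGAND_LIBRARY[bp.ligand]
    lig_elements = entry.heavy_atoms()
    if len(lig_elements) < len(bp.site_positions):
        raise GenerationError("ligand has fewer heavy atoms than planted site residues")

    lines = [
        f"HEADER    SYNTHETIC COMPLEX                       {_fmt_date(bp.deposition)}   {bp.structure_id}",
        "EXPDTA    X-RAY DIFFRACTION",
        f"REMARK   2 RESOLUTION.{bp.resolution:8.2f} ANGSTROMS.",
        f"REMARK   3   R VALUE            (WORKING SET) : {bp.r_factor:.3f}",
        f"REMARK   3   FREE R VALUE                     : {bp.r_free:.3f}",
    ]
    if bp.with_decoys:
        lines.append("REMARK 470 MISSING ATOM")
        lines.append("REMARK 470     CVL A 300    O1")
    if bp.seqadv is not None:
        pos, ref_aa = bp.seqadv
        lines.append(
            _seqadv_line(bp.structure_id, "A", pos + 1, AA1TO3[bp.sequence[pos]], AA1TO3[ref_aa])
        )
    lines.extend(_seqres_lines("A", bp.sequence))
    if bp.with_decoys:
        lines.append(_link_line("C1", "CVL", "A", 300, "CA", AA1TO3[bp.sequence[1]], "A", 2))

    serial = 1
    for i, aa in enumerate(bp.sequence):
        res3 = AA1TO3[aa]
        x = CA_SPACING * i
        lines.append(_atom_line("ATOM", serial, "CA", "C", res3, "A", i + 1, x, 0.0, 0.0))
        serial += 1
        if aa != "G":
            lines.append(_atom_line("ATOM", serial, "CB", "C", res3, "A", i + 1, x, -1.5, 0.0))
            serial += 1
    lines.append(f"TER   {serial:>5d}      {AA1TO3[bp.sequence[-1]]:<3s} A{L:>4d}")
    serial += 1

    names = _element_names(lig_elements)
    lig_resnum = 200
    for k, (name, el) in enumerate(zip(names, lig_elements)):
        if k < len(bp.site_positions):
            x = CA_SPACING * bp.site_positions[k]
            y = LIGAND_OFFSET
        else:
            x = CA_SPACING * bp.site_positions[0]
            y = 8.0 + 1.5 * (k - len(bp.site_positions))
        lines.append(_atom_line("HETATM", serial, name, el, entry.het_code, "A", lig_resnum, x, y, 0.0))
        serial += 1

    truth = StructureTruth(structure_id=bp.structure_id)
    truth.ligands[f"{entry.het_code}/A/{lig_resnum}"] = {
        "heavy_atoms": len(lig_elements),
        "skip_reasons": [],
        "covalent": False,
    }
    truth.site_residues[f"{entry.het_code}/A/{lig_resnum}"] = sorted(
        p + 1 for p in bp.site_positions
    )

    if bp.with_decoys:
        cvl = LIGAND_LIBRARY["CVL"]
        cvl_elements = cvl.heavy_atoms()
        cvl_names = _element_names(cvl_elements)
        for name, el in zip(cvl_names, cvl_elements):
            # parked far in -x so no polymer residue is in its site
            lines.append(_atom_line("HETATM", serial, name, el, "CVL", "A", 300, -30.0, 8.0, 0.0))
            serial += 1
        truth.ligands["CVL/A/300"] = {
            "heavy_atoms": len(cvl_elements),
            "skip_reasons": ["COVALENT_LINK", "MISSING_ATOMS_ANNOTATED"],
            "covalent": True,
        }
        lines.append(_atom_line("HETATM", serial, "FE", "FE", "MFE", "A", 301, -40.0, 8.0, 0.0))
        serial += 1
        truth.ligands["MFE/A/301"] = {
            "heavy_atoms": 1,
            "skip_reasons": ["UNSUPPORTED_ELEMENT"],
            "covalent": False,
        }
        lines.append(_atom_line("HETATM", serial, "O", "O", "HOH", "A", 400, -50.0, 0.0, 0.0))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n", truth


# --- bioactivity table ------------------------------------------------------

ACTIVITY_COLUMNS = [
    "assay_id", "target_accession", "target_type", "component_sequence",
    "variant_sequence", "smiles", "activity_type", "value", "units",
    "pchembl", "document_date", "data_validity_comment",
]


def _apply_mutations(seq: str, mutations: list[tuple[int, str]]) -> str:
    chars = list(seq)
    for pos, aa in mutations:
        if chars[pos] == aa:
            raise GenerationError(f"mutation at {pos} does not change residue {aa}")
        chars[pos] = aa
    return "".join(chars)


def generate_bioactivities(spec: ScenarioSpec, rng: np.random.Generator | None = None):
    """Activity rows realizing every blueprint, plus truth fragments.

    Returns ``(pandas.DataFrame, dict[structure_id, StructureTruth])`` where
    the truth fragments carry the activity-side expectations (candidate
    attributes, per-assay molecule levels, variant handling, winners).
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    rows = []
    truths: dict[str, StructureTruth] = {}
    for bp in spec.structures:
        truth = StructureTruth(structure_id=bp.structure_id)
        entry = LIGAND_LIBRARY[bp.ligand]
        L = bp.chain_length
        site_set = set(bp.site_positions)
        for tgt in bp.targets:
            if tgt.via_seqadv:
                if bp.seqadv is None:
                    raise GenerationError("via_seqadv target without a SEQADV entry")
                pos, ref_aa = bp.seqadv
                component = _apply_mutations(bp.sequence, [(pos, ref_aa)])
                identity = 100.0
            else:
                component = _apply_mutations(bp.sequence, tgt.component_mutations)
                identity = 100.0 * (L - len(tgt.component_mutations)) / L
            n_site_mut = sum(1 for pos, _ in tgt.component_mutations if pos in site_set)

            n_points = 0
            best_identity = identity
            best_mut = n_site_mut
            levels = []
            doc_year = 2002 + int(rng.integers(0, 18))
            for assay in tgt.assays:
                variant_seq = ""
                if assay.variant == "match":
                    variant_seq = bp.sequence          # construct used = modeled chain
                elif assay.variant == "undefined":
                    variant_seq = "UNDEFINED MUTATION"
                smiles = entry.smiles_for(assay.molecule_kind)
                base_pchembl = round(float(rng.uniform(4.5, 9.0)), 2)
                for v in range(assay.n_values):
                    pchembl = round(base_pchembl + 0.17 * v, 2)  # distinct by construction
                    rows.append({
                        "assay_id": assay.assay_id,
                        "target_accession": tgt.accession,
                        "target_type": tgt.target_type,
                        "component_sequence": component,
                        "variant_sequence": variant_seq,
                        "smiles": smiles,
                        "activity_type": "IC50",
                        "value": round(10 ** (9 - pchembl), 3),
                        "units": "nM",
                        "pchembl": pchembl,
                        "document_date": f"{doc_year}-03-0{1 + v}",
                        "data_validity_comment": "",
                    })
                truth.assay_levels[assay.assay_id] = assay.planted_level
                if assay.variant == "match":
                    truth.assay_rows[assay.assay_id] = {"variant_used": True, "n_site_mutations": 0}
                    best_identity = 100.0
                    best_mut = 0
                elif assay.variant == "undefined":
                    truth.assay_rows[assay.assay_id] = {
                        "variant_used": False, "n_site_mutations": n_site_mut,
                    }
                if assay.planted_level > 0:
                    n_points += assay.n_values
                    levels.append(assay.planted_level)
            truth.candidates[tgt.accession] = {
                "identity": best_identity,
                "coverage": 100.0,
                "molecule_level": max(levels) if levels else 0,
                "n_site_mutations": best_mut,
                "n_datapoints": n_points,
                "from_seqadv": tgt.via_seqadv,
                "target_type": tgt.target_type,
            }
        _plant_winners(bp, truth)
        truths[bp.structure_id] = truth
    return pd.DataFrame(rows, columns=ACTIVITY_COLUMNS), truths


_TYPE_RANK = {"SINGLE PROTEIN": 0, "PROTEIN COMPLEX": 1, "PROTEIN FAMILY": 2}


def _plant_winners(bp: StructureBlueprint, truth: StructureTruth) -> None:
    """Winner + deciding step for both modes, by independent brute force.

    This is a straight lexicographic sort over the planted attributes —
    deliberately not the cascade implementation — so blueprint consistency
    is checked against a second opinion at generation time.
    """
    for mode in ("binding", "target"):
        cands = {
            acc: c for acc, c in truth.candidates.items() if not c["from_seqadv"]
        }
        cands = {acc: c for acc, c in cands.items() if acc != DUMMY_TARGET}
        if not cands:
            removed_all = truth.candidates and all(
                c["from_seqadv"] or acc == DUMMY_TARGET
                for acc, c in truth.candidates.items()
            )
            winner, decided = None, "DUMMY" if any(
                acc == DUMMY_TARGET for acc in truth.candidates
            ) else "SINGLE"
            assert removed_all or not truth.candidates
        else:
            def sort_key(item):
                acc, c = item
                key = [-round(c["identity"] * c["coverage"] / 1e4, 6)]
                if mode == "binding":
                    key.append(-c["molecule_level"])
                    key.append(c["n_site_mutations"])
                key.append(_TYPE_RANK.get(c["target_type"], 99))
                if mode == "binding":
                    key.append(-c["n_datapoints"])
                key.append(int(acc[len("CHEMBL"):]))
                return tuple(key)

            ranked = sorted(cands.items(), key=sort_key)
            winner = ranked[0][0]
            if len(truth.candidates) == 1:
                decided = "SINGLE"
            else:
                decided = _deciding_step(ranked, mode, truth.candidates)
        if mode == "binding":
            truth.winner_binding, truth.decided_binding = winner, decided
        else:
            truth.winner_target, truth.decided_target = winner, decided


def _deciding_step(ranked, mode, all_candidates) -> str:
    """Last attribute that strictly reduced the survivor set (brute force)."""
    pool = [acc for acc, _ in ranked]
    c = dict(ranked)
    steps: list[tuple[str, callable]] = [
        ("SEQUENCE", lambda x: -round(c[x]["identity"] * c[x]["coverage"] / 1e4, 6)),
    ]
    if mode == "binding":
        steps.append(("MOLECULE", lambda x: -c[x]["molecule_level"]))
        steps.append(("MUTATIONS", lambda x: c[x]["n_site_mutations"]))
    steps.append(("TARGET_TYPE", lambda x: _TYPE_RANK.get(c[x]["target_type"], 99)))
    if mode == "binding":
        steps.append(("DATAPOINTS", lambda x: -c[x]["n_datapoints"]))
    steps.append(("TIEBREAK", lambda x: int(x[len("CHEMBL"):])))

    decided = "SINGLE"
    if len(all_candidates) > len(pool) and any(
        acc == DUMMY_TARGET for acc in all_candidates
    ):
        decided = "DUMMY"
    for name, keyf in steps:
        if name == "TARGET_TYPE" and not any(
            c[x]["target_type"] in _TYPE_RANK for x in pool
        ):
            continue
        best = min(keyf(x) for x in pool)
        new_pool = [x for x in pool if keyf(x) == best]
        if len(new_pool) < len(pool):
            decided = name
        pool = new_pool
    return decided


# --- scenario construction --------------------------------------------------

SCENARIO_KINDS = [
    "SINGLE", "DUMMY", "SEQUENCE", "MOLECULE", "MUTATIONS",
    "TARGET_TYPE", "DATAPOINTS", "TIEBREAK", "SEQADV",
    "VARIANT_MATCH", "VARIANT_UNDEF",
]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AA_LETTERS[i] for i in rng.integers(0, len(AA_LETTERS), length))


def _pick_positions(rng, length, n, exclude=(), margin=5):
    """n distinct positions away from the termini and the excluded set."""
    pool = [p for p in range(margin, length - margin) if p not in exclude]
    if len(pool) < n:
        raise GenerationError("chain too short for requested positions")
    idx = rng.choice(len(pool), size=n, replace=False)
    return sorted(pool[i] for i in idx)


def _mutate_letter(rng, aa: str) -> str:
    choices = [c for c in AA_LETTERS if c != aa]
    return choices[int(rng.integers(0, len(choices)))]


def random_scenario(
    seed: int,
    n_structures: int = len(SCENARIO_KINDS),
    chain_length_range: tuple[int, int] = (34, 50),
) -> ScenarioSpec:
    """A scenario cycling through every cascade-deciding case.

    With the default ``n_structures`` each deciding step, the SEQADV
    discard and both variant-sequence behaviours are exercised once;
    larger values repeat the cycle with fresh random sequences.
    """
    rng = np.random.default_rng(seed)
    structures = []
    for i in range(n_structures):
        kind = SCENARIO_KINDS[i % len(SCENARIO_KINDS)]
        L = int(rng.integers(chain_length_range[0], chain_length_range[1] + 1))
        seq = _random_sequence(rng, L)
        sid = f"S{i:03d}"
        base = 1000 + 100 * i
        site = _pick_positions(rng, L, 3)
        lig = {"MOLECULE": "L01", "SINGLE": "L01",
               "TARGET_TYPE": "L03", "DATAPOINTS": "L03"}.get(kind, "L02")
        acc = lambda j: f"CHEMBL{base + j}"
        targets: list[TargetBlueprint] = []
        seqadv = None
        decoys = kind == "SINGLE"

        def out_positions(n, exclude=()):
            return _pick_positions(rng, L, n, exclude=set(site) | set(exclude))

        if kind == "SINGLE":
            targets = [TargetBlueprint(acc(7), assays=[
                AssayBlueprint("A%s_1" % sid, "exact", n_values=2, planted_level=5),
                AssayBlueprint("A%s_2" % sid, "enantiomer", planted_level=3),
                AssayBlueprint("A%s_3" % sid, "tautomer", planted_level=1),
                AssayBlueprint("A%s_4" % sid, "unrelated", planted_level=0),
            ])]
        elif kind == "DUMMY":
            targets = [TargetBlueprint(DUMMY_TARGET, assays=[
                AssayBlueprint("A%s_1" % sid)])]
        elif kind == "SEQUENCE":
            muts = [(p, _mutate_letter(rng, seq[p])) for p in out_positions(4)]
            targets = [
                TargetBlueprint(acc(5), assays=[AssayBlueprint("A%s_1" % sid)]),
                TargetBlueprint(acc(2), component_mutations=muts,
                                assays=[AssayBlueprint("A%s_2" % sid)]),
            ]
        elif kind == "MOLECULE":
            targets = [
                TargetBlueprint(acc(5), assays=[AssayBlueprint("A%s_1" % sid)]),
                TargetBlueprint(acc(2), assays=[
                    AssayBlueprint("A%s_2" % sid, "enantiomer", planted_level=3)]),
            ]
        elif kind == "MUTATIONS":
            p_out = out_positions(1)[0]
            p_in = site[int(rng.integers(0, len(site)))]
            targets = [
                TargetBlueprint(acc(5), component_mutations=[(p_out, _mutate_letter(rng, seq[p_out]))],
                                assays=[AssayBlueprint("A%s_1" % sid)]),
                TargetBlueprint(acc(2), component_mutations=[(p_in, _mutate_letter(rng, seq[p_in]))],
                                assays=[AssayBlueprint("A%s_2" % sid)]),
            ]
        elif kind == "TARGET_TYPE":
            targets = [
                TargetBlueprint(acc(5), assays=[AssayBlueprint("A%s_1" % sid)]),
                TargetBlueprint(acc(2), target_type="PROTEIN FAMILY",
                                assays=[AssayBlueprint("A%s_2" % sid)]),
                TargetBlueprint(acc(3), target_type="CHIMERIC PROTEIN",
                                assays=[AssayBlueprint("A%s_3" % sid)]),
            ]
        elif kind == "DATAPOINTS":
            targets = [
                TargetBlueprint(acc(5), assays=[AssayBlueprint("A%s_1" % sid, n_values=3)]),
                TargetBlueprint(acc(2), assays=[AssayBlueprint("A%s_2" % sid)]),
            ]
        elif kind == "TIEBREAK":
            targets = [
                TargetBlueprint(acc(2), assays=[AssayBlueprint("A%s_1" % sid)]),
                TargetBlueprint(acc(5), assays=[AssayBlueprint("A%s_2" % sid)]),
            ]
        elif kind == "SEQADV":
            p = out_positions(1)[0]
            seqadv = (p, _mutate_letter(rng, seq[p]))
            targets = [
                TargetBlueprint(acc(5), assays=[AssayBlueprint("A%s_1" % sid)]),
                TargetBlueprint(acc(2), via_seqadv=True,
                                assays=[AssayBlueprint("A%s_2" % sid)]),
            ]
        elif kind in ("VARIANT_MATCH", "VARIANT_UNDEF"):
            p_in = site[int(rng.integers(0, len(site)))]
            variant = "match" if kind == "VARIANT_MATCH" else "undefined"
            targets = [
                TargetBlueprint(acc(5), component_mutations=[(p_in, _mutate_letter(rng, seq[p_in]))],
                                assays=[AssayBlueprint("A%s_1" % sid, variant=variant)]),
            ]

        structures.append(StructureBlueprint(
            structure_id=sid,
            kind=kind,
            chain_length=L,
            sequence=seq,
            ligand=lig,
            site_positions=site,
            targets=targets,
            seqadv=seqadv,
            with_decoys=decoys,
            resolution=round(float(rng.uniform(1.2, 3.2)), 2),
            deposition=date(2000 + int(rng.integers(0, 20)), 1 + int(rng.integers(0, 12)), 15),
        ))
    return ScenarioSpec(
        seed=seed,
        n_structures=n_structures,
        chain_length_range=chain_length_range,
        structures=structures,
    )


def generate_scenario_files(spec: ScenarioSpec, out_dir) -> TruthBundle:
    """Emit PDB files, the activity TSV and the truth JSON to ``out_dir``."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = TruthBundle()
    for i, bp in enumerate(spec.structures):
        pdb_text, struct_truth = generate_structure(spec, i)
        (out / f"{bp.structure_id}.pdb").write_text(pdb_text)
        bundle.structures[bp.structure_id] = struct_truth
    activities, act_truths = generate_bioactivities(spec)
    activities.to_csv(out / "activities.tsv", sep="\t", index=False)
    for sid, t in act_truths.items():
        base = bundle.structures[sid]
        base.candidates = t.candidates
        base.assay_levels = t.assay_levels
        base.assay_rows = t.assay_rows
        base.winner_binding, base.decided_binding = t.winner_binding, t.decided_binding
        base.winner_target, base.decided_target = t.winner_target, t.decided_target
    (out / "truth.json").write_text(bundle.to_json())
    return bundle


def generate_scenario(seed: int, n_structures: int = len(SCENARIO_KINDS)):
    """Convenience: (spec, pdb_texts, activities, truth) fully in memory."""
    spec = random_scenario(seed, n_structures)
    bundle = TruthBundle()
    texts = []
    for i, bp in enumerate(spec.structures):
        text, truth = generate_structure(spec, i)
        texts.append(text)
        bundle.structures[bp.structure_id] = truth
    activities, act_truths = generate_bioactivities(spec)
    for sid, t in act_truths.items():
        base = bundle.structures[sid]
        base.candidates = t.candidates
        base.assay_levels = t.assay_levels
        base.assay_rows = t.assay_rows
        base.winner_binding, base.decided_binding = t.winner_binding, t.decided_binding
        base.winner_target, base.decided_target = t.winner_target, t.decided_target
    return spec, texts, activities, bundle
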