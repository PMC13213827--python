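"""Structure parsing, ligand discovery and binding-site computation.

Protein–ligand complexes arrive as PDB-format text.  Coordinates, polymer
sequences, covalent LINK annotations and the resolution header are read
through :mod:`gemmi`; a small supplementary scan recovers the header records
gemmi does not surface from PDB text (EXPDTA, REMARK 3 R-factors, SEQADV,
and REMARK 470/600 ligand-peculiarity notes).

Every non-water hetero-group is reported as a candidate ligand.  Problems
are never fatal: consistency issues (annotated missing atoms, covalent
attachment to the polymer, unsupported elements, formula disagreement,
polymer-residue codes) are encoded as :class:`SkipReason` flags so that a
downstream user can make an informed, automated keep/drop decision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "SkipReason",
    "Atom",
    "ResidueRecord",
    "ChainRecord",
    "HetGroup",
    "LigandInstance",
    "SeqadvEntry",
    "LinkRecord",
    "BindingSite",
    "StructureRecord",
    "StructureFormatError",
    "EmptyStructureError",
    "DegenerateLigandError",
    "parse_structure",
    "extract_ligands",
    "find_binding_site",
    "read_formula_table",
    "write_ligand_inventory",
    "DEFAULT_SITE_CUTOFF",
]

#: Default binding-site cutoff radius in Å (a 6.5 Å-diameter sphere around
#: each ligand heavy atom).
DEFAULT_SITE_CUTOFF = 3.25

#: Elements the small-molecule chemistry model supports; anything else
#: (metals in particular) flags the ligand as UNSUPPORTED_ELEMENT.
SUPPORTED_ELEMENTS = frozenset(
    {"H", "D", "C", "N", "O", "P", "S", "F", "CL", "BR", "I", "B", "SE"}
)

WATER_CODES = frozenset({"HOH", "DOD", "WAT"})

STANDARD_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_NUCLEOTIDES = frozenset(
    {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}
)
POLYMER_CODES = frozenset(STANDARD_AA3) | STANDARD_NUCLEOTIDES


class StructureFormatError(ValueError):
    """The input text is not parseable as a PDB structure."""


class EmptyStructureError(ValueError):
    """The structure contains no polymer chain."""


class DegenerateLigandError(ValueError):
    """The ligand has no heavy atoms to define a binding site with."""


class SkipReason(Enum):
    """Consistency flags attached to extracted ligands (never fatal)."""

    MISSING_ATOMS_ANNOTATED = "header remarks annotate missing atoms for this ligand"
    COVALENT_LINK = "LINK record covalently joins a ligand atom to a polymer atom"
    UNSUPPORTED_ELEMENT = "ligand contains an element outside the supported organic set"
    FORMULA_MISMATCH = "observed element counts disagree with the reference formula"
    METADATA_PECULIARITY = "header remarks annotate a peculiarity for this ligand"
    POLYMER_LIGAND = "hetero-group uses a standard amino-acid or nucleotide code"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str  # upper-case element symbol
    x: float
    y: float
    z: float


@dataclass
class ResidueRecord:
    name: str
    number: int
    atoms: list[Atom]


@dataclass
class ChainRecord:
    """One polymer chain: ordered residues plus its one-letter sequence.

    ``one_letter_sequence`` comes from SEQRES when present (the full
    construct), otherwise from the modeled ATOM residues; the ATOM-derived
    sequence is kept alongside because binding-site positions index the
    modeled residues.
    """

    chain_id: str
    residues: list[ResidueRecord]
    one_letter_sequence: str
    atom_sequence: str

    def position_of(self, residue_number: int) -> int:
        """Index of a residue (by author numbering) into the modeled sequence."""
        for i, res in enumerate(self.residues):
            if res.number == residue_number:
                return i
        raise KeyError(f"residue {residue_number} not in chain {self.chain_id}")


@dataclass
class HetGroup:
    het_code: str
    chain_id: str
    residue_number: int
    atoms: list[Atom]


@dataclass(frozen=True)
class SeqadvEntry:
    chain_id: str
    residue_number: int
    modeled_residue: str
    reference_residue: str
    comment: str


@dataclass(frozen=True)
class LinkRecord:
    atom1: str
    res1: str
    chain1: str
    num1: int
    atom2: str
    res2: str
    chain2: str
    num2: int


@dataclass
class LigandInstance:
    structure_id: str
    het_code: str
    chain_id: str
    residue_number: int
    heavy_atom_coordinates: list[Atom]
    heavy_atom_count: int
    molecular_weight: float
    skip_reasons: set[SkipReason] = field(default_factory=set)
    covalent: bool = False

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.structure_id, self.het_code, self.chain_id, self.residue_number)


@dataclass
class BindingSite:
    ligand_ref: tuple[str, str, str, int]
    cutoff: float
    residues: set[tuple[str, int]]
    sequence_positions: dict[str, set[int]]


@dataclass
class StructureRecord:
    structure_id: str
    chains: list[ChainRecord]
    het_groups: list[HetGroup]
    seqadv_entries: list[SeqadvEntry]
    resolution: float | None
    r_factor: float | None
    r_free: float | None
    experimental_method: str | None
    deposition_date: date | None
    link_records: list[LinkRecord]
    metadata_peculiarities: list[tuple[str, str]]

    def chain(self, chain_id: str) -> ChainRecord:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id} in {self.structure_id}")


# --- header records gemmi does not expose from PDB text -------------------

_RE_RVALUE = re.compile(r"REMARK   3\s+R VALUE\s+\(WORKING SET\)\s*:\s*([0-9.]+)")
_RE_RFREE = re.compile(r"REMARK   3\s+FREE R VALUE\s+:\s*([0-9.]+)")


def _scan_header(lines: Sequence[str]):
    r_factor = r_free = None
    method = None
    seqadv: list[SeqadvEntry] = []
    peculiarities: list[tuple[str, str]] = []
    for ln in lines:
        rec = ln[:6].strip()
        if rec == "EXPDTA":
            method = ln[10:].strip() or None
        elif rec == "REMARK":
            m = _RE_RVALUE.match(ln)
            if m:
                r_factor = float(m.group(1))
                continue
            m = _RE_RFREE.match(ln)
            if m:
                r_free = float(m.group(1))
                continue
            remark_no = ln[7:10].strip()
            if remark_no in {"470", "475", "600", "610", "615"}:
                body = ln[11:].strip()
                fields = body.split()
                if fields and 1 <= len(fields[0]) <= 3 and fields[0].isalnum() \
                        and fields[0].upper() not in {"RES", "M", "MISSING", "ZERO", "HETEROGEN"}:
                    issue = "missing atoms" if remark_no in {"470", "475"} else body
                    peculiarities.append((fields[0].upper(), issue))
        elif rec == "SEQADV":
            # columns: idCode, resName, chain, seqNum, database, dbAccession,
            # dbRes, dbSeq, conflict comment
            try:
                seqadv.append(
                    SeqadvEntry(
                        chain_id=ln[16].strip(),
                        residue_number=int(ln[18:22]),
                        modeled_residue=ln[12:15].strip(),
                        reference_residue=ln[39:42].strip(),
                        comment=ln[49:].strip(),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise StructureFormatError(f"malformed SEQADV line: {ln!r}") from exc
    return r_factor, r_free, method, seqadv, peculiarities


def _one_letter(residue_names: Iterable[str]) -> str:
    return "".join(STANDARD_AA3.get(name, "X") for name in residue_names)


_KNOWN_RECORDS = {
    "HEADER", "TITLE", "COMPND", "SOURCE", "KEYWDS", "EXPDTA", "AUTHOR",
    "REVDAT", "JRNL", "REMARK", "DBREF", "SEQADV", "SEQRES", "MODRES",
    "HET", "HETNAM", "HETSYN", "FORMUL", "HELIX", "SHEET", "SSBOND",
    "LINK", "CISPEP", "SITE", "CRYST1", "ORIGX1", "ORIGX2", "ORIGX3",
    "SCALE1", "SCALE2", "SCALE3", "MTRIX1", "MTRIX2", "MTRIX3", "MODEL",
    "ATOM", "ANISOU", "TER", "HETATM", "ENDMDL", "CONECT", "MASTER", "END",
    "OBSLTE", "SPLIT", "CAVEAT", "NUMMDL", "SPRSDE", "SEQADV", "SIGATM",
    "SIGUIJ", "DBREF1", "DBREF2",
}


def parse_structure(pdb_text: str) -> StructureRecord:
    """Parse PDB-format text into a :class:`StructureRecord`.

    Chain sequences come from SEQRES when present, otherwise from the ATOM
    records.  All non-water hetero-groups are collected.  Only the first
    model of a multi-model file is used.
    """
    if not pdb_text.strip():
        raise StructureFormatError("empty input")

    lines = pdb_text.splitlines()
    for ln in lines:
        if ln.strip() and ln[:6].strip() not in _KNOWN_RECORDS:
            raise StructureFormatError(f"unrecognized record: {ln!r}")

    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(str(exc)) from exc
    st.setup_entities()

    r_factor, r_free, method, seqadv, peculiarities = _scan_header(lines)

    seqres_by_chain: dict[str, list[str]] = {}
    for ent in st.entities:
        if ent.entity_type == gemmi.EntityType.Polymer and ent.full_sequence:
            for sub in ent.subchains:
                seqres_by_chain[sub] = [
                    gemmi.Entity.first_mon(m) for m in ent.full_sequence
                ]

    chains: list[ChainRecord] = []
    het_groups: list[HetGroup] = []
    if len(st) == 0:
        raise EmptyStructureError("structure contains no model")
    model = st[0]
    for ch in model:
        residues: list[ResidueRecord] = []
        for res in ch:
            name = res.name.upper()
            atoms = [
                Atom(a.name, a.element.name.upper(), a.pos.x, a.pos.y, a.pos.z)
                for a in res
            ]
            if name in WATER_CODES:
                continue
            if res.het_flag == "H":
                het_groups.append(HetGroup(name, ch.name, res.seqid.num, atoms))
            else:
                residues.append(ResidueRecord(name, res.seqid.num, atoms))
        if residues:
            atom_seq = _one_letter(r.name for r in residues)
            seqres_names = None
            for res in ch:
                if res.het_flag != "H" and res.subchain in seqres_by_chain:
                    seqres_names = seqres_by_chain[res.subchain]
                    break
            seq = _one_letter(seqres_names) if seqres_names else atom_seq
            chains.append(ChainRecord(ch.name, residues, seq, atom_seq))

    if not chains:
        raise EmptyStructureError("structure contains no polymer chain")

    link_records = []
    for con in st.connections:
        p1, p2 = con.partner1, con.partner2
        link_records.append(
            LinkRecord(
                p1.atom_name, p1.res_id.name.upper(), p1.chain_name, p1.res_id.seqid.num,
                p2.atom_name, p2.res_id.name.upper(), p2.chain_name, p2.res_id.seqid.num,
            )
        )

    info = dict(st.info)
    dep = info.get("_pdbx_database_status.recvd_initial_deposition_date")
    deposition = date.fromisoformat(dep) if dep else None
    resolution = st.resolution if st.resolution and st.resolution > 0 else None

    return StructureRecord(
        structure_id=(info.get("_entry.id") or st.name or "XXXX").strip(),
        chains=chains,
        het_groups=het_groups,
        seqadv_entries=seqadv,
        resolution=resolution,
        r_factor=r_factor,
        r_free=r_free,
        experimental_method=method,
        deposition_date=deposition,
        link_records=link_records,
        metadata_peculiarities=peculiarities,
    )


# --- ligand extraction -----------------------------------------------------

_RE_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula(formula: str) -> dict[str, int]:
    """Element counts from a Hill-style formula, spaced or compact."""
    counts: dict[str, int] = {}
    for token in formula.replace("+", " ").replace("-", " ").split():
        for sym, num in _RE_FORMULA_TOKEN.findall(token):
            if not sym:
                continue
            counts[sym.upper()] = counts.get(sym.upper(), 0) + (int(num) if num else 1)
    return counts


def _is_polymer_atom(s: StructureRecord, chain_id: str, residue_number: int, resname: str) -> bool:
    for ch in s.chains:
        if ch.chain_id != chain_id:
            continue
        for res in ch.residues:
            if res.number == residue_number and res.name == resname:
                return True
    return False


def extract_ligands(
    s: StructureRecord,
    reference_formulas: Mapping[str, str] | None = None,
) -> list[LigandInstance]:
    """One :class:`LigandInstance` per non-water hetero-group.

    Descriptors (heavy-atom count, molecular weight) are computed from the
    atoms actually present in the file.  All ligands are reported; problems
    are encoded as skip reasons.
    """
    ligands: list[LigandInstance] = []
    for grp in s.het_groups:
        heavy = [a for a in grp.atoms if a.element not in {"H", "D"}]
        mw = sum(gemmi.Element(a.element).weight for a in grp.atoms)
        reasons: set[SkipReason] = set()
        covalent = False

        for het_code, issue in s.metadata_peculiarities:
            if het_code == grp.het_code:
                if "missing atom" in issue.lower():
                    reasons.add(SkipReason.MISSING_ATOMS_ANNOTATED)
                else:
                    reasons.add(SkipReason.METADATA_PECULIARITY)

        lig_key = (grp.het_code, grp.chain_id, grp.residue_number)
        for lk in s.link_records:
            ends = [
                (lk.res1, lk.chain1, lk.num1, lk.res2, lk.chain2, lk.num2),
                (lk.res2, lk.chain2, lk.num2, lk.res1, lk.chain1, lk.num1),
            ]
            for (res_a, ch_a, num_a, res_b, ch_b, num_b) in ends:
                if (res_a, ch_a, num_a) == lig_key and _is_polymer_atom(s, ch_b, num_b, res_b):
                    covalent = True
                    reasons.add(SkipReason.COVALENT_LINK)

        if any(a.element not in SUPPORTED_ELEMENTS for a in grp.atoms):
            reasons.add(SkipReason.UNSUPPORTED_ELEMENT)

        if reference_formulas and grp.het_code in reference_formulas:
            ref = _parse_formula(reference_formulas[grp.het_code])
            ref.pop("H", None)  # hydrogens are routinely unmodeled
            obs: dict[str, int] = {}
            for a in heavy:
                obs[a.element.capitalize().upper()] = obs.get(a.element.capitalize().upper(), 0) + 1
            ref_norm = {k.upper(): v for k, v in ref.items()}
            if obs != ref_norm:
                reasons.add(SkipReason.FORMULA_MISMATCH)

        if grp.het_code in POLYMER_CODES:
            reasons.add(SkipReason.POLYMER_LIGAND)

        ligands.append(
            LigandInstance(
                structure_id=s.structure_id,
                het_code=grp.het_code,
                chain_id=grp.chain_id,
                residue_number=grp.residue_number,
                heavy_atom_coordinates=heavy,
                heavy_atom_count=len(heavy),
                molecular_weight=mw,
                skip_reasons=reasons,
                covalent=covalent,
            )
        )
    return ligands


def find_binding_site(
    s: StructureRecord,
    lig: LigandInstance,
    cutoff: float = DEFAULT_SITE_CUTOFF,
) -> BindingSite:
    """Polymer residues with any atom within ``cutoff`` Å of any ligand heavy atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not lig.heavy_atom_coordinates:
        raise DegenerateLigandError(
            f"ligand {lig.het_code} {lig.chain_id}{lig.residue_number} has no heavy atoms"
        )
    lig_xyz = np.array([[a.x, a.y, a.z] for a in lig.heavy_atom_coordinates])
    residues: set[tuple[str, int]] = set()
    positions: dict[str, set[int]] = {}
    for ch in s.chains:
        for idx, res in enumerate(ch.residues):
            res_xyz = np.array([[a.x, a.y, a.z] for a in res.atoms])
            d2 = ((res_xyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(axis=2)
            if d2.min() <= cutoff * cutoff:
                residues.add((ch.chain_id, res.number))
                positions.setdefault(ch.chain_id, set()).add(idx)
    return BindingSite(
        ligand_ref=(s.structure_id, lig.het_code, lig.chain_id, lig.residue_number),
        cutoff=cutoff,
        residues=residues,
        sequence_positions=positions,
    )


# --- tabular I/O ------------------------------------------------------------

def read_formula_table(path) -> dict[str, str]:
    """Two-column TSV (het_code, formula) → mapping."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            code, formula = ln.split("\t")[:2]
            table[code.strip().upper()] = formula.strip()
    return table


def write_ligand_inventory(ligands: Iterable[LigandInstance], path) -> None:
    header = "structure_id\thet_code\tchain\tresidue_number\theavy_atoms\tmol_weight\tcovalent\tskip_reasons\n"
    with open(path, "w") as fh:
        fh.write(header)
        for lig in ligands:
            reasons = ";".join(sorted(r.name for r in lig.skip_reasons))
            fh.write(
                f"{lig.structure_id}\t{lig.het_code}\t{lig.chain_id}\t{lig.residue_number}\t"
                f"{lig.heavy_atom_count}\t{lig.molecular_weight:.3f}\t{lig.covalent}\t{reasons}\n"
            )
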