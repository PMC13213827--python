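"""Small-molecule canonicalization and five-level match grading.

Structure-derived and registry-derived representations of the same compound
rarely agree verbatim, so correspondence is graded on a five-level scale:

    5  identical standard InChIKey            (identical molecules)
    4  identical canonical SMILES with stereo (identical molecules)
    3  identical canonical SMILES, stereo stripped (stereo-distinct)
    2  identical InChI truncated after the hydrogen layer
    1  identical InChI truncated after the atom-connection layer
    0  no correspondence

Levels 1–2 capture "potentially identical" molecules — tautomers and
protomers share connectivity but differ in the hydrogen layer.  The level
reported is always the HIGHEST criterion satisfied.

Canonicalization is delegated to RDKit (standard InChI, InChIKey,
canonical isomeric/achiral SMILES); for salts and mixtures the largest
covalently connected component is used.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeForms",
    "MatchLevel",
    "SanitizationError",
    "InchiFormatError",
    "mol_from_smiles",
    "mol_from_inchi",
    "compute_forms",
    "truncate_inchi",
    "match_level",
    "write_match_table",
]


class SanitizationError(ValueError):
    """Chemically invalid input (valence violation etc.)."""


class InchiFormatError(ValueError):
    """String does not start with the standard InChI prefix."""


class MatchLevel(enum.IntEnum):
    NONE = 0
    CONNECTION_LAYER = 1
    HYDROGEN_LAYER = 2
    ACHIRAL_SMILES = 3
    CHIRAL_SMILES = 4
    INCHI_KEY = 5


@dataclass(frozen=True)
class MoleculeForms:
    """All canonical representations used for matching, for one molecule."""

    inchi: str
    inchi_key: str
    smiles_chiral: str
    smiles_achiral: str
    inchi_trunc_h: str
    inchi_trunc_c: str


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    return max(frags, key=lambda f: f.GetNumHeavyAtoms())


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SanitizationError(f"unparseable SMILES: {smiles!r}")
    return _sanitize(mol)


def mol_from_inchi(inchi: str) -> Chem.Mol:
    if not inchi.startswith("InChI="):
        raise InchiFormatError(f"not an InChI: {inchi!r}")
    mol = Chem.MolFromInchi(inchi, sanitize=False, treatWarningAsError=False)
    if mol is None:
        raise SanitizationError(f"unparseable InChI: {inchi!r}")
    return _sanitize(mol)


def _sanitize(mol: Chem.Mol) -> Chem.Mol:
    try:
        Chem.SanitizeMol(mol)
    except Chem.AtomValenceException as exc:
        idx = getattr(exc, "cause", None)
        atom_idx = idx.GetAtomIdx() if idx is not None else -1
        raise SanitizationError(f"valence violation at atom {atom_idx}") from exc
    except Exception as exc:  # kekulization and friends
        raise SanitizationError(str(exc)) from exc
    return mol


def compute_forms(mol: Chem.Mol | str) -> MoleculeForms:
    """Canonical forms of a molecule (SMILES string or RDKit Mol).

    Pure function of the molecular graph: independent of atom ordering.
    Salts/mixtures are reduced to the largest covalent component first;
    charges are preserved.
    """
    if isinstance(mol, str):
        mol = mol_from_smiles(mol)
    if mol.GetNumHeavyAtoms() == 0:
        raise SanitizationError("molecule has no heavy atoms")
    mol = _largest_fragment(mol)
    inchi = Chem.MolToInchi(mol)
    if not inchi:
        raise SanitizationError("InChI generation failed")
    key = Chem.InchiToInchiKey(inchi)
    smiles_chiral = Chem.MolToSmiles(mol)
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    smiles_achiral = Chem.MolToSmiles(flat)
    return MoleculeForms(
        inchi=inchi,
        inchi_key=key,
        smiles_chiral=smiles_chiral,
        smiles_achiral=smiles_achiral,
        inchi_trunc_h=truncate_inchi(inchi, "hydrogen"),
        inchi_trunc_c=truncate_inchi(inchi, "connection"),
    )


def truncate_inchi(inchi: str, cut_after: str) -> str:
    """Prefix of a standard InChI up to and including the named layer.

    ``cut_after`` is one of ``formula``, ``connection``, ``hydrogen``.
    A missing layer truncates at the last earlier layer that is present,
    so e.g. methane (no /c layer) keeps only the formula.
    """
    if not inchi.startswith("InChI="):
        raise InchiFormatError(f"not an InChI: {inchi!r}")
    if cut_after not in {"formula", "connection", "hydrogen"}:
        raise ValueError(f"unknown layer {cut_after!r}")
    parts = inchi.split("/")
    # parts[0] = "InChI=1S", parts[1] = formula, then lettered layers
    kept = parts[:2]
    if cut_after != "formula":
        stop_letters = {"c"} if cut_after == "connection" else {"c", "h"}
        for layer in parts[2:]:
            if layer and layer[0] in stop_letters:
                kept.append(layer)
            else:
                break
    return "/".join(kept)


def match_level(a: MoleculeForms, b: MoleculeForms) -> MatchLevel:
    """Highest-level correspondence between two canonicalized molecules."""
    if a.inchi_key == b.inchi_key:
        return MatchLevel.INCHI_KEY
    if a.smiles_chiral == b.smiles_chiral:
        return MatchLevel.CHIRAL_SMILES
    if a.smiles_achiral == b.smiles_achiral:
        return MatchLevel.ACHIRAL_SMILES
    if a.inchi_trunc_h == b.inchi_trunc_h:
        return MatchLevel.HYDROGEN_LAYER
    if a.inchi_trunc_c == b.inchi_trunc_c:
        return MatchLevel.CONNECTION_LAYER
    return MatchLevel.NONE


_MATCHED_REPR = {
    MatchLevel.INCHI_KEY: "inchi_key",
    MatchLevel.CHIRAL_SMILES: "smiles_chiral",
    MatchLevel.ACHIRAL_SMILES: "smiles_achiral",
    MatchLevel.HYDROGEN_LAYER: "inchi_trunc_h",
    MatchLevel.CONNECTION_LAYER: "inchi_trunc_c",
    MatchLevel.NONE: "",
}


def write_match_table(pairs, path) -> None:
    """``pairs``: iterable of (id_a, id_b, MatchLevel); writes a TSV."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tlevel\tmatched_representation\n")
        for id_a, id_b, level in pairs:
            fh.write(f"{id_a}\t{id_b}\t{int(level)}\t{_MATCHED_REPR[MatchLevel(level)]}\n")


def molecular_weight(smiles: str) -> float:
    return Descriptors.MolWt(mol_from_smiles(smiles))
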