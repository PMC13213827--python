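"""End-to-end orchestration: structures + bioactivity table -> linked tables.

The flow mirrors the five-step generation workflow: (1) per-structure
ligand extraction and header profiling, (2) sequence matching of every
structure chain against every target's component sequence — or an assay's
variant sequence where one exists — plus, for chains with SEQADV entries,
against the SEQADV-reverted chain (such matches are flagged and discarded
in filtering, since the header mutations are absent from the model),
(3) molecule matching between the ligand's reference structure and each
assay molecule, (4) the best-target cascade in both modes, and (5) full
outer joins into the four table variants.

A link requires at least 80% sequence identity; because the internal
Smith-Waterman has no e-value machinery, a minimum query coverage stands
in for search-tool significance and suppresses spurious short local hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import tables
from .cascade import (
    CascadeAudit,
    CascadeMode,
    TargetCandidate,
    run_cascade,
    select_best_alignment,
)
from .molecules import MatchLevel, MoleculeForms, SanitizationError, compute_forms, match_level
from .seqmatch import (
    AlignmentResult,
    align,
    count_site_mutations,
    resolve_assay_sequence,
    score_match,
)
from .structures import (
    DEFAULT_SITE_CUTOFF,
    LigandInstance,
    StructureRecord,
    extract_ligands,
    find_binding_site,
    parse_structure,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "LinkedData", "run_pipeline", "load_activity_table"]


@dataclass
class PipelineConfig:
    site_cutoff: float = DEFAULT_SITE_CUTOFF
    identity_floor: float = 80.0
    #: significance proxy for the internal aligner: minimum % of query
    #: residues that must be aligned for a match to count as a link
    min_query_coverage: float = 50.0
    #: binding mode aligns only chains contributing binding-site residues
    restrict_to_site_chains: bool = True
    reference_formulas: Mapping[str, str] | None = None


@dataclass
class LinkedData:
    """All per-tool outputs plus cascade results for one pipeline run."""

    ligand_table: pd.DataFrame
    structure_table: pd.DataFrame
    activity_binding: pd.DataFrame
    activity_target: pd.DataFrame
    binding_candidates: dict[tuple[str, str], list[TargetCandidate]]
    target_candidates: dict[str, list[TargetCandidate]]
    binding_results: dict[tuple[str, str], tuple[str | None, CascadeAudit]] = field(
        default_factory=dict
    )
    target_results: dict[str, tuple[str | None, CascadeAudit]] = field(default_factory=dict)

    def binding_winners(self) -> dict[tuple, str]:
        return {
            k: w.target_accession
            for k, (w, _) in self.binding_results.items()
            if w is not None
        }

    def target_winners(self) -> dict[tuple, str]:
        return {
            (k,): w.target_accession
            for k, (w, _) in self.target_results.items()
            if w is not None
        }

    def variant(self, variant: tables.TableVariant) -> pd.DataFrame:
        """Assemble one of the four linked-table variants."""
        act = self.activity_binding if variant.binding_mode else self.activity_target
        merged = tables.merge_outputs(self.ligand_table, self.structure_table, act)
        results = self.binding_winners() if variant.binding_mode else self.target_winners()
        return tables.build_variant(merged, variant, results)


def load_activity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"assay_id": str}, keep_default_na=False,
                     na_values=[""])
    missing = {"assay_id", "target_accession", "component_sequence", "smiles"} - set(df.columns)
    if missing:
        raise ValueError(f"activity table lacks required columns: {sorted(missing)}")
    return df


def _seqadv_reverted(structure: StructureRecord, chain) -> str | None:
    """Chain sequence with SEQADV reference residues restored, if any apply."""
    from .structures import STANDARD_AA3

    entries = [e for e in structure.seqadv_entries if e.chain_id == chain.chain_id]
    if not entries:
        return None
    seq = list(chain.atom_sequence)
    changed = False
    for e in entries:
        try:
            pos = chain.position_of(e.residue_number)
        except KeyError:
            continue
        ref1 = STANDARD_AA3.get(e.reference_residue, "X")
        if seq[pos] != ref1:
            seq[pos] = ref1
            changed = True
    return "".join(seq) if changed else None


@dataclass
class _Route:
    chain_id: str
    query: str
    from_seqadv: bool


def _chain_routes(structure: StructureRecord, chain_ids=None) -> list[_Route]:
    routes = []
    for ch in structure.chains:
        if chain_ids is not None and ch.chain_id not in chain_ids:
            continue
        routes.append(_Route(ch.chain_id, ch.atom_sequence, False))
        reverted = _seqadv_reverted(structure, ch)
        if reverted:
            routes.append(_Route(ch.chain_id, reverted, True))
    return routes


class _AlignCache:
    """Alignments keyed by (query, hit) text; sequences repeat heavily."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self._store: dict[tuple[str, str], AlignmentResult] = {}

    def get(self, query: str, hit: str, query_id: str, hit_id: str) -> AlignmentResult:
        key = (query, hit)
        if key not in self._store:
            self._store[key] = align(query, hit, query_id=query_id, hit_id=hit_id)
        return self._store[key]

    def qualifying(self, query: str, hit: str, query_id: str, hit_id: str):
        a = self.get(query, hit, query_id, hit_id)
        if a.identity < self.config.identity_floor:
            return None
        if a.coverage_query < self.config.min_query_coverage:
            return None
        return a


def _clone_with_flag(a: AlignmentResult, from_seqadv: bool) -> AlignmentResult:
    import copy

    if a.from_seqadv == from_seqadv:
        return a
    b = copy.copy(a)
    b.from_seqadv = from_seqadv
    return b


def _forms_or_none(smiles: str, cache: dict) -> MoleculeForms | None:
    if smiles in cache:
        return cache[smiles]
    try:
        forms = compute_forms(smiles)
    except (SanitizationError, ValueError):
        logger.warning("cannot canonicalize molecule %r", smiles)
        forms = None
    cache[smiles] = forms
    return forms


def run_pipeline(
    pdb_texts: list[str],
    activities: pd.DataFrame,
    het_smiles: Mapping[str, str],
    config: PipelineConfig | None = None,
    density: pd.DataFrame | None = None,
) -> LinkedData:
    """Run the full linking workflow on in-memory inputs.

    ``het_smiles`` is the chemical-component dictionary mapping each het
    code to its reference SMILES; ligands without an entry (or that fail
    canonicalization) keep their inventory row but cannot link bioactivity.
    ``density`` optionally carries a per-structure ``density_support``
    column that is passed through unchanged.
    """
    config = config or PipelineConfig()
    structures = [parse_structure(t) for t in pdb_texts]

    mol_cache: dict[str, MoleculeForms | None] = {}
    het_forms = {code: _forms_or_none(smi, mol_cache) for code, smi in het_smiles.items()}

    ligand_rows, structure_rows = [], []
    ligands_by_structure: dict[str, list[LigandInstance]] = {}
    for s in structures:
        ligs = extract_ligands(s, config.reference_formulas)
        ligands_by_structure[s.structure_id] = ligs
        for lig in ligs:
            ligand_rows.append({
                "structure_id": s.structure_id,
                "het_code": lig.het_code,
                "chain_id": lig.chain_id,
                "residue_number": lig.residue_number,
                "heavy_atoms": lig.heavy_atom_count,
                "mol_weight": round(lig.molecular_weight, 3),
                "covalent": lig.covalent,
                "skip_reasons": ";".join(sorted(r.name for r in lig.skip_reasons)),
            })
        structure_rows.append({
            "structure_id": s.structure_id,
            "resolution": s.resolution,
            "r_factor": s.r_factor,
            "r_free": s.r_free,
            "method": s.experimental_method,
            "deposition_date": s.deposition_date.isoformat() if s.deposition_date else None,
        })

    ligand_table = pd.DataFrame(ligand_rows, columns=[
        "structure_id", "het_code", "chain_id", "residue_number", "heavy_atoms",
        "mol_weight", "covalent", "skip_reasons",
    ])
    structure_table = pd.DataFrame(structure_rows, columns=[
        "structure_id", "resolution", "r_factor", "r_free", "method", "deposition_date",
    ])
    if density is not None and "density_support" in density.columns:
        structure_table = structure_table.merge(
            density[["structure_id", "density_support"]], on="structure_id", how="left"
        )

    targets = _target_index(activities)
    cache = _AlignCache(config)

    binding_rows, binding_candidates = _binding_mode(
        structures, ligands_by_structure, targets, het_forms, mol_cache, cache, config
    )
    target_rows, target_candidates = _target_mode(structures, targets, cache)

    data = LinkedData(
        ligand_table=ligand_table,
        structure_table=structure_table,
        activity_binding=pd.DataFrame(binding_rows, columns=_BINDING_COLUMNS),
        activity_target=pd.DataFrame(target_rows, columns=_TARGET_COLUMNS),
        binding_candidates=binding_candidates,
        target_candidates=target_candidates,
    )
    for key, cands in binding_candidates.items():
        data.binding_results[key] = run_cascade(cands, CascadeMode.BINDING)
    for sid, cands in target_candidates.items():
        data.target_results[sid] = run_cascade(cands, CascadeMode.TARGET)
    return data


_BINDING_COLUMNS = [
    "structure_id", "het_code", "chain_id", "target_accession", "target_type",
    "assay_id", "activity_type", "value", "units", "pchembl", "document_date",
    "data_validity_comment", "identity", "coverage", "cov_id", "d_query",
    "d_hit", "quality", "molecule_level", "n_site_mutations",
    "molecule_inchikey", "variant_used", "from_seqadv", "best_alignment",
]

_TARGET_COLUMNS = [
    "structure_id", "chain_id", "target_accession", "target_type", "assay_id",
    "activity_type", "value", "units", "pchembl", "document_date",
    "data_validity_comment", "identity", "coverage", "cov_id", "d_query",
    "d_hit", "quality", "variant_used", "from_seqadv", "best_alignment",
]


@dataclass
class _Target:
    accession: str
    target_type: str
    component: str
    assays: list  # of (assay_id, variant_sequence|None, rows DataFrame)


def _target_index(activities: pd.DataFrame) -> list[_Target]:
    out = []
    for acc, tgroup in activities.groupby("target_accession", sort=True):
        component = str(tgroup["component_sequence"].iloc[0])
        ttype = str(tgroup.get("target_type", pd.Series(["UNKNOWN"])).iloc[0])
        assays = []
        for aid, agroup in tgroup.groupby("assay_id", sort=True):
            variant = None
            if "variant_sequence" in agroup.columns:
                v = agroup["variant_sequence"].iloc[0]
                if isinstance(v, str) and v.strip():
                    variant = v.strip()
            assays.append((aid, variant, agroup))
        out.append(_Target(acc, ttype, component, assays))
    return out


def _best_route_alignment(routes, eff_seq: str, hit_id: str, cache: _AlignCache):
    """Best qualifying alignment of any chain route against one hit sequence."""
    found = []
    for route in routes:
        a = cache.qualifying(route.query, eff_seq, query_id=route.chain_id, hit_id=hit_id)
        if a is not None:
            found.append((_clone_with_flag(a, route.from_seqadv), route))
    if not found:
        return None, None
    best = select_best_alignment([a for a, _ in found])
    for a, route in found:
        if a is best:
            return a, route
    return None, None


def _binding_mode(structures, ligands_by_structure, targets, het_forms, mol_cache, cache, config):
    rows = []
    candidates: dict[tuple[str, str], list[TargetCandidate]] = {}
    for s in structures:
        for lig in ligands_by_structure[s.structure_id]:
            if not lig.heavy_atom_coordinates:
                continue
            forms = het_forms.get(lig.het_code)
            if forms is None:
                continue
            site = find_binding_site(s, lig, config.site_cutoff)
            if not site.residues:
                continue
            chain_ids = set(site.sequence_positions) if config.restrict_to_site_chains else None
            routes = _chain_routes(s, chain_ids)
            if not routes:
                continue
            case = (s.structure_id, lig.het_code)
            for target in targets:
                cand_alignments = []
                assay_entries = []
                for (aid, variant, agroup) in target.assays:
                    eff = resolve_assay_sequence(variant, target.component)
                    a, route = _best_route_alignment(routes, eff.sequence, target.accession, cache)
                    if a is None:
                        continue
                    level = MatchLevel.NONE
                    for smiles, mgroup in agroup.groupby("smiles", sort=True):
                        mforms = _forms_or_none(str(smiles), mol_cache)
                        if mforms is None:
                            continue
                        lvl = match_level(forms, mforms)
                        if lvl > level:
                            level = lvl
                    if level == MatchLevel.NONE:
                        continue
                    n_mut = count_site_mutations(a, site, route.chain_id)
                    cand_alignments.append(a)
                    assay_entries.append((aid, eff, a, route, level, n_mut, agroup))
                if not assay_entries:
                    continue
                best = select_best_alignment(cand_alignments)
                best_entry = next(e for e in assay_entries if e[2] is best)
                n_points = 0
                for (aid, eff, a, route, level, n_mut, agroup) in assay_entries:
                    n_points += len(
                        agroup[["assay_id", "activity_type", "value", "units"]].drop_duplicates()
                    )
                score_best = score_match(best)
                candidates.setdefault(case, []).append(TargetCandidate(
                    target_accession=target.accession,
                    target_type=target.target_type,
                    best_score=score_best,
                    best_alignment=best,
                    molecule_level=max(e[4] for e in assay_entries),
                    n_site_mutations=best_entry[5],
                    n_unique_datapoints=n_points,
                    from_seqadv=best.from_seqadv,
                ))
                best_cov = round(score_best.cov_id, 6)
                for (aid, eff, a, route, level, n_mut, agroup) in assay_entries:
                    sc = score_match(a)
                    for _, arow in agroup.iterrows():
                        mforms = _forms_or_none(str(arow["smiles"]), mol_cache)
                        if mforms is None or match_level(forms, mforms) == MatchLevel.NONE:
                            continue
                        rows.append({
                            "structure_id": s.structure_id,
                            "het_code": lig.het_code,
                            "chain_id": route.chain_id,
                            "target_accession": target.accession,
                            "target_type": target.target_type,
                            "assay_id": aid,
                            "activity_type": arow.get("activity_type"),
                            "value": arow.get("value"),
                            "units": arow.get("units"),
                            "pchembl": arow.get("pchembl"),
                            "document_date": arow.get("document_date"),
                            "data_validity_comment": arow.get("data_validity_comment"),
                            "identity": a.identity,
                            "coverage": a.coverage_query,
                            "cov_id": sc.cov_id,
                            "d_query": sc.d_query,
                            "d_hit": sc.d_hit,
                            "quality": sc.quality.value,
                            "molecule_level": int(match_level(forms, mforms)),
                            "n_site_mutations": n_mut,
                            "molecule_inchikey": mforms.inchi_key,
                            "variant_used": eff.origin == "VARIANT",
                            "from_seqadv": a.from_seqadv,
                            "best_alignment": round(sc.cov_id, 6) == best_cov,
                        })
    return rows, candidates


def _target_mode(structures, targets, cache):
    rows = []
    candidates: dict[str, list[TargetCandidate]] = {}
    for s in structures:
        routes = _chain_routes(s)
        for target in targets:
            cand_alignments = []
            assay_entries = []
            for (aid, variant, agroup) in target.assays:
                eff = resolve_assay_sequence(variant, target.component)
                a, route = _best_route_alignment(routes, eff.sequence, target.accession, cache)
                if a is None:
                    continue
                cand_alignments.append(a)
                assay_entries.append((aid, eff, a, route, agroup))
            if not assay_entries:
                continue
            best = select_best_alignment(cand_alignments)
            score_best = score_match(best)
            candidates.setdefault(s.structure_id, []).append(TargetCandidate(
                target_accession=target.accession,
                target_type=target.target_type,
                best_score=score_best,
                best_alignment=best,
                from_seqadv=best.from_seqadv,
            ))
            best_cov = round(score_best.cov_id, 6)
            for (aid, eff, a, route, agroup) in assay_entries:
                sc = score_match(a)
                for _, arow in agroup.iterrows():
                    rows.append({
                        "structure_id": s.structure_id,
                        "chain_id": route.chain_id,
                        "target_accession": target.accession,
                        "target_type": target.target_type,
                        "assay_id": aid,
                        "activity_type": arow.get("activity_type"),
                        "value": arow.get("value"),
                        "units": arow.get("units"),
                        "pchembl": arow.get("pchembl"),
                        "document_date": arow.get("document_date"),
                        "data_validity_comment": arow.get("data_validity_comment"),
                        "identity": a.identity,
                        "coverage": a.coverage_query,
                        "cov_id": sc.cov_id,
                        "d_query": sc.d_query,
                        "d_hit": sc.d_hit,
                        "quality": sc.quality.value,
                        "variant_used": eff.origin == "VARIANT",
                        "from_seqadv": a.from_seqadv,
                        "best_alignment": round(sc.cov_id, 6) == best_cov,
                    })
    return rows, candidates
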