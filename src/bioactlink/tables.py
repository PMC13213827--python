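"""Assembly of the linked tables: outer joins, variants, timeline, filters.

The three per-tool outputs — ligand inventory, structure quality header,
and linked bioactivity rows — are combined with full outer joins into one
table whose rows carry merge indicators saying which sources contributed.
Four variants exist:

    FULL             all candidate targets, per structure-ligand pair
    TARGET           all candidate targets, per structure
    FILTERED         cascade winners only, per structure-ligand pair
    TARGET_FILTERED  cascade winners only, per structure

Rows are plain :class:`pandas.DataFrame` records; the column vocabulary is
defined here and shipped as a machine-readable manifest.
"""

from __future__ import annotations

import enum
import json
import logging
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TableVariant",
    "DuplicateKeyError",
    "ConfigurationError",
    "merge_outputs",
    "build_variant",
    "growth_timeline",
    "apply_quality_filters",
    "column_manifest",
    "LIGAND_KEY",
    "ACTIVITY_KEY",
]

#: Join key of ligand rows onto structure rows.
LIGAND_KEY = ["structure_id", "het_code", "chain_id"]
#: Join key of binding-mode activity rows onto ligand rows.
ACTIVITY_KEY = ["structure_id", "het_code", "chain_id"]

#: Columns that only make sense when the ligand is known; TARGET variants
#: drop them from the activity block.
LIGAND_SPECIFIC_ACTIVITY_COLUMNS = ["molecule_level", "n_site_mutations", "molecule_inchikey"]


class TableVariant(enum.Enum):
    FULL = "FULL"
    TARGET = "TARGET"
    FILTERED = "FILTERED"
    TARGET_FILTERED = "TARGET_FILTERED"

    @property
    def binding_mode(self) -> bool:
        return self in (TableVariant.FULL, TableVariant.FILTERED)

    @property
    def filtered(self) -> bool:
        return self in (TableVariant.FILTERED, TableVariant.TARGET_FILTERED)


class DuplicateKeyError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


def _check_unique(df: pd.DataFrame, key: list[str], source: str) -> None:
    present = [k for k in key if k in df.columns]
    if not present or df.empty:
        return
    dup = df.duplicated(subset=present, keep=False)
    if dup.any():
        first = df.loc[dup, present].iloc[0].tolist()
        raise DuplicateKeyError(f"duplicate key in {source} rows: {first}")


def merge_outputs(
    ligand_rows: pd.DataFrame,
    structure_rows: pd.DataFrame,
    activity_rows: pd.DataFrame,
) -> pd.DataFrame:
    """Full outer join of the three sources with merge indicators.

    ``merge_ligand_structure`` records which of ligand/structure sources
    contributed (``both``/``ligand_only``/``structure_only``);
    ``merge_activity`` records whether bioactivity data is attached
    (``present``/``absent``).  Every input row survives into at least one
    output row.
    """
    lig = ligand_rows.copy()
    struct = structure_rows.copy()
    act = activity_rows.copy()

    _check_unique(lig, LIGAND_KEY + ["residue_number"], "ligand")
    _check_unique(struct, ["structure_id"], "structure")
    act_key = ACTIVITY_KEY + ["target_accession", "assay_id", "activity_type", "value", "units"]
    _check_unique(act, act_key, "activity")

    merged = lig.merge(struct, on="structure_id", how="outer", indicator="_ls")
    merged["merge_ligand_structure"] = (
        merged["_ls"]
        .map({"both": "both", "left_only": "ligand_only", "right_only": "structure_only"})
        .astype(object)
    )
    merged = merged.drop(columns="_ls")

    act_join = [k for k in ACTIVITY_KEY if k in act.columns]
    merged = merged.merge(act, on=act_join, how="outer", indicator="_a")
    merged["merge_activity"] = np.where(merged["_a"].isin(["both", "right_only"]), "present", "absent")
    # activity-only rows (alternative binding chains) carry no lig/struct block
    merged.loc[merged["_a"] == "right_only", "merge_ligand_structure"] = ""
    merged = merged.drop(columns="_a")
    return merged


def build_variant(
    rows: pd.DataFrame,
    variant: TableVariant,
    cascade_results: Mapping[tuple, str] | None = None,
) -> pd.DataFrame:
    """Reduce a merged table to one of the four variants.

    ``cascade_results`` maps a case key — ``(structure_id, het_code)`` for
    binding mode, ``(structure_id,)`` for target mode — to the winning
    target accession.  FILTERED variants keep activity blocks only for
    winners (and only best alignments); rows whose every activity row is
    removed fall back to their ligand/structure block so no complex
    disappears from the table.
    """
    out = rows.copy()
    if variant is TableVariant.FULL:
        return out
    if not variant.binding_mode:
        drop = [c for c in LIGAND_SPECIFIC_ACTIVITY_COLUMNS if c in out.columns]
        out = out.drop(columns=drop)
    if not variant.filtered:
        return out
    if cascade_results is None:
        raise ConfigurationError(f"variant {variant.value} needs cascade results")

    has_act = out["merge_activity"] == "present"
    act = out[has_act]
    rest = out[~has_act]

    def case_key(row) -> tuple:
        if variant.binding_mode:
            return (row["structure_id"], row["het_code"])
        return (row["structure_id"],)

    keep_mask = []
    for _, row in act.iterrows():
        winner = cascade_results.get(case_key(row))
        ok = winner is not None and row["target_accession"] == winner
        if ok and bool(row.get("from_seqadv", False)):
            ok = False
        if ok and "best_alignment" in act.columns and not pd.isna(row["best_alignment"]):
            ok = bool(row["best_alignment"])
        keep_mask.append(ok)
    kept = act[pd.Series(keep_mask, index=act.index)] if len(act) else act

    # complexes that lost every activity row keep a data-less row
    dropped = act[~pd.Series(keep_mask, index=act.index)] if len(act) else act
    orphan_rows = []
    if len(dropped):
        lig_key = [k for k in LIGAND_KEY if k in out.columns]
        surviving = set(map(tuple, kept[lig_key].itertuples(index=False))) if len(kept) else set()
        surviving |= set(map(tuple, rest[lig_key].dropna().itertuples(index=False)))
        seen = set()
        activity_cols = [c for c in dropped.columns if c in _ACTIVITY_COLUMNS]
        for _, row in dropped.iterrows():
            key = tuple(row[k] for k in lig_key)
            if key in surviving or key in seen or row["merge_ligand_structure"] == "":
                continue
            seen.add(key)
            orphan = row.copy()
            orphan[activity_cols] = np.nan
            orphan["merge_activity"] = "absent"
            orphan_rows.append(orphan)

    parts = [rest, kept] + ([pd.DataFrame(orphan_rows)] if orphan_rows else [])
    return pd.concat(parts, ignore_index=True)


_ACTIVITY_COLUMNS = {
    "target_accession", "target_type", "assay_id", "activity_type", "value",
    "units", "pchembl", "document_date", "data_validity_comment", "identity",
    "coverage", "cov_id", "d_query", "d_hit", "quality", "molecule_level",
    "n_site_mutations", "molecule_inchikey", "variant_used", "from_seqadv",
    "best_alignment",
}


def growth_timeline(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-year and cumulative counts of complexes with linked bioactivity.

    Each unique complex (structure, het code) with at least one activity is
    dated by the later of structure deposition and document publication —
    the first moment both halves of the link existed.  Rows missing both
    dates are excluded with a warning.
    """
    act = rows[rows["merge_activity"] == "present"] if len(rows) else rows
    if len(act) == 0:
        return pd.DataFrame(columns=["year", "new_complexes", "cumulative"]).astype(
            {"year": int, "new_complexes": int, "cumulative": int}
        )
    dates = {}
    for _, row in act.iterrows():
        key = (row["structure_id"], row.get("het_code"))
        dep = pd.to_datetime(row.get("deposition_date"), errors="coerce")
        doc = pd.to_datetime(row.get("document_date"), errors="coerce")
        if pd.isna(dep) and pd.isna(doc):
            logger.warning("complex %s has neither deposition nor document date", key)
            continue
        linked = max(d for d in (dep, doc) if not pd.isna(d))
        if key not in dates or linked > dates[key]:
            dates[key] = linked
    if not dates:
        return pd.DataFrame(columns=["year", "new_complexes", "cumulative"]).astype(
            {"year": int, "new_complexes": int, "cumulative": int}
        )
    years = pd.Series([d.year for d in dates.values()])
    counts = years.value_counts().sort_index()
    return pd.DataFrame(
        {
            "year": counts.index.astype(int),
            "new_complexes": counts.values.astype(int),
            "cumulative": counts.cumsum().values.astype(int),
        }
    )


_QUALITY_ORDER = {"GOLD": 3, "SILVER": 2, "BRONZE": 1, "NONE": 0}

_KNOWN_CRITERIA = {
    "skip_reasons_allowed", "density_min", "density_max", "resolution_max",
    "remove_duplicates", "remove_data_validity", "molecule_level_min",
    "identity_min", "site_mutations_max", "quality_min",
}


def apply_quality_filters(rows: pd.DataFrame, criteria: Mapping) -> pd.DataFrame:
    """Conjunction of quality criteria; rows lacking a filtered field drop.

    Supported criteria:

    - ``skip_reasons_allowed``: iterable of allowed skip-reason names; rows
      whose ligand carries any other reason are removed
    - ``density_min`` / ``density_max``: density-support score range
      (the released convention uses −1 for "not computable", so any
      non-negative lower bound also removes those rows, as well as rows
      with no density value at all — e.g. non-crystallographic structures)
    - ``resolution_max``: strict upper bound on resolution in Å
    - ``remove_duplicates``: collapse identical
      (molecule, target, activity type, value, units) measurements
    - ``remove_data_validity``: drop rows with a data-validity comment
    - ``molecule_level_min`` / ``identity_min`` / ``site_mutations_max`` /
      ``quality_min``: floors/caps on link quality
    """
    unknown = set(criteria) - _KNOWN_CRITERIA
    if unknown:
        raise ConfigurationError(f"unknown quality criteria: {sorted(unknown)}")
    out = rows.copy()

    def col(name):
        if name in out.columns:
            return out[name]
        return pd.Series(np.nan, index=out.index)

    if "skip_reasons_allowed" in criteria:
        allowed = set(criteria["skip_reasons_allowed"])
        def ok(sr):
            if not isinstance(sr, str):
                return False
            reasons = {r for r in sr.split(";") if r}
            return reasons <= allowed
        out = out[col("skip_reasons").map(ok)]
    if "density_min" in criteria:
        out = out[pd.to_numeric(col("density_support"), errors="coerce") >= criteria["density_min"]]
    if "density_max" in criteria:
        out = out[pd.to_numeric(col("density_support"), errors="coerce") <= criteria["density_max"]]
    if "resolution_max" in criteria:
        out = out[pd.to_numeric(col("resolution"), errors="coerce") < criteria["resolution_max"]]
    if criteria.get("remove_data_validity"):
        comments = col("data_validity_comment").fillna("")
        out = out[comments.astype(str).str.strip() == ""]
    if criteria.get("remove_duplicates"):
        dup_key = [c for c in ("molecule_inchikey", "target_accession", "activity_type", "value", "units")
                   if c in out.columns]
        if dup_key:
            out = out[~out.duplicated(subset=dup_key, keep="first")]
    if "molecule_level_min" in criteria:
        out = out[pd.to_numeric(col("molecule_level"), errors="coerce") >= criteria["molecule_level_min"]]
    if "identity_min" in criteria:
        out = out[pd.to_numeric(col("identity"), errors="coerce") > criteria["identity_min"]]
    if "site_mutations_max" in criteria:
        out = out[pd.to_numeric(col("n_site_mutations"), errors="coerce") <= criteria["site_mutations_max"]]
    if "quality_min" in criteria:
        floor = _QUALITY_ORDER[str(criteria["quality_min"]).upper()]
        out = out[col("quality").map(lambda q: _QUALITY_ORDER.get(q, -1)) >= floor]
    return out


def column_manifest() -> dict:
    """The machine-readable column schema shipped with the package."""
    with resources.files("bioactlink").joinpath("data/columns.json").open() as fh:
        return json.load(fh)
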