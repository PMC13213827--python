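# bioactlink

Cross-links protein–ligand complex structures (PDB format) with bioactivity
records (a ChEMBL-style tabular extract) into a single curated table, for
people who build structure–activity data sets: every ligand in every
structure, annotated with the bioactivity measurements that were most
plausibly measured on that protein–ligand pair, together with explicit,
filterable quality criteria for each link.

The hard part of such linking is that neither the protein nor the molecule
matches exactly. bioactlink therefore grades both sides:

**Protein side.** Each structure chain (query) is locally aligned against a
target's component sequence — or an assay-specific variant sequence, which
overrides the component when present — and scored with the
coverage-weighted identity

```
CovId = (Identity / 100) · |Cov_query / 100|
```

plus two relative length-discrepancy metrics
`D_query = |1 − len(alignment)/len(query)|` and
`D_hit = |1 − len(alignment)/len(hit)|`, which define three quality tiers:
**Gold** (identity ≥ 95 %, both D ≤ 0.05), **Silver** (identity ≥ 95 %,
D_query ≤ 0.10) and **Bronze** (identity ≥ 80 %). Mutations inside the
ligand binding site (a 3.25 Å-radius sphere around every ligand heavy atom)
are counted per link.

**Molecule side.** Correspondence is graded on a five-level scale:
identical InChIKey (5), identical canonical SMILES with stereo (4), without
stereo (3), identical InChI truncated after the hydrogen layer (2), after
the atom-connection layer (1), no match (0). Levels 5–4 are identical
molecules, 3 a stereo-distinct isomer, 2–1 potentially identical compounds
(tautomers, protomers, isotopologues).

When several targets remain for one structure (or structure–ligand pair), a
deterministic seven-step **filter cascade** picks one winner — discard
SEQADV-based matches, drop the heterogeneous "Unchecked" dummy target, keep
the best CovId, best molecule level, fewest site mutations, preferred
target type (single protein > protein complex > protein family), most
unique data points, lowest accession number — with a full audit of which
step removed which candidate. The final tables are full outer joins of the
ligand, structure and bioactivity blocks with merge indicators, in four
variants: FULL and TARGET (all candidate targets, per pair / per
structure) and FILTERED / TARGET_FILTERED (cascade winners only).

## Worked example

```bash
python examples/link_end_to_end.py
```

generates eleven synthetic complexes with a matching activity table — each
engineered so that a different cascade step decides its best target — runs
the whole pipeline and prints:

```
11 structures, 25 activity records
FULL       26 rows,  24 with bioactivity
FILTERED   18 rows,  15 with bioactivity

cascade decisions (binding mode):
  S000/L01: CHEMBL1007     decided at SINGLE
  S001/L02: -              decided at DUMMY
  S002/L02: CHEMBL1205     decided at SEQUENCE
  S003/L01: CHEMBL1305     decided at MOLECULE
  ...
high-quality rows (identity>95, no site mutations, identical molecule): 12
```

The FULL table keeps every candidate target (24 bioactivity rows); the
FILTERED table keeps only cascade winners and best alignments (15 rows),
while every extracted ligand keeps at least one row even when its only
matches were discarded (the `S001` pair, whose sole candidate was the dummy
target, survives as a structure/ligand row without bioactivity). The other
examples each show one capability: `extract_ligands.py` (skip reasons and
binding sites), `grade_molecule_matches.py` (the five levels),
`score_protein_match.py` (CovId and tiers), `select_best_target.py` (the
cascade audit).

A thin CLI wraps the same functions
(`bioactlink extract|match|cascade|build|timeline|filter|fixtures`); see
`bioactlink --help`.

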