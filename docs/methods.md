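# Methods

## Problem and model

Given protein–ligand complexes in PDB format and a tabular bioactivity
extract (assay, target accession and type, component sequence, optional
assay variant sequence, molecule SMILES/InChI, activity type/value/units,
pChEMBL, document date, validity comment), the package links each
structure — or each structure–ligand pair — to the bioactivity target it
most plausibly corresponds to, and assembles the evidence into one joined
table. Links are never binary: both the protein match and the molecule
match carry graded quality, and the selection among competing targets is a
deterministic, fully audited filter cascade.

## Ligand extraction

Every non-water hetero-group is a candidate ligand. Descriptors
(heavy-atom count, molecular weight) are computed from the atoms actually
modeled, not from an idealized formula — the table describes what is in
the file. Problems are encoded as skip reasons, never as failures:
annotated missing atoms and other header peculiarities (REMARK 470/475,
600-series), covalent attachment to the polymer (LINK records whose other
end resolves to a polymer atom), elements outside the supported organic
set {H, C, N, O, P, S, F, Cl, Br, I, B, Se} — metals in particular —
disagreement with an optional per-het-code reference formula (hydrogens
ignored, since they are routinely unmodeled), and standard amino-acid or
nucleotide codes appearing as hetero-groups (flagged POLYMER_LIGAND, not
dropped). Water (HOH/DOD/WAT) is never a ligand. Coordinates and parsing
go through gemmi; a small supplementary header scan recovers the PDB-text
records gemmi does not expose (EXPDTA, REMARK 3 R-factors, SEQADV,
peculiarity remarks). Only the first model of multi-model files is used;
mmCIF is out of scope.

The binding site of a ligand is every polymer residue with at least one
atom within the cutoff radius of at least one ligand heavy atom. The
default cutoff is **3.25 Å** — a 6.5 Å-diameter sphere read literally.
Because binding-site cutoffs of 6.5 Å radius are also common practice, the
radius is an explicit configuration parameter (`PipelineConfig.site_cutoff`,
CLI key `cutoff`) rather than a constant.

## Molecule matching

Both sides are canonicalized with RDKit: standard InChI, InChIKey,
canonical SMILES with and without stereochemistry, and two truncated
InChIs (after the atom-connection `/c` layer and after the hydrogen `/h`
layer; a missing layer truncates at the last earlier layer present). For
salts and mixtures the largest covalently connected component is used;
charges are preserved and no protonation normalization is applied beyond
what standard InChI itself performs. The match level is the *highest*
satisfied criterion of: identical InChIKey (5), identical stereo SMILES
(4), identical stereo-stripped SMILES (3), identical hydrogen-layer
truncation (2), identical connection-layer truncation (1). The level-1/
level-2 layer assignment follows the explicit layer-by-layer definition of
the five-level scale (level 1 = connection layer, level 2 = hydrogen
layer). Note that InChI's mobile-hydrogen convention already collapses
many tautomer pairs to one InChI (they grade 5); pairs it distinguishes —
fixed-H tautomers such as keto/enol — grade 1, and isotopologues grade 2.

## Sequence matching

Alignments are local Smith–Waterman over BLOSUM62 with affine gap costs
matching the common search-tool defaults (open 11, extend 1; in
Biopython's convention `open_gap_score=-12`, `extend_gap_score=-1`, since
it charges the opening score for the first gap position). Identity is
computed over alignment columns; query coverage over gap-free aligned
query residues. Precomputed hits in the standard 12-column tabular format
are accepted as an alternative input for users who ran an external search
tool. Matches below 80 % identity are flagged sub-threshold; the pipeline
additionally requires a minimum query coverage (default 50 %) for a match
to count as a link — a pragmatic significance proxy, since a bare
Smith–Waterman reports arbitrarily short perfect local hits that an
e-value-based tool would suppress. Scoring follows the equations in the
README; all tier thresholds are inclusive, with a 1e-9 epsilon so that
exact-boundary ratios (e.g. alignment/query = 0.95) classify inclusively
despite binary floating point.

Assay variant sequences override the target component sequence; the
literal label `UNDEFINED MUTATION` carries no sequence and falls back to
the component. Binding-site mutations are substitutions (or query
positions aligned to gaps) at site positions of the aligned chain; a
variant that carries the same mutation as the structure therefore counts
zero. For chains with SEQADV entries a second query — the chain with the
database reference residues restored — is also aligned; matches won
through it are flagged `from_seqadv` and discarded during filtering,
because those mutations are by definition absent from the modeled
structure.

## Target selection

Candidates for one case (a structure–ligand pair in BINDING mode, a
structure in TARGET mode) are filtered in order: SEQADV discard,
dummy-target removal (`CHEMBL612545`, a container of heterogeneous
unchecked data), highest CovId, best molecule level, fewest site mutations,
preferred target type, most unique data points, lowest accession number.
TARGET mode skips the three ligand-dependent steps. Decisions taken:

- CovId ties use equality after rounding to 6 decimals, so platform-level
  float noise cannot split a genuine tie.
- The target-type step is skipped only when *no* candidate carries one of
  the three preferred labels; otherwise candidates with the best-ranked
  present label are kept. Unlisted labels are unranked and lose to any
  listed one.
- "Unique data points" are distinct (assay, activity type, value, units)
  tuples among a candidate's linked rows.
- The audit's `decided_at` is the last step that strictly reduced the
  candidate set (SINGLE for singletons); the SEQADV discard is
  pre-cascade bookkeeping and never counts as deciding, matching the view
  that pairs matching only via SEQADV are excluded from filtering
  statistics.
- The final tiebreak by lowest accession number makes the winner a total
  function of the candidate set: the cascade is permutation-invariant and
  equivalent to one lexicographic sort, which the test suite exploits as
  an independent brute-force oracle.

## Table assembly

The ligand, structure and bioactivity blocks are combined by full outer
joins (pandas) keyed on structure id and, for activity rows, structure +
het code + chain; `merge_ligand_structure` (both/ligand_only/
structure_only) and `merge_activity` (present/absent) record provenance.
FILTERED variants keep bioactivity only for cascade winners and only
best-scoring alignments; a complex whose every activity row is removed
keeps a data-less row so no ligand disappears. TARGET variants drop the
ligand-specific activity columns. An optional per-structure density-support
score is passed through unchanged (−1 meaning "not computable"); no
electron-density computation is performed. The growth timeline dates each
linked complex by the later of structure deposition and document
publication — the first moment both halves of the link existed — and
reports per-year and cumulative counts. Quality filtering is a conjunction
of named criteria (skip-reason whitelist, density range, strict resolution
bound, duplicate/validity removal, molecule-level floor, identity floor,
site-mutation cap, tier floor); rows lacking a filtered field are removed
by that criterion, so e.g. a density bound drops non-crystallographic
structures. The column vocabulary ships as `data/columns.json`;
bit-compatibility with any particular released archive layout is a
non-goal.

## Synthetic data generator

The generator emulates the study conditions end to end with planted ground
truth. Chains are idealized extended backbones (Cα every 3.8 Å along one
axis, Cβ stubs 1.5 Å opposite the ligand; glycine without Cβ), 34–50
residues of uniformly random sequence. Ligand heavy atom *k* sits 2.8 Å
above the Cα of the *k*-th planted site residue and remaining atoms are
parked ≥ 8 Å away, so the computed binding site at the default cutoff is
exactly the planted residue set (neighbouring Cα are √(3.8² + 2.8²) ≈
4.7 Å from the nearest ligand atom). The molecule library provides, per
compound, an enantiomer, a fixed-H tautomer and an unrelated decoy, so
assays can be planted at levels 5/3/1/0. Scenarios cycle through eleven
per-structure blueprints: one for each cascade-deciding step (SINGLE,
DUMMY, SEQUENCE, MOLECULE, MUTATIONS, TARGET_TYPE, DATAPOINTS, TIEBREAK),
a SEQADV decoy target, and the two variant-sequence behaviours (variant
matching the structure's mutation; `UNDEFINED MUTATION`). Mutation-step
candidates carry equally many substitutions placed in- versus out-of-site,
so CovId ties exactly and only the mutation count separates them.
Positions are kept ≥ 5 residues from the termini so local alignment never
trims a planted mismatch. The SINGLE structure additionally carries the
skip-reason decoys (covalently linked aldehyde with a missing-atom remark,
a lone Fe hetero-group, a water). All randomness flows from one seeded
`numpy` generator; generation is byte-identical per seed. Planted winners
and deciding steps are re-derived at generation time by an independent
brute-force sort, not by the cascade implementation.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic folds and packing (binding sites are
geometric, not chemical), crystallographic artifacts, sequence families
with homologs (random sequences make cross-matches essentially
impossible, so the 80 %/50 % link thresholds are never stressed by
near-homologs), registry-scale molecule diversity, and the long tail of
malformed real-world records.

## Problem sizes and numerics

Default test/acceptance sizes: 1000 random alignments for the equation
suite (agreement to 1e-12), 200 random molecules for grading invariances,
1000 random candidate sets per cascade mode against the brute-force
oracle, and 50 seeded scenarios (11 structures each) for exact end-to-end
recovery; a 22-structure scenario serves as the assembled demo. These
sizes keep the whole suite in seconds while exercising every code path;
all are parameters, not constants, and scale up trivially.

## Known limitations

- No e-value statistics: the coverage floor is a stand-in, adequate for
  curated inputs but not for genome-scale sequence searching; precomputed
  tabular hits from a real search tool are the intended route there.
- Bond perception from bare coordinates is not attempted; structure-side
  molecule identity comes from a het-code→SMILES component dictionary.
- Enhanced (AND/OR) stereochemistry, metal-organic bonding and tautomer
  enumeration are out of scope; covalent ligands are flagged but their
  bioactivity is not linked.
- mmCIF input, NMR/cryo-EM multi-model handling beyond "first model", and
  live database connectivity are not implemented.
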