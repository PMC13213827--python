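"""Sequence alignment, CovId scoring, quality tiers and site mutations.

A structure chain (query) is matched against a bioactivity target's
component sequence, or against an assay-specific variant sequence when one
exists (hit).  Matching is scored with the coverage-weighted identity

    CovId = (Identity / 100) * |Cov_query / 100|

where Identity is the percent identity over the alignment and Cov_query is
the percentage of query residues covered by the alignment.  Two relative
length-discrepancy metrics

    D_query = |1 - alignment_length / query_length|
    D_hit   = |1 - alignment_length / hit_length|

define three absolute quality tiers:

    GOLD    identity >= 95 and D_query <= 0.05 and D_hit <= 0.05
    SILVER  identity >= 95 and D_query <= 0.10
    BRONZE  identity >= 80

Alignments are local Smith-Waterman with BLOSUM62 and BLAST-default affine
gap costs (open 11, extend 1), computed with Biopython; precomputed hits in
the standard 12-column tabular format are accepted as an alternative input.
Matches below 80% identity are flagged sub-threshold rather than dropped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .structures import BindingSite

__all__ = [
    "Quality",
    "AlignmentResult",
    "MatchScore",
    "EffectiveAssaySequence",
    "UNDEFINED_MUTATION",
    "IDENTITY_FLOOR",
    "align",
    "score_match",
    "resolve_assay_sequence",
    "count_site_mutations",
    "read_tabular_hits",
    "write_scored_matches",
]

#: Reporting floor: alignments under 80% identity are flagged sub-threshold.
IDENTITY_FLOOR = 80.0

#: Variant-sequence label meaning "mutant, sequence unknown"; such assays are
#: handled as if no variant annotation existed.
UNDEFINED_MUTATION = "UNDEFINED MUTATION"

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class Quality(enum.Enum):
    GOLD = "GOLD"
    SILVER = "SILVER"
    BRONZE = "BRONZE"
    NONE = "NONE"


@dataclass
class AlignmentResult:
    query_id: str
    hit_id: str
    identity: float            # percent, 0-100, over alignment columns
    alignment_length: int      # aligned columns incl. gaps
    query_length: int
    hit_length: int
    coverage_query: float      # percent of query residues aligned (gap-free)
    aligned_pairs: list[tuple[int | None, int | None, str | None, str | None]] = field(
        default_factory=list
    )
    substitutions: list[tuple[int, int, str, str]] = field(default_factory=list)
    from_seqadv: bool = False
    sub_threshold: bool = False
    raw_score: float = 0.0
    query_start: int = 0


@dataclass(frozen=True)
class MatchScore:
    cov_id: float
    d_query: float
    d_hit: float
    quality: Quality


@dataclass(frozen=True)
class EffectiveAssaySequence:
    sequence: str
    origin: str               # "COMPONENT" or "VARIANT"
    variant_label: str | None = None


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "local"
    # BLAST "open 11 / extend 1" charges 11+k for a gap of length k;
    # Biopython charges open for the first gap position, hence -12/-1.
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def align(query: str, hit: str, query_id: str = "query", hit_id: str = "hit") -> AlignmentResult:
    """Best local alignment of ``query`` against ``hit``.

    Ties between equal-scoring alignments are broken deterministically by
    lower query start (the first alignment Biopython enumerates).
    """
    for name, seq in (("query", query), ("hit", hit)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq.upper()) - _AA
        if bad:
            raise ValueError(f"{name} sequence has non-amino-acid letters: {sorted(bad)}")
    query = query.upper()
    hit = hit.upper()

    alignments = _ALIGNER.align(query, hit)
    best = alignments[0]

    aligned_pairs: list[tuple[int | None, int | None, str | None, str | None]] = []
    substitutions: list[tuple[int, int, str, str]] = []
    identical = 0
    n_cols = 0
    q_aligned = 0

    q_blocks, h_blocks = best.aligned
    prev_q_end: int | None = None
    prev_h_end: int | None = None
    for (qs, qe), (hs, he) in zip(q_blocks, h_blocks):
        if prev_q_end is not None:
            for qpos in range(prev_q_end, qs):      # deletion in hit
                aligned_pairs.append((qpos, None, query[qpos], None))
                n_cols += 1
            for hpos in range(prev_h_end, hs):      # insertion in hit
                aligned_pairs.append((None, hpos, None, hit[hpos]))
                n_cols += 1
        for qpos, hpos in zip(range(qs, qe), range(hs, he)):
            qres, hres = query[qpos], hit[hpos]
            aligned_pairs.append((qpos, hpos, qres, hres))
            n_cols += 1
            q_aligned += 1
            if qres == hres:
                identical += 1
            else:
                substitutions.append((qpos, hpos, qres, hres))
        prev_q_end, prev_h_end = qe, he

    identity = 100.0 * identical / n_cols if n_cols else 0.0
    coverage = 100.0 * q_aligned / len(query)
    return AlignmentResult(
        query_id=query_id,
        hit_id=hit_id,
        identity=identity,
        alignment_length=n_cols,
        query_length=len(query),
        hit_length=len(hit),
        coverage_query=coverage,
        aligned_pairs=aligned_pairs,
        substitutions=substitutions,
        sub_threshold=identity < IDENTITY_FLOOR,
        raw_score=float(best.score),
        query_start=int(q_blocks[0][0]) if len(q_blocks) else 0,
    )


def score_match(a: AlignmentResult) -> MatchScore:
    """CovId, D-metrics and quality tier for one alignment."""
    cov_id = (a.identity / 100.0) * abs(a.coverage_query / 100.0)
    d_query = abs(1.0 - a.alignment_length / a.query_length)
    d_hit = abs(1.0 - a.alignment_length / a.hit_length)
    # thresholds are inclusive; the epsilon keeps exact-boundary inputs
    # (e.g. an alignment/query ratio of exactly 0.95) on the inclusive side
    # despite binary-float rounding
    eps = 1e-9
    if a.identity >= 95.0 - eps and d_query <= 0.05 + eps and d_hit <= 0.05 + eps:
        quality = Quality.GOLD
    elif a.identity >= 95.0 - eps and d_query <= 0.10 + eps:
        quality = Quality.SILVER
    elif a.identity >= 80.0 - eps:
        quality = Quality.BRONZE
    else:
        quality = Quality.NONE
    return MatchScore(cov_id=cov_id, d_query=d_query, d_hit=d_hit, quality=quality)


def resolve_assay_sequence(assay_variant: str | None, component: str) -> EffectiveAssaySequence:
    """Pick the sequence an assay was actually run against.

    A usable variant sequence overrides the component sequence; the literal
    label ``UNDEFINED MUTATION`` carries no sequence and falls back to the
    component.
    """
    if not component:
        raise ValueError("component sequence is empty")
    if assay_variant and assay_variant.strip() and assay_variant.strip() != UNDEFINED_MUTATION:
        return EffectiveAssaySequence(
            sequence=assay_variant.strip(), origin="VARIANT", variant_label=assay_variant.strip()
        )
    return EffectiveAssaySequence(sequence=component, origin="COMPONENT")


def count_site_mutations(a: AlignmentResult, site: BindingSite, chain_id: str) -> int:
    """Mutations within the binding site, from the alignment's point of view.

    Counts substitutions whose query position lies in the site, plus site
    positions aligned to a gap in the hit.  When the hit is a variant
    sequence carrying the same mutation as the structure, the aligned
    residues agree and nothing is counted.
    """
    if chain_id not in site.sequence_positions:
        raise IndexError(f"binding site has no positions for chain {chain_id!r}")
    site_pos = site.sequence_positions[chain_id]
    n = sum(1 for (qpos, _h, _qr, _hr) in a.substitutions if qpos in site_pos)
    n += sum(
        1
        for (qpos, hpos, _qr, _hr) in a.aligned_pairs
        if qpos is not None and hpos is None and qpos in site_pos
    )
    return n


# --- tabular I/O ------------------------------------------------------------

def read_tabular_hits(path) -> list[AlignmentResult]:
    """Read precomputed hits in the standard 12-column tabular format.

    Columns: query, subject, % identity, alignment length, mismatches, gap
    opens, q.start, q.end, s.start, s.end, e-value, bit score.  Query and
    hit lengths are not part of the format; coverage is taken over the query
    span, and length fields are filled with the spans (callers that know
    true sequence lengths should overwrite them before scoring).
    """
    results = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            f = ln.split("\t")
            if len(f) < 12:
                raise ValueError(f"expected 12 tab-separated columns, got {len(f)}: {ln!r}")
            qstart, qend, sstart, send = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            length = int(f[3])
            results.append(
                AlignmentResult(
                    query_id=f[0],
                    hit_id=f[1],
                    identity=float(f[2]),
                    alignment_length=length,
                    query_length=qend - qstart + 1,
                    hit_length=send - sstart + 1,
                    coverage_query=100.0,
                    sub_threshold=float(f[2]) < IDENTITY_FLOOR,
                    raw_score=float(f[11]),
                    query_start=qstart - 1,
                )
            )
    return results


def write_scored_matches(rows: Iterable[tuple[AlignmentResult, MatchScore, int | None]], path) -> None:
    """TSV of (alignment, score, n_site_mutations) triples."""
    with open(path, "w") as fh:
        fh.write(
            "query_id\thit_id\tidentity\talignment_length\tquery_length\thit_length\t"
            "coverage\tcov_id\td_query\td_hit\tquality\tn_site_mutations\tfrom_seqadv\n"
        )
        for a, s, n_mut in rows:
            fh.write(
                f"{a.query_id}\t{a.hit_id}\t{a.identity:.4f}\t{a.alignment_length}\t"
                f"{a.query_length}\t{a.hit_length}\t{a.coverage_query:.4f}\t{s.cov_id:.6f}\t"
                f"{s.d_query:.6f}\t{s.d_hit:.6f}\t{s.quality.value}\t"
                f"{'' if n_mut is None else n_mut}\t{a.from_seqadv}\n"
            )
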