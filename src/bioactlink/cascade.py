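"""Best-target selection: a deterministic filter cascade with audit trail.

For one structure (TARGET mode) or one structure-ligand pair (BINDING
mode), several bioactivity targets may match the protein sequence.  The
cascade reduces them to exactly one winner:

    0. discard candidates whose match was constructed through a
       SEQADV-adjusted sequence (such mutations are absent from the model)
    1. discard the heterogeneous "Unchecked" dummy target CHEMBL612545
    2. keep only candidates with the highest CovId
    3. keep only the best molecule match level        [BINDING only]
    4. keep only the fewest binding-site mutations    [BINDING only]
    5. prefer target types SINGLE PROTEIN > PROTEIN COMPLEX >
       PROTEIN FAMILY; skipped when no candidate carries any of the three
    6. keep only the most unique activity data points [BINDING only]
    7. tiebreak: lowest numeric part of the target accession

Steps 3, 4 and 6 need a known ligand and binding site, so TARGET mode
skips them.  Every removal is attributed to a step in the audit, and the
audit records the last step that strictly reduced the candidate set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .molecules import MatchLevel
from .seqmatch import AlignmentResult, MatchScore

__all__ = [
    "DUMMY_TARGET",
    "CascadeMode",
    "CascadeStep",
    "TargetCandidate",
    "CascadeAudit",
    "run_cascade",
    "select_best_alignment",
    "write_audit_table",
]

#: The "Unchecked" registry target that aggregates heterogeneous data.
DUMMY_TARGET = "CHEMBL612545"

#: Preference order of target type labels; unlisted labels are unranked and
#: lose to any listed one (the step is skipped when no listed label occurs).
TYPE_RANK = {"SINGLE PROTEIN": 0, "PROTEIN COMPLEX": 1, "PROTEIN FAMILY": 2}


class CascadeMode(enum.Enum):
    BINDING = "BINDING"   # per structure-ligand pair; all steps
    TARGET = "TARGET"     # per structure; molecule/mutation/datapoint steps skipped


class CascadeStep(enum.Enum):
    SINGLE = "SINGLE"
    SEQADV = "SEQADV"
    DUMMY = "DUMMY"
    SEQUENCE = "SEQUENCE"
    MOLECULE = "MOLECULE"
    MUTATIONS = "MUTATIONS"
    TARGET_TYPE = "TARGET_TYPE"
    DATAPOINTS = "DATAPOINTS"
    TIEBREAK = "TIEBREAK"


@dataclass
class TargetCandidate:
    target_accession: str
    target_type: str
    best_score: MatchScore
    best_alignment: AlignmentResult | None = None
    molecule_level: MatchLevel | None = None
    n_site_mutations: int | None = None
    n_unique_datapoints: int | None = None
    from_seqadv: bool = False

    @property
    def target_numeric(self) -> int:
        acc = self.target_accession
        if not acc.startswith("CHEMBL"):
            raise ValueError(f"not a CHEMBL accession: {acc!r}")
        return int(acc[len("CHEMBL"):])

    @property
    def cov_id(self) -> float:
        return self.best_score.cov_id


@dataclass
class CascadeAudit:
    decided_at: CascadeStep
    removals: dict[str, CascadeStep] = field(default_factory=dict)
    winner: str | None = None


def _round6(x: float) -> float:
    # exact-equality comparisons on CovId use 6-decimal rounding so that
    # platform-level float noise cannot split a genuine tie
    return round(x, 6)


def run_cascade(
    candidates: list[TargetCandidate],
    mode: CascadeMode = CascadeMode.BINDING,
) -> tuple[TargetCandidate | None, CascadeAudit]:
    """Apply the filter cascade; returns (winner or None, audit).

    The result is invariant under permutation of ``candidates`` because the
    final tiebreak (lowest accession number) is a total order.
    """
    removals: dict[str, CascadeStep] = {}
    pool = list(candidates)
    decided_at = CascadeStep.SINGLE

    def drop(pred, step: CascadeStep):
        nonlocal pool, decided_at
        keep = [c for c in pool if not pred(c)]
        if len(keep) != len(pool):
            for c in pool:
                if pred(c):
                    removals[c.target_accession] = step
            pool = keep
            # SEQADV discard is pre-cascade bookkeeping: its removals are
            # audited but never count as the deciding step.
            if step is not CascadeStep.SEQADV:
                decided_at = step

    drop(lambda c: c.from_seqadv, CascadeStep.SEQADV)
    drop(lambda c: c.target_accession == DUMMY_TARGET, CascadeStep.DUMMY)

    if not pool:
        return None, CascadeAudit(decided_at=decided_at, removals=removals, winner=None)

    best_cov = max(_round6(c.cov_id) for c in pool)
    drop(lambda c: _round6(c.cov_id) < best_cov, CascadeStep.SEQUENCE)

    if mode is CascadeMode.BINDING:
        best_level = max(int(c.molecule_level or 0) for c in pool)
        drop(lambda c: int(c.molecule_level or 0) < best_level, CascadeStep.MOLECULE)

        fewest = min(c.n_site_mutations or 0 for c in pool)
        drop(lambda c: (c.n_site_mutations or 0) > fewest, CascadeStep.MUTATIONS)

    ranks = [TYPE_RANK[c.target_type] for c in pool if c.target_type in TYPE_RANK]
    if ranks:  # skipped entirely when no candidate carries a preferred label
        best_rank = min(ranks)
        drop(lambda c: TYPE_RANK.get(c.target_type, 99) != best_rank, CascadeStep.TARGET_TYPE)

    if mode is CascadeMode.BINDING:
        most = max(c.n_unique_datapoints or 0 for c in pool)
        drop(lambda c: (c.n_unique_datapoints or 0) < most, CascadeStep.DATAPOINTS)

    lowest = min(c.target_numeric for c in pool)
    drop(lambda c: c.target_numeric != lowest, CascadeStep.TIEBREAK)

    assert len(pool) == 1
    winner = pool[0]
    return winner, CascadeAudit(decided_at=decided_at, removals=removals, winner=winner.target_accession)


def select_best_alignment(alignments: list[AlignmentResult]) -> AlignmentResult:
    """Single best alignment for one candidate pair: maximal CovId, ties by
    higher identity, longer alignment, then lexicographic hit id."""
    if not alignments:
        raise ValueError("no alignments to select from")

    def key(a: AlignmentResult):
        cov_id = (a.identity / 100.0) * abs(a.coverage_query / 100.0)
        return (-_round6(cov_id), -a.identity, -a.alignment_length, a.hit_id)

    return min(alignments, key=key)


def write_audit_table(audits: dict[str, CascadeAudit], path) -> None:
    """Per-candidate removal steps plus the per-case deciding step, as TSV.

    Aggregating the two columns reproduces the cascade statistics view:
    how many cases each step decided, and how many candidates it removed.
    """
    with open(path, "w") as fh:
        fh.write("case\tcandidate\tremoved_by_step\tdecided_at\twinner\n")
        for case, audit in sorted(audits.items()):
            w = audit.winner or ""
            if audit.winner:
                fh.write(f"{case}\t{audit.winner}\t\t{audit.decided_at.value}\t{w}\n")
            for cand, step in sorted(audit.removals.items()):
                fh.write(f"{case}\t{cand}\t{step.value}\t{audit.decided_at.value}\t{w}\n")
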