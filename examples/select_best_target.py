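"""Reduce competing candidate targets to one winner with the filter cascade.

Three candidates tie on sequence quality; the cascade then prefers the
better molecule match, the preferred target type, and finally the lowest
accession number, recording which step removed each candidate.
"""

from bioactlink.cascade import CascadeMode, TargetCandidate, run_cascade
from bioactlink.seqmatch import MatchScore, Quality


def candidate(acc, cov_id, level, ttype):
    return TargetCandidate(
        target_accession=acc, target_type=ttype,
        best_score=MatchScore(cov_id=cov_id, d_query=0.0, d_hit=0.0,
                              quality=Quality.GOLD),
        molecule_level=level, n_site_mutations=0, n_unique_datapoints=1,
    )


candidates = [
    candidate("CHEMBL301", cov_id=1.00, level=5, ttype="PROTEIN FAMILY"),
    candidate("CHEMBL205", cov_id=1.00, level=5, ttype="SINGLE PROTEIN"),
    candidate("CHEMBL999", cov_id=1.00, level=3, ttype="SINGLE PROTEIN"),
    candidate("CHEMBL612545", cov_id=1.00, level=5, ttype="UNCHECKED"),  # dummy
]

winner, audit = run_cascade(candidates, CascadeMode.BINDING)
print("winner:", winner.target_accession)
print("decided at step:", audit.decided_at.value)
for acc, step in sorted(audit.removals.items()):
    print(f"  removed {acc:<14s} by {step.value}")

# CHEMBL612545 is the heterogeneous "Unchecked" container and is always
# dropped first; CHEMBL999 loses on molecule match level, CHEMBL301 on
# target type, leaving CHEMBL205 without needing the numeric tiebreak.
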