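"""Filter-cascade semantics, determinism and brute-force equivalence."""

import numpy as np
import pytest

from bioactlink.cascade import (
    DUMMY_TARGET,
    CascadeMode,
    CascadeStep,
    TargetCandidate,
    run_cascade,
    select_best_alignment,
)
from bioactlink.seqmatch import AlignmentResult, MatchScore, Quality


def cand(acc, cov_id=1.0, level=5, muts=0, ttype="SINGLE PROTEIN", points=1,
         seqadv=False):
    return TargetCandidate(
        target_accession=acc,
        target_type=ttype,
        best_score=MatchScore(cov_id=cov_id, d_query=0.0, d_hit=0.0, quality=Quality.GOLD),
        molecule_level=level,
        n_site_mutations=muts,
        n_unique_datapoints=points,
        from_seqadv=seqadv,
    )


class TestRunCascade:
    def test_singleton_decided_single(self):
        w, audit = run_cascade([cand("CHEMBL7")])
        assert w.target_accession == "CHEMBL7"
        assert audit.decided_at is CascadeStep.SINGLE
        assert audit.removals == {}

    def test_covid_decides(self):
        w, audit = run_cascade([cand("CHEMBL9", cov_id=0.99), cand("CHEMBL1", cov_id=0.80)])
        assert w.target_accession == "CHEMBL9"
        assert audit.decided_at is CascadeStep.SEQUENCE
        assert audit.removals == {"CHEMBL1": CascadeStep.SEQUENCE}

    def test_lowest_accession_tiebreak(self):
        w, audit = run_cascade([cand("CHEMBL10"), cand("CHEMBL2")])
        assert w.target_accession == "CHEMBL2"
        assert audit.decided_at is CascadeStep.TIEBREAK

    def test_target_type_preference_order(self):
        w, audit = run_cascade([
            cand("CHEMBL2", ttype="PROTEIN FAMILY"),
            cand("CHEMBL9", ttype="SINGLE PROTEIN"),
        ])
        assert w.target_accession == "CHEMBL9"
        assert audit.decided_at is CascadeStep.TARGET_TYPE

    def test_type_step_skipped_when_no_preferred_label(self):
        w, audit = run_cascade([
            cand("CHEMBL9", ttype="CHIMERIC PROTEIN"),
            cand("CHEMBL2", ttype="NUCLEIC-ACID"),
        ])
        assert w.target_accession == "CHEMBL2"
        assert audit.decided_at is CascadeStep.TIEBREAK

    def test_molecule_step_skipped_in_target_mode(self):
        cands = [cand("CHEMBL9", level=5), cand("CHEMBL2", level=3)]
        w, audit = run_cascade(cands, CascadeMode.TARGET)
        assert w.target_accession == "CHEMBL2"
        assert audit.decided_at is CascadeStep.TIEBREAK
        wb, audit_b = run_cascade(cands, CascadeMode.BINDING)
        assert wb.target_accession == "CHEMBL9"
        assert audit_b.decided_at is CascadeStep.MOLECULE

    def test_dummy_only_leaves_no_winner(self):
        w, audit = run_cascade([cand(DUMMY_TARGET)])
        assert w is None
        assert audit.decided_at is CascadeStep.DUMMY
        assert audit.removals == {DUMMY_TARGET: CascadeStep.DUMMY}

    def test_seqadv_discard_never_decides(self):
        w, audit = run_cascade([cand("CHEMBL9"), cand("CHEMBL2", seqadv=True)])
        assert w.target_accession == "CHEMBL9"
        assert audit.decided_at is CascadeStep.SINGLE
        assert audit.removals == {"CHEMBL2": CascadeStep.SEQADV}

    def test_empty_input(self):
        w, audit = run_cascade([])
        assert w is None and audit.removals == {}

    def test_mutations_and_datapoints_steps(self):
        w, audit = run_cascade([cand("CHEMBL2", muts=1), cand("CHEMBL9", muts=0)])
        assert w.target_accession == "CHEMBL9"
        assert audit.decided_at is CascadeStep.MUTATIONS
        w, audit = run_cascade([cand("CHEMBL2", points=1), cand("CHEMBL9", points=4)])
        assert w.target_accession == "CHEMBL9"
        assert audit.decided_at is CascadeStep.DATAPOINTS


TYPES = ["SINGLE PROTEIN", "PROTEIN COMPLEX", "PROTEIN FAMILY", "CHIMERIC PROTEIN",
         "UNCHECKED"]
_TYPE_RANK = {"SINGLE PROTEIN": 0, "PROTEIN COMPLEX": 1, "PROTEIN FAMILY": 2}


def brute_force_winner(cands, mode):
    """Independent oracle: one lexicographic sort over the active keys."""
    pool = [c for c in cands if not c.from_seqadv and c.target_accession != DUMMY_TARGET]
    if not pool:
        return None
    def key(c):
        parts = [-round(c.cov_id, 6)]
        if mode is CascadeMode.BINDING:
            parts += [-int(c.molecule_level or 0), c.n_site_mutations or 0]
        if any(x.target_type in _TYPE_RANK for x in pool):
            parts.append(_TYPE_RANK.get(c.target_type, 99))
        if mode is CascadeMode.BINDING:
            parts.append(-(c.n_unique_datapoints or 0))
        parts.append(c.target_numeric)
        return tuple(parts)
    return min(pool, key=key).target_accession


def random_candidates(rng, n):
    accs = rng.choice(np.arange(1, 40), size=n, replace=False)
    out = []
    for acc in accs:
        accession = DUMMY_TARGET if rng.random() < 0.08 else f"CHEMBL{acc}"
        out.append(cand(
            accession,
            cov_id=float(rng.choice([0.6, 0.8, 0.95, 1.0])),
            level=int(rng.integers(1, 6)),
            muts=int(rng.integers(0, 3)),
            ttype=TYPES[int(rng.integers(0, len(TYPES)))],
            points=int(rng.integers(1, 5)),
            seqadv=bool(rng.random() < 0.1),
        ))
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", [CascadeMode.BINDING, CascadeMode.TARGET])
    def test_matches_brute_force_on_random_sets(self, mode, rng):
        for _ in range(1000):
            cands = random_candidates(rng, int(rng.integers(1, 9)))
            w, audit = run_cascade(cands, mode)
            expected = brute_force_winner(cands, mode)
            got = w.target_accession if w else None
            assert got == expected
            # audit partitions the non-winning candidates
            removed = set(audit.removals)
            inputs = {c.target_accession for c in cands}
            assert removed | ({got} if got else set()) == inputs
            assert got not in removed

    def test_permutation_invariance(self, rng):
        for _ in range(200):
            cands = random_candidates(rng, int(rng.integers(2, 8)))
            w1, a1 = run_cascade(cands, CascadeMode.BINDING)
            perm = [cands[i] for i in rng.permutation(len(cands))]
            w2, a2 = run_cascade(perm, CascadeMode.BINDING)
            assert (w1.target_accession if w1 else None) == (
                w2.target_accession if w2 else None)
            assert a1.decided_at == a2.decided_at
            assert a1.removals == a2.removals


def aln(cov_id, identity=None, length=100, hit_id="CHEMBL1"):
    identity = identity if identity is not None else cov_id * 100
    coverage = 100.0 * cov_id / (identity / 100.0) if identity else 0.0
    return AlignmentResult(
        query_id="q", hit_id=hit_id, identity=identity, alignment_length=length,
        query_length=length, hit_length=length, coverage_query=coverage,
    )


class TestSelectBestAlignment:
    def test_single_alignment(self):
        a = aln(0.9)
        assert select_best_alignment([a]) is a

    def test_highest_cov_id_wins(self):
        lo, hi = aln(0.8), aln(0.9)
        assert select_best_alignment([lo, hi]) is hi

    def test_tie_broken_by_identity(self):
        a = aln(0.9, identity=97)
        b = aln(0.9, identity=96)
        assert select_best_alignment([b, a]) is a

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best_alignment([])
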