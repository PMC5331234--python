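"""Local alignment: worked example, bit scores, invariants, oracles."""

import itertools
import math
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from yfrag.align import (
    DEL,
    INS,
    MATCH,
    MISMATCH,
    LocalAlignment,
    ScoringScheme,
    bit_score,
    insertion_positions,
    local_align,
    query_coverage,
    rescore_trace,
)
from yfrag.resources import EV_YF1, hy4_record
from yfrag.synthetic import inject_errors

from oracle_utils import enumerate_local_score, make_reference_aligner

dna = st.text(alphabet="ACGT", min_size=1, max_size=25)


@pytest.fixture(scope="module")
def aln():
    return local_align(EV_YF1, hy4_record().sequence,
                       query_id="EV-YF1", ref_id="hY4")


class TestWorkedAlignment:
    """The printed 57-nt EV fragment against full-length hY4."""

    def test_identities_and_single_insertion(self, aln):
        assert aln.identities == 56
        assert aln.alignment_length == 57
        assert aln.query_gap_columns == 1
        assert aln.ref_gap_columns == 0
        assert aln.mismatches == 0

    def test_inserted_thymine_called_at_position_16(self, aln):
        assert insertion_positions(aln) == [16]
        assert EV_YF1[15] == "T"

    def test_bit_score_under_documented_constants(self, aln):
        assert aln.raw_score == 49
        assert aln.bit_score == pytest.approx(97.62, abs=0.01)


class TestScores:
    def test_identical_20mers_score_perfectly(self):
        a = local_align("ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT")
        assert (a.raw_score, a.identities, a.alignment_length) == (20, 20, 20)
        assert a.query_gap_columns == a.ref_gap_columns == 0

    def test_no_positive_pair_gives_empty_alignment(self):
        a = local_align("AAAA", "CCCC")
        assert a.raw_score == 0
        assert a.alignment_length == 0
        assert a.trace == ()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_n_never_counts_as_identity(self):
        a = local_align("ACGTN", "ACGTN")
        assert a.identities == 4

    @pytest.mark.parametrize(
        "raw,expected,tol",
        [(0, 0.492, 5e-4), (49, 97.62, 0.01)],
    )
    def test_bit_score_hand_calculations(self, raw, expected, tol):
        assert bit_score(raw) == pytest.approx(expected, abs=tol)

    def test_bit_score_strictly_increasing(self):
        assert bit_score(11) > bit_score(10)

    def test_bit_score_formula(self, scoring):
        for s in (0, 7, 23, 49):
            expected = (scoring.lam * s - math.log(scoring.K)) / math.log(2)
            assert bit_score(s, scoring) == expected


class TestCoverage:
    def test_full_and_partial_spans(self):
        full = local_align("ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT")
        assert query_coverage(full, 20) == 1.0
        frag = LocalAlignment(
            "q", "r", 10, bit_score(10), 10, 10, 0, 0, 0,
            query_span=(5, 15), ref_span=(0, 10), trace=(MATCH,) * 10,
        )
        assert query_coverage(frag, 20) == 0.5

    def test_invalid_query_length(self):
        a = local_align("ACGT", "ACGT")
        with pytest.raises(ValueError):
            query_coverage(a, 0)


class TestInsertionPositions:
    def test_gapless_alignment_has_none(self):
        a = local_align("ACGTACGTACGT", "ACGTACGTACGT")
        assert insertion_positions(a) == []

    @pytest.mark.parametrize("pos0", [10, 19, 28])
    @pytest.mark.parametrize("parent_idx", [0, 2])
    def test_unambiguous_interior_insertion_called_exactly(self, pos0, parent_idx,
                                                          hy_refs):
        """A base inserted in the fragment interior, differing from both
        neighbours, is called at exactly its 1-based position.  (Insertions
        within a few bases of a fragment end are legitimately absorbed by
        truncating the HSP instead: the gap costs more than the rescued
        matches.)"""
        parent = hy_refs[parent_idx]
        frag = parent.sequence[0:40]
        base = next(b for b in "ACGT" if b not in (frag[pos0 - 1], frag[pos0]))
        mutated = frag[:pos0] + base + frag[pos0:]
        aln = local_align(mutated, parent.sequence)
        assert insertion_positions(aln) == [pos0 + 1]

    @pytest.mark.parametrize("seed", range(8))
    def test_injected_insertion_removal_restores_parent_substring(self, seed,
                                                                  hy_refs):
        """For interior injected insertions the single called INS column,
        once removed, restores an exact parent substring."""
        rng = np.random.default_rng(seed)
        parent = hy_refs[seed % len(hy_refs)]
        frag = parent.sequence[0:40]
        while True:  # draw until the insertion lands >= 8 nt from both ends
            mutated, edits = inject_errors(frag, 0.0, 1.0, rng)
            p_true = edits[0][1]
            if 9 <= p_true <= len(mutated) - 8:
                break
        assert len(mutated) == len(frag) + 1
        aln = local_align(mutated, parent.sequence)
        called = insertion_positions(aln)
        assert len(called) == 1
        p = called[0]
        restored = mutated[: p - 1] + mutated[p:]
        assert restored in parent.sequence


class TestInvariants:
    @given(q=dna, r=dna)
    def test_column_counts_partition_alignment_length(self, q, r):
        a = local_align(q, r)
        assert (
            a.identities + a.mismatches + a.query_gap_columns + a.ref_gap_columns
            == a.alignment_length
        )
        q_cols = sum(op in (MATCH, MISMATCH, INS) for op in a.trace)
        r_cols = sum(op in (MATCH, MISMATCH, DEL) for op in a.trace)
        assert a.query_span[1] - a.query_span[0] == q_cols
        assert a.ref_span[1] - a.ref_span[0] == r_cols

    @given(q=dna, r=dna)
    def test_trace_rescoring_reproduces_raw_score(self, q, r):
        a = local_align(q, r)
        if a.alignment_length:
            assert rescore_trace(a.trace) == a.raw_score

    @given(q=dna, r=dna)
    def test_score_symmetry_under_swap(self, q, r):
        fwd = local_align(q, r)
        rev = local_align(r, q)
        assert fwd.raw_score == rev.raw_score
        assert fwd.query_gap_columns == rev.ref_gap_columns

    @given(q=dna, r=dna)
    def test_coverage_always_a_fraction(self, q, r):
        a = local_align(q, r)
        assert 0.0 <= query_coverage(a, len(q)) <= 1.0

    def test_percent_identity_matches_reported_rounding(self):
        a = local_align(EV_YF1, hy4_record().sequence)
        assert round(a.percent_identity) == 98


class TestOracle:
    def test_matches_enumeration_for_all_short_two_letter_pairs(self, scoring):
        """Exhaustive agreement with the enumeration oracle, lengths <= 5."""
        seqs = [
            "".join(t)
            for n in range(1, 6)
            for t in itertools.product("AC", repeat=n)
        ]
        for q in seqs:
            for r in seqs:
                expected = enumerate_local_score(q, r, scoring)
                assert local_align(q, r, scoring).raw_score == expected, (q, r)

    @given(q=dna, r=dna)
    def test_matches_independent_reference_aligner(self, q, r, scoring):
        """Cross-check against Biopython's C local aligner on random pairs."""
        al = make_reference_aligner(scoring)
        assert local_align(q, r, scoring).raw_score == max(0, int(al.score(q, r)))


def test_scoring_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(match=0)
    with pytest.raises(ValueError):
        ScoringScheme(mismatch=1)
    with pytest.raises(ValueError):
        ScoringScheme(gap_open=-1)
    assert ScoringScheme().gap_cost(3) == 5 + 3 * 2
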