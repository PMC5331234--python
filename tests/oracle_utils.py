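"""Independent scoring oracles shared by the alignment test modules."""

from functools import lru_cache

from yfrag.align import ScoringScheme


def enumerate_local_score(q: str, r: str, sc: ScoringScheme) -> int:
    """Best local alignment score by explicit enumeration of all monotone
    alignments (every start point, every gap placement), memoised on
    (position, position, previous op).  Independent of the production DP:
    top-down, allows alignments that start or end with gap columns (these
    are never optimal, so the optimum agrees)."""

    first = sc.gap_open + sc.gap_extend

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, last: str) -> int:
        best = 0  # stopping here is always allowed
        if i < len(q) and j < len(r):
            s = sc.match if q[i] == r[j] else sc.mismatch
            best = max(best, s + ext(i + 1, j + 1, "M"))
        if i < len(q):
            best = max(
                best, -(sc.gap_extend if last == "I" else first) + ext(i + 1, j, "I")
            )
        if j < len(r):
            best = max(
                best, -(sc.gap_extend if last == "D" else first) + ext(i, j + 1, "D")
            )
        return best

    return max(ext(i, j, "start") for i in range(len(q)) for j in range(len(r)))


def make_reference_aligner(sc: ScoringScheme):
    """Biopython local aligner configured to the same affine scheme
    (first gap base costs open+extend, each further base extend)."""
    from Bio import Align

    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = sc.match
    al.mismatch_score = sc.mismatch
    al.open_gap_score = -(sc.gap_open + sc.gap_extend)
    al.extend_gap_score = -sc.gap_extend
    return al
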