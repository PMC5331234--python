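"""Y RNA fragment analysis.

Reads annotated as Y RNA are collapsed to distinct fragment sequences, each
fragment is re-aligned against the four full-length hY genes to assign a
parent, the fragment's end of origin (5' vs 3') is classified from where
its best alignment sits on the parent, and length / parent-composition
summaries are produced.

End-of-origin rule: a fragment is 5'-derived iff the midpoint of its aligned
reference span lies in the 5' half of the parent (midpoint strictly less
than half the parent length; an exact tie also goes 5').  The rule is
parameter-free and exact on fragments anchored at a terminus that are
shorter than half their parent — longer fragments necessarily straddle the
midpoint and their label follows the side holding most of the alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .align import (
    LocalAlignment,
    ScoringScheme,
    insertion_positions,
    local_align,
)
from .annotate import ANNOTATED, ReadAnnotation
from .io_formats import ConfigurationError, RefSeqRecord, SmallRead, write_tsv_report

FIVE_PRIME = "FIVE_PRIME"
THREE_PRIME = "THREE_PRIME"


@dataclass(frozen=True)
class YFragmentRecord:
    """A distinct Y-derived fragment sequence with its classification."""

    sequence: str
    read_count: int
    parent_id: str
    end_origin: str
    ref_span: tuple[int, int]  # 0-based half-open on the parent
    insertions: tuple[int, ...]  # 1-based fragment positions

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ParentComposition:
    percentages: dict[str, float]
    weight_by: str


def collapse_fragments(
    y_reads: Sequence[tuple[SmallRead, ReadAnnotation]],
) -> list[tuple[str, int]]:
    """Collapse Y-annotated reads to distinct sequences with multiplicities.

    Output sorted by descending read count, then lexicographic sequence.
    """
    counts: Counter[str] = Counter()
    for read, ann in y_reads:
        if ann.status != ANNOTATED or ann.biotype != "Y_RNA":
            raise ValueError(
                f"read {read.id!r} is not an annotated Y RNA read "
                f"(status={ann.status}, biotype={ann.biotype})"
            )
        counts[read.sequence] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def assign_parent(
    fragment: str,
    hy_refs: Sequence[RefSeqRecord],
    scoring: ScoringScheme | None = None,
) -> tuple[str, LocalAlignment]:
    """Best-scoring parent hY gene for a fragment sequence.

    Ties break to more identities, then the lexicographically smallest id.
    """
    if not hy_refs:
        raise ConfigurationError("no parent references supplied")
    scoring = scoring or ScoringScheme()
    best: tuple[int, int, str] | None = None
    best_aln: LocalAlignment | None = None
    best_id: str | None = None
    for ref in hy_refs:
        aln = local_align(fragment, ref.sequence, scoring,
                          query_id="fragment", ref_id=ref.id)
        key = (aln.raw_score, aln.identities, ref.id)
        if (
            best is None
            or key[0] > best[0]
            or (key[0] == best[0] and key[1] > best[1])
            or (key[0] == best[0] and key[1] == best[1] and key[2] < best[2])
        ):
            best, best_aln, best_id = key, aln, ref.id
    assert best_id is not None and best_aln is not None
    return best_id, best_aln


def classify_end(aln: LocalAlignment, parent_length: int) -> str:
    """5' vs 3' end of origin from the aligned span's midpoint."""
    lo, hi = aln.ref_span
    if not (0 <= lo <= hi <= parent_length):
        raise ValueError(f"ref span {aln.ref_span} outside [0, {parent_length}]")
    midpoint = (lo + hi) / 2.0
    return FIVE_PRIME if midpoint <= parent_length / 2.0 else THREE_PRIME


def build_fragment_records(
    collapsed: Sequence[tuple[str, int]],
    hy_refs: Sequence[RefSeqRecord],
    scoring: ScoringScheme | None = None,
) -> list[YFragmentRecord]:
    """Classify each distinct fragment: parent, end origin, span, insertions."""
    by_id = {r.id: r for r in hy_refs}
    records: list[YFragmentRecord] = []
    for seq, count in collapsed:
        parent_id, aln = assign_parent(seq, hy_refs, scoring)
        records.append(
            YFragmentRecord(
                sequence=seq,
                read_count=count,
                parent_id=parent_id,
                end_origin=classify_end(aln, by_id[parent_id].length),
                ref_span=aln.ref_span,
                insertions=tuple(insertion_positions(aln)),
            )
        )
    return records


def length_distribution(
    fragments: Iterable[YFragmentRecord],
) -> tuple[dict[int, int], tuple[int, int] | None]:
    """Histogram of distinct-fragment lengths plus the observed (min, max)."""
    hist: Counter[int] = Counter()
    for frag in fragments:
        hist[frag.length] += 1
    if not hist:
        return {}, None
    return dict(sorted(hist.items())), (min(hist), max(hist))


def _weights(fragments: Sequence[YFragmentRecord], weight_by: str) -> list[float]:
    if weight_by == "fragments":
        return [1.0] * len(fragments)
    if weight_by == "reads":
        return [float(f.read_count) for f in fragments]
    raise ValueError(f"weight_by must be 'fragments' or 'reads', got {weight_by!r}")


def parent_composition(
    fragments: Sequence[YFragmentRecord], weight_by: str = "fragments"
) -> ParentComposition:
    """Percent of fragments (or reads) attributed to each parent gene."""
    w = _weights(fragments, weight_by)
    total = sum(w)
    acc: dict[str, float] = {}
    for frag, wt in zip(fragments, w):
        acc[frag.parent_id] = acc.get(frag.parent_id, 0.0) + wt
    percentages = {p: 100.0 * v / total for p, v in acc.items()} if total else {}
    return ParentComposition(percentages=percentages, weight_by=weight_by)


def end_origin_proportions(
    fragments: Sequence[YFragmentRecord], weight_by: str = "fragments"
) -> dict[str, float]:
    """Fraction of fragments (or reads) derived from each end."""
    w = _weights(fragments, weight_by)
    total = sum(w)
    if not total:
        return {}
    five = sum(wt for frag, wt in zip(fragments, w) if frag.end_origin == FIVE_PRIME)
    return {FIVE_PRIME: five / total, THREE_PRIME: (total - five) / total}


FRAGMENT_COLUMNS = (
    "sequence",
    "length",
    "read_count",
    "parent_id",
    "end_origin",
    "ref_start",
    "ref_end",
    "insertions",
)


def write_fragment_table(
    fragments: Sequence[YFragmentRecord], path: str | Path
) -> None:
    """Fragment table TSV; reference spans rendered 1-based inclusive."""
    rows = [
        {
            "sequence": f.sequence,
            "length": f.length,
            "read_count": f.read_count,
            "parent_id": f.parent_id,
            "end_origin": f.end_origin,
            "ref_start": f.ref_span[0] + 1,
            "ref_end": f.ref_span[1],
            "insertions": ",".join(str(p) for p in f.insertions),
        }
        for f in fragments
    ]
    write_tsv_report(rows, path, columns=list(FRAGMENT_COLUMNS))
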