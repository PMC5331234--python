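"""Read annotation: length filter, best-hit assignment, class profiling.

The stage mirrors a small-RNA EV-cargo workflow: reads shorter than 15 nt
are excluded, each remaining read is aligned to every reference, and the
read is annotated with the class of its best hit only when the best HSP
covers strictly more than 75% of the read.  Best hit means maximum bit
score; ties go to more identity columns, then the lexicographically
smallest reference id, so annotation is deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .align import LocalAlignment, ScoringScheme, local_align, query_coverage
from .io_formats import ConfigurationError, RefSeqRecord, SmallRead, write_tsv_report

ANNOTATED = "ANNOTATED"
UNANNOTATED = "UNANNOTATED"
FILTERED_SHORT = "FILTERED_SHORT"


@dataclass(frozen=True)
class AnnotationConfig:
    min_read_length: int = 15
    coverage_threshold: float = 0.75  # strict: coverage must exceed this
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        if self.min_read_length < 1:
            raise ValueError("min_read_length must be >= 1")
        if not (0.0 < self.coverage_threshold < 1.0):
            raise ValueError("coverage_threshold must be in (0, 1)")


@dataclass(frozen=True)
class ReadAnnotation:
    read_id: str
    status: str
    ref_id: str | None
    biotype: str | None
    coverage: float
    alignment: LocalAlignment | None


@dataclass(frozen=True)
class ClassProfile:
    """Class composition of the annotated fraction of a library.

    Percentages are over ANNOTATED reads only; unannotated and
    length-filtered reads are tallied separately.
    """

    counts: dict[str, int]
    percentages: dict[str, float]
    total_annotated: int
    total_unannotated: int
    total_filtered: int


def filter_short_reads(
    reads: Sequence[SmallRead], config: AnnotationConfig | None = None
) -> tuple[list[SmallRead], int]:
    """Drop reads shorter than the minimum length; order preserved."""
    config = config or AnnotationConfig()
    kept = [r for r in reads if r.length >= config.min_read_length]
    return kept, len(reads) - len(kept)


def annotate_read(
    read: SmallRead,
    refdb: Sequence[RefSeqRecord],
    config: AnnotationConfig | None = None,
) -> ReadAnnotation:
    """Best-hit annotation of one length-filtered read.

    Aligns the read against every reference, keeps the single best HSP,
    and annotates iff its query coverage strictly exceeds the threshold.
    """
    config = config or AnnotationConfig()
    if not refdb:
        raise ConfigurationError("reference database is empty")

    best: tuple[int, int, str] | None = None  # (raw, identities, id) for tie-break
    best_ref: RefSeqRecord | None = None
    best_aln: LocalAlignment | None = None
    for ref in refdb:
        aln = local_align(
            read.sequence, ref.sequence, config.scoring,
            query_id=read.id, ref_id=ref.id,
        )
        key = (aln.raw_score, aln.identities, ref.id)
        if (
            best is None
            or key[0] > best[0]
            or (key[0] == best[0] and key[1] > best[1])
            or (key[0] == best[0] and key[1] == best[1] and key[2] < best[2])
        ):
            best, best_ref, best_aln = key, ref, aln

    assert best_aln is not None and best_ref is not None
    cov = query_coverage(best_aln, read.length)
    if cov > config.coverage_threshold:
        return ReadAnnotation(read.id, ANNOTATED, best_ref.id, best_ref.biotype,
                              cov, best_aln)
    return ReadAnnotation(read.id, UNANNOTATED, None, None, cov, best_aln)


def annotate_reads(
    reads: Sequence[SmallRead],
    refdb: Sequence[RefSeqRecord],
    config: AnnotationConfig | None = None,
) -> list[ReadAnnotation]:
    """Annotate a whole library, including the length-filter stage.

    Every input read gets exactly one status (FILTERED_SHORT, ANNOTATED or
    UNANNOTATED) in input order.
    """
    config = config or AnnotationConfig()
    out: list[ReadAnnotation] = []
    for read in reads:
        if read.length < config.min_read_length:
            out.append(ReadAnnotation(read.id, FILTERED_SHORT, None, None, 0.0, None))
        else:
            out.append(annotate_read(read, refdb, config))
    return out


def profile_classes(annotations: Iterable[ReadAnnotation]) -> ClassProfile:
    """Class composition over the annotated reads (pie-chart numbers)."""
    counts: Counter[str] = Counter()
    n_un = n_filt = 0
    for ann in annotations:
        if ann.status == ANNOTATED:
            counts[ann.biotype] += 1
        elif ann.status == UNANNOTATED:
            n_un += 1
        elif ann.status == FILTERED_SHORT:
            n_filt += 1
        else:  # pragma: no cover
            raise ValueError(f"unknown status {ann.status!r}")
    total = sum(counts.values())
    percentages = (
        {b: 100.0 * c / total for b, c in counts.items()} if total else {}
    )
    return ClassProfile(
        counts=dict(counts),
        percentages=percentages,
        total_annotated=total,
        total_unannotated=n_un,
        total_filtered=n_filt,
    )


ANNOTATION_COLUMNS = ("read_id", "status", "ref_id", "biotype", "coverage", "bit_score")


def annotation_report_rows(annotations: Sequence[ReadAnnotation]) -> list[dict[str, object]]:
    return [
        {
            "read_id": a.read_id,
            "status": a.status,
            "ref_id": a.ref_id or "",
            "biotype": a.biotype or "",
            "coverage": a.coverage,
            "bit_score": a.alignment.bit_score if a.alignment else 0.0,
        }
        for a in annotations
    ]


def write_annotation_report(annotations: Sequence[ReadAnnotation], path: str | Path) -> None:
    write_tsv_report(annotation_report_rows(annotations), path,
                     columns=list(ANNOTATION_COLUMNS))


def write_class_profile(profile: ClassProfile, path: str | Path) -> None:
    rows = [
        {
            "biotype": b,
            "reads": profile.counts[b],
            "percent": profile.percentages[b],
        }
        for b in sorted(profile.counts)
    ]
    write_tsv_report(rows, path, columns=["biotype", "reads", "percent"])
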