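"""Two-library fragment comparison and donor-potency statistics.

The inventory comparison is exact set arithmetic on fragment sequence
strings (the Venn of unique/shared fragments between two EV sources), plus
per-fragment fold enrichment of read counts and abundance ranking.  The
potency analysis groups EV donors by the sign of their post-infarct change
in ejection fraction (dEF%) and relates a chosen fragment's abundance to
that functional outcome with a rank (default) or linear correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from scipy import stats

from .io_formats import write_tsv_report

FragmentTable = Sequence[tuple[str, int]]  # collapse_fragments output


@dataclass(frozen=True)
class LibraryComparison:
    unique_to_a: frozenset[str]
    unique_to_b: frozenset[str]
    shared: frozenset[str]
    counts_a: dict[str, int]
    counts_b: dict[str, int]


@dataclass(frozen=True)
class PotencyRecord:
    """One EV donor: ejection-fraction change (dEF%) and fragment abundance."""

    donor_id: str
    delta_ef: float
    abundance: float

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")


@dataclass(frozen=True)
class PotencyCorrelation:
    coefficient: float  # NaN when undefined (zero variance)
    method: str
    potent_mean: float  # mean abundance, potent group (NaN if group empty)
    non_potent_mean: float
    undefined: bool


def compare_libraries(a: FragmentTable, b: FragmentTable) -> LibraryComparison:
    """Exact unique/shared set arithmetic between two fragment tables."""
    counts_a = dict(a)
    counts_b = dict(b)
    set_a, set_b = set(counts_a), set(counts_b)
    return LibraryComparison(
        unique_to_a=frozenset(set_a - set_b),
        unique_to_b=frozenset(set_b - set_a),
        shared=frozenset(set_a & set_b),
        counts_a=counts_a,
        counts_b=counts_b,
    )


def fold_enrichment(
    sequence: str,
    comparison: LibraryComparison,
    normalization: str = "raw",
    pseudocount: float = 1.0,
) -> float:
    """(count_A + pseudocount) / (count_B + pseudocount), optionally per-million.

    The default pseudocount of 1 keeps fragments absent from one library at
    a finite enrichment.
    """
    if sequence not in comparison.counts_a and sequence not in comparison.counts_b:
        raise ValueError(f"sequence absent from both libraries: {sequence!r}")
    if normalization not in {"raw", "per_million"}:
        raise ValueError(f"unknown normalization {normalization!r}")
    c_a = float(comparison.counts_a.get(sequence, 0))
    c_b = float(comparison.counts_b.get(sequence, 0))
    if normalization == "per_million":
        tot_a = sum(comparison.counts_a.values())
        tot_b = sum(comparison.counts_b.values())
        if tot_a == 0 or tot_b == 0:
            raise ValueError("per-million scaling requires non-empty libraries")
        c_a *= 1e6 / tot_a
        c_b *= 1e6 / tot_b
    return (c_a + pseudocount) / (c_b + pseudocount)


def rank_fragments(lib: FragmentTable, n: int) -> list[tuple[str, int]]:
    """Top ``n`` fragments by read count; ties lexicographic; deterministic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(lib, key=lambda kv: (-kv[1], kv[0]))
    return ordered[:n]


def split_by_potency(
    records: Sequence[PotencyRecord],
) -> tuple[list[PotencyRecord], list[PotencyRecord]]:
    """Potent iff dEF% > 0 (a zero change counts as non-potent)."""
    potent = [r for r in records if r.delta_ef > 0]
    non_potent = [r for r in records if r.delta_ef <= 0]
    return potent, non_potent


def correlate_abundance_potency(
    records: Sequence[PotencyRecord], method: str = "spearman"
) -> PotencyCorrelation:
    """Correlate fragment abundance with dEF% across donors.

    Spearman by default (robust at the handful-of-donors scale this models).
    With zero variance in either variable the coefficient is undefined (NaN,
    flagged) but the group means are still reported.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 donor records")
    if method not in {"spearman", "pearson"}:
        raise ValueError(f"unknown method {method!r}")
    potent, non_potent = split_by_potency(records)
    pmean = (
        sum(r.abundance for r in potent) / len(potent) if potent else math.nan
    )
    npmean = (
        sum(r.abundance for r in non_potent) / len(non_potent)
        if non_potent
        else math.nan
    )
    x = [r.abundance for r in records]
    y = [r.delta_ef for r in records]
    if len(set(x)) < 2 or len(set(y)) < 2:
        return PotencyCorrelation(math.nan, method, pmean, npmean, undefined=True)
    if method == "spearman":
        coef = float(stats.spearmanr(x, y).statistic)
    else:
        coef = float(stats.pearsonr(x, y).statistic)
    return PotencyCorrelation(coef, method, pmean, npmean, undefined=False)


COMPARISON_COLUMNS = ("sequence", "count_a", "count_b", "membership", "fold_enrichment")


def comparison_rows(
    comparison: LibraryComparison,
    normalization: str = "raw",
    pseudocount: float = 1.0,
) -> list[dict[str, object]]:
    """Stable-ordered comparison table (shared first, by descending count_a)."""
    rows = []
    for seq in sorted(
        comparison.shared | comparison.unique_to_a | comparison.unique_to_b,
        key=lambda s: (
            -(comparison.counts_a.get(s, 0) + comparison.counts_b.get(s, 0)),
            s,
        ),
    ):
        if seq in comparison.shared:
            membership = "shared"
        elif seq in comparison.unique_to_a:
            membership = "unique_to_a"
        else:
            membership = "unique_to_b"
        rows.append(
            {
                "sequence": seq,
                "count_a": comparison.counts_a.get(seq, 0),
                "count_b": comparison.counts_b.get(seq, 0),
                "membership": membership,
                "fold_enrichment": fold_enrichment(
                    seq, comparison, normalization, pseudocount
                ),
            }
        )
    return rows


def write_comparison_table(
    comparison: LibraryComparison,
    path: str | Path,
    normalization: str = "raw",
    pseudocount: float = 1.0,
) -> None:
    write_tsv_report(
        comparison_rows(comparison, normalization, pseudocount),
        path,
        columns=list(COMPARISON_COLUMNS),
    )


def write_potency_table(
    records: Sequence[PotencyRecord], result: PotencyCorrelation, path: str | Path
) -> None:
    rows: list[dict[str, object]] = [
        {
            "donor_id": r.donor_id,
            "delta_ef_percent": r.delta_ef,
            "abundance": r.abundance,
            "group": "potent" if r.delta_ef > 0 else "non_potent",
        }
        for r in records
    ]
    write_tsv_report(
        rows, path, columns=["donor_id", "delta_ef_percent", "abundance", "group"]
    )
    summary_path = Path(path).with_name(Path(path).stem + "_summary.tsv")
    write_tsv_report(
        [
            {
                "method": result.method,
                "coefficient": result.coefficient,
                "potent_mean_abundance": result.potent_mean,
                "non_potent_mean_abundance": result.non_potent_mean,
                "undefined": result.undefined,
            }
        ],
        summary_path,
        columns=[
            "method",
            "coefficient",
            "potent_mean_abundance",
            "non_potent_mean_abundance",
            "undefined",
        ],
    )
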