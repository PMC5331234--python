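"""Readers and writers for the formats the pipeline touches.

Sequence input is FASTA or FASTQ (Sanger qualities, ignored); references are
FASTA plus a tab-separated biotype table; every report the pipeline emits is
TSV.  All sequences are normalised on load to an uppercase DNA alphabet:
RNA inputs are mapped U->T so printed oligoribonucleotides and genomic
reference entries live in one alphabet.  ``N`` is retained but never counts
as an identity downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

#: Controlled vocabulary for reference classes.
BIOTYPES = frozenset({"Y_RNA", "tRNA", "rRNA", "miRNA", "lncRNA", "other"})

_ALLOWED = frozenset("ACGTN")
_NORMALISE = str.maketrans("acgtunU", "ACGTTNT")


class ParseError(ValueError):
    """A sequence file or table could not be parsed."""


class ConfigurationError(ValueError):
    """Inputs are structurally valid but inconsistent with each other."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map U to T.

    Idempotent.  Raises :class:`ParseError` on characters outside
    ``{A,C,G,T,U,N}`` (case-insensitive).
    """
    out = seq.strip().translate(_NORMALISE)
    bad = set(out) - _ALLOWED
    if bad:
        raise ParseError(f"sequence contains unsupported characters: {sorted(bad)!r}")
    return out


@dataclass(frozen=True)
class SmallRead:
    """One small-RNA read (15-200 nt in the assays this package models)."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RefSeqRecord:
    """A reference ncRNA sequence with its class label.

    ``accession`` carries the external identifier (GenBank / RNAcentral) and
    may be empty for synthetic references.
    """

    id: str
    accession: str
    biotype: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ConfigurationError(f"reference {self.id!r} has an empty sequence")
        if self.biotype not in BIOTYPES:
            raise ConfigurationError(
                f"reference {self.id!r} has unknown biotype {self.biotype!r}; "
                f"expected one of {sorted(BIOTYPES)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def _detect_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                return "fasta"
            if s.startswith("@"):
                return "fastq"
            raise ParseError(
                f"{path}: cannot detect format from first character {s[0]!r}"
            )
    return "fasta"  # empty file: parses to an empty list either way


def read_sequences(path: str | Path, format_hint: str = "auto") -> list[SmallRead]:
    """Read a FASTA/FASTQ file into a list of normalised reads.

    ``format_hint`` is ``auto`` (detect from the first non-blank character),
    ``fasta`` or ``fastq``.  Record order is preserved; qualities are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint not in {"auto", "fasta", "fastq"}:
        raise ValueError(f"unknown format hint {format_hint!r}")
    fmt = _detect_format(path) if format_hint == "auto" else format_hint

    reads: list[SmallRead] = []
    try:
        for idx, rec in enumerate(SeqIO.parse(str(path), fmt)):
            try:
                seq = normalize_sequence(str(rec.seq))
            except ParseError as exc:
                raise ParseError(f"{path}: record {idx} ({rec.id!r}): {exc}") from exc
            reads.append(SmallRead(id=rec.id, sequence=seq))
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(
            f"{path}: malformed {fmt} near record {len(reads)}: {exc}"
        ) from exc
    return reads


def write_fasta(records: Iterable[SmallRead | RefSeqRecord], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA, one sequence per line."""
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def load_reference_db(
    fasta_path: str | Path, biotype_path: str | Path
) -> list[RefSeqRecord]:
    """Load a reference FASTA plus its biotype table.

    The table is TSV with a ``id<TAB>biotype<TAB>accession`` header.  Every
    FASTA id must appear in the table and carry a known biotype; duplicated
    FASTA ids are rejected.
    """
    table: dict[str, tuple[str, str]] = {}
    with open(biotype_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["id", "biotype"]:
            raise ConfigurationError(
                f"{biotype_path}: expected header starting 'id\\tbiotype', got {header!r}"
            )
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rid, biotype = parts[0], parts[1]
            accession = parts[2] if len(parts) > 2 else ""
            table[rid] = (biotype, accession)

    records: list[RefSeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ConfigurationError(f"{fasta_path}: duplicated FASTA id {rec.id!r}")
        seen.add(rec.id)
        if rec.id not in table:
            raise ConfigurationError(
                f"{fasta_path}: id {rec.id!r} missing from biotype table {biotype_path}"
            )
        biotype, accession = table[rec.id]
        records.append(
            RefSeqRecord(
                id=rec.id,
                accession=accession,
                biotype=biotype,
                sequence=normalize_sequence(str(rec.seq)),
            )
        )
    return records


def write_reference_db(
    records: Sequence[RefSeqRecord], fasta_path: str | Path, biotype_path: str | Path
) -> None:
    """Materialise a reference set as FASTA + biotype TSV (inverse of load)."""
    write_fasta(records, fasta_path)
    with open(biotype_path, "w", newline="\n") as fh:
        fh.write("id\tbiotype\taccession\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.biotype}\t{rec.accession}\n")


def _render(value: object) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def write_tsv_report(rows: Sequence[Mapping[str, object]], path: str | Path,
                     columns: Sequence[str] | None = None) -> None:
    """Write flat records as a TSV report.

    All rows must share one field set.  Floats are rendered with 6
    significant digits; lines end with ``\\n``.  An empty row list with
    explicit ``columns`` yields a header-only file.
    """
    if columns is None:
        if not rows:
            raise ValueError("cannot infer columns from an empty row list")
        columns = list(rows[0].keys())
    for i, row in enumerate(rows):
        if set(row.keys()) != set(columns):
            raise ValueError(f"row {i} fields {sorted(row)} != header {sorted(columns)}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_render(row[c]) for c in columns) + "\n")


def read_tsv_report(path: str | Path) -> list[dict[str, str]]:
    """Read a TSV report back as a list of string-valued records."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        out = []
        for line in fh:
            if line.strip() == "":
                continue
            out.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return out
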