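"""Synthetic small-RNA libraries with ground truth.

Generates reference sets and read libraries with the statistical structure
the downstream analysis assumes, so every stage is testable without any
sequencing download:

* a mixture of ncRNA classes (Y RNA, tRNA, rRNA, miRNA, other) with
  configurable proportions;
* fragments cut from parent references, 15-62 nt, anchored exactly at the
  5' or 3' terminus (5' with configurable bias for the Y class, reflecting
  the observed dominance of 5'-derived Y fragments in EV cargo);
* one dominant Y parent gene (hY4 by default, ~85% of fragments);
* per-base substitution and at most one per-read single-base insertion —
  the one edit class documented in the EV-YF1/hY4 worked alignment;
* a heavy-tailed (discrete power-law / Zipf) per-fragment abundance law so
  identical fragments recur across reads.

Every read carries a :class:`TruthRecord`, and generation is byte-for-byte
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .compare import PotencyRecord
from .io_formats import (
    ConfigurationError,
    RefSeqRecord,
    SmallRead,
    read_tsv_report,
    write_tsv_report,
)
from .resources import hy_reference_records
from .yrna import FIVE_PRIME, THREE_PRIME

_BASES = "ACGT"

#: Default class mixture (Y RNA prominent but tRNA-dominated, as in EV cargo).
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "Y_RNA": 0.20,
    "tRNA": 0.50,
    "rRNA": 0.20,
    "miRNA": 0.05,
    "other": 0.05,
}

#: Default Y-parent mixture: one dominant parent gene.
DEFAULT_PARENT_WEIGHTS: dict[str, float] = {
    "hY4": 0.85,
    "hY1": 0.05,
    "hY3": 0.05,
    "hY5": 0.05,
}

#: Reference length ranges per class (nt), loosely realistic for small ncRNA.
DEFAULT_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "Y_RNA": (83, 112),
    "tRNA": (70, 90),
    "rRNA": (120, 200),
    "miRNA": (60, 80),
    "lncRNA": (150, 200),
    "other": (60, 120),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic library.

    ``abundance_shape`` is the Zipf exponent over distinct fragments
    (larger = steeper ranking); ``fragments_per_class`` bounds the number
    of distinct fragments the library draws reads from.
    """

    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    n_reads: int = 10_000
    parent_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARENT_WEIGHTS)
    )
    five_prime_bias: float = 0.8
    fragment_len_min: int = 15
    fragment_len_max: int = 62
    sub_rate: float = 0.005
    ins_rate: float = 0.01
    abundance_shape: float = 1.5
    fragments_per_class: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if any(not (0.0 <= p <= 1.0) for p in self.class_proportions.values()):
            raise ValueError("class proportions must lie in [0, 1]")
        ptot = sum(self.parent_weights.values())
        if abs(ptot - 1.0) > 1e-9:
            raise ValueError(f"parent weights sum to {ptot}, not 1")
        if not (0.0 <= self.five_prime_bias <= 1.0):
            raise ValueError("five_prime_bias must lie in [0, 1]")
        if self.fragment_len_min < 15:
            raise ValueError("fragment_len_min must be >= 15")
        if self.fragment_len_max < self.fragment_len_min:
            raise ValueError("fragment_len_max must be >= fragment_len_min")
        if not (0.0 <= self.sub_rate <= 1.0 and 0.0 <= self.ins_rate <= 1.0):
            raise ValueError("error rates must lie in [0, 1]")
        if self.abundance_shape <= 0:
            raise ValueError("abundance_shape must be positive")
        if self.n_reads < 0 or self.fragments_per_class < 1:
            raise ValueError("n_reads must be >= 0 and fragments_per_class >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth label for one simulated read."""

    read_id: str
    true_class: str
    parent_id: str
    end_origin: str  # FIVE_PRIME or THREE_PRIME
    ref_span: tuple[int, int]  # 0-based half-open on the parent
    fragment_sequence: str  # error-free fragment the read was derived from
    edits: tuple[tuple[str, int], ...]  # (op, 1-based final-seq position)


@dataclass(frozen=True)
class FragmentSpec:
    """One distinct fragment in a library's abundance pool."""

    sequence: str
    parent_id: str
    end_origin: str
    ref_span: tuple[int, int]


def make_reference_set(
    n_per_class: Mapping[str, int],
    length_range: Mapping[str, tuple[int, int]] | None = None,
    seed: int = 0,
    include: Sequence[RefSeqRecord] = (),
) -> list[RefSeqRecord]:
    """Random uniform-composition reference sequences, one id per class+index.

    ``include`` prepends real records (e.g. the four hY genes) ahead of the
    generated ones.  Deterministic for a given seed.
    """
    length_range = length_range or DEFAULT_LENGTH_RANGES
    rng = np.random.default_rng(seed)
    records = list(include)
    for biotype in sorted(n_per_class):
        count = n_per_class[biotype]
        if count < 0:
            raise ValueError(f"negative count for {biotype!r}")
        lo, hi = length_range[biotype]
        if lo < 20:
            raise ValueError("reference length minimum must be >= 20 nt")
        for k in range(count):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
            records.append(
                RefSeqRecord(
                    id=f"{biotype}_{k:03d}", accession="", biotype=biotype, sequence=seq
                )
            )
    return records


def default_reference_set(seed: int = 0) -> list[RefSeqRecord]:
    """The four real hY genes plus random references for the other classes."""
    return make_reference_set(
        {"tRNA": 6, "rRNA": 4, "miRNA": 4, "other": 3},
        seed=seed,
        include=hy_reference_records(),
    )


def inject_errors(
    sequence: str,
    sub_rate: float,
    ins_rate: float,
    rng: np.random.Generator,
) -> tuple[str, tuple[tuple[str, int], ...]]:
    """Apply the error channel to one fragment.

    Each base substitutes independently with ``sub_rate`` (to a uniformly
    drawn different base); with probability ``ins_rate`` exactly one base is
    inserted at a uniform 1-based position.  Edit positions are reported in
    final-sequence coordinates, ascending.
    """
    if not (0.0 <= sub_rate <= 1.0 and 0.0 <= ins_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    seq = list(sequence)
    sub_pos: list[int] = []  # 0-based, pre-insertion coordinates
    for i in range(len(seq)):
        if rng.random() < sub_rate:
            others = _BASES.replace(seq[i], "") if seq[i] in _BASES else _BASES
            seq[i] = others[int(rng.integers(0, len(others)))]
            sub_pos.append(i)
    edits: list[tuple[str, int]] = []
    if rng.random() < ins_rate:
        p = int(rng.integers(1, len(seq) + 2))  # 1-based final position
        base = _BASES[int(rng.integers(0, 4))]
        seq.insert(p - 1, base)
        for i in sub_pos:
            edits.append(("SUB", i + 1 if i + 1 < p else i + 2))
        edits.append(("INS", p))
    else:
        edits = [("SUB", i + 1) for i in sub_pos]
    edits.sort(key=lambda e: e[1])
    return "".join(seq), tuple(edits)


def _zipf_weights(n: int, shape: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-shape)
    return w / w.sum()


def build_fragment_pools(
    refset: Sequence[RefSeqRecord],
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, list[FragmentSpec]]:
    """Draw the distinct-fragment pool for each class with nonzero proportion.

    Fragments are end-anchored: a 5'-origin fragment starts at parent
    position 0, a 3'-origin fragment ends at the parent terminus.  The
    number of pool slots per parent is drawn first (so the distinct-fragment
    parent composition is binomial around ``parent_weights``), then each
    slot samples an unused (end, length) span of its parent — without
    replacement, so the pool never silently re-weights toward minor parents
    when a dominant parent's distinct-fragment space is small.  Pools are
    deduplicated on the fragment sequence string and shuffled before the
    abundance ranks are assigned downstream.
    """
    by_class: dict[str, list[RefSeqRecord]] = {}
    for rec in refset:
        by_class.setdefault(rec.biotype, []).append(rec)

    pools: dict[str, list[FragmentSpec]] = {}
    for biotype in sorted(config.class_proportions):
        prop = config.class_proportions[biotype]
        if prop == 0.0:
            continue
        refs = by_class.get(biotype, [])
        if not refs:
            raise ConfigurationError(
                f"class {biotype!r} has proportion {prop} but no reference sequences"
            )
        if biotype == "Y_RNA":
            usable = [(r, config.parent_weights.get(r.id, 0.0)) for r in refs]
            wsum = sum(w for _, w in usable)
            if wsum <= 0:
                # parent_weights name no reference present: fall back to uniform
                usable = [(r, 1.0) for r in refs]
                wsum = float(len(refs))
            parents = [r for r, _ in usable]
            pweights = np.array([w / wsum for _, w in usable])
        else:
            parents = refs
            pweights = np.full(len(refs), 1.0 / len(refs))

        bias = config.five_prime_bias if biotype == "Y_RNA" else 0.5
        slot_draws = rng.choice(len(parents), size=config.fragments_per_class,
                                p=pweights)
        slot_counts = np.bincount(slot_draws, minlength=len(parents))

        specs: list[FragmentSpec] = []
        seen: set[str] = set()
        for p_idx, n_slots in enumerate(slot_counts):
            if n_slots == 0:
                continue
            parent = parents[p_idx]
            lmax = min(config.fragment_len_max, parent.length)
            lmin = min(config.fragment_len_min, lmax)
            lengths = np.arange(lmin, lmax + 1)
            five = [(0, int(L)) for L in rng.permutation(lengths)]
            three = [(parent.length - int(L), parent.length)
                     for L in rng.permutation(lengths)]
            for _ in range(int(n_slots)):
                primary, secondary = (
                    (five, three) if rng.random() < bias else (three, five)
                )
                source = primary if primary else secondary
                if not source:
                    break  # parent's distinct-fragment space exhausted
                span = source.pop()
                end = FIVE_PRIME if span[0] == 0 else THREE_PRIME
                seq = parent.sequence[span[0] : span[1]]
                if seq in seen:
                    continue
                seen.add(seq)
                specs.append(FragmentSpec(seq, parent.id, end, span))
        pools[biotype] = [specs[i] for i in rng.permutation(len(specs))]
    return pools


def _simulate_from_pools(
    pools: Mapping[str, list[FragmentSpec]],
    weights: Mapping[str, np.ndarray],
    config: SimConfig,
    rng: np.random.Generator,
    id_prefix: str = "read",
) -> tuple[list[SmallRead], list[TruthRecord]]:
    classes = sorted(b for b, p in config.class_proportions.items() if p > 0)
    probs = np.array([config.class_proportions[b] for b in classes])
    class_draws = rng.choice(len(classes), size=config.n_reads, p=probs)

    reads: list[SmallRead] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_reads):
        biotype = classes[int(class_draws[i])]
        pool = pools[biotype]
        spec = pool[int(rng.choice(len(pool), p=weights[biotype]))]
        seq, edits = inject_errors(spec.sequence, config.sub_rate, config.ins_rate, rng)
        rid = f"{id_prefix}_{i:06d}"
        reads.append(SmallRead(id=rid, sequence=seq))
        truths.append(
            TruthRecord(
                read_id=rid,
                true_class=biotype,
                parent_id=spec.parent_id,
                end_origin=spec.end_origin,
                ref_span=spec.ref_span,
                fragment_sequence=spec.sequence,
                edits=edits,
            )
        )
    return reads, truths


def simulate_reads(
    refset: Sequence[RefSeqRecord],
    config: SimConfig,
    id_prefix: str = "read",
) -> tuple[list[SmallRead], list[TruthRecord]]:
    """Simulate one library: exactly ``config.n_reads`` reads plus truth.

    Per read: draw a class, then a distinct fragment from that class's
    Zipf-weighted pool, then apply the error channel.
    """
    rng = np.random.default_rng(config.seed)
    pools = build_fragment_pools(refset, config, rng)
    weights = {b: _zipf_weights(len(p), config.abundance_shape) for b, p in pools.items()}
    return _simulate_from_pools(pools, weights, config, rng, id_prefix)


def simulate_library_pair(
    refset: Sequence[RefSeqRecord],
    config_a: SimConfig,
    config_b: SimConfig,
    shared_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[SmallRead], list[TruthRecord], list[SmallRead], list[TruthRecord]]:
    """Two libraries drawing from partially overlapping fragment inventories.

    A master pool per class is generated once; each fragment is then marked
    shared (probability ``shared_fraction``) or unique to one library.  Each
    library ranks its own pool independently, so the same fragment can carry
    very different abundance in the two libraries (the basis of the
    fold-enrichment comparison).
    """
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must lie in [0, 1]")
    ss = np.random.SeedSequence(seed)
    rng_pool, rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(3))

    master_cfg = replace(config_a, seed=0)
    pools = build_fragment_pools(refset, master_cfg, rng_pool)

    pool_a: dict[str, list[FragmentSpec]] = {}
    pool_b: dict[str, list[FragmentSpec]] = {}
    for biotype, specs in pools.items():
        a_list: list[FragmentSpec] = []
        b_list: list[FragmentSpec] = []
        for spec in specs:
            u = rng_pool.random()
            if u < shared_fraction:
                a_list.append(spec)
                b_list.append(spec)
            elif u < shared_fraction + (1.0 - shared_fraction) / 2.0:
                a_list.append(spec)
            else:
                b_list.append(spec)
        if not a_list:
            a_list.append(specs[0])
        if not b_list:
            b_list.append(specs[0])
        pool_a[biotype] = a_list
        pool_b[biotype] = b_list

    def _lib(pool, cfg, rng, prefix):
        ranked = {b: [p[i] for i in rng.permutation(len(p))] for b, p in pool.items()}
        # drop classes with zero proportion in this library's config
        ranked = {b: v for b, v in ranked.items() if cfg.class_proportions.get(b, 0) > 0}
        for b, prop in cfg.class_proportions.items():
            if prop > 0 and b not in ranked:
                raise ConfigurationError(f"class {b!r} missing from master pool")
        w = {b: _zipf_weights(len(p), cfg.abundance_shape) for b, p in ranked.items()}
        return _simulate_from_pools(ranked, w, cfg, rng, prefix)

    reads_a, truth_a = _lib(pool_a, config_a, rng_a, "A")
    reads_b, truth_b = _lib(pool_b, config_b, rng_b, "B")
    return reads_a, truth_a, reads_b, truth_b


#: The six EV donor lines: three potent (positive dEF%), three non-potent.
POTENT_DONOR_IDS = ("ZCI", "YKT", "OD220")
NON_POTENT_DONOR_IDS = ("LO88", "BM030", "ZKN")


def make_potency_records(
    seed: int = 0,
    potent_abundance_mean: float = 3000.0,
    non_potent_abundance_mean: float = 1000.0,
    effect_range: tuple[float, float] = (1.0, 8.0),
) -> list[PotencyRecord]:
    """Synthetic donor potency table with the study's six donor ids.

    Potent donors draw positive ejection-fraction changes and 3x the mean
    fragment abundance of non-potent donors by default; magnitudes are
    synthetic (only the grouping structure is taken from the study design).
    """
    rng = np.random.default_rng(seed)
    lo, hi = effect_range
    records: list[PotencyRecord] = []
    for donor in POTENT_DONOR_IDS:
        records.append(
            PotencyRecord(
                donor_id=donor,
                delta_ef=float(rng.uniform(lo, hi)),
                abundance=float(rng.gamma(9.0, potent_abundance_mean / 9.0)),
            )
        )
    for donor in NON_POTENT_DONOR_IDS:
        records.append(
            PotencyRecord(
                donor_id=donor,
                delta_ef=float(-rng.uniform(lo, hi)),
                abundance=float(rng.gamma(9.0, non_potent_abundance_mean / 9.0)),
            )
        )
    return records


TRUTH_COLUMNS = (
    "read_id",
    "true_class",
    "parent_id",
    "end_origin",
    "ref_start",
    "ref_end",
    "fragment_sequence",
    "edits",
)


def write_truth_table(truths: Sequence[TruthRecord], path: str | Path) -> None:
    rows = [
        {
            "read_id": t.read_id,
            "true_class": t.true_class,
            "parent_id": t.parent_id,
            "end_origin": t.end_origin,
            "ref_start": t.ref_span[0],
            "ref_end": t.ref_span[1],
            "fragment_sequence": t.fragment_sequence,
            "edits": ";".join(f"{op}:{pos}" for op, pos in t.edits),
        }
        for t in truths
    ]
    write_tsv_report(rows, path, columns=list(TRUTH_COLUMNS))


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    out = []
    for row in read_tsv_report(path):
        edits = tuple(
            (op, int(pos))
            for op, pos in (e.split(":") for e in row["edits"].split(";") if e)
        )
        out.append(
            TruthRecord(
                read_id=row["read_id"],
                true_class=row["true_class"],
                parent_id=row["parent_id"],
                end_origin=row["end_origin"],
                ref_span=(int(row["ref_start"]), int(row["ref_end"])),
                fragment_sequence=row["fragment_sequence"],
                edits=edits,
            )
        )
    return out
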