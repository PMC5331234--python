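"""End-to-end orchestration: simulate -> filter -> annotate -> Y-fragment
analysis -> two-library comparison -> potency.

Every stage materialises its output (FASTA/TSV) under the run directory so
any stage can be re-run and diffed, and a JSON manifest records the seed,
per-stage record counts and SHA-256 checksums of every artefact.  A run is
byte-for-byte reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import annotate as ann_mod
from . import compare as cmp_mod
from . import synthetic as syn_mod
from . import yrna as yrna_mod
from .align import ScoringScheme
from .annotate import ANNOTATED, FILTERED_SHORT, UNANNOTATED, AnnotationConfig
from .io_formats import (
    ConfigurationError,
    RefSeqRecord,
    SmallRead,
    load_reference_db,
    read_sequences,
    read_tsv_report,
    write_fasta,
    write_reference_db,
    write_tsv_report,
)

log = logging.getLogger("yfrag")


@dataclass(frozen=True)
class LibrarySpec:
    """One input library: either a reads file or a simulation config."""

    name: str
    reads_path: Path | None = None
    sim: syn_mod.SimConfig | None = None

    def __post_init__(self) -> None:
        if (self.reads_path is None) == (self.sim is None):
            raise ConfigurationError(
                f"library {self.name!r}: supply exactly one of reads path / sim config"
            )


@dataclass(frozen=True)
class PipelineConfig:
    library_a: LibrarySpec
    library_b: LibrarySpec | None
    reference_fasta: Path | None  # None -> synthetic default reference set
    reference_biotypes: Path | None
    annotation: AnnotationConfig
    comparison_normalization: str = "raw"
    comparison_pseudocount: float = 1.0
    top_n: int = 20
    shared_fraction: float = 0.7
    potency_table: Path | None = None  # None -> synthetic donor table
    seed: int = 0
    out_dir: Path = Path("yfrag_out")


def _sim_config_from_dict(d: Mapping[str, Any], seed: int) -> syn_mod.SimConfig:
    known = {f.name for f in fields(syn_mod.SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown sim config keys: {sorted(unknown)}")
    return syn_mod.SimConfig(**{**d, "seed": int(d.get("seed", seed))})


def _library_from_dict(name: str, d: Mapping[str, Any] | None, seed: int) -> LibrarySpec | None:
    if d is None:
        return None
    reads = d.get("reads")
    sim = d.get("sim")
    return LibrarySpec(
        name=name,
        reads_path=Path(reads) if reads else None,
        sim=_sim_config_from_dict(sim, seed) if sim is not None else None,
    )


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML config file into a plain dict."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return data


def build_pipeline_config(
    data: Mapping[str, Any],
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> PipelineConfig:
    """Assemble and validate a :class:`PipelineConfig` from a config mapping.

    ``seed``/``out_dir`` override the config file.  Referenced files must
    exist at build time (the run fails before any stage starts otherwise).
    """
    eff_seed = int(seed if seed is not None else data.get("seed", 0))
    scoring = ScoringScheme(**data.get("scoring", {}))
    ann_d = dict(data.get("annotation", {}))
    annotation = AnnotationConfig(
        min_read_length=int(ann_d.get("min_read_length", 15)),
        coverage_threshold=float(ann_d.get("coverage_threshold", 0.75)),
        scoring=scoring,
    )

    lib_a = _library_from_dict("A", data.get("library_a", {"sim": {}}), eff_seed)
    lib_b = _library_from_dict("B", data.get("library_b"), eff_seed)
    if lib_a is None:
        raise ConfigurationError("library_a is required")

    ref = data.get("reference", {}) or {}
    ref_fasta = Path(ref["fasta"]) if ref.get("fasta") else None
    ref_biotypes = Path(ref["biotypes"]) if ref.get("biotypes") else None
    if (ref_fasta is None) != (ref_biotypes is None):
        raise ConfigurationError("reference needs both fasta and biotypes (or neither)")

    comp = data.get("comparison", {}) or {}
    pot = data.get("potency", {}) or {}

    cfg = PipelineConfig(
        library_a=lib_a,
        library_b=lib_b,
        reference_fasta=ref_fasta,
        reference_biotypes=ref_biotypes,
        annotation=annotation,
        comparison_normalization=comp.get("normalization", "raw"),
        comparison_pseudocount=float(comp.get("pseudocount", 1.0)),
        top_n=int(comp.get("top_n", 20)),
        shared_fraction=float(data.get("shared_fraction", 0.7)),
        potency_table=Path(pot["table"]) if pot.get("table") else None,
        seed=eff_seed,
        out_dir=Path(out_dir if out_dir is not None else data.get("out_dir", "yfrag_out")),
    )

    for p in (cfg.reference_fasta, cfg.reference_biotypes, cfg.potency_table,
              cfg.library_a.reads_path,
              cfg.library_b.reads_path if cfg.library_b else None):
        if p is not None and not Path(p).exists():
            raise ConfigurationError(f"configured input does not exist: {p}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _get_reference(cfg: PipelineConfig) -> list[RefSeqRecord]:
    if cfg.reference_fasta is not None:
        return load_reference_db(cfg.reference_fasta, cfg.reference_biotypes)
    return syn_mod.default_reference_set(seed=cfg.seed)


def _annotate_library(
    name: str,
    reads: Sequence[SmallRead],
    refdb: Sequence[RefSeqRecord],
    cfg: PipelineConfig,
    out: Path,
) -> tuple[list[ann_mod.ReadAnnotation], dict[str, Any]]:
    t0 = time.perf_counter()
    annotations = ann_mod.annotate_reads(reads, refdb, cfg.annotation)
    profile = ann_mod.profile_classes(annotations)
    ann_mod.write_annotation_report(annotations, out / f"annotations_{name}.tsv")
    ann_mod.write_class_profile(profile, out / f"class_profile_{name}.tsv")
    counts = {
        "n_reads": len(reads),
        "filtered_short": profile.total_filtered,
        "annotated": profile.total_annotated,
        "unannotated": profile.total_unannotated,
    }
    log.info(
        "library %s: annotated %d / filtered %d / unannotated %d of %d reads (%.1fs)",
        name, profile.total_annotated, profile.total_filtered,
        profile.total_unannotated, len(reads), time.perf_counter() - t0,
    )
    return annotations, counts


def _y_fragments(
    name: str,
    reads: Sequence[SmallRead],
    annotations: Sequence[ann_mod.ReadAnnotation],
    hy_refs: Sequence[RefSeqRecord],
    cfg: PipelineConfig,
    out: Path,
) -> list[yrna_mod.YFragmentRecord]:
    by_id = {r.id: r for r in reads}
    y_pairs = [
        (by_id[a.read_id], a)
        for a in annotations
        if a.status == ANNOTATED and a.biotype == "Y_RNA"
    ]
    collapsed = yrna_mod.collapse_fragments(y_pairs)
    records = yrna_mod.build_fragment_records(collapsed, hy_refs, cfg.annotation.scoring)
    yrna_mod.write_fragment_table(records, out / f"y_fragments_{name}.tsv")
    log.info("library %s: %d Y reads -> %d distinct fragments",
             name, len(y_pairs), len(records))
    return records


def read_potency_table(path: str | Path) -> list[cmp_mod.PotencyRecord]:
    records = []
    for row in read_tsv_report(path):
        records.append(
            cmp_mod.PotencyRecord(
                donor_id=row["donor_id"],
                delta_ef=float(row["delta_ef_percent"]),
                abundance=float(row["abundance"]),
            )
        )
    return records


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns (and writes) the run manifest."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": cfg.seed, "stages": {}, "checksums": {},
                                "input_checksums": {}}

    for p in (cfg.reference_fasta, cfg.reference_biotypes,
              cfg.library_a.reads_path,
              cfg.library_b.reads_path if cfg.library_b else None,
              cfg.potency_table):
        if p is not None:
            manifest["input_checksums"][str(p)] = _sha256(Path(p))

    # --- reference
    refdb = _get_reference(cfg)
    write_reference_db(refdb, out / "reference.fasta", out / "reference_biotypes.tsv")
    hy_refs = [r for r in refdb if r.biotype == "Y_RNA"]
    manifest["stages"]["reference"] = {"n_records": len(refdb), "n_y_rna": len(hy_refs)}

    # --- reads (simulate or load)
    libraries: dict[str, list[SmallRead]] = {}
    if (
        cfg.library_b is not None
        and cfg.library_a.sim is not None
        and cfg.library_b.sim is not None
    ):
        ra, ta, rb, tb = syn_mod.simulate_library_pair(
            refdb, cfg.library_a.sim, cfg.library_b.sim,
            shared_fraction=cfg.shared_fraction, seed=cfg.seed,
        )
        libraries["A"], libraries["B"] = ra, rb
        syn_mod.write_truth_table(ta, out / "truth_A.tsv")
        syn_mod.write_truth_table(tb, out / "truth_B.tsv")
    else:
        for spec in filter(None, (cfg.library_a, cfg.library_b)):
            if spec.sim is not None:
                reads, truth = syn_mod.simulate_reads(refdb, spec.sim,
                                                      id_prefix=spec.name)
                syn_mod.write_truth_table(truth, out / f"truth_{spec.name}.tsv")
            else:
                reads = read_sequences(spec.reads_path)
            libraries[spec.name] = reads
    for name, reads in libraries.items():
        write_fasta(reads, out / f"reads_{name}.fasta")

    # --- annotation + class profiles
    annotations: dict[str, list[ann_mod.ReadAnnotation]] = {}
    for name, reads in libraries.items():
        annotations[name], counts = _annotate_library(name, reads, refdb, cfg, out)
        manifest["stages"][f"annotate_{name}"] = counts

    # --- Y fragment analysis
    fragments: dict[str, list[yrna_mod.YFragmentRecord]] = {}
    for name in libraries:
        frags = _y_fragments(name, libraries[name], annotations[name],
                             hy_refs, cfg, out)
        fragments[name] = frags
        hist, rng = yrna_mod.length_distribution(frags)
        comp = yrna_mod.parent_composition(frags)
        ends = yrna_mod.end_origin_proportions(frags)
        manifest["stages"][f"y_fragments_{name}"] = {
            "distinct_fragments": len(frags),
            "y_reads": sum(f.read_count for f in frags),
            "length_range": list(rng) if rng else None,
            "parent_percent": {k: round(v, 4) for k, v in sorted(comp.percentages.items())},
            "five_prime_fraction": round(ends.get(yrna_mod.FIVE_PRIME, 0.0), 6)
            if ends else None,
        }

    # --- two-library comparison
    if len(fragments) == 2:
        table_a = [(f.sequence, f.read_count) for f in fragments["A"]]
        table_b = [(f.sequence, f.read_count) for f in fragments["B"]]
        comparison = cmp_mod.compare_libraries(table_a, table_b)
        cmp_mod.write_comparison_table(
            comparison, out / "comparison.tsv",
            cfg.comparison_normalization, cfg.comparison_pseudocount,
        )
        top = cmp_mod.rank_fragments(table_a, cfg.top_n)
        write_tsv_report(
            [{"rank": i + 1, "sequence": s, "read_count": c}
             for i, (s, c) in enumerate(top)],
            out / "top_fragments_A.tsv",
            columns=["rank", "sequence", "read_count"],
        )
        manifest["stages"]["comparison"] = {
            "distinct_a": len(comparison.counts_a),
            "distinct_b": len(comparison.counts_b),
            "unique_to_a": len(comparison.unique_to_a),
            "unique_to_b": len(comparison.unique_to_b),
            "shared": len(comparison.shared),
        }

    # --- potency
    if cfg.potency_table is not None:
        potency = read_potency_table(cfg.potency_table)
    else:
        potency = syn_mod.make_potency_records(seed=cfg.seed)
    result = cmp_mod.correlate_abundance_potency(potency)
    cmp_mod.write_potency_table(potency, result, out / "potency.tsv")
    manifest["stages"]["potency"] = {
        "n_donors": len(potency),
        "method": result.method,
        "coefficient": None if result.undefined else round(result.coefficient, 6),
        "potent_mean_abundance": round(result.potent_mean, 6),
        "non_potent_mean_abundance": round(result.non_potent_mean, 6),
    }

    for path in sorted(out.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["checksums"][path.name] = _sha256(path)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
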