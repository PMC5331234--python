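# yfrag

Small-RNA cargo analysis for extracellular vesicles (EVs), centred on
Y RNA-derived fragments.

Secreted EVs — including exosomes — carry a cargo of short non-coding RNAs
between cells. In EVs from therapeutic cell types such as cardiosphere-derived
cells, fragments of the four human Y RNA genes (hY1, hY3, hY4, hY5) are among
the most abundant species, most of them 15–62 nt, 5′-derived, and
overwhelmingly traceable to hY4. `yfrag` implements the computational side of
that kind of study as a reusable, deterministic pipeline:

1. **Annotation** — short reads (15–200 nt, FASTA/FASTQ) are aligned against a
   class-labelled ncRNA reference set with exact affine-gap Smith–Waterman
   under blastn-short-style scoring (match +1, mismatch −3, gap open 5,
   extend 2). A read is annotated with its best hit's class only when the
   best HSP covers **strictly more than 75 %** of the read; reads under 15 nt
   are excluded up front. Raw scores are reported in bits via the
   Karlin–Altschul normalisation *S′ = (λS − ln K)/ln 2* (defaults λ = 1.374,
   K = 0.711, the ungapped +1/−3 constants).
2. **Y fragment analysis** — Y-annotated reads are collapsed to distinct
   fragment sequences, re-aligned to the four full-length hY genes to assign a
   parent, classified as 5′- or 3′-derived from the midpoint of their aligned
   span, and summarised (length histogram, parent composition, insertion
   calls relative to the parent).
3. **Library comparison** — exact unique/shared set arithmetic between two
   fragment inventories plus per-fragment fold enrichment
   *(c_A + ψ)/(c_B + ψ)* with optional per-million scaling.
4. **Donor potency** — donors are split by the sign of their post-infarct
   ejection-fraction change (ΔEF %) and fragment abundance is related to
   potency with a Spearman (default) or Pearson correlation.
5. **Assay closed forms** — ΔΔCt relative expression *2^(−ΔΔCt)*, per-section
   infarct mass *(infarct area / LV area) × weight*, and percent-positive
   cell tabulation.

A fully deterministic synthetic-library generator (class mixtures,
end-anchored fragments with a dominant parent and 5′ bias, substitution +
single-insertion errors, Zipf-distributed fragment abundances, per-read truth
labels) makes every stage testable without any sequencing download.

## Worked example

The 57-nt fragment EV-YF1 (printed as RNA, normalised U→T on load) aligned
against full-length hY4:

```python
from yfrag import local_align, insertion_positions, EV_YF1, hy4_record

aln = local_align(EV_YF1, hy4_record().sequence, query_id="EV-YF1", ref_id="hY4")
print(f"raw score      : {aln.raw_score}")
print(f"bit score      : {aln.bit_score:.1f}")
print(f"identities     : {aln.identities}/{aln.alignment_length} ({aln.percent_identity:.0f}%)")
print(f"insertion at   : {insertion_positions(aln)}")
```

prints

```
raw score      : 49
bit score      : 97.6
identities     : 56/57 (98%)
insertion at   : [16]
```

i.e. the fragment is a 5′ copy of hY4 carrying a single inserted thymine at
position 16 — 56 identity columns in a 57-column alignment, 98 % identity.
The bit value depends on the λ/K constants configured on `ScoringScheme`;
different aligner releases ship different (often unstated) gapped constants,
so bits are used for ranking and reporting, never for the coverage-based
annotation rule.

The whole pipeline runs from one config and seed:

```bash
yfrag run --config docs/example_config.yaml --seed 42 --out out/
```

which simulates two libraries (an EV-like and a fibroblast-EV-like mixture),
annotates both, extracts and classifies Y fragments, compares the
inventories, runs the potency analysis, and writes every intermediate as
FASTA/TSV plus a `manifest.json` with per-stage counts and SHA-256 checksums.
Re-running with the same config and seed reproduces every file byte for byte.

## Notes

The bundled full-length hY sequences are literature-consensus
reconstructions standing in for the GenBank records (NR_004391, NR_004392,
NR_004393, NR_001571) so the package runs offline; see
`yfrag/resources.py` and `docs/methods.md` for exactly what is and is not
pinned by printed data.
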