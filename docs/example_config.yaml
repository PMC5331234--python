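# Full annotated pipeline configuration.
#
# Exactly one of `reads` (a FASTA/FASTQ path) or `sim` (a synthetic-library
# block) must be given per library.  When both libraries are simulated they
# draw fragments from one partially shared master inventory, so the
# comparison stage has genuinely common fragments.

seed: 42          # master seed; --seed on the command line overrides it
out_dir: out      # --out overrides it

library_a:        # EV-like mixture: Y RNA prominent, tRNA-dominated
  sim:
    n_reads: 10000
    class_proportions: {Y_RNA: 0.20, tRNA: 0.50, rRNA: 0.20, miRNA: 0.05, other: 0.05}
    parent_weights: {hY4: 0.85, hY1: 0.05, hY3: 0.05, hY5: 0.05}
    five_prime_bias: 0.8        # P(a Y fragment is anchored at the 5' end)
    fragment_len_min: 15        # nt
    fragment_len_max: 62        # nt
    sub_rate: 0.005             # per-base substitution probability
    ins_rate: 0.01              # per-read single-insertion probability
    abundance_shape: 1.5        # Zipf exponent over distinct fragments
    fragments_per_class: 60     # distinct fragments per class in the pool

library_b:        # fibroblast-EV-like control: stronger tRNA dominance
  sim:
    n_reads: 10000
    class_proportions: {Y_RNA: 0.10, tRNA: 0.70, rRNA: 0.12, miRNA: 0.04, other: 0.04}

# fraction of master-pool fragments available to both libraries
shared_fraction: 0.7

# reference:                    # omit to use the bundled synthetic default
#   fasta: refs.fasta           # (four hY genes + random per-class records)
#   biotypes: refs_biotypes.tsv # TSV: id <TAB> biotype <TAB> accession

annotation:
  min_read_length: 15           # reads shorter than this are excluded
  coverage_threshold: 0.75      # best HSP must cover STRICTLY more than this

scoring:                        # blastn-short-style defaults
  match: 1
  mismatch: -3
  gap_open: 5
  gap_extend: 2
  lam: 1.374                    # Karlin-Altschul lambda (bits reporting only)
  K: 0.711

comparison:
  normalization: raw            # raw | per_million
  pseudocount: 1                # keeps single-library fragments finite
  top_n: 20                     # rows in the abundance-ranking report

potency:
  # table: donors.tsv           # donor_id <TAB> delta_ef_percent <TAB> abundance;
  #                             # omitted -> synthetic six-donor table
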