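# Methods

## Scope and model

`yfrag` models the discovery-style analysis of short non-coding RNA cargo in
extracellular vesicles: annotate reads by ncRNA class, zoom into Y RNA
fragments, compare two vesicle sources, and relate one fragment's abundance
to a functional readout of the donor cells. The statistical content is
deliberately descriptive — composition percentages, set arithmetic, fold
ratios, a rank correlation — because the underlying designs (one library per
source, six donors) do not support count-model inference with dispersion
estimates; differential-abundance testing is explicitly out of scope.

## Alignment

Reads are at most ~200 nt and the references are individual small ncRNA
genes, so the aligner computes the exact optimum rather than a seeded
heuristic: affine-gap Smith–Waterman (Gotoh) over the DNA alphabet, match
+1, mismatch −3, and a length-L gap costing `gap_open + L·gap_extend`
(defaults 5 and 2). All parameters sit on `ScoringScheme`.

*Alphabet.* Everything is normalised to uppercase DNA on load; RNA inputs
(printed oligos) map U→T. `N` is retained but scores as a mismatch against
every base including `N`, so it can never contribute an identity.

*Determinism.* Among co-optimal alignments the tie-break is fully specified:
fewer gap columns, then smaller query start, then smaller reference start,
then gap columns placed as far 3′ as possible. The last rule resolves the
only ambiguity the others leave — gap placement inside a repeated-base run —
and is what makes the worked EV-YF1/hY4 alignment call its inserted T at
position 16 (the 3′-most placement within the TT run) rather than 15.
The tie-break is implemented inside the DP as a lexicographic optimisation
over `(score, −gap columns, −query start, −ref start, Σ query indices of
gap columns)`; every component is additive along an alignment path, so the
lexicographic DP is exact, not a heuristic.

*Bit scores.* Raw scores are converted to bits with
`(λ·S − ln K)/ln 2`. The default constants λ = 1.374, K = 0.711 are the
standard ungapped values for +1/−3 scoring; under them the EV-YF1/hY4
alignment (S = 49) is 97.6 bits. Published gapped constants vary by aligner
release and are often not stated alongside printed bit values, so bits are
reported for ranking and display only — the annotation decision never uses
them — and the constants are configurable.

*Kernel.* The DP is JIT-compiled with numba when importable; the identical
function runs as pure Python otherwise (slower, same results). Correctness
is pinned three ways: an exhaustive enumeration oracle over all monotone
alignments (all 2-letter pairs up to length 5), an independent C
implementation (Biopython `PairwiseAligner`, local mode, exhaustively to
length 8 and on random pairs), and re-scoring of every emitted trace.

*Truncation vs gap.* A single insertion within ~7 nt of a fragment end is
correctly absorbed by truncating the local alignment instead of opening the
gap (the gap costs 7; fewer than 8 rescued matches cannot pay for it). Tests
of exact insertion recovery therefore use interior positions; this is a
property of optimal local alignment, not an implementation quirk.

## Annotation rule

A read is annotated iff the query coverage of its single best HSP strictly
exceeds 0.75, where coverage is the fraction of the read's length consumed
by the HSP (matches, mismatches and insertion columns; reference-side gaps
do not reduce it). The rule is threshold-on-extent, not threshold-on-score:
the score reading has no well-defined denominator, while the extent reading
is exact and testable (a read whose best HSP spans exactly 75 % is rejected).
Best hit means highest bit score, ties to more identities, then the
lexicographically smallest reference id, so annotation is deterministic.
Unannotated and length-filtered reads are tallied but excluded from the
class-profile denominator, matching how composition pie charts are usually
drawn.

## Y fragment classification

Fragment identity is the exact sequence string — no mismatch-tolerant
clustering — because distinct-sequence counting is what inventory Venn
comparisons are defined on. Parent assignment re-aligns each distinct
fragment to the four full-length hY genes with the same best-hit rule. End
origin is classified by the midpoint of the aligned reference span: 5′ iff
the midpoint lies at or before the parent's midpoint. The rule is
parameter-free and provably exact for end-anchored fragments shorter than
half their parent; longer fragments straddle the midpoint and take the label
of the side holding most of their alignment. Both fragment-weighted and
read-weighted parent/end summaries are emitted, since published proportions
rarely state their weighting.

## Reference sequences

The four hY records bundled in `resources.py` are literature-consensus
reconstructions labelled as synthetic stand-ins for their GenBank
accessions, letting the package run with no network. One region is pinned
harder than the rest: the hY4 5′ prefix is derivable from printed data alone
(the EV-YF1 oligo with its documented position-16 insertion removed), and
that prefix is the only reference stretch any numeric check depends on.
Users with the real GenBank records can supply them as an external reference
FASTA + biotype table and bypass the bundled set entirely.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
defaults chosen once to mirror a typical EV small-RNA library:

| parameter | default | rationale |
|---|---|---|
| class proportions | Y 0.20, tRNA 0.50, rRNA 0.20, miRNA 0.05, other 0.05 | tRNA-dominated mixture with a prominent Y fraction, as seen in EV cargo |
| parent weights | hY4 0.85, others 0.05 | one dominant parent gene (~85 % hY4) |
| five_prime_bias | 0.8 | strong but not exclusive 5′ origin |
| fragment length | uniform 15–62 nt | observed range; no published length law, uniform is least assumptive |
| sub_rate / ins_rate | 0.005 / 0.01 | placeholder error channel; platform error rates are rarely published |
| abundance law | Zipf, exponent 1.5 | steeply ranked abundance lists; exponent configurable |
| fragments_per_class | 60 | see capacity note below |

Fragments are end-anchored: a 5′ fragment starts at reference position 0, a
3′ fragment ends at the terminus. Anchoring gives unambiguous truth labels;
the classifier's midpoint rule absorbs the softness of real data.

*Pool construction.* Each class's distinct-fragment pool draws per-parent
slot counts first (so the parent composition of the pool is binomial around
the parent weights), then samples (end, length) spans without replacement
within each parent. The obvious simpler scheme — draw with replacement and
discard duplicate sequences — silently re-weights toward minor parents once
the dominant parent's distinct-span space saturates, and was rejected for
that reason. A ~93-nt hY4 admits only 48 distinct 5′-anchored spans in the
15–62 nt range; the default pool size of 60 keeps the expected hY4 5′ demand
(~41) below that capacity.

*Error channel.* Each base substitutes independently (to a uniformly drawn
different base); with probability `ins_rate` exactly one base is inserted at
a uniform position — the single edit class the downstream insertion caller
is designed to detect. Deletions are not modelled. Edit positions are
reported in final-sequence coordinates.

*Two-library mode.* A master pool is generated once; each fragment is marked
shared (probability `shared_fraction`) or unique to one library, and each
library ranks its own pool independently before Zipf weights are applied.
Shared fragments therefore genuinely recur across libraries with different
abundances, which is what the Venn and fold-enrichment stages need.

*What passing tests do and do not show.* The generator produces exact
substrings of known parents with a clean two-parameter error channel and
hard end anchoring. Real libraries add adapter remnants, platform-specific
indel profiles, post-transcriptional modifications, ragged fragment ends and
reference ambiguity from >1,000 Y pseudogenes; recovery rates measured here
are upper bounds on real-data performance, not estimates of it.

*A note on convergence checks.* With a Zipf-weighted recurring-fragment
pool, read-level fractions of fragment-attached attributes (end origin,
parent) do not converge at rate 1/√n_reads — the effective sample size is
the inverse participation ratio of the Zipf weights (≈6 at the defaults),
not the read count. Distributional tests therefore check class proportions
at the read level (reads draw classes i.i.d.) but parent/end proportions at
the distinct-fragment level, where the binomial SE is the correct yardstick.

## Potency analysis

Donors are split on the sign of ΔEF % (zero counts as non-potent: "potent"
means a strictly positive change). The abundance–potency association uses
Spearman by default — at six donors a rank statistic is the defensible
choice and is invariant to any monotone rescaling of abundance (tested). A
zero-variance input yields a flagged undefined coefficient with group means
still reported. The synthetic donor table uses the six study donor ids and
the 3-potent/3-non-potent sign structure with synthetic magnitudes (gamma
noise, potent mean 3× non-potent by default); no numeric ΔEF % or abundance
values are taken from published data.

## Assay closed forms

ΔΔCt assumes ideal amplification efficiency 2 and a single reference gene
per measurement (multi-gene geometric-mean normalisation is out of scope);
`2^(−ΔΔCt)` with ΔCt = target − reference per sample. Infarct mass is the
sum over TTC sections of `(infarct area / LV area) × section weight`, linear
in weights and additive over sections by construction. Percent-positive is
plain tabulation with a guarded zero denominator.

## Problem sizes and numerical choices

Recovery and distribution checks run at 10,000 reads per library against a
reference set of 21 records (4 hY + 17 random per-class records), the scale
at which binomial 3-SE bands are tight enough to be meaningful while the
exact aligner stays comfortably fast; the acceptance script uses 5,000 reads
per library for the two-library comparison, which only needs stable
inventories, not tight percentages. Proportion maps must sum to 1 within
1e-9; composition percentages sum to 100 within 1e-6; coverage and the
annotation threshold are compared with strict inequality; all internal
coordinates are 0-based half-open, with every user-facing report 1-based
inclusive. The master seed drives per-stage child generators
(`numpy.random.SeedSequence.spawn`), so the whole pipeline — generation
through manifest checksums — is byte-for-byte reproducible from (config,
seed).

## Known limitations

- Single best HSP per read; no HSP chaining, no multi-mapping resolution,
  no E-values (database-size dependent by design).
- Pseudogene-aware mapping is out of scope: reads are attributed to the four
  canonical hY genes even though the genome contains many Y pseudogenes.
- The bit-score constants reproduce the *formula*, not any particular
  aligner release's gapped values; printed bit scores from other tools are
  expected to differ by a few percent.
- Secondary-structure prediction of fragments and all wet-lab-side
  computations beyond the three closed forms are out of scope.
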