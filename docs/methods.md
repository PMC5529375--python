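# Methods

## Scope and data model

`mitochar` operates on *annotated* circular mitochondrial genomes: a DNA
sequence over {A, C, G, T, N} plus an ordered feature table. It performs
no de novo annotation (no tRNA scanning, no ORF finding) and no
phylogenetics; annotations are inputs, taken from GenBank flat files or
from a six-column feature TSV (`name klass strand start end anticodon`).
Coordinates are 1-based inclusive, the GenBank convention; a feature
with `end < start` wraps across the origin of the circle. Strand `F` is
the majority strand (the one the sequence records), `R` the minority
strand. Feature names are normalized through a synonym table to stable
canonical labels (`cox1`…`cox3`, `cob`, `nad1`…`nad6`, `nad4L`, `atp6`,
`atp8`, `rrnL`, `rrnS`, 22 `trnX` labels with `trnL1`/`trnL2` and
`trnS1`/`trnS2` disambiguating the leucine and serine isoacceptors, and
`AT_rich_region`), because gene-order comparison needs identical keys
across genomes. Unrecognized names are preserved with class `other`.

The two reference annotations bundled in `mitochar.reference_data` (the
published *A. rubiginosa* and *R. menciana* genomes, with their
published per-class composition counts and pooled codon counts) carry
placeholder all-`N` sequences: every coordinate-derived statistic (gene
sizes, spacers, gene order, control-region location) is computable from
them, and the count tables stand in for the sequences in composition
and RSCU arithmetic. The deposited sequences themselves are not
redistributed.

## Per-gene summary

Size is `end − start + 1` (wrapped: `L − start + 1 + end`). The
intergenic spacer attributed to a gene is `next.start − end − 1`;
negative values are overlaps, and the last feature's spacer closes the
circle. On any circular annotation, Σ(size + spacer) equals the genome
length exactly; this identity is asserted on both reference annotations
and on synthetic genomes.

Start codons are classified canonical when in {ATA, ATT, ATC, ATG, CGA};
CGA is included because it is the conserved *cox1* initiator in
Lepidoptera. Stop classification reads the sense-strand CDS: a complete
`TAA`/`TAG` when the length is a multiple of 3; a single `T` or `A` when
length ≡ 1 (mod 3); `TA` when length ≡ 2 (mod 3) — the truncated stops
completed to UAA by polyadenylation. `A` is accepted alongside `T` in
the ≡1 case because published lepidopteran annotations report it
(*nad5*). Anything else is `OTHER` with an inconsistency flag: the
classifier reports what the sequence shows rather than trusting the
annotation, since published tables contain internally inconsistent rows
(a 1722-nt gene — a multiple of 3 — annotated with stop "A").

## Composition and skews

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C); both are NaN when the
denominator is zero and flip sign exactly under reverse complementation
(a property test). The whole genome is counted once on the majority
strand. Each gene class is the concatenation of its members'
reading-direction sequences — this choice, rather than counting the
majority strand throughout, is what produces the characteristic negative
PCG AT skew (T-richness) of lepidopteran coding strands. Overlapping
features are counted per feature, not deduplicated; `N` counts toward
size but neither AT nor GC. Report rounding follows the field's print
conventions: percentages to 1 decimal, skews to 3 decimals; raw
fractions remain available (`--raw` on the CLI).

A note on validating against published tables: the bundled reference
table's percentage columns are internally *closed* — the four base
percentages print so they sum to exactly 100 (one of G%/C% is the
complement of the other three printed columns) and AT% prints as the sum
of the printed A% and T%. The tests accept a printed cell when it is
within one rounding unit of either the raw fraction or the closure
value. One cell (the *A. rubiginosa* PCG GC skew, printed 0.038 where
the printed counts give 0.036) reproduces under neither reading and is
treated as a misprint.

## Codon usage

Codons are counted as non-overlapping triplets from position 1 of each
sense-strand CDS, pooled across the 13 PCGs; a trailing 1–2 nt
(incomplete stop) is discarded; complete stop codons are counted.
Whether published MEGA-based tables excluded start codons or incomplete
stops is not stated anywhere; this discard-trailing rule is this
package's convention and is validated against family-internal
arithmetic, not by regenerating published counts from sequence.

The genetic code is NCBI transl_table 5, taken from Biopython's codon
tables and re-asserted in tests (AGA/AGG→Ser giving an 8-codon Ser
family, AUA→Met, UGA→Trp, stops exactly UAA/UAG). RSCU for codon *i* in
a family of size *k* with total *n* is `count_i · k / n`; an unused
family yields RSCU 0 for all members, and the two stop codons form
their own 2-codon family (published tables print RSCU 2 for a UAA-only
stop usage). Σ RSCU over a nonzero family equals the family size — an
invariant checked on published rows and synthetic counts. Computation
uses DNA internally; reports transliterate to RNA spelling.

## Gene order and rearrangement

A gene order is a circular sequence of signed labels (+ majority, −
minority). The adjacency set is the set of consecutive ordered signed
pairs including the closing pair; it is rotation-invariant, so no
canonical rotation is needed for comparison. Breakpoint distance is
|adj(a) \ adj(b)|, symmetric over a shared label set; signs participate
in identity so inversions register. Whole-molecule reflections are not
normalized away — inputs are assumed to use the majority-strand
convention. `detect_translocated_genes` returns every label whose
removal from both circular orders leaves identical adjacency sets: the
minimal single-gene translocation explanation. For a neighbour swap both
participants qualify, and both are reported. Two arrangements are built
in: the ancestral insect order (…control region, *trnI*, −*trnQ*,
*trnM*, *nad2*…) and the derived lepidopteran order (*trnM* moved ahead
of *trnI*); the 33 other genes follow the shared pancrustacean backbone.
Comparing them yields breakpoint distance 3 and {trnM} — the hallmark
ditrysian rearrangement. Breakpoint distance is this package's chosen
rearrangement metric (descriptive papers typically show the orders
without quantifying); no inversion/DCJ distance and no
tandem-duplication–random-loss reconstruction is attempted.

## Control region

If no control feature is annotated, the region is located as the
longest unannotated span (≥ 50 nt) immediately downstream of *rrnS*,
scanning circularly. The "ATAGA + poly-T" search reports every ATAGA
whose downstream window (default 20 nt from its last base) contains a
run of ≥ `min_polyt` (default 5) consecutive T, with the first
qualifying run's length. Tandem repeats are exact-match arrays found by
self-alignment — extend while `region[i] == region[i−p]` — reported
maximal, at the smallest period when the unit is itself periodic,
subject to copies ≥ 2.0 and span ≥ 10 nt, with arrays contained in a
reported longer array suppressed. Defaults (`min_period` 2,
`max_period` 200) are this package's choices — no published thresholds
exist for these structures — and all are CLI flags. Approximate
(mismatch-tolerant) repeats are out of scope; published repeat counts
for the reference genomes come from an external tool with unstated
parameters, so they are not asserted anywhere.

The detector is verified against a brute-force oracle (every
start/period pair tested directly) on random strings up to 200 nt, and
every reported span is re-verified position by position.

## Synthetic genomes

The generator assembles a genome feature by feature in template order,
with the control region last so coordinates begin at the first tRNA as
in real genomes. Defaults are the published organization of the
reference hawk-moth genome: its per-gene lengths and anticodons, its
pooled codon counts as PCG codon weights, its per-class base
frequencies for tRNA/rRNA/control/spacer filler — so a default synthetic
genome is ~15.1 kb (exact gene lengths, zero default spacers) with
realistic composition bias. PCGs get a sampled ATN start (CGA for
*cox1*), internal codons drawn from the weight profile excluding stops,
and a stop determined by length mod 3 (TAA / T / TA), so the incomplete
stop pattern follows gene length exactly as in real annotations.
Requested overlaps write the downstream gene's bases over the upstream
tail (keeping the downstream start codon intact); a clipped upstream
stop then surfaces as a flagged inconsistency downstream — used
deliberately in the CLI tests.

The control region is AT-biased filler with one planted motif and one
planted tandem array (defaults: ATAGA at offset 40 with an 8-T run; a
23-nt AT-only aperiodic unit × 3.5 copies at offset 120), then
*sanitized*: any accidental qualifying motif or repeat array in the
filler is broken by point mutations outside the planted elements, so
detection tests can assert exact equality with exactly one hit each.
Sanitization raises rather than silently emitting an unclean region.

Ground truth records *realized* values tallied from the emitted
sequence (base counts per class, pooled codon counts, per-gene
start/stop, gene order, control-region elements), so downstream
recovery tests are exact equalities. What the generator does **not**
emulate: real tRNA/rRNA secondary structure (bodies are i.i.d. draws),
codon autocorrelation along genes, sequencing error, length variation
of the control region between individuals, and approximate repeats.
Passing recovery tests therefore demonstrate the *accounting* of the
pipeline is exact, not that the detectors are robust to the noise of
real data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: the two bundled
38-feature annotations; exhaustive breakpoint-oracle comparison over all
pairs of signed circular orders at n ≤ 3 (2,304 pairs) plus 500 seeded
random pairs at n = 4–8; tandem-repeat oracle agreement on 1,000 random
strings of 10–200 nt over two alphabets; and exact planted-truth
recovery on 20 synthetic genomes per run. The full suite completes in
well under a minute. Ties in tandem-repeat reporting are broken by
(start, −span, period); RSCU, skews and percentages are computed in
double precision and rounded only in reports (2, 3 and 1 decimals
respectively). Degenerate inputs are defined, not errors: empty region
classes give size-0 stats with NaN skews, all-zero codon tables give
all-zero RSCU, and a single-feature genome's spacer is the rest of the
circle.
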