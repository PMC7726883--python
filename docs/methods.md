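# Methods

## Problem and approach

A circular mitogenome assembly is compared against a trusted reference in
five stages: orientation normalization, global alignment, canonicalization,
error classification, and downstream proxies (ORF integrity, barcoding).
Every stage is deterministic given its inputs; stochastic steps (synthetic
genome generation, error injection) are pure functions of an explicit seed.

## Orientation normalization

A circular assembly is defined only up to rotation and strand. The k-mer at
reference position 0 (default k = 31, long enough to be effectively unique in
a 16 kb genome, short enough that a chance error hitting it is unlikely) is
searched exactly in the doubled assembly sequence, forward strand first. A
hit fixes the rotation (`anchor_matched = true`). If the anchor is absent on
both strands — e.g. an assembly error inside the anchor — the orientation
minimizing edit distance to the reference over 8 rotations at L/8 spacing ×
2 strands is chosen and flagged approximate (`anchor_matched = false`). Edit
distances in the fallback are computed with edlib. After rotation the pair is
aligned linearly; there is no cyclic dynamic program. Residual end effects
are bounded by the largest terminal indel and surface in the error profile.
Non-circular assemblies are never rotated (offset fixed at 0); only the
strand is chosen.

## Alignment and canonical form

Global pairwise alignment uses affine gap costs: match +1, mismatch −2, a gap
of length k costs −(4 + 2k). The penalties are chosen so that a length-k
homopolymer indel is always cheaper than k substitutions, matching the
indel-dominated error structure of nanopore assemblies; with mismatch at −2
and a 1-base gap at −6, isolated base differences are represented as
substitutions rather than insertion/deletion pairs. The alignment engine is
Biopython's `PairwiseAligner`; its score is verified against an independent
affine-gap dynamic program (and exhaustive enumeration of all alignments at
tiny sizes) in the test suite.

Optimal alignments are not unique: a gap inside a homopolymer run can sit at
any offset in the run. `left_justify` shifts every gap run leftward while an
equivalent placement exists (the displaced character re-pairs with an
identical partner), which preserves the ungapped rows, the match/mismatch
counts, and the gap run lengths — hence the score. The fixed point is the
canonical alignment on which events are extracted; event extraction rejects
non-canonical input. This makes error counts reproducible regardless of
which co-optimal traceback the aligner happened to return.

## p-distance

p = (differing comparable columns) / (comparable columns), where a column is
comparable when both rows are in {A, C, G, T}. Gap columns and N-bearing
columns are excluded from numerator and denominator (pairwise deletion, the
MEGA-style default). Zero comparable columns is an error rather than a zero
distance.

## Error taxonomy

Event segmentation: each maximal run of gap columns in one row is one indel
event; each mismatch column is one substitution event. Events jointly cover
every differing column exactly once. Columns containing N produce no event
(ambiguous bases are filtered, not scored, mirroring how N-bearing records
are handled in barcode panels).

Classification evaluates homopolymer context on the reference — the trusted
sequence — with runs allowed to wrap the origin of a circular reference:

- deletion of d identical bases b → `hp_del_d` iff the reference run of b
  containing the deleted stretch is ≥ 3 bases and d ≤ 5; otherwise
  `single_deletion` (d = 1), `short_deletion` (2 ≤ d ≤ 3), else overflow;
- insertion of i identical bases b → `hp_ins_i` iff the reference run of b
  immediately left or right of the insertion point is ≥ 3 bases and i ≤ 5;
  otherwise `single_insertion` (i = 1), `short_insertion` (2 ≤ i ≤ 5), else
  overflow;
- mixed-base indels are never homopolymer events; mismatches are
  substitutions.

The run threshold (3), the homopolymer multiplicity cap (5), and the short
insertion/deletion bounds (5/3) are `TaxonomyConfig` knobs. The asymmetric
short bounds follow the convention that insertions up to 5 bp and deletions
up to 3 bp are "short"; `long_indel_other` is an overflow bin so that the
profile always accounts for every event on arbitrary input. The homopolymer
run is measured before the event (a 2-base deletion from a 3-base run is
`hp_del_2`), and totals count events, not bases.

## ORF integrity

Reference annotations are lifted through the alignment column map: the lifted
start is the assembly coordinate of the first aligned reference base at/after
the gene start, the lifted end one past the last aligned base before the gene
end; boundary deletions shrink the interval, a fully deleted gene is flagged
absent. Genes spanning the origin are lifted piecewise and stay single
intervals (`wraps_origin`), preserving gene identity for translation.

Translation uses NCBI table 5 (invertebrate mitochondrial: AGA/AGG = Ser,
ATA = Met, TGA = Trp, stops TAA/TAG), sourced from Biopython's codon tables
and cross-checked in the tests against an independently typed 64-codon table.
⌊len/3⌋ codons are translated; trailing sub-codon bases are ignored
(incomplete terminal stops, completed by polyadenylation, are normal in
mitogenomes); codons containing N render 'X', never '*'. `internal_stops`
counts '*' excluding the final codon, in the annotated frame only — no search
for downstream frame restoration, since the quantity of interest is how often
errors interrupt the reading frame at all. A single frameshift is expected
to create at least one stop with high probability: at GC 0.40 the per-codon
stop probability in a shifted frame is ≈ 0.045, so a shifted tail of ~100
codons is essentially never stop-free.

## Barcoding

Panel preparation applies, in order: (1) removal of records containing any N;
(2) slicing of the master alignment into the window (w1 = columns 1–500,
w2 = 501–1000, w3 = 1001–1539, 1-based inclusive; `full` keeps everything);
(3) removal of records with fewer than 250 non-gap bases in-window. Counts
removed by each filter are logged. Raw (unaligned) records are projected onto
the coordinates of the longest record via global alignment, dropping bases
inserted relative to that frame; pre-aligned panels (equal lengths) pass
through unchanged.

Identification is nearest-neighbor by p-distance after pairwise global
alignment of the query to each panel record. Ties are broken by species-level
mean distance, then lexicographic label. This deliberately replaces
maximum-likelihood tree inference: the claim being tested — an error-laden
assembly fragment groups with conspecific sequences and away from congeners —
reduces to relative distance ordering at this scale. Tree building,
bootstrap support, and model selection are out of scope.

## Synthetic data

`simulate_mitogenome` emulates a pancrustacean-style mitogenome: default
length 15,739 bp, 13 PCGs, 22 tRNAs (66 bp placeholders), 2 rRNAs (850 and
1,330 bp placeholders), one 801 bp control region, GC 0.40 (a typical AT-rich
invertebrate composition; a config default, not a claim), 2 bp spacers, and
gene order shuffled per seed. At least 4 PCGs, 8 tRNAs and both rRNAs go on
the minus strand, mirroring the asymmetric strand usage of these genomes.
PCGs are valid ORFs under table 5 (ATG start, stop-free body, TAA terminator;
minus-strand genes are inserted as reverse complements). Homopolymer runs are
seeded at `hp_enrichment` = 2.0 runs (length ≥ 5) per kb: inside PCGs as
codon-aligned 6-mers of one base (AAA AAA, TTT TTT, CCC CCC, GGG GGG — all
stop-free on both strands), elsewhere as free runs of 5–8 bases.

`inject_errors` mutates a copy with exactly the requested per-category
counts and returns a truth ledger. Under `context_policy='unambiguous'`
(the default) sites are chosen so that alignment plus classification must
recover the ledger: events ≥ 10 bp apart, at least 50 bp from the linear
ends, one event per homopolymer run (two would merge into a single gap),
homopolymer deletions only in runs long enough to survive (run ≥ max(4, d+1)),
non-homopolymer events in contexts where the gap cannot shift into or out of
a run. `anywhere` relaxes the context constraints (events may interact) and
is used for stress tests such as barcoding robustness, where exact ledger
recovery is not the question. The nanopore-like preset (277 events: 150
single homopolymer deletions, 45 single homopolymer insertions, down to rare
quadruple/quintuple insertions and short deletions) mirrors the error-rank
structure of unpolished long-read assemblies; a polished-like preset (~50
events) mirrors consensus-polished ones.

### What the synthetic benchmark does and does not show

Passing tests establish that the pipeline measures exactly what was put in:
orientation recovery, exact profile recovery under unambiguous placement,
frameshift sensitivity of the ORF proxy, and distance-based identifiability
under realistic error loads. They do not establish anything about real reads:
the generator produces i.i.d. base composition (no codon usage bias, no tRNA
secondary structure), placeholder RNA genes, idealized error placement, and
no coverage or basecalling model. Real assemblies may contain clustered
errors, which the `anywhere` policy only approximates, and structural
problems (duplications, chimeras) that this toolkit reports only indirectly
(as length differences and overflow indels).

## Numerical and degenerate-input choices

- All internal coordinates are 0-based half-open; exports are 1-based
  inclusive. Origin-wrapping genes are written in GFF3/BED with end > L and
  normalized on read.
- Alignment tie-breaks: the aligner's first optimal traceback is taken and
  canonicalized by left-justification; classification is therefore
  deterministic even when co-optimal paths exist.
- Identification ties (equal best distance) resolve by species mean distance,
  then lexicographic label, and are reported with margin 0.
- Degenerate inputs raise: empty FASTA, non-ACGTN characters (with record and
  1-based position), annotation intervals out of bounds, alignments with no
  comparable sites, panels that empty out after filtering, injection requests
  without enough valid contexts (naming the starving category).
- Problem sizes in the test suite and acceptance script: 20 full-length
  (15,739 bp) round-trip seeds, 2 kb genomes for per-test pipeline checks,
  100 frameshift trials on one gene, 50 barcoding trials on 1,539 bp
  fragments — sizes at which every property is exercised at full fidelity
  while the whole suite stays fast.
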