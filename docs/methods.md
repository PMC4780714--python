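# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind plastomekit. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and containers

Internal coordinates are 0-based half-open on a circular sequence; reports
and GFF3/GenBank I/O use 1-based inclusive coordinates. An interval with
`start > end` wraps the origin; `start == end` is rejected as ambiguous
(empty vs. full circle). IR-duplicated genes are kept as distinct feature
records and de-duplicated only in the gene census. 'N' bases count toward
lengths but are excluded from both the numerator and denominator of GC%, so
GC reflects called bases only.

## Inverted-repeat detection

The two IRs of a plastome are exact reverse complements in deposited
assemblies, so detection is exact-match (Hamming distance 0): a position pair
(a, b) with `seq[a] == complement(seq[b])` lies on the anti-diagonal
a + b = c (mod n), and the IR pair is precisely a maximal run along one
anti-diagonal. Seeds are 20-mers shared between the genome and its reverse
complement, probed at a stride small enough that any interval of
`min_ir_len` (default 10,000 bp, well below the ~25 kb of typical IRs and
above the scale of dispersed repeats) must contain a probe. Runs are extended
base-by-base in circular coordinates, so the result is rotation-invariant;
the longer gap between the two copies is labelled LSC, the shorter SSC, and
the genome is rotated so the LSC starts at position 0. If no disjoint pair
reaches `min_ir_len` a structured no-IR result is returned (some plastomes
genuinely lack an IR); ties between distinct maximal pairs raise an error
listing the candidates. Junction names follow the LSC → IR_B → SSC → IR_A
reading order; because subscript conventions differ between papers, every
report also prints the explicit flanking pair (e.g. `LSC|IR_B`).

## Composition accounting

Feature classes overlap in real annotations (matK lies inside the trnK-UUU
intron; ndhF overlaps the ψycf1 fragment), so class statistics are computed
per base under the precedence CDS > tRNA > rRNA > intron > intergenic. This
makes the five class lengths an exact partition of the genome, which the
suite asserts on every run. The IR row of the region table reports the
single-copy length but counts both copies in its percentage, the convention
of plastome papers. Trans-spliced genes (rps12) contribute their sub-5 kb
between-exon gaps as cis introns; the tens-of-kb trans junction is not an
intron. Pseudogene fragments are excluded from all class and census counts.

## Repeat scanners

All three scans run on LSC + IR_B + SSC (one IR copy removed) to avoid
double-counting the duplicated region.

**SSRs.** For each motif length m = 1..5 the scanner finds maximal runs of
positions j with `seq[j] == seq[j-m]`; a run of total length T yields
floor(T/m) copies, reported when it meets the thresholds (mono ≥ 8, di ≥ 4,
tri/tetra/penta ≥ 3). Only primitive motifs are reported (a poly-A run is
never re-reported as "AA"), and motifs are canonicalized to the
lexicographically smallest rotation — rotation only, not reverse complement,
so A- and T-type homopolymers stay distinct as in conventional plastome SSR
tables. Compound/interrupted SSRs are reported as separate loci. The scanner
is set-equal to a brute-force (start, motif-length) enumerator on exhaustive
short binary strings and random sequences.

**Tandem arrays.** A simplified reimplementation of the Tandem Repeats
Finder criteria, not a bit-compatible clone: for each period p in the
reported 15–30 bp range, candidate arrays are maximal lag-p match runs
(bridging mismatch holes ≤ 2 columns); each candidate is scored against its
per-column majority consensus (ties to the first copy) at +2 per match and
−7 per mismatch over the positions beyond the first period, and kept when
the score reaches 50 — so an exact k-mer repeated c times scores
2·(c−1)·k. Overlapping reports of one array at different periods collapse to
the best score.

**Dispersed repeats.** Maximal pairs of length ≥ 30 within Hamming
distance ≤ 3 in four orientations (forward s≈t; reverse s≈reverse(t);
complement s≈complement(t); palindromic s≈revcomp(t)). Forward/complement
pairs live on diagonals (i, i+d), reverse/palindromic on anti-diagonals
(a, c−a). Exact q-gram seeds with q = ceil((L−h)/(h+1)) = 7 at the default
30/3 guarantee by pigeonhole that every qualifying pair contains a seed;
each seed's inter-mismatch segment is extended to all maximal windows over
the mismatch budget (up to h+1 per segment, deduplicated). A "maximal
window" cannot be extended on either side without exceeding the budget or
leaving the sequence. Forward/complement hits whose two intervals overlap
are suppressed (they are tandem arrays); reverse/palindromic hits whose
halves overlap are genuine (near-)palindromes and are flagged instead. The
scanner is set-equal to an exhaustive full-diagonal oracle in the tests.
`merge_overlapping` unions same-class hits whose both intervals overlap and
is idempotent.

## In-silico PCR and intron calls

Primer binding requires ≤ 2 mismatches with the 3'-terminal 3 bases exact —
mismatch counting only, no melting-temperature model. Products are capped at
5 kb and searched on both strands, across the origin for circular templates.
Amplicon classification uses ±20 % bands around the two diagnostic lengths
(750 bp = intron lost, 1,400 bp = intron present); the band width is an
implementation decision recorded with every call, since only approximate
lengths are diagnostic. The annotation-based call demands agreement between
IR copies; the exon-junction comparison calls a sequence absent only when
the reference's intron columns are entirely gapped, present at ≥ 50 %
filled, indeterminate between, flagging calls within 5 points of the 50 %
rule boundary.

## Marker screen

Shared regions are one per gene (spliced exons of the first non-pseudo
copy), one per shared intron index, and one per intergenic spacer whose
flanking genes are adjacent in every genome; regions < 200 bp in the first
genome are dropped, and IR-duplicated regions are taken once. Alignment is
progressive — pairwise distances, UPGMA guide tree, profile–profile merges
with match 1 / mismatch 0 / gap open 10 / gap extend 0.5 — with two
shortcuts: pre-gapped input is ingested verbatim (real studies hand-adjust
alignments, which are not bit-reproducible), and equal-length ungapped
inputs are taken as positionally homologous, since with these gap costs a
gap pair is never optimal for point-substituted sequences and plastid CDS
are typically indel-free. Gap opening is allowed from the match state or the
opposite gap state.

Site statistics treat gaps and N as missing (the common parsimony-software
default): a column is conserved when one state occurs among non-missing
rows, parsimony-informative when ≥ 2 states each occur in ≥ 2 rows, and
entirely-missing columns are unscored. PIC% divides by the full aligned
length including gap columns — the convention confirmed by the worked
examples 77/1101 = 6.99 % and 98/1593 = 6.15 %. The ensemble retention
index is RI = (G − S)/(G − M) with per-column minimum m = (observed
states − 1), maximum g = (non-missing rows − largest state class), and S
the Fitch length; when G = M (no potentially homoplastic variation) RI is
undefined and reported as 1.0 with a flag. By default RI uses each region's
own maximum-parsimony tree, recorded in the output; a fixed tree can be
supplied instead. Sliding windows (1,000 bp / 500 bp step) apply to regions
longer than 1,500 bp, anchored at column 0, with the final window truncated
at the region end.

## Parsimony search

Columns are encoded as nucleotide bitmasks with gaps/ambiguity = all states,
so missing data never forces a change; site patterns are deduplicated and
Fitch scoring is vectorised across patterns. Search is exact up to 9 taxa
(exhaustive enumeration of all unrooted topologies to 7; branch-and-bound
with a greedy-addition upper bound to 9 — the partial-tree score is a valid
bound because adding leaves never decreases Fitch length). Above 9 taxa the
heuristic runs greedy parsimony stepwise addition from random taxon orders
(10 replicates, seeded) followed by TBR hill-climbing: every edge is
bisected and every pair of reattachment edges in the two components is
tried. Stepwise-addition starts were chosen over a neighbor-joining start
because they need no distance model and feed TBR equally well at these
problem sizes. All co-optimal trees found are returned, deduplicated by
split set. Bootstrap resamples columns with replacement and reports split
frequencies as percentages on the best original tree; the generator is
seeded and recorded.

## Synthetic data

The simulator's defaults are the study conditions the pipeline targets:
LSC 83,921 bp, SSC 16,933 bp, IR 25,793 bp (152,440 bp total, the
architecture of the deposited reference genome), background GC 38 %, and a
112-unique-gene complement (60 + 22 genes in the LSC, 12 + 1 in the SSC,
6 + 7 + 4 duplicated in the IRs → 129 gene copies), with the canonical
17 intron-containing genes, the 2,497 bp trnK-UUU intron hosting a 1,491 bp
matK, trans-spliced rps12, rps19 extending 75 bp into the IR, ndhF
extending 38 bp with a 20 bp overlap of the mirrored ψycf1 fragment, and an
intron-less rpl2 (the focal condition; `rpl2_intron=True` plants the 660 bp
intron for ancestral genomes). Exon/intron lengths approximate typical
plastid values. The rpl2 survey primer sites are written into the rpl2
exons so that the spliced amplicon is exactly 750 bp, and 660 bp longer
with the intron. Planted SSRs/tandems/dispersed repeats are placed in
intergenic gaps with guard bases that stop run extension exactly at the
planted boundaries; one base on each side of the four region junctions is
fixed so exact IR extension stops exactly at the planted borders.

Evolution along a user tree applies Jukes–Cantor substitutions per branch
(per-site difference probability ¾(1 − e^(−4t/3))) — the simplest model with
a closed-form expectation for the site-count statistics the pipeline
measures; no rate heterogeneity. The IRs evolve concertedly: mutations
arise on IR_B and are copy-corrected into IR_A, mimicking the gene
conversion that keeps real IR copies near-identical, which is also what
makes exact-match IR detection valid on evolved genomes. Small (1–5 bp)
indels occur only in single-copy intergenic DNA (rate 0.0001 per site per
unit branch length — roughly an order of magnitude below the substitution
rate, as in plastid data), so genic planted truth stays exact. An optional
intron loss is excised once on a named branch (all gene copies, both IRs)
and inherited by the clade. Annotations are carried through with coordinate
shifts at indels only; they are not re-inferred.

What the simulator does **not** emulate: codon structure and selection,
rate variation across sites or lineages, IR boundary expansion/contraction,
genomic rearrangement beyond a single planted inversion helper, compound
SSR interruption patterns, and sequencing artefacts. Passing tests
therefore demonstrate algorithmic correctness on genomes with known truth,
not robustness to annotation error or assembly noise in real data.

## Problem sizes and determinism

The default test suite and the acceptance script run full-scale single
genomes (152 kb) for structure/composition/repeat scans and scaled-down
multi-species analyses (7 taxa, ~25 concatenated genes for tree searches;
brute-force oracle comparisons at 0.15–3 kb; 50 random architectures for IR
recovery; 100 kb for the Jukes–Cantor calibration) — sizes chosen so each
property suite completes in minutes on one CPU while keeping every
comparison exact. All randomness flows from explicit seeds; pipeline
outputs carry no timestamps, so identical configurations produce
byte-identical outputs, which the suite asserts.

## Known limitations

* IR detection is exact-match; a deposited assembly whose IR copies differ
  would need the (deferred) mismatch tolerance. Real deposited plastomes
  have identical or near-identical IR copies.
* The tandem-repeat scanner reproduces the stated parameter semantics,
  not Tandem Repeats Finder's stochastic alignment model; counts on real
  genomes can differ from TRF's where arrays are highly degenerate.
* The progressive aligner is adequate for the low-divergence, mostly
  indel-free regions the screen targets; for distant or structurally
  variable regions an external alignment should be supplied (and is
  ingested verbatim).
* Published SSR totals from legacy tools depend on undocumented maximality
  and compounding rules; this implementation documents its rules (above)
  and reports its own counts rather than absorbing discrepancies silently.
* The exon-junction 50 % rule and the ±20 % amplicon bands are decisions
  where the diagnostic is inherently approximate; both are flagged in
  output.
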