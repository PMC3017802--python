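# Methods

This note records the models, conventions and numerical choices behind
`organellarch`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and genome representation

All internal coordinates are 0-based half-open; GenBank's 1-based inclusive
locations are converted only at the I/O boundary. A feature part that
crosses the origin of a circular genome is kept as an explicit wrapping
interval (`start > end`), never silently linearized; every statistic is
required (and tested) to be invariant under rotation of the circle and
under strand flip. Multi-part locations are stored in ascending genomic
order; a minus-strand transcript is the reverse complement of the
concatenated ascending parts, which matches GenBank `complement(join(...))`
semantics.

Feature kinds are inferred from the GenBank key plus qualifiers: a `/pseudo`
qualifier (or a ψ/psi-marked name) makes a pseudogene; a CDS whose parts lie
entirely inside an intron feature is reclassified as an intronic ORF. Both
are excluded from the coding total, which the partition definitions require.

## Partition accounting

The four quantities are computed from boolean position masks:
coding = union(CDS, rRNA, tRNA parts) minus intron positions;
noncoding = G − coding; intergenic = G − union(locus envelopes), where a
locus envelope runs from the first to the last part of a gene (so introns
and intronic ORFs inside a gene are part of its locus); intronic =
noncoding − intergenic. When a genome annotates no `gene` features, each
coding feature's envelope stands in for its locus. Intron-like features
located between loci therefore count as intergenic sequence, while still
counting as introns for the intron/gene ratio (the ratio's default includes
them; a flag excludes them).

Gene counting merges fragment-labelled loci (suffixes like `_S1`, `-L3`,
`-a`) into one gene when at least two loci share the base name — fragmented
rRNAs such as rrns S1–S3 / rrnl L1–L6 count once, with a fragment count —
while duplicate loci with identical names (inverted-repeat copies, duplicate
tRNAs) count separately unless deduplication is requested. An explicit
fragment map can override the suffix heuristic. Reported ratios are rounded
to two decimals, percentages to one, kb to one, matching the conventions of
the comparative literature.

## GC statistics

GC fractions exclude N from numerator and denominator and error on all-N
input. Codon-position GC uses the annotation's frame (`codon_start`),
truncates unflagged partial trailing codons with a warning, and is
order-free (a position-wise tally). Cumulative GC skew uses the standard
per-window (G−C)/(G+C) with a running sum; windows and steps default to
1 kb, circular genomes wrap their final windows, and a window with G+C = 0
contributes 0 rather than NaN. The formula and window are the field's
standard choice for replication-origin diagnostics; nothing in the package
depends on them beyond these defaults.

## Inverted-repeat detection

Candidates come from exact 25-mer matches between the forward strand and
its reverse complement on the doubled sequence (doubling makes the search
rotation-invariant; images created by the doubling are removed by interval
deduplication modulo G). Seeds sharing an anti-diagonal are chained;
chains are split where consecutive seeds are more than 200 nt apart, since
distinct pairings can share an anti-diagonal. Arms are extended by X-drop
(match +1, mismatch −3, drop 20) and trimmed to the maximal-score endpoint,
then accepted if the arm-wide mismatch fraction is within budget (default
1 %). A cumulative-mismatch-fraction boundary rule was considered and
rejected: on an L-nt arm it lets extension absorb ≈ 0.01·L of random flank
before the budget binds (≈ 25 nt on a 2 kb arm), whereas the X-drop rule
overshoots only when flank bases happen to pair (expected < 1 nt, and
bounded by the planted-repeat tests at ±10 nt). Equal-length candidates are
broken by smallest start coordinate. The two gaps between the arms are
labelled LSC/SSC by size; per-region statistics clip features into the
region holding the majority of their span.

## Maximal repeat finding

A repeat pair of type F/R/C/RC is *maximal* when it starts and ends on
matching positions and no one-position extension keeps the Hamming mismatch
count ≤ k; sequence bounds and, for the reverse/reverse-complement types,
arm disjointness (arms may touch, not overlap) count as blocking. Matches
are reported once, with the left instance first; the trivial full-length
self-match is excluded. Seeds of length ⌊min_len/(k+1)⌋ are
pigeonhole-complete: any qualifying match contains an exact seed, so
enumerating all maximal mismatch-windows on every seeded (anti-)diagonal is
exhaustive. The tests assert set-equality against a brute-force
all-diagonal enumeration on 500-nt sequences for all four types and
k ∈ {0, 1}. Repeat-family clustering is single linkage on edit-distance
identity (default 0.8), strand-symmetric (best of the two orientations).
Reported family counts depend on (min_len, k, identity) conventions and are
exposed as parameters, not asserted as constants.

## Hairpin and cluster analysis

Hairpins are combinatorial stem-loops: arms pair by Watson–Crick complement
(G·T wobble off by default, flag available), the innermost pair must close
the loop, stems are extended maximally allowing ≤ max_arm_mismatch unpaired
positions, and overlapping calls are resolved longest-stem-first, then
leftmost. Thermodynamic folding is deliberately out of scope; the default
constraints (stem ≥ 8, loop 3–12, ≤ 1 mispairing) admit elements of
19 nt and up, covering the 23–38 nt range organellar palindromic elements
occupy. Every reported hairpin is re-verified by an independent
arm-comparison check in the tests. Clusters are gap-chains (≤ 30 nt);
family consensus aligns members to the longest member (edlib) and takes
column majorities, emitting an IUPAC code on ties; a cluster and its
reverse complement are one object (lexicographically smaller strand is the
family key).

On a realistic AT-rich background the scanner also reports chance
stem-loops, mostly as singletons; cluster-level statistics are therefore
reported over clusters with ≥ 2 hairpins, and gap-chaining can append an
adjacent chance hairpin to a planted cluster, so detected mean spans sit
slightly above the planted ~110 nt.

## Recruitment, assembly, walking, circularization

The trace model is substitution-only (a documented generator limitation:
no indels, no chromatogram noise, no vector contamination). That licenses
two simplifications, both of which would need gapped alignment for real
traces: recruitment locates the best trace-vs-bait placement by seeded
diagonal voting (word size 11, both strands) and scores the gap-free
overlap under the stated scheme (match 2, mismatch −3; gap costs 5/2 are
carried in the interface); assembly verifies candidate overlaps by Hamming
identity at the seed-voted offset. Recruitment keeps hits with identity
> 0.80 over ≥ 100 aligned nt; the identity denominator is the aligned span.
E-value thresholding is not reproduced — it depends on database-size
semantics foreign to this artifact.

Assembly is greedy overlap-layout-consensus: all pairwise candidate
overlaps ≥ 500 nt at ≥ 98 % identity (either strand) are sorted by score
(match 1, mismatch −2), then overlap length, then trace ids, and merged in
that order through a union-find that composes (offset, strand) placements
transitively; the consensus is a per-column coverage-weighted majority with
deterministic tie-breaking, computed once per component. For
substitution-only reads this is equivalent to repeatedly merging the
best-overlapping pair, and it is deterministic given input order.

Walking re-baits with 1 kb contig end windows against the unused archive
each round and re-assembles recruits with the current contigs, up to 50
rounds. Progress is measured by the longest assembled sequence: the naive
sum of contig lengths *drops* when two overlapping contigs merge, which is
progress, not loss, so the monotonicity guarantee is on the longest contig.
After the last round the entire recruited set is re-assembled from scratch,
because incremental rounds let an existing contig vote as a single trace,
which would otherwise freeze early low-coverage errors into the consensus
and misstate coverage.

Circular closure trims one copy of an end-to-end overlap (≥ 500 nt at
≥ 98 % identity), warns and stays linear when two well-separated closure
offsets qualify (tandem end repeat), and rotates the result to the
lexicographically minimal rotation of the lexicographically smaller strand
(Booth's algorithm), so the reported sequence is independent of where the
simulator cut the circle. Large inverted repeats can collapse under greedy
overlap assembly; the evaluator reports identity and coverage against truth
but does not attempt IR resolution.

## Synthetic genomes

The generator builds an annotated circle to a target architecture: the
coding total is solved exactly from the noncoding fraction (protein exon
lengths in codon multiples, the ≤ 2 nt rounding residue absorbed by a
tRNA), introns are distributed across protein genes, intronic ORFs inside
enlarged introns, and the intergenic budget is split among gaps by a
Dirichlet draw, with palindrome clusters, dispersed AT-rich repeat
families, intergenic introns and pseudogene fragments planted into gaps and
annotated as truth. An inverted repeat duplicates its genes (strands
mirrored) between explicitly sized single-copy regions. Coding sequence is
codon-sampled to per-position GC targets with stop codons rejected (the
rejection slightly raises first-position GC above its target — visible as
~40 % measured against a 38 % target); minus-strand genes are emitted so
their transcripts read correctly. Palindrome clusters are drawn from a
small set of family prototypes (2 % copy divergence) so consensus
occurrence counts are meaningful; arm GC is solved per element so the
element lands on the cluster GC target despite the AT-rich loop motif.

Two presets encode the study conditions: a mitochondrial-style genome
(28.3 kb, 12 genes — 7 protein, 2 fragmented rRNAs (3+6 modules), 3 tRNAs —
all one strand, 18 introns of ~440 nt (2 with ORFs), 58 % noncoding split
~29/29 between intergenic and intronic, 18 palindrome clusters, category GC
33/34/37 %, codon GC 38/38/19 %) and a plastid-style genome (269 kb, 102
genes of which 5 are IR duplicates, 43 introns — 7 intergenic, 11
IR-duplicated — of ~800 nt, 65.5 % noncoding, a 14.4 kb IR flanking
127.3 kb and 112.9 kb single-copy regions, 8 AT-rich repeat families,
category GC 34/32/31 %, codon GC 42/52/13 %).

The shredder draws reads uniformly over the circle (wrapping), normal
lengths (default 750 ± 80 nt), random strands, i.i.d. substitutions, and
appends decoy reads from a GC-matched random "nuclear" sequence at a given
fold-coverage, optionally with a diverged organelle-like insertion to
stress recruitment purity. What passing tests show is therefore limited to
this model: uniform coverage, substitution-only errors, and a repeat
structure no harder than one large IR plus short dispersed elements. Real
trace archives add indels, coverage biases, chimeras and organelle-to-
nucleus transfers that the purity test only caricatures.

## Problem sizes and runtime

The test suite and the acceptance script run the architecture statistics at
the full study scales (28.3 kb and 269 kb), the repeat-finder oracle
comparisons at 500 nt, the dispersed-repeat survey on a 40 kb single-copy
slice (min_len 12, exact matches), and the assembly round trip on a 30 kb
circle at 30× organelle coverage plus 3× decoys — sizes at which the whole
suite completes in a few minutes on one CPU while exercising every code
path at realistic densities.

## Known limitations

- Annotation-driven throughout: no gene prediction, no intron discovery or
  classification, no secondary-structure thermodynamics.
- Gap-free alignment in recruitment/assembly (substitution-only trace
  model); gapped repeat detection is likewise out of scope (Hamming only).
- Greedy OLC does not resolve large repeats; an IR-spanning archive can
  collapse its copies.
- The per-region assignment of boundary-spanning genes is by majority span,
  logged, not split.
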