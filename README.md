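# organellarch

Organelle genomes — mitochondrial and plastid DNA — vary enormously in how
much of them actually codes for anything. Chlamydomonadalean green algae in
particular carry some of the most noncoding-DNA-inflated organelle genomes
known: circular-mapping molecules in which well over half the sequence is
intergenic spacer, introns, and repeats. Quantifying that architecture takes
a stack of small, exacting computations: a strict coding/noncoding
accounting, composition statistics, detection of the large inverted repeat
that splits a plastid genome into its quadripartite structure, dispersed and
palindromic repeat finding, and — when the genome itself has to be mined out
of a nuclear whole-genome-shotgun trace archive — a bait-and-walk assembly
procedure.

`organellarch` is a library and CLI implementing all of these for anyone
analysing annotated organelle genomes (GenBank records) or assembling them
from read archives, with a synthetic-genome generator that plants every
feature with known truth so the whole stack is testable without downloads.

## The accounting and the algorithms

**Partition.** For a genome of length *G* with annotated features,

- coding nt = |union of CDS, rRNA and tRNA parts| − |positions also
  annotated as intron| (pseudogenes and ORFs inside introns never count);
- noncoding nt = *G* − coding nt;
- intergenic nt = *G* − |union of gene loci| (a locus spans its exons,
  introns and intronic ORFs);
- intronic nt = noncoding − intergenic.

Both identities (coding + noncoding = *G*; intergenic + intronic =
noncoding) hold by construction and are property-tested, together with
invariance under rotation of the circle and strand flip.

**Composition.** GC content overall, per category, and per codon position
over strand-resolved intron-free CDSs; cumulative GC skew
Σ<sub>w</sub> (G−C)/(G+C) over sliding windows (default 1 kb), the standard
replication-origin diagnostic.

**Quadripartite map.** The inverted-repeat pair (IR_A/IR_B) is found by
exact 25-mer seeding of the forward strand against its reverse complement,
chaining seeds on a common anti-diagonal, and X-drop extension (match +1,
mismatch −3) trimmed to the maximal-score endpoint under a mismatch budget;
the two single-copy gaps are labelled LSC/SSC by size. Detection runs on
the doubled sequence, so it is rotation-invariant.

**Repeats.** Maximal repeat pairs of all four types — forward, reverse,
complement, reverse-complement — with up to *k* Hamming mismatches, found by
pigeonhole-complete seeds of length ⌊min_len/(k+1)⌋ and exhaustive
per-diagonal window enumeration; verified against a brute-force oracle in
the tests. Single-linkage clustering into repeat families and JDotter-style
sliding-window dotplots (window 50) complete the picture.

**Palindromes.** Hairpin-capable elements (two reverse-complementary arms,
stem ≥ 8 bp with ≤ 1 mispairing, loop 3–12 nt) are found by a combinatorial
stem-loop scan, chained into genomic clusters (gap ≤ 30 nt), grouped into
families by strand-canonicalized identity, and summarized as IUPAC
consensus sequences with occurrence counts and loop-motif tallies
(5'-TTTA-3'/5'-TTT-3').

**Bait and walk.** Traces are recruited by 11-mer-seeded similarity to bait
sequences (BLAST-style scoring 2/−3, gaps 5/2; kept at > 80 % identity over
≥ 100 aligned nt, both strands), assembled by greedy overlap-layout-consensus
(identity ≥ 98 % over ≥ 500 nt; scores 1/−2/−2/−3) with a coverage-weighted
majority consensus, iteratively extended by re-baiting with contig ends, and
closed into a circle when the contig ends overlap — reported at a canonical
rotation of the canonical strand.

## Worked example

```python
import organellarch as oa

g = oa.generate_genome(oa.mt_like_spec(seed=1))   # 28.3 kb circular genome
part = oa.partition_genome(g)
print(len(g), part.coding_nt, part.intergenic_nt, part.intronic_nt)
print(round(oa.intron_gene_ratio(g), 2))
```

prints

```
28300 11886 8174 8240
1.5
```

i.e. a 28.3 kb circle that is 42.0 % coding, 28.9 % intergenic and 29.1 %
intronic, with 18 introns over 12 genes — an intron/gene ratio of 1.5. The
hairpin scanner on the same genome finds the 18 planted palindromic-repeat
clusters among its intergenic regions (28 multi-hairpin clusters in total,
including chance stem-loops of the AT-rich background), with TTTA in 42
hairpin loops. Equivalent CLI:

```bash
organellarch synth genome --preset mt --seed 1 --out mt.gb
organellarch partition mt.gb
organellarch ratio mt.gb
organellarch palindromes mt.gb
organellarch report mt.gb          # composite JSON report
```

For a plastid-style genome, `organellarch ir` reports the quadripartite map
(on the 269 kb synthetic preset: a 14.4 kb IR pair flanking 127.3 kb and
112.9 kb single-copy regions), and `organellarch baitwalk --archive reads.fa
--baits baits.fa` runs the full assembly pipeline on a trace archive.

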