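"""Synthetic annotated organelle genomes and simulated trace archives.

The generator emulates chlamydomonadalean-style organelle genome
architecture: a circular molecule with a configurable noncoding fraction,
single-strand gene clusters, introns (optionally carrying intronic ORFs),
intergenic group-II-like introns, an optional large inverted-repeat pair
duplicating its genes, AT-rich dispersed repeat families, GC-balanced
palindromic hairpin clusters in intergenic DNA, and pseudogene fragments.
All planted truth is returned as annotations; all randomness flows from the
spec seed.

The shredder produces substitution-only reads drawn uniformly over the
circle (wrapping the origin), on random strands, with an optional
nuclear-background decoy archive for recruitment-purity stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import gc_fraction, revcomp
from .genbank_io import AnnotatedGenome, Feature, Interval

STOPS = {"TAA", "TAG", "TGA"}


class InfeasibleSpec(ValueError):
    pass


@dataclass(frozen=True)
class PalindromeClusterSpec:
    count: int = 0
    hairpins_per_cluster: int = 3
    stem_range: tuple = (8, 13)
    loop_range: tuple = (4, 9)
    spacer_range: tuple = (8, 18)
    gc: float = 0.5
    loop_motif: str = "TTTA"
    families: int = 6            # distinct cluster families reused genome-wide
    copy_divergence: float = 0.02


@dataclass(frozen=True)
class DispersedRepeatSpec:
    family_count: int = 0
    copies_per_family: int = 5
    length_range: tuple = (30, 60)
    at_range: tuple = (0.7, 0.9)


@dataclass(frozen=True)
class GenomeSpec:
    length: int
    seed: int
    circular: bool = True
    # gene complement
    n_protein: int = 7
    n_trna: int = 3
    rrna_genes: tuple = ()          # ((base_name, n_fragments), ...)
    trna_len: int = 75
    rrna_frag_len: int = 400
    # architecture
    noncoding_fraction: float = 0.58
    introns_in_genes: int = 0       # single-copy (non-IR) gene introns
    intronic_orfs: int = 0
    intergenic_introns: int = 0
    intron_len: int = 450
    pseudogenes: int = 0
    all_plus_strand: bool = True
    # inverted repeat
    ir_length: int = 0
    ir_n_protein: int = 0
    ir_n_trna: int = 0
    ir_introns: int = 0             # introns inside IR genes (per arm)
    lsc_length: int | None = None   # explicit single-copy split (optional)
    # repetitive elements
    palindromes: PalindromeClusterSpec = PalindromeClusterSpec()
    repeats: DispersedRepeatSpec = DispersedRepeatSpec()
    # composition
    gc_coding: float = 0.33
    gc_intron: float = 0.34
    gc_intergenic: float = 0.37
    codon_gc: tuple = (0.38, 0.38, 0.19)


def mt_like_spec(seed: int = 0) -> GenomeSpec:
    """A 28.3 kb circular mitochondrial-style genome: 12 genes (7 protein,
    2 fragmented rRNAs, 3 tRNAs) on one strand, 18 introns (2 with ORFs),
    58% noncoding, 18 palindromic hairpin clusters, no inverted repeat."""
    return GenomeSpec(
        length=28300, seed=seed, n_protein=7, n_trna=3,
        rrna_genes=(("rrns", 3), ("rrnl", 6)),
        rrna_frag_len=300,
        noncoding_fraction=0.58, introns_in_genes=18, intronic_orfs=2,
        intron_len=440,
        palindromes=PalindromeClusterSpec(count=18),
        repeats=DispersedRepeatSpec(family_count=2, copies_per_family=4),
        gc_coding=0.33, gc_intron=0.34, gc_intergenic=0.37,
        codon_gc=(0.38, 0.38, 0.19))


def pt_like_spec(seed: int = 0) -> GenomeSpec:
    """A 269 kb circular plastid-style genome: 102 genes of which five are
    IR duplicates, a 14.4 kb inverted-repeat pair flanking 127.3 kb and
    112.9 kb single-copy regions, 43 introns (7 intergenic, 11 of the
    in-gene introns IR-duplicated), 65.5% noncoding, AT-rich dispersed
    repeat families."""
    return GenomeSpec(
        length=269000, seed=seed,
        n_protein=61, n_trna=28,
        rrna_genes=(("rrn16", 2), ("rrn23", 3), ("rrn5", 1)),
        noncoding_fraction=0.655, introns_in_genes=14, intronic_orfs=4,
        intergenic_introns=7, intron_len=800, pseudogenes=3,
        all_plus_strand=False,
        ir_length=14400, ir_n_protein=2, ir_n_trna=3, ir_introns=11,
        lsc_length=127300,
        repeats=DispersedRepeatSpec(family_count=8, copies_per_family=12),
        palindromes=PalindromeClusterSpec(count=0),
        gc_coding=0.34, gc_intron=0.32, gc_intergenic=0.31,
        codon_gc=(0.42, 0.52, 0.13))


# ------------------------------------------------------------- sequence gen

def _rand_seq(rng, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    r = rng.random(n)
    bases = np.where(r < gc / 2, "G",
             np.where(r < gc, "C",
              np.where(r < gc + (1 - gc) / 2, "A", "T")))
    return "".join(bases)


def _rand_cds(rng, n_nt: int, codon_gc) -> str:
    """Codon-sampled coding sequence with per-position GC targets and no
    internal stop codons; length must be a multiple of 3."""
    assert n_nt % 3 == 0
    n_codons = n_nt // 3
    out = []
    for _ in range(n_codons):
        while True:
            codon = "".join(
                ("G" if r < g / 2 else "C" if r < g else
                 "A" if r < g + (1 - g) / 2 else "T")
                for r, g in zip(rng.random(3), codon_gc))
            if codon not in STOPS:
                out.append(codon)
                break
    return "".join(out)


def _hairpin_element(rng, spec: PalindromeClusterSpec) -> str:
    stem = int(rng.integers(spec.stem_range[0], spec.stem_range[1] + 1))
    loop_len = int(rng.integers(spec.loop_range[0], spec.loop_range[1] + 1))
    motif = spec.loop_motif
    if loop_len >= len(motif):
        pad = _rand_seq(rng, loop_len - len(motif), spec.gc)
        loop = motif + pad
    else:
        loop = _rand_seq(rng, loop_len, spec.gc)
    # choose the arm GC so the whole element lands on the target GC
    loop_gc = (loop.count("G") + loop.count("C")) / max(len(loop), 1)
    elem_len = 2 * stem + loop_len
    arm_gc = (spec.gc * elem_len - loop_gc * loop_len) / (2 * stem)
    arm = _rand_seq(rng, stem, min(max(arm_gc, 0.0), 1.0))
    return arm + loop + revcomp(arm)


def _mutate_keep_acgt(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[int(rng.integers(4))]
    return "".join(out)


def _palindrome_cluster(rng, spec: PalindromeClusterSpec) -> str:
    parts = []
    for i in range(spec.hairpins_per_cluster):
        parts.append(_hairpin_element(rng, spec))
        if i < spec.hairpins_per_cluster - 1:
            gap = int(rng.integers(spec.spacer_range[0],
                                   spec.spacer_range[1] + 1))
            parts.append(_rand_seq(rng, gap, spec.gc))
    return "".join(parts)


# ------------------------------------------------------------- locus plan

@dataclass
class _Locus:
    name: str
    cls: str               # protein | tRNA | rRNA
    exon_len: int = 0
    intron_lens: list = field(default_factory=list)
    orf_introns: list = field(default_factory=list)  # indices with ORFs
    strand: str = "+"
    fragments: int = 1     # rRNA modules

    def envelope_len(self) -> int:
        return self.exon_len + sum(self.intron_lens)


def _plan_loci(spec: GenomeSpec, rng) -> tuple[list, list]:
    """Returns (single_copy_loci, ir_loci). Exon lengths are solved so the
    genome-wide coding total (IR counted twice) hits the noncoding target
    exactly (+-1 nt of rounding)."""
    sc, ir = [], []
    for i in range(spec.n_protein):
        sc.append(_Locus(f"prot{i + 1}", "protein"))
    for i in range(spec.n_trna):
        sc.append(_Locus(f"trn{chr(65 + i % 26)}{i // 26 or ''}", "tRNA",
                         exon_len=spec.trna_len))
    for base, nfrag in spec.rrna_genes:
        for j in range(nfrag):
            tag = "S" if "s" in base or "16" in base else "L"
            sc.append(_Locus(f"{base}_{tag}{j + 1}", "rRNA",
                             exon_len=spec.rrna_frag_len))
    for i in range(spec.ir_n_protein):
        ir.append(_Locus(f"irp{i + 1}", "protein"))
    for i in range(spec.ir_n_trna):
        ir.append(_Locus(f"trnIR{i + 1}", "tRNA", exon_len=spec.trna_len))

    coding_total = round((1 - spec.noncoding_fraction) * spec.length)
    fixed = (sum(l.exon_len for l in sc) +
             2 * sum(l.exon_len for l in ir))
    protein_budget = coding_total - fixed
    sc_prot = [l for l in sc if l.cls == "protein"]
    ir_prot = [l for l in ir if l.cls == "protein"]
    eff = len(sc_prot) + 2 * len(ir_prot)
    if eff == 0:
        if protein_budget > 2:
            raise InfeasibleSpec("coding budget exceeds gene capacity "
                                 "(no protein genes to absorb it)")
    else:
        base = (protein_budget // eff) // 3 * 3
        if base < 150:
            raise InfeasibleSpec("coding budget too small: protein genes "
                                 f"would be {base} nt (< 150)")
        for l in sc_prot + ir_prot:
            l.exon_len = base
        rem = protein_budget - base * eff
        i = 0
        while rem >= 3 and sc_prot:
            sc_prot[i % len(sc_prot)].exon_len += 3
            rem -= 3
            i += 1
        # absorb the <3 nt residue in a tRNA so the total is exact
        if rem:
            trnas = [l for l in sc if l.cls == "tRNA"]
            if trnas:
                trnas[0].exon_len += rem
                rem = 0

    # introns: single-copy introns across single-copy protein genes,
    # IR introns across IR protein genes
    def _spread(loci, count, tag):
        prots = [l for l in loci if l.cls == "protein"]
        if count and not prots:
            raise InfeasibleSpec(f"{tag}: introns requested but no protein "
                                 "genes to hold them")
        for k in range(count):
            prots[k % len(prots)].intron_lens.append(spec.intron_len)

    _spread(sc, spec.introns_in_genes, "single-copy")
    _spread(ir, spec.ir_introns, "inverted-repeat")
    placed = 0
    for l in sc:
        for idx in range(len(l.intron_lens)):
            if placed >= spec.intronic_orfs:
                break
            # an ORF-bearing intron must be long enough for the ORF + flanks
            l.intron_lens[idx] = max(l.intron_lens[idx], 600)
            l.orf_introns.append(idx)
            placed += 1
    if placed < spec.intronic_orfs:
        raise InfeasibleSpec("more intronic ORFs requested than introns")
    if not spec.all_plus_strand:
        for l in sc:
            l.strand = "+" if rng.random() < 0.5 else "-"
    return sc, ir


# ------------------------------------------------------------- assembly

class _Builder:
    def __init__(self, genome_id):
        self.chunks: list[str] = []
        self.pos = 0
        self.features: list[Feature] = []
        self.id = genome_id

    def emit(self, seq: str):
        self.chunks.append(seq)
        self.pos += len(seq)

    def feature(self, kind, name, strand, start, end, **quals):
        self.features.append(Feature(kind=kind, name=name, strand=strand,
                                     parts=[Interval(start, end)],
                                     qualifiers=quals))


def _emit_locus(b: _Builder, l: _Locus, spec: GenomeSpec, rng):
    start = b.pos
    if l.cls == "protein":
        n_introns = len(l.intron_lens)
        # split the transcript into n_introns+1 codon-aligned pieces
        per = (l.exon_len // (n_introns + 1)) // 3 * 3
        if n_introns and per < 3:
            raise InfeasibleSpec(f"gene {l.name}: too many introns for its "
                                 "exon budget")
        pieces = [per] * n_introns + [l.exon_len - per * n_introns]
        cds = _rand_cds(rng, l.exon_len, spec.codon_gc)
        chunks, off = [], 0
        for piece in pieces:
            chunks.append(cds[off:off + piece])
            off += piece
        if l.strand == "-":
            # genomic order carries the transcript 3' -> 5'
            chunks = [revcomp(c) for c in reversed(chunks)]
        cds_parts = []
        for i, chunk in enumerate(chunks):
            s = b.pos
            b.emit(chunk)
            cds_parts.append(Interval(s, b.pos))
            if i < n_introns:
                ilen = l.intron_lens[i]
                istart = b.pos
                if i in l.orf_introns:
                    orf_len = (ilen - 150) // 3 * 3
                    flank = ilen - orf_len
                    b.emit(_rand_seq(rng, flank // 2, spec.gc_intron))
                    orf_start = b.pos
                    orf = _rand_cds(rng, orf_len, (spec.gc_intron,) * 3)
                    b.emit(revcomp(orf) if l.strand == "-" else orf)
                    b.feature("intronic_ORF", f"{l.name}_orf{i + 1}",
                              l.strand, orf_start, b.pos)
                    b.emit(_rand_seq(rng, flank - flank // 2,
                                     spec.gc_intron))
                else:
                    b.emit(_rand_seq(rng, ilen, spec.gc_intron))
                b.feature("intron", f"{l.name}_i{i + 1}", l.strand,
                          istart, b.pos)
        b.feature("CDS", l.name, l.strand, cds_parts[0].start,
                  cds_parts[0].end)
        b.features[-1].parts = cds_parts
        b.feature("gene", l.name, l.strand, start, b.pos)
    else:
        kind = "tRNA" if l.cls == "tRNA" else "rRNA"
        b.emit(_rand_seq(rng, l.exon_len, spec.gc_coding))
        b.feature(kind, l.name, l.strand, start, b.pos)
        b.feature("gene", l.name, l.strand, start, b.pos)


def _emit_gap(b: _Builder, total: int, elements, spec: GenomeSpec, rng):
    """Fill ``total`` nt of intergenic space, embedding the given elements
    (tuples of (tag, seq-or-callable, feature kind/name))."""
    elem_len = sum(len(e[1]) for e in elements)
    filler = total - elem_len
    if filler < 0:
        raise InfeasibleSpec("intergenic gap too small for planted elements")
    n_slots = len(elements) + 1
    cuts = sorted(rng.integers(0, filler + 1, size=n_slots - 1)) if n_slots > 1 else []
    sizes = np.diff([0, *cuts, filler]).astype(int)
    for i, (kind, seq, name) in enumerate(elements):
        b.emit(_rand_seq(rng, int(sizes[i]), spec.gc_intergenic))
        s = b.pos
        b.emit(seq)
        if kind:
            b.feature(kind, name, "+", s, b.pos, planted="yes")
    b.emit(_rand_seq(rng, int(sizes[-1]), spec.gc_intergenic))


def generate_genome(spec: GenomeSpec) -> AnnotatedGenome:
    """Deterministically build the annotated genome for a spec."""
    rng = np.random.default_rng(spec.seed)
    sc, ir = _plan_loci(spec, rng)

    # planted intergenic elements (palindrome clusters, dispersed repeats,
    # intergenic introns, pseudogene fragments)
    elements = []
    pal = spec.palindromes
    if pal.count:
        n_fam = max(1, min(pal.families, pal.count))
        prototypes = [_palindrome_cluster(rng, pal) for _ in range(n_fam)]
        for i in range(pal.count):
            fam = i % n_fam
            copy = _mutate_keep_acgt(rng, prototypes[fam],
                                     pal.copy_divergence)
            elements.append(("repeat_region", copy,
                             f"palindrome_cluster_{i + 1}"))
    rep_fams = []
    for fi in range(spec.repeats.family_count):
        ln = int(rng.integers(*spec.repeats.length_range))
        at = rng.uniform(*spec.repeats.at_range)
        motif = _rand_seq(rng, ln, 1 - at)
        rep_fams.append(motif)
        for ci in range(spec.repeats.copies_per_family):
            elements.append(("repeat_region", motif,
                             f"repfam{fi + 1}_copy{ci + 1}"))
    for i in range(spec.intergenic_introns):
        elements.append(("intron", _rand_seq(rng, spec.intron_len,
                                             spec.gc_intron),
                         f"ig_intron_{i + 1}"))
    for i in range(spec.pseudogenes):
        frag = _rand_cds(rng, 201, spec.codon_gc)
        elements.append(("pseudogene", frag, f"prot{i + 1}_psi"))
    rng.shuffle(elements)

    ir_env = sum(l.envelope_len() for l in ir)
    if spec.ir_length:
        if ir_env + 200 > spec.ir_length:
            raise InfeasibleSpec("ir_length too small for IR gene content")
    sc_env = sum(l.envelope_len() for l in sc)
    gap_total = spec.length - sc_env - 2 * spec.ir_length
    if spec.ir_length and spec.lsc_length is not None:
        lsc_len = spec.lsc_length
        ssc_len = spec.length - 2 * spec.ir_length - lsc_len
    elif spec.ir_length:
        single = spec.length - 2 * spec.ir_length
        lsc_len = int(single * 0.53)
        ssc_len = single - lsc_len
    total_elem = sum(len(e[1]) for e in elements)
    if gap_total < total_elem + 20 * (len(sc) + 1):
        raise InfeasibleSpec(
            f"intergenic budget {gap_total} nt cannot hold {total_elem} nt "
            "of planted elements plus spacers")

    b = _Builder("synthetic")
    rng.shuffle(sc)

    if spec.ir_length == 0:
        # simple circle: locus, gap, locus, gap, ...
        gaps = _split_gap_budget(rng, gap_total, len(sc), elements)
        for l, gap in zip(sc, gaps):
            _emit_locus(b, l, spec, rng)
            _emit_gap(b, gap[0], gap[1], spec, rng)
        seq = "".join(b.chunks)
    else:
        # layout: LSC | IR_A | SSC | IR_B(revcomp of IR_A)
        n_lsc = max(1, round(len(sc) * lsc_len / (lsc_len + ssc_len)))
        lsc_loci, ssc_loci = sc[:n_lsc], sc[n_lsc:]
        lsc_gap = lsc_len - sum(l.envelope_len() for l in lsc_loci)
        ssc_gap = ssc_len - sum(l.envelope_len() for l in ssc_loci)
        if lsc_gap < 0 or ssc_gap < 0:
            raise InfeasibleSpec("single-copy regions too small for genes")
        n_elem_lsc = round(len(elements) * lsc_gap / max(lsc_gap + ssc_gap, 1))
        e_lsc, e_ssc = elements[:n_elem_lsc], elements[n_elem_lsc:]
        for loci, gap_budget, elems in ((lsc_loci, lsc_gap, e_lsc),):
            gaps = _split_gap_budget(rng, gap_budget, len(loci), elems)
            for l, gap in zip(loci, gaps):
                _emit_locus(b, l, spec, rng)
                _emit_gap(b, gap[0], gap[1], spec, rng)
        # IR_A
        ira_start = b.pos
        ir_b_builder_start = len(b.features)
        ir_gap = spec.ir_length - ir_env
        gaps = _split_gap_budget(rng, ir_gap, len(ir), [])
        for l, gap in zip(ir, gaps):
            _emit_locus(b, l, spec, rng)
            _emit_gap(b, gap[0], gap[1], spec, rng)
        ira_end = b.pos
        ir_feats = [f for f in b.features
                    if f.parts[0].start >= ira_start]
        # SSC
        gaps = _split_gap_budget(rng, ssc_gap, len(ssc_loci), e_ssc)
        for l, gap in zip(ssc_loci, gaps):
            _emit_locus(b, l, spec, rng)
            _emit_gap(b, gap[0], gap[1], spec, rng)
        # IR_B = revcomp(IR_A), features mirrored
        irb_start = b.pos
        ira_seq = "".join(b.chunks)[ira_start:ira_end]
        b.emit(revcomp(ira_seq))
        for f in ir_feats:
            parts = []
            for p in reversed(f.parts):
                s = irb_start + (ira_end - p.end)
                e = irb_start + (ira_end - p.start)
                parts.append(Interval(s, e))
            b.features.append(Feature(
                kind=f.kind, name=f.name,
                strand="-" if f.strand == "+" else "+",
                parts=parts, qualifiers=dict(f.qualifiers)))
        seq = "".join(b.chunks)

    if len(seq) != spec.length:
        raise InfeasibleSpec(
            f"layout length {len(seq)} != requested {spec.length}")
    feats = sorted(b.features, key=lambda f: (f.parts[0].start,
                                              f.kind, f.name))
    return AnnotatedGenome(id=f"synth_{spec.seed}", sequence=seq,
                           circular=spec.circular, features=feats)


def _split_gap_budget(rng, total: int, n_loci: int, elements):
    """Distribute the intergenic budget over the gaps that follow each
    locus and assign planted elements to gaps. Returns a list of
    (gap_size, gap_elements) aligned with the loci."""
    if n_loci == 0:
        return []
    elem_by_gap = [[] for _ in range(n_loci)]
    need = [0] * n_loci
    order = rng.permutation(n_loci)
    for i, el in enumerate(elements):
        g = int(order[i % n_loci])
        elem_by_gap[g].append(el)
        need[g] += len(el[1]) + 2
    spare = total - sum(need)
    if spare < 0:
        raise InfeasibleSpec("planted elements exceed intergenic budget")
    w = rng.dirichlet(np.ones(n_loci))
    extra = np.floor(w * spare).astype(int)
    extra[0] += spare - int(extra.sum())
    return [(need[i] + int(extra[i]), elem_by_gap[i]) for i in range(n_loci)]


# ------------------------------------------------------------- shredding

@dataclass(frozen=True)
class Trace:
    id: str
    sequence: str
    origin: str = "unknown"


@dataclass(frozen=True)
class ShredSpec:
    coverage: float
    seed: int
    read_length_mean: int = 750
    read_length_sd: int = 80
    substitution_error: float = 0.01
    nuclear_background: float = 0.0
    decoy_length: int | None = None
    decoy_gc: float | None = None
    decoy_insert: str | None = None


_BASES = np.array(list("ACGT"))


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(seq)) < rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def _shred(rng, source: str, circular: bool, coverage: float, mean: int,
           sd: int, err: float, origin: str, prefix: str) -> list[Trace]:
    L = len(source)
    if mean > L:
        raise ValueError("read length exceeds source length")
    n_reads = int(round(coverage * L / mean))
    doubled = source + source if circular else source
    traces = []
    for i in range(n_reads):
        ln = int(np.clip(rng.normal(mean, sd), 100, L))
        if circular:
            start = int(rng.integers(0, L))
        else:
            start = int(rng.integers(0, max(L - ln, 1)))
        read = doubled[start:start + ln]
        if len(read) < ln:  # linear tail
            read = doubled[start:]
        if rng.random() < 0.5:
            read = revcomp(read)
        read = _mutate(rng, read, err)
        traces.append(Trace(id=f"{prefix}{i:05d}", sequence=read,
                            origin=origin))
    return traces


def shred_traces(genome: AnnotatedGenome, spec: ShredSpec) -> list[Trace]:
    """Simulated trace archive: organelle reads at the requested coverage
    plus optional nuclear-background decoy reads."""
    if not 0 <= spec.substitution_error <= 0.2:
        raise ValueError("substitution_error outside [0, 0.2]")
    if spec.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(spec.seed)
    traces = _shred(rng, genome.sequence, genome.circular, spec.coverage,
                    spec.read_length_mean, spec.read_length_sd,
                    spec.substitution_error, "organelle", "org")
    if spec.nuclear_background > 0:
        dlen = spec.decoy_length or len(genome)
        dgc = (spec.decoy_gc if spec.decoy_gc is not None
               else gc_fraction(genome.sequence))
        decoy = _rand_seq(rng, dlen, dgc)
        if spec.decoy_insert:
            mid = dlen // 2
            ins = spec.decoy_insert
            decoy = decoy[:mid] + ins + decoy[mid + len(ins):]
            decoy = decoy[:dlen]
        traces += _shred(rng, decoy, False, spec.nuclear_background,
                         spec.read_length_mean, spec.read_length_sd,
                         spec.substitution_error, "nuclear", "nuc")
    return traces


# ------------------------------------------------------------- toy fixture

def toy_fixture():
    """A fixed 1.2 kb hand-written genome with hand-computed expected
    partition statistics (coding 535, intergenic 565, intronic 100)."""
    from .architecture import PartitionReport

    rng = np.random.default_rng(12345)
    seq = _rand_seq(rng, 1200, 0.40)
    # cob: exons (100,250)+(350,500), intron (250,350)
    seq = (seq[:100] + _rand_cds(rng, 150, (0.4, 0.4, 0.3)) +
           seq[250:])
    feats = [
        Feature("gene", "cob", "+", [Interval(100, 500)]),
        Feature("CDS", "cob", "+", [Interval(100, 250), Interval(350, 500)]),
        Feature("intron", "cob_i1", "+", [Interval(250, 350)]),
        Feature("gene", "trnM", "+", [Interval(600, 675)]),
        Feature("tRNA", "trnM", "+", [Interval(600, 675)]),
        Feature("gene", "rrnl_L1", "+", [Interval(800, 880)]),
        Feature("rRNA", "rrnl_L1", "+", [Interval(800, 880)]),
        Feature("gene", "rrnl_L2", "+", [Interval(900, 980)]),
        Feature("rRNA", "rrnl_L2", "+", [Interval(900, 980)]),
    ]
    genome = AnnotatedGenome(id="toy", sequence=seq, circular=True,
                             features=feats)
    expected = PartitionReport(genome_length=1200, coding_nt=535,
                               noncoding_nt=665, intergenic_nt=565,
                               intronic_nt=100)
    return genome, expected
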