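"""Genome-accounting and composition statistics.

The partition follows the four-definition accounting used for organelle
genome surveys:

  i)   coding nt  = union length of annotated protein- (CDS), rRNA- and
       tRNA-coding regions, minus any positions also annotated as intron;
  ii)  noncoding nt = genome length - coding nt;
  iii) intergenic nt = genome length - union length of gene loci
       (a locus spans its exons, introns and intronic ORFs);
  iv)  intronic nt = noncoding nt - intergenic nt.

Pseudogenes and intronic ORFs never count as coding. All statistics are
invariant under rotation of a circular genome and under strand flip.
"""

from __future__ import annotations

import logging
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._util import gc_fraction
from .genbank_io import AnnotatedGenome, Feature, feature_sequence

log = logging.getLogger(__name__)

CODING_KINDS = ("CDS", "tRNA", "rRNA")
# Gene loci for the intergenic accounting: explicit gene features plus any
# coding feature not already covered by one (locus = envelope incl. introns).
_LOCUS_KINDS = ("gene",) + CODING_KINDS


@dataclass(frozen=True)
class PartitionReport:
    genome_length: int
    coding_nt: int
    noncoding_nt: int
    intergenic_nt: int
    intronic_nt: int

    @property
    def coding_fraction(self) -> float:
        return self.coding_nt / self.genome_length

    @property
    def noncoding_fraction(self) -> float:
        return self.noncoding_nt / self.genome_length

    @property
    def intergenic_fraction(self) -> float:
        return self.intergenic_nt / self.genome_length

    @property
    def intronic_fraction(self) -> float:
        return self.intronic_nt / self.genome_length

    def as_dict(self) -> dict:
        return {
            "genome_length": self.genome_length,
            "coding_nt": self.coding_nt,
            "noncoding_nt": self.noncoding_nt,
            "intergenic_nt": self.intergenic_nt,
            "intronic_nt": self.intronic_nt,
            "coding_fraction": self.coding_fraction,
            "noncoding_fraction": self.noncoding_fraction,
            "intergenic_fraction": self.intergenic_fraction,
            "intronic_fraction": self.intronic_fraction,
        }


@dataclass(frozen=True)
class GCProfile:
    overall: float
    by_category: dict
    by_codon_position: tuple

    def as_dict(self) -> dict:
        return {
            "overall": self.overall,
            "by_category": dict(self.by_category),
            "by_codon_position": list(self.by_codon_position),
        }


@dataclass(frozen=True)
class SkewSeries:
    positions: np.ndarray
    values: np.ndarray
    window: int
    step: int


@dataclass
class GeneInventory:
    protein: int = 0
    rRNA: int = 0
    tRNA: int = 0
    protein_dedup: int = 0
    rRNA_dedup: int = 0
    tRNA_dedup: int = 0
    names: Counter = field(default_factory=Counter)
    fragments: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.protein + self.rRNA + self.tRNA

    @property
    def total_dedup(self) -> int:
        return self.protein_dedup + self.rRNA_dedup + self.tRNA_dedup

    def name_set(self) -> set:
        return set(self.names)

    def as_dict(self) -> dict:
        return {
            "protein": self.protein, "rRNA": self.rRNA, "tRNA": self.tRNA,
            "total": self.total,
            "protein_dedup": self.protein_dedup, "rRNA_dedup": self.rRNA_dedup,
            "tRNA_dedup": self.tRNA_dedup, "total_dedup": self.total_dedup,
            "fragments": dict(self.fragments),
        }


def _mask(parts, n: int, arr: np.ndarray) -> None:
    for p in parts:
        if p.wraps:
            arr[p.start:] = True
            arr[:p.end] = True
        else:
            arr[p.start:p.end] = True


def _check_bounds(genome: AnnotatedGenome) -> None:
    n = len(genome)
    for f in genome.features:
        for p in f.parts:
            hi = max(p.start, p.end)
            if hi > n:
                raise ValueError(f"feature '{f.name}' extends beyond sequence")


def _locus_features(genome: AnnotatedGenome) -> list[Feature]:
    """Gene loci: gene features, plus coding features not covered by one."""
    n = len(genome)
    genes = genome.features_of("gene")
    if not genes:
        return genome.features_of(*CODING_KINDS)
    covered = np.zeros(n, dtype=bool)
    for g in genes:
        _mask([g.envelope(n)], n, covered)
    extra = []
    for f in genome.features_of(*CODING_KINDS):
        inside = all(covered[pos] for p in f.parts
                     for pos in ([p.start, (p.end - 1) % n] if not p.wraps
                                 else [p.start, p.end - 1]))
        if not inside:
            extra.append(f)
    return genes + extra


def partition_genome(genome: AnnotatedGenome) -> PartitionReport:
    """The i-iv accounting. Overlapping coding parts are unioned; positions
    covered by both a coding part and an intron count as intronic."""
    _check_bounds(genome)
    n = len(genome)
    if not genome.features:
        warnings.warn("genome has no features; coding=0")
    coding = np.zeros(n, dtype=bool)
    for f in genome.features_of(*CODING_KINDS):
        _mask(f.parts, n, coding)
    intron = np.zeros(n, dtype=bool)
    for f in genome.features_of("intron"):
        _mask(f.parts, n, intron)
    coding &= ~intron

    gene_region = np.zeros(n, dtype=bool)
    for f in _locus_features(genome):
        _mask([f.envelope(n)], n, gene_region)

    coding_nt = int(coding.sum())
    noncoding_nt = n - coding_nt
    intergenic_nt = n - int(gene_region.sum())
    intronic_nt = noncoding_nt - intergenic_nt
    return PartitionReport(n, coding_nt, noncoding_nt, intergenic_nt,
                           intronic_nt)


def gc_content(seq_or_regions) -> float:
    """GC fraction of a sequence or an iterable of sequences."""
    if isinstance(seq_or_regions, str):
        return gc_fraction(seq_or_regions)
    return gc_fraction("".join(seq_or_regions))


def gc_by_codon_position(genome: AnnotatedGenome) -> tuple[float, float, float]:
    """GC at codon sites 1/2/3 over all protein-coding codons (intron-free,
    strand-resolved CDS concatenation; trailing partial codons dropped)."""
    counts = np.zeros((3, 2), dtype=np.int64)  # (pos, [gc, total])
    any_cds = False
    for f in genome.features_of("CDS"):
        seq = feature_sequence(genome, f)
        frame = int(f.qualifiers.get("codon_start", 1)) - 1
        seq = seq[frame:]
        if len(seq) % 3:
            warnings.warn(f"CDS '{f.name}' length not divisible by 3; "
                          "truncating trailing partial codon")
            seq = seq[:len(seq) - len(seq) % 3]
        if not seq:
            continue
        any_cds = True
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).reshape(-1, 3)
        for pos in range(3):
            col = arr[:, pos]
            valid = col != ord("N")
            counts[pos, 0] += int(np.count_nonzero(
                (col == ord("G")) | (col == ord("C"))))
            counts[pos, 1] += int(valid.sum())
    if not any_cds:
        raise ValueError("no protein-coding features")
    return tuple(counts[p, 0] / counts[p, 1] for p in range(3))


def cumulative_gc_skew(genome, window: int = 1000, step: int = 1000) -> SkewSeries:
    """Per-window (G-C)/(G+C), accumulated by running sum. Circular genomes
    wrap the final windows; a window with G+C=0 contributes 0."""
    if isinstance(genome, AnnotatedGenome):
        seq, circular = genome.sequence, genome.circular
    else:
        seq, circular = genome, False
    n = len(seq)
    if window < 1 or step < 1 or window > n:
        raise ValueError("window/step invalid for sequence length")
    src = seq + seq[:window] if circular else seq
    starts = range(0, n, step) if circular else range(0, n - window + 1, step)
    skews = []
    positions = []
    for s in starts:
        w = src[s:s + window]
        g, c = w.count("G"), w.count("C")
        if g + c == 0:
            log.debug("window at %d has G+C=0; skew set to 0", s)
            skews.append(0.0)
        else:
            skews.append((g - c) / (g + c))
        positions.append(s + window // 2)
    return SkewSeries(np.asarray(positions), np.cumsum(skews), window, step)


_FRAG_RE = re.compile(r"^(?P<base>.+?)[-_](?P<frag>(?:[SL]\d+|[a-f]|\d+))$")


def _fragment_base(name: str, fragment_map: dict | None) -> tuple[str, bool]:
    """(base name, is-fragment-labeled). Explicit map wins; otherwise a
    conservative suffix pattern like rrnl_L3 / rps2-a marks a candidate."""
    if fragment_map and name in fragment_map:
        return fragment_map[name], True
    m = _FRAG_RE.match(name)
    if m:
        return m.group("base"), True
    return name, False


def _merged_loci(genome: AnnotatedGenome, fragment_map: dict | None):
    """Gene loci with fragment-labeled modules of the same base gene merged
    (a fragmented rRNA like rrnl_L1..L6 counts as one gene with a fragment
    count). Fragment merging applies only when >=2 loci share a base name,
    so a lone dash-suffixed name keeps its own locus."""
    loci = _locus_features(genome)
    cand: dict[str, list[Feature]] = {}
    entries = []
    for f in loci:
        base, is_frag = _fragment_base(f.name, fragment_map)
        entries.append((f, base, is_frag))
        if is_frag:
            cand.setdefault(base, []).append(f)
    merged: list[tuple[str, list[Feature]]] = []
    seen_bases = set()
    for f, base, is_frag in entries:
        if is_frag and len(cand[base]) >= 2:
            if base not in seen_bases:
                seen_bases.add(base)
                merged.append((base, cand[base]))
        else:
            merged.append((f.name, [f]))
    return merged


def count_genes(genome: AnnotatedGenome, dedupe_ir: bool = False,
                fragment_map: dict | None = None) -> int:
    loci = _merged_loci(genome, fragment_map)
    if dedupe_ir:
        return len({name for name, _ in loci})
    return len(loci)


def intron_gene_ratio(genome: AnnotatedGenome,
                      include_intergenic_introns: bool = True,
                      dedupe_ir: bool = False,
                      fragment_map: dict | None = None) -> float:
    """(#introns) / (#genes). Defaults keep IR duplicates and include
    intergenic introns."""
    n_genes = count_genes(genome, dedupe_ir=dedupe_ir,
                          fragment_map=fragment_map)
    if n_genes == 0:
        raise ValueError("zero genes: intron/gene ratio undefined")
    introns = genome.features_of("intron")
    if not include_intergenic_introns:
        n = len(genome)
        gene_region = np.zeros(n, dtype=bool)
        for f in _locus_features(genome):
            _mask([f.envelope(n)], n, gene_region)
        introns = [f for f in introns
                   if gene_region[f.parts[0].start]]
    if dedupe_ir:
        # Collapse IR-duplicated introns by (name) when names repeat.
        n_introns = len({f.name for f in introns})
    else:
        n_introns = len(introns)
    return n_introns / n_genes


def _locus_class(genome: AnnotatedGenome, feats: list[Feature]) -> str:
    n = len(genome)
    kinds = {f.kind for f in feats}
    if kinds & {"tRNA", "rRNA", "CDS"}:
        for k, cls in (("tRNA", "tRNA"), ("rRNA", "rRNA"), ("CDS", "protein")):
            if k in kinds:
                return cls
    # gene feature without typed child among the merged loci: look for a
    # contained coding feature, then fall back to the naming convention.
    env = [f.envelope(n) for f in feats]
    for child in genome.features_of(*CODING_KINDS):
        cs = child.parts[0].start
        if any(e.contains(cs, n) for e in env):
            return {"CDS": "protein"}.get(child.kind, child.kind)
    name = feats[0].name.lower()
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn"):
        return "rRNA"
    return "protein"


def gene_inventory(genome: AnnotatedGenome,
                   fragment_map: dict | None = None) -> GeneInventory:
    inv = GeneInventory()
    loci = _merged_loci(genome, fragment_map)
    by_class_names: dict[str, list[str]] = {"protein": [], "rRNA": [], "tRNA": []}
    for name, feats in loci:
        cls = _locus_class(genome, feats)
        by_class_names[cls].append(name)
        inv.names[name] += 1
        if len(feats) > 1:
            inv.fragments[name] = len(feats)
    inv.protein = len(by_class_names["protein"])
    inv.rRNA = len(by_class_names["rRNA"])
    inv.tRNA = len(by_class_names["tRNA"])
    inv.protein_dedup = len(set(by_class_names["protein"]))
    inv.rRNA_dedup = len(set(by_class_names["rRNA"]))
    inv.tRNA_dedup = len(set(by_class_names["tRNA"]))
    return inv


def gene_set_compare(inventories: dict, synonyms: dict | None = None) -> dict:
    """Venn-style partition of deduplicated gene-name sets.

    ``inventories`` maps a label to a GeneInventory or a set of names.
    Returns {frozenset(labels): sorted gene names exclusive to that subset};
    cells are disjoint and union to the full name universe.
    """
    if len(inventories) < 2:
        raise ValueError("need at least two inventories")
    syn = synonyms or {}
    sets = {}
    for label, inv in inventories.items():
        names = inv.name_set() if isinstance(inv, GeneInventory) else set(inv)
        sets[label] = {syn.get(nm, nm) for nm in names}
    cells: dict[frozenset, list] = {}
    universe = set().union(*sets.values())
    for gene in sorted(universe):
        cell = frozenset(lbl for lbl, s in sets.items() if gene in s)
        cells.setdefault(cell, []).append(gene)
    return cells


def gc_profile(genome: AnnotatedGenome) -> GCProfile:
    """Overall GC plus GC by category (coding / intron+intronic ORF /
    intergenic) and by codon position."""
    n = len(genome)
    coding = np.zeros(n, dtype=bool)
    for f in genome.features_of(*CODING_KINDS):
        _mask(f.parts, n, coding)
    intron = np.zeros(n, dtype=bool)
    for f in genome.features_of("intron", "intronic_ORF"):
        _mask(f.parts, n, intron)
    coding &= ~intron
    gene_region = np.zeros(n, dtype=bool)
    for f in _locus_features(genome):
        _mask([f.envelope(n)], n, gene_region)
    arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)

    def _gc(mask):
        sel = arr[mask]
        denom = int(np.count_nonzero(sel != ord("N")))
        if denom == 0:
            return float("nan")
        gc = int(np.count_nonzero((sel == ord("G")) | (sel == ord("C"))))
        return gc / denom

    by_cat = {
        "coding": _gc(coding),
        "intron": _gc(intron),
        "intergenic": _gc(~gene_region),
    }
    try:
        codon = gc_by_codon_position(genome)
    except ValueError:
        codon = (float("nan"),) * 3
    return GCProfile(overall=gc_content(genome.sequence),
                     by_category=by_cat, by_codon_position=codon)
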