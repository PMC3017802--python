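"""Palindromic (hairpin-capable) element detection and cluster analysis.

A hairpin here is a combinatorial stem-loop: two arms that are mutually
reverse-complementary within a small mismatch budget, separated by a short
loop. Detection is a direct stem-loop scan (no thermodynamic folding);
G-T wobble pairs do not count as pairing unless enabled. Hairpins are
grouped into genomic clusters by gap chaining, clusters into families by
strand-canonicalized sequence identity, and each family gets a
column-majority IUPAC consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import IUPAC, gc_fraction, revcomp
from .genbank_io import AnnotatedGenome, Interval

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class Hairpin:
    position: Interval  # whole element, half-open
    stem_len: int
    loop: str
    arm_mismatches: int
    gc: float

    @property
    def length(self) -> int:
        return self.position.end - self.position.start


@dataclass
class PalindromeCluster:
    region: Interval
    hairpins: list
    length: int
    gc: float
    context: str = "unknown"


@dataclass
class ClusterConsensus:
    members: list
    consensus: str
    occurrences: int


def _pairs_ok(a: str, b: str, allow_wobble: bool) -> bool:
    if (a, b) in _PAIRS:
        return True
    return allow_wobble and (a, b) in _WOBBLE


def find_hairpins(seq: str, min_stem: int = 8, loop_range=(3, 12),
                  max_arm_mismatch: int = 1,
                  allow_wobble: bool = False) -> list[Hairpin]:
    """All maximal stem-loops with stem >= min_stem, loop length within
    loop_range and <= max_arm_mismatch unpaired stem positions; overlapping
    calls resolved to the longest stem, then leftmost."""
    seq = seq.upper()
    n = len(seq)
    lo, hi = loop_range
    if n < 2 * min_stem + lo:
        return []
    candidates = []
    for loop_len in range(lo, hi + 1):
        for loop_start in range(1, n - loop_len):
            left = loop_start - 1
            right = loop_start + loop_len
            # innermost pair must close the loop
            if right >= n or not _pairs_ok(seq[left], seq[right], allow_wobble):
                continue
            mm = 0
            stem = 0
            best_stem, best_mm = 0, 0
            while left >= 0 and right < n:
                if _pairs_ok(seq[left], seq[right], allow_wobble):
                    stem += 1
                    best_stem, best_mm = stem, mm
                else:
                    mm += 1
                    if mm > max_arm_mismatch:
                        break
                    stem += 1
                left -= 1
                right += 1
            if best_stem >= min_stem:
                start = loop_start - best_stem
                end = loop_start + loop_len + best_stem
                element = seq[start:end]
                candidates.append(Hairpin(
                    position=Interval(start, end), stem_len=best_stem,
                    loop=seq[loop_start:loop_start + loop_len],
                    arm_mismatches=best_mm, gc=gc_fraction(element)))
    # longest stem first, then leftmost; keep non-overlapping
    candidates.sort(key=lambda h: (-h.stem_len, h.position.start,
                                   h.position.end))
    chosen: list[Hairpin] = []
    taken = np.zeros(n, dtype=bool)
    for h in candidates:
        if taken[h.position.start:h.position.end].any():
            continue
        taken[h.position.start:h.position.end] = True
        chosen.append(h)
    chosen.sort(key=lambda h: h.position.start)
    return chosen


def verify_hairpin(seq: str, h: Hairpin, allow_wobble: bool = False) -> bool:
    """Independent re-check: revcomp(left arm) matches the right arm within
    the recorded mismatch budget."""
    left = seq[h.position.start:h.position.start + h.stem_len]
    right = seq[h.position.end - h.stem_len:h.position.end]
    rc = revcomp(right)
    if len(left) != len(rc):
        return False
    mm = sum(1 for a, b in zip(left, rc)
             if a != b and not (allow_wobble and
                                (a, b) in {("G", "A"), ("A", "G"),
                                           ("T", "C"), ("C", "T")}))
    return mm <= h.arm_mismatches


def cluster_hairpins(hairpins: list[Hairpin], max_gap: int = 30,
                     genome: AnnotatedGenome | None = None,
                     seq: str | None = None) -> list[PalindromeCluster]:
    """Single-linkage chaining: adjacent hairpins separated by <= max_gap
    join one cluster. Cluster length spans first hairpin start to last
    hairpin end. Context is classified from genome annotations if given."""
    if not hairpins:
        return []
    hairpins = sorted(hairpins, key=lambda h: h.position.start)
    clusters = []
    cur = [hairpins[0]]
    for h in hairpins[1:]:
        if h.position.start - cur[-1].position.end <= max_gap:
            cur.append(h)
        else:
            clusters.append(cur)
            cur = [h]
    clusters.append(cur)
    out = []
    for group in clusters:
        region = Interval(group[0].position.start, group[-1].position.end)
        if seq is not None:
            gc = gc_fraction(seq[region.start:region.end])
        else:
            gc = float(np.mean([h.gc for h in group]))
        context = "unknown"
        if genome is not None:
            context = _classify_context(genome, region)
        out.append(PalindromeCluster(
            region=region, hairpins=group, length=region.end - region.start,
            gc=gc, context=context))
    return out


def _classify_context(genome: AnnotatedGenome, region: Interval) -> str:
    """Majority context of the region: coding / intronic / intergenic."""
    from .architecture import CODING_KINDS, _locus_features, _mask

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
    sl = slice(region.start, min(region.end, n))
    counts = {
        "coding": int(coding[sl].sum()),
        "intronic": int(intron[sl].sum()),
        "intergenic": int((~gene_region[sl]).sum()),
    }
    return max(counts, key=counts.get)


def _cluster_seq(seq: str, cluster: PalindromeCluster) -> str:
    return seq[cluster.region.start:cluster.region.end]


def _canon(s: str) -> str:
    """Strand canonicalization: a cluster and its reverse complement are
    the same object; the lexicographically smaller strand is the key."""
    rc = revcomp(s)
    return min(s, rc)


def build_consensus(clusters: list[PalindromeCluster], seq: str,
                    identity: float = 0.7) -> list[ClusterConsensus]:
    """Group clusters into families by pairwise identity of their
    strand-canonicalized sequences (single linkage), then build a
    column-majority IUPAC consensus per family against its longest member."""
    import edlib

    if not clusters:
        raise ValueError("no clusters")
    seqs = [_canon(_cluster_seq(seq, c)) for c in clusters]
    n = len(clusters)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(n):
        for b in range(a + 1, n):
            if find(a) == find(b):
                continue
            la, lb = len(seqs[a]), len(seqs[b])
            span = max(la, lb)
            res = edlib.align(seqs[a], seqs[b], mode="NW", task="distance")
            if 1 - res["editDistance"] / span >= identity:
                parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for idx in groups.values():
        members = [clusters[i] for i in idx]
        mseqs = [seqs[i] for i in idx]
        ref = max(mseqs, key=len)
        cols: list[list[str]] = [[] for _ in range(len(ref))]
        for s in mseqs:
            if s == ref:
                for i, ch in enumerate(s):
                    cols[i].append(ch)
                continue
            res = edlib.align(s, ref, mode="NW", task="path")
            qi = ti = 0
            for count, op in _cigar_ops(res["cigar"]):
                for _ in range(count):
                    if op in "=XM":
                        cols[ti].append(s[qi])
                        qi += 1
                        ti += 1
                    elif op == "I":   # insertion in query: no ref column
                        qi += 1
                    elif op == "D":   # deletion: ref column gets a gap
                        cols[ti].append("-")
                        ti += 1
        consensus = []
        for col in cols:
            bases = [b for b in col if b != "-"]
            if not bases:
                continue
            counts = {}
            for b in bases:
                counts[b] = counts.get(b, 0) + 1
            top = max(counts.values())
            tied = frozenset(b for b, c in counts.items() if c == top)
            consensus.append(IUPAC.get(tied, "N") if len(tied) > 1
                             else next(iter(tied)))
        out.append(ClusterConsensus(members=members,
                                    consensus="".join(consensus),
                                    occurrences=len(members)))
    out.sort(key=lambda c: -c.occurrences)
    return out


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def loop_motif_tally(hairpins: list[Hairpin],
                     motifs=("TTTA", "TTT")) -> dict:
    """Count hairpins whose loop contains each motif; longest motif first,
    each hairpin counted at most once."""
    ordered = sorted(motifs, key=len, reverse=True)
    tally = {m: 0 for m in motifs}
    for h in hairpins:
        for m in ordered:
            if m in h.loop:
                tally[m] += 1
                break
    return tally
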