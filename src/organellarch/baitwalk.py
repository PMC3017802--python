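"""Bait-and-walk assembly of organelle genomes from shotgun trace archives.

The pipeline mirrors how organelle genomes are mined from whole-genome
shotgun trace archives: recruit organelle-like traces by seeded similarity
to bait sequences (word size 11, BLAST-style scoring: match 2, mismatch -3,
gap open 5, gap extend 2, similarity cutoff 80% over >=100 aligned nt),
assemble recruits by greedy overlap-layout-consensus (identity >= 98% over
>= 500 nt overlaps; match 1, mismatch -2, gap -2, first gap -3), then
iteratively re-bait with contig ends ("walking") until nothing grows, and
close the circle when the contig ends overlap.

Traces are treated as substitution-only (no indel) sequences: overlaps are
located by exact-seed diagonal voting and verified by Hamming identity,
and the consensus is a coverage-weighted per-column majority.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._util import encode, kmer_ints, minimal_rotation, revcomp
from .synth import Trace

log = logging.getLogger(__name__)

RECRUIT_SCORES = (2, -3, 5, 2)   # match, mismatch, gap open, gap extend
ASSEMBLY_SCORES = (1, -2, -2, -3)  # match, mismatch, gap, first gap
_WORD = 11
_ASM_K = 21
_STRIDE = 4


@dataclass(frozen=True)
class RecruitmentHit:
    trace_id: str
    bait_id: str
    aligned_length: int
    identity: float
    score: int
    strand: str
    offset: int  # trace start in bait coordinates


@dataclass(frozen=True)
class LayoutEntry:
    trace_id: str
    offset: int
    strand: int  # +1 / -1
    length: int
    identity: float


@dataclass
class Contig:
    consensus: str
    layout: list
    coverage: np.ndarray
    circular: bool = False

    def __len__(self):
        return len(self.consensus)


def _as_traces(items) -> list[Trace]:
    out = []
    for t in items:
        if isinstance(t, Trace):
            out.append(t)
        else:
            tid, seq = t
            out.append(Trace(id=tid, sequence=seq.upper()))
    return out


def _best_diagonal(votes: Counter):
    (key, n), = votes.most_common(1) or [((None, None), 0)]
    return key, n


def recruit_traces(archive, baits, min_similarity: float = 0.80,
                   min_span: int = 100, word_size: int = _WORD) -> list[RecruitmentHit]:
    """Best local (gap-free, seeded) alignment of every trace against the
    baits on both strands; hits kept when identity over the aligned span
    exceeds ``min_similarity`` and the span is at least ``min_span``."""
    archive = _as_traces(archive)
    if not baits:
        raise ValueError("no bait sequences")
    baits = [b if isinstance(b, tuple) else (f"bait{i}", b)
             for i, b in enumerate(baits)]
    bait_idx = []
    for bid, bseq in baits:
        km = kmer_ints(bseq.upper(), word_size)
        order = np.argsort(km, kind="stable")
        bait_idx.append((bid, bseq.upper(), km[order], order))
    match_s, mismatch_s = RECRUIT_SCORES[0], RECRUIT_SCORES[1]
    hits = []
    for tr in archive:
        best = None
        for strand, seq in (("+", tr.sequence), ("-", revcomp(tr.sequence))):
            if len(seq) < word_size:
                continue
            tk = kmer_ints(seq, word_size)[::_STRIDE]
            tpos = np.arange(0, len(seq) - word_size + 1)[::_STRIDE]
            for bid, bseq, skm, order in bait_idx:
                loc = np.searchsorted(skm, tk)
                votes: Counter = Counter()
                for qi, v in enumerate(tk):
                    if v < 0:
                        continue
                    li = loc[qi]
                    while li < len(skm) and skm[li] == v:
                        votes[int(order[li]) - int(tpos[qi])] += 1
                        li += 1
                if not votes:
                    continue
                for d, _ in votes.most_common(3):
                    t0 = max(0, -d)
                    b0 = max(0, d)
                    span = min(len(seq) - t0, len(bseq) - b0)
                    if span < min_span:
                        continue
                    a = encode(seq[t0:t0 + span])
                    b = encode(bseq[b0:b0 + span])
                    matches = int(np.count_nonzero(a == b))
                    ident = matches / span
                    score = matches * match_s + (span - matches) * mismatch_s
                    cand = (score, span, ident, bid, strand, d)
                    if best is None or cand[:2] > best[:2]:
                        best = cand
        if best is not None:
            score, span, ident, bid, strand, d = best
            if ident > min_similarity and span >= min_span:
                hits.append(RecruitmentHit(
                    trace_id=tr.id, bait_id=bid, aligned_length=span,
                    identity=ident, score=score, strand=strand, offset=d))
    return hits


# ----------------------------------------------------------------- assembly

def _compose(parent_place, o, s, la, lx):
    """Placement of x relative to the root, given x's placement (o, s) in
    a frame whose owner (length ``la``) is placed at ``parent_place``."""
    op, sp = parent_place
    if sp == 1:
        return (op + o, s)
    return (op + la - o - lx, -s)


class _Layout:
    """Union-find over traces carrying (offset, strand) placements."""

    def __init__(self, lengths):
        self.parent = list(range(len(lengths)))
        self.place = [(0, 1)] * len(lengths)  # relative to parent
        self.size = [1] * len(lengths)
        self.lengths = lengths

    def find(self, x):
        chain = []
        while self.parent[x] != x:
            chain.append(x)
            x = self.parent[x]
        root = x
        # recompose placements top-down, then compress
        place = (0, 1)
        for node in reversed(chain):
            p = self.parent[node]
            pplace = (0, 1) if p == root else self.place[p]
            o, s = self.place[node]
            mine = _compose(pplace, o, s, self.lengths[p], self.lengths[node])
            self.parent[node] = root
            self.place[node] = mine
        if chain:
            return root, self.place[chain[0]]
        return root, (0, 1)

    def union(self, a, b, rel, d) -> bool:
        """b (oriented ``rel``) sits at offset d in a's forward frame."""
        ra, pa = self.find(a)
        rb, pb = self.find(b)
        if ra == rb:
            return False
        la, lb = self.lengths[a], self.lengths[b]
        target = _compose(pa, d, rel, la, lb)  # b in ra frame
        ob, sb = pb
        ot, st = target
        if sb == st:
            O, S = ot - ob, 1
        else:
            O, S = ot + ob + lb, -1
        lrb = self.lengths[rb]
        if S == 1:
            self.parent[rb] = ra
            self.place[rb] = (O, 1)
        else:
            self.parent[rb] = ra
            self.place[rb] = (O - lrb, -1)
        self.size[ra] += self.size[rb]
        return True


def _overlap_candidates(seqs, k=_ASM_K, stride=_STRIDE):
    """Candidate pairwise overlaps via shared-k-mer diagonal voting.
    Returns {(a, b): Counter({(rel, d): votes})} with a < b and d the
    offset of oriented-b in a's forward frame."""
    index: dict[int, list] = {}
    for rid, seq in enumerate(seqs):
        km = kmer_ints(seq, k)
        for p in range(0, len(km), stride):
            v = int(km[p])
            if v >= 0:
                index.setdefault(v, []).append((rid, p))
    votes: dict[tuple, Counter] = {}
    for rid, seq in enumerate(seqs):
        for rel, s in ((1, seq), (-1, revcomp(seq))):
            km = kmer_ints(s, k)
            for j in range(len(km)):
                v = int(km[j])
                if v < 0 or v not in index:
                    continue
                for aid, i in index[v]:
                    if aid >= rid:
                        continue
                    votes.setdefault((aid, rid), Counter())[(rel, i - j)] += 1
    return votes


def _verify_overlap(sa: str, sb: str, rel: int, d: int):
    """(span, identity, matches) of the implied gap-free overlap."""
    ob = sb if rel == 1 else revcomp(sb)
    a0 = max(0, d)
    b0 = max(0, -d)
    span = min(len(sa) - a0, len(ob) - b0)
    if span <= 0:
        return 0, 0.0, 0
    ea = encode(sa[a0:a0 + span])
    eb = encode(ob[b0:b0 + span])
    matches = int(np.count_nonzero(ea == eb))
    return span, matches / span, matches


def assemble(traces, min_identity: float = 0.98, min_overlap: int = 500,
             scores=ASSEMBLY_SCORES) -> list[Contig]:
    """Greedy overlap-layout-consensus: pairwise candidate overlaps are
    verified (identity >= min_identity over >= min_overlap nt, either
    strand) and merged best-score-first (ties: longer overlap, then trace
    ids); consensus is a per-column coverage-weighted majority. Singletons
    come back as one-trace contigs."""
    traces = _as_traces(traces)
    if not traces:
        raise ValueError("no traces to assemble")
    shortest = min(len(t.sequence) for t in traces)
    if min_overlap > shortest:
        warnings.warn(f"min_overlap {min_overlap} exceeds shortest trace "
                      f"({shortest} nt); lowering to it")
        min_overlap = max(50, shortest)
    seqs = [t.sequence for t in traces]
    ids = [t.id for t in traces]
    match_s, mismatch_s = scores[0], scores[1]
    cand = _overlap_candidates(seqs)
    overlaps = []
    for (a, b), ctr in cand.items():
        for (rel, d), _ in ctr.most_common(2):
            span, ident, matches = _verify_overlap(seqs[a], seqs[b], rel, d)
            if span >= min_overlap and ident >= min_identity:
                score = matches * match_s + (span - matches) * mismatch_s
                overlaps.append((score, span, ident, a, b, rel, d))
                break
    overlaps.sort(key=lambda o: (-o[0], -o[1], ids[o[3]], ids[o[4]]))
    lay = _Layout([len(s) for s in seqs])
    for score, span, ident, a, b, rel, d in overlaps:
        lay.union(a, b, rel, d)
    comps: dict[int, list] = {}
    for i in range(len(seqs)):
        root, place = lay.find(i)
        comps.setdefault(root, []).append((i, place))
    contigs = []
    for members in comps.values():
        contigs.append(_consensus(members, seqs, ids))
    contigs.sort(key=lambda c: (-len(c.consensus),
                                c.layout[0].trace_id if c.layout else ""))
    return contigs


def _consensus(members, seqs, ids) -> Contig:
    off0 = min(o for _, (o, _) in members)
    L = max(o - off0 + len(seqs[i]) for i, (o, _) in members)
    votes = np.zeros((L, 4), dtype=np.int32)
    placed = []
    for i, (o, s) in members:
        seq = seqs[i] if s == 1 else revcomp(seqs[i])
        codes = encode(seq)
        start = o - off0
        valid = codes < 4
        idx = np.arange(start, start + len(seq))[valid]
        votes[idx, codes[valid]] += 1
        placed.append((i, start, s))
    best = votes.argmax(axis=1)
    cov = votes.sum(axis=1)
    cons = np.array(list("ACGT"))[best]
    cons[cov == 0] = "N"
    consensus = "".join(cons)
    ccodes = encode(consensus)
    layout = []
    for i, start, s in placed:
        seq = seqs[i] if s == 1 else revcomp(seqs[i])
        codes = encode(seq)
        seg = ccodes[start:start + len(seq)]
        ident = float(np.count_nonzero(seg == codes)) / len(seq)
        layout.append(LayoutEntry(ids[i], start, s, len(seq), ident))
    layout.sort(key=lambda e: (e.offset, e.trace_id))
    return Contig(consensus=consensus, layout=layout, coverage=cov)


# ----------------------------------------------------------------- walking

def _contig_as_traces(contigs):
    return [Trace(id=f"__contig{i}__", sequence=c.consensus)
            for i, c in enumerate(contigs)]


def _expand_pseudo(contig: Contig, originals: list[Contig]) -> Contig:
    """Replace pseudo contig-traces in a layout by their member traces."""
    layout = []
    for e in contig.layout:
        if e.trace_id.startswith("__contig") and e.trace_id.endswith("__"):
            src = originals[int(e.trace_id[8:-2])]
            for m in src.layout:
                if e.strand == 1:
                    layout.append(LayoutEntry(m.trace_id, e.offset + m.offset,
                                              m.strand, m.length, m.identity))
                else:
                    off = e.offset + len(src.consensus) - m.offset - m.length
                    layout.append(LayoutEntry(m.trace_id, off, -m.strand,
                                              m.length, m.identity))
        else:
            layout.append(e)
    layout.sort(key=lambda e: (e.offset, e.trace_id))
    return Contig(consensus=contig.consensus, layout=layout,
                  coverage=contig.coverage, circular=contig.circular)


def walk(archive, contigs: list[Contig], max_rounds: int = 50,
         end_window: int = 1000, min_similarity: float = 0.80,
         min_identity: float = 0.98, min_overlap: int = 500) -> list[Contig]:
    """Iteratively re-bait with contig ends against the unused archive and
    re-assemble recruits with the current contigs. Stops when no contig
    grows or after max_rounds. Total assembled length never decreases."""
    archive = _as_traces(archive)
    by_id = {t.id: t for t in archive}
    used = {e.trace_id for c in contigs for e in c.layout}
    for _ in range(max_rounds):
        baits = []
        for i, c in enumerate(contigs):
            if c.circular:
                continue
            w = min(end_window, len(c.consensus))
            baits.append((f"end_{i}_head", c.consensus[:w]))
            baits.append((f"end_{i}_tail", c.consensus[-w:]))
        if not baits:
            break
        unused = [t for t in archive if t.id not in used]
        if not unused:
            break
        hits = recruit_traces(unused, baits, min_similarity=min_similarity)
        new_ids = {h.trace_id for h in hits}
        if not new_ids:
            break
        new_traces = [by_id[i] for i in sorted(new_ids)]
        merged = assemble(_contig_as_traces(contigs) + new_traces,
                          min_identity=min_identity, min_overlap=min_overlap)
        merged = [_expand_pseudo(c, contigs) for c in merged]
        # Progress metric: the longest assembled sequence. The naive sum of
        # contig lengths can drop when two overlapping contigs merge, which
        # is progress, not loss.
        new_max = max(len(c) for c in merged)
        old_max = max(len(c) for c in contigs)
        if new_max < old_max:
            log.warning("walk round would shrink the assembly; stopping")
            break
        used |= new_ids
        grew = new_max > old_max or len(merged) < len(contigs)
        contigs = merged
        if not grew:
            break
    # Final pass: re-assemble every recruited trace from scratch so the
    # consensus is a true coverage-weighted majority (the incremental merges
    # let a contig vote as a single trace) and the coverage track is real.
    final_ids = sorted({e.trace_id for c in contigs for e in c.layout
                        if e.trace_id in by_id})
    if final_ids:
        rebuilt = assemble([by_id[i] for i in final_ids],
                           min_identity=min_identity,
                           min_overlap=min_overlap)
        # prefer the true-majority rebuild unless it broke the assembly
        if max(len(c) for c in rebuilt) >= 0.95 * max(len(c) for c in contigs):
            contigs = rebuilt
    return contigs


# ----------------------------------------------------------- circularization

def detect_circularity(contig: Contig, min_end_overlap: int = 500,
                       min_identity: float = 0.98) -> Contig:
    """If the contig's two ends overlap at >= min_identity over >=
    min_end_overlap nt, trim one copy, mark circular, and rotate to the
    canonical origin (lexicographically minimal rotation of the canonical
    strand). An ambiguous double closure leaves the contig linear."""
    s = contig.consensus
    L = len(s)
    if contig.circular or L < 2 * min_end_overlap:
        return contig
    km = kmer_ints(s, _ASM_K)
    head_limit = L // 2
    index: dict[int, list] = {}
    for p in range(0, head_limit, 1):
        v = int(km[p]) if p < len(km) else -1
        if v >= 0:
            index.setdefault(v, []).append(p)
    votes: Counter = Counter()
    for p in range(max(head_limit, L - head_limit - _ASM_K), len(km)):
        v = int(km[p])
        if v < 0 or v not in index:
            continue
        for q in index[v]:
            d = p - q
            if L - d >= min_end_overlap:
                votes[d] += 1
    qualifying = []
    for d, _ in votes.most_common(5):
        ov = L - d
        if ov < min_end_overlap or ov > L - 1:
            continue
        a = encode(s[d:])
        b = encode(s[:ov])
        ident = float(np.count_nonzero(a == b)) / ov
        if ident >= min_identity:
            qualifying.append((d, ov, ident))
    if not qualifying:
        return contig
    qualifying.sort()
    if len(qualifying) > 1 and qualifying[1][0] - qualifying[0][0] > _ASM_K:
        warnings.warn("ambiguous circular closure (tandem end repeat); "
                      "leaving contig linear")
        return contig
    d, ov, ident = qualifying[0]
    circ = s[:d]
    cov = contig.coverage
    cov2 = cov[:d].copy()
    cov2[:ov] += cov[d:d + ov]
    rot_f = minimal_rotation(circ)
    cand_f = circ[rot_f:] + circ[:rot_f]
    rc = revcomp(circ)
    rot_r = minimal_rotation(rc)
    cand_r = rc[rot_r:] + rc[:rot_r]
    if cand_f <= cand_r:
        final, rot, flip = cand_f, rot_f, False
    else:
        final, rot, flip = cand_r, rot_r, True
    Lc = len(circ)
    layout = []
    for e in contig.layout:
        o, st = e.offset % Lc, e.strand
        if flip:
            o, st = (Lc - o - e.length) % Lc, -st
        o = (o - rot) % Lc
        layout.append(LayoutEntry(e.trace_id, o, st, e.length, e.identity))
    layout.sort(key=lambda e: (e.offset, e.trace_id))
    cov_final = np.roll(cov2[::-1] if flip else cov2, -rot)
    return Contig(consensus=final, layout=layout, coverage=cov_final,
                  circular=True)


# ----------------------------------------------------------------- reporting

def evaluate_assembly(contig: Contig, truth, archive=None,
                      recruited=None) -> dict:
    """Identity to a known truth genome (rotation- and strand-aware), mean
    and minimum coverage, and recruited-trace purity when the archive
    carries origin tags. Purity is computed over ``recruited`` trace ids
    when given (everything recruitment pulled in), else over the traces in
    the contig layout."""
    import edlib

    truth_seq = truth.sequence if hasattr(truth, "sequence") else str(truth)
    circular = getattr(truth, "circular", False)
    target = truth_seq + truth_seq if circular else truth_seq
    best = 0.0
    for cand in (contig.consensus, revcomp(contig.consensus)):
        res = edlib.align(cand, target, mode="HW", task="distance")
        ident = 1.0 - res["editDistance"] / len(cand)
        best = max(best, ident)
    total_bases = sum(e.length for e in contig.layout)
    mean_cov = total_bases / len(contig.consensus) if len(contig.consensus) else 0
    min_cov = int(contig.coverage.min()) if len(contig.coverage) else 0
    purity = None
    if archive is not None:
        origins = {t.id: t.origin for t in _as_traces(archive)
                   if isinstance(t, Trace)}
        pool = (list(recruited) if recruited is not None
                else [e.trace_id for e in contig.layout])
        tagged = [origins.get(tid) for tid in pool]
        tagged = [o for o in tagged if o in ("organelle", "nuclear")]
        if tagged:
            purity = tagged.count("organelle") / len(tagged)
    return {
        "identity_to_truth": best,
        "length": len(contig.consensus),
        "mean_coverage": mean_cov,
        "min_coverage": min_cov,
        "recruited_purity": purity,
        "n_traces": len(contig.layout),
        "circular": contig.circular,
    }
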