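"""Large inverted-repeat detection and quadripartite partitioning.

Plastid genomes typically carry two long reverse-complementary segments
(IR_A / IR_B) separating a large and a small single-copy region (LSC/SSC).
Detection is exact-seed matching (k-mers of the forward strand against
their reverse complements), chaining of seeds on a common anti-diagonal,
and X-drop extension of the best candidate, all on the doubled sequence so
the result is rotation-invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._util import encode, kmer_ints, revcomp
from .genbank_io import AnnotatedGenome, Interval, extract

log = logging.getLogger(__name__)

SEED_K = 25
_XDROP = 20
_MATCH, _MISMATCH = 1, -3


@dataclass(frozen=True)
class QuadripartiteMap:
    ir_a: Interval
    ir_b: Interval
    lsc: Interval
    ssc: Interval
    ir_length: int
    mismatches: int

    def regions(self) -> dict:
        return {"IR_A": self.ir_a, "LSC": self.lsc,
                "IR_B": self.ir_b, "SSC": self.ssc}

    def as_dict(self, seq_len: int | None = None) -> dict:
        def iv(i):
            return {"start": i.start, "end": i.end, "wraps": i.wraps}
        return {"ir_a": iv(self.ir_a), "ir_b": iv(self.ir_b),
                "lsc": iv(self.lsc), "ssc": iv(self.ssc),
                "ir_length": self.ir_length, "mismatches": self.mismatches}


def _rc_kmer_positions(seq: str, k: int):
    """Anti-diagonal seed pairs (i, j), i < j: seq[i:i+k] is the reverse
    complement of seq[j:j+k]. Returned as the constant c = i + j + k - 1
    per pair (pairs on the same inverted-repeat share c)."""
    fw = kmer_ints(seq, k)
    rc = kmer_ints(revcomp(seq), k)[::-1]  # rc[i] = kmer of revcomp(seq[i:i+k])
    order_f = np.argsort(fw, kind="stable")
    order_r = np.argsort(rc, kind="stable")
    fs, rs = fw[order_f], rc[order_r]
    pairs = []
    ia = ib = 0
    nf, nr = len(fs), len(rs)
    while ia < nf and ib < nr:
        a, b = fs[ia], rs[ib]
        if a < b:
            ia += 1
        elif a > b:
            ib += 1
        else:
            ja = ia
            while ja < nf and fs[ja] == a:
                ja += 1
            jb = ib
            while jb < nr and rs[jb] == b:
                jb += 1
            if a >= 0 and (ja - ia) * (jb - ib) <= 4096:
                for x in order_f[ia:ja]:
                    for y in order_r[ib:jb]:
                        if x < y:
                            pairs.append((int(x), int(y)))
            ia, ib = ja, jb
    return pairs


def _extend_anti(codes: np.ndarray, comp_codes: np.ndarray, a0: int, b_last: int,
                 length: int, lo: int, hi: int):
    """X-drop extension of an anti-diagonal match. Pairs are
    (a0+t, b_last-t); extension left decrements a0 (increments b_last),
    extension right increments a-end (decrements b-start). ``lo``/``hi``
    bound the usable coordinate range. Returns (a0, b_last, length, mm)."""
    c = a0 + b_last  # invariant pair-sum

    def ok(i):
        j = c - i
        return comp_codes[j] == codes[i]

    # right: grow a-end while arms stay disjoint
    best_gain, gain = 0, 0
    score, best = 0, 0
    i = a0 + length
    right = 0
    while i <= (c - 1) // 2 and c - i <= hi and i < len(codes):
        score += _MATCH if ok(i) else _MISMATCH
        if score > best:
            best, right = score, i - (a0 + length) + 1
        if best - score > _XDROP:
            break
        i += 1
    # left: grow a-start downwards
    score, best = 0, 0
    i = a0 - 1
    left = 0
    while i >= lo and c - i < len(codes):
        score += _MATCH if ok(i) else _MISMATCH
        if score > best:
            best, left = score, a0 - i
        if best - score > _XDROP:
            break
        i -= 1
    a0 -= left
    length += left + right
    b_last = c - a0
    mm = sum(0 if ok(i) else 1 for i in range(a0, a0 + length))
    return a0, b_last, length, mm


def find_inverted_repeat(genome, min_len: int = 1000,
                         max_mismatch_frac: float = 0.01,
                         seed_k: int = SEED_K):
    """Maximal pair of disjoint reverse-complementary segments >= min_len
    on the circle, or None. Ties broken by smallest start after canonical
    rotation (here: smallest start modulo the genome length)."""
    if isinstance(genome, AnnotatedGenome):
        seq, circular = genome.sequence, genome.circular
    else:
        seq, circular = str(genome).upper(), True
    if not circular:
        raise ValueError("inverted-repeat partitioning expects a circular genome")
    n = len(seq)
    s2 = seq + seq
    codes = encode(s2)
    comp_codes = np.where(codes < 4, 3 - codes, 4).astype(codes.dtype)
    pairs = [(i, j) for (i, j) in _rc_kmer_positions(s2, seed_k) if i < n]

    # chain seeds by anti-diagonal constant
    chains: dict[int, list[int]] = {}
    for i, j in pairs:
        c = i + j + seed_k - 1
        chains.setdefault(c, []).append(i)
    candidates = []
    clusters = []
    for c, starts in chains.items():
        # distinct pairings (e.g. doubled-sequence images) can share an
        # anti-diagonal; split seed runs separated by large gaps
        starts = sorted(starts)
        run = [starts[0]]
        for s in starts[1:]:
            if s - run[-1] > 8 * seed_k:
                clusters.append((c, run))
                run = [s]
            else:
                run.append(s)
        clusters.append((c, run))
    for c, starts in clusters:
        a0 = min(starts)
        a_end = max(starts) + seed_k
        a0, b_last, length, mm = _extend_anti(
            codes, comp_codes, a0, c - a0, a_end - a0,
            lo=max(0, c - 2 * n + 1), hi=2 * n - 1)
        if length < min_len or mm > max_mismatch_frac * length:
            continue
        b0 = b_last - length + 1
        if b0 < a0 + length:  # overlapping arms on the line
            continue
        if (b0 - a0) >= n:   # same arm seen across the doubling
            continue
        # arm intervals modulo n; reject arms that overlap on the circle
        arm_a = _mod_interval(a0, a0 + length, n)
        arm_b = _mod_interval(b0, b0 + length, n)
        if 2 * length >= n or _circ_overlap(arm_a, arm_b, n):
            continue
        candidates.append((length, a0 % n, arm_a, arm_b, mm))
    if not candidates:
        return None
    # dedupe doubled-sequence images, keep max length then smallest start
    seen = {}
    for length, a_mod, arm_a, arm_b, mm in candidates:
        key = tuple(sorted([(arm_a.start, arm_a.end), (arm_b.start, arm_b.end)]))
        if key not in seen or length > seen[key][0]:
            seen[key] = (length, a_mod, arm_a, arm_b, mm)
    length, _, arm_a, arm_b, mm = sorted(
        seen.values(), key=lambda t: (-t[0], t[1]))[0]
    if arm_b.start < arm_a.start:
        arm_a, arm_b = arm_b, arm_a
    gap1 = _gap_after(arm_a, arm_b, n)   # between end of A and start of B
    gap2 = _gap_after(arm_b, arm_a, n)
    g1len = gap1.span(n) if gap1 else 0
    g2len = gap2.span(n) if gap2 else 0
    if g1len >= g2len:
        lsc, ssc = gap1, gap2
    else:
        lsc, ssc = gap2, gap1
    return QuadripartiteMap(ir_a=arm_a, ir_b=arm_b, lsc=lsc, ssc=ssc,
                            ir_length=length, mismatches=mm)


def _mod_interval(s: int, e: int, n: int) -> Interval:
    length = min(e - s, n)
    s %= n
    if s + length <= n:
        return Interval(s, s + length)
    return Interval(s, (s + length) - n, wraps=True)


def _circ_positions(iv: Interval, n: int) -> set:
    if iv.wraps:
        return set(range(iv.start, n)) | set(range(0, iv.end))
    return set(range(iv.start, iv.end))


def _circ_overlap(a: Interval, b: Interval, n: int) -> bool:
    return bool(_circ_positions(a, n) & _circ_positions(b, n))


def _gap_after(a: Interval, b: Interval, n: int):
    """Interval between the end of a and the start of b on the circle."""
    s = a.end % n
    e = b.start % n
    if s == e:
        return Interval(s, s)  # empty gap
    if s < e:
        return Interval(s, e)
    return Interval(s, e, wraps=True)


def region_subgenome(genome: AnnotatedGenome, region: Interval,
                     name: str) -> AnnotatedGenome:
    """Extract a region as a linear AnnotatedGenome; features are assigned
    to the region holding the majority of their span and clipped to it."""
    n = len(genome)
    pos_region = _circ_positions(region, n)
    offset = region.start
    rlen = region.span(n)
    feats = []
    for f in genome.features:
        fpos = set()
        for p in f.parts:
            fpos |= _circ_positions(p, n)
        inside = fpos & pos_region
        if not inside or len(inside) * 2 < len(fpos):
            continue
        if len(inside) < len(fpos):
            log.debug("feature %s spans a region boundary; assigned to %s "
                      "by majority", f.name, name)
        new_parts = []
        for p in f.parts:
            ppos = sorted(((q - offset) % n) for q in
                          (_circ_positions(p, n) & pos_region))
            if not ppos:
                continue
            # contiguous runs -> intervals in region coordinates
            run_start = prev = ppos[0]
            for q in ppos[1:]:
                if q != prev + 1:
                    new_parts.append(Interval(run_start, prev + 1))
                    run_start = q
                prev = q
            new_parts.append(Interval(run_start, prev + 1))
        if new_parts:
            feats.append(type(f)(kind=f.kind, name=f.name, strand=f.strand,
                                 parts=new_parts,
                                 qualifiers=dict(f.qualifiers)))
    seq = extract(genome, region if region.span(n) else Interval(0, 1))
    if region.span(n) == 0:
        seq, feats = "N", []
    return AnnotatedGenome(id=f"{genome.id}|{name}", sequence=seq,
                           circular=False, features=feats)


def partition_quadripartite(genome: AnnotatedGenome, qmap: QuadripartiteMap):
    """Per-region partition reports and GC profiles for the four regions."""
    from .architecture import gc_profile, partition_genome

    out = {}
    for name, region in qmap.regions().items():
        sub = region_subgenome(genome, region, name)
        out[name] = {
            "length": region.span(len(genome)),
            "partition": partition_genome(sub),
            "gc": gc_profile(sub),
            "genes": len([f for f in sub.features if f.kind == "gene"]),
        }
    return out
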