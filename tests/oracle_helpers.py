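"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's algorithms: positions are classified
one nucleotide at a time, repeats are enumerated per diagonal over the whole
sequence, and alignments are full dynamic programming.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def complement(seq):
    return "".join(_COMP[c] for c in seq)


def revcomp(seq):
    return complement(seq)[::-1]


# ------------------------------------------------------- partition oracle

def per_position_partition(genome):
    """Label every nucleotide coding / intronic / intergenic by scanning all
    features position-by-position."""
    n = len(genome.sequence)

    def positions(iv):
        if iv.wraps:
            return list(range(iv.start, n)) + list(range(iv.end))
        return list(range(iv.start, iv.end))

    coding = set()
    for f in genome.features:
        if f.kind in ("CDS", "tRNA", "rRNA"):
            for p in f.parts:
                coding.update(positions(p))
    introns = set()
    for f in genome.features:
        if f.kind == "intron":
            for p in f.parts:
                introns.update(positions(p))
    coding -= introns

    gene_region = set()
    has_gene = any(f.kind == "gene" for f in genome.features)
    for f in genome.features:
        if f.kind == "gene" or (not has_gene and
                                f.kind in ("CDS", "tRNA", "rRNA")):
            env = f.envelope(n)
            gene_region.update(positions(env))
    if has_gene:
        # coding features not under any gene feature form their own locus
        for f in genome.features:
            if f.kind in ("CDS", "tRNA", "rRNA"):
                pts = [q for p in f.parts for q in positions(p)]
                if not all(q in gene_region for q in
                           (pts[0], pts[-1])):
                    gene_region.update(positions(f.envelope(n)))
    coding_nt = len(coding)
    intergenic_nt = n - len(gene_region)
    return {
        "coding": coding_nt,
        "noncoding": n - coding_nt,
        "intergenic": intergenic_nt,
        "intronic": (n - coding_nt) - intergenic_nt,
    }


# --------------------------------------------------------- repeat oracle

def brute_force_repeats(seq, min_len, k, types=("F", "R", "C", "RC")):
    """Exhaustive per-diagonal enumeration of maximal <=k-mismatch repeat
    pairs, as (type, start_a, start_b, length, mismatches) tuples."""
    n = len(seq)
    out = set()
    comp = complement(seq)
    for rtype, tgt in (("F", seq), ("C", comp)):
        if rtype not in types:
            continue
        for d in range(1, n):
            prof = [seq[i] == tgt[i + d] for i in range(n - d)]
            out |= _windows(prof, rtype,
                            lambda w0, w1, d=d: (w0, w0 + d),
                            min_len, k, n)
    for rtype, tgt in (("R", seq), ("RC", comp)):
        if rtype not in types:
            continue
        for c in range(2 * n - 1):
            lo = max(0, c - n + 1)
            hi = (c - 1) // 2 + 1
            if hi <= lo:
                continue
            prof = [seq[i] == tgt[c - i] for i in range(lo, hi)]
            out |= _windows(prof, rtype,
                            lambda w0, w1, c=c: (w0, c - w1),
                            min_len, k, n, base=lo)
    return out


def _windows(prof, rtype, mapfn, min_len, k, n, base=0):
    res = set()
    m = len(prof)
    mmpos = [i for i, v in enumerate(prof) if not v]
    B = [-1] + mmpos + [m]
    k_eff = min(k, len(B) - 2)
    for u in range(len(B) - k_eff - 1):
        w0, w1 = B[u] + 1, B[u + k_eff + 1] - 1
        if w1 < w0:
            continue
        ln = w1 - w0 + 1
        if ln < min_len:
            continue
        mm = sum(1 for p in mmpos if w0 <= p <= w1)
        a0, b0 = mapfn(w0 + base, w1 + base)
        if rtype == "F" and a0 == b0 and ln == n:
            continue
        res.add((rtype, a0, b0, ln, mm))
    return res


# --------------------------------------------------- local alignment oracle

def smith_waterman_identity(a, b, match=2, mismatch=-3, gap_open=5,
                            gap_extend=2):
    """Best local alignment identity over its aligned span (affine gaps,
    costs as positive penalties). Returns (identity, span)."""
    la, lb = len(a), len(b)
    NEG = -10 ** 9
    H = np.zeros((la + 1, lb + 1))
    E = np.full((la + 1, lb + 1), NEG, dtype=float)
    F = np.full((la + 1, lb + 1), NEG, dtype=float)
    back = {}
    best, bi, bj = 0.0, 0, 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            sub = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
            if H[i, j] > best:
                best, bi, bj = H[i, j], i, j
    if best == 0:
        return 0.0, 0
    # traceback (greedy, on score recomputation)
    i, j = bi, bj
    matches = span = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = match if a[i - 1] == b[j - 1] else mismatch
        if abs(H[i, j] - (H[i - 1, j - 1] + sub)) < 1e-9:
            matches += a[i - 1] == b[j - 1]
            span += 1
            i, j = i - 1, j - 1
        elif abs(H[i, j] - E[i, j]) < 1e-9:
            while j > 0 and abs(H[i, j] - E[i, j]) < 1e-9 and \
                    abs(E[i, j] - (H[i, j - 1] - gap_open)) > 1e-9:
                span += 1
                j -= 1
            span += 1
            j -= 1
        else:
            while i > 0 and abs(H[i, j] - F[i, j]) < 1e-9 and \
                    abs(F[i, j] - (H[i - 1, j] - gap_open)) > 1e-9:
                span += 1
                i -= 1
            span += 1
            i -= 1
    return (matches / span if span else 0.0), span
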