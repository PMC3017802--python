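"""Maximal repeat finding (forward / reverse / complement / reverse
complement, exact and Hamming-approximate), repeat-family clustering, and
sliding-window dotplot matrices.

The finder is seed-and-extend: exact seeds of length floor(min_len/(k+1))
(pigeonhole-complete for the configured minimum length and mismatch budget
k) locate candidate diagonals; maximal windows with <= k mismatches are then
enumerated exhaustively on each candidate diagonal. A match is *maximal*
when it starts and ends on matching positions and no one-position extension
keeps the mismatch count within budget (sequence bounds and, for the
anti-diagonal types, arm disjointness count as blocking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import at_fraction, complement, encode, kmer_ints, revcomp

REPEAT_TYPES = ("F", "R", "C", "RC")


@dataclass(frozen=True)
class Instance:
    start: int
    end: int  # half-open


@dataclass(frozen=True)
class RepeatMatch:
    type: str
    pos_a: Instance
    pos_b: Instance
    length: int
    mismatches: int
    at_fraction: float

    def key(self):
        return (self.type, self.pos_a.start, self.pos_b.start, self.length)


@dataclass
class RepeatFamily:
    members: list
    representative: str
    size: int
    length_range: tuple
    at_fraction: float


def _pair_positions(vals_a: np.ndarray, vals_b: np.ndarray):
    """All index pairs (i, j) with vals_a[i] == vals_b[j] (valid k-mers
    only), via sorted merge. Every pair is emitted: completeness of the
    seeding is what makes the finder provably exhaustive."""
    oa = np.argsort(vals_a, kind="stable")
    ob = np.argsort(vals_b, kind="stable")
    sa, sb = vals_a[oa], vals_b[ob]
    ia = ib = 0
    na, nb = len(sa), len(sb)
    out = []
    while ia < na and ib < nb:
        va, vb = sa[ia], sb[ib]
        if va < vb:
            ia += 1
        elif va > vb:
            ib += 1
        else:
            ja = ia
            while ja < na and sa[ja] == va:
                ja += 1
            jb = ib
            while jb < nb and sb[jb] == vb:
                jb += 1
            if va >= 0:
                for x in oa[ia:ja]:
                    for y in ob[ib:jb]:
                        out.append((int(x), int(y)))
            ia, ib = ja, jb
    return out


def _maximal_windows(ok, lo: int, hi: int, center: int, k: int):
    """Maximal <=k-mismatch windows intersecting ``center`` in the profile
    ok(i) over [lo, hi). Expands from center until k+1 mismatches per side
    (or a bound), then enumerates blocker-delimited windows."""
    left_hard = right_hard = False
    mmL, i = 0, center - 1
    left_mm = []
    while True:
        if i < lo:
            left_hard = True
            break
        if not ok(i):
            left_mm.append(i)
            mmL += 1
            if mmL > k:
                break
        i -= 1
    mmR, i = 0, center
    right_mm = []
    while True:
        if i >= hi:
            right_hard = True
            break
        if not ok(i):
            right_mm.append(i)
            mmR += 1
            if mmR > k:
                break
        i += 1
    B = []
    if left_hard:
        B.append(lo - 1)
    B.extend(reversed(left_mm))
    B.extend(right_mm)
    if right_hard:
        B.append(hi)
    if len(B) < 2:  # whole profile is mismatch-free and unbounded? only if
        # both ends hard with zero mm; guarded by construction
        return [(lo, hi - 1, 0)]
    k_eff = min(k, len(B) - 2)
    wins = []
    for u in range(len(B) - k_eff - 1):
        w0, w1 = B[u] + 1, B[u + k_eff + 1] - 1
        if w1 >= w0:
            wins.append((w0, w1, k_eff))
    return wins


def find_maximal_repeats(seq: str, min_len: int = 12, hamming_k: int = 0,
                         types=("F", "R", "C", "RC")) -> list[RepeatMatch]:
    """All maximal repeat pairs of length >= min_len with <= hamming_k
    mismatches, reported once with pos_a.start < pos_b.start (arms of the
    anti-diagonal types R/RC are required to be disjoint); the trivial
    full-length self match is excluded."""
    if min_len < 4:
        raise ValueError("min_len < 4: seeding infeasible")
    if not 0 <= hamming_k <= 3:
        raise ValueError("hamming_k must be in 0..3")
    n = len(seq)
    if n < min_len:
        return []
    seq = seq.upper()
    s_len = max(4, min_len // (hamming_k + 1))
    codes = encode(seq)
    comp_codes = np.where(codes < 4, 3 - codes, 4).astype(codes.dtype)
    fw = kmer_ints(seq, s_len)
    results: dict = {}

    def emit(rtype, a0, b0, length, mm):
        if length < min_len:
            return
        if a0 == b0 and length == n:
            return
        key = (rtype, a0, b0, length)
        if key not in results:
            sub = seq[a0:a0 + length] + seq[b0:b0 + length]
            results[key] = RepeatMatch(
                rtype, Instance(a0, a0 + length), Instance(b0, b0 + length),
                length, mm, at_fraction(sub))

    # ---- parallel geometries: F (identity) and C (complement) ----
    for rtype in ("F", "C"):
        if rtype not in types:
            continue
        target = codes if rtype == "F" else comp_codes

        def ok_par(i, d, tgt=target):
            return codes[i] == tgt[i + d]

        if rtype == "F":
            pairs = _pair_positions(fw, fw)
        else:
            cw = kmer_ints(complement(seq), s_len)
            pairs = _pair_positions(fw, cw)
        by_diag: dict[int, list[int]] = {}
        for i, j in pairs:
            d = j - i
            if d > 0:
                by_diag.setdefault(d, []).append(i)
        for d, starts in by_diag.items():
            lo, hi = 0, n - d
            last_st = None
            for st in sorted(set(starts)):
                # A seed separated from the previous one only by matching
                # positions cannot start a window the previous enumeration
                # missed (any maximal window through it extends left across
                # the matches into the previous seed).
                if (last_st is not None and st - last_st < s_len
                        and all(ok_par(i, d) for i in range(last_st, st))):
                    last_st = st
                    continue
                last_st = st
                for w0, w1, _ in _maximal_windows(
                        lambda i: ok_par(i, d), lo, hi, st, hamming_k):
                    mm = sum(0 if ok_par(i, d) else 1 for i in range(w0, w1 + 1))
                    emit(rtype, w0, w0 + d, w1 - w0 + 1, mm)

    # ---- anti-diagonal geometries: R (reverse) and RC (revcomp) ----
    for rtype in ("R", "RC"):
        if rtype not in types:
            continue
        target = codes if rtype == "R" else comp_codes

        def ok_anti(i, c, tgt=target):
            return codes[i] == tgt[c - i]

        if rtype == "R":
            rv = kmer_ints(seq[::-1], s_len)
            # rv[p] is the k-mer of reverse(seq)[p:p+s], i.e. reversed
            # seq[n-p-s : n-p]; a pair (i, p) gives c = i + (n-p-1).
            pairs = _pair_positions(fw, rv)
            cs = [(i, i + (n - p - 1)) for i, p in pairs]
        else:
            rc = kmer_ints(revcomp(seq), s_len)
            pairs = _pair_positions(fw, rc)
            cs = [(i, i + (n - p - 1)) for i, p in pairs]
        by_c: dict[int, list[int]] = {}
        for i, c in cs:
            by_c.setdefault(c, []).append(i)
        for c, starts in by_c.items():
            lo = max(0, c - n + 1)
            hi = (c - 1) // 2 + 1  # domain: i <= (c-1)//2 keeps arms disjoint
            last_st = None
            for st in sorted(set(starts)):
                if st >= hi:
                    continue
                if (last_st is not None and st - last_st < s_len
                        and all(ok_anti(i, c) for i in range(last_st, st))):
                    last_st = st
                    continue
                last_st = st
                for w0, w1, _ in _maximal_windows(
                        lambda i: ok_anti(i, c), lo, hi, min(st, hi - 1),
                        hamming_k):
                    mm = sum(0 if ok_anti(i, c) else 1
                             for i in range(w0, w1 + 1))
                    length = w1 - w0 + 1
                    b0 = c - w1
                    emit(rtype, w0, b0, length, mm)

    out = sorted(results.values(),
                 key=lambda m: (m.pos_a.start, m.pos_b.start, m.type))
    return out


def cluster_repeats(matches: list[RepeatMatch], seq: str,
                    identity: float = 0.8) -> list[RepeatFamily]:
    """Single-linkage clustering of repeat instances by pairwise identity
    (edit-distance identity of strand-canonicalized instance sequences)."""
    import edlib

    if not matches:
        raise ValueError("no matches to cluster")
    inst = [seq[m.pos_a.start:m.pos_a.end] for m in matches]
    inst_rc = [revcomp(s) for s in inst]
    nmatch = len(matches)
    parent = list(range(nmatch))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # length buckets: identity >= t forces |len_a - len_b| <= (1-t)*max_len
    order = sorted(range(nmatch), key=lambda i: len(inst[i]))
    for ai in range(nmatch):
        a = order[ai]
        la = len(inst[a])
        for bi in range(ai + 1, nmatch):
            b = order[bi]
            lb = len(inst[b])
            if lb - la > (1 - identity) * lb:
                break
            if find(a) == find(b):
                continue
            # strand-symmetric identity: best of the two orientations
            kmax = int((1 - identity) * lb) + 1
            d = min(r["editDistance"] % (1 << 30) for r in (
                edlib.align(inst[a], inst[b], mode="NW", task="distance",
                            k=kmax),
                edlib.align(inst[a], inst_rc[b], mode="NW", task="distance",
                            k=kmax)))
            if d < (1 << 29) and 1 - d / lb >= identity:
                parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for i in range(nmatch):
        groups.setdefault(find(i), []).append(i)
    fams = []
    for members_idx in groups.values():
        members = [matches[i] for i in members_idx]
        seqs = [inst[i] for i in members_idx]
        rep = max(seqs, key=len)
        lens = [m.length for m in members]
        fams.append(RepeatFamily(
            members=members, representative=rep, size=len(members),
            length_range=(min(lens), max(lens)),
            at_fraction=float(np.mean([m.at_fraction for m in members]))))
    fams.sort(key=lambda f: -f.size)
    return fams


@dataclass
class DotplotMatrix:
    window: int
    scores: np.ndarray
    axes: tuple
    rc_scores: np.ndarray | None = None


def dotplot(seq_a: str, seq_b: str | None = None, window: int = 50,
            min_score: int | None = None, rc_channel: bool = False,
            max_cells: int = 40_000_000) -> DotplotMatrix:
    """score(i, j) = identities between seq_a[i:i+window] and
    seq_b[j:j+window]. Self-plots pass seq_b=None."""
    ids = ("A", "B" if seq_b is not None else "A")
    if seq_b is None:
        seq_b = seq_a
    if window > min(len(seq_a), len(seq_b)):
        raise ValueError("window exceeds sequence length")
    na, nb = len(seq_a) - window + 1, len(seq_b) - window + 1
    if na * nb > max_cells:
        raise ValueError("dotplot too large; subsample or raise max_cells")
    a = encode(seq_a)

    def _scores(bseq):
        b = encode(bseq)
        la, lb = len(a), len(b)
        S = np.zeros((na, nb), dtype=np.int32)
        for d in range(-(la - 1), lb):
            i0 = max(0, -d)
            j0 = i0 + d
            L = min(la - i0, lb - j0)
            if L < window:
                continue
            eq = (a[i0:i0 + L] == b[j0:j0 + L]).astype(np.int32)
            cs = np.concatenate([[0], np.cumsum(eq)])
            wsum = cs[window:] - cs[:-window]
            ii = np.arange(i0, i0 + L - window + 1)
            jj = ii + d
            keep = (ii < na) & (jj >= 0) & (jj < nb)
            S[ii[keep], jj[keep]] = wsum[keep]
        return S

    scores = _scores(seq_b)
    if min_score is not None:
        scores = np.where(scores >= min_score, scores, 0)
    rc = None
    if rc_channel:
        rc = _scores(revcomp(seq_b))[:, ::-1]
        if min_score is not None:
            rc = np.where(rc >= min_score, rc, 0)
    return DotplotMatrix(window=window, scores=scores, axes=ids, rc_scores=rc)


def dotplot_sparse_tsv(mat: DotplotMatrix, path, threshold: int) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\tscore\tchannel\n")
        for channel, S in (("fwd", mat.scores), ("rc", mat.rc_scores)):
            if S is None:
                continue
            for i, j in zip(*np.nonzero(S >= threshold)):
                fh.write(f"{i}\t{j}\t{S[i, j]}\t{channel}\n")


def dotplot_ascii(mat: DotplotMatrix, width: int = 60) -> str:
    """Coarse ASCII heat map of the forward channel."""
    S = mat.scores
    h = max(1, S.shape[0] // width + (S.shape[0] % width > 0))
    w = max(1, S.shape[1] // width + (S.shape[1] % width > 0))
    shades = " .:-=+*#%@"
    rows = []
    for i0 in range(0, S.shape[0], h):
        row = []
        for j0 in range(0, S.shape[1], w):
            v = S[i0:i0 + h, j0:j0 + w].max(initial=0)
            row.append(shades[min(int(v / mat.window * (len(shades) - 1)),
                                  len(shades) - 1)])
        rows.append("".join(row))
    return "\n".join(rows)
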