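"""Low-level sequence helpers shared across modules.

Everything here operates on plain uppercase DNA strings over {A,C,G,T,N}
or on their 2-bit numpy encodings. Nothing imports domain types.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC codes for unordered base sets, used by consensus builders.
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

_CODE = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); N is excluded from both sides. Errors on all-N."""
    g = seq.count("G") + seq.count("g")
    c = seq.count("C") + seq.count("c")
    denom = len(seq) - seq.count("N") - seq.count("n")
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return (g + c) / denom


def at_fraction(seq: str) -> float:
    return 1.0 - gc_fraction(seq)


def encode(seq: str) -> np.ndarray:
    """2-bit-ish codes: A=0 C=1 G=2 T=3, anything else 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_ints(seq: str, k: int) -> np.ndarray:
    """Integer codes of every k-mer (Horner scheme); k-mers containing
    non-ACGT characters are returned as -1."""
    codes = encode(seq).astype(np.int64)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bad = codes >= 4
    vals = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    for t in range(k):
        vals = vals * 4 + np.where(bad[t:t + n], 0, codes[t:t + n])
        invalid |= bad[t:t + n]
    vals[invalid] = -1
    return vals


def minimal_rotation(seq: str) -> int:
    """Index of the lexicographically minimal rotation (Booth's algorithm)."""
    s = seq + seq
    n = len(seq)
    f = [-1] * len(s)
    kk = 0
    for j in range(1, len(s)):
        sj = s[j]
        i = f[j - kk - 1]
        while i != -1 and sj != s[kk + i + 1]:
            if sj < s[kk + i + 1]:
                kk = j - i - 1
            i = f[i]
        if sj != s[kk + i + 1]:
            if sj < s[kk]:
                kk = j
            f[j - kk] = -1
        else:
            f[j - kk] = i + 1
    return kk % n


def canonical_rotation(seq: str, circular: bool = True) -> str:
    """Canonical representative of a (possibly circular) sequence: the
    lexicographically smaller strand, rotated to its minimal rotation."""
    rc = revcomp(seq)
    if not circular:
        return min(seq, rc)
    cands = []
    for s in (seq, rc):
        i = minimal_rotation(s)
        cands.append(s[i:] + s[:i])
    return min(cands)


def hamming_matches(a: str, b: str) -> int:
    """Number of equal positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("length mismatch")
    if not a:
        return 0
    return int(np.count_nonzero(encode(a) == encode(b)))


def identity(a: str, b: str) -> float:
    """Global edit-distance identity between two strings (edlib),
    normalized by alignment length."""
    import edlib

    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="distance")
    span = max(len(a), len(b))
    return 1.0 - res["editDistance"] / span
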