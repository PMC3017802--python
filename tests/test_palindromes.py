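import numpy as np

from organellarch._util import revcomp
from organellarch.palindromes import (build_consensus, cluster_hairpins,
                                      find_hairpins, loop_motif_tally,
                                      verify_hairpin)


def test_hand_foldable_toy():
    hp = find_hairpins("GGGAAATTTCCC", min_stem=3, loop_range=(3, 6),
                       max_arm_mismatch=0)
    assert len(hp) == 1
    h = hp[0]
    assert (h.position.start, h.position.end) == (0, 12)
    assert h.stem_len >= 3 and h.arm_mismatches == 0
    assert verify_hairpin("GGGAAATTTCCC", h)


def test_no_stem_and_homopolymer_are_empty():
    # brute check: no (arm >=3, loop >=3) decomposition of ACGTACGT pairs
    seq = "ACGTACGT"
    ok = []
    for stem in range(3, 4):
        for loop in range(3, len(seq) - 2 * stem + 1):
            for s0 in range(0, len(seq) - 2 * stem - loop + 1):
                left = seq[s0:s0 + stem]
                right = seq[s0 + stem + loop:s0 + 2 * stem + loop]
                if left == revcomp(right):
                    ok.append((s0, stem, loop))
    assert not ok
    assert find_hairpins(seq, min_stem=3, loop_range=(3, 6)) == []
    assert find_hairpins("A" * 60, min_stem=3, loop_range=(3, 6)) == []


def test_every_reported_hairpin_reverifies(mt_genome):
    hps = find_hairpins(mt_genome.sequence)
    assert hps
    assert all(verify_hairpin(mt_genome.sequence, h) for h in hps)


def test_cluster_chaining_by_gap():
    seq = "GCGCGC" + "AAATTTA" + "GCGCGC"  # one hairpin element, 19 nt
    elem = "GGCCGCGC" + "TTTA" + revcomp("GGCCGCGC")
    rng = np.random.default_rng(0)
    filler = lambda n: "".join(rng.choice(list("AC"), n))
    s = elem + filler(10) + elem + filler(15) + elem + filler(500) + elem
    hps = find_hairpins(s, min_stem=6, loop_range=(3, 6), max_arm_mismatch=0)
    assert len(hps) == 4
    clusters = cluster_hairpins(hps, max_gap=30, seq=s)
    assert [len(c.hairpins) for c in clusters] == [3, 1]
    c0 = clusters[0]
    assert c0.length == (c0.hairpins[-1].position.end -
                         c0.hairpins[0].position.start)


def test_consensus_families_and_iupac_tie():
    elem = "GGATCGCC" + "TTTA" + revcomp("GGATCGCC")
    rng = np.random.default_rng(1)
    # A/C alphabet cannot base-pair with itself: no chance hairpins
    filler = lambda n: "".join(rng.choice(list("AC"), n))
    cluster = elem + filler(8) + elem
    s = ""
    for _ in range(4):
        s += cluster + filler(300)
    hps = find_hairpins(s, min_stem=6, loop_range=(3, 6), max_arm_mismatch=0)
    clusters = cluster_hairpins(hps, max_gap=30, seq=s)
    assert len(clusters) == 4
    fams = build_consensus(clusters, s, identity=0.7)
    assert fams[0].occurrences == 4
    canon = min(cluster, revcomp(cluster))
    assert fams[0].consensus == canon

    # two copies differing at one column -> IUPAC ambiguity there
    from organellarch.palindromes import PalindromeCluster
    from organellarch.genbank_io import Interval
    a = "GGATCGCCTTTAGGCGATCC"
    b = "GGATCGCCTTTCGGCGATCC"  # A->C at column 11
    s2 = a + "G" * 50 + b
    cl = [PalindromeCluster(region=Interval(0, len(a)), hairpins=[],
                            length=len(a), gc=0.5),
          PalindromeCluster(region=Interval(len(a) + 50,
                                            len(a) + 50 + len(b)),
                            hairpins=[], length=len(b), gc=0.5)]
    fam = build_consensus(cl, s2, identity=0.7)
    assert len(fam) == 1
    cons = fam[0].consensus
    assert "M" in cons or "K" in cons  # {A,C} or revcomp {T,G}


def test_consensus_strand_canonicalization():
    from organellarch.palindromes import PalindromeCluster
    from organellarch.genbank_io import Interval
    a = "GGATCGCCTTTAGGCGATCA"
    s = a + "G" * 30 + revcomp(a)
    cl = [PalindromeCluster(region=Interval(0, len(a)), hairpins=[],
                            length=len(a), gc=0.5),
          PalindromeCluster(region=Interval(len(a) + 30, 2 * len(a) + 30),
                            hairpins=[], length=len(a), gc=0.5)]
    fam = build_consensus(cl, s, identity=0.7)
    assert len(fam) == 1 and fam[0].occurrences == 2


def test_loop_motif_tally_longest_first():
    from organellarch.palindromes import Hairpin
    from organellarch.genbank_io import Interval

    def hp(loop):
        return Hairpin(position=Interval(0, 10), stem_len=3, loop=loop,
                       arm_mismatches=0, gc=0.5)

    tal = loop_motif_tally([hp("TTTA"), hp("GGG"), hp("TTTC")])
    assert tal == {"TTTA": 1, "TTT": 1}
    assert loop_motif_tally([]) == {"TTTA": 0, "TTT": 0}
    hps = [hp("TTTA"), hp("TTTAT"), hp("ATTTC")]
    tal = loop_motif_tally(hps)
    assert sum(tal.values()) <= len(hps)


def test_planted_cluster_recovery_with_defaults(mt_genome):
    """Every planted hairpin cluster is recovered as a detected cluster with
    about three elements at the scanner's default parameters."""
    hps = find_hairpins(mt_genome.sequence)
    clusters = cluster_hairpins(hps, genome=mt_genome,
                                seq=mt_genome.sequence)
    multi = [c for c in clusters if len(c.hairpins) >= 2]
    planted = [f for f in mt_genome.features
               if f.name.startswith("palindrome_cluster")]
    assert len(planted) == 18
    recovered = 0
    for f in planted:
        s, e = f.parts[0].start, f.parts[0].end
        hits = [c for c in multi
                if c.region.start < e and c.region.end > s]
        if hits and sum(len(c.hairpins) for c in hits) >= 3:
            recovered += 1
    assert recovered == len(planted)
    lengths = [c.length for c in multi]
    assert 80 <= np.mean(lengths) <= 140
    per = np.mean([len(c.hairpins) for c in multi])
    assert 2.0 <= per <= 4.0
    # planted clusters sit in intergenic context
    ctx = [c.context for c in multi]
    assert ctx.count("intergenic") >= len(planted) * 0.8
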