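import numpy as np
import pytest

import organellarch as oa
from organellarch.architecture import (count_genes, cumulative_gc_skew,
                                       gc_by_codon_position, gc_content,
                                       gene_inventory, gene_set_compare,
                                       intron_gene_ratio, partition_genome)
from organellarch.genbank_io import (AnnotatedGenome, Feature, Interval,
                                     flip_genome, rotate_genome)
from oracle_helpers import per_position_partition


def _genome(n, feats, circular=True):
    rng = np.random.default_rng(42)
    return AnnotatedGenome(id="t", circular=circular,
                           sequence="".join(rng.choice(list("ACGT"), n)),
                           features=feats)


def test_partition_single_cds_with_intron():
    g = _genome(1000, [
        Feature("CDS", "g1", "+", [Interval(100, 200), Interval(300, 400)]),
        Feature("intron", "g1_i1", "+", [Interval(200, 300)]),
    ])
    rep = partition_genome(g)
    assert (rep.coding_nt, rep.noncoding_nt, rep.intergenic_nt,
            rep.intronic_nt) == (200, 800, 700, 100)


def test_partition_overlapping_genes_count_once():
    g = _genome(1000, [
        Feature("gene", "a", "+", [Interval(100, 300)]),
        Feature("CDS", "a", "+", [Interval(100, 300)]),
        Feature("gene", "b", "+", [Interval(250, 450)]),
        Feature("CDS", "b", "+", [Interval(250, 450)]),
    ])
    rep = partition_genome(g)
    oracle = per_position_partition(g)
    assert rep.coding_nt == oracle["coding"] == 350
    assert rep.intergenic_nt == oracle["intergenic"] == 650


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_partition_matches_per_position_oracle_on_random_genomes(seed):
    spec = oa.GenomeSpec(length=9000, seed=seed, n_protein=4, n_trna=2,
                         rrna_genes=(("rrnl", 2),), noncoding_fraction=0.55,
                         introns_in_genes=5, intronic_orfs=1,
                         intergenic_introns=2)
    g = oa.generate_genome(spec)
    rep = partition_genome(g)
    oracle = per_position_partition(g)
    assert rep.coding_nt == oracle["coding"]
    assert rep.noncoding_nt == oracle["noncoding"]
    assert rep.intergenic_nt == oracle["intergenic"]
    assert rep.intronic_nt == oracle["intronic"]
    # conservation identities
    assert rep.coding_nt + rep.noncoding_nt == rep.genome_length
    assert rep.intergenic_nt + rep.intronic_nt == rep.noncoding_nt


def test_partition_rotation_and_flip_invariance(mt_genome):
    rep = partition_genome(mt_genome)
    for off in (1, 777, 15000):
        rot = partition_genome(rotate_genome(mt_genome, off))
        assert rot == rep
    flipped = partition_genome(flip_genome(mt_genome))
    assert flipped == rep


def test_partition_empty_genome_warns():
    g = _genome(500, [])
    with pytest.warns(UserWarning):
        rep = partition_genome(g)
    assert rep.coding_nt == 0 and rep.noncoding_nt == 500


def test_gc_content_examples_and_revcomp_property():
    assert gc_content("ATGC") == 0.5
    assert gc_content("AAAA") == 0.0
    with pytest.raises(ValueError):
        gc_content("NNN")
    rng = np.random.default_rng(5)
    from organellarch._util import revcomp
    for _ in range(20):
        s = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 300))))
        assert gc_content(s) == pytest.approx(gc_content(revcomp(s)))


def test_gc_by_codon_position_hand_counted():
    g = _genome(12, [Feature("CDS", "x", "+", [Interval(0, 6)])])
    g.sequence = "ATGGCC" + g.sequence[6:]
    f1, f2, f3 = gc_by_codon_position(g)
    assert (f1, f2, f3) == (0.5, 0.5, 1.0)


def test_gc_by_codon_position_strand_invariance(mt_genome):
    fwd = gc_by_codon_position(mt_genome)
    rev = gc_by_codon_position(flip_genome(mt_genome))
    assert fwd == pytest.approx(rev)


def test_gc_by_codon_position_truncates_partial_codon():
    g = _genome(20, [Feature("CDS", "x", "+", [Interval(0, 7)])])
    g.sequence = "ATGGCCG" + g.sequence[7:]
    with pytest.warns(UserWarning):
        vals = gc_by_codon_position(g)
    assert vals == (0.5, 0.5, 1.0)


def test_cumulative_skew_examples():
    s = cumulative_gc_skew("GGGGCCCC", window=4, step=4)
    assert list(s.values) == [1.0, 0.0]
    z = cumulative_gc_skew("A" * 100, window=10, step=10)
    assert np.allclose(z.values, 0)
    assert np.all(np.diff(z.positions) > 0)


def test_skew_revcomp_symmetry():
    from organellarch._util import revcomp
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), 1000))
    w = 100
    fwd = np.diff(np.concatenate([[0], cumulative_gc_skew(seq, w, w).values]))
    rev = np.diff(np.concatenate(
        [[0], cumulative_gc_skew(revcomp(seq), w, w).values]))
    assert np.allclose(fwd, -rev[::-1])


def test_skew_wraps_circular_genome():
    g = AnnotatedGenome(id="c", sequence="GGGGCCCC", circular=True)
    s = cumulative_gc_skew(g, window=4, step=4)
    assert len(s.values) == 2  # windows at 0 and 4, second one no wrap needed
    g2 = AnnotatedGenome(id="c", sequence="GGGGCCCCAA", circular=True)
    s2 = cumulative_gc_skew(g2, window=4, step=4)
    assert len(s2.values) == 3  # third window wraps the origin


def test_intron_gene_ratio_mt_and_pt_conditions(mt_genome, pt_genome):
    assert intron_gene_ratio(mt_genome) == pytest.approx(18 / 12)
    assert round(intron_gene_ratio(mt_genome), 2) == 1.5
    assert intron_gene_ratio(pt_genome) == pytest.approx(43 / 102)
    assert round(intron_gene_ratio(pt_genome), 2) == 0.42
    assert count_genes(pt_genome) == 102


def test_intron_gene_ratio_edge_cases():
    g = _genome(1000, [
        Feature("gene", "a", "+", [Interval(10, 100)]),
        Feature("CDS", "a", "+", [Interval(10, 100)]),
    ])
    assert intron_gene_ratio(g) == 0.0
    empty = _genome(100, [])
    with pytest.raises(ValueError):
        intron_gene_ratio(empty)


def test_gene_inventory_duplicates_and_fragments():
    feats = []
    for name, kind, lo in (("cob", "CDS", 0), ("nad4", "CDS", 200),
                           ("trnM", "tRNA", 400), ("trnM", "tRNA", 500)):
        feats.append(Feature("gene", name, "+", [Interval(lo, lo + 90)]))
        feats.append(Feature(kind, name, "+", [Interval(lo, lo + 90)]))
    g = _genome(1000, feats)
    inv = gene_inventory(g)
    assert inv.protein == 2 and inv.tRNA == 2 and inv.tRNA_dedup == 1

    frag_feats = []
    for i in range(6):
        nm = f"rrnl_L{i + 1}"
        frag_feats.append(Feature("gene", nm, "+",
                                  [Interval(i * 150, i * 150 + 100)]))
        frag_feats.append(Feature("rRNA", nm, "+",
                                  [Interval(i * 150, i * 150 + 100)]))
    g2 = _genome(1000, frag_feats)
    inv2 = gene_inventory(g2)
    assert inv2.rRNA == 1 and inv2.fragments == {"rrnl": 6}


def test_inventory_rotation_invariance(mt_genome):
    base = gene_inventory(mt_genome).as_dict()
    rot = gene_inventory(rotate_genome(mt_genome, 9999)).as_dict()
    assert base == rot


def test_gene_set_compare_cells_partition_universe():
    cells = gene_set_compare({"A": {"cob", "nad4"}, "B": {"cob", "trnM"}})
    assert cells[frozenset({"A", "B"})] == ["cob"]
    assert cells[frozenset({"A"})] == ["nad4"]
    assert cells[frozenset({"B"})] == ["trnM"]
    same = gene_set_compare({"A": {"x", "y"}, "B": {"x", "y"}})
    assert set(same) == {frozenset({"A", "B"})}
    # disjoint cells, union = universe
    inv = {"A": {"a", "b", "c"}, "B": {"b", "c", "d"}, "C": {"c", "e"}}
    cells = gene_set_compare(inv)
    all_genes = [g for v in cells.values() for g in v]
    assert sorted(all_genes) == sorted(set(all_genes))
    assert set(all_genes) == set.union(*inv.values())
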