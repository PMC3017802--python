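import numpy as np
import pytest

import organellarch as oa
from organellarch.genbank_io import (CoordinateError, Interval, extract,
                                     flip_genome, read_fasta, read_genbank,
                                     rotate_genome, write_fasta,
                                     write_genbank, write_gff3)
from organellarch._util import revcomp

GB_TOY = """LOCUS       TOY1                    1000 bp    DNA     circular PLN 01-JAN-2010
DEFINITION  toy record.
ACCESSION   TOY1
VERSION     TOY1.1
FEATURES             Location/Qualifiers
     source          1..1000
                     /organism="synthetic"
     gene            101..400
                     /gene="cob"
     CDS             join(101..250,351..400)
                     /gene="cob"
     intron          251..350
                     /gene="cob"
     tRNA            complement(501..575)
                     /gene="trnM"
     gene            complement(join(10..20,30..40))
                     /gene="mini"
     CDS             join(951..1000,1..50)
                     /gene="wrapper"
ORIGIN
{origin}
//
"""


def _origin_block(seq):
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60].lower()
        lines.append(f"{i + 1:>9} " +
                     " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10)))
    return "\n".join(lines)


@pytest.fixture()
def toy_gb(tmp_path):
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 1000))
    path = tmp_path / "toy.gb"
    path.write_text(GB_TOY.format(origin=_origin_block(seq)))
    return path, seq


def test_parse_toy_record_features_and_strands(toy_gb):
    path, seq = toy_gb
    g = read_genbank(path)
    assert g.circular and len(g) == 1000
    kinds = {(f.name, f.kind, f.strand) for f in g.features}
    assert ("cob", "gene", "+") in kinds
    assert ("cob", "CDS", "+") in kinds
    assert ("trnM", "tRNA", "-") in kinds


def test_complement_join_converted_to_half_open_ascending(toy_gb):
    g = read_genbank(toy_gb[0])
    mini = next(f for f in g.features if f.name == "mini")
    assert mini.strand == "-"
    assert [(p.start, p.end) for p in mini.parts] == [(9, 20), (29, 40)]


def test_origin_wrapping_join_merged_into_wrap_interval(toy_gb):
    path, seq = toy_gb
    g = read_genbank(path)
    wrapper = next(f for f in g.features if f.name == "wrapper")
    assert len(wrapper.parts) == 1 and wrapper.parts[0].wraps
    sub = extract(g, wrapper.parts[0])
    assert len(sub) == 100
    assert sub == seq[950:] + seq[:50]


def test_location_beyond_sequence_is_coordinate_error(tmp_path):
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), 1000))
    text = GB_TOY.format(origin=_origin_block(seq)).replace(
        "join(101..250,351..400)", "join(101..250,351..1400)")
    p = tmp_path / "bad.gb"
    p.write_text(text)
    with pytest.raises(Exception) as exc:
        read_genbank(p)
    assert "cob" in str(exc.value) or "location" in str(exc.value).lower()


def test_fasta_roundtrip_order_case_and_alphabet(tmp_path):
    p = tmp_path / "x.fa"
    write_fasta([("b", "acgtacgt"), ("a", "TTTT")], p)
    recs = read_fasta(p)
    assert [r[0] for r in recs] == ["b", "a"]
    assert recs[0][1] == "ACGTACGT"
    q = tmp_path / "u.fa"
    q.write_text(">r1\nACGU\n")
    with pytest.raises(ValueError):
        read_fasta(q)
    assert read_fasta(q, map_to_N=True)[0][1] == "ACGN"
    empty = tmp_path / "e.fa"
    empty.write_text("")
    with pytest.raises(ValueError):
        read_fasta(empty)


def test_extract_examples():
    g = oa.AnnotatedGenome(id="x", sequence="ACGTAC", circular=True)
    assert extract(g, Interval(1, 4), "+") == "CGT"
    assert extract(g, Interval(1, 4), "-") == "ACG"
    assert extract(g, Interval(4, 2, wraps=True)) == "ACAC"
    lin = oa.AnnotatedGenome(id="y", sequence="ACGTAC", circular=False)
    with pytest.raises(CoordinateError):
        extract(lin, Interval(4, 2, wraps=True))


def test_extract_strand_is_revcomp_property():
    rng = np.random.default_rng(3)
    for _ in range(25):
        n = int(rng.integers(10, 200))
        g = oa.AnnotatedGenome(id="r", circular=True,
                               sequence="".join(rng.choice(list("ACGT"), n)))
        s = int(rng.integers(0, n))
        e = int(rng.integers(s + 1, n + 1))
        iv = Interval(s, e)
        assert revcomp(extract(g, iv, "+")) == extract(g, iv, "-")


def test_genbank_roundtrip_preserves_features(tmp_path, mt_genome):
    p = tmp_path / "mt.gb"
    write_genbank(mt_genome, p)
    back = read_genbank(p)
    assert len(back.features) == len(mt_genome.features)
    assert back.circular == mt_genome.circular
    a = sorted((f.kind, f.strand, tuple((q.start, q.end, q.wraps)
                                        for q in f.parts))
               for f in mt_genome.features)
    b = sorted((f.kind, f.strand, tuple((q.start, q.end, q.wraps)
                                        for q in f.parts))
               for f in back.features)
    assert a == b


def test_rotation_and_flip_are_inverses(mt_genome):
    r = rotate_genome(mt_genome, 1234)
    assert len(r) == len(mt_genome)
    back = rotate_genome(r, len(mt_genome) - 1234)
    assert back.sequence == mt_genome.sequence
    ff = flip_genome(flip_genome(mt_genome))
    assert ff.sequence == mt_genome.sequence
    a = sorted((f.kind, tuple((q.start, q.end) for q in f.parts))
               for f in mt_genome.features)
    b = sorted((f.kind, tuple((q.start, q.end) for q in f.parts))
               for f in ff.features)
    assert a == b


def test_gff3_writer_emits_every_part(tmp_path, toy):
    genome, _ = toy
    p = tmp_path / "toy.gff3"
    write_gff3(genome, p)
    lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
    n_parts = sum(len(f.parts) for f in genome.features)
    assert len(lines) == n_parts
    assert all(len(l.split("\t")) == 9 for l in lines)
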