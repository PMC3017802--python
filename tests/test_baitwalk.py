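import numpy as np
import pytest

import organellarch as oa
from organellarch._util import revcomp
from organellarch.baitwalk import (Contig, LayoutEntry, assemble,
                                   detect_circularity, evaluate_assembly,
                                   recruit_traces, walk)
from organellarch.synth import Trace
from oracle_helpers import smith_waterman_identity


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[i]]
    return "".join(out)


def test_recruitment_planted_fragments_only():
    rng = np.random.default_rng(0)
    bait = _rand(rng, 3000)
    archive = []
    for i in range(20):
        s = int(rng.integers(0, len(bait) - 800))
        archive.append(Trace(f"frag{i:02d}", bait[s:s + 800], "organelle"))
    for i in range(20):
        archive.append(Trace(f"rand{i:02d}", _rand(rng, 800), "nuclear"))
    hits = recruit_traces(archive, [("b", bait)])
    assert {h.trace_id for h in hits} == {f"frag{i:02d}" for i in range(20)}
    assert all(h.identity == 1.0 for h in hits)


def test_recruitment_searches_both_strands():
    rng = np.random.default_rng(1)
    bait = _rand(rng, 2000)
    tr = Trace("rc", revcomp(bait[500:1300]), "organelle")
    hits = recruit_traces([tr], [("b", bait)])
    assert len(hits) == 1 and hits[0].strand == "-"
    assert hits[0].aligned_length == 800


def test_recruitment_identity_threshold_agrees_with_alignment_oracle():
    rng = np.random.default_rng(2)
    bait = _rand(rng, 1200)
    frag = bait[200:800]
    ok = _mutate(rng, frag, 0.15)
    bad = _mutate(rng, frag, 0.25)
    hits_ok = recruit_traces([Trace("ok", ok)], [("b", bait)])
    hits_bad = recruit_traces([Trace("bad", bad)], [("b", bait)])
    assert [h.trace_id for h in hits_ok] == ["ok"]
    assert hits_bad == []
    # oracle: full local alignment identity agrees with the decisions
    ident_ok, _ = smith_waterman_identity(ok, bait)
    ident_bad, _ = smith_waterman_identity(bad, bait)
    assert ident_ok > 0.8 > ident_bad
    assert hits_ok[0].identity == pytest.approx(ident_ok, abs=0.02)


def test_recruitment_score_consistent_with_scheme():
    rng = np.random.default_rng(3)
    bait = _rand(rng, 1000)
    tr = Trace("t", _mutate(rng, bait[100:700], 0.05))
    h, = recruit_traces([tr], [("b", bait)])
    matches = round(h.identity * h.aligned_length)
    assert h.score == 2 * matches - 3 * (h.aligned_length - matches)


def test_assemble_error_free_tiling_reconstructs_source():
    rng = np.random.default_rng(4)
    src = _rand(rng, 5000)
    traces = []
    step, ln = 400, 1000  # 600 nt overlaps
    for i, s in enumerate(range(0, 4001, step)):
        traces.append(Trace(f"t{i:02d}", src[s:s + ln]))
    contigs = assemble(traces, min_overlap=500)
    assert len(contigs) == 1
    assert contigs[0].consensus == src
    assert int(contigs[0].coverage.min()) >= 1


def test_assemble_respects_min_overlap():
    rng = np.random.default_rng(5)
    src = _rand(rng, 1600)
    t1, t2 = Trace("a", src[:1000]), Trace("b", src[450:1600])  # 550 overlap
    assert len(assemble([t1, t2], min_overlap=500)) == 1
    t3 = Trace("c", src[:800])
    t4 = Trace("d", src[400:1600])  # 400 nt overlap < 500
    assert len(assemble([t3, t4], min_overlap=500)) == 2


def test_assemble_noisy_reads_high_identity():
    rng = np.random.default_rng(6)
    src = _rand(rng, 10000)
    traces = []
    i = 0
    for s in range(0, 9250, 50):  # 20x coverage, 750 nt reads
        read = src[s:s + 750]
        if len(read) < 750:
            read = src[s:]
        read = _mutate(rng, read, 0.01)
        if rng.random() < 0.5:
            read = revcomp(read)
        traces.append(Trace(f"r{i:03d}", read))
        i += 1
    contigs = assemble(traces)
    main = max(contigs, key=len)
    import edlib
    d = edlib.align(main.consensus, src, mode="HW", task="distance")
    ident = 1 - d["editDistance"] / len(main.consensus)
    assert ident >= 0.999


def test_walk_identity_and_fixpoint():
    rng = np.random.default_rng(7)
    src = _rand(rng, 4000)
    traces = [Trace(f"t{i}", src[s:s + 900])
              for i, s in enumerate(range(0, 3100, 300))]
    contigs = assemble(traces[:3], min_overlap=500)
    assert walk([], contigs, max_rounds=0) == contigs
    # archive without any new organelle traces: unchanged after round 1
    decoys = [Trace(f"n{i}", _rand(rng, 800)) for i in range(10)]
    same = walk(decoys, contigs, max_rounds=5)
    assert sum(len(c) for c in same) == sum(len(c) for c in contigs)
    # full archive: walking recovers everything the traces cover (3900 nt)
    grown = walk(traces, contigs, max_rounds=20)
    assert max(len(c) for c in grown) == 3900


def test_detect_circularity_closure_and_threshold():
    rng = np.random.default_rng(8)
    src = _rand(rng, 10000)
    contig = Contig(consensus=src + src[:600],
                    layout=[LayoutEntry("x", 0, 1, 10600, 1.0)],
                    coverage=np.ones(10600, dtype=int))
    closed = detect_circularity(contig)
    assert closed.circular and len(closed) == 10000
    short = Contig(consensus=src + src[:300],
                   layout=[LayoutEntry("x", 0, 1, 10300, 1.0)],
                   coverage=np.ones(10300, dtype=int))
    assert not detect_circularity(short).circular


def test_canonical_rotation_invariant_to_cut_point():
    rng = np.random.default_rng(9)
    src = _rand(rng, 8000)
    outs = set()
    for cut in rng.integers(0, 8000, size=10):
        rotated = src[cut:] + src[:cut]
        contig = Contig(consensus=rotated + rotated[:600],
                        layout=[LayoutEntry("x", 0, 1, 8600, 1.0)],
                        coverage=np.ones(8600, dtype=int))
        closed = detect_circularity(contig)
        assert closed.circular
        outs.add(closed.consensus)
    assert len(outs) == 1


def test_evaluate_assembly_reports():
    rng = np.random.default_rng(10)
    src = _rand(rng, 3000)
    truth = oa.AnnotatedGenome(id="t", sequence=src, circular=True)
    traces = [Trace(f"t{i}", src[s:s + 800], "organelle")
              for i, s in enumerate(range(0, 2300, 200))]
    contigs = assemble(traces, min_overlap=500)
    main = max(contigs, key=len)
    rep = evaluate_assembly(main, truth, archive=traces)
    assert rep["identity_to_truth"] == 1.0
    assert rep["recruited_purity"] == 1.0
    total = sum(e.length for e in main.layout)
    assert rep["mean_coverage"] == pytest.approx(total / len(main.consensus))


def test_purity_drops_with_organelle_like_decoy():
    rng = np.random.default_rng(11)
    spec = oa.GenomeSpec(length=12000, seed=12, n_protein=4, n_trna=1,
                         noncoding_fraction=0.5)
    g = oa.generate_genome(spec)
    ins = g.sequence[2000:2800]  # numt/nupt mimic inside the decoy
    shred = oa.ShredSpec(coverage=15, seed=13, substitution_error=0.01,
                         nuclear_background=3.0, decoy_insert=ins)
    archive = oa.shred_traces(g, shred)
    hits = recruit_traces(archive, [("b", g.sequence[1500:3500])])
    by_id = {t.id: t for t in archive}
    recruited = [by_id[h.trace_id] for h in hits]
    origins = {t.origin for t in recruited}
    assert "nuclear" in origins, "decoy with planted insert must recruit"
    contigs = assemble(recruited)
    main = max(contigs, key=len)
    rep = evaluate_assembly(main, g, archive=archive,
                            recruited=[h.trace_id for h in hits])
    assert rep["recruited_purity"] < 1.0
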