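"""Annotated-genome I/O and the internal coordinate convention.

All coordinates inside the package are 0-based half-open; GenBank's 1-based
inclusive convention is converted at this boundary only. Circular genomes
keep origin-spanning feature parts as explicit wrapping intervals — nothing
downstream may silently linearize a circle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation
from Bio.SeqRecord import SeqRecord

from ._util import revcomp

FEATURE_KINDS = {
    "gene", "CDS", "tRNA", "rRNA", "intron", "intronic_ORF",
    "pseudogene", "repeat_region", "misc",
}

_DIRECT_KINDS = {"gene", "CDS", "tRNA", "rRNA", "intron", "repeat_region"}


class GenBankParseError(ValueError):
    pass


class CoordinateError(ValueError):
    pass


@dataclass(frozen=True)
class Interval:
    """Half-open [start, end); ``wraps`` marks a region crossing the origin
    of a circular sequence (then end < start and the region is
    [start, L) + [0, end))."""

    start: int
    end: int
    wraps: bool = False

    def span(self, seq_len: int | None = None) -> int:
        if self.wraps:
            if seq_len is None:
                raise ValueError("wrapping interval needs sequence length")
            return seq_len - self.start + self.end
        return self.end - self.start

    def contains(self, pos: int, seq_len: int | None = None) -> bool:
        if self.wraps:
            return pos >= self.start or pos < self.end
        return self.start <= pos < self.end

    def shift(self, offset: int, seq_len: int) -> "Interval":
        """Rotate by ``offset`` on a circle of size ``seq_len``."""
        s = (self.start - offset) % seq_len
        e_excl = (self.end - offset) % seq_len
        length = self.span(seq_len)
        if s + length <= seq_len:
            return Interval(s, s + length)
        return Interval(s, (s + length) - seq_len, wraps=True)


@dataclass
class Feature:
    kind: str
    name: str
    strand: str  # '+' or '-'
    parts: list[Interval]
    qualifiers: dict = field(default_factory=dict)

    def envelope(self, seq_len: int) -> Interval:
        """Contiguous span from the first part's start to the last part's
        end (circular order), i.e. the locus including its introns."""
        if len(self.parts) == 1:
            return self.parts[0]
        start = self.parts[0].start
        end = self.parts[-1].end
        if any(p.wraps for p in self.parts) or end <= start:
            return Interval(start, end, wraps=True)
        return Interval(start, end)

    def total_length(self, seq_len: int) -> int:
        return sum(p.span(seq_len) for p in self.parts)


@dataclass
class AnnotatedGenome:
    id: str
    sequence: str
    circular: bool
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty sequence")
        if re.search(r"[^ACGTN]", self.sequence):
            raise ValueError("sequence contains characters outside ACGTN")

    def __len__(self) -> int:
        return len(self.sequence)

    def extract(self, interval: Interval, strand: str = "+") -> str:
        return extract(self, interval, strand)

    def features_of(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]


def extract(genome: AnnotatedGenome, interval: Interval, strand: str = "+") -> str:
    """Subsequence for an interval; wrapping intervals concatenate
    suffix + prefix; strand '-' returns the reverse complement."""
    if interval.wraps:
        if not genome.circular:
            raise CoordinateError("wrapping interval on a non-circular genome")
        seq = genome.sequence[interval.start:] + genome.sequence[:interval.end]
    else:
        if interval.end > len(genome) or interval.start < 0:
            raise CoordinateError("interval outside sequence")
        seq = genome.sequence[interval.start:interval.end]
    return revcomp(seq) if strand == "-" else seq


def feature_sequence(genome: AnnotatedGenome, feature: Feature) -> str:
    """Transcript-style sequence: parts concatenated in ascending genomic
    order, reverse-complemented as a whole for '-' strand features."""
    s = "".join(extract(genome, p, "+") for p in feature.parts)
    return revcomp(s) if feature.strand == "-" else s


def _infer_name(f: SeqFeature, idx: int) -> str:
    q = f.qualifiers
    for key in ("gene", "locus_tag", "product", "label", "standard_name", "note"):
        if key in q and q[key]:
            return str(q[key][0])
    return f"{f.type}_{idx}"


def _is_pseudo(f: SeqFeature, name: str) -> bool:
    if "pseudo" in f.qualifiers or "pseudogene" in f.qualifiers:
        return True
    low = name.lower()
    return "ψ" in name or low.endswith("psi") or low.startswith("psi_")


def _convert_location(f: SeqFeature, seq_len: int, circular: bool, name: str):
    raw = []
    for part in f.location.parts:
        s, e = int(part.start), int(part.end)
        if e > seq_len or s < 0 or s >= e:
            raise CoordinateError(
                f"feature '{name}' has part ({s},{e}) outside sequence of length {seq_len}"
            )
        raw.append((s, e))
    raw.sort()
    # Merge an end-of-sequence part with an origin part into a wrap.
    parts: list[Interval] = []
    if circular and len(raw) >= 2 and raw[0][0] == 0 and raw[-1][1] == seq_len:
        wrap = Interval(raw[-1][0], raw[0][1], wraps=True)
        middle = [Interval(s, e) for s, e in raw[1:-1]]
        parts = middle + [wrap] if middle else [wrap]
    else:
        parts = [Interval(s, e) for s, e in raw]
    strand = "-" if f.location.strand == -1 else "+"
    return parts, strand


def read_genbank(path) -> AnnotatedGenome:
    """Parse a single-record GenBank flat file into an AnnotatedGenome."""
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise GenBankParseError(f"no GenBank record found in {path}")
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) == 0:
        raise GenBankParseError(f"record {record.id} has no sequence")
    if "N" in seq and len(seq.replace("N", "")) == 0:
        raise GenBankParseError(f"record {record.id} has no sequence content")
    circular = record.annotations.get("topology", "linear") == "circular"
    feats: list[Feature] = []
    for idx, f in enumerate(record.features):
        if f.type == "source":
            continue
        name = _infer_name(f, idx)
        parts, strand = _convert_location(f, len(seq), circular, name)
        quals = {k: (v[0] if isinstance(v, list) and len(v) == 1 else v)
                 for k, v in f.qualifiers.items()}
        if f.type in _DIRECT_KINDS:
            kind = f.type
        else:
            kind = "misc"
            quals.setdefault("original_key", f.type)
        if _is_pseudo(f, name) and kind in {"gene", "CDS", "tRNA", "rRNA"}:
            kind = "pseudogene"
            quals.setdefault("original_key", f.type)
        feats.append(Feature(kind=kind, name=name, strand=strand,
                             parts=parts, qualifiers=quals))
    genome = AnnotatedGenome(id=record.id or record.name, sequence=seq,
                             circular=circular, features=feats)
    _classify_intronic_orfs(genome)
    return genome


def _classify_intronic_orfs(genome: AnnotatedGenome) -> None:
    """A CDS fully contained within an intron feature is an intronic ORF
    (counted as noncoding by the partition accounting)."""
    intron_parts = [p for f in genome.features if f.kind == "intron"
                    for p in f.parts]

    def inside(iv: Interval) -> bool:
        for ip in intron_parts:
            if ip.wraps or iv.wraps:
                n = len(genome)
                pos = set(_positions(iv, n))
                if pos <= set(_positions(ip, n)):
                    return True
            elif ip.start <= iv.start and iv.end <= ip.end:
                return True
        return False

    for f in genome.features:
        if f.kind == "CDS" and f.parts and all(inside(p) for p in f.parts):
            f.kind = "intronic_ORF"


def _positions(iv: Interval, seq_len: int):
    if iv.wraps:
        return list(range(iv.start, seq_len)) + list(range(0, iv.end))
    return range(iv.start, iv.end)


# ---------------------------------------------------------------- writers

_KIND_TO_KEY = {
    "gene": "gene", "CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
    "intron": "intron", "intronic_ORF": "CDS", "repeat_region": "repeat_region",
}


def _to_seqfeature(f: Feature, seq_len: int) -> SeqFeature:
    strand = -1 if f.strand == "-" else 1
    locs = []
    for p in f.parts:
        if p.wraps:
            locs.append(SimpleLocation(p.start, seq_len, strand))
            locs.append(SimpleLocation(0, p.end, strand))
        else:
            locs.append(SimpleLocation(p.start, p.end, strand))
    loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
    if f.kind == "pseudogene":
        key = f.qualifiers.get("original_key", "gene")
    elif f.kind == "misc":
        key = f.qualifiers.get("original_key", "misc_feature")
    else:
        key = _KIND_TO_KEY[f.kind]
    quals = {k: v for k, v in f.qualifiers.items() if k != "original_key"}
    quals.setdefault("gene", f.name)
    if f.kind == "pseudogene":
        quals.setdefault("pseudo", "")
    return SeqFeature(location=loc, type=key,
                      qualifiers={k: ([v] if not isinstance(v, list) else v)
                                  for k, v in quals.items()})


def write_genbank(genome: AnnotatedGenome, path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description="organellarch annotated genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    record.features = [_to_seqfeature(f, len(genome)) for f in genome.features]
    SeqIO.write(record, str(path), "genbank")


def write_fasta(records, path) -> None:
    """records: iterable of (id, sequence) pairs."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_fasta(path, map_to_N: bool = False) -> list[tuple[str, str]]:
    """Multi-record FASTA as (id, uppercase sequence) pairs in file order."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if re.search(r"[^ACGTN]", seq):
            if map_to_N:
                seq = re.sub(r"[^ACGTN]", "N", seq)
            else:
                raise ValueError(
                    f"record {rec.id}: non-ACGTN characters (use map_to_N)")
        out.append((rec.id, seq))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def read_fastq(path) -> list[tuple[str, str]]:
    out = [(rec.id, str(rec.seq).upper())
           for rec in SeqIO.parse(str(path), "fastq")]
    if not out:
        raise ValueError(f"no FASTQ records in {path}")
    return out


def write_gff3(genome: AnnotatedGenome, path) -> None:
    """Re-emit features as GFF3 (1-based inclusive); wrapping parts are
    split at the origin."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for f in genome.features:
            segs = []
            for p in f.parts:
                if p.wraps:
                    segs.append((p.start, len(genome)))
                    segs.append((0, p.end))
                else:
                    segs.append((p.start, p.end))
            for s, e in segs:
                fh.write("\t".join([
                    genome.id, "organellarch", f.kind, str(s + 1), str(e),
                    ".", f.strand, ".", f"Name={f.name}",
                ]) + "\n")


def write_bed(intervals, path, seq_len: int | None = None, names=None) -> None:
    """0-based half-open BED; wrapping intervals split at the origin."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region_{i}"
            chrom = "seq"
            if iv.wraps:
                fh.write(f"{chrom}\t{iv.start}\t{seq_len}\t{name}\n")
                fh.write(f"{chrom}\t0\t{iv.end}\t{name}\n")
            else:
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def rotate_genome(genome: AnnotatedGenome, offset: int) -> AnnotatedGenome:
    """New origin at ``offset`` (circular genomes only); features are
    shifted, wrap flags recomputed, part order preserved."""
    if not genome.circular:
        raise ValueError("cannot rotate a linear genome")
    n = len(genome)
    offset %= n
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    feats = []
    for f in genome.features:
        feats.append(Feature(kind=f.kind, name=f.name, strand=f.strand,
                             parts=[p.shift(offset, n) for p in f.parts],
                             qualifiers=dict(f.qualifiers)))
    return AnnotatedGenome(id=genome.id, sequence=seq, circular=True,
                           features=feats)


def flip_genome(genome: AnnotatedGenome) -> AnnotatedGenome:
    """Reverse-complement the genome, mirroring features and swapping
    strands (used by strand-invariance checks)."""
    n = len(genome)
    feats = []
    for f in genome.features:
        parts = []
        for p in reversed(f.parts):
            if p.wraps:
                parts.append(Interval((n - p.end) % n, (n - p.start) % n,
                                      wraps=True))
            else:
                parts.append(Interval(n - p.end, n - p.start))
        feats.append(Feature(kind=f.kind, name=f.name,
                             strand="-" if f.strand == "+" else "+",
                             parts=parts, qualifiers=dict(f.qualifiers)))
    return AnnotatedGenome(id=genome.id, sequence=revcomp(genome.sequence),
                           circular=genome.circular, features=feats)
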