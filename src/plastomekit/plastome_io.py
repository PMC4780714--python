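"""Reading, writing and circular-coordinate arithmetic for annotated plastomes.

Land-plant plastid genomes are single circular molecules of roughly 115-165 kb.
Everything downstream (structure detection, composition accounting, repeat
scans) works on the containers defined here: an :class:`AnnotatedPlastome`
holding the circular sequence plus typed :class:`Feature` records whose exon
locations are :class:`CircularInterval` objects.

Coordinate convention: internal coordinates are 0-based half-open; GenBank and
GFF3 input/output use 1-based inclusive coordinates and are converted at the
boundary.  An interval with ``start > end`` wraps the origin.  ``start == end``
is disallowed (ambiguous empty-vs-full-circle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

IUPAC_DNA = set("ACGTNRYSWKMBDHV")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PlastomeError(ValueError):
    """Raised for malformed inputs or invalid coordinate arithmetic."""


@dataclass(frozen=True)
class CircularInterval:
    """Half-open interval on a circular sequence; start > end means it wraps."""

    start: int
    end: int

    def length(self, genome_length: int) -> int:
        if self.start == self.end:
            raise PlastomeError(
                f"interval ({self.start},{self.end}) is ambiguous (empty or full circle)")
        return (self.end - self.start) % genome_length

    def wraps(self) -> bool:
        return self.start > self.end

    def contains(self, pos: int, genome_length: int) -> bool:
        pos %= genome_length
        if self.wraps():
            return pos >= self.start or pos < self.end
        return self.start <= pos < self.end

    def positions(self, genome_length: int):
        """Iterate genomic positions in order (wrapping past the origin)."""
        n = self.length(genome_length)
        for i in range(n):
            yield (self.start + i) % genome_length

    def shifted(self, offset: int, genome_length: int) -> "CircularInterval":
        s = (self.start - offset) % genome_length
        e = (self.end - offset) % genome_length
        return CircularInterval(s, e)


@dataclass
class Feature:
    """One annotated gene copy (CDS, tRNA, rRNA, ...).

    ``parts`` are the exons in genomic order; for cis-spliced features the
    intron count is ``len(parts) - 1``.  Trans-spliced features (plastid
    *rps12*) are flagged so that composition statistics do not treat the
    between-part gaps as introns.
    """

    name: str
    kind: str  # CDS | tRNA | rRNA | gene | pseudogene
    strand: str  # '+' or '-'
    parts: list[CircularInterval]
    pseudo: bool = False
    trans_spliced: bool = False
    note: str = ""

    def span(self) -> CircularInterval:
        return CircularInterval(self.parts[0].start, self.parts[-1].end)

    def length(self, genome_length: int) -> int:
        return sum(p.length(genome_length) for p in self.parts)

    # gaps wider than this inside a trans-spliced feature are the trans
    # junction, not a cis intron (plastid rps12's 5'/3' halves lie ~tens of
    # kb apart while its real cis intron is a few hundred bp)
    MAX_CIS_GAP = 5000

    def intron_intervals(self, genome_length: int) -> list[CircularInterval]:
        """Cis-intron gaps between consecutive exons."""
        out = []
        for a, b in zip(self.parts, self.parts[1:]):
            if a.end == b.start:
                continue
            iv = CircularInterval(a.end, b.start)
            if self.trans_spliced and iv.length(genome_length) > self.MAX_CIS_GAP:
                continue
            out.append(iv)
        return out

    def n_introns(self, genome_length: int) -> int:
        return len(self.intron_intervals(genome_length))


@dataclass
class AnnotatedPlastome:
    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise PlastomeError("empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise PlastomeError(f"non-IUPAC symbol(s) in {self.id}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def sorted_features(self) -> list[Feature]:
        return sorted(self.features, key=lambda f: (f.parts[0].start, f.parts[-1].end))

    def extract(self, interval: CircularInterval, strand: str = "+") -> str:
        return extract(self, interval, strand)

    def rotate(self, offset: int) -> "AnnotatedPlastome":
        """Return a copy rotated so old position ``offset`` becomes position 0."""
        n = len(self)
        offset %= n
        if offset == 0:
            return self
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = [
            replace(f, parts=[p.shifted(offset, n) for p in f.parts])
            for f in self.features
        ]
        return AnnotatedPlastome(self.id, seq, self.circular, feats)

    def gc_percent(self) -> float:
        return gc_percent(self.sequence)


def gc_percent(seq: str) -> float:
    """GC percentage over called (non-N) bases; ambiguity codes are excluded."""
    called = sum(seq.count(b) for b in "ACGT")
    if called == 0:
        return 0.0
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / called


def extract(genome: AnnotatedPlastome, interval: CircularInterval, strand: str = "+") -> str:
    """Subsequence for a (possibly origin-wrapping) interval; '-' reverse-complements."""
    if interval.start == interval.end:
        raise PlastomeError(
            f"interval ({interval.start},{interval.end}) is ambiguous (empty or full circle)")
    if interval.wraps():
        if not genome.circular:
            raise PlastomeError("wrapping interval on a linear sequence")
        s = genome.sequence[interval.start:] + genome.sequence[:interval.end]
    else:
        s = genome.sequence[interval.start:interval.end]
    return reverse_complement(s) if strand == "-" else s


# ---------------------------------------------------------------------------
# GenBank input
# ---------------------------------------------------------------------------

_FEATURE_KINDS = {"CDS", "tRNA", "rRNA"}


def _location_to_parts(location, n: int) -> tuple[list[CircularInterval], str]:
    strand = "-" if location.strand == -1 else "+"
    raw = [(int(p.start), int(p.end)) for p in location.parts]
    raw.sort()
    # merge a trailing part ending at n with a leading part starting at 0: the
    # feature wraps the origin of the circular record
    if len(raw) >= 2 and raw[0][0] == 0 and raw[-1][1] == n:
        first, last = raw[0], raw[-1]
        raw = raw[1:-1]
        raw.append((last[0], first[1]))  # wrap interval
    parts = [CircularInterval(s, e) for s, e in raw]
    return parts, strand


def read_genbank(path) -> AnnotatedPlastome:
    """Parse a single-record GenBank flat file into an AnnotatedPlastome.

    gene/CDS/tRNA/rRNA records are mapped to features; join()/complement()
    locations become exon parts and strand.  Bare ``gene`` records are only
    kept when no CDS/tRNA/rRNA record shares their name (e.g. pseudogenes).
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise PlastomeError(f"cannot parse GenBank file {path}: {exc}") from exc
    n = len(record.seq)
    circular = record.annotations.get("topology", "circular") != "linear"
    feats: list[Feature] = []
    gene_only: list[Feature] = []
    for sf in record.features:
        if sf.type not in _FEATURE_KINDS and sf.type != "gene":
            continue
        name = (sf.qualifiers.get("gene") or sf.qualifiers.get("locus_tag") or ["?"])[0]
        parts, strand = _location_to_parts(sf.location, n)
        pseudo = "pseudo" in sf.qualifiers or "pseudogene" in sf.qualifiers
        trans = any("trans" in v for v in sf.qualifiers.get("exception", []))
        feat = Feature(name=name, kind=sf.type if sf.type != "gene" else "gene",
                       strand=strand, parts=parts, pseudo=pseudo, trans_spliced=trans)
        (gene_only if sf.type == "gene" else feats).append(feat)
    named = {f.name for f in feats}
    for f in gene_only:
        if f.name not in named:
            f.kind = "pseudogene" if f.pseudo else "gene"
            feats.append(f)
    return AnnotatedPlastome(record.id or record.name, str(record.seq), circular, feats)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[AnnotatedPlastome]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise PlastomeError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        if "N" in seq:
            log.info("record %s contains %d 'N' bases", rec.id, seq.count("N"))
        out.append(AnnotatedPlastome(rec.id, seq, circular=True, features=[]))
    return out


def write_fasta(genomes, path, width: int = 70) -> None:
    if isinstance(genomes, AnnotatedPlastome):
        genomes = [genomes]
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff_rows_for_interval(iv: CircularInterval, n: int):
    """1-based inclusive (start, end) rows; wrap intervals split into two rows."""
    if iv.wraps():
        return [(iv.start + 1, n), (1, iv.end)]
    return [(iv.start + 1, iv.end)]


def write_gff3(genome: AnnotatedPlastome, path) -> None:
    n = len(genome)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {n}\n")
        for idx, f in enumerate(genome.sorted_features()):
            gid = f"gene{idx:04d}"
            attrs = f"ID={gid};Name={f.name};kind={f.kind}"
            if f.pseudo:
                attrs += ";pseudo=true"
            if f.trans_spliced:
                attrs += ";trans_spliced=true"
            span_rows = _gff_rows_for_interval(f.span(), n)
            for s, e in span_rows:
                fh.write(f"{genome.id}\tplastomekit\tgene\t{s}\t{e}\t.\t{f.strand}\t.\t{attrs}\n")
            for pi, part in enumerate(f.parts):
                for s, e in _gff_rows_for_interval(part, n):
                    fh.write(
                        f"{genome.id}\tplastomekit\texon\t{s}\t{e}\t.\t{f.strand}\t."
                        f"\tID={gid}.e{pi};Parent={gid}\n")


def read_gff3(genome_or_fasta, path) -> AnnotatedPlastome:
    """Re-attach features written by :func:`write_gff3` to a sequence.

    Accepts an AnnotatedPlastome (features replaced) or a FASTA path.
    """
    if isinstance(genome_or_fasta, AnnotatedPlastome):
        genome = genome_or_fasta
    else:
        genome = read_fasta(genome_or_fasta)[0]
    n = len(genome)
    genes: dict[str, Feature] = {}
    exon_rows: dict[str, list[tuple[int, tuple[int, int]]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise PlastomeError(f"malformed GFF3 row: {line!r}")
            _, _, ftype, start, end, _, strand, _, attrs = cols
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = a["ID"]
                if gid not in genes:
                    genes[gid] = Feature(
                        name=a.get("Name", gid), kind=a.get("kind", "gene"),
                        strand=strand, parts=[],
                        pseudo=a.get("pseudo") == "true",
                        trans_spliced=a.get("trans_spliced") == "true")
                    order.append(gid)
            elif ftype == "exon":
                eid = a["ID"]
                gid = a["Parent"]
                idx = int(eid.rsplit(".e", 1)[1])
                exon_rows.setdefault(gid, []).append((idx, (int(start) - 1, int(end))))
    feats = []
    for gid in order:
        rows = sorted(exon_rows.get(gid, []))
        parts = []
        by_idx: dict[int, list[tuple[int, int]]] = {}
        for idx, (s, e) in rows:
            by_idx.setdefault(idx, []).append((s, e))
        for idx in sorted(by_idx):
            segs = sorted(by_idx[idx])
            if len(segs) == 2 and segs[0][0] == 0 and segs[1][1] == n:
                parts.append(CircularInterval(segs[1][0], segs[0][1]))  # wrapped
            else:
                for s, e in segs:
                    parts.append(CircularInterval(s, e))
        f = genes[gid]
        f.parts = parts
        feats.append(f)
    return AnnotatedPlastome(genome.id, genome.sequence, genome.circular, feats)
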