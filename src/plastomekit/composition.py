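"""Genome-composition accounting: region stats, class stats, gene census, introns.

All statistics are computed from the annotation; where feature classes overlap
(e.g. matK inside the trnK-UUU intron) the per-base precedence
CDS > tRNA > rRNA > intron > intergenic makes the partition well defined, so
class lengths always sum exactly to the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plastome_io import AnnotatedPlastome, PlastomeError, gc_percent
from .structure import QuadripartiteMap

_GENE_KINDS = {"CDS", "tRNA", "rRNA"}


@dataclass(frozen=True)
class RegionStats:
    region: str            # LSC | SSC | IR | total
    length_bp: int
    gc_percent: float
    length_percent_of_total: float


@dataclass(frozen=True)
class ClassStats:
    cls: str               # protein_coding | tRNA | rRNA | intron | intergenic
    length_bp: int
    gc_percent: float
    length_percent: float


@dataclass
class GeneCensus:
    total_genes: int
    by_class: dict          # kind -> copy count
    duplicated_in_IR: int   # unique genes with a copy in each IR
    unique_genes: int
    unique_by_region: dict  # region -> count (boundary genes by majority length)
    intron_containing: list
    boundary_spanning: list


@dataclass(frozen=True)
class IntronRecord:
    gene: str
    exon_lengths: tuple
    intron_lengths: tuple
    region: str
    trans_spliced: bool
    nested_genes: tuple = ()


# ---------------------------------------------------------------------------

def region_stats(genome: AnnotatedPlastome, qmap: QuadripartiteMap):
    """Length and GC per region; the IR row reports the single-copy length but
    its length percentage counts both copies, so percentages sum to 100."""
    n = len(genome)
    rows = []
    for name, iv, mult in (("LSC", qmap.lsc, 1), ("SSC", qmap.ssc, 1),
                           ("IR", qmap.ir_a, 2)):
        seq = genome.extract(iv)
        rows.append(RegionStats(name, iv.length(n), gc_percent(seq),
                                100.0 * mult * iv.length(n) / n))
    rows.append(RegionStats("total", n, genome.gc_percent(), 100.0))
    return rows


def _class_array(genome: AnnotatedPlastome) -> np.ndarray:
    """Per-base class codes under the precedence CDS > tRNA > rRNA > intron."""
    n = len(genome)
    arr = np.zeros(n, dtype=np.uint8)  # 0 intergenic
    CODE = {"intron": 1, "rRNA": 2, "tRNA": 3, "CDS": 4}

    def paint(iv, code):
        if iv.wraps():
            arr[iv.start:] = np.maximum(arr[iv.start:], code)
            arr[:iv.end] = np.maximum(arr[:iv.end], code)
        else:
            arr[iv.start:iv.end] = np.maximum(arr[iv.start:iv.end], code)

    for f in genome.features:
        if f.pseudo or f.kind not in _GENE_KINDS:
            continue
        for iv in f.intron_intervals(n):
            paint(iv, CODE["intron"])
    for kind in ("rRNA", "tRNA", "CDS"):  # increasing precedence
        for f in genome.features:
            if f.pseudo or f.kind != kind:
                continue
            for p in f.parts:
                paint(p, CODE[kind])
    return arr


def class_stats(genome: AnnotatedPlastome):
    """Coding/non-coding partition of the full genome (both IR copies counted)."""
    arr = _class_array(genome)
    n = len(genome)
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    names = {4: "protein_coding", 3: "tRNA", 2: "rRNA", 1: "intron", 0: "intergenic"}
    rows = []
    for code in (4, 3, 2, 1, 0):
        sel = arr == code
        length = int(sel.sum())
        sub = seq[sel].tobytes().decode()
        rows.append(ClassStats(names[code], length, gc_percent(sub),
                               100.0 * length / n))
    assert sum(r.length_bp for r in rows) == n
    return rows


# ---------------------------------------------------------------------------

def _majority_region(f, qmap: QuadripartiteMap, n: int) -> str:
    counts = {"LSC": 0, "IR_B": 0, "SSC": 0, "IR_A": 0}
    for p in f.parts:
        for pos in p.positions(n):
            counts[qmap.region_of(pos)] += 1
    region = max(counts, key=counts.get)
    return "IR" if region.startswith("IR") else region


def gene_census(genome: AnnotatedPlastome, qmap: QuadripartiteMap) -> GeneCensus:
    """Gene counts with IR duplication resolved by name + opposite-IR location."""
    n = len(genome)
    real = [f for f in genome.features if f.kind in _GENE_KINDS and not f.pseudo]
    by_class: dict[str, int] = {}
    for f in real:
        by_class[f.kind] = by_class.get(f.kind, 0) + 1
    groups: dict[str, list] = {}
    for f in real:
        groups.setdefault(f.name, []).append(f)

    duplicated = 0
    unique_by_region = {"LSC": 0, "SSC": 0, "IR": 0}
    boundary = []
    intron_genes = []
    for name, copies in sorted(groups.items()):
        if len(copies) > 2:
            import logging
            logging.getLogger(__name__).warning(
                "gene %s has %d copies; counted per copy", name, len(copies))
        regions = [_majority_region(f, qmap, n) for f in copies]
        is_dup = (len(copies) >= 2 and all(r == "IR" for r in regions[:2]))
        if is_dup:
            duplicated += len(copies) - 1
            unique_by_region["IR"] += 1
        else:
            unique_by_region[regions[0]] += 1
        spans = False
        for f in copies:
            span = f.span()
            for _, pos, _, _ in qmap.junctions():
                if span.contains(pos, n) and span.contains((pos - 1) % n, n):
                    spans = True
        if spans:
            boundary.append(name)
        if any(f.n_introns(n) > 0 for f in copies):
            intron_genes.append(name)

    total = len(real)
    return GeneCensus(
        total_genes=total, by_class=by_class, duplicated_in_IR=duplicated,
        unique_genes=total - duplicated, unique_by_region=unique_by_region,
        intron_containing=intron_genes, boundary_spanning=sorted(boundary))


def intron_inventory(genome: AnnotatedPlastome, qmap: QuadripartiteMap | None = None):
    """One record per intron-containing unique gene (IR copies reported once).

    Trans-spliced genes are flagged; genes nested inside another gene's intron
    (matK within trnK-UUU) are noted on the host's record.
    """
    n = len(genome)
    seen: set[str] = set()
    records = []
    feats = [f for f in genome.features if f.kind in _GENE_KINDS and not f.pseudo]
    for f in sorted(feats, key=lambda f: f.parts[0].start):
        if f.name in seen:
            continue
        introns = f.intron_intervals(n)
        if not introns:
            continue
        seen.add(f.name)
        nested = []
        for iv in introns:
            for g in feats:
                if g.name == f.name:
                    continue
                gs = g.span()
                if (iv.contains(gs.start, n)
                        and iv.contains((gs.end - 1) % n, n)):
                    nested.append(g.name)
        region = _majority_region(f, qmap, n) if qmap else "?"
        records.append(IntronRecord(
            gene=f.name,
            exon_lengths=tuple(p.length(n) for p in f.parts),
            intron_lengths=tuple(iv.length(n) for iv in introns),
            region=region, trans_spliced=f.trans_spliced,
            nested_genes=tuple(sorted(set(nested)))))
    return records
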