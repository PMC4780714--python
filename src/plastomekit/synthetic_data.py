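"""Synthetic annotated plastomes with fully known ("planted") structure.

The generator emulates the canonical angiosperm plastome: a circular
quadripartite genome assembled as LSC + IR_B + SSC + revcomp(IR_B), annotated
with the standard gene complement (protein-coding / tRNA / rRNA, introns,
IR-duplicated genes, a trans-spliced rps12, matK nested in the trnK-UUU
intron, and genes spanning the single-copy/IR junctions), plus planted SSRs,
tandem arrays and dispersed repeats at recorded coordinates.  Background
sequence is i.i.d. with a target GC fraction.

Defaults reproduce the architecture of the *Lagerstroemia fauriei*-like study
system: LSC 83,921 bp, SSC 16,933 bp, IR 25,793 bp (total 152,440 bp),
GC 38%, 129 gene copies of which 17 unique genes are IR-duplicated, rps19
extending 75 bp into the IR, ndhF extending 38 bp into the IR with a 20 bp
overlap with the mirrored ψycf1 fragment, and an intron-less rpl2.

A companion :func:`evolve_along_tree` derives multi-species datasets by
Jukes-Cantor substitution along a user tree, with an optional single intron
deletion on a named branch and small intergenic indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import dendropy

from .plastome_io import (AnnotatedPlastome, CircularInterval, Feature,
                          PlastomeError, reverse_complement)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Specs and truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneTemplate:
    name: str
    kind: str                  # CDS | tRNA | rRNA
    region: str                # LSC | SSC | IR
    strand: str = "+"
    exons: tuple = (300,)
    introns: tuple = ()

    @property
    def span(self) -> int:
        return sum(self.exons) + sum(self.introns)


@dataclass(frozen=True)
class PlantedSSR:
    motif: str
    copies: int
    region: str  # LSC | SSC | IR


@dataclass(frozen=True)
class PlantedTandem:
    unit_len: int
    copies: int
    region: str


@dataclass(frozen=True)
class PlantedDispersed:
    length: int
    cls: str      # forward | palindromic | reverse | complement
    region_a: str
    region_b: str


@dataclass
class PlastomeSpec:
    """Study-condition defaults: the architecture reported for the focal genome."""

    lsc_len: int = 83_921
    ssc_len: int = 16_933
    ir_len: int = 25_793
    gene_templates: list | None = None   # None -> full default complement
    planted_ssrs: list = field(default_factory=lambda: [
        PlantedSSR("A", 10, "LSC"), PlantedSSR("T", 9, "LSC"),
        PlantedSSR("AT", 6, "LSC"), PlantedSSR("AAG", 5, "SSC"),
        PlantedSSR("A", 12, "SSC"), PlantedSSR("AATT", 4, "IR"),
        PlantedSSR("AACCT", 3, "LSC"), PlantedSSR("CT", 5, "IR"),
    ])
    planted_tandems: list = field(default_factory=lambda: [
        PlantedTandem(18, 3, "LSC"), PlantedTandem(25, 3, "LSC"),
        PlantedTandem(16, 4, "SSC"),
    ])
    planted_dispersed: list = field(default_factory=lambda: [
        PlantedDispersed(40, "forward", "LSC", "LSC"),
        PlantedDispersed(36, "palindromic", "LSC", "SSC"),
        PlantedDispersed(32, "forward", "SSC", "LSC"),
    ])
    gc_target: float = 0.38
    rpl2_intron: bool = False
    label: str = "SIM"
    seed: int = 42

    @property
    def total_len(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass
class SimTruth:
    """Every planted element with its realized genomic coordinates."""

    lsc: tuple
    ir_b: tuple
    ssc: tuple
    ir_a: tuple
    ssrs: list = field(default_factory=list)        # (motif, copies, start, end, region)
    tandems: list = field(default_factory=list)     # (unit, copies, start, end, region)
    dispersed: list = field(default_factory=list)   # (cls, start1, start2, length)
    genes: list = field(default_factory=list)       # Feature records (shared)
    rpl2_amplicon: int | None = None                # expected in-silico PCR product


@dataclass
class EvolutionSpec:
    tree: str                                  # newick with branch lengths
    intron_loss_clade: tuple = ()              # leaf names below the loss branch
    intron_loss_gene: str = "rpl2"
    indel_rate: float = 0.0001                 # expected indels / intergenic site / unit length
    seed: int = 0


# ---------------------------------------------------------------------------
# Default gene complement (name, kind, region, strand, exons, introns)
# ---------------------------------------------------------------------------

def default_gene_templates(rpl2_intron: bool = False) -> dict[str, list[GeneTemplate]]:
    """The standard plastome gene complement grouped by region.

    112 unique genes: 60 protein + 22 tRNA in the LSC, 12 protein + 1 tRNA in
    the SSC, and 6 protein + 7 tRNA + 4 rRNA duplicated in the IRs (129 gene
    copies in total).  Exon/intron lengths approximate typical plastid values;
    the trnK-UUU intron is 2,497 bp and hosts a 1,491 bp matK reading frame.
    """
    t = GeneTemplate
    lsc = [
        # trnH first (3 bp inside the LSC start), rps19 last (spans into the IR)
        t("trnH-GUG", "tRNA", "LSC", "-", (74,)),
        t("psbA", "CDS", "LSC", "-", (1062,)),
        t("trnK-UUU", "tRNA", "LSC", "-", (37, 35), (2497,)),
        t("rps16", "CDS", "LSC", "-", (40, 221), (860,)),
        t("trnQ-UUG", "tRNA", "LSC", "-", (72,)),
        t("psbK", "CDS", "LSC", "+", (186,)),
        t("psbI", "CDS", "LSC", "+", (111,)),
        t("trnS-GCU", "tRNA", "LSC", "-", (88,)),
        t("trnG-UCC", "tRNA", "LSC", "+", (23, 48), (691,)),
        t("trnR-UCU", "tRNA", "LSC", "+", (72,)),
        t("atpA", "CDS", "LSC", "-", (1524,)),
        t("atpF", "CDS", "LSC", "-", (145, 410), (695,)),
        t("atpH", "CDS", "LSC", "-", (246,)),
        t("atpI", "CDS", "LSC", "-", (744,)),
        t("rps2", "CDS", "LSC", "-", (711,)),
        t("rpoC2", "CDS", "LSC", "-", (4110,)),
        t("rpoC1", "CDS", "LSC", "-", (432, 1617), (738,)),
        t("rpoB", "CDS", "LSC", "-", (3213,)),
        t("trnC-GCA", "tRNA", "LSC", "+", (71,)),
        t("petN", "CDS", "LSC", "+", (90,)),
        t("psbM", "CDS", "LSC", "-", (105,)),
        t("trnD-GUC", "tRNA", "LSC", "-", (74,)),
        t("trnY-GUA", "tRNA", "LSC", "-", (84,)),
        t("trnE-UUC", "tRNA", "LSC", "-", (73,)),
        t("trnT-GGU", "tRNA", "LSC", "+", (72,)),
        t("psbD", "CDS", "LSC", "+", (1062,)),
        t("psbC", "CDS", "LSC", "+", (1386,)),
        t("trnS-UGA", "tRNA", "LSC", "-", (93,)),
        t("psbZ", "CDS", "LSC", "+", (189,)),
        t("trnG-GCC", "tRNA", "LSC", "+", (71,)),
        t("trnfM-CAU", "tRNA", "LSC", "-", (74,)),
        t("rps14", "CDS", "LSC", "-", (303,)),
        t("psaB", "CDS", "LSC", "-", (2205,)),
        t("psaA", "CDS", "LSC", "-", (2253,)),
        t("ycf3", "CDS", "LSC", "-", (124, 230, 153), (730, 780)),
        t("trnS-GGA", "tRNA", "LSC", "-", (87,)),
        t("rps4", "CDS", "LSC", "-", (606,)),
        t("trnT-UGU", "tRNA", "LSC", "-", (73,)),
        t("trnL-UAA", "tRNA", "LSC", "+", (35, 50), (491,)),
        t("trnF-GAA", "tRNA", "LSC", "+", (73,)),
        t("ndhJ", "CDS", "LSC", "-", (477,)),
        t("ndhK", "CDS", "LSC", "-", (678,)),
        t("ndhC", "CDS", "LSC", "-", (363,)),
        t("trnV-UAC", "tRNA", "LSC", "-", (39, 35), (571,)),
        t("trnM-CAU", "tRNA", "LSC", "+", (73,)),
        t("atpE", "CDS", "LSC", "-", (402,)),
        t("atpB", "CDS", "LSC", "-", (1497,)),
        t("rbcL", "CDS", "LSC", "+", (1428,)),
        t("accD", "CDS", "LSC", "+", (1470,)),
        t("psaI", "CDS", "LSC", "+", (111,)),
        t("ycf4", "CDS", "LSC", "+", (555,)),
        t("cemA", "CDS", "LSC", "+", (690,)),
        t("petA", "CDS", "LSC", "+", (963,)),
        t("psbJ", "CDS", "LSC", "-", (123,)),
        t("psbL", "CDS", "LSC", "-", (117,)),
        t("psbF", "CDS", "LSC", "-", (120,)),
        t("psbE", "CDS", "LSC", "-", (252,)),
        t("petL", "CDS", "LSC", "+", (96,)),
        t("petG", "CDS", "LSC", "+", (114,)),
        t("trnW-CCA", "tRNA", "LSC", "-", (74,)),
        t("trnP-UGG", "tRNA", "LSC", "-", (74,)),
        t("psaJ", "CDS", "LSC", "+", (129,)),
        t("rpl33", "CDS", "LSC", "+", (201,)),
        t("rps18", "CDS", "LSC", "+", (306,)),
        t("rpl20", "CDS", "LSC", "-", (354,)),
        t("rps12_5p", "CDS", "LSC", "-", (114,)),   # trans-spliced 5' exon
        t("clpP", "CDS", "LSC", "-", (71, 292, 228), (800, 640)),
        t("psbB", "CDS", "LSC", "+", (1527,)),
        t("psbT", "CDS", "LSC", "+", (108,)),
        t("psbN", "CDS", "LSC", "-", (132,)),
        t("psbH", "CDS", "LSC", "+", (222,)),
        t("petB", "CDS", "LSC", "+", (6, 642), (751,)),
        t("petD", "CDS", "LSC", "+", (8, 475), (742,)),
        t("rpoA", "CDS", "LSC", "-", (1002,)),
        t("rps11", "CDS", "LSC", "-", (417,)),
        t("rpl36", "CDS", "LSC", "-", (114,)),
        t("rps8", "CDS", "LSC", "-", (405,)),
        t("rpl14", "CDS", "LSC", "-", (369,)),
        t("rpl16", "CDS", "LSC", "-", (9, 399), (1020,)),
        t("rps3", "CDS", "LSC", "-", (657,)),
        t("rpl22", "CDS", "LSC", "-", (471,)),
        t("rps19", "CDS", "LSC", "-", (279,)),      # spans 75 bp into IR_B
    ]
    rpl2 = (t("rpl2", "CDS", "IR", "-", (393, 429), (660,)) if rpl2_intron
            else t("rpl2", "CDS", "IR", "-", (822,)))
    ir = [
        rpl2,
        t("rpl23", "CDS", "IR", "-", (282,)),
        t("trnI-CAU", "tRNA", "IR", "-", (74,)),
        t("ycf2", "CDS", "IR", "+", (6828,)),
        t("trnL-CAA", "tRNA", "IR", "-", (81,)),
        t("ndhB", "CDS", "IR", "-", (775, 758), (679,)),
        t("rps7", "CDS", "IR", "-", (468,)),
        t("rps12_3p", "CDS", "IR", "-", (232, 26), (536,)),  # trans-spliced 3' exons
        t("trnV-GAC", "tRNA", "IR", "+", (72,)),
        t("rrn16", "rRNA", "IR", "+", (1491,)),
        t("trnI-GAU", "tRNA", "IR", "+", (37, 35), (945,)),
        t("trnA-UGC", "tRNA", "IR", "+", (38, 35), (800,)),
        t("rrn23", "rRNA", "IR", "+", (2810,)),
        t("rrn4.5", "rRNA", "IR", "+", (103,)),
        t("rrn5", "rRNA", "IR", "+", (121,)),
        t("trnR-ACG", "tRNA", "IR", "+", (74,)),
        t("trnN-GUU", "tRNA", "IR", "-", (72,)),
    ]
    ssc = [
        t("ycf1", "CDS", "SSC", "+", (5613,)),      # starts 20 bp inside IR_B
        t("rpl32", "CDS", "SSC", "+", (174,)),
        t("trnL-UAG", "tRNA", "SSC", "+", (80,)),
        t("ccsA", "CDS", "SSC", "+", (960,)),
        t("ndhD", "CDS", "SSC", "-", (1503,)),
        t("psaC", "CDS", "SSC", "-", (246,)),
        t("ndhE", "CDS", "SSC", "-", (306,)),
        t("ndhG", "CDS", "SSC", "-", (531,)),
        t("ndhI", "CDS", "SSC", "-", (504,)),
        t("ndhA", "CDS", "SSC", "-", (553, 539), (1082,)),
        t("ndhH", "CDS", "SSC", "-", (1182,)),
        t("rps15", "CDS", "SSC", "-", (273,)),
        t("ndhF", "CDS", "SSC", "-", (2244,)),      # ends 38 bp inside IR_A
    ]
    return {"LSC": lsc, "IR": ir, "SSC": ssc}


MATK = GeneTemplate("matK", "CDS", "LSC", "-", (1491,))
_MATK_OFFSET = 400          # offset of matK within the trnK-UUU intron
_RPS19_IR_EXT = 75
_YCF1_IR_EXT = 20
_NDHF_IR_EXT = 38
_TRNH_GAP = 3


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------

def _rand_seq(rng, n, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _feature_from_template(tpl: GeneTemplate, start: int) -> Feature:
    parts = []
    pos = start
    for i, ex in enumerate(tpl.exons):
        parts.append(CircularInterval(pos, pos + ex))
        pos += ex
        if i < len(tpl.introns):
            pos += tpl.introns[i]
    return Feature(name=tpl.name, kind=tpl.kind, strand=tpl.strand, parts=parts)


def _spread(templates, lo, hi, label):
    """Place templates sequentially in [lo, hi) with even gaps; return features."""
    total = sum(t.span for t in templates)
    free = (hi - lo) - total
    if free < 0:
        raise PlastomeError(
            f"overcrowded spec: cannot place {templates[0].name if templates else label}"
            f" (need {total} bp in {hi - lo} bp of {label})")
    gap = free // (len(templates) + 1) if templates else 0
    feats, pos = [], lo + gap
    for tpl in templates:
        feats.append(_feature_from_template(tpl, pos))
        pos += tpl.span + gap
    return feats


def _exon_mask(features, n):
    mask = np.zeros(n, dtype=bool)
    for f in features:
        for p in f.parts:
            if p.wraps():
                mask[p.start:] = True
                mask[:p.end] = True
            else:
                mask[p.start:p.end] = True
    return mask


def _free_gaps(mask, lo, hi, margin=4):
    """Maximal unoccupied intervals within [lo, hi), shrunk by margin."""
    gaps, i = [], lo
    while i < hi:
        if not mask[i]:
            j = i
            while j < hi and not mask[j]:
                j += 1
            if j - i > 2 * margin:
                gaps.append([i + margin, j - margin])
            i = j
        else:
            i += 1
    return gaps


def _take_gap(gaps, need, rng):
    order = sorted(range(len(gaps)), key=lambda g: gaps[g][1] - gaps[g][0], reverse=True)
    for gi in order:
        lo, hi = gaps[gi]
        if hi - lo >= need:
            start = lo if hi - lo == need else lo + int(rng.integers(0, hi - lo - need))
            if start - lo >= need + 2:
                gaps[gi] = [lo, start]
                gaps.append([start + need, hi])
            else:
                gaps[gi] = [start + need, hi]
            return start
    return None


def _canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def simulate_plastome(spec: PlastomeSpec):
    """Build an annotated circular plastome and its planted-truth table.

    Returns ``(AnnotatedPlastome, SimTruth)``.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    L, S, I = spec.lsc_len, spec.ssc_len, spec.ir_len
    n = spec.total_len

    features: list[Feature] = []
    if spec.gene_templates is None:
        groups = default_gene_templates(spec.rpl2_intron)
        # --- LSC: trnH pinned near origin, rps19 pinned at the IR_B border
        lsc_t = groups["LSC"]
        trnh, middle, rps19 = lsc_t[0], lsc_t[1:-1], lsc_t[-1]
        f_trnh = _feature_from_template(trnh, _TRNH_GAP)
        rps19_start = L - (rps19.span - _RPS19_IR_EXT)
        f_rps19 = _feature_from_template(rps19, rps19_start)
        feats_mid = _spread(middle, f_trnh.span().end + 10, rps19_start - 10, "LSC")
        features += [f_trnh] + feats_mid + [f_rps19]
        # matK nested inside the trnK-UUU intron
        trnk = next(f for f in feats_mid if f.name == "trnK-UUU")
        intron_start = trnk.parts[0].end
        features.append(_feature_from_template(MATK, intron_start + _MATK_OFFSET))
        # --- IR_B interior
        ir_feats = _spread(groups["IR"], L + _RPS19_IR_EXT + 40,
                           L + I - _YCF1_IR_EXT - 40, "IR_B")
        # --- SSC: ycf1 pinned at the IR_B border, ndhF at the IR_A border
        ssc_t = groups["SSC"]
        ycf1, ssc_mid, ndhf = ssc_t[0], ssc_t[1:-1], ssc_t[-1]
        f_ycf1 = _feature_from_template(ycf1, L + I - _YCF1_IR_EXT)
        ndhf_start = L + I + S + _NDHF_IR_EXT - ndhf.span
        f_ndhf = _feature_from_template(ndhf, ndhf_start)
        features += [f_ycf1] + _spread(ssc_mid, f_ycf1.span().end + 10,
                                       ndhf_start - 10, "SSC") + [f_ndhf]
        # --- assemble trans-spliced rps12 from its placed pieces
        p5 = next(f for f in features if f.name == "rps12_5p")
        p3 = next(f for f in ir_feats if f.name == "rps12_3p")
        features.remove(p5)
        ir_feats.remove(p3)
        rps12_b = Feature("rps12", "CDS", "-", p5.parts + p3.parts,
                          trans_spliced=True)
        features.append(rps12_b)
        # --- mirror IR_B features into IR_A
        base = L + I + S

        def mirror_iv(iv: CircularInterval) -> CircularInterval:
            j1, j2 = iv.start - L, iv.end - L
            return CircularInterval(base + I - j2, base + I - j1)

        flip = {"+": "-", "-": "+"}
        for f in ir_feats:
            mirrored = [mirror_iv(p) for p in reversed(f.parts)]
            features.append(Feature(f.name, f.kind, flip[f.strand], mirrored))
        features += ir_feats
        features.append(Feature("rps12", "CDS", "+",
                                p5.parts + [mirror_iv(p) for p in reversed(p3.parts)],
                                trans_spliced=True))
        # --- pseudogene fragments mirrored across the junctions
        features.append(Feature("rps19", "CDS", "+",
                                [CircularInterval(n - _RPS19_IR_EXT, n)], pseudo=True,
                                note="IR-duplicated 3' fragment"))
        features.append(Feature("ycf1", "CDS", "-",
                                [CircularInterval(base, base + _YCF1_IR_EXT)], pseudo=True,
                                note="IR-duplicated fragment"))
    else:
        by_region = {"LSC": [], "IR": [], "SSC": []}
        for tpl in spec.gene_templates:
            by_region[tpl.region].append(tpl)
        features += _spread(by_region["LSC"], 10, L - 10, "LSC")
        ir_feats = _spread(by_region["IR"], L + 10, L + I - 10, "IR_B")
        features += _spread(by_region["SSC"], L + I + 10, L + I + S - 10, "SSC")
        base = L + I + S
        flip = {"+": "-", "-": "+"}
        for f in ir_feats:
            mirrored = [CircularInterval(base + I - (p.end - L), base + I - (p.start - L))
                        for p in reversed(f.parts)]
            features.append(Feature(f.name, f.kind, flip[f.strand], mirrored))
        features += ir_feats

    # ------------------------------------------------------------------
    # sequence: background + planted repeats (written before IR_A mirroring)
    # ------------------------------------------------------------------
    seq = list(_rand_seq(rng, L + I + S, spec.gc_target))
    mask = _exon_mask(features, n)[:L + I + S]
    gaps = {
        "LSC": _free_gaps(mask, 0, L),
        "IR": _free_gaps(mask, L, L + I),
        "SSC": _free_gaps(mask, L + I, L + I + S),
    }
    truth = SimTruth(lsc=(0, L), ir_b=(L, L + I), ssc=(L + I, L + I + S),
                     ir_a=(L + I + S, n), genes=features)

    alphabet = "ACGT"

    def guard_base(*avoid):
        for b in alphabet:
            if b not in avoid:
                return b
        return "A"

    for p in spec.planted_ssrs:
        m, c = len(p.motif), p.copies
        need = m * c + 2
        start = _take_gap(gaps[p.region], need, rng)
        if start is None:
            raise PlastomeError(f"overcrowded spec: cannot place SSR {p.motif}x{c}")
        run = (p.motif * c)
        seq[start + 1:start + 1 + len(run)] = list(run)
        seq[start] = guard_base(run[m - 1])          # breaks period-m left extension
        seq[start + 1 + len(run)] = guard_base(run[(len(run) - m) % m], run[0])
        truth.ssrs.append((_canonical_rotation(p.motif), c, start + 1,
                           start + 1 + len(run), p.region))

    for p in spec.planted_tandems:
        unit = _rand_seq(rng, p.unit_len, 0.5)
        run = unit * p.copies
        start = _take_gap(gaps[p.region], len(run) + 2, rng)
        if start is None:
            raise PlastomeError(f"overcrowded spec: cannot place tandem {p.unit_len}x{p.copies}")
        seq[start + 1:start + 1 + len(run)] = list(run)
        seq[start] = guard_base(unit[-1])
        seq[start + 1 + len(run)] = guard_base(unit[0])
        truth.tandems.append((unit, p.copies, start + 1, start + 1 + len(run),
                              p.unit_len, p.region))

    for p in spec.planted_dispersed:
        chunk = _rand_seq(rng, p.length, 0.5)
        s1 = _take_gap(gaps[p.region_a], p.length + 2, rng)
        s2 = _take_gap(gaps[p.region_b], p.length + 2, rng)
        if s1 is None or s2 is None:
            raise PlastomeError(f"overcrowded spec: cannot place dispersed repeat {p}")
        if p.cls == "forward":
            other = chunk
        elif p.cls == "palindromic":
            other = reverse_complement(chunk)
        elif p.cls == "reverse":
            other = chunk[::-1]
        elif p.cls == "complement":
            other = reverse_complement(chunk)[::-1]
        else:
            raise PlastomeError(f"unknown repeat class {p.cls}")
        seq[s1 + 1:s1 + 1 + p.length] = list(chunk)
        seq[s2 + 1:s2 + 1 + p.length] = list(other)
        a, b = sorted([s1 + 1, s2 + 1])
        truth.dispersed.append((p.cls, a, b, p.length))

    # write the rpl2 survey primer sites into the rpl2 exons (IR_B copy; the
    # IR_A copy inherits them via the reverse-complement assembly) so that the
    # in-silico PCR amplicon is 750 bp across the spliced exons, and 660 bp
    # longer when the intron is present
    if spec.gene_templates is None:
        from .intron_survey import RPL2_FORWARD, RPL2_REVERSE
        rpl2_feat = next(f for f in ir_feats if f.name == "rpl2")

        def spliced_to_genomic(o):
            for p in rpl2_feat.parts:
                w = p.end - p.start
                if o < w:
                    return p.start + o
                o -= w
            raise PlastomeError("rpl2 too short for primer placement")

        fpos = spliced_to_genomic(50)
        rpos = spliced_to_genomic(780)
        seq[fpos:fpos + 20] = list(RPL2_FORWARD)
        seq[rpos:rpos + 20] = list(reverse_complement(RPL2_REVERSE))
        truth.rpl2_amplicon = 750 + sum(
            iv.length(n) for iv in rpl2_feat.intron_intervals(n))

    body = "".join(seq)
    genome_seq = body + reverse_complement(body[L:L + I])
    glist = list(genome_seq)
    # guard bases so exact IR extension stops exactly at the planted borders
    glist[0] = "A"
    glist[L - 1] = "A"
    glist[L + I] = "A"
    glist[L + I + S - 1] = "A"
    genome = AnnotatedPlastome(spec.label, "".join(glist), circular=True,
                               features=sorted(features, key=lambda f: f.parts[0].start))
    truth.genes = genome.features
    return genome, truth


# ---------------------------------------------------------------------------
# Structural edits
# ---------------------------------------------------------------------------

def apply_inversion(genome: AnnotatedPlastome, start: int, end: int) -> AnnotatedPlastome:
    """Reverse-complement genome[start:end) (features inside are dropped)."""
    seq = (genome.sequence[:start]
           + reverse_complement(genome.sequence[start:end])
           + genome.sequence[end:])
    kept = [f for f in genome.features
            if f.span().end <= start or f.span().start >= end]
    return AnnotatedPlastome(genome.id + "_inv", seq, genome.circular, kept)


def delete_interval(genome: AnnotatedPlastome, start: int, end: int,
                    marks: list | None = None) -> AnnotatedPlastome:
    """Delete genome[start:end) and shift/truncate feature coordinates.

    ``marks`` is an optional flat list of tracked positions updated in place
    (used to carry IR boundaries through edits).
    """
    d = end - start
    if d <= 0:
        return genome
    seq = genome.sequence[:start] + genome.sequence[end:]

    def map_pos(p):
        if p <= start:
            return p
        if p >= end:
            return p - d
        return start

    if marks is not None:
        marks[:] = [map_pos(p) for p in marks]
    feats = []
    for f in genome.features:
        parts = []
        for p in f.parts:
            s, e = map_pos(p.start), map_pos(p.end)
            if e > s:
                parts.append(CircularInterval(s, e))
        if parts:
            feats.append(replace(f, parts=parts))
    return AnnotatedPlastome(genome.id, seq, genome.circular, feats)


def _delete_gene_introns(genome: AnnotatedPlastome, gene: str,
                         marks: list | None = None) -> AnnotatedPlastome:
    """Precisely excise every cis intron of every copy of ``gene``."""
    targets = []
    for f in genome.features:
        if f.name == gene and not f.pseudo:
            targets += [(iv.start, iv.end) for iv in f.intron_intervals(len(genome))]
    if not targets:
        raise PlastomeError(f"intron loss requested but {gene} has no intron")
    for s, e in sorted(set(targets), reverse=True):
        genome = delete_interval(genome, s, e, marks)
    # merge now-adjacent exons of the target gene
    for f in genome.features:
        if f.name == gene and len(f.parts) > 1 and not f.trans_spliced:
            merged = [f.parts[0]]
            for p in f.parts[1:]:
                if p.start == merged[-1].end:
                    merged[-1] = CircularInterval(merged[-1].start, p.end)
                else:
                    merged.append(p)
            f.parts = merged
    return genome


# ---------------------------------------------------------------------------
# Evolution along a tree
# ---------------------------------------------------------------------------

def jc_expected_difference(t: float) -> float:
    """Jukes-Cantor expected fraction of differing sites after branch length t."""
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))


_CODE = {b: i for i, b in enumerate("ACGT")}


def _mutate(seq: str, t: float, rng) -> str:
    if t <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    p = jc_expected_difference(t)
    hit = np.nonzero(rng.random(arr.size) < p)[0]
    if hit.size:
        # replace by one of the three other bases, uniformly
        cur = np.searchsorted(_BASES, 0)  # placeholder; map bytes -> 0..3
        idx = np.zeros(256, dtype=np.int8)
        for b, i in _CODE.items():
            idx[ord(b)] = i
        cur = idx[arr[hit]]
        step = rng.integers(1, 4, size=hit.size)
        arr[hit] = _BASES[(cur + step) % 4]
    return arr.tobytes().decode()


def _intergenic_positions(genome: AnnotatedPlastome) -> np.ndarray:
    mask = _exon_mask(genome.features, len(genome))
    # introns also excluded: indels there would disturb intron-length truth
    for f in genome.features:
        for iv in f.intron_intervals(len(genome)):
            if not iv.wraps():
                mask[iv.start:iv.end] = True
    return np.nonzero(~mask)[0]


def _apply_indels(genome: AnnotatedPlastome, t: float, rate: float, rng,
                  marks: list | None = None):
    """Small (1-5 bp) indels in single-copy intergenic DNA only: genic truth
    stays exact and the inverted repeats keep their planted boundaries."""
    if rate <= 0 or t <= 0:
        return genome

    def candidate_sites():
        sites = _intergenic_positions(genome)
        if marks:
            irb_s, irb_e, ira_s, ira_e = marks
            keep = ~(((sites >= irb_s) & (sites < irb_e))
                     | ((sites >= ira_s) & (sites < ira_e)))
            sites = sites[keep]
        return sites

    n_events = rng.poisson(rate * t * candidate_sites().size)
    for _ in range(n_events):
        sites = candidate_sites()
        if sites.size == 0:
            break
        pos = int(sites[int(rng.integers(0, sites.size))])
        size = int(rng.integers(1, 6))
        if rng.random() < 0.5:
            genome = delete_interval(genome, pos, min(pos + size, len(genome)), marks)
        else:
            ins = _rand_seq(rng, size, 0.38)
            seq = genome.sequence[:pos] + ins + genome.sequence[pos:]
            feats = []
            for f in genome.features:
                parts = [CircularInterval(p.start + size if p.start >= pos else p.start,
                                          p.end + size if p.end > pos else p.end)
                         for p in f.parts]
                feats.append(replace(f, parts=parts))
            if marks is not None:
                marks[:] = [p + size if p >= pos else p for p in marks]
            genome = AnnotatedPlastome(genome.id, seq, genome.circular, feats)
    return genome


def evolve_along_tree(root: AnnotatedPlastome, espec: EvolutionSpec):
    """Evolve the root genome along a tree; returns {leaf name: genome}.

    Substitutions are Jukes-Cantor per branch (per-site difference probability
    3/4 (1 - e^(-4t/3))); annotations are carried through unchanged except at
    intergenic indels.  If ``intron_loss_clade`` names a set of leaves, the cis
    intron(s) of ``intron_loss_gene`` are excised once on that clade's stem
    branch and inherited by all its descendants.

    The inverted repeats evolve concertedly: mutations arise on the IR_B copy
    and are copy-corrected into IR_A (real plastid IRs are homogenised by gene
    conversion, which is what keeps the two copies near-identical), and indels
    are restricted to single-copy intergenic DNA.
    """
    from .structure import QuadripartiteMap, detect_inverted_repeat
    tree = dendropy.Tree.get(data=espec.tree, schema="newick")
    rng = np.random.default_rng(espec.seed)
    _, qmap0 = detect_inverted_repeat(root, rotate=False)
    root_marks = None
    if isinstance(qmap0, QuadripartiteMap):
        n0 = len(root)

        def linear(iv):
            s, e = iv.start, iv.end
            if e <= s:
                e += n0
            return (s, e) if e <= n0 else None  # None: wraps the origin

        lb, la = linear(qmap0.ir_b), linear(qmap0.ir_a)
        if lb and la:
            root_marks = [lb[0], lb[1], la[0], la[1]]
    loss_set = frozenset(espec.intron_loss_clade)
    if loss_set:
        present = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if not loss_set <= present:
            raise PlastomeError(f"intron_loss_clade {sorted(loss_set)} not in tree")
        if not any(f.name == espec.intron_loss_gene and f.n_introns(len(root))
                   for f in root.features):
            raise PlastomeError(
                f"intron loss requested but {espec.intron_loss_gene} has no intron in root")

    out: dict[str, AnnotatedPlastome] = {}

    def leafset(node):
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def mirror_ir(g: AnnotatedPlastome, marks):
        if marks is None:
            return g
        irb_s, irb_e, ira_s, ira_e = marks
        assert irb_e - irb_s == ira_e - ira_s
        seq = (g.sequence[:ira_s]
               + reverse_complement(g.sequence[irb_s:irb_e])
               + g.sequence[ira_e:])
        return AnnotatedPlastome(g.id, seq, g.circular, g.features)

    def walk(node, genome, marks):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_marks = list(marks) if marks is not None else None
            g = AnnotatedPlastome(genome.id, _mutate(genome.sequence, t, rng),
                                  genome.circular,
                                  [replace(f, parts=list(f.parts)) for f in genome.features])
            g = _apply_indels(g, t, espec.indel_rate, rng, child_marks)
            if loss_set and leafset(child) == loss_set:
                g = _delete_gene_introns(g, espec.intron_loss_gene, child_marks)
            g = mirror_ir(g, child_marks)
            if child.is_leaf():
                g.id = child.taxon.label
                out[child.taxon.label] = g
            else:
                walk(child, g, child_marks)

    walk(tree.seed_node, root, root_marks)
    return out


DEFAULT_TREE7 = "((Ona:0.04,(LagA:0.015,LagB:0.015):0.03):0.02,(MyrA:0.015,(MyrB:0.012,(MyrC:0.008,MyrD:0.008):0.006):0.008):0.02):0.0;"


def myrtales7(seed: int = 42, indel_rate: float = 0.0001,
              spec: PlastomeSpec | None = None):
    """Seven-taxon study preset: root plastome with the rpl2 intron present,
    intron loss planted on the (LagA, LagB) stem branch."""
    spec = spec or PlastomeSpec(seed=seed, rpl2_intron=True, label="root")
    root, truth = simulate_plastome(spec)
    espec = EvolutionSpec(tree=DEFAULT_TREE7,
                          intron_loss_clade=("LagA", "LagB"),
                          intron_loss_gene="rpl2",
                          indel_rate=indel_rate, seed=seed + 1)
    genomes = evolve_along_tree(root, espec)
    return root, truth, genomes
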