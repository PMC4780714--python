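"""Marker screening: shared-region extraction, alignment, site classes, PIC%, RI.

For a set of annotated plastomes, every shared CDS, intron and intergenic
spacer (>= 200 bp in the reference) is extracted and aligned; per-region
statistics count conserved / variable / parsimony-informative columns and the
ensemble retention index RI = (G - S) / (G - M), where S is the Fitch tree
length, M = sum of per-column minimum steps (observed states - 1) and G = sum
of per-column maximum steps (non-missing rows minus the largest state class).
Long regions (> 1,500 bp) are additionally screened in 1,000 bp windows at
500 bp increments.  Gaps and N are treated as missing throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .plastome_io import AnnotatedPlastome, PlastomeError
from .parsimony import (PhyloTree, encode_alignment, fitch_column_steps,
                        fitch_steps, mp_search)

log = logging.getLogger(__name__)

_GENE_KINDS = {"CDS", "tRNA", "rRNA"}


@dataclass
class Region:
    name: str
    region_class: str        # CDS | intron | IGS
    sequences: dict          # species -> unaligned sequence
    reference_length: int


@dataclass
class RegionAlignment:
    region_name: str
    region_class: str
    sequences: dict          # species -> gapped rows of equal length
    aligned_length: int
    source: str = "internal_aligner"


@dataclass
class VariabilityStats:
    region_name: str
    region_class: str
    length_in_reference: int
    aligned_length: int
    conserved_sites: int
    variable_sites: int
    parsimony_informative: int
    singletons: int
    pic_percent: float
    retention_index: float
    ri_defined: bool = True
    tree_newick: str = ""


@dataclass(frozen=True)
class WindowSpec:
    window: int = 1000
    step: int = 500
    min_region: int = 1500   # windows only for regions longer than this


# ---------------------------------------------------------------------------
# Shared-region extraction
# ---------------------------------------------------------------------------

def _unique_gene_map(genome: AnnotatedPlastome):
    """First non-pseudo copy of each gene name, in genomic order."""
    out: dict[str, object] = {}
    for f in genome.sorted_features():
        if f.pseudo or f.kind not in _GENE_KINDS:
            continue
        out.setdefault(f.name, f)
    return out


def _spliced(genome: AnnotatedPlastome, feat) -> str:
    n = len(genome)
    chunks = [genome.extract(p) for p in feat.parts]
    seq = "".join(chunks)
    if feat.strand == "-":
        from .plastome_io import reverse_complement
        seq = reverse_complement(seq)
    return seq


def extract_shared_regions(genomes: dict[str, AnnotatedPlastome],
                           min_len: int = 200):
    """Shared CDS / intron / IGS regions across >= 2 annotated genomes.

    Gene regions use the spliced exon sequence of the first (non-pseudo) copy;
    introns are matched by index within each shared gene; intergenic spacers
    are named by their flanking gene pair and require the two genes to be
    adjacent in every genome.  Regions shorter than ``min_len`` in the first
    (reference) genome are dropped.
    """
    if len(genomes) < 2:
        raise PlastomeError("need >= 2 genomes")
    names = list(genomes)
    ref = names[0]
    maps = {sp: _unique_gene_map(genomes[sp]) for sp in names}
    shared = set(maps[ref])
    for sp in names[1:]:
        shared &= set(maps[sp])
    if not shared:
        raise PlastomeError("genomes share no gene names")

    regions: list[Region] = []
    for gene in sorted(shared, key=lambda g: maps[ref][g].parts[0].start):
        seqs = {sp: _spliced(genomes[sp], maps[sp][gene]) for sp in names}
        if len(seqs[ref]) >= min_len:
            kind = maps[ref][gene].kind
            regions.append(Region(gene, "CDS" if kind == "CDS" else kind,
                                  seqs, len(seqs[ref])))
        n_introns = min(len(maps[sp][gene].intron_intervals(len(genomes[sp])))
                        for sp in names)
        for i in range(n_introns):
            iseqs = {}
            for sp in names:
                iv = maps[sp][gene].intron_intervals(len(genomes[sp]))[i]
                iseqs[sp] = genomes[sp].extract(iv)
            if len(iseqs[ref]) >= min_len:
                suffix = f".intron{i + 1}" if n_introns > 1 else ".intron"
                regions.append(Region(gene + suffix, "intron", iseqs,
                                      len(iseqs[ref])))

    # intergenic spacers between genes adjacent in every genome
    ref_order = sorted(shared, key=lambda g: maps[ref][g].parts[0].start)
    for a, b in zip(ref_order, ref_order[1:]):
        seqs = {}
        ok = True
        for sp in names:
            fa, fb = maps[sp][a], maps[sp][b]
            s, e = fa.span().end, fb.span().start
            if e <= s:
                ok = False
                break
            between = [g for g, f in maps[sp].items()
                       if g not in (a, b) and s <= f.parts[0].start < e]
            if between:
                ok = False
                break
            seqs[sp] = genomes[sp].sequence[s:e]
        if ok and len(seqs[ref]) >= min_len:
            regions.append(Region(f"{a}-{b}", "IGS", seqs, len(seqs[ref])))
    return regions


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

def _profile(rows: list[str]) -> np.ndarray:
    """(L, 4) base-frequency profile over non-gap characters."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(rows[0])
    prof = np.zeros((L, 4))
    for r in rows:
        for j, ch in enumerate(r):
            k = idx.get(ch)
            if k is not None:
                prof[j, k] += 1
    tot = prof.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1
    return prof / tot


def _profile_align(rows_a: list[str], rows_b: list[str],
                   gap_open: float = 10.0, gap_ext: float = 0.5):
    """Global profile-profile alignment (match 1, mismatch 0, affine gaps)."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    NEG = -1e9
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)   # gap in B (consumes A rows)
    Y = np.full((la + 1, lb + 1), NEG)   # gap in A
    M[0, 0] = 0.0
    X[1:, 0] = -gap_open - gap_ext * np.arange(la)
    Y[0, 1:] = -gap_open - gap_ext * np.arange(lb)
    S = pa @ pb.T                        # column-pair scores
    for i in range(1, la + 1):
        X[i, :] = np.maximum(M[i - 1, :] - gap_open, X[i - 1, :] - gap_ext)
        diag = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = diag + S[i - 1, :]
        # Y along the row: running-max formulation of the affine recurrence
        base = np.maximum(M[i, :-1], X[i, :-1]) + gap_ext * np.arange(lb)
        run = np.maximum.accumulate(base)
        Y[i, 1:] = run - gap_open - gap_ext * np.arange(1, lb + 1) + gap_ext
    # traceback
    out_a, out_b = [], []
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a.append(i - 1)
            out_b.append(j - 1)
            prev = np.array([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]])
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 or j == 0:
            out_a.append(i - 1)
            out_b.append(None)
            take_m = M[i - 1, j] - gap_open
            take_x = X[i - 1, j] - gap_ext
            i -= 1
            state = 0 if take_m >= take_x else 1
            if j == 0 and i == 0:
                break
        else:
            out_a.append(None)
            out_b.append(j - 1)
            take = np.array([M[i, j - 1] - gap_open, X[i, j - 1] - gap_open,
                             Y[i, j - 1] - gap_ext])
            j -= 1
            state = int(np.argmax(take))
    out_a.reverse()
    out_b.reverse()
    merged_a = ["".join(r[k] if k is not None else "-" for k in out_a)
                for r in rows_a]
    merged_b = ["".join(r[k] if k is not None else "-" for k in out_b)
                for r in rows_b]
    return merged_a + merged_b


def _pdistance(a: str, b: str) -> float:
    rows = _profile_align([a], [b])
    diff = tot = 0
    for x, y in zip(rows[0], rows[1]):
        if x in "ACGT" and y in "ACGT":
            tot += 1
            diff += x != y
    return diff / tot if tot else 1.0


def align_region(sequences: dict[str, str], region_name: str = "",
                 region_class: str = "?") -> RegionAlignment:
    """Progressive alignment (pairwise distances -> UPGMA guide tree -> profile
    merges).  Pre-aligned input (rows of equal length containing gaps) is
    passed through verbatim."""
    names = list(sequences)
    seqs = [sequences[sp].upper() for sp in names]
    if len(seqs) < 2:
        raise PlastomeError("need >= 2 sequences")
    lens = [len(s) for s in seqs]
    if any("-" in s for s in seqs):
        if len(set(lens)) != 1:
            raise PlastomeError("gapped input rows differ in length")
        return RegionAlignment(region_name, region_class, dict(sequences),
                               lens[0], source="external_file")
    if len(set(lens)) == 1:
        # equal-length ungapped input: positions are taken as homologous (the
        # gapless alignment; with affine gap open 10 vs match 1 any gap pair
        # is dominated unless a shift realigns >21 columns, which point
        # substitutions alone never produce)
        return RegionAlignment(region_name, region_class,
                               {sp: s.upper() for sp, s in sequences.items()},
                               lens[0])
    if max(lens) > 3 * min(lens):
        log.warning("region %s: sequence lengths differ more than 3-fold", region_name)

    k = len(seqs)
    if k == 2:
        rows = _profile_align([seqs[0]], [seqs[1]])
        order = [0, 1]
    else:
        D = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                D[i, j] = D[j, i] = _pdistance(seqs[i], seqs[j])
        # UPGMA joins
        clusters = {i: ([i], [seqs[i]]) for i in range(k)}
        dist = {(i, j): D[i, j] for i in range(k) for j in range(i + 1, k)}
        nxt = k
        while len(clusters) > 1:
            (a, b) = min(dist, key=dist.get)
            mem_a, rows_a = clusters.pop(a)
            mem_b, rows_b = clusters.pop(b)
            merged = _profile_align(rows_a, rows_b)
            na, nb = len(mem_a), len(mem_b)
            new_members = mem_a + mem_b
            for key in [key for key in dist if a in key or b in key]:
                del dist[key]
            for c, (mem_c, _) in clusters.items():
                dc = np.mean([D[x, y] for x in new_members for y in mem_c])
                dist[(min(c, nxt), max(c, nxt))] = dc
            clusters[nxt] = (new_members, merged)
            nxt += 1
        order, rows = clusters.popitem()[1]
    aligned = {names[idx]: rows[pos] for pos, idx in enumerate(order)}
    return RegionAlignment(region_name, region_class, aligned, len(rows[0]))


# ---------------------------------------------------------------------------
# Site statistics
# ---------------------------------------------------------------------------

def site_classes(alignment: dict[str, str] | RegionAlignment):
    """(conserved, variable, parsimony_informative, singleton) column counts.

    Gaps/N are missing; a column is conserved when exactly one state occurs
    among non-missing rows, parsimony-informative when >= 2 states each occur
    in >= 2 rows; entirely-missing columns are unscored.
    """
    aln = alignment.sequences if isinstance(alignment, RegionAlignment) else alignment
    if len(aln) < 3:
        raise PlastomeError("site statistics require >= 3 rows")
    rows = list(aln.values())
    L = len(rows[0])
    conserved = variable = informative = singleton = 0
    for j in range(L):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[j]
            if ch in "ACGT":
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            continue
        if len(counts) == 1:
            conserved += 1
        else:
            variable += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                informative += 1
            else:
                singleton += 1
    return conserved, variable, informative, singleton


def pic_percent(informative: int, aligned_length: int) -> float:
    """Percentage of parsimony-informative columns, to 2 decimals."""
    if aligned_length <= 0:
        raise PlastomeError("aligned length must be positive")
    return round(100.0 * informative / aligned_length, 2)


def _column_bounds(alignment: dict[str, str]):
    """Per-column (m, g): minimum and maximum (star-tree) possible steps."""
    rows = list(alignment.values())
    L = len(rows[0])
    m = np.zeros(L, dtype=np.int64)
    g = np.zeros(L, dtype=np.int64)
    for j in range(L):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[j]
            if ch in "ACGT":
                counts[ch] = counts.get(ch, 0) + 1
        if counts:
            m[j] = len(counts) - 1
            g[j] = sum(counts.values()) - max(counts.values())
    return m, g


def retention_index(tree: PhyloTree, alignment: dict[str, str] | RegionAlignment):
    """Ensemble retention index (G - S) / (G - M) on the given tree.

    Returns ``(ri, defined)``; when G == M (no potentially homoplastic
    variation) the RI is undefined and reported as 1.0 with ``defined=False``.
    """
    aln = alignment.sequences if isinstance(alignment, RegionAlignment) else alignment
    m, g = _column_bounds(aln)
    s = fitch_column_steps(tree, aln)
    G, M, S = int(g.sum()), int(m.sum()), int(s.sum())
    if G == M:
        return 1.0, False
    return (G - S) / (G - M), True


def sliding_windows(region_length: int, spec: WindowSpec | None = None):
    """Window (start, end) pairs; none for regions at or below the threshold.

    The final window is truncated at the region end and terminates the grid.
    """
    spec = spec or WindowSpec()
    if spec.step > spec.window:
        raise PlastomeError("step must be <= window")
    if region_length <= spec.min_region:
        return []
    out = []
    start = 0
    while True:
        end = start + spec.window
        if end >= region_length:
            out.append((start, region_length))
            break
        out.append((start, end))
        start += spec.step
    return out


# ---------------------------------------------------------------------------
# Scoring and ranking
# ---------------------------------------------------------------------------

def score_region(alignment: RegionAlignment, reference_length: int,
                 tree: PhyloTree | None = None, search_seed: int = 0) -> VariabilityStats:
    """Full per-region statistics; the RI tree defaults to the region's own
    maximum-parsimony tree (recorded in the output for reproducibility)."""
    cons, var, inf, sing = site_classes(alignment)
    if tree is None:
        tree = mp_search(alignment.sequences, seed=search_seed).best_trees[0]
    ri, defined = retention_index(tree, alignment)
    return VariabilityStats(
        region_name=alignment.region_name, region_class=alignment.region_class,
        length_in_reference=reference_length, aligned_length=alignment.aligned_length,
        conserved_sites=cons, variable_sites=var, parsimony_informative=inf,
        singletons=sing, pic_percent=pic_percent(inf, alignment.aligned_length),
        retention_index=round(ri, 2), ri_defined=defined,
        tree_newick=tree.newick())


def rank_regions(stats: list[VariabilityStats], k: int = 10):
    """Top-k coding and non-coding tables, ranked by PIC%; ties broken by
    aligned length (longer first) then name."""
    def top(rows):
        rows = sorted(rows, key=lambda s: (-s.pic_percent, -s.aligned_length,
                                           s.region_name))
        if len(rows) < k:
            log.warning("only %d regions available (k=%d)", len(rows), k)
        return rows[:k]

    coding = [s for s in stats if s.region_class == "CDS"]
    noncoding = [s for s in stats if s.region_class != "CDS"]
    return top(coding), top(noncoding)


def screen_genomes(genomes: dict[str, AnnotatedPlastome], min_len: int = 200,
                   window_spec: WindowSpec | None = None, k: int = 10,
                   seed: int = 0):
    """End-to-end screen: extract shared regions, align, score, window, rank.

    Returns ``(all_stats, window_stats, top_coding, top_noncoding)``.
    """
    regions = extract_shared_regions(genomes, min_len=min_len)
    stats: list[VariabilityStats] = []
    window_stats: list[VariabilityStats] = []
    for reg in regions:
        aln = align_region(reg.sequences, reg.name, reg.region_class)
        st = score_region(aln, reg.reference_length, search_seed=seed)
        stats.append(st)
        for (ws, we) in sliding_windows(aln.aligned_length, window_spec):
            sub = RegionAlignment(f"{reg.name}[{ws}:{we}]", reg.region_class,
                                  {sp: s[ws:we] for sp, s in aln.sequences.items()},
                                  we - ws, aln.source)
            window_stats.append(score_region(sub, we - ws, search_seed=seed))
    top_c, top_n = rank_regions(stats, k=k)
    return stats, window_stats, top_c, top_n
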