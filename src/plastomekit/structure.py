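"""Quadripartite structure: inverted-repeat detection, junction report, dot-plots.

The canonical plastome layout is LSC + IR_B + SSC + IR_A where the two IRs are
exact reverse complements of one another.  Detection is by exact matching:
seed k-mers shared between the genome and its reverse complement lie on a
common anti-diagonal (positions a, b with a + b constant modulo the genome
length), and maximal runs along that anti-diagonal are exactly the candidate
IR pairs.  The longest disjoint pair wins; the two gaps between the copies are
labelled LSC (longer) and SSC (shorter) and the genome is rotated so the LSC
starts at position 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from .plastome_io import (AnnotatedPlastome, CircularInterval, PlastomeError,
                          reverse_complement)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class QuadripartiteMap:
    """LSC/SSC/IR intervals plus the four junction positions.

    Junction positions are the 0-based coordinate of the first base of the
    downstream region, reading LSC -> IR_B -> SSC -> IR_A around the circle:
    ``j_lb`` = LSC|IR_B, ``j_sb`` = IR_B|SSC, ``j_sa`` = SSC|IR_A,
    ``j_la`` = IR_A|LSC (the origin after rotation).
    """

    lsc: CircularInterval
    ir_b: CircularInterval
    ssc: CircularInterval
    ir_a: CircularInterval
    genome_length: int

    @property
    def j_lb(self) -> int:
        return self.lsc.end

    @property
    def j_sb(self) -> int:
        return self.ssc.start

    @property
    def j_sa(self) -> int:
        return self.ssc.end

    @property
    def j_la(self) -> int:
        return self.ir_a.end % self.genome_length

    @property
    def ir_length(self) -> int:
        return self.ir_a.length(self.genome_length)

    def junctions(self):
        """(name, position, upstream region, downstream region) for all four."""
        return [
            ("J_LB", self.j_lb, "LSC", "IR_B"),
            ("J_SB", self.j_sb, "IR_B", "SSC"),
            ("J_SA", self.j_sa, "SSC", "IR_A"),
            ("J_LA", self.j_la, "IR_A", "LSC"),
        ]

    def region_of(self, pos: int) -> str:
        for name, iv in (("LSC", self.lsc), ("IR_B", self.ir_b),
                         ("SSC", self.ssc), ("IR_A", self.ir_a)):
            if iv.contains(pos, self.genome_length):
                return name
        raise PlastomeError(f"position {pos} outside genome")


@dataclass(frozen=True)
class NoIRResult:
    """Structured outcome for plastomes lacking a large inverted repeat."""

    reason: str = "no inverted repeat at or above min_ir_len"


def _char(seq: str, i: int) -> str:
    return seq[i % len(seq)]


def _antidiagonal_run(seq: str, c: int, a0: int):
    """Maximal circular run through a0 on anti-diagonal c.

    Positions a with seq[a] == complement(seq[(c - a) mod n]) form the run.
    Returns (lo, hi) inclusive in unwrapped coordinates around a0, or None.
    """
    n = len(seq)

    def ok(a: int) -> bool:
        x = seq[a % n]
        y = seq[(c - a) % n]
        return _COMP.get(x) == y

    if not ok(a0):
        return None
    lo = a0
    while lo - 1 > a0 - n and ok(lo - 1):
        lo -= 1
    hi = a0
    while hi + 1 < lo + n and ok(hi + 1):
        hi += 1
    return lo, hi


def detect_inverted_repeat(genome: AnnotatedPlastome, min_ir_len: int = 10_000,
                           k: int = 20, rotate: bool = True):
    """Find the maximal IR pair and partition the genome.

    Returns ``(rotated_genome, QuadripartiteMap)`` with the LSC starting at
    position 0, or ``(genome, NoIRResult)`` when no reverse-complement pair of
    disjoint intervals of length >= ``min_ir_len`` exists.  With
    ``rotate=False`` the genome is returned unrotated and the map uses the
    deposited coordinates.
    """
    seq = genome.sequence
    n = len(seq)
    if min_ir_len < k:
        k = max(4, min_ir_len // 2)
    if 2 * min_ir_len >= n:
        return genome, NoIRResult("genome shorter than twice min_ir_len")

    rc = reverse_complement(seq)
    index: dict[str, list[int]] = {}
    for p in range(n - k + 1):
        index.setdefault(rc[p:p + k], []).append(p)

    stride = max(1, min_ir_len - k)  # any interval >= min_ir_len holds a probe
    seen_runs: set[tuple[int, int]] = set()
    candidates = []  # (length, iv1, iv2)
    probes = list(range(0, n, stride))
    for x in probes:
        kmer = (seq + seq[:k])[x:x + k]
        for p in index.get(kmer, ()):
            # S[x+i] == rc[p+i] == complement(S[n-1-p-i]) -> anti-diagonal
            c = (x + (n - 1 - p)) % n
            run = _antidiagonal_run(seq, c, x)
            if run is None:
                continue
            lo, hi = run
            length_run = hi - lo + 1
            key = (c, lo % n)
            if key in seen_runs:
                continue
            seen_runs.add(key)
            if length_run >= n:  # whole genome self-complementary (degenerate)
                continue
            iv1 = (lo % n, (hi + 1) % n)
            b_lo = (c - hi) % n
            b_hi = (c - lo) % n
            iv2 = (b_lo, (b_hi + 1) % n)
            if iv1 == iv2:
                continue  # self-palindrome, not an IR pair
            if length_run < min_ir_len:
                continue
            # require disjoint copies on the circle
            i1 = CircularInterval(*iv1)
            i2 = CircularInterval(*iv2)
            if _circular_overlap(i1, i2, n):
                continue
            pair = tuple(sorted([iv1, iv2]))
            candidates.append((length_run, pair))

    if not candidates:
        return genome, NoIRResult()

    best_len = max(c[0] for c in candidates)
    best_pairs = {pair for length, pair in candidates if length == best_len}
    if len(best_pairs) > 1:
        raise PlastomeError(
            f"ambiguous IR detection: {len(best_pairs)} maximal candidate pairs "
            f"of length {best_len}: {sorted(best_pairs)}")
    (a_iv, b_iv) = next(iter(best_pairs))
    i1, i2 = CircularInterval(*a_iv), CircularInterval(*b_iv)

    # gaps between the copies, walking the circle from i1.end to i2.start etc.
    gap1 = CircularInterval(i1.end, i2.start)
    gap2 = CircularInterval(i2.end, i1.start)
    len1 = gap1.length(n) if gap1.start != gap1.end else 0
    len2 = gap2.length(n) if gap2.start != gap2.end else 0
    if len1 == 0 or len2 == 0:
        return genome, NoIRResult("IR copies are adjacent; no single-copy regions")
    if len1 >= len2:
        lsc, ssc = gap1, gap2
        ir_b, ir_a = i2, i1  # order LSC -> ir after lsc -> SSC -> other ir
    else:
        lsc, ssc = gap2, gap1
        ir_b, ir_a = i1, i2

    if not rotate:
        return genome, QuadripartiteMap(lsc=lsc, ir_b=ir_b, ssc=ssc, ir_a=ir_a,
                                        genome_length=n)
    rotated = genome.rotate(lsc.start)
    off = lsc.start
    qmap = QuadripartiteMap(
        lsc=lsc.shifted(off, n), ir_b=ir_b.shifted(off, n),
        ssc=ssc.shifted(off, n), ir_a=ir_a.shifted(off, n), genome_length=n)
    return rotated, qmap


def _circular_overlap(a: CircularInterval, b: CircularInterval, n: int) -> bool:
    segs = []
    for iv in (a, b):
        if iv.wraps():
            segs_iv = [(iv.start, n), (0, iv.end)]
        else:
            segs_iv = [(iv.start, iv.end)]
        segs.append(segs_iv)
    for s1, e1 in segs[0]:
        for s2, e2 in segs[1]:
            if s1 < e2 and s2 < e1:
                return True
    return False


# ---------------------------------------------------------------------------
# Junction report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionEvent:
    gene: str
    junction: str          # J_LA / J_LB / J_SA / J_SB
    border: str            # explicit flanking pair, e.g. "LSC|IR_B"
    relation: str          # "spans" or "inside_distance"
    extension_bp: int | None  # bases on the IR side of the border (spans)
    gap_bp: int | None        # distance from gene end to the border otherwise
    side: str              # region the (non-spanning) gene lies in
    pseudo: bool = False


def _overlap_len_with_region(f, iv: CircularInterval, n: int) -> int:
    total = 0
    for part in f.parts:
        for pos in part.positions(n):
            if iv.contains(pos, n):
                total += 1
    return total


def junction_report(genome: AnnotatedPlastome, qmap: QuadripartiteMap):
    """For each junction, the spanning gene (if any) and nearest flanking genes.

    For a gene spanning a single-copy/IR border, ``extension_bp`` is the part
    of the gene lying inside the IR.  Truncated IR-duplicated fragments carry
    ``pseudo=True`` (annotated pseudogenes, or name-duplicates much shorter
    than their longest copy).
    """
    if not genome.features:
        raise PlastomeError("junction_report requires an annotated genome")
    n = len(genome)
    regions = {"LSC": qmap.lsc, "IR_B": qmap.ir_b, "SSC": qmap.ssc, "IR_A": qmap.ir_a}
    by_name_maxlen: dict[str, int] = {}
    for f in genome.features:
        by_name_maxlen[f.name] = max(by_name_maxlen.get(f.name, 0), f.length(n))

    events: list[JunctionEvent] = []
    for jname, pos, up, down in qmap.junctions():
        near_up = None   # (gap, feature)
        near_down = None
        for f in genome.features:
            span = f.span()
            is_pseudo = f.pseudo or f.length(n) < 0.9 * by_name_maxlen[f.name]
            if span.contains(pos, n) and span.contains((pos - 1) % n, n):
                ir_side = up if up.startswith("IR") else down
                ext = _overlap_len_with_region(f, regions[ir_side], n)
                events.append(JunctionEvent(
                    gene=f.name, junction=jname, border=f"{up}|{down}",
                    relation="spans", extension_bp=ext, gap_bp=None,
                    side=ir_side, pseudo=is_pseudo))
                continue
            gap_before = (pos - span.end) % n    # gene upstream of junction
            gap_after = (span.start - pos) % n   # gene downstream of junction
            if near_up is None or gap_before < near_up[0]:
                near_up = (gap_before, f, is_pseudo)
            if near_down is None or gap_after < near_down[0]:
                near_down = (gap_after, f, is_pseudo)
        for item, side in ((near_up, up), (near_down, down)):
            if item is None:
                continue
            gap, f, is_pseudo = item
            events.append(JunctionEvent(
                gene=f.name, junction=jname, border=f"{up}|{down}",
                relation="inside_distance", extension_bp=None, gap_bp=gap,
                side=side, pseudo=is_pseudo))
    return events


# ---------------------------------------------------------------------------
# Dot-plot
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DotplotMatch:
    x: int
    y: int
    length: int
    orientation: str  # "forward" | "inverted"


def dotplot(genome_a, genome_b, k: int = 20, merge_gap: int = 2):
    """Shared k-mers of two genomes in both orientations, merged into segments.

    Forward matches lie on diagonals (y - x constant); inverted matches (k-mer
    equal to the reverse complement) lie on anti-diagonals (y + x constant).
    Collinear matches separated by at most ``merge_gap`` are merged.
    """
    sa = genome_a.sequence if hasattr(genome_a, "sequence") else genome_a
    sb = genome_b.sequence if hasattr(genome_b, "sequence") else genome_b
    if k < 8:
        raise PlastomeError("dotplot k must be >= 8")
    if k > min(len(sa), len(sb)):
        raise PlastomeError("k exceeds sequence length")

    index: dict[str, list[int]] = {}
    for j in range(len(sb) - k + 1):
        index.setdefault(sb[j:j + k], []).append(j)

    fwd: dict[int, list[int]] = {}   # diagonal -> x starts
    inv: dict[int, list[int]] = {}   # anti-diagonal (x + y) -> x starts
    for i in range(len(sa) - k + 1):
        kmer = sa[i:i + k]
        for j in index.get(kmer, ()):
            fwd.setdefault(j - i, []).append(i)
        for j in index.get(reverse_complement(kmer), ()):
            inv.setdefault(i + j, []).append(i)

    out: list[DotplotMatch] = []
    for d, xs in fwd.items():
        for x0, x1 in _merge_runs(xs, k, merge_gap):
            out.append(DotplotMatch(x=x0, y=x0 + d, length=x1 - x0, orientation="forward"))
    for c, xs in inv.items():
        for x0, x1 in _merge_runs(xs, k, merge_gap):
            # match at x covers A[x..x+k) vs B[c-x .. c-x+k) reverse-complemented
            out.append(DotplotMatch(x=x0, y=c - (x1 - k), length=x1 - x0,
                                    orientation="inverted"))
    out.sort(key=lambda m: (m.orientation, m.x, m.y))
    return out


def _merge_runs(starts: list[int], k: int, gap: int):
    starts = sorted(set(starts))
    runs = []
    s0 = prev = starts[0]
    for s in starts[1:]:
        if s - prev <= gap + 1:
            prev = s
        else:
            runs.append((s0, prev + k))
            s0 = prev = s
    runs.append((s0, prev + k))
    return runs
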