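"""Repeat scanners: SSRs, tandem arrays, and dispersed repeat pairs.

All three scans run on the redundancy-free analysis sequence
LSC + IR_B + SSC (one IR copy removed).

* SSRs: maximal runs of a primitive 1-5 bp motif; minimum copy numbers
  mono >= 8, di >= 4, tri/tetra/penta >= 3.
* Tandem repeats: arrays of >= 2 adjacent copies of a 15-30 bp unit whose
  copy-vs-consensus alignment score under (+2 match, -7 mismatch) reaches 50
  (positions beyond the first period are scored), a simplified reimplementation
  of the Tandem Repeats Finder criteria.
* Dispersed repeats: maximal pairs of length >= 30 within Hamming distance 3
  in four orientations (forward, reverse, complement, palindromic), found by
  exact q-gram seeding (q = 7: by pigeonhole any 30 bp match with <= 3
  mismatches contains an exact 7-mer) followed by maximal bidirectional
  extension over the mismatch budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .plastome_io import AnnotatedPlastome, PlastomeError
from .structure import QuadripartiteMap

_COMP = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SSRThresholds:
    """Minimum copy numbers per motif length (1..5)."""

    mono: int = 8
    di: int = 4
    tri: int = 3
    tetra: int = 3
    penta: int = 3

    def min_copies(self, motif_len: int) -> int:
        return (self.mono, self.di, self.tri, self.tetra, self.penta)[motif_len - 1]


@dataclass(frozen=True)
class TandemParams:
    min_score: int = 50
    max_period: int = 500
    report_period_min: int = 15
    report_period_max: int = 30
    match: int = 2
    mismatch: int = -7
    indel: int = -7          # retained for interface parity; arrays are ungapped
    merge_hole: int = 2      # consecutive mismatch columns bridged when seeding


@dataclass(frozen=True)
class RepeatSearchParams:
    min_len: int = 30
    max_hamming: int = 3
    classes: tuple = ("forward", "reverse", "complement", "palindromic")
    q: int | None = None     # exact seed length; None -> pigeonhole bound

    def seed_len(self) -> int:
        if self.q is not None:
            return self.q
        # a window of min_len with <= max_hamming mismatches contains an exact
        # run of at least ceil((min_len - h) / (h + 1)) bases
        h = self.max_hamming
        return max(2, -((self.min_len - h) // -(h + 1)))


# ---------------------------------------------------------------------------
# Hits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SSRHit:
    motif: str               # canonical (lexicographically smallest rotation)
    motif_len: int
    copies: int
    start: int
    end: int                 # start + motif_len * copies
    region: str = "?"
    context: str = "?"       # coding | noncoding


@dataclass(frozen=True)
class TandemHit:
    start: int
    end: int
    period: int
    copies: float
    score: int
    consensus: str
    region: str = "?"


@dataclass(frozen=True)
class RepeatHit:
    cls: str                 # forward | reverse | complement | palindromic
    start1: int
    end1: int
    start2: int
    end2: int
    length: int
    mismatches: int
    self_overlap: bool = False


# ---------------------------------------------------------------------------
# Analysis sequence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMap:
    """Maps analysis-sequence coordinates back to the rotated genome."""

    lsc_end: int
    irb_end: int
    ssc_end: int
    has_ir: bool = True

    def region_of(self, pos: int) -> str:
        if not self.has_ir:
            return "?"
        if pos < self.lsc_end:
            return "LSC"
        if pos < self.irb_end:
            return "IR"
        return "SSC"

    def to_genomic(self, pos: int) -> int:
        return pos  # analysis sequence is a genome prefix


def analysis_sequence(genome: AnnotatedPlastome, qmap):
    """LSC + IR_B + SSC with one IR copy removed; identity coordinate map.

    For no-IR genomes the full sequence is returned with a degenerate map.
    """
    import logging
    if qmap is None or not isinstance(qmap, QuadripartiteMap):
        logging.getLogger(__name__).info(
            "no quadripartite map for %s; repeat scans use the full sequence", genome.id)
        n = len(genome)
        return genome.sequence, RegionMap(n, n, n, has_ir=False)
    n = len(genome)
    cut = qmap.lsc.length(n) + qmap.ir_length + qmap.ssc.length(n)
    return genome.sequence[:cut], RegionMap(
        qmap.lsc.length(n), qmap.lsc.length(n) + qmap.ir_length, cut)


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------

def is_primitive(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _annotate(hit_start, hit_end, region_map, features):
    region = region_map.region_of(hit_start) if region_map else "?"
    context = "?"
    if features is not None:
        context = "noncoding"
        for f in features:
            if f.pseudo or f.kind not in ("CDS", "tRNA", "rRNA"):
                continue
            for p in f.parts:
                if not p.wraps() and p.start < hit_end and hit_start < p.end:
                    context = "coding"
    return region, context


def find_ssrs(seq: str, thresholds: SSRThresholds | None = None,
              features=None, region_map=None):
    """Maximal primitive-motif microsatellite runs meeting the copy thresholds.

    The periodic region for motif length m is the maximal run of positions j
    with seq[j] == seq[j-m]; a partial trailing period counts toward the run
    but the reported interval is truncated to whole copies.  Non-primitive
    motifs (poly-A reported as 'AA') are suppressed.
    """
    thresholds = thresholds or SSRThresholds()
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    hits = []
    for m in range(1, 6):
        thr = thresholds.min_copies(m)
        if thr < 2:
            raise PlastomeError("SSR thresholds must be >= 2")
        if n <= m:
            continue
        match = arr[m:] == arr[:-m]
        # run starts/ends over the boolean array
        padded = np.concatenate(([False], match, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        for j0, j1 in zip(starts, ends):
            total = (j1 - j0) + m          # periodic region length
            copies = total // m
            if copies < thr:
                continue
            s0 = j0                        # region starts at j0 (match index offset m)
            motif = seq[s0:s0 + m]
            if "N" in motif or not is_primitive(motif):
                continue
            region, context = _annotate(s0, s0 + m * copies, region_map, features)
            hits.append(SSRHit(canonical_motif(motif), m, copies,
                               s0, s0 + m * copies, region, context))
    hits.sort(key=lambda h: (h.start, h.motif_len))
    return hits


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def _consensus_score(seg: str, p: int, match: int, mismatch: int):
    """Majority consensus per column (ties to the first copy); positions beyond
    the first period scored +match/-mismatch against the consensus."""
    cons = []
    for col in range(p):
        counts: dict[str, int] = {}
        for i in range(col, len(seg), p):
            counts[seg[i]] = counts.get(seg[i], 0) + 1
        first = seg[col]
        best = max(counts, key=lambda b: (counts[b], b == first))
        if counts[best] == counts.get(first, 0):
            best = first
        cons.append(best)
    cons = "".join(cons)
    score = 0
    for i in range(p, len(seg)):
        score += match if seg[i] == cons[i % p] else mismatch
    return score, cons


def find_tandem_repeats(seq: str, params: TandemParams | None = None,
                        region_map=None):
    """Arrays of >= 2 adjacent copies of a unit within the reported period
    range whose consensus alignment score reaches ``min_score``.  Overlapping
    reports of one array at different periods collapse to the best score."""
    params = params or TandemParams()
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    raw: list[TandemHit] = []
    pmax = min(params.report_period_max, params.max_period, n // 2)
    for p in range(params.report_period_min, pmax + 1):
        match = arr[p:] == arr[:-p]
        # bridge short mismatch holes so imperfect arrays stay one candidate
        m2 = match.copy()
        i = 0
        L = m2.size
        while i < L:
            if not m2[i]:
                j = i
                while j < L and not m2[j]:
                    j += 1
                if j - i <= params.merge_hole and i > 0 and j < L:
                    m2[i:j] = True
                i = j
            else:
                i += 1
        padded = np.concatenate(([False], m2, [False]))
        d = np.diff(padded.astype(np.int8))
        for j0, j1 in zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]):
            total = (j1 - j0) + p
            if total < 2 * p:
                continue
            s0 = j0
            seg = seq[s0:s0 + total]
            score, cons = _consensus_score(seg, p, params.match, params.mismatch)
            if score >= params.min_score:
                region = region_map.region_of(s0) if region_map else "?"
                raw.append(TandemHit(s0, s0 + total, p, round(total / p, 1),
                                     score, cons, region))
    # collapse overlapping reports, best score first (ties: shortest period)
    raw.sort(key=lambda h: (-h.score, h.period, h.start))
    kept: list[TandemHit] = []
    for h in raw:
        if all(h.end <= k.start or k.end <= h.start for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


# ---------------------------------------------------------------------------
# Dispersed repeats
# ---------------------------------------------------------------------------

def _seed_pairs(seq: str, cls: str, q: int):
    """Yield (diag, offset) seed candidates for each orientation class.

    Diagonal conventions: for forward/complement the pairing is
    (i, i+d) with d >= 1; for reverse/palindromic positions a and c-a pair up
    on the anti-diagonal c.
    """
    n = len(seq)
    index: dict[str, list[int]] = {}
    for i in range(n - q + 1):
        index.setdefault(seq[i:i + q], []).append(i)

    if cls == "forward":
        for positions in index.values():
            for x in range(len(positions)):
                for y in range(x + 1, len(positions)):
                    yield positions[y] - positions[x], positions[x]
    elif cls == "complement":
        comp = seq.translate(_COMP)
        for i in range(n - q + 1):
            for j in index.get(comp[i:i + q], ()):
                if j > i:
                    yield j - i, i
    elif cls in ("reverse", "palindromic"):
        target = seq[::-1] if cls == "reverse" else seq.translate(_COMP)[::-1]
        for j in range(n - q + 1):
            for i in index.get(target[j:j + q], ()):
                b = n - j - q
                yield i + b + q - 1, i
    else:
        raise PlastomeError(f"unknown repeat class {cls}")


def _match_fn(seq: str, cls: str):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if cls == "forward":
        return lambda a, d: seq[a] == seq[a + d]
    if cls == "complement":
        return lambda a, d: comp.get(seq[a]) == seq[a + d]
    if cls == "reverse":
        return lambda a, c: seq[a] == seq[c - a]
    return lambda a, c: comp.get(seq[a]) == seq[c - a]  # palindromic


def _windows_from_seed(ok, lo, hi, s0, s1, h):
    """All maximal <=h-mismatch windows containing the exact run [s0, s1].

    ok(a) tests position a; valid offsets are [lo, hi].  Returns
    (start, end_inclusive, n_mismatches) triples.
    """
    lm, rm = [], []
    a = s0 - 1
    while len(lm) <= h and a >= lo:
        if not ok(a):
            lm.append(a)
        a -= 1
    left_real = len(lm)
    while len(lm) <= h:
        lm.append(lo - 1)
    a = s1 + 1
    while len(rm) <= h and a <= hi:
        if not ok(a):
            rm.append(a)
        a += 1
    right_real = len(rm)
    while len(rm) <= h:
        rm.append(hi + 1)
    out = set()
    if left_real + right_real < h:
        # fewer mismatches than the budget between the two boundaries: the
        # whole stretch is the single maximal window
        out.add((lo, hi, left_real + right_real))
    for t in range(h + 1):
        # budget splits that run past a boundary yield windows strictly
        # contained in the boundary-capped split; skip them
        if t > left_real or h - t > right_real:
            continue
        start = lm[t] + 1
        end = rm[h - t] - 1
        mm = min(t, left_real) + min(h - t, right_real)
        out.add((start, end, mm))
    return out


def find_dispersed_repeats(seq: str, params: RepeatSearchParams | None = None):
    """Maximal repeat pairs (length >= min_len, Hamming <= max_hamming) in the
    requested orientation classes.  Forward/complement pairs whose intervals
    overlap are suppressed (those are tandem arrays); reverse/palindromic hits
    whose two halves overlap are reported with ``self_overlap=True``.
    """
    params = params or RepeatSearchParams()
    n = len(seq)
    if n < params.min_len:
        return []
    h = params.max_hamming
    q = params.seed_len()
    results: dict[tuple, RepeatHit] = {}
    for cls in params.classes:
        ok_rel = _match_fn(seq, cls)
        anti = cls in ("reverse", "palindromic")
        per_diag: dict[int, list[int]] = {}
        for diag, off in _seed_pairs(seq, cls, q):
            per_diag.setdefault(diag, []).append(off)
        for diag, offs in per_diag.items():
            if anti:
                lo, hi = max(0, diag - (n - 1)), min(n - 1, diag)
                ok = lambda a, c=diag: ok_rel(a, c)
            else:
                lo, hi = 0, n - 1 - diag
                ok = lambda a, d=diag: ok_rel(a, d)
            offs = sorted(set(offs))
            seg_end = -1
            for off in offs:
                if off < seg_end:
                    continue
                # the exact q-run containing this seed defines its segment
                a = off + q - 1
                while a + 1 <= hi and ok(a + 1):
                    a += 1
                seg_end = a + 1
                for start, end, mm in _windows_from_seed(ok, lo, hi, off, a, h):
                    length = end - start + 1
                    if length < params.min_len:
                        continue
                    if anti:
                        o1 = (start, end + 1)
                        o2 = (diag - end, diag - start + 1)
                    else:
                        o1 = (start, end + 1)
                        o2 = (start + diag, end + 1 + diag)
                    iv1, iv2 = sorted([o1, o2])
                    overlap = iv1[1] > iv2[0]
                    if overlap and not anti:
                        continue
                    key = (cls, iv1, iv2)
                    if key not in results:
                        results[key] = RepeatHit(cls, iv1[0], iv1[1], iv2[0],
                                                 iv2[1], length, mm, overlap)
    out = list(results.values())
    out.sort(key=lambda r: (r.cls, r.start1, r.start2))
    return out


# ---------------------------------------------------------------------------
# Overlap merging
# ---------------------------------------------------------------------------

def merge_overlapping(hits):
    """Union repeat hits of one class whose both intervals overlap a partner's.

    Idempotent; the merged record keeps the union extent of each interval and
    the maximum observed length/mismatch count.
    """
    hits = list(hits)
    changed = True
    while changed:
        changed = False
        out: list[RepeatHit] = []
        for h in hits:
            merged = False
            for i, k in enumerate(out):
                if (h.cls == k.cls
                        and h.start1 < k.end1 and k.start1 < h.end1
                        and h.start2 < k.end2 and k.start2 < h.end2):
                    out[i] = RepeatHit(
                        k.cls, min(h.start1, k.start1), max(h.end1, k.end1),
                        min(h.start2, k.start2), max(h.end2, k.end2),
                        max(h.length, k.length), max(h.mismatches, k.mismatches),
                        h.self_overlap or k.self_overlap)
                    merged = changed = True
                    break
            if not merged:
                out.append(h)
        hits = out
    return hits
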