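"""Independent brute-force oracles used to validate the optimized scanners.

These deliberately avoid the implementations' algorithmic shortcuts: the SSR
oracle enumerates (start, motif length) pairs directly; the dispersed-repeat
oracle scans every diagonal/anti-diagonal exhaustively instead of q-gram
seeding; the Fitch oracle enumerates all internal-node state assignments.
"""

import itertools

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------

def _primitive(motif):
    m = len(motif)
    return all(motif != motif[:d] * (m // d) for d in range(1, m) if m % d == 0)


def _canonical(motif):
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def oracle_ssrs(seq, thresholds=(8, 4, 3, 3, 3)):
    """Set of (canonical motif, copies, start, end) maximal primitive runs."""
    n = len(seq)
    out = set()
    for m in range(1, 6):
        thr = thresholds[m - 1]
        for start in range(n - m + 1):
            # region length: longest t with seq[start+j] periodic at m
            t = m
            while start + t < n and seq[start + t] == seq[start + t - m]:
                t += 1
            copies = t // m
            if copies < thr:
                continue
            motif = seq[start:start + m]
            if "N" in motif or not _primitive(motif):
                continue
            # left-maximality of the periodic region
            if start > 0 and start - 1 + m < n and seq[start - 1] == seq[start - 1 + m]:
                continue
            out.add((_canonical(motif), copies, start, start + m * copies))
    return out


# ---------------------------------------------------------------------------
# Dispersed repeats
# ---------------------------------------------------------------------------

def _maximal_windows(ok, h, min_len=1):
    """All maximal windows with <= h mismatches over boolean sequence ok."""
    import numpy as np
    L = len(ok)
    if isinstance(ok, np.ndarray):
        mism = [int(i) for i in np.nonzero(~ok)[0]]
    else:
        mism = [int(i) for i, v in enumerate(ok) if not v]
    M = len(mism)
    ext = [-1] + mism + [L] * (h + 1)
    cands = []
    for i in range(M + 1):
        start = ext[i] + 1
        end = ext[i + h + 1] - 1
        if end - start + 1 < min_len:
            continue
        # window spans mismatch indices i+1 .. i+h of ext (those that exist)
        mm = max(0, min(i + h, M) - i)
        cands.append((start, end, mm))
    # sentinel collapse at the boundaries can emit contained windows; a
    # contained window is by definition not maximal.  Sweep by start.
    cands.sort(key=lambda w: (w[0], -w[1]))
    out, maxend = [], -1
    for w in cands:
        if w[1] > maxend:
            out.append(w)
            maxend = w[1]
    return out


def oracle_dispersed(seq, min_len=30, h=3,
                     classes=("forward", "reverse", "complement", "palindromic")):
    """Exhaustive diagonal scan; returns {(cls, iv1, iv2, length, mm, overlap)}."""
    import numpy as np
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    table = np.zeros(256, dtype=np.uint8)
    for x, y in _COMP.items():
        table[ord(x)] = ord(y)
    carr = table[arr]  # complement (0 for non-ACGT: never equal)
    hits = {}
    for cls in classes:
        anti = cls in ("reverse", "palindromic")
        left = arr if cls in ("forward", "reverse") else carr
        if not anti:
            for d in range(1, n):
                ok = left[:n - d] == arr[d:]
                for s, e, mm in _maximal_windows(ok, h, min_len):
                    length = e - s + 1
                    if length < min_len:
                        continue
                    iv1, iv2 = (s, e + 1), (s + d, e + 1 + d)
                    if iv1[1] > iv2[0]:
                        continue
                    hits[(cls, iv1, iv2)] = (length, mm, False)
        else:
            for c in range(2 * n - 1):
                amin, amax = max(0, c - n + 1), min(n - 1, c)
                xs = left[amin:amax + 1]
                ys = arr[c - amax:c - amin + 1][::-1]
                ok = xs == ys
                for s, e, mm in _maximal_windows(ok, h, min_len):
                    a0, a1 = amin + s, amin + e
                    length = a1 - a0 + 1
                    if length < min_len:
                        continue
                    o1 = (a0, a1 + 1)
                    o2 = (c - a1, c - a0 + 1)
                    iv1, iv2 = sorted([o1, o2])
                    overlap = iv1[1] > iv2[0]
                    hits[(cls, iv1, iv2)] = (length, mm, overlap)
    return {(cls, iv1, iv2, v[0], v[1], v[2]) for (cls, iv1, iv2), v in hits.items()}


def dispersed_to_set(hits):
    return {(h.cls, (h.start1, h.end1), (h.start2, h.end2), h.length,
             h.mismatches, h.self_overlap) for h in hits}


# ---------------------------------------------------------------------------
# Fitch
# ---------------------------------------------------------------------------

def oracle_fitch_column(topology, leaf_state_of_index):
    """Minimum substitutions for one column by enumerating internal states.

    ``topology`` is the nested-tuple form (taxon 0 implicit at the root edge);
    ``leaf_state_of_index`` maps taxon index -> state character or None
    (missing).  Missing leaves are free to take any state.
    """
    internals = []
    leaves = []

    def collect(node):
        if isinstance(node, tuple):
            internals.append(node)
            collect(node[0])
            collect(node[1])
        else:
            leaves.append(node)

    collect(topology)
    free_leaves = [l for l in leaves if leaf_state_of_index.get(l) is None]
    root_state = leaf_state_of_index.get(0)
    best = None
    for assign in itertools.product("ACGT", repeat=len(internals) + len(free_leaves)
                                    + (1 if root_state is None else 0)):
        amap = dict(zip(map(id, internals), assign))
        fmap = dict(zip(free_leaves, assign[len(internals):]))
        rs = root_state if root_state is not None else assign[-1]

        def state(node):
            if isinstance(node, tuple):
                return amap[id(node)]
            s = leaf_state_of_index.get(node)
            return s if s is not None else fmap[node]

        cost = 0

        def walk(node):
            nonlocal cost
            if isinstance(node, tuple):
                for ch in node:
                    if state(ch) != state(node):
                        cost += 1
                    walk(ch)

        walk(topology)
        if state(topology) != rs:
            cost += 1
        if best is None or cost < best:
            best = cost
    return best
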