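"""Maximum-parsimony tree inference at small scale.

Unrooted binary trees over n taxa are represented as nested pair tuples over
taxon indices 1..n-1, with taxon 0 attached above the root pair — the usual
"rooted at leaf 0" encoding, under which the 1·3·5···(2n-5) unrooted
topologies enumerate by stepwise insertion.  Column scores use Fitch's
algorithm on nucleotide bitmasks (gaps and ambiguity codes = all-states, so
missing data never forces a change), vectorised across deduplicated site
patterns.

Search strategy (``method="auto"``): exhaustive enumeration for <= 7 taxa,
branch-and-bound for 8-9, and for larger problems greedy stepwise addition
with random addition orders followed by tree-bisection-reconnection (TBR)
hill-climbing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import dendropy

from .plastome_io import PlastomeError

_MASK = {"A": 1, "C": 2, "G": 4, "T": 8,
         "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
         "B": 14, "D": 13, "H": 11, "V": 7}
MISSING = 15


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhyloTree:
    """Unrooted binary tree: taxon labels plus a nested-tuple topology."""

    taxa: tuple
    topology: tuple  # nested pairs over indices 1..n-1 (0 implicit at root)
    support: dict = field(default_factory=dict, compare=False)  # split -> %

    def splits(self) -> frozenset:
        return tree_splits(self.topology, len(self.taxa))

    def newick(self) -> str:
        return to_newick(self)


@dataclass
class SearchResult:
    best_trees: list
    best_score: int
    method: str
    evaluations: int


# ---------------------------------------------------------------------------
# Alignment encoding
# ---------------------------------------------------------------------------

def encode_alignment(alignment: dict[str, str]):
    """-> (taxa tuple, columns uint8 array [n_taxa, n_cols])."""
    taxa = tuple(alignment)
    rows = []
    for t in taxa:
        s = alignment[t].upper()
        rows.append(np.array([_MASK.get(ch, MISSING) for ch in s], dtype=np.uint8))
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise PlastomeError("alignment rows differ in length")
    return taxa, np.vstack(rows)


def _patterns(cols: np.ndarray):
    uniq, counts = np.unique(cols, axis=1, return_counts=True)
    return uniq, counts


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------

def _fitch_node(node, leaf_states):
    """Vectorised Fitch over all patterns at once: returns (state sets, changes)."""
    if isinstance(node, (int, np.integer)):
        return leaf_states[node], 0
    ls, lc = _fitch_node(node[0], leaf_states)
    rs, rc = _fitch_node(node[1], leaf_states)
    inter = ls & rs
    empty = inter == 0
    states = np.where(empty, ls | rs, inter)
    return states, lc + rc + empty.astype(np.int64)


def _score_patterns(topology, uniq, counts):
    leaf_states = {i: uniq[i] for i in range(uniq.shape[0])}
    states, changes = _fitch_node(topology, leaf_states)
    root = leaf_states[0]
    inter = states & root
    changes = changes + (inter == 0).astype(np.int64)
    return int((changes * counts).sum())


def fitch_steps(tree: PhyloTree, alignment: dict[str, str]) -> int:
    """Total Fitch parsimony length of the alignment on the given tree."""
    taxa, cols = encode_alignment(alignment)
    if set(taxa) != set(tree.taxa):
        raise PlastomeError("tree taxa do not match alignment taxa")
    order = [taxa.index(t) for t in tree.taxa]
    cols = cols[order]
    uniq, counts = _patterns(cols)
    return _score_patterns(tree.topology, uniq, counts)


def fitch_column_steps(tree: PhyloTree, alignment: dict[str, str]) -> np.ndarray:
    """Per-column Fitch steps (same order as alignment columns)."""
    taxa, cols = encode_alignment(alignment)
    if set(taxa) != set(tree.taxa):
        raise PlastomeError("tree taxa do not match alignment taxa")
    cols = cols[[taxa.index(t) for t in tree.taxa]]
    leaf_states = {i: cols[i] for i in range(cols.shape[0])}
    states, changes = _fitch_node(tree.topology, leaf_states)
    changes = changes + ((states & leaf_states[0]) == 0).astype(np.int64)
    return np.asarray(changes, dtype=np.int64)


# ---------------------------------------------------------------------------
# Topology utilities
# ---------------------------------------------------------------------------

def _leafset(node):
    if isinstance(node, (int, np.integer)):
        return frozenset([int(node)])
    return _leafset(node[0]) | _leafset(node[1])


def tree_splits(topology, n_taxa) -> frozenset:
    """Non-trivial splits, each as the frozenset side not containing taxon 0."""
    full = frozenset(range(n_taxa))
    out = set()

    def walk(node):
        ls = _leafset(node)
        if 1 < len(ls) < n_taxa - 1:
            out.add(ls)
        if not isinstance(node, (int, np.integer)):
            walk(node[0])
            walk(node[1])

    walk(topology)
    return frozenset(out)


def _insertions(node, leaf):
    """All trees formed by inserting ``leaf`` into any edge of ``node``."""
    yield (node, leaf)
    if not isinstance(node, (int, np.integer)):
        for a in _insertions(node[0], leaf):
            yield (a, node[1])
        for b in _insertions(node[1], leaf):
            yield (node[0], b)


def enumerate_topologies(n_taxa: int):
    """All unrooted binary topologies (nested tuples over indices 1..n-1)."""
    if n_taxa < 3:
        raise PlastomeError("need >= 3 taxa")

    def build(k, tree):
        if k == n_taxa:
            yield tree
            return
        for t in _insertions(tree, k):
            yield from build(k + 1, t)

    yield from build(3, (1, 2))


# ---------------------------------------------------------------------------
# Adjacency form + TBR
# ---------------------------------------------------------------------------

def _to_adjacency(topology, n_taxa):
    adj: dict[int, set] = {i: set() for i in range(n_taxa)}
    nxt = [n_taxa]

    def walk(node):
        if isinstance(node, (int, np.integer)):
            return int(node)
        me = nxt[0]
        nxt[0] += 1
        adj[me] = set()
        for child in node:
            c = walk(child)
            adj[me].add(c)
            adj[c].add(me)
        return me

    root = walk(topology)
    adj[0].add(root)
    adj[root].add(0)
    return adj


def _to_tuple(adj, n_taxa):
    def walk(node, parent):
        if node < n_taxa:
            return node
        kids = [c for c in adj[node] if c != parent]
        assert len(kids) == 2
        return (walk(kids[0], node), walk(kids[1], node))

    root = next(iter(adj[0]))
    return walk(root, 0)


def _edges(adj):
    return [(u, v) for u in adj for v in adj[u] if u < v]


def _component(adj, start, banned_edge):
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if (u, v) == banned_edge or (v, u) == banned_edge:
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def tbr_neighbors(topology, n_taxa):
    """All trees reachable by one tree-bisection-reconnection move."""
    adj = _to_adjacency(topology, n_taxa)
    seen_splits = set()
    for u, v in _edges(adj):
        comp_u = _component(adj, u, (u, v))
        comp_v = _component(adj, v, (u, v))

        def smoothed(comp, cut):
            """Adjacency of one component with the cut endpoint smoothed out."""
            sub = {x: {y for y in adj[x] if y in comp} for x in comp}
            if len(sub[cut]) == 2:      # degree-2 internal node: contract
                a, b = sub[cut]
                sub[a].discard(cut)
                sub[b].discard(cut)
                sub[a].add(b)
                sub[b].add(a)
                del sub[cut]
            return sub

        su = smoothed(comp_u, u)
        sv = smoothed(comp_v, v)
        eu = _edges(su) or [None]
        ev = _edges(sv) or [None]
        for e1 in eu:
            for e2 in ev:
                new = {x: set(ys) for x, ys in su.items()}
                for x, ys in sv.items():
                    new[x] = set(ys)
                fresh = max(new) + 1 if new else 0

                def attach(sub_adj, edge, comp_nodes):
                    nonlocal fresh
                    if edge is None:   # single-node component
                        (node,) = comp_nodes
                        if node not in new:
                            new[node] = set()
                        return node
                    a, b = edge
                    mid = fresh
                    fresh += 1
                    new[a].discard(b)
                    new[b].discard(a)
                    new[mid] = {a, b}
                    new[a].add(mid)
                    new[b].add(mid)
                    return mid

                p1 = attach(su, e1, su.keys() if e1 else {next(iter(comp_u)) if len(comp_u) == 1 else u})
                p2 = attach(sv, e2, sv.keys() if e2 else {next(iter(comp_v)) if len(comp_v) == 1 else v})
                new.setdefault(p1, set()).add(p2)
                new.setdefault(p2, set()).add(p1)
                topo = _relabel_and_tuple(new, n_taxa)
                if topo is None:
                    continue
                key = tree_splits(topo, n_taxa)
                if key not in seen_splits:
                    seen_splits.add(key)
                    yield topo


def _relabel_and_tuple(adj, n_taxa):
    # validity: all leaves degree 1, internals degree 3
    for x, ys in adj.items():
        if x < n_taxa:
            if len(ys) != 1:
                return None
        elif len(ys) != 3:
            return None
    return _to_tuple(adj, n_taxa)


# ---------------------------------------------------------------------------
# Searches
# ---------------------------------------------------------------------------

def _greedy_addition(uniq, counts, order):
    tree = (order[1], order[2]) if order[0] == 0 else None
    # build with taxon 0 as the implicit root; insert remaining in given order
    rest = [i for i in order if i != 0]
    tree = (rest[0], rest[1])
    for leaf in rest[2:]:
        best, best_s = None, None
        for cand in _insertions(tree, leaf):
            s = _score_patterns(cand, uniq, counts)
            if best_s is None or s < best_s:
                best, best_s = cand, s
        tree = best
    return tree


def _bnb(uniq, counts, n_taxa, upper):
    """Branch and bound over stepwise-addition order 3..n-1."""
    best_trees, best_score, evals = [], upper, 0

    def recurse(k, tree):
        nonlocal best_trees, best_score, evals
        s = _score_patterns(tree, uniq, counts)
        evals += 1
        if s > best_score:
            return
        if k == n_taxa:
            if s < best_score:
                best_score, best_trees = s, [tree]
            elif s == best_score:
                best_trees.append(tree)
            return
        for cand in _insertions(tree, k):
            recurse(k + 1, cand)

    recurse(3, (1, 2))
    return best_trees, best_score, evals


def mp_search(alignment: dict[str, str], method: str = "auto", seed: int = 0,
              n_random_addition: int = 10) -> SearchResult:
    """Maximum-parsimony search; returns all co-optimal trees found.

    Exhaustive for <= 7 taxa, branch-and-bound for 8-9, otherwise greedy
    random-addition starts refined by TBR hill-climbing (seeded).
    """
    taxa, cols = encode_alignment(alignment)
    n = len(taxa)
    if n < 3:
        raise PlastomeError("need >= 3 taxa")
    uniq, counts = _patterns(cols)
    if n == 3:
        tree = (1, 2)
        return SearchResult([PhyloTree(taxa, tree)],
                            _score_patterns(tree, uniq, counts), "trivial", 1)
    if method == "auto":
        method = "exhaustive" if n <= 7 else ("branch_and_bound" if n <= 9 else "tbr")

    if method == "exhaustive":
        best, best_s, evals = [], None, 0
        for t in enumerate_topologies(n):
            s = _score_patterns(t, uniq, counts)
            evals += 1
            if best_s is None or s < best_s:
                best, best_s = [t], s
            elif s == best_s:
                best.append(t)
        trees = best
        score = best_s
    elif method == "branch_and_bound":
        rng = np.random.default_rng(seed)
        order = list(range(n))
        start = _greedy_addition(uniq, counts, order)
        upper = _score_patterns(start, uniq, counts)
        trees, score, evals = _bnb(uniq, counts, n, upper)
    elif method == "tbr":
        rng = np.random.default_rng(seed)
        best_trees: dict[frozenset, tuple] = {}
        best_s, evals = None, 0
        for _ in range(n_random_addition):
            order = [0] + list(rng.permutation(np.arange(1, n)))
            tree = _greedy_addition(uniq, counts, [int(x) for x in order])
            s = _score_patterns(tree, uniq, counts)
            improved = True
            while improved:
                improved = False
                for cand in tbr_neighbors(tree, n):
                    cs = _score_patterns(cand, uniq, counts)
                    evals += 1
                    if cs < s:
                        tree, s = cand, cs
                        improved = True
                        break
            if best_s is None or s < best_s:
                best_s = s
                best_trees = {tree_splits(tree, n): tree}
            elif s == best_s:
                best_trees.setdefault(tree_splits(tree, n), tree)
        trees, score = list(best_trees.values()), best_s
    else:
        raise PlastomeError(f"unknown search method {method}")

    # deduplicate by split set
    uniq_trees: dict[frozenset, tuple] = {}
    for t in trees:
        uniq_trees.setdefault(tree_splits(t, n), t)
    return SearchResult([PhyloTree(taxa, t) for t in uniq_trees.values()],
                        int(score), method, evals)


def strict_consensus_splits(trees: list[PhyloTree]) -> frozenset:
    sets = [t.splits() for t in trees]
    common = sets[0]
    for s in sets[1:]:
        common &= s
    return common


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap(alignment: dict[str, str], replicates: int = 100, seed: int = 0,
              method: str = "auto") -> PhyloTree:
    """Column-resampling bootstrap; supports (%) annotated on the MP tree."""
    if replicates < 1:
        raise PlastomeError("replicates must be >= 1")
    base = mp_search(alignment, method=method, seed=seed)
    best = base.best_trees[0]
    n_cols = len(next(iter(alignment.values())))
    rng = np.random.default_rng(seed)
    tally: dict[frozenset, int] = {s: 0 for s in best.splits()}
    for _ in range(replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        res = {t: "".join(s[i] for i in idx) for t, s in alignment.items()}
        rep = mp_search(res, method=method, seed=int(rng.integers(0, 2**31 - 1)))
        rep_splits = rep.best_trees[0].splits()
        for s in tally:
            if s in rep_splits:
                tally[s] += 1
    support = {s: 100.0 * c / replicates for s, c in tally.items()}
    return PhyloTree(best.taxa, best.topology, support)


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

def concatenate_genes(alignments: dict[str, dict[str, str]], gene_list=None):
    """Concatenate per-gene alignments into a supermatrix.

    Returns ``(supermatrix, partitions)`` where partitions maps gene ->
    (start, end) column interval.  All genes must share the same taxon set.
    """
    genes = list(gene_list) if gene_list is not None else list(alignments)
    taxa = None
    parts: dict[str, tuple] = {}
    rows: dict[str, list] = {}
    pos = 0
    for g in genes:
        aln = alignments[g]
        if taxa is None:
            taxa = set(aln)
            rows = {t: [] for t in taxa}
        if set(aln) != taxa:
            raise PlastomeError(f"gene {g}: taxon set differs from the first gene")
        width = len(next(iter(aln.values())))
        for t in taxa:
            if len(aln[t]) != width:
                raise PlastomeError(f"gene {g}: ragged alignment")
            rows[t].append(aln[t])
        parts[g] = (pos, pos + width)
        pos += width
    return {t: "".join(chunks) for t, chunks in rows.items()}, parts


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def to_newick(tree: PhyloTree) -> str:
    n = len(tree.taxa)
    support = tree.support or {}

    def walk(node):
        if isinstance(node, (int, np.integer)):
            return tree.taxa[int(node)]
        label = ""
        ls = _leafset(node)
        if ls in support:
            v = support[ls]
            label = str(int(v)) if float(v).is_integer() else f"{v:.1f}"
        return f"({walk(node[0])},{walk(node[1])}){label}"

    return f"({tree.taxa[0]},{walk(tree.topology)});"


def read_newick(source) -> PhyloTree:
    """Parse newick text (or a path) into a PhyloTree.

    Non-binary nodes are arbitrarily resolved into binary pairs; internal-node
    labels are interpreted as support values.
    """
    text = source
    try:
        import os
        if os.path.exists(str(source)):
            with open(source) as fh:
                text = fh.read()
    except (OSError, ValueError):
        pass
    try:
        dt = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise PlastomeError(f"newick parse error: {exc}") from exc
    labels = sorted(lf.taxon.label for lf in dt.leaf_node_iter())
    taxa = tuple(labels)
    index = {l: i for i, l in enumerate(taxa)}
    support: dict[frozenset, float] = {}

    def conv(node):
        if node.is_leaf():
            return index[node.taxon.label]
        kids = [conv(c) for c in node.child_nodes()]
        while len(kids) > 2:
            kids = [(kids[0], kids[1])] + kids[2:]
        sub = kids[0] if len(kids) == 1 else (kids[0], kids[1])
        if node.label is not None:
            try:
                support[_leafset(sub)] = float(node.label)
            except ValueError:
                pass
        return sub

    root_kids = [conv(c) for c in dt.seed_node.child_nodes()]
    while len(root_kids) > 2:
        root_kids = [(root_kids[0], root_kids[1])] + root_kids[2:]
    topo = root_kids[0] if len(root_kids) == 1 else tuple(root_kids)
    # re-root at taxon 0 for the canonical representation
    tree = PhyloTree(taxa, topo, support)
    return _reroot_at_zero(tree)


def _reroot_at_zero(tree: PhyloTree) -> PhyloTree:
    n = len(tree.taxa)
    topo = tree.topology
    if isinstance(topo, tuple):
        adj = _to_adjacency_any(topo, n)
    else:
        raise PlastomeError("degenerate tree")
    topo0 = _to_tuple(adj, n)
    # recompute support keyed on canonical leafsets (sides not containing 0)
    supp = {}
    for ls, v in tree.support.items():
        side = ls if 0 not in ls else frozenset(range(n)) - ls
        if 1 < len(side) < n - 1:
            supp[side] = v
    return PhyloTree(tree.taxa, topo0, supp)


def _to_adjacency_any(topology, n_taxa):
    """Adjacency for a tuple tree that may have taxon 0 anywhere."""
    adj: dict[int, set] = {}
    nxt = [n_taxa]

    def walk(node):
        if isinstance(node, (int, np.integer)):
            adj.setdefault(int(node), set())
            return int(node)
        me = nxt[0]
        nxt[0] += 1
        adj[me] = set()
        for child in node:
            c = walk(child)
            adj[me].add(c)
            adj[c].add(me)
        return me

    top = walk(topology)
    # the top node has degree 2 (it was the newick root): smooth it
    if len(adj[top]) == 2:
        a, b = adj[top]
        adj[a].discard(top)
        adj[b].discard(top)
        adj[a].add(b)
        adj[b].add(a)
        del adj[top]
    return adj


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
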