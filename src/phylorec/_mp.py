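"""Internal maximum-parsimony engine.

Unrooted binary topologies are held as plain adjacency lists (``list[list[int]]``,
leaves ``0..n-1`` first, then internal nodes), and site data as IUPAC bitmask
patterns with multiplicity weights.  Everything here is deliberately low-level:
the public API in :mod:`phylorec.treekit` converts to/from dendropy trees.

Fitch counting roots the unrooted tree at leaf 0 (or the lowest-id leaf
present), which makes every internal node binary; nodes with more than two
children (pre-existing polytomies) are folded sequentially, which is exact for
binary trees and a deterministic convention otherwise.
"""

from __future__ import annotations

import numpy as np

from .seqdata import IUPAC_STATE_SETS

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

#: 256-entry lookup: ASCII byte of an IUPAC code -> 4-bit state-set mask.
CHAR_TO_MASK = np.zeros(256, dtype=np.uint8)
for _code, _bases in IUPAC_STATE_SETS.items():
    CHAR_TO_MASK[ord(_code)] = np.uint8(sum(_BASE_BIT[b] for b in _bases))


def encode_columns(rows: np.ndarray) -> np.ndarray:
    """(n, L) '|S1' alignment rows -> (n, L) uint8 bitmask matrix."""
    return CHAR_TO_MASK[rows.view(np.uint8)]


def compress_patterns(masks: np.ndarray, drop_uninformative: bool = True
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical columns into patterns with weights.

    Columns whose state sets share a common base (Fitch length 0 on every
    topology) are dropped when ``drop_uninformative`` is set; they contribute
    nothing to any tree length.
    Returns (patterns (n, P) uint8, weights (P,) int64).
    """
    cols = masks.T  # (L, n)
    if drop_uninformative and cols.size:
        inter = cols[:, 0].copy()
        for j in range(1, cols.shape[1]):
            inter &= cols[:, j]
        cols = cols[inter == 0]
    if cols.shape[0] == 0:
        n = masks.shape[0]
        return np.empty((n, 0), dtype=np.uint8), np.empty(0, dtype=np.int64)
    uniq, counts = np.unique(cols, axis=0, return_counts=True)
    return uniq.T.copy(), counts.astype(np.int64)


# ---------------------------------------------------------------------------
# Topology plumbing


def star_topology(leaves: list[int], internal: int) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {leaf: [internal] for leaf in leaves}
    adj[internal] = list(leaves)
    return adj


def edges_of(adj: dict[int, list[int]]) -> list[tuple[int, int]]:
    """Deterministically ordered undirected edge list."""
    out = []
    for u in sorted(adj):
        for v in adj[u]:
            if u < v:
                out.append((u, v))
    return out


def attach_leaf(adj, edge, leaf, internal):
    """Subdivide ``edge`` with ``internal`` and hang ``leaf`` from it."""
    u, v = edge
    adj[u][adj[u].index(v)] = internal
    adj[v][adj[v].index(u)] = internal
    adj[internal] = [u, v, leaf]
    adj[leaf] = [internal]


def detach_leaf(adj, edge, leaf, internal):
    u, v = edge
    adj[u][adj[u].index(internal)] = v
    adj[v][adj[v].index(internal)] = u
    del adj[internal]
    del adj[leaf]


try:  # compiled Fitch kernel; the numpy fallback is semantically identical
    from numba import njit as _njit

    @_njit(cache=False)
    def _fitch_kernel(left, right, states, weights, n_leaves):  # pragma: no cover
        total = 0
        P = states.shape[1]
        for idx in range(left.shape[0]):
            li = left[idx]
            ri = right[idx]
            out = n_leaves + idx
            for p in range(P):
                inter = states[li, p] & states[ri, p]
                if inter == 0:
                    states[out, p] = states[li, p] | states[ri, p]
                    total += weights[p]
                else:
                    states[out, p] = inter
        return total

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _fitch_kernel(left, right, states, weights, n_leaves):
        total = 0
        for idx in range(left.shape[0]):
            a = states[left[idx]]
            b = states[right[idx]]
            inter = a & b
            empty = inter == 0
            out = n_leaves + idx
            if empty.any():
                total += int(weights[empty].sum())
                states[out] = np.where(empty, a | b, inter)
            else:
                states[out] = inter
        return total


def fitch_score(adj: dict[int, list[int]], n_leaves: int,
                patterns: np.ndarray, weights: np.ndarray,
                root_leaf: int | None = None) -> int:
    """Total Fitch parsimony length of the topology over all patterns.

    The unrooted tree is rooted at a leaf (every internal node then binary for
    degree-3 trees; higher-degree nodes are folded as sequential cherries) and
    scored pattern-wise by the usual intersection/union sweep.
    """
    if weights.size == 0:
        return 0
    if root_leaf is None:
        root_leaf = min(u for u in adj if u < n_leaves)
    root = adj[root_leaf][0]
    parent = {root: root_leaf}
    order = []
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                stack.append(v)
    # emit binary fold steps in postorder; rows: leaves, then one per step
    left: list[int] = []
    right: list[int] = []
    row_of: dict[int, int] = {}
    for u in reversed(order):
        if u < n_leaves:
            row_of[u] = u
            continue
        children = [v for v in adj[u] if v != parent[u]]
        acc = row_of[children[0]]
        for c in children[1:]:
            left.append(acc)
            right.append(row_of[c])
            acc = n_leaves + len(left) - 1
        row_of[u] = acc
    left.append(row_of[root])
    right.append(root_leaf)
    n_steps = len(left)
    states = np.empty((n_leaves + n_steps, patterns.shape[1]), dtype=np.uint8)
    states[:n_leaves] = patterns
    return int(_fitch_kernel(np.asarray(left, dtype=np.int64),
                             np.asarray(right, dtype=np.int64),
                             states, weights, n_leaves))


# ---------------------------------------------------------------------------
# Exhaustive enumeration


def enumerate_topologies(n_leaves: int):
    """Yield every unrooted topology on leaves 0..n-1 (shared mutable adjacency).

    (2n-5)!! topologies; callers must not retain the yielded dict across
    iterations without copying.
    """
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves to enumerate unrooted topologies")
    internal0 = n_leaves
    adj = star_topology([0, 1, 2], internal0)

    def _recurse(next_leaf: int, next_internal: int):
        if next_leaf == n_leaves:
            yield adj
            return
        for edge in edges_of(adj):
            attach_leaf(adj, edge, next_leaf, next_internal)
            yield from _recurse(next_leaf + 1, next_internal + 1)
            detach_leaf(adj, edge, next_leaf, next_internal)

    yield from _recurse(3, internal0 + 1)


def exact_search(patterns, weights, n_leaves):
    best_len = None
    best_adj = None
    for adj in enumerate_topologies(n_leaves):
        ln = fitch_score(adj, n_leaves, patterns, weights)
        if best_len is None or ln < best_len:
            best_len = ln
            best_adj = {u: list(vs) for u, vs in adj.items()}
    return best_adj, best_len


# ---------------------------------------------------------------------------
# Heuristic search: random-order stepwise addition + NNI hill climbing


def stepwise_addition(order, patterns, weights):
    """Greedy stepwise addition following ``order`` (a permutation of leaves)."""
    order = list(order)
    n_leaves = patterns.shape[0]
    next_internal = n_leaves
    adj = star_topology(order[:3], next_internal)
    next_internal += 1
    for leaf in order[3:]:
        best = None
        for edge in edges_of(adj):
            attach_leaf(adj, edge, leaf, next_internal)
            ln = fitch_score(adj, n_leaves, patterns, weights)
            detach_leaf(adj, edge, leaf, next_internal)
            if best is None or ln < best[0]:
                best = (ln, edge)
        attach_leaf(adj, best[1], leaf, next_internal)
        next_internal += 1
    return adj


def _nni_neighbours(adj, u, v):
    """The two NNI rearrangements around internal edge (u, v), as swap ops."""
    a, b = [x for x in adj[u] if x != v]
    c, d = [x for x in adj[v] if x != u]
    return [(b, c), (b, d)]


def _apply_swap(adj, u, v, x, y):
    """Swap subtree x (neighbour of u) with subtree y (neighbour of v)."""
    adj[u][adj[u].index(x)] = y
    adj[v][adj[v].index(y)] = x
    adj[x][adj[x].index(u)] = v
    adj[y][adj[y].index(v)] = u


def nni_hill_climb(adj, patterns, weights, n_leaves):
    """First-improvement NNI until a local optimum; deterministic edge order."""
    current = fitch_score(adj, n_leaves, patterns, weights)
    improved = True
    while improved:
        improved = False
        internal_edges = [(u, v) for u, v in edges_of(adj)
                          if u >= n_leaves and v >= n_leaves]
        for u, v in internal_edges:
            for x, y in _nni_neighbours(adj, u, v):
                _apply_swap(adj, u, v, x, y)
                ln = fitch_score(adj, n_leaves, patterns, weights)
                if ln < current:
                    current = ln
                    improved = True
                    break
                _apply_swap(adj, u, v, y, x)  # revert
            if improved:
                break
    return adj, current


def heuristic_search(patterns, weights, n_leaves, n_starts, rng):
    best_adj, best_len = None, None
    for _ in range(n_starts):
        order = [int(x) for x in rng.permutation(n_leaves)]
        adj = stepwise_addition(order, patterns, weights)
        adj, ln = nni_hill_climb(adj, patterns, weights, n_leaves)
        if best_len is None or ln < best_len:
            best_adj, best_len = adj, ln
    return best_adj, best_len
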