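"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (nested-tuple trees, recursive set-based
Fitch, exhaustive enumeration) that share no code with the package internals.
"""

from itertools import combinations

FULL = frozenset("ACGT")

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"), "K": frozenset("GT"),
    "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": FULL, "-": FULL,
}


def rooted_trees(leaves):
    """All rooted binary tree shapes over the given leaves (nested tuples)."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    for sub in rooted_trees(leaves[:-1]):
        yield from _attach(sub, leaves[-1])


def _attach(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        a, b = tree
        for t in _attach(a, leaf):
            yield (t, b)
        for t in _attach(b, leaf):
            yield (a, t)


def unrooted_trees(leaves):
    """All unrooted binary topologies: rooted trees over leaves[1:], with
    leaves[0] joined at the root edge."""
    for sub in rooted_trees(list(leaves[1:])):
        yield (sub, leaves[0])


def fitch_column(tree, column):
    """(state set, change count) of one column on a rooted nested-tuple tree.

    ``column`` maps leaf label -> IUPAC character.
    """
    if not isinstance(tree, tuple):
        return IUPAC[column[tree]], 0
    (sa, ca) = fitch_column(tree[0], column)
    (sb, cb) = fitch_column(tree[1], column)
    inter = sa & sb
    if inter:
        return inter, ca + cb
    return sa | sb, ca + cb + 1


def min_parsimony_length(leaves, columns):
    """Exhaustive-topology minimum of the summed Fitch length."""
    best = None
    for tree in unrooted_trees(list(leaves)):
        total = sum(fitch_column(tree, col)[1] for col in columns)
        if best is None or total < best:
            best = total
    return best


def min_joint_pair_length(leaves, col_a, col_b):
    """Minimum over all topologies of the two sites' summed Fitch length."""
    return min_parsimony_length(leaves, [col_a, col_b])


def parsimony_floor(column):
    """(#observed concrete states - 1) using only unambiguous characters."""
    states = {c for c in column.values() if c in "ACGT"}
    return max(len(states) - 1, 0)


def patristic_all_pairs(tree):
    """All-pairs leaf path lengths of a dendropy tree via plain BFS."""
    # adjacency over node ids with edge lengths
    adj = {}
    labels = {}
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            labels[id(node)] = node.taxon.label
        if node.parent_node is not None:
            u, v = id(node.parent_node), id(node)
            w = node.edge.length or 0.0
            adj.setdefault(u, []).append((v, w))
            adj.setdefault(v, []).append((u, w))
    out = {}
    for start, lab in labels.items():
        dist = {start: 0.0}
        queue = [start]
        while queue:
            u = queue.pop()
            for v, w in adj.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        for other, lab2 in labels.items():
            out[(lab, lab2)] = dist[other]
    return out


def max_disjoint_incompatible_intervals(intervals):
    """Exhaustive maximum set of pairwise non-overlapping open intervals."""
    best = 0
    items = sorted(intervals)
    n = len(items)
    for r in range(1, n + 1):
        found = False
        for subset in combinations(items, r):
            ok = all(subset[k][1] <= subset[k + 1][0]
                     for k in range(len(subset) - 1))
            if ok:
                found = True
                break
        if found:
            best = r
        else:
            break
    return best
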