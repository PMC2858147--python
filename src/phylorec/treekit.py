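"""Distance matrices, neighbour-joining trees, parsimony and split utilities.

Trees are dendropy :class:`~dendropy.Tree` objects throughout.  Edge supports
(bootstrap proportions in [0, 1]) are stored as internal-node labels, the
newick convention understood by most phylogenetics software.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from . import _mp
from .errors import DistanceError, IdError, SaturationError, SizeError
from .seqdata import LocusAlignment

logger = logging.getLogger(__name__)

Split = tuple[frozenset, frozenset]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances over an ordered id list."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T) or not np.all(np.isfinite(v)):
            raise ValueError("distance matrix must be symmetric and finite")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t")


# ---------------------------------------------------------------------------
# Model distances

# Substitution classes for the Kimura 3-ST model: transitions (P), A<->T/G<->C
# transversions (Q), A<->C/G<->T transversions (R).
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_TV_Q = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def _encode_acgt(rows: np.ndarray) -> np.ndarray:
    """'|S1' rows -> int codes A=0 C=1 G=2 T=3, anything else (gap/ambig) = 4."""
    lut = np.full(256, 4, dtype=np.uint8)
    for k, c in enumerate("ACGT"):
        lut[ord(c)] = k
    return lut[rows.view(np.uint8)]


def _p_distance_from_codes(codes: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """Vectorised mismatch fraction with pairwise deletion."""
    ok = codes < 4
    valid = ok.astype(np.int64) @ ok.astype(np.int64).T
    if (valid == 0).any():
        i, j = np.argwhere(valid == 0)[0]
        raise DistanceError(
            f"no comparable sites for pair ({ids[i]!r}, {ids[j]!r})")
    # mismatches among mutually called sites, via one-hot matrix products
    onehot = np.stack([(codes == k) for k in range(4)]).astype(np.int64)
    match = sum(onehot[k] @ onehot[k].T for k in range(4))
    d = (valid - match) / valid
    np.fill_diagonal(d, 0.0)
    return d


def distance_matrix(alignment: LocusAlignment, model: str = "K3ST"
                    ) -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap/ambiguous sites.

    model='p' gives the mismatch fraction; model='K3ST' the Kimura
    three-substitution-type distance
    d = -1/4 ln[(1-2P-2Q)(1-2P-2R)(1-2Q-2R)] with P, Q, R the frequencies of
    the three substitution classes.
    """
    if model not in ("p", "K3ST"):
        raise ValueError(f"unknown model {model!r}")
    codes = _encode_acgt(alignment.rows)
    if model == "p":
        return DistanceMatrix(tuple(alignment.strain_ids),
                              _p_distance_from_codes(codes, alignment.strain_ids))
    n = alignment.n_strains
    d = np.zeros((n, n))
    # class of an ordered base pair: 0 same, 1 transition, 2 Q-tv, 3 R-tv
    pair_class = np.zeros((4, 4), dtype=np.int8)
    for i, a in enumerate("ACGT"):
        for j, b in enumerate("ACGT"):
            if a == b:
                pair_class[i, j] = 0
            elif (a, b) in _TRANSITIONS:
                pair_class[i, j] = 1
            elif (a, b) in _TV_Q:
                pair_class[i, j] = 2
            else:
                pair_class[i, j] = 3
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            ok = (a < 4) & (b < 4)
            m = int(ok.sum())
            if m == 0:
                raise DistanceError(
                    f"no comparable sites for pair "
                    f"({alignment.strain_ids[i]!r}, {alignment.strain_ids[j]!r})")
            cls = pair_class[a[ok], b[ok]]
            if model == "p":
                d[i, j] = d[j, i] = float((cls != 0).mean())
            else:
                P = float((cls == 1).mean())
                Q = float((cls == 2).mean())
                R = float((cls == 3).mean())
                args = (1 - 2 * P - 2 * Q, 1 - 2 * P - 2 * R, 1 - 2 * Q - 2 * R)
                if min(args) <= 0:
                    raise SaturationError(
                        f"K3ST distance saturated for pair "
                        f"({alignment.strain_ids[i]!r}, {alignment.strain_ids[j]!r})")
                d[i, j] = d[j, i] = -0.25 * math.log(args[0] * args[1] * args[2])
    return DistanceMatrix(tuple(alignment.strain_ids), d)


# ---------------------------------------------------------------------------
# Neighbour joining


def neighbor_joining(matrix: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbour joining.

    Ties in the Q criterion resolve to the first (row-major) minimum, which
    makes the output deterministic.  Negative branch lengths are clamped to 0
    and the total clamped deficit is logged.
    """
    n = len(matrix.ids)
    if n < 3:
        raise SizeError("neighbor joining needs >= 3 taxa")
    taxa = dendropy.TaxonNamespace(list(matrix.ids))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in matrix.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    d = matrix.values.astype(float).copy()
    active = list(range(n))
    deficit = 0.0

    def _edge_len(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[active[i]])
        nodes[active[i]].edge.length = _edge_len(li)
        parent.add_child(nodes[active[j]])
        nodes[active[j]].edge.length = _edge_len(lj)
        new_d = 0.5 * (d[active, :][:, [active[i]]].ravel()
                       + d[active, :][:, [active[j]]].ravel() - dij)
        gi = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k, ak in enumerate(active):
            d[gi, ak] = d[ak, gi] = new_d[k]
        ai, aj = active[i], active[j]
        active = [a for a in active if a not in (ai, aj)] + [gi]
    # resolve the final three clusters around a central node
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    centre = dendropy.Node()
    for idx, ln in ((a, 0.5 * (dab + dac - dbc)),
                    (b, 0.5 * (dab + dbc - dac)),
                    (c, 0.5 * (dac + dbc - dab))):
        centre.add_child(nodes[idx])
        nodes[idx].edge.length = _edge_len(ln)
    tree.seed_node = centre
    tree.is_rooted = False
    if deficit > 0:
        logger.info("neighbor_joining: clamped %.6g of negative branch length",
                    deficit)
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits of the tree, each as the frozenset of leaf labels on
    one side (the side not containing the first leaf, canonically)."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = min(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        out.add(side if anchor not in side else leaves - side)
    return out


def nj_tree(alignment: LocusAlignment, model: str = "p",
            bootstrap: int = 0, seed: int | None = None) -> dendropy.Tree:
    """Neighbour-joining tree, optionally with bootstrap supports.

    Supports are the proportion of column-resampled replicates whose NJ tree
    contains each split, written as internal-node labels in [0, 1].
    """
    tree = neighbor_joining(distance_matrix(alignment, model=model))
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        counts: dict[frozenset, int] = {}
        codes = _encode_acgt(alignment.rows) if model == "p" else None
        for _ in range(bootstrap):
            cols = rng.integers(0, alignment.length, size=alignment.length)
            try:
                if codes is not None:
                    dm = DistanceMatrix(
                        tuple(alignment.strain_ids),
                        _p_distance_from_codes(codes[:, cols],
                                               alignment.strain_ids))
                else:
                    rep = LocusAlignment(alignment.locus_name,
                                         alignment.strain_ids,
                                         alignment.rows[:, cols])
                    dm = distance_matrix(rep, model=model)
                rep_tree = neighbor_joining(dm)
            except DistanceError:
                continue
            for split in bipartitions(rep_tree):
                counts[split] = counts.get(split, 0) + 1
        leaves = frozenset(alignment.strain_ids)
        anchor = min(leaves)
        for node in tree.preorder_node_iter():
            if node is tree.seed_node or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(side) < 2 or len(side) > len(leaves) - 2:
                continue
            key = side if anchor not in side else leaves - side
            node.label = f"{counts.get(key, 0) / bootstrap:.4f}"
    return tree


# ---------------------------------------------------------------------------
# Newick I/O


def read_tree(path) -> dendropy.Tree:
    """Read a newick tree; internal-node labels are kept (support values)."""
    return dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)


def parse_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


# ---------------------------------------------------------------------------
# Parsimony


def _tree_adjacency(tree: dendropy.Tree, leaf_order: Sequence[str]):
    """Undirected adjacency (degree-2 nodes suppressed) with leaves mapped to
    their index in ``leaf_order``."""
    index = {label: k for k, label in enumerate(leaf_order)}
    node_ids: dict[int, int] = {}
    next_id = len(leaf_order)
    edges = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in index:
                raise IdError(f"leaf {label!r} has no alignment row")
            node_ids[id(node)] = index[label]
        else:
            node_ids[id(node)] = next_id
            next_id += 1
        if node.parent_node is not None:
            edges.append((node_ids[id(node.parent_node)], node_ids[id(node)]))
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    # suppress degree-2 nodes (rooted representation of an unrooted tree)
    for u in [u for u, vs in adj.items() if len(vs) == 2]:
        a, b = adj.pop(u)
        adj[a][adj[a].index(u)] = b
        adj[b][adj[b].index(u)] = a
    return adj


def fitch_length(tree: dendropy.Tree, alignment: LocusAlignment) -> int:
    """Fitch parsimony length of ``tree`` on ``alignment``.

    Ambiguity codes contribute their IUPAC state sets; '-' counts as fully
    missing (the full state set).  Tree leaves must be a subset of the
    alignment's strain ids; extra alignment rows are ignored.
    """
    leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    sub = alignment.take(leaf_labels)
    masks = _mp.encode_columns(sub.rows)
    patterns, weights = _mp.compress_patterns(masks)
    adj = _tree_adjacency(tree, leaf_labels)
    return _mp.fitch_score(adj, len(leaf_labels), patterns, weights)


def _adjacency_to_tree(adj, leaf_order: Sequence[str]) -> dendropy.Tree:
    n_leaves = len(leaf_order)
    taxa = dendropy.TaxonNamespace(list(leaf_order))
    tree = dendropy.Tree(taxon_namespace=taxa)
    start = max(adj)  # an internal node
    nodes = {start: tree.seed_node}
    stack = [(start, None)]
    while stack:
        u, parent = stack.pop()
        for v in adj[u]:
            if v == parent:
                continue
            node = dendropy.Node()
            if v < n_leaves:
                node.taxon = taxa.get_taxon(leaf_order[v])
            nodes[u].add_child(node)
            nodes[v] = node
            stack.append((v, u))
    tree.is_rooted = False
    return tree


def mp_search(alignment: LocusAlignment, n_starts: int = 4,
              seed: int | None = None, mode: str = "heuristic"
              ) -> tuple[dendropy.Tree, int]:
    """Maximum-parsimony tree search.

    mode='heuristic' (default): random-order stepwise addition followed by
    first-improvement NNI hill climbing, best of ``n_starts`` starts.
    mode='exact': exhaustive enumeration of all unrooted topologies (<= 11
    taxa).  Returns (tree, Fitch length).
    """
    n = alignment.n_strains
    masks = _mp.encode_columns(alignment.rows)
    patterns, weights = _mp.compress_patterns(masks)
    if n < 3:
        raise SizeError("parsimony search needs >= 3 taxa")
    if n == 3:
        adj = _mp.star_topology([0, 1, 2], 3)
        return (_adjacency_to_tree(adj, alignment.strain_ids),
                _mp.fitch_score(adj, 3, patterns, weights))
    if mode == "exact":
        if n > 11:
            raise SizeError("exact parsimony search is limited to 11 taxa")
        adj, length = _mp.exact_search(patterns, weights, n)
    elif mode == "heuristic":
        rng = np.random.default_rng(seed)
        adj, length = _mp.heuristic_search(patterns, weights, n, n_starts, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _adjacency_to_tree(adj, alignment.strain_ids), int(length)


def parsimony_length(alignment: LocusAlignment, **kwargs) -> int:
    """Best tree length only (convenience wrapper around :func:`mp_search`)."""
    return mp_search(alignment, **kwargs)[1]


# ---------------------------------------------------------------------------
# Clade tables and split compatibility


@dataclass(frozen=True)
class CladeTable:
    """Supported bipartitions of one gene tree."""

    locus_name: str
    taxa: frozenset
    splits: tuple[tuple[frozenset, float], ...]  # (one side, support)

    def sides(self) -> list[frozenset]:
        return [s for s, _ in self.splits]


def node_support(node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def extract_clades(tree: dendropy.Tree, support_threshold: float = 0.95,
                   locus_name: str = "") -> CladeTable:
    """Bipartitions whose support is >= the threshold; trivial splits excluded.

    Nodes without a parseable support label count as unsupported.
    """
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    found: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        support = node_support(node)
        if support is None or support < support_threshold:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        key = min(side, leaves - side, key=lambda s: (len(s), tuple(sorted(s))))
        found[key] = max(found.get(key, 0.0), support)
    splits = tuple(sorted(found.items(),
                          key=lambda kv: (len(kv[0]), tuple(sorted(kv[0])))))
    return CladeTable(locus_name or "", leaves, splits)


def clades_compatible(split1: Split, split2: Split,
                      shared_taxa: frozenset) -> bool:
    """Split compatibility on the shared taxon set.

    Each split is a (sideA, sideB) pair of taxon sets.  Both splits are first
    restricted to ``shared_taxa``; they are compatible iff at least one of the
    four pairwise side intersections is empty.  Fewer than 4 shared taxa is
    vacuously compatible.
    """
    if len(shared_taxa) < 4:
        logger.debug("clades_compatible: < 4 shared taxa, vacuously compatible")
        return True
    a1, b1 = (s & shared_taxa for s in split1)
    a2, b2 = (s & shared_taxa for s in split2)
    return (not (a1 & a2) or not (a1 & b2) or not (b1 & a2) or not (b1 & b2))


# ---------------------------------------------------------------------------
# Patristic distances


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """All-pairs path-length distances between leaves."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]],
                                                       taxa[labels[j]])
    return DistanceMatrix(tuple(labels), d)


def patristic_distance(tree: dendropy.Tree, id1: str, id2: str) -> float:
    """Sum of branch lengths on the path between two leaves."""
    if id1 == id2:
        return 0.0
    taxa = {lf.taxon.label: lf.taxon for lf in tree.leaf_node_iter()}
    for x in (id1, id2):
        if x not in taxa:
            raise IdError(f"leaf {x!r} not in tree")
    pdm = tree.phylogenetic_distance_matrix()
    return float(pdm.patristic_distance(taxa[id1], taxa[id2]))
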