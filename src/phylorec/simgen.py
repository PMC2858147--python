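"""Synthetic multilocus data with known truth.

The generator emulates the statistical structure that multilocus recombination
tests are applied to: a set of haploid strains typed at a few unlinked loci,
whose genealogies are either shared across all sites (clonality), independent
per locus (free recombination), independent per intra-locus block (intragenic
recombination), structured into two diverged demes, or a "border" scenario
with a clonal core, a recombining halo and distant outgroup controls.

Time is measured in coalescent units; a locus with population mutation rate
theta accumulates mutations at rate theta/2 per lineage per unit time, so that
for n sampled lineages E[number of segregating sites] = theta * sum_{i<n} 1/i
under infinite sites.  All randomness flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .errors import CapacityError, ConfigError, SizeError
from .seqdata import (
    LocusAlignment,
    MultiLocusDataset,
    StrainRecord,
    dataset_from_alignments,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

MODES = ("clonal", "free_recomb", "intralocus", "structured", "border_scenario")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a desk-scale multilocus sample: 20 haploid strains,
    three unlinked loci of 300 nt, theta = 10 per locus (0.033 per site,
    typical of variable fungal typing loci), infinite-sites mutation.
    """

    n_strains: int = 20
    n_loci: int = 3
    locus_lengths: tuple[int, ...] = (300, 300, 300)
    theta_per_locus: tuple[float, ...] = (10.0, 10.0, 10.0)
    mode: str = "clonal"
    n_blocks: int = 4
    divergence_time: float = 6.0
    deme_sizes: tuple[int, int] = (10, 10)
    core_size: int = 8
    halo_size: int = 10
    control_size: int = 5
    halo_intensity: float = 1.0
    control_spacing: float = 1.0
    mutation_model: str = "infinite_sites"
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mutation_model not in ("infinite_sites", "JC"):
            raise ConfigError(f"unknown mutation model {self.mutation_model!r}")
        if len(self.locus_lengths) != self.n_loci:
            raise ConfigError("locus_lengths must have n_loci entries")
        if len(self.theta_per_locus) != self.n_loci:
            raise ConfigError("theta_per_locus must have n_loci entries")
        if min(self.locus_lengths) < 1 or min(self.theta_per_locus) <= 0:
            raise ConfigError("locus lengths must be >= 1 and theta > 0")
        if self.n_strains < 2 or self.n_blocks < 1:
            raise ConfigError("need n_strains >= 2 and n_blocks >= 1")
        if self.mode == "intralocus" and self.n_blocks > min(self.locus_lengths):
            raise ConfigError("more blocks than columns in a locus")
        if self.mode == "structured":
            if sum(self.deme_sizes) != self.n_strains:
                raise ConfigError("deme sizes must sum to n_strains")
            if self.divergence_time < 0:
                raise ConfigError("divergence time must be >= 0")
        if self.mode == "border_scenario":
            if self.core_size + self.halo_size + self.control_size != self.n_strains:
                raise ConfigError("core + halo + controls must equal n_strains")
            if not 0.0 <= self.halo_intensity <= 1.0:
                raise ConfigError("halo_intensity must be in [0, 1]")


@dataclass(frozen=True)
class SimulatedDataset:
    dataset: MultiLocusDataset
    #: locus name -> tuple of ((start, stop), genealogy) per block
    true_trees: Mapping[str, tuple]
    truth_labels: Mapping[str, str]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Genealogies (internal light-weight representation)


class _SimNode:
    __slots__ = ("children", "height", "label")

    def __init__(self, height: float = 0.0, label: str | None = None):
        self.children: list[_SimNode] = []
        self.height = height
        self.label = label

    def leaves(self):
        if not self.children:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()


def _copy_subtree(node: _SimNode, mapping: dict) -> _SimNode:
    clone = _SimNode(node.height, node.label)
    mapping[id(node)] = clone
    clone.children = [_copy_subtree(c, mapping) for c in node.children]
    return clone


def _kingman(labels: Sequence[str], rng: np.random.Generator,
             start_height: float = 0.0,
             stop_height: float | None = None,
             lineages: list[_SimNode] | None = None
             ) -> list[_SimNode]:
    """Pairwise coalescence with Exp(k(k-1)/2) waiting times.

    Returns the surviving lineages (a single root, unless ``stop_height``
    truncated the process first).
    """
    if lineages is None:
        lineages = [_SimNode(0.0, lab) for lab in labels]
    t = start_height
    while len(lineages) > 1:
        k = len(lineages)
        t_next = t + rng.exponential(2.0 / (k * (k - 1)))
        if stop_height is not None and t_next > stop_height:
            return lineages
        t = t_next
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        parent = _SimNode(t)
        parent.children = [lineages[i], lineages[j]]
        lineages = [x for k_, x in enumerate(lineages) if k_ not in (i, j)]
        lineages.append(parent)
    return lineages


def _to_dendropy(root: _SimNode, taxa: dendropy.TaxonNamespace | None = None
                 ) -> dendropy.Tree:
    if taxa is None:
        taxa = dendropy.TaxonNamespace(sorted(lf.label for lf in root.leaves()))
    tree = dendropy.Tree(taxon_namespace=taxa)

    def _build(sim_node, dp_node):
        for child in sim_node.children:
            dp_child = dendropy.Node()
            dp_node.add_child(dp_child)
            dp_child.edge.length = sim_node.height - child.height
            if child.children:
                _build(child, dp_child)
            else:
                dp_child.taxon = taxa.get_taxon(child.label)

    _build(root, tree.seed_node)
    tree.is_rooted = True
    return tree


def simulate_coalescent_tree(n: int, seed: int | None = None,
                             labels: Sequence[str] | None = None,
                             rng: np.random.Generator | None = None
                             ) -> dendropy.Tree:
    """A standard Kingman coalescent genealogy for ``n`` haploid lineages.

    Leaves are labelled s1..sn unless ``labels`` is given.  E[time to the most
    recent common ancestor] = 2(1 - 1/n) coalescent units.
    """
    if n < 2:
        raise SizeError("coalescent simulation needs n >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"s{i}" for i in range(1, n + 1)]
    root = _kingman(labels, rng)[0]
    return _to_dendropy(root)


def tree_height(tree: dendropy.Tree) -> float:
    """Root-to-leaf distance (trees from this module are ultrametric)."""
    node = next(tree.seed_node.leaf_iter())
    h = 0.0
    while node.parent_node is not None:
        h += node.edge.length
        node = node.parent_node
    return h


# ---------------------------------------------------------------------------
# Mutation models


def _edge_table(tree: dendropy.Tree):
    edges, lengths = [], []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        edges.append(node)
        lengths.append(node.edge.length)
    return edges, np.asarray(lengths, dtype=float)


def evolve_sequences(tree: dendropy.Tree, length: int, theta: float,
                     model: str = "infinite_sites",
                     seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     locus_name: str = "simulated",
                     on_capacity: str = "error") -> LocusAlignment:
    """Drop mutations on a genealogy and return the leaf alignment.

    infinite_sites: Poisson(theta/2 * total branch length) mutations, each at
    a distinct column (guarantees zero homoplasy); more mutations than columns
    raises :class:`CapacityError` (or redraws, with on_capacity='resample').
    JC: per-site substitution rate theta/(2*length) along every branch, with
    Jukes-Cantor replacement (recurrent mutation possible).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    edges, lengths = _edge_table(tree)
    total = float(lengths.sum())

    if model == "infinite_sites":
        for _attempt in range(1000):
            m = int(rng.poisson(theta / 2.0 * total))
            if m <= length:
                break
            if on_capacity != "resample":
                raise CapacityError(
                    f"{m} infinite-sites mutations but only {length} columns")
        else:
            raise CapacityError("could not draw <= length mutations")
        anc = rng.integers(0, 4, size=length)
        matrix = np.tile(anc, (n, 1))
        if m > 0:
            positions = rng.choice(length, size=m, replace=False)
            probs = lengths / total if total > 0 else None
            which = rng.choice(len(edges), size=m, p=probs)
            leaf_index = {id(lf): k for k, lf in enumerate(leaves)}
            below_cache: dict[int, np.ndarray] = {}
            for pos, ei in zip(positions, which):
                node = edges[int(ei)]
                key = id(node)
                if key not in below_cache:
                    below_cache[key] = np.array(
                        [leaf_index[id(lf)] for lf in node.leaf_iter()], dtype=int)
                rows = below_cache[key]
                derived = (anc[pos] + rng.integers(1, 4)) % 4
                matrix[rows, pos] = derived
    elif model == "JC":
        rate = theta / (2.0 * length)
        states: dict[int, np.ndarray] = {
            id(tree.seed_node): rng.integers(0, 4, size=length)}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            parent_state = states[id(node.parent_node)]
            p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * node.edge.length))
            hit = rng.random(length) < p_change
            state = parent_state.copy()
            k = int(hit.sum())
            if k:
                state[hit] = (state[hit] + rng.integers(1, 4, size=k)) % 4
            states[id(node)] = state
        matrix = np.vstack([states[id(lf)] for lf in leaves])
    else:
        raise ConfigError(f"unknown mutation model {model!r}")
    rows = _BASES[matrix]
    return LocusAlignment(locus_name, tuple(labels), rows)


# ---------------------------------------------------------------------------
# Multilocus scenarios


def _block_ranges(length: int, n_blocks: int):
    cuts = np.linspace(0, length, n_blocks + 1).astype(int)
    return [(int(cuts[k]), int(cuts[k + 1])) for k in range(n_blocks)]


def _finalise(config, per_locus_alignments, true_trees, labels_map,
              strain_order):
    manifest = tuple(
        StrainRecord(strain_id=s, subclade_label=labels_map[s])
        for s in strain_order)
    loci = tuple(a.take(strain_order) for a in per_locus_alignments)
    dataset = dataset_from_alignments(loci, manifest)
    return SimulatedDataset(dataset, true_trees, dict(labels_map), config)


def simulate_multilocus(config: SimulationConfig) -> SimulatedDataset:
    """Generate one dataset under the configured scenario (see module docs)."""
    if config.mode == "border_scenario":
        return simulate_border_scenario(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_strains
    strain_order = [f"s{i}" for i in range(1, n + 1)]
    locus_names = [f"locus{k + 1}" for k in range(config.n_loci)]

    if config.mode == "structured":
        n1, n2 = config.deme_sizes
        labels_map = {s: ("deme1" if i < n1 else "deme2")
                      for i, s in enumerate(strain_order)}
    elif config.mode == "clonal":
        labels_map = {s: "clonal_core" for s in strain_order}
    else:
        labels_map = {s: "recombining" for s in strain_order}

    def _draw_tree() -> dendropy.Tree:
        if config.mode == "structured":
            n1, _ = config.deme_sizes
            tau = config.divergence_time
            l1 = _kingman(strain_order[:n1], rng, stop_height=tau)
            l2 = _kingman(strain_order[n1:], rng, stop_height=tau)
            merged = _kingman([], rng, start_height=tau, lineages=l1 + l2)
            return _to_dendropy(merged[0])
        return simulate_coalescent_tree(n, labels=strain_order, rng=rng)

    shared = _draw_tree() if config.mode == "clonal" else None
    alignments, true_trees = [], {}
    for name, length, theta in zip(locus_names, config.locus_lengths,
                                   config.theta_per_locus):
        if config.mode == "intralocus":
            parts, trees = [], []
            for (start, stop) in _block_ranges(length, config.n_blocks):
                tree = _draw_tree()
                block_len = stop - start
                aln = evolve_sequences(tree, block_len,
                                       theta * block_len / length,
                                       model=config.mutation_model, rng=rng,
                                       locus_name=name)
                parts.append(aln.take(strain_order).rows)
                trees.append(((start, stop), tree))
            rows = np.hstack(parts)
            alignments.append(LocusAlignment(name, tuple(strain_order), rows))
            true_trees[name] = tuple(trees)
        else:
            tree = shared if shared is not None else _draw_tree()
            aln = evolve_sequences(tree, length, theta,
                                   model=config.mutation_model, rng=rng,
                                   locus_name=name)
            alignments.append(aln.take(strain_order))
            true_trees[name] = (((0, length), tree),)
    return _finalise(config, alignments, true_trees, labels_map, strain_order)


# ---------------------------------------------------------------------------
# Border scenario


def _attachment_edges(core_root: _SimNode):
    """Edges of the core crown group as (child_node, low_height, high_height)."""
    out = []

    def _walk(node):
        for child in node.children:
            out.append((child, child.height, node.height))
            _walk(child)

    _walk(core_root)
    return out


def simulate_border_scenario(config: SimulationConfig) -> SimulatedDataset:
    """Clonal core + recombining halo + distant controls.

    The core and the controls share one genealogy in every block of every
    locus (a clonal backbone: the core is a tight crown clade, the controls
    hang off a ladder of long branches above it).  Each halo strain has a
    "home" attachment point inside the core crown; in each block it re-draws
    that attachment with probability ``halo_intensity``, which makes its
    sequence a mosaic of different positions within the core — the classic
    signature of recombination.  ``halo_intensity = 0`` collapses to full
    clonality.
    """
    if config.mode != "border_scenario":
        raise ConfigError("config.mode must be 'border_scenario'")
    rng = np.random.default_rng(config.seed)
    core = [f"core{i}" for i in range(1, config.core_size + 1)]
    halo = [f"halo{i}" for i in range(1, config.halo_size + 1)]
    ctrl = [f"ctrl{i}" for i in range(1, config.control_size + 1)]
    strain_order = core + halo + ctrl
    labels_map = {s: "clonal_core" for s in core}
    labels_map.update({s: "recombining" for s in halo})
    labels_map.update({s: "control" for s in ctrl})

    # backbone: core crown + control ladder, fixed for the whole scenario
    core_root = _kingman(core, rng)[0]
    spine = core_root
    h = core_root.height
    for c in ctrl:
        h += config.control_spacing
        node = _SimNode(h)
        node.children = [spine, _SimNode(0.0, c)]
        spine = node
    backbone_root = spine

    edges = _attachment_edges(core_root)
    lengths = np.array([hi - lo for _, lo, hi in edges])
    probs = lengths / lengths.sum()

    def _draw_attachment():
        k = int(rng.choice(len(edges), p=probs))
        child, lo, hi = edges[k]
        return (id(child), float(rng.uniform(lo, hi)))

    home = {s: _draw_attachment() for s in halo}
    node_by_id = {}

    def _index(node):
        node_by_id[id(node)] = node
        for c in node.children:
            _index(c)

    _index(backbone_root)

    locus_names = [f"locus{k + 1}" for k in range(config.n_loci)]
    alignments, true_trees = [], {}
    for name, length, theta in zip(locus_names, config.locus_lengths,
                                   config.theta_per_locus):
        parts, trees = [], []
        for (start, stop) in _block_ranges(length, config.n_blocks):
            atts = {}
            for s in halo:
                if rng.random() < config.halo_intensity:
                    atts[s] = _draw_attachment()
                else:
                    atts[s] = home[s]
            mapping: dict[int, _SimNode] = {}
            root = _copy_subtree(backbone_root, mapping)
            # graft halo leaves, innermost attachment first on each edge
            by_edge: dict[int, list] = {}
            for s, (child_id, height) in atts.items():
                by_edge.setdefault(child_id, []).append((height, s))
            for child_id, items in by_edge.items():
                child = mapping[child_id]
                parent = _parent_of(root, child)
                lower = child
                for height, s in sorted(items):
                    joint = _SimNode(height)
                    joint.children = [lower, _SimNode(0.0, s)]
                    lower = joint
                parent.children[parent.children.index(child)] = lower
            tree = _to_dendropy(root)
            block_len = stop - start
            aln = evolve_sequences(tree, block_len,
                                   theta * block_len / length,
                                   model=config.mutation_model, rng=rng,
                                   locus_name=name, on_capacity="resample")
            parts.append(aln.take(strain_order).rows)
            trees.append(((start, stop), tree))
        rows = np.hstack(parts)
        alignments.append(LocusAlignment(name, tuple(strain_order), rows))
        true_trees[name] = tuple(trees)
    return _finalise(config, alignments, true_trees, labels_map, strain_order)


def border_scenario_config(seed: int | None = None, **overrides) -> SimulationConfig:
    """The default border-scan study conditions.

    8 clonal core strains, 10 recombining halo strains, 5 distant controls;
    three 600-nt loci of 4 blocks each with theta = 16 per locus (per-site
    diversity comparable to the variable intron-bearing typing loci these
    scans are run on), full halo reshuffling, infinite-sites mutation.
    """
    params = dict(mode="border_scenario", n_strains=23,
                  locus_lengths=(600, 600, 600),
                  theta_per_locus=(16.0, 16.0, 16.0),
                  core_size=8, halo_size=10, control_size=5,
                  halo_intensity=1.0, control_spacing=0.4,
                  n_blocks=4, mutation_model="infinite_sites", seed=seed)
    params.update(overrides)
    return SimulationConfig(**params)


def _parent_of(root: _SimNode, target: _SimNode) -> _SimNode:
    for node in _iter_nodes(root):
        if target in node.children:
            return node
    raise RuntimeError("target is the root")


def _iter_nodes(root: _SimNode):
    yield root
    for c in root.children:
        yield from _iter_nodes(c)
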