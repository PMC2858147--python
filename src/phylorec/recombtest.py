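"""Recombination detectors: Phi test, index of association, partition homogeneity.

All three are permutation tests; p-values use the (1 + b)/(n + 1) estimator so
they can never be exactly zero, and every result records the seed and the
parameters it was computed with.

Phi (the pairwise homoplasy index) scores the *refined incompatibility* of
pairs of polymorphic sites — the minimum number of extra (homoplasious) state
changes needed to fit both sites on any single tree — and averages it over
pairs of informative sites lying within a window of ``window_w`` alignment
positions of one another.  Under clonality any homoplasy is spread evenly
along the sequence; under recombination genealogical correlation decays with
distance, so *nearby* pairs are systematically more compatible than a random
re-arrangement of site positions would make them.  The permutation null
shuffles the informative sites among their positions and the test rejects in
the left tail (observed mean incompatibility unusually small).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

from . import _mp
from .errors import MonomorphicError, NotComputableError, SizeError
from .seqdata import LocusAlignment, MultiLocusDataset, SitePartition, clone_correct

# state codes: A,C,G,T -> 0..3; gap/ambiguity -> 4 (missing)
_MISSING = 4


def _encode(rows: np.ndarray) -> np.ndarray:
    lut = np.full(256, _MISSING, dtype=np.uint8)
    for k, c in enumerate("ACGT"):
        lut[ord(c)] = k
    return lut[rows.view(np.uint8)]


# ---------------------------------------------------------------------------
# Refined incompatibility of a site pair


def pair_incompatibility(site_a: Sequence, site_b: Sequence) -> int:
    """Refined incompatibility score of two aligned columns.

    Rows missing/ambiguous at either site are excluded pairwise.  With V the
    number of distinct joint states, C the number of connected components of
    the graph that links joint states sharing a state at either site, and
    k_a, k_b the per-site state counts, the score is

        l = (V - 1) + (C - 1) - (k_a - 1) - (k_b - 1)

    i.e. the minimum summed parsimony length of the two sites on their best
    common tree, minus each site's own parsimony floor.  l = 0 iff the sites
    are compatible; the classic four-gamete conflict of two biallelic sites
    scores 1.
    """
    a = _encode(np.asarray(list(site_a), dtype="S1"))
    b = _encode(np.asarray(list(site_b), dtype="S1"))
    if a.shape != b.shape:
        raise ValueError("sites must cover the same taxa")
    ok = (a != _MISSING) & (b != _MISSING)
    if int(ok.sum()) < 2:
        raise NotComputableError("fewer than 2 usable taxa at this site pair")
    return _score_pair(a[ok], b[ok])


def _score_pair(a: np.ndarray, b: np.ndarray) -> int:
    """Closed-form refined incompatibility for complete-data state vectors."""
    joint = np.unique(a.astype(np.int16) * 8 + b)
    V = len(joint)
    sa = joint // 8
    sb = joint % 8
    k_a = len(np.unique(sa))
    k_b = len(np.unique(sb))
    # union-find over joint states; link states sharing either margin
    parent = list(range(V))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for group in (sa, sb):
        first: dict[int, int] = {}
        for idx, g in enumerate(group):
            g = int(g)
            if g in first:
                ra, rb = find(first[g]), find(idx)
                if ra != rb:
                    parent[rb] = ra
            else:
                first[g] = idx
    C = len({find(i) for i in range(V)})
    return (V - 1) + (C - 1) - (k_a - 1) - (k_b - 1)


# ---------------------------------------------------------------------------
# Phi test


@dataclass(frozen=True)
class PhiResult:
    phi: float
    window_w: int
    n_informative_sites: int
    p_permutation: float
    p_analytic: float | None
    n_permutations: int
    seed: int | None

    @property
    def significant(self) -> bool:
        return self.p_permutation < 0.05


def informative_site_indices(codes: np.ndarray) -> np.ndarray:
    """Columns with >= 2 states each carried by >= 2 sequences (missing ignored)."""
    out = []
    for j in range(codes.shape[1]):
        col = codes[:, j]
        col = col[col != _MISSING]
        if col.size < 4:
            continue
        _, counts = np.unique(col, return_counts=True)
        if int((counts >= 2).sum()) >= 2:
            out.append(j)
    return np.asarray(out, dtype=int)


def _incompatibility_matrix(cols: np.ndarray) -> np.ndarray:
    """(q, n) informative columns -> (q, q) pairwise refined-incompatibility.

    Biallelic complete-data pairs are scored wholesale by the four-gamete
    rule (vectorised); anything involving a third state or missing data falls
    back to the closed form, which the four-gamete rule is a special case of.
    """
    q, n = cols.shape
    M = np.zeros((q, q))
    missing = (cols == _MISSING).any(axis=1)
    n_states = np.array([len(np.unique(c[c != _MISSING])) for c in cols])
    simple = (~missing) & (n_states == 2)
    idx = np.nonzero(simple)[0]
    if idx.size >= 2:
        sub = cols[idx]
        minor = sub.min(axis=1, keepdims=True)
        B = (sub != minor).astype(np.int64)  # 0/1 by state identity
        Bc = 1 - B
        n11 = B @ B.T
        n10 = B @ Bc.T
        n00 = Bc @ Bc.T
        four = (n11 > 0) & (n10 > 0) & (n10.T > 0) & (n00 > 0)
        M[np.ix_(idx, idx)] = four.astype(float)
    hard = np.nonzero(~simple)[0]
    for i in hard:
        for j in range(q):
            if j == i:
                continue
            a, b = cols[i], cols[j]
            ok = (a != _MISSING) & (b != _MISSING)
            if int(ok.sum()) < 2:
                continue
            M[i, j] = M[j, i] = _score_pair(a[ok], b[ok])
    return M


def phi_test(alignment: LocusAlignment, window_w: int = 100,
             n_permutations: int = 1000, seed: int | None = None,
             analytic: bool = False) -> PhiResult:
    """Pairwise homoplasy index test for recombination.

    Small p-values mean the observed mean incompatibility of nearby
    informative-site pairs is lower than expected if incompatibility were
    position-independent — the signature of recombination.
    """
    if alignment.n_strains < 4:
        raise SizeError("phi test needs >= 4 sequences")
    codes = _encode(alignment.rows)
    info = informative_site_indices(codes)
    q = info.size
    if q < 2:
        raise NotComputableError(
            f"only {q} informative site(s); Phi is undefined")
    positions = info
    cols = codes[:, info].T  # (q, n)
    M = _incompatibility_matrix(cols)
    # index pairs of *positions* within the window
    pi, pj = np.triu_indices(q, k=1)
    in_window = (positions[pj] - positions[pi]) <= window_w
    pi, pj = pi[in_window], pj[in_window]
    if pi.size == 0:
        raise NotComputableError("no informative-site pair within the window")
    phi_obs = float(M[pi, pj].mean())
    rng = np.random.default_rng(seed)
    b = 0
    perm_values = np.empty(n_permutations)
    for k in range(n_permutations):
        perm = rng.permutation(q)
        perm_values[k] = M[perm[pi], perm[pj]].mean()
    b = int((perm_values <= phi_obs + 1e-12).sum())
    p_perm = (1 + b) / (n_permutations + 1)
    p_analytic = None
    if analytic:
        mu = float(perm_values.mean())
        sd = float(perm_values.std())
        if sd == 0:
            p_analytic = 1.0
        else:
            z = (phi_obs - mu) / sd
            p_analytic = 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
    return PhiResult(phi=phi_obs, window_w=window_w, n_informative_sites=int(q),
                     p_permutation=p_perm, p_analytic=p_analytic,
                     n_permutations=n_permutations, seed=seed)


# ---------------------------------------------------------------------------
# Index of association


@dataclass(frozen=True)
class IAResult:
    ia: float
    v_obs: float
    v_exp: float
    p_permutation: float
    n_haplotypes_after_clone_correction: int
    n_permutations: int
    seed: int | None
    #: the informal reading used in clonality studies: IA well below 1 is read
    #: as consistent with recombination, above 1 as clonality.  The permutation
    #: p-value is the formal result.
    heuristic_reading: str = ""


def index_of_association(dataset: MultiLocusDataset, n_permutations: int = 999,
                         seed: int | None = None,
                         apply_clone_correction: bool = True) -> IAResult:
    """Index of association over multilocus haplotypes.

    Per-locus alleles are the distinct sequence strings at that locus; the
    pairwise distance between two haplotypes is the number of loci at which
    their alleles differ.  IA = V_obs / V_exp - 1, where V_obs is the variance
    of that distance over all pairs and V_exp the sum of the per-locus
    mismatch-indicator variances (its expectation under linkage equilibrium).
    The null permutes allele assignments independently at each locus; large IA
    (association between loci) is the clonality signal, so p counts
    permutations with IA >= observed.
    """
    if apply_clone_correction:
        dataset, _ = clone_correct(dataset)
    n = dataset.n_strains
    if n < 3:
        raise SizeError(
            f"only {n} haplotype(s) after clone correction; need >= 3")
    alleles = []
    for aln in dataset.loci:
        _, inv = np.unique(aln.rows, axis=0, return_inverse=True)
        if len(set(inv.tolist())) > 1:
            alleles.append(np.asarray(inv, dtype=int))
    if len(alleles) < 2:
        raise MonomorphicError(
            "fewer than 2 polymorphic loci; IA is undefined")
    A = np.vstack(alleles)  # (n_loci, n)
    i, j = np.triu_indices(n, k=1)

    def _ia(mat: np.ndarray) -> tuple[float, float, float]:
        mism = (mat[:, i] != mat[:, j])  # (n_loci, n_pairs)
        d = mism.sum(axis=0)
        v_obs = float(d.var())
        v_exp = float(mism.var(axis=1).sum())
        return v_obs / v_exp - 1.0, v_obs, v_exp

    ia, v_obs, v_exp = _ia(A)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_permutations):
        permuted = np.vstack([row[rng.permutation(n)] for row in A])
        if _ia(permuted)[0] >= ia - 1e-12:
            b += 1
    p = (1 + b) / (n_permutations + 1)
    reading = ("IA > 1: consistent with clonality (informal reading)"
               if ia > 1 else
               "IA < 1: consistent with recombination (informal reading)")
    return IAResult(ia=ia, v_obs=v_obs, v_exp=v_exp, p_permutation=p,
                    n_haplotypes_after_clone_correction=n,
                    n_permutations=n_permutations, seed=seed,
                    heuristic_reading=reading)


# ---------------------------------------------------------------------------
# Partition homogeneity (incongruence length difference) test


@dataclass(frozen=True)
class PHTResult:
    t_obs: int
    replicate_lengths: tuple[int, ...]
    p_value: float
    n_replicates: int
    seed: int | None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def pht_test(concatenated: LocusAlignment, partition: SitePartition,
             n_replicates: int = 1000, seed: int | None = None,
             search_opts: dict | None = None) -> PHTResult:
    """Partition homogeneity test (incongruence length difference).

    T = sum over partitions of the maximum-parsimony tree length on that
    partition's columns.  Replicates reassign columns to partitions at random
    (sizes preserved) and recompute T; congruent (clonal) data give T_obs
    similar to the replicates, while recombination between partitions makes
    T_obs smaller (each locus fits its own tree better than a random mixture
    does), so p = (1 + #{T_rep <= T_obs}) / (n_replicates + 1).
    """
    if len(partition.boundaries) < 2:
        raise SizeError("partition homogeneity test needs >= 2 partitions")
    if concatenated.n_strains < 4:
        raise SizeError("partition homogeneity test needs >= 4 taxa")
    opts = {"n_starts": 1, "mode": "heuristic"}
    if search_opts:
        opts.update(search_opts)
    rng = np.random.default_rng(seed)
    labels = partition.column_labels()
    n_parts = len(partition.boundaries)
    n_taxa = concatenated.n_strains
    masks = _mp.encode_columns(concatenated.rows)

    def _length(cols: np.ndarray, search_rng) -> int:
        patterns, weights = _mp.compress_patterns(masks[:, cols])
        if weights.size == 0:
            return 0
        if opts["mode"] == "exact":
            return _mp.exact_search(patterns, weights, n_taxa)[1]
        return _mp.heuristic_search(patterns, weights, n_taxa,
                                    opts["n_starts"], search_rng)[1]

    def _total(col_labels: np.ndarray) -> int:
        search_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
        return sum(_length(np.nonzero(col_labels == k)[0], search_rng)
                   for k in range(n_parts))

    for k, (name, start, stop) in enumerate(partition.boundaries):
        if _mp.compress_patterns(masks[:, start:stop])[1].size == 0:
            logger.warning("pht_test: partition %r has no variable columns "
                           "(contributes length 0)", name)
    t_obs = _total(labels)
    reps = []
    for _ in range(n_replicates):
        shuffled = labels[rng.permutation(labels.size)]
        reps.append(_total(shuffled))
    reps_arr = np.asarray(reps)
    b = int((reps_arr <= t_obs).sum())
    p = (1 + b) / (n_replicates + 1)
    return PHTResult(t_obs=int(t_obs), replicate_lengths=tuple(int(x) for x in reps),
                     p_value=p, n_replicates=n_replicates, seed=seed)
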