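import math

import numpy as np
import pytest

from phylorec import (
    clades_compatible,
    distance_matrix,
    extract_clades,
    fitch_length,
    mp_search,
    neighbor_joining,
    parse_tree,
    patristic_distance,
    patristic_matrix,
)
from phylorec.errors import DistanceError, SaturationError, SizeError
from phylorec.treekit import DistanceMatrix, bipartitions
from phylorec.simgen import SimulationConfig, simulate_multilocus
from phylorec.seqdata import concatenate

import _oracles
from conftest import make_alignment, random_alignment


class TestDistances:
    def test_identical_sequences_zero(self):
        aln = make_alignment("l", "ab", ["ACGTACGT", "ACGTACGT"])
        for model in ("p", "K3ST"):
            assert distance_matrix(aln, model).get("a", "b") == 0.0

    def test_p_distance_half(self):
        aln = make_alignment("l", "ab", ["AAAA", "AATT"])
        assert distance_matrix(aln, "p").get("a", "b") == 0.5

    def test_pairwise_deletion(self):
        aln = make_alignment("l", "ab", ["AC-T", "ACNT"])
        # only 3 columns comparable, all matching
        assert distance_matrix(aln, "p").get("a", "b") == 0.0

    def test_k3st_matches_closed_form_recount(self, rng):
        for _ in range(10):
            s1 = "".join(rng.choice(list("ACGT"), size=400))
            # moderately diverged partner (15% random substitutions)
            s2 = list(s1)
            for j in np.nonzero(rng.random(400) < 0.15)[0]:
                s2[j] = rng.choice([c for c in "ACGT" if c != s1[j]])
            s2 = "".join(s2)
            aln = make_alignment("l", ["x", "y"], [s1, s2])
            P = sum(a != b and {a, b} in ({"A", "G"}, {"C", "T"})
                    for a, b in zip(s1, s2)) / 400
            Q = sum({a, b} in ({"A", "T"}, {"G", "C"})
                    for a, b in zip(s1, s2)) / 400
            R = sum({a, b} in ({"A", "C"}, {"G", "T"})
                    for a, b in zip(s1, s2)) / 400
            expect = -0.25 * math.log((1 - 2 * P - 2 * Q) * (1 - 2 * P - 2 * R)
                                      * (1 - 2 * Q - 2 * R))
            got = distance_matrix(aln, "K3ST").get("x", "y")
            assert got == pytest.approx(expect, rel=1e-12)

    def test_saturation_error_names_pair(self):
        aln = make_alignment("l", "ab", ["ACGT" * 5, "GACT" * 5])
        with pytest.raises(SaturationError, match="'a'.*'b'"):
            distance_matrix(aln, "K3ST")

    def test_no_comparable_sites(self):
        aln = make_alignment("l", "ab", ["A---", "-CGT"])
        with pytest.raises(DistanceError):
            distance_matrix(aln, "p")


class TestNeighborJoining:
    def test_three_taxa_three_point(self):
        ids = ("a", "b", "c")
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(ids, d))
        # three-point solution: la=1, lb=2, lc=3
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_additive_matrix_recovered_exactly(self):
        src = parse_tree("((a:1,b:2):1.5,(c:0.5,d:1):2,(e:3,f:0.25):0.5);")
        dm = patristic_matrix(src)
        tree = neighbor_joining(dm)
        assert bipartitions(tree) == bipartitions(src)
        dm2 = patristic_matrix(tree)
        np.testing.assert_allclose(dm2.values, dm.values, atol=1e-12)

    def test_equal_distances_zero_internal_lengths(self):
        ids = tuple("abcd")
        d = np.ones((4, 4)) - np.eye(4)
        tree = neighbor_joining(DistanceMatrix(ids, d))
        internal = [nd.edge.length for nd in tree.preorder_node_iter()
                    if not nd.is_leaf() and nd.parent_node is not None]
        assert all(x == pytest.approx(0.0, abs=1e-12) for x in internal)

    def test_too_few_taxa(self):
        with pytest.raises(SizeError):
            neighbor_joining(DistanceMatrix(("a", "b"), np.zeros((2, 2))))

    def test_agrees_with_skbio(self, rng):
        """Cross-check against an independent NJ implementation."""
        import skbio
        src = parse_tree("((a:1,b:2):0.7,((c:0.5,d:1):0.4,e:2):0.9,f:1.2);")
        dm = patristic_matrix(src)
        ours = neighbor_joining(dm)
        sk = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=list(dm.ids)))
        sk_tree = parse_tree(str(sk))
        assert bipartitions(ours) == bipartitions(sk_tree)


class TestFitchAndSearch:
    def test_constant_column_zero(self):
        tree = parse_tree("((a,b),(c,d));")
        aln = make_alignment("l", "abcd", ["A", "A", "A", "A"])
        assert fitch_length(tree, aln) == 0

    def test_split_column_one_change(self):
        tree = parse_tree("((a1,a2),(c1,c2));")
        aln = make_alignment("l", ["a1", "a2", "c1", "c2"],
                             ["A", "A", "C", "C"])
        assert fitch_length(tree, aln) == 1

    def test_matches_exhaustive_oracle_on_random_columns(self, rng):
        """Fitch on a fixed tree >= exhaustive minimum; equality at the best
        tree found by exact search (6 taxa, all 105 topologies)."""
        ids = list("abcdef")
        for _ in range(5):
            aln = random_alignment(rng, 6, 8, ids=ids)
            cols = [{t: aln.sequence(t)[j] for t in ids}
                    for j in range(aln.length)]
            oracle_best = _oracles.min_parsimony_length(ids, cols)
            tree, length = mp_search(aln, mode="exact")
            assert length == oracle_best
            assert fitch_length(tree, aln) == length

    def test_invariant_to_rerooting_and_leaf_order(self, rng):
        ids = list("abcdefg")
        aln = random_alignment(rng, 7, 12, ids=ids)
        t1 = parse_tree("((a,(b,c)),(d,e),(f,g));")
        length = fitch_length(t1, aln)
        t2 = parse_tree("(((d,e),(f,g)),a,(b,c));")  # same unrooted topology
        assert fitch_length(t2, aln) == length
        shuffled = aln.take(list(np.array(ids)[rng.permutation(7)]))
        assert fitch_length(t1, shuffled) == length

    def test_heuristic_matches_exact_on_strong_signal(self):
        cfg = SimulationConfig(n_strains=7, n_loci=1, locus_lengths=(200,),
                               theta_per_locus=(8.0,), mode="clonal", seed=42)
        sim = simulate_multilocus(cfg)
        concat, _ = concatenate(sim.dataset)
        _, exact_len = mp_search(concat, mode="exact")
        _, heur_len = mp_search(concat, n_starts=4, seed=0)
        assert heur_len == exact_len

    def test_all_constant_alignment_zero(self):
        aln = make_alignment("l", "abcde", ["AAAA"] * 5)
        _, length = mp_search(aln, seed=0)
        assert length == 0

    def test_three_taxa_single_topology(self):
        aln = make_alignment("l", "abc", ["AC", "AG", "CG"])
        tree, _ = mp_search(aln, seed=0)
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == set("abc")


class TestClades:
    def test_star_tree_empty(self):
        tree = parse_tree("(a,b,c,d,e);")
        assert extract_clades(tree, 0.95).splits == ()

    def test_resolved_five_taxon_counts(self):
        tree = parse_tree("((a,b)0.99,((c,d)0.99,e)0.99);")
        table = extract_clades(tree, 0.95)
        assert len(table.splits) == 2  # n - 3 non-trivial splits

    def test_threshold_boundary(self):
        tree = parse_tree("((a,b)0.94,((c,d)0.96,e));")
        table = extract_clades(tree, 0.95)
        assert [set(s) for s, _ in table.splits] == [{"c", "d"}]

    def test_sides_partition_leafset(self):
        tree = parse_tree("((a,b)0.99,((c,d)0.99,e)0.99);")
        table = extract_clades(tree, 0.95)
        for side, _ in table.splits:
            assert side and side < table.taxa

    def test_compatibility(self):
        s = frozenset
        taxa = s("abcd")
        assert clades_compatible((s("ab"), s("cd")), (s("ab"), s("cd")), taxa)
        assert not clades_compatible((s("ab"), s("cd")), (s("ac"), s("bd")),
                                     taxa)
        # degenerate: < 4 shared taxa is vacuously compatible
        assert clades_compatible((s("ab"), s("c")), (s("ac"), s("b")), s("abc"))


class TestPatristic:
    def test_cherry(self):
        tree = parse_tree("(a:1,b:2);")
        assert patristic_distance(tree, "a", "b") == 3.0
        assert patristic_distance(tree, "a", "a") == 0.0

    def test_matches_traversal_oracle(self, rng):
        tree = parse_tree("((a:1,b:2):1.5,(c:0.5,d:1):2,(e:3,f:0.25):0.5);")
        oracle = _oracles.patristic_all_pairs(tree)
        pm = patristic_matrix(tree)
        for i, x in enumerate(pm.ids):
            for j, y in enumerate(pm.ids):
                assert pm.values[i, j] == pytest.approx(oracle[(x, y)])
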