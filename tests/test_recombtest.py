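import numpy as np
import pytest

from phylorec import (
    concatenate,
    dataset_from_alignments,
    index_of_association,
    pair_incompatibility,
    pht_test,
    phi_test,
)
from phylorec.errors import (
    MonomorphicError,
    NotComputableError,
    SizeError,
)
from phylorec.simgen import SimulationConfig, simulate_multilocus

import _oracles
from conftest import make_alignment


class TestPairIncompatibility:
    def test_compatible_split(self):
        assert pair_incompatibility("AAGG", "CCTT") == 0

    def test_four_gamete_conflict(self):
        assert pair_incompatibility("AAGG", "CTCT") == 1

    def test_symmetry_and_all_distinct(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=6))
            b = "".join(rng.choice(list("ACGT"), size=6))
            assert pair_incompatibility(a, b) == pair_incompatibility(b, a)
        # a site whose states are all distinct conflicts with nothing
        assert pair_incompatibility("ACGT", "AAGG") == 0

    def test_missing_rows_excluded_pairwise(self):
        # row 0 is missing at site b -> effective columns AGG / CCT
        assert pair_incompatibility("AAGG", "-CCT") == \
            pair_incompatibility("AGG", "CCT")

    def test_too_few_usable_taxa(self):
        with pytest.raises(NotComputableError):
            pair_incompatibility("A---", "-CGT")

    def test_matches_exhaustive_fitch_oracle(self, rng):
        """Closed form == min over all topologies of the joint Fitch length
        minus each site's parsimony floor (60 random pairs, <= 6 taxa)."""
        for _ in range(60):
            n = int(rng.integers(4, 7))
            ids = [f"t{i}" for i in range(n)]
            a = "".join(rng.choice(list("ACGT"), size=n,
                                   p=[0.4, 0.3, 0.2, 0.1]))
            b = "".join(rng.choice(list("ACGT"), size=n,
                                   p=[0.4, 0.3, 0.2, 0.1]))
            col_a = dict(zip(ids, a))
            col_b = dict(zip(ids, b))
            oracle = (_oracles.min_joint_pair_length(ids, col_a, col_b)
                      - _oracles.parsimony_floor(col_a)
                      - _oracles.parsimony_floor(col_b))
            assert pair_incompatibility(a, b) == oracle


class TestPhi:
    def test_infinite_sites_clonal_phi_zero_p_one(self):
        cfg = SimulationConfig(mode="clonal", seed=7)
        sim = simulate_multilocus(cfg)
        concat, _ = concatenate(sim.dataset)
        res = phi_test(concat, n_permutations=200, seed=1)
        assert res.phi == 0.0
        assert res.p_permutation == 1.0

    def test_detects_intralocus_recombination(self):
        cfg = SimulationConfig(mode="intralocus", seed=11)
        sim = simulate_multilocus(cfg)
        concat, _ = concatenate(sim.dataset)
        res = phi_test(concat, n_permutations=200, seed=1)
        assert res.p_permutation < 0.05

    def test_reproducible_given_seed(self):
        cfg = SimulationConfig(mode="intralocus", mutation_model="JC", seed=3)
        sim = simulate_multilocus(cfg)
        concat, _ = concatenate(sim.dataset)
        r1 = phi_test(concat, n_permutations=150, seed=9, analytic=True)
        r2 = phi_test(concat, n_permutations=150, seed=9, analytic=True)
        assert r1 == r2
        assert 1 / 151 <= r1.p_permutation <= 1.0

    def test_too_few_informative_sites(self):
        aln = make_alignment("l", "abcd", ["AAAA", "AAAA", "AAAT", "AAAT"])
        with pytest.raises(NotComputableError):
            phi_test(aln, seed=0)

    def test_needs_four_sequences(self):
        aln = make_alignment("l", "abc", ["AC", "AG", "CG"])
        with pytest.raises(SizeError):
            phi_test(aln, seed=0)

    def test_window_limits_pairs(self):
        # two informative sites 150 apart: no pair within a 100-nt window
        seqs = []
        for pattern in ("AA", "AA", "TT", "TT"):
            row = ["A"] * 200
            row[10] = pattern[0]
            row[160] = pattern[1]
            seqs.append("".join(row))
        aln = make_alignment("l", "abcd", seqs)
        with pytest.raises(NotComputableError):
            phi_test(aln, window_w=100, seed=0)
        res = phi_test(aln, window_w=199, seed=0)
        assert res.n_informative_sites == 2


class TestIndexOfAssociation:
    def _dataset(self, haplotypes):
        """haplotypes: list of tuples of per-locus allele symbols."""
        n_loci = len(haplotypes[0])
        ids = [f"s{i}" for i in range(len(haplotypes))]
        base = {"1": "AAAA", "2": "TTTT", "3": "CCCC", "4": "GGGG"}
        loci = []
        for k in range(n_loci):
            seqs = [base[str(h[k])] for h in haplotypes]
            loci.append(make_alignment(f"l{k}", ids, seqs))
        return dataset_from_alignments(loci)

    def test_perfect_association_worked_example(self):
        ds = self._dataset([(1, 1, 1), (1, 1, 1), (2, 2, 2), (2, 2, 2)])
        res = index_of_association(ds, n_permutations=99, seed=0,
                                   apply_clone_correction=False)
        assert res.ia == pytest.approx(2.0)
        assert "clonality" in res.heuristic_reading

    def test_clone_correction_makes_example_degenerate(self):
        ds = self._dataset([(1, 1, 1), (1, 1, 1), (2, 2, 2), (2, 2, 2)])
        with pytest.raises(SizeError):
            index_of_association(ds, seed=0)

    def test_invariant_to_allele_relabelling_and_locus_order(self):
        h1 = [(1, 1, 2), (1, 2, 2), (2, 1, 1), (2, 2, 1), (1, 2, 1)]
        swap = {1: 2, 2: 1}
        relabelled = [(swap[a], b, swap[c]) for a, b, c in h1]
        reordered = [(c, a, b) for a, b, c in h1]
        r0 = index_of_association(self._dataset(h1), n_permutations=49, seed=5)
        r1 = index_of_association(self._dataset(relabelled),
                                  n_permutations=49, seed=5)
        r2 = index_of_association(self._dataset(reordered),
                                  n_permutations=49, seed=5)
        assert r0.ia == pytest.approx(r1.ia)
        assert r0.ia == pytest.approx(r2.ia)

    def test_monomorphic_loci_dropped_then_error(self):
        ds = self._dataset([(1, 1, 1), (1, 1, 2), (1, 1, 1), (1, 1, 2)])
        # loci 0 and 1 monomorphic -> fewer than 2 polymorphic loci remain
        with pytest.raises(MonomorphicError):
            index_of_association(ds, seed=0, apply_clone_correction=False)

    def test_panmixia_mean_near_zero(self, rng):
        """Alleles drawn independently per locus: E[IA] ~ 0."""
        values = []
        for s in range(300):
            cfg = SimulationConfig(mode="free_recomb", n_strains=16,
                                   locus_lengths=(200, 200, 200),
                                   theta_per_locus=(5, 5, 5), seed=s)
            sim = simulate_multilocus(cfg)
            try:
                res = index_of_association(sim.dataset, n_permutations=0,
                                           seed=0)
            except (SizeError, MonomorphicError):
                continue
            values.append(res.ia)
        assert abs(float(np.mean(values))) < 0.05


class TestPHT:
    def test_identical_compatible_partitions_p_one(self):
        # both partitions are copies of the same mutually compatible columns:
        # every reassignment yields the same summed length
        cfg = SimulationConfig(n_strains=6, n_loci=1, locus_lengths=(120,),
                               theta_per_locus=(5.0,), mode="clonal", seed=2)
        sim = simulate_multilocus(cfg)
        aln = sim.dataset.loci[0]
        rows = np.hstack([aln.rows, aln.rows])
        from phylorec.seqdata import LocusAlignment, SitePartition
        double = LocusAlignment("dup", aln.strain_ids, rows)
        part = SitePartition((("a", 0, 120), ("b", 120, 240)))
        res = pht_test(double, part, n_replicates=100, seed=0)
        assert res.p_value == 1.0
        assert set(res.replicate_lengths) == {res.t_obs}

    def test_detects_conflicting_trees(self):
        cfg = SimulationConfig(n_strains=10, n_loci=2, locus_lengths=(150, 150),
                               theta_per_locus=(20, 20), mode="free_recomb",
                               mutation_model="JC", seed=4)
        sim = simulate_multilocus(cfg)
        concat, part = concatenate(sim.dataset)
        res = pht_test(concat, part, n_replicates=200, seed=0)
        assert res.p_value < 0.05

    def test_reproducible_and_p_bounds(self):
        cfg = SimulationConfig(n_strains=8, n_loci=2, locus_lengths=(100, 100),
                               theta_per_locus=(8, 8), mode="clonal",
                               mutation_model="JC", seed=5)
        sim = simulate_multilocus(cfg)
        concat, part = concatenate(sim.dataset)
        r1 = pht_test(concat, part, n_replicates=99, seed=3)
        r2 = pht_test(concat, part, n_replicates=99, seed=3)
        assert r1 == r2
        assert 1 / 100 <= r1.p_value <= 1.0

    def test_needs_two_partitions(self):
        from phylorec.seqdata import SitePartition
        aln = make_alignment("l", "abcd", ["ACGT", "AGGT", "ACTT", "TCGT"])
        with pytest.raises(SizeError):
            pht_test(aln, SitePartition((("a", 0, 4),)), seed=0)
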