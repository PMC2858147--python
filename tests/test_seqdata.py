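import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylorec import (
    assemble_dataset,
    clone_correct,
    concatenate,
    dataset_from_alignments,
    filter_columns,
    load_packaged_manifest,
    read_fasta_alignment,
    read_strain_manifest,
)
from phylorec.errors import (
    AlignmentError,
    AlphabetError,
    DatasetError,
    IdError,
    SchemaError,
)

from conftest import make_alignment, random_alignment


class TestFastaReading:
    def test_identity_parse(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">a\nACGTACGTAC\n>b\nacgtacgtac\n>c\nACGUACGUAC\n")
        aln = read_fasta_alignment(p, "tef1")
        assert aln.length == 10 and aln.n_strains == 3
        # lower case and U are normalised
        assert aln.sequence("b") == "ACGTACGTAC"
        assert aln.sequence("c") == "ACGTACGTAC"

    def test_ragged_input_rejected(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">a\nACGTACGTAC\n>b\nACGTACGTA\n")
        with pytest.raises(AlignmentError):
            read_fasta_alignment(p, "x")

    def test_duplicate_header_rejected(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(IdError):
            read_fasta_alignment(p, "x")

    def test_illegal_character_rejected(self):
        with pytest.raises(AlphabetError):
            make_alignment("x", "ab", ["ACGZ", "ACGT"])


class TestManifest:
    def test_packaged_table_complete(self):
        records = load_packaged_manifest()
        assert len(records) == 93
        assert all(r.is_complete for r in records)

    def test_packaged_subclades(self):
        records = load_packaged_manifest()
        hz = [r for r in records if r.subclade_label == "T. harzianum"]
        assert len(hz) == 16
        assert {r.strain_id for r in hz} == {f"hz.{i:02d}" for i in range(1, 17)}
        # teleomorph isolates (bold rows of the source table)
        assert sum(r.is_teleomorph for r in records) == 14
        # ex-type strains of T. harzianum, H. lixii and T. inhamatum
        assert {r.strain_id for r in records if r.is_ex_type} == {
            "hz.07", "li.13", "X.15"}

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("strain_id\talt_ids\torigin\n" "s1\t\t\n")
        with pytest.raises(SchemaError):
            read_strain_manifest(p)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("")
        with pytest.raises(SchemaError):
            read_strain_manifest(p)


class TestAssembly:
    def _alignments(self, ids_by_locus):
        return {name: make_alignment(name, ids, ["ACGT"] * len(ids))
                for name, ids in ids_by_locus.items()}

    def test_strict_success(self, toy_dataset):
        assert toy_dataset.n_strains == 4
        assert toy_dataset.locus_names == ("l1", "l2", "l3")

    def test_intersect_drops_partial_strain(self):
        from phylorec import StrainRecord
        manifest = [StrainRecord(strain_id=s) for s in "abcd"]
        alns = self._alignments({"l1": "abcd", "l2": "abc", "l3": "abcd"})
        ds = assemble_dataset(manifest, alns, policy="intersect")
        assert ds.strain_ids == ("a", "b", "c")

    def test_strict_missing_strain_errors(self):
        from phylorec import StrainRecord
        manifest = [StrainRecord(strain_id=s) for s in "abcd"]
        alns = self._alignments({"l1": "abcd", "l2": "abc"})
        with pytest.raises(DatasetError):
            assemble_dataset(manifest, alns, policy="strict")

    def test_empty_intersection_errors(self):
        from phylorec import StrainRecord
        manifest = [StrainRecord(strain_id=s) for s in "ab"]
        alns = self._alignments({"l1": "ab", "l2": "cd"})
        with pytest.raises(DatasetError):
            assemble_dataset(manifest, alns, policy="intersect")


class TestConcatenate:
    def test_lengths_and_ranges(self, rng):
        loci = [random_alignment(rng, 3, L, locus=f"l{k}")
                for k, L in enumerate((100, 200, 50))]
        ds = dataset_from_alignments(loci)
        concat, part = concatenate(ds)
        assert concat.length == 350
        assert part.boundaries == (("l0", 0, 100), ("l1", 100, 300),
                                   ("l2", 300, 350))

    def test_positional_round_trip(self, toy_dataset):
        concat, part = concatenate(toy_dataset)
        for aln in toy_dataset.loci:
            start, stop = part.range_of(aln.locus_name)
            np.testing.assert_array_equal(concat.rows[:, start:stop], aln.rows)

    def test_single_locus_identity(self):
        aln = make_alignment("only", "ab", ["ACGT", "AGGT"])
        ds = dataset_from_alignments([aln])
        concat, part = concatenate(ds)
        assert concat.sequences() == aln.sequences()
        assert part.total_length == 4


class TestCloneCorrection:
    def test_collapses_identical_pair(self, toy_dataset):
        reduced, groups = clone_correct(toy_dataset)
        assert reduced.n_strains == 3
        assert groups == {"a": ("a", "b")}

    def test_identity_when_all_distinct(self):
        loci = [make_alignment("l", "abc", ["AAAA", "AAAT", "AATT"])]
        ds = dataset_from_alignments(loci)
        reduced, groups = clone_correct(ds)
        assert reduced.strain_ids == ("a", "b", "c") and groups == {}

    def test_all_identical_degenerates_to_one(self):
        loci = [make_alignment("l", "abc", ["AAAA"] * 3)]
        ds = dataset_from_alignments(loci)
        reduced, groups = clone_correct(ds)
        assert reduced.strain_ids == ("a",)
        assert groups == {"a": ("a", "b", "c")}

    def test_idempotent(self, toy_dataset):
        once, _ = clone_correct(toy_dataset)
        twice, groups = clone_correct(once)
        assert twice.strain_ids == once.strain_ids and groups == {}


class TestColumnFilter:
    def test_no_gaps_identity(self, rng):
        aln = random_alignment(rng, 4, 30)
        out, removed = filter_columns(aln, 0.5)
        assert out.length == 30 and removed == []

    def test_all_gap_column_removed(self):
        aln = make_alignment("l", "ab", ["A-GT", "A-GT"])
        out, removed = filter_columns(aln, 0.5)
        assert out.length == 3 and removed == [1]
        assert out.sequences() == ["AGT", "AGT"]

    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_recount(self, seed, threshold):
        rng = np.random.default_rng(seed)
        rows = rng.choice(list("ACGT-N"), size=(5, 40),
                          p=[0.2, 0.2, 0.2, 0.2, 0.15, 0.05])
        seqs = ["".join(r) for r in rows]
        aln = make_alignment("l", "abcde", seqs)
        expected_keep = [
            j for j in range(40)
            if sum(s[j] in "-N" for s in seqs) / 5 <= threshold]
        if not expected_keep:
            with pytest.raises(AlignmentError):
                filter_columns(aln, threshold)
            return
        out, removed = filter_columns(aln, threshold)
        assert out.length == len(expected_keep)
        # order preserved: surviving columns equal the brute-force selection
        for new_j, old_j in enumerate(expected_keep):
            np.testing.assert_array_equal(out.rows[:, new_j],
                                          aln.rows[:, old_j])
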