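"""Strain manifests, per-locus alignments and multilocus datasets.

The in-memory model mirrors how multilocus sequence-typing studies of haploid
fungi are organised: a *manifest* of strains (one row per isolate, with
collection numbers, origin and one GenBank accession per locus), and one
aligned FASTA per locus whose headers are the manifest's strain ids.  A
:class:`MultiLocusDataset` ties the two together and guarantees that every
strain is present exactly once in every locus.

Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentError,
    AlphabetError,
    DatasetError,
    IdError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes (after 'U'->'T' normalisation) plus gap.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN-")

#: Characters that count as "missing/ambiguous" for column filtering,
#: pairwise deletion and informative-site detection.
AMBIGUOUS_CODES = frozenset("RYSWKMBDHVN-")

#: Map from IUPAC code to the set of concrete bases it may represent.
IUPAC_STATE_SETS: Mapping[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"), "-": frozenset("ACGT"),
}

REQUIRED_MANIFEST_COLUMNS = (
    "strain_id", "alt_ids", "origin", "habitat",
    "tef1", "cal1", "chi18-5", "subclade", "teleomorph", "ex_type",
)

#: Locus names of the three markers used for the species complex.
DEFAULT_LOCI = ("tef1", "cal1", "chi18-5")


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class StrainRecord:
    """One manifest row: a single haploid isolate."""

    strain_id: str
    alt_ids: tuple[str, ...] = ()
    origin: str = ""
    habitat: str = ""
    subclade_label: str = ""
    is_teleomorph: bool = False
    is_ex_type: bool = False
    accessions: Mapping[str, str] = field(default_factory=dict)

    @property
    def is_complete(self) -> bool:
        """True when an accession is recorded for all three standard loci."""
        return all(self.accessions.get(locus) for locus in DEFAULT_LOCI)


@dataclass(frozen=True)
class LocusAlignment:
    """An aligned set of sequences for one locus.

    ``rows`` is an (n_strains, length) array of single-byte characters; use
    :meth:`sequence` / :meth:`sequences` for string views.
    """

    locus_name: str
    strain_ids: tuple[str, ...]
    rows: np.ndarray  # dtype '|S1', shape (n, length)

    def __post_init__(self):
        if self.rows.ndim != 2:
            raise AlignmentError("alignment rows must form a 2-D array")
        if len(self.strain_ids) != self.rows.shape[0]:
            raise AlignmentError(
                f"{len(self.strain_ids)} ids but {self.rows.shape[0]} rows")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise IdError(f"duplicate strain ids in locus {self.locus_name!r}")
        observed = {c.decode() for c in np.unique(self.rows)}
        illegal = observed - IUPAC_CODES
        if illegal:
            raise AlphabetError(
                f"illegal characters {sorted(illegal)} in locus {self.locus_name!r}")

    @classmethod
    def from_sequences(cls, locus_name: str, ids: Sequence[str],
                       seqs: Sequence[str]) -> "LocusAlignment":
        seqs = [_normalise(s) for s in seqs]
        if not seqs:
            raise AlignmentError(f"locus {locus_name!r}: no sequences")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentError(
                f"locus {locus_name!r}: unequal row lengths {sorted(lengths)}")
        rows = np.array([list(s) for s in seqs], dtype="S1")
        return cls(locus_name, tuple(ids), rows)

    @property
    def n_strains(self) -> int:
        return self.rows.shape[0]

    @property
    def length(self) -> int:
        return self.rows.shape[1]

    def sequence(self, strain_id: str) -> str:
        try:
            i = self.strain_ids.index(strain_id)
        except ValueError:
            raise IdError(f"strain {strain_id!r} not in locus {self.locus_name!r}")
        return self.rows[i].tobytes().decode()

    def sequences(self) -> list[str]:
        return [row.tobytes().decode() for row in self.rows]

    def take(self, strain_ids: Sequence[str]) -> "LocusAlignment":
        """Restrict (and reorder) to the given strains."""
        index = {s: i for i, s in enumerate(self.strain_ids)}
        try:
            idx = [index[s] for s in strain_ids]
        except KeyError as exc:
            raise IdError(f"strain {exc.args[0]!r} not in locus {self.locus_name!r}")
        return LocusAlignment(self.locus_name, tuple(strain_ids), self.rows[idx])

    def slice_columns(self, start: int, stop: int) -> "LocusAlignment":
        return LocusAlignment(self.locus_name, self.strain_ids,
                              self.rows[:, start:stop])


@dataclass(frozen=True)
class SitePartition:
    """Half-open column ranges of each locus within a concatenated alignment."""

    boundaries: tuple[tuple[str, int, int], ...]  # (locus_name, start, stop)

    def __post_init__(self):
        pos = 0
        for name, start, stop in self.boundaries:
            if start != pos or stop < start:
                raise DatasetError("partition ranges must be contiguous and ordered")
            pos = stop

    @property
    def total_length(self) -> int:
        return self.boundaries[-1][2] if self.boundaries else 0

    def range_of(self, locus_name: str) -> tuple[int, int]:
        for name, start, stop in self.boundaries:
            if name == locus_name:
                return start, stop
        raise IdError(f"no locus {locus_name!r} in partition")

    def column_labels(self) -> np.ndarray:
        """Per-column partition index (0-based), length = total_length."""
        labels = np.empty(self.total_length, dtype=int)
        for k, (_, start, stop) in enumerate(self.boundaries):
            labels[start:stop] = k
        return labels


@dataclass(frozen=True)
class MultiLocusDataset:
    loci: tuple[LocusAlignment, ...]
    manifest: tuple[StrainRecord, ...]

    def __post_init__(self):
        names = [a.locus_name for a in self.loci]
        if len(set(names)) != len(names):
            raise DatasetError("locus names must be unique")
        ids = self.strain_ids
        for aln in self.loci:
            if tuple(aln.strain_ids) != ids:
                raise DatasetError(
                    f"locus {aln.locus_name!r} strain set/order differs from manifest")

    @property
    def strain_ids(self) -> tuple[str, ...]:
        return tuple(r.strain_id for r in self.manifest)

    @property
    def n_strains(self) -> int:
        return len(self.manifest)

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(a.locus_name for a in self.loci)

    def locus(self, name: str) -> LocusAlignment:
        for aln in self.loci:
            if aln.locus_name == name:
                return aln
        raise IdError(f"no locus {name!r}")

    def record(self, strain_id: str) -> StrainRecord:
        for rec in self.manifest:
            if rec.strain_id == strain_id:
                return rec
        raise IdError(f"no strain {strain_id!r}")

    def subset(self, strain_ids: Sequence[str]) -> "MultiLocusDataset":
        wanted = set(strain_ids)
        manifest = tuple(r for r in self.manifest if r.strain_id in wanted)
        if len(manifest) != len(wanted):
            missing = wanted - {r.strain_id for r in manifest}
            raise IdError(f"unknown strains {sorted(missing)}")
        order = tuple(r.strain_id for r in manifest)
        return MultiLocusDataset(tuple(a.take(order) for a in self.loci), manifest)


# ---------------------------------------------------------------------------
# I/O


def read_fasta_alignment(path, locus_name: str) -> LocusAlignment:
    """Read an aligned FASTA file into a :class:`LocusAlignment`.

    Rows are upper-cased and 'U' is normalised to 'T'.  Raises
    :class:`AlignmentError` on ragged input, :class:`IdError` on duplicate
    headers and :class:`AlphabetError` on non-IUPAC characters.
    """
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IdError(f"duplicate FASTA headers {dupes} in {path}")
    return LocusAlignment.from_sequences(locus_name, ids, seqs)


def write_fasta_alignment(alignment: LocusAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(alignment.strain_ids, alignment.sequences()):
            fh.write(f">{sid}\n{seq}\n")


def read_strain_manifest(path) -> list[StrainRecord]:
    """Read a tab-separated strain manifest.

    The header must contain the columns in :data:`REQUIRED_MANIFEST_COLUMNS`;
    ``alt_ids`` is ';'-separated, ``teleomorph``/``ex_type`` are 0/1 flags.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"manifest {path} is empty")
    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest {path} lacks required columns {missing}")
    if df.empty:
        raise SchemaError(f"manifest {path} has a header but no rows")
    records = []
    for _, row in df.iterrows():
        records.append(StrainRecord(
            strain_id=row["strain_id"],
            alt_ids=tuple(x for x in row["alt_ids"].split(";") if x),
            origin=row["origin"],
            habitat=row["habitat"],
            subclade_label=row["subclade"],
            is_teleomorph=row["teleomorph"] == "1",
            is_ex_type=row["ex_type"] == "1",
            accessions={loc: row[loc] for loc in DEFAULT_LOCI if row[loc]},
        ))
    ids = [r.strain_id for r in records]
    if len(set(ids)) != len(ids):
        raise IdError("duplicate strain ids in manifest")
    return records


def load_packaged_manifest() -> list[StrainRecord]:
    """The packaged 93-strain manifest of the *H. lixii / T. harzianum* complex."""
    ref = resources.files("phylorec.data") / "manifest_hlixii.tsv"
    with resources.as_file(ref) as path:
        return read_strain_manifest(path)


# ---------------------------------------------------------------------------
# Dataset assembly and manipulation


def assemble_dataset(manifest: Sequence[StrainRecord],
                     alignments: Mapping[str, LocusAlignment],
                     policy: str = "strict") -> MultiLocusDataset:
    """Combine a manifest with per-locus alignments.

    policy='strict' requires every manifest strain in every alignment;
    policy='intersect' keeps the strains present in all loci and logs drops.
    """
    if policy not in ("strict", "intersect"):
        raise DatasetError(f"unknown policy {policy!r}")
    manifest_ids = [r.strain_id for r in manifest]
    common = set(manifest_ids)
    for aln in alignments.values():
        common &= set(aln.strain_ids)
    if policy == "strict":
        for name, aln in alignments.items():
            missing = set(manifest_ids) - set(aln.strain_ids)
            if missing:
                raise DatasetError(
                    f"strains {sorted(missing)} missing from locus {name!r}")
        keep = manifest_ids
    else:
        dropped = [s for s in manifest_ids if s not in common]
        if dropped:
            logger.info("assemble_dataset: dropped strains %s", dropped)
        keep = [s for s in manifest_ids if s in common]
    if not keep:
        raise DatasetError("no strain is present in every locus")
    manifest_kept = tuple(r for r in manifest if r.strain_id in set(keep))
    loci = tuple(alignments[name].take(keep) for name in alignments)
    return MultiLocusDataset(loci, manifest_kept)


def concatenate(dataset: MultiLocusDataset) -> tuple[LocusAlignment, SitePartition]:
    """Concatenate all loci into one alignment (manifest row order).

    Returns the concatenated alignment and the :class:`SitePartition` that maps
    each locus to its half-open column range.
    """
    rows = np.hstack([aln.rows for aln in dataset.loci])
    boundaries, pos = [], 0
    for aln in dataset.loci:
        boundaries.append((aln.locus_name, pos, pos + aln.length))
        pos += aln.length
    concat = LocusAlignment("concatenated", dataset.strain_ids, rows)
    return concat, SitePartition(tuple(boundaries))


def clone_correct(dataset: MultiLocusDataset
                  ) -> tuple[MultiLocusDataset, dict[str, tuple[str, ...]]]:
    """Collapse strains with identical concatenated sequences.

    Identity is exact string equality on the aligned rows (gaps and ambiguity
    codes compared literally).  The representative of each group is the first
    strain in manifest order.  Returns the reduced dataset and a mapping
    representative -> group members, for groups of size >= 2 only.
    """
    concat, _ = concatenate(dataset)
    seen: dict[bytes, str] = {}
    groups: dict[str, list[str]] = {}
    keep = []
    for sid, row in zip(concat.strain_ids, concat.rows):
        key = row.tobytes()
        if key in seen:
            groups.setdefault(seen[key], [seen[key]]).append(sid)
        else:
            seen[key] = sid
            keep.append(sid)
    reduced = dataset.subset(keep)
    return reduced, {rep: tuple(members) for rep, members in groups.items()}


def filter_columns(alignment: LocusAlignment, max_gap_fraction: float
                   ) -> tuple[LocusAlignment, list[int]]:
    """Drop columns whose fraction of gap/ambiguity characters exceeds the threshold.

    A light-weight stand-in for alignment-trimming tools: any column in which
    more than ``max_gap_fraction`` of rows carry '-' or an ambiguity code is
    removed.  Column order is preserved.  Returns the filtered alignment and
    the list of removed column indices (original coordinates).
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    amb = np.frombuffer("".join(sorted(AMBIGUOUS_CODES)).encode(), dtype="S1")
    bad = np.isin(alignment.rows, amb)
    frac = bad.mean(axis=0)
    keep_mask = frac <= max_gap_fraction
    removed = [int(j) for j in np.nonzero(~keep_mask)[0]]
    if not keep_mask.any():
        raise AlignmentError("column filter removed every column")
    if removed:
        logger.info("filter_columns: removed %d/%d columns",
                    len(removed), alignment.length)
    filtered = LocusAlignment(alignment.locus_name, alignment.strain_ids,
                              alignment.rows[:, keep_mask])
    return filtered, removed


def dataset_from_alignments(loci: Iterable[LocusAlignment],
                            manifest: Sequence[StrainRecord] | None = None
                            ) -> MultiLocusDataset:
    """Convenience constructor: build a dataset from alignments alone.

    If no manifest is supplied, minimal records are synthesised from the first
    locus's strain order.
    """
    loci = tuple(loci)
    if manifest is None:
        manifest = tuple(StrainRecord(strain_id=s) for s in loci[0].strain_ids)
    order = tuple(r.strain_id for r in manifest)
    return MultiLocusDataset(tuple(a.take(order) for a in loci), tuple(manifest))
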