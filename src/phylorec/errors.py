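"""Exception hierarchy.

Every error raised by the library derives from :class:`PhylorecError`, so callers
(and the pipeline driver) can distinguish domain failures from programming bugs.
"""


class PhylorecError(Exception):
    """Base class for all library errors."""


class AlignmentError(PhylorecError):
    """Ragged rows, empty alignments, or otherwise malformed alignments."""


class AlphabetError(PhylorecError):
    """A sequence contains a character outside IUPAC nucleotide codes + '-'."""


class IdError(PhylorecError):
    """Duplicate, unknown or missing sequence/strain/leaf identifiers."""


class SchemaError(PhylorecError):
    """A tabular input lacks a required column."""


class DatasetError(PhylorecError):
    """Multilocus dataset assembly failed (e.g. empty strain intersection)."""


class DistanceError(PhylorecError):
    """A pairwise distance is undefined (no comparable sites)."""


class SaturationError(DistanceError):
    """The K3ST log argument is non-positive for a pair of sequences."""


class SizeError(PhylorecError):
    """Too few taxa/sequences for the requested operation."""


class NotComputableError(PhylorecError):
    """A test statistic is undefined on this input (e.g. < 2 informative sites)."""


class MonomorphicError(PhylorecError):
    """All (or too many) loci are monomorphic for an allele-based statistic."""


class BaselineError(PhylorecError):
    """The border-scan baseline sample already shows recombination."""


class ScanError(PhylorecError):
    """Border scan misconfiguration (e.g. empty candidate list)."""


class ConfigError(PhylorecError):
    """Invalid simulation or pipeline configuration."""


class CapacityError(PhylorecError):
    """More infinite-sites mutations than available columns."""
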