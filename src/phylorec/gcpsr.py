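"""Genealogical concordance phylogenetic species recognition (GCPSR).

A candidate clade is *recognized* as an independent evolutionary lineage
(phylogenetic species) when it is supported in at least one gene tree and not
contradicted in any of the others: "supported" means the clade, restricted to
that locus's taxa, exactly equals one side of a supported bipartition;
"contradicted" means some supported bipartition of that locus is incompatible
with the candidate split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import PhylorecError
from .treekit import CladeTable, clades_compatible


class TrivialCladeError(PhylorecError):
    """Candidate of size < 2 or spanning the whole taxon set."""


@dataclass(frozen=True)
class SpeciesHypothesis:
    clade: frozenset
    supporting_loci: tuple[str, ...]
    contradicting_loci: tuple[str, ...]
    verdict: str  # recognized | contradicted | unsupported
    contains: tuple[frozenset, ...] = ()  # nested recognized clades

    @property
    def recognized(self) -> bool:
        return self.verdict == "recognized"


def evaluate_candidate(clade: Iterable, clade_tables: Sequence[CladeTable],
                       support_threshold: float = 0.95) -> SpeciesHypothesis:
    """Apply the support/contradiction rule to one candidate clade.

    Taxa missing from a locus are dropped from the candidate before the
    comparison; restrictions smaller than 2 taxa count as neither support nor
    contradiction.  ``support_threshold`` re-filters each table's splits, so
    tables extracted at a laxer threshold can be reused.
    """
    clade = frozenset(clade)
    all_taxa = frozenset().union(*(t.taxa for t in clade_tables))
    if len(clade) < 2 or clade >= all_taxa:
        raise TrivialCladeError(f"candidate of size {len(clade)} is trivial")
    supporting, contradicting = [], []
    for table in clade_tables:
        restricted = clade & table.taxa
        if len(restricted) < 2 or restricted == table.taxa:
            continue
        complement = table.taxa - restricted
        supported_here = False
        contradicted_here = False
        for side, support in table.splits:
            if support < support_threshold:
                continue
            if side == restricted or table.taxa - side == restricted:
                supported_here = True
            elif not clades_compatible((side, table.taxa - side),
                                       (restricted, complement), table.taxa):
                contradicted_here = True
        if supported_here:
            supporting.append(table.locus_name)
        if contradicted_here:
            contradicting.append(table.locus_name)
    if contradicting:
        verdict = "contradicted"
    elif supporting:
        verdict = "recognized"
    else:
        verdict = "unsupported"
    return SpeciesHypothesis(clade=clade, supporting_loci=tuple(supporting),
                             contradicting_loci=tuple(contradicting),
                             verdict=verdict)


def recognize_species(clade_tables: Sequence[CladeTable],
                      candidates: Iterable[Iterable] | None = None,
                      support_threshold: float = 0.95
                      ) -> list[SpeciesHypothesis]:
    """Evaluate candidate clades against all loci.

    By default candidates are the union of every locus's supported clades
    (both sides of each split, minus trivial ones); a user list can be passed
    instead (e.g. the clades of a combined tree).  Results are ordered by
    clade size then lexicographically, and recognized hypotheses are annotated
    with the nested recognized clades they contain.
    """
    all_taxa = frozenset().union(*(t.taxa for t in clade_tables))
    if candidates is None:
        pool: set[frozenset] = set()
        for table in clade_tables:
            for side, support in table.splits:
                if support < support_threshold:
                    continue
                for s in (side, table.taxa - side):
                    if 2 <= len(s) < len(all_taxa):
                        pool.add(frozenset(s))
        candidate_sets = pool
    else:
        candidate_sets = {frozenset(c) for c in candidates}
    ordered = sorted(candidate_sets, key=lambda s: (len(s), tuple(sorted(s))))
    results = [evaluate_candidate(c, clade_tables, support_threshold)
               for c in ordered]
    recognized = [h.clade for h in results if h.recognized]
    annotated = []
    for h in results:
        if h.recognized:
            nested = tuple(sorted((c for c in recognized if c < h.clade),
                                  key=lambda s: (len(s), tuple(sorted(s)))))
            h = SpeciesHypothesis(h.clade, h.supporting_loci,
                                  h.contradicting_loci, h.verdict, nested)
        annotated.append(h)
    return annotated
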