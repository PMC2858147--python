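"""Iterative Phi-test scan for the borders of a recombining population.

The procedure starts from a baseline sample that must show no recombination —
a focal clade plus a handful of genetically distant control strains — and then
tests progressively closer outside strains one at a time.  A candidate whose
addition makes the Phi test significant (p < alpha) has a recombination
history with the focal group; the first such strain marks the inner border of
the recombining population and the most distant one the outer border.  In the
default fixed-baseline mode each candidate is tested against the unchanged
baseline and triggering strains are kept out of later samples; in cumulative
mode non-triggering candidates accumulate into the growing sample.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .errors import BaselineError, IdError, NotComputableError, ScanError, SizeError
from .recombtest import phi_test
from .seqdata import MultiLocusDataset, concatenate
from .treekit import patristic_matrix

NOT_COMPUTABLE = "not-computable"


@dataclass(frozen=True)
class ScanStep:
    candidate: str
    rank_distance: float
    sample_size: int
    phi_p: float | str     # probability, or "not-computable"
    triggered: bool


@dataclass(frozen=True)
class BorderScanResult:
    focal_clade: frozenset
    baseline: frozenset
    baseline_phi_p: float
    steps: tuple[ScanStep, ...]
    inner_border_trigger: str | None
    outer_border: str | None
    recombining_population: frozenset
    alpha: float
    mode: str
    seed: int | None

    def to_rows(self) -> list[dict]:
        return [
            {"candidate": s.candidate, "rank_distance": s.rank_distance,
             "sample_size": s.sample_size, "phi_p": s.phi_p,
             "triggered": s.triggered}
            for s in self.steps
        ]


def rank_candidates(tree: dendropy.Tree, focal_clade: Sequence[str],
                    candidates: Sequence[str]) -> list[tuple[str, float]]:
    """Candidates ordered by mean patristic distance to the focal clade.

    Ascending order ("phylogenetically closer" first); ties break
    lexicographically by strain id.
    """
    if not focal_clade:
        raise ScanError("focal clade must be non-empty")
    pm = patristic_matrix(tree)
    known = set(pm.ids)
    for s in list(focal_clade) + list(candidates):
        if s not in known:
            raise IdError(f"strain {s!r} not in the ranking tree")
    idx = {s: k for k, s in enumerate(pm.ids)}
    focal_idx = [idx[s] for s in focal_clade]
    scored = []
    for cand in candidates:
        d = float(np.mean([pm.values[idx[cand], f] for f in focal_idx]))
        scored.append((cand, d))
    return sorted(scored, key=lambda t: (t[1], t[0]))


def scan_borders(dataset: MultiLocusDataset, tree: dendropy.Tree,
                 focal_clade: Sequence[str], distant_controls: Sequence[str],
                 candidates: Sequence[str] | None = None,
                 alpha: float = 0.05, phi_opts: dict | None = None,
                 mode: str = "fixed-baseline",
                 seed: int | None = None) -> BorderScanResult:
    """Locate the inner and outer borders of a recombining population.

    The scan continues past the first trigger through all remaining (more
    distant) candidates, so the outer border is the most distant strain still
    showing recombination with the focal group.  Per-step permutation seeds
    are derived from the master seed by step index, making the whole scan
    reproducible.  Steps where Phi is not computable (e.g. too few informative
    sites) are recorded as such and skipped.
    """
    if mode not in ("fixed-baseline", "cumulative"):
        raise ScanError(f"unknown mode {mode!r}")
    focal = list(dict.fromkeys(focal_clade))
    controls = list(dict.fromkeys(distant_controls))
    if candidates is None:
        used = set(focal) | set(controls)
        candidates = [s for s in dataset.strain_ids if s not in used]
    if not candidates:
        raise ScanError("empty candidate list")
    opts = dict(phi_opts or {})
    opts.pop("seed", None)

    def _derived_seed(tag: str) -> int:
        # bound to the candidate identity, so a step's permutation stream does
        # not depend on which other candidates are in the scan
        ss = np.random.SeedSequence([int(seed or 0), zlib.crc32(tag.encode())])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def _phi_p(strains: Sequence[str], step_seed: int) -> float | str:
        sub = dataset.subset(strains)
        concat, _ = concatenate(sub)
        try:
            return phi_test(concat, seed=int(step_seed), **opts).p_permutation
        except (NotComputableError, SizeError):
            return NOT_COMPUTABLE

    baseline = focal + controls
    p0 = _phi_p(baseline, _derived_seed("__baseline__"))
    if p0 == NOT_COMPUTABLE:
        raise BaselineError("Phi is not computable on the baseline sample")
    if p0 < alpha:
        raise BaselineError(
            f"baseline sample already shows recombination (p = {p0:.4g})")

    ranked = rank_candidates(tree, focal, list(candidates))
    steps = []
    triggers: list[str] = []
    cumulative_extra: list[str] = []
    for cand, dist in ranked:
        if mode == "cumulative":
            sample = baseline + cumulative_extra + [cand]
        else:
            sample = baseline + [cand]
        p = _phi_p(sample, _derived_seed(cand))
        if p == NOT_COMPUTABLE:
            steps.append(ScanStep(cand, dist, len(sample), NOT_COMPUTABLE, False))
            continue
        triggered = p < alpha
        steps.append(ScanStep(cand, dist, len(sample), float(p), triggered))
        if triggered:
            triggers.append(cand)
        elif mode == "cumulative":
            cumulative_extra.append(cand)
    return BorderScanResult(
        focal_clade=frozenset(focal),
        baseline=frozenset(baseline),
        baseline_phi_p=float(p0),
        steps=tuple(steps),
        inner_border_trigger=triggers[0] if triggers else None,
        outer_border=triggers[-1] if triggers else None,
        recombining_population=frozenset(focal) | frozenset(triggers),
        alpha=alpha, mode=mode, seed=seed)


def classification_accuracy(result: BorderScanResult,
                            truth_labels: dict[str, str]) -> float:
    """Fraction of non-control strains whose clonal/recombining status the
    scan got right (truth labels as produced by the border-scenario simulator)."""
    correct = total = 0
    flagged = result.recombining_population - result.focal_clade
    for strain, label in truth_labels.items():
        if label == "control":
            continue
        total += 1
        if label == "recombining":
            correct += strain in flagged
        else:  # clonal_core
            correct += strain not in flagged
    if total == 0:
        raise ScanError("no non-control strains in the truth labels")
    return correct / total
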