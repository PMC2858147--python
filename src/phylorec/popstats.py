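"""Population diversity and divergence statistics.

Standard summaries for haploid sequence samples: segregating sites, nucleotide
diversity pi, Watterson's theta, Tajima's D, Hudson's FST (1 - Hw/Hb) and the
Hudson-Kaplan lower bound Rm on the number of recombination events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DistanceError, SizeError
from .seqdata import LocusAlignment

_MISSING = 4


def _encode(rows: np.ndarray) -> np.ndarray:
    lut = np.full(256, _MISSING, dtype=np.uint8)
    for k, c in enumerate("ACGT"):
        lut[ord(c)] = k
    return lut[rows.view(np.uint8)]


@dataclass(frozen=True)
class DiversityStats:
    n_sequences: int
    n_sites_used: int          # complete-deletion site count
    S: int                     # segregating sites (complete deletion)
    pi: float                  # mean pairwise differences, pairwise deletion
    pi_per_site: float
    theta_w: float             # Watterson, per sequence (S / a1)
    theta_w_per_site: float
    tajima_d: float | None     # None when S == 0


def _harmonics(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    return a1, a2


def diversity_stats(alignment: LocusAlignment) -> DiversityStats:
    """Standard neutrality/diversity summaries.

    S, theta_w and Tajima's D use complete deletion (columns with any
    gap/ambiguity dropped); pi is reported with pairwise deletion.
    Tajima's D follows the textbook variance constants; it is flagged as
    undefined (None) when S = 0.
    """
    n = alignment.n_strains
    if n < 2:
        raise SizeError("diversity statistics need >= 2 sequences")
    codes = _encode(alignment.rows)
    complete = ~(codes == _MISSING).any(axis=0)
    used = codes[:, complete]
    S = int(sum(len(np.unique(c)) > 1 for c in used.T))
    # pi with pairwise deletion
    total, pairs = 0.0, 0
    pi_complete_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            ok = (a != _MISSING) & (b != _MISSING)
            if not ok.any():
                raise DistanceError("a pair of sequences shares no called site")
            total += int(((a != b) & ok).sum())
            pi_complete_total += int((used[i] != used[j]).sum())
            pairs += 1
    pi = total / pairs
    a1, a2 = _harmonics(n)
    theta_w = S / a1
    tajima_d = None
    if S > 0:
        pi_cd = pi_complete_total / pairs  # same site set as S
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
        e1 = c1 / a1
        e2 = c2 / (a1 ** 2 + a2)
        var = e1 * S + e2 * S * (S - 1)
        tajima_d = (pi_cd - theta_w) / np.sqrt(var) if var > 0 else None
    n_sites = int(complete.sum())
    return DiversityStats(
        n_sequences=n, n_sites_used=n_sites, S=S,
        pi=pi, pi_per_site=pi / n_sites if n_sites else float("nan"),
        theta_w=theta_w,
        theta_w_per_site=theta_w / n_sites if n_sites else float("nan"),
        tajima_d=None if tajima_d is None else float(tajima_d))


@dataclass(frozen=True)
class FstResult:
    pop_labels: tuple[str, str]
    hw: float   # mean within-population pairwise differences (pair-weighted)
    hb: float   # mean between-population pairwise differences
    fst: float  # 1 - hw/hb; negative values are reported as computed


def hudson_fst(alignment: LocusAlignment,
               pop_assignment: dict[str, str]) -> FstResult:
    """Hudson's FST = 1 - Hw/Hb for exactly two populations.

    Hw is the mean pairwise difference count within populations (pooled over
    all within-population pairs), Hb the mean across populations.  Pairwise
    deletion of missing sites.  Values near 0 indicate little differentiation;
    near 1, strong differentiation.  Negative estimates (sampling noise around
    zero) are reported as computed, not truncated.
    """
    pops: dict[str, list[int]] = {}
    for k, sid in enumerate(alignment.strain_ids):
        if sid in pop_assignment:
            pops.setdefault(pop_assignment[sid], []).append(k)
    if len(pops) != 2:
        raise SizeError(f"hudson_fst needs exactly 2 populations, got {len(pops)}")
    (la, ia), (lb, ib) = sorted(pops.items())
    if len(ia) < 2 or len(ib) < 2:
        raise SizeError("each population needs >= 2 sequences")
    codes = _encode(alignment.rows)

    def _mean_diff(rows_i: Sequence[int], rows_j: Sequence[int],
                   within: bool) -> tuple[float, int]:
        total, count = 0.0, 0
        for x in rows_i:
            for y in rows_j:
                if within and y <= x:
                    continue
                a, b = codes[x], codes[y]
                ok = (a != _MISSING) & (b != _MISSING)
                total += int(((a != b) & ok).sum())
                count += 1
        return total, count

    wa, ca = _mean_diff(ia, ia, within=True)
    wb, cb = _mean_diff(ib, ib, within=True)
    hw = (wa + wb) / (ca + cb)
    tb, cbt = _mean_diff(ia, ib, within=False)
    hb = tb / cbt
    if hb == 0:
        raise DistanceError("between-population diversity is zero; FST undefined")
    return FstResult(pop_labels=(la, lb), hw=hw, hb=hb, fst=1.0 - hw / hb)


def min_recombination_events(alignment: LocusAlignment) -> int:
    """Hudson-Kaplan Rm: a lower bound on the number of recombination events.

    Considers biallelic sites only (others skipped; missing data excluded
    pairwise).  Site pairs failing the four-gamete test define open intervals;
    Rm is the size of a maximal set of non-overlapping incompatible intervals,
    found by the standard left-to-right greedy sweep.
    """
    codes = _encode(alignment.rows)
    biallelic = []
    for j in range(codes.shape[1]):
        col = codes[:, j]
        if len(np.unique(col[col != _MISSING])) == 2:
            biallelic.append(j)
    intervals = []
    for ai in range(len(biallelic)):
        for bi in range(ai + 1, len(biallelic)):
            x, y = biallelic[ai], biallelic[bi]
            a, b = codes[:, x], codes[:, y]
            ok = (a != _MISSING) & (b != _MISSING)
            av, bv = a[ok], b[ok]
            if len(np.unique(av)) < 2 or len(np.unique(bv)) < 2:
                continue
            joint = {(int(p), int(q)) for p, q in zip(av, bv)}
            if len(joint) == 4:
                intervals.append((x, y))
    # greedy: scan by right endpoint, keep disjoint open intervals
    intervals.sort(key=lambda iv: iv[1])
    rm, last_end = 0, -1
    for start, end in intervals:
        if start >= last_end:
            rm += 1
            last_end = end
    return rm
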