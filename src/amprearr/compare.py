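"""Cross-passage junction-set algebra: shared, lost and gained junctions.

Junction identity for matching is the unordered pair of (chrom, pos, orient)
breakend triples.  The default position tolerance is 0 because junction
coordinates are typically confirmed to the base; a tolerance > 0 switches to
greedy nearest matching (by summed arm distance) for noisy callers — at
tolerances of a few bp this coincides with optimal bipartite matching while
staying transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .coverage import AmplifiedComparison
from .model import Breakend, Junction


@dataclass
class JunctionSetComparison:
    shared: List[tuple]  # (junction in A, matched junction in B)
    lost: List[Junction]  # A only
    gained: List[Junction]  # B only
    tolerance: int = 0

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_lost(self) -> int:
        return len(self.lost)

    @property
    def n_gained(self) -> int:
        return len(self.gained)

    @property
    def n_union(self) -> int:
        return self.n_shared + self.n_lost + self.n_gained


def _arm_pairing(j1: Junction, j2: Junction, tol: int) -> Optional[int]:
    """Summed arm distance under the best arm pairing, or None if the
    junctions are incompatible within ``tol``."""

    def dist(a: Breakend, b: Breakend) -> Optional[int]:
        if a.chrom != b.chrom or a.orient != b.orient:
            return None
        d = abs(a.pos - b.pos)
        return d if d <= tol else None

    best: Optional[int] = None
    for pa, pb in (
        ((j1.arm_a, j2.arm_a), (j1.arm_b, j2.arm_b)),
        ((j1.arm_a, j2.arm_b), (j1.arm_b, j2.arm_a)),
    ):
        d1 = dist(*pa)
        d2 = dist(*pb)
        if d1 is not None and d2 is not None:
            total = d1 + d2
            if best is None or total < best:
                best = total
    return best


def match_junctions(
    set_a: Sequence[Junction], set_b: Sequence[Junction], tol: int = 0
) -> JunctionSetComparison:
    """Match two junction sets; each junction is matched at most once.

    With ``tol = 0`` matching is exact on the unordered breakend-pair key;
    otherwise candidate pairs within ``tol`` bp per arm are matched greedily
    by ascending summed arm distance.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if tol == 0:
        by_key: Dict[frozenset, List[int]] = {}
        for idx, j in enumerate(set_b):
            by_key.setdefault(j.key, []).append(idx)
        shared = []
        lost = []
        used = set()
        for j in set_a:
            pool = [i for i in by_key.get(j.key, []) if i not in used]
            if pool:
                used.add(pool[0])
                shared.append((j, set_b[pool[0]]))
            else:
                lost.append(j)
        gained = [j for i, j in enumerate(set_b) if i not in used]
        return JunctionSetComparison(shared, lost, gained, tolerance=tol)
    candidates = []
    for ia, ja in enumerate(set_a):
        for ib, jb in enumerate(set_b):
            d = _arm_pairing(ja, jb, tol)
            if d is not None:
                candidates.append((d, ia, ib))
    candidates.sort()
    used_a = set()
    used_b = set()
    shared = []
    for d, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        shared.append((set_a[ia], set_b[ib]))
    lost = [j for i, j in enumerate(set_a) if i not in used_a]
    gained = [j for i, j in enumerate(set_b) if i not in used_b]
    return JunctionSetComparison(shared, lost, gained, tolerance=tol)


@dataclass
class ComparisonSummary:
    n_a: int
    n_b: int
    n_shared: int
    n_lost: int
    n_gained: int
    n_distinct: int
    per_chrom_a: Dict[str, int] = field(default_factory=dict)
    per_chrom_b: Dict[str, int] = field(default_factory=dict)
    inter_chromosomal_a: int = 0
    inter_chromosomal_b: int = 0
    fraction_amplified_lost: Dict[str, float] = field(default_factory=dict)


def _tally(junctions: Sequence[Junction]):
    per_chrom: Dict[str, int] = {}
    inter = 0
    for j in junctions:
        if j.is_interchromosomal:
            inter += 1
        for chrom in {j.arm_a.chrom, j.arm_b.chrom}:
            per_chrom[chrom] = per_chrom.get(chrom, 0) + 1
    return per_chrom, inter


def comparison_summary(
    cmp: JunctionSetComparison,
    amplified_cmp: Optional[AmplifiedComparison] = None,
) -> ComparisonSummary:
    """Joint report of junction fates, per-chromosome and inter- vs
    intra-chromosomal tallies, and the lost amplified fraction."""
    set_a = [a for a, _ in cmp.shared] + cmp.lost
    set_b = [b for _, b in cmp.shared] + cmp.gained
    per_a, inter_a = _tally(set_a)
    per_b, inter_b = _tally(set_b)
    return ComparisonSummary(
        n_a=len(set_a),
        n_b=len(set_b),
        n_shared=cmp.n_shared,
        n_lost=cmp.n_lost,
        n_gained=cmp.n_gained,
        n_distinct=cmp.n_union,
        per_chrom_a=per_a,
        per_chrom_b=per_b,
        inter_chromosomal_a=inter_a,
        inter_chromosomal_b=inter_b,
        fraction_amplified_lost=(
            dict(amplified_cmp.fraction_lost) if amplified_cmp else {}
        ),
    )


def fate_table(cmp: JunctionSetComparison) -> List[dict]:
    rows = []
    for a, b in cmp.shared:
        rows.append({"id": a.id, "fate": "shared", "matched_id": b.id})
    for j in cmp.lost:
        rows.append({"id": j.id, "fate": "lost", "matched_id": "."})
    for j in cmp.gained:
        rows.append({"id": j.id, "fate": "gained", "matched_id": "."})
    return rows
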