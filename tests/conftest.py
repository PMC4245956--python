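"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from amprearr.junctions import arm_flanks
from amprearr.model import Breakend, Interval, Junction, Orientation

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=60
)
settings.load_profile("suite")

LEFT = Orientation.LEFT_RETAINED
RIGHT = Orientation.RIGHT_RETAINED


def random_genome(rng: np.random.Generator, lengths: dict) -> dict:
    return {
        c: "".join(rng.choice(list("ACGT"), size=n)) for c, n in lengths.items()
    }


@pytest.fixture(scope="session")
def genome_2x10kb():
    rng = np.random.default_rng(42)
    return random_genome(rng, {"c1": 10_000, "c2": 10_000})


def random_junction(rng: np.random.Generator, genome: dict, margin: int = 200) -> Junction:
    chroms = list(genome)
    arms = []
    for _ in range(2):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(margin, len(genome[chrom]) - margin))
        orient = LEFT if rng.random() < 0.5 else RIGHT
        arms.append(Breakend(chrom, pos, orient))
    if arms[0].key == arms[1].key:
        return random_junction(rng, genome, margin)
    return Junction(id=f"r{rng.integers(1 << 30)}", arm_a=arms[0], arm_b=arms[1])


# ---------------------------------------------------------------------------
# independent microhomology oracle: exhaustive breakpoint-shift enumeration


def _advance(be: Breakend, d: int, side: str) -> Breakend:
    """Move a breakend d bases along the junction reading direction."""
    if side == "left":
        newpos = be.pos + d if be.orient is LEFT else be.pos - d
    else:
        newpos = be.pos + d if be.orient is RIGHT else be.pos - d
    return Breakend(be.chrom, newpos, be.orient)


def mh_shift_oracle(j: Junction, genome: dict, max_shift: int = 12) -> tuple:
    """(mh_left, mh_right) by exhaustively testing alternative breakpoint
    placements: a shift of the seam by d is valid iff the reconstructed
    fused molecule is unchanged.  Completely independent of the prefix-
    matching implementation."""
    w = 30
    big = w + max_shift

    def window(ja: Junction, wa: int, wb: int) -> str:
        ka, _, _ = arm_flanks(ja.arm_a, genome, wa, "left")
        kb, _, _ = arm_flanks(ja.arm_b, genome, wb, "right")
        return ka[-wa:], kb[:wb]

    ka_ext, kb_ext = window(j, big, big)
    molecule = ka_ext + kb_ext  # seam at index `big`

    def valid(d: int) -> bool:
        shifted = Junction(
            id="shifted",
            arm_a=_advance(j.arm_a, d, "left"),
            arm_b=_advance(j.arm_b, d, "right"),
        )
        try:
            ka, kb = window(shifted, w, w)
        except ValueError:
            return False
        return ka + kb == molecule[big + d - w : big + d + w]

    right = 0
    for d in range(1, max_shift + 1):
        if valid(d):
            right = d
        else:
            break
    left = 0
    for d in range(1, max_shift + 1):
        if valid(-d):
            left = d
        else:
            break
    return left, right


# ---------------------------------------------------------------------------
# independent clustering oracle: O(n^2) transitive closure


def cluster_closure_oracle(positions, max_gap):
    """Partition positions (single chromosome) by transitive closure of the
    relation |x - y| <= max_gap, via union-find over all pairs."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for k in range(i + 1, n):
            if abs(positions[i] - positions[k]) <= max_gap:
                ri, rk = find(i), find(k)
                if ri != rk:
                    parent[ri] = rk
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(sorted(g) for g in groups.values())
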