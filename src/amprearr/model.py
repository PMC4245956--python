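"""Domain types for amplicon rearrangement analysis.

Coordinate convention: all in-memory positions are 1-based and intervals are
closed (inclusive on both ends).  On-disk interval formats (BED, BEDPE,
bedGraph) are 0-based half-open, per convention; conversion happens only in
:mod:`amprearr.io`.

A *breakend* is one oriented side of a fusion.  ``pos`` is the last retained
reference base on that side:

* ``LEFT_RETAINED`` ('+' on disk): reference upstream of ``pos`` is kept, the
  fragment ends at ``pos``.
* ``RIGHT_RETAINED`` ('-' on disk): reference downstream is kept, the fragment
  starts at ``pos``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional


class Orientation(enum.Enum):
    LEFT_RETAINED = "+"
    RIGHT_RETAINED = "-"

    @classmethod
    def from_symbol(cls, sym: str) -> "Orientation":
        for o in cls:
            if o.value == sym:
                return o
        raise ValueError(f"orientation token {sym!r} not in {{'+', '-'}}")


@dataclass(frozen=True, order=True)
class Breakend:
    """One oriented side of a fusion junction."""

    chrom: str
    pos: int
    orient: Orientation
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("breakend chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"breakend pos must be >= 1, got {self.pos}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.orient)


@dataclass(frozen=True)
class Interval:
    """1-based, closed genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("interval start must be >= 1")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


#: sentinel for "microhomology length not determined"
UNSET = None


@dataclass
class Junction:
    """A fusion of two breakends, with read support and optional sequence calls.

    ``mh_len`` is the total two-sided microhomology (bp) or ``None`` when not
    yet determined.  ``inserted_seq`` non-empty and ``mh_len`` set and non-zero
    is rejected: microhomology and untemplated insertion are mutually
    exclusive calls at one junction.
    """

    id: str
    arm_a: Breakend
    arm_b: Breakend
    support: int = 0
    inserted_seq: str = ""
    mh_len: Optional[int] = UNSET
    span_seq: Optional[str] = None
    samples: frozenset = frozenset()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.support < 0:
            raise ValueError("junction support must be >= 0")
        if self.arm_a.key == self.arm_b.key:
            raise ValueError(
                f"junction {self.id}: the two arms are the same breakend"
            )
        if self.inserted_seq and self.mh_len not in (UNSET, 0):
            raise ValueError(
                f"junction {self.id}: non-empty insertion with mh_len="
                f"{self.mh_len}; insertion implies mh_len 0"
            )
        self.samples = frozenset(self.samples)

    @property
    def key(self) -> frozenset:
        """Arm-order-insensitive identity used for set operations."""
        return frozenset((self.arm_a.key, self.arm_b.key))

    @property
    def is_interchromosomal(self) -> bool:
        return self.arm_a.chrom != self.arm_b.chrom

    def with_(self, **kw) -> "Junction":
        return replace(self, **kw)


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")
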