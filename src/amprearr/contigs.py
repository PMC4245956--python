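"""Junction-arm adjacency graph and contig assembly.

When two junctions each have one arm in closely neighbouring reference
positions, the short retained fragment between those arms may link the two
junctions into a contig: an alternating chain junction - fragment - junction.
Candidate links are *facing* breakend pairs from distinct junctions — the
lower-coordinate breakend retains the reference to its right
(RIGHT_RETAINED) and the higher one retains to its left (LEFT_RETAINED) —
within ``max_link`` bp.  Each breakend keeps only its shortest-fragment
candidate (the in-silico counterpart of resolving ambiguity by PCR);
conflicting choices are broken and flagged per the ambiguity policy.
Maximal simple paths become linear contigs; cycles are emitted as circular
contigs (the topology of an episome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .junctions import JunctionCall
from .model import Breakend, Interval, Junction, Orientation

DEFAULT_MAX_LINK = 5000


@dataclass(frozen=True)
class ArmLink:
    """A retained reference fragment between facing arms of two junctions."""

    junction_low: str  # junction owning the lower (RIGHT_RETAINED) breakend
    arm_low: str  # "a" | "b"
    junction_high: str
    arm_high: str
    fragment: Interval

    @property
    def length(self) -> int:
        return self.fragment.length


def _arms(j: Junction):
    yield "a", j.arm_a
    yield "b", j.arm_b


def build_arm_links(
    junctions: Sequence[Junction], max_link: int = DEFAULT_MAX_LINK
) -> List[ArmLink]:
    """All facing breakend pairs from distinct junctions within ``max_link``,
    sorted by fragment length.  A breakend may appear in several candidate
    links."""
    rights: List[Tuple[Breakend, str, str]] = []
    lefts: List[Tuple[Breakend, str, str]] = []
    for j in junctions:
        for side, arm in _arms(j):
            if arm.orient is Orientation.RIGHT_RETAINED:
                rights.append((arm, j.id, side))
            else:
                lefts.append((arm, j.id, side))
    links: List[ArmLink] = []
    for r_arm, r_id, r_side in rights:
        for l_arm, l_id, l_side in lefts:
            if r_id == l_id or r_arm.chrom != l_arm.chrom:
                continue
            if not (r_arm.pos <= l_arm.pos):
                continue
            length = l_arm.pos - r_arm.pos + 1
            if length > max_link:
                continue
            links.append(
                ArmLink(
                    junction_low=r_id,
                    arm_low=r_side,
                    junction_high=l_id,
                    arm_high=l_side,
                    fragment=Interval(r_arm.chrom, r_arm.pos, l_arm.pos),
                )
            )
    links.sort(key=lambda lk: (lk.length, lk.junction_low, lk.junction_high))
    return links


@dataclass
class Contig:
    """Ordered alternating chain of junctions and retained fragments."""

    junction_ids: List[str]
    fragments: List[Interval]
    circular: bool = False
    ambiguous_breakends: List[str] = field(default_factory=list)

    @property
    def n_junctions(self) -> int:
        return len(self.junction_ids)

    def fragment_lengths(self) -> List[int]:
        return [f.length for f in self.fragments]

    def source_distances(self) -> List[Optional[int]]:
        """Distance in the normal genome between consecutive fragments
        (None for different chromosomes)."""
        out: List[Optional[int]] = []
        for f1, f2 in zip(self.fragments, self.fragments[1:]):
            if f1.chrom != f2.chrom:
                out.append(None)
            else:
                lo, hi = sorted([f1, f2], key=lambda f: f.start)
                out.append(max(hi.start - lo.end, 0))
        return out


def assemble_contigs(
    links: Sequence[ArmLink],
    junctions: Sequence[Junction],
    ambiguity_policy: str = "break",
) -> List[Contig]:
    """Greedy contig assembly from candidate arm links.

    Each breakend keeps only its shortest-fragment candidate link; a link
    survives when it is the choice of both of its breakends.  With policy
    "break" (default) conflicting breakends are left unlinked and flagged;
    with policy "strict" a conflict raises.  Connected junctions form
    maximal simple paths (linear contigs) or cycles (circular contigs,
    flagged by ``circular``).  Deterministic: permuting the input changes
    nothing.
    """
    if ambiguity_policy not in ("break", "strict"):
        raise ValueError(f"unknown ambiguity_policy {ambiguity_policy!r}")
    def ends_of(link: ArmLink):
        return (
            (link.junction_low, link.arm_low),
            (link.junction_high, link.arm_high),
        )

    ordered = sorted(
        links, key=lambda lk: (lk.length, lk.junction_low, lk.junction_high)
    )
    best: Dict[Tuple[str, str], ArmLink] = {}
    tied = set()
    for link in ordered:
        for end in ends_of(link):
            cur = best.get(end)
            if cur is None:
                best[end] = link
            elif cur != link and cur.length == link.length:
                tied.add(end)  # equal-length alternatives: ambiguous
    for end in tied:
        best.pop(end, None)
    ambiguous: List[str] = [f"{jid}.{arm}" for jid, arm in tied]
    kept = []
    for link in ordered:
        e1, e2 = ends_of(link)
        if best.get(e1) == link and best.get(e2) == link:
            kept.append(link)
        elif best.get(e1) == link or best.get(e2) == link:
            # one side prefers another partner: break the chain here
            loser = e1 if best.get(e1) == link else e2
            ambiguous.append(f"{loser[0]}.{loser[1]}")
    if ambiguous and ambiguity_policy == "strict":
        raise ValueError(f"ambiguous breakends: {sorted(set(ambiguous))}")

    graph = nx.Graph()
    for j in junctions:
        graph.add_node(j.id)
    for link in kept:
        graph.add_edge(link.junction_low, link.junction_high, link=link)
    contigs: List[Contig] = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        sub = graph.subgraph(comp)
        degrees = dict(sub.degree())
        is_cycle = all(d == 2 for d in degrees.values())
        if is_cycle:
            start = min(comp)
            order = [start]
            prev = None
            while True:
                nbrs = [n for n in sub.neighbors(order[-1]) if n != prev]
                nxt = nbrs[0]
                if nxt == start:
                    break
                prev = order[-1]
                order.append(nxt)
            frags = [
                sub.edges[a, b]["link"].fragment
                for a, b in zip(order, order[1:] + [start])
            ]
            contigs.append(
                Contig(order, frags, circular=True, ambiguous_breakends=sorted(set(ambiguous)))
            )
        else:
            ends = sorted(n for n, d in degrees.items() if d == 1)
            start = ends[0]
            order = [start]
            prev = None
            while True:
                nbrs = [n for n in sub.neighbors(order[-1]) if n != prev]
                if not nbrs:
                    break
                prev = order[-1]
                order.append(nbrs[0])
            frags = [
                sub.edges[a, b]["link"].fragment for a, b in zip(order, order[1:])
            ]
            contigs.append(
                Contig(order, frags, ambiguous_breakends=sorted(set(ambiguous)))
            )
    contigs.sort(key=lambda c: c.junction_ids)
    return contigs


def write_link_graph(links: Sequence[ArmLink], path) -> None:
    """Export the candidate arm-link graph as a plain edge list."""
    with open(path, "w") as fh:
        fh.write(
            "junction_low\tarm_low\tjunction_high\tarm_high\t"
            "chrom\tstart\tend\tlength\n"
        )
        for lk in links:
            fh.write(
                f"{lk.junction_low}\t{lk.arm_low}\t{lk.junction_high}\t"
                f"{lk.arm_high}\t{lk.fragment.chrom}\t{lk.fragment.start}\t"
                f"{lk.fragment.end}\t{lk.length}\n"
            )


# ---------------------------------------------------------------------------
# reporting


def contig_report(
    contigs: Sequence[Contig],
    mh_by_junction: Optional[Dict[str, Optional[int]]] = None,
    insertion_by_junction: Optional[Dict[str, int]] = None,
) -> dict:
    """Per-contig rows and summary statistics.

    ``mh_by_junction`` maps junction id to its microhomology length (None
    when the junction carries an insertion instead); blunt means mh == 0 and
    no insertion.  Summary: fraction of contig junctions blunt, fraction
    with mh > 2.
    """
    mh_by_junction = mh_by_junction or {}
    insertion_by_junction = insertion_by_junction or {}
    rows = []
    n_total = 0
    n_blunt = 0
    n_mh_gt2 = 0
    for idx, c in enumerate(contigs, start=1):
        mhs = []
        for jid in c.junction_ids:
            mh = mh_by_junction.get(jid)
            ins = insertion_by_junction.get(jid, 0)
            n_total += 1
            if ins > 0:
                mhs.append(f"ins{ins}")
            else:
                mhs.append("na" if mh is None else str(mh))
                if mh == 0:
                    n_blunt += 1
                if mh is not None and mh > 2:
                    n_mh_gt2 += 1
        rows.append(
            {
                "contig": idx,
                "junctions": " - ".join(c.junction_ids),
                "microhomology": " - ".join(mhs),
                "fragment_lengths": c.fragment_lengths(),
                "distances_kb": [
                    (None if d is None else d / 1000.0)
                    for d in c.source_distances()
                ],
                "circular": c.circular,
            }
        )
    return {
        "rows": rows,
        "n_junctions": n_total,
        "fraction_blunt": n_blunt / n_total if n_total else float("nan"),
        "fraction_mh_gt2": n_mh_gt2 / n_total if n_total else float("nan"),
    }


# ---------------------------------------------------------------------------
# coordinated junction pairs


@dataclass(frozen=True)
class CoordinatedPair:
    junction_1: str
    junction_2: str
    locus_x: Tuple[str, int, int]  # chrom, pos of each junction's arm at X
    locus_y: Tuple[str, int, int]
    separation: int


def detect_coordinated_pairs(
    junctions: Sequence[Junction],
    max_intra: int = 2000,
    min_inter: int = 100_000,
) -> List[CoordinatedPair]:
    """Junction pairs whose arms fall pairwise into two remote loci.

    A pair (J1, J2) is coordinated when one arm of each lies within
    ``max_intra`` bp at a locus X, the remaining two arms lie within
    ``max_intra`` at a locus Y, and X and Y are at least ``min_inter`` apart
    (same chromosome) — the signature of concomitant repair of two
    juxtaposed double-strand breaks.
    """
    out: List[CoordinatedPair] = []
    for i, j1 in enumerate(junctions):
        for j2 in junctions[i + 1 :]:
            for a1, a2 in (
                ((j1.arm_a, j1.arm_b), (j2.arm_a, j2.arm_b)),
                ((j1.arm_a, j1.arm_b), (j2.arm_b, j2.arm_a)),
            ):
                x1, y1 = a1
                x2, y2 = a2
                if x1.chrom != x2.chrom or y1.chrom != y2.chrom:
                    continue
                if abs(x1.pos - x2.pos) > max_intra:
                    continue
                if abs(y1.pos - y2.pos) > max_intra:
                    continue
                if x1.chrom != y1.chrom:
                    continue
                sep = abs(x1.pos - y1.pos)
                if sep < min_inter:
                    continue
                out.append(
                    CoordinatedPair(
                        junction_1=j1.id,
                        junction_2=j2.id,
                        locus_x=(x1.chrom, x1.pos, x2.pos),
                        locus_y=(y1.chrom, y1.pos, y2.pos),
                        separation=sep,
                    )
                )
                break
    return out
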