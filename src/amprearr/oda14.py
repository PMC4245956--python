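"""Published summary tables for the ODA14 oligodendroglioma amplicon.

ODA14 is a xenografted human oligodendroglioma in which the EGFR (7p11) and
MYC (8q24) loci are co-amplified — on double minutes at passage 2 (ODA14p2)
and on a homogeneously staining region at passage 4 (ODA14p4).  The printed
per-cluster and per-contig summaries of that amplicon are embedded here as
worked-example inputs: chromosome-7 breakpoint clusters for both passages
(member arm labels with the distances between consecutive breakpoints, the
cluster length and the position of the first breakpoint), the per-contig
junction/microhomology/fragment-length columns, and the printed bounds of
the amplified regions.

In the contig table's microhomology column a negative value denotes an
untemplated insertion of that many bp at the junction (no microhomology
call); non-negative values are microhomology lengths in bp.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from .model import Breakend, Interval, Orientation

# cluster, member arm labels, gaps between consecutive members (bp),
# printed length (bp), position of the first breakpoint (chromosome 7)
CLUSTERS_P2: List[Tuple[str, List[str], List[int], int, int]] = [
    ("A", ["a3", "a4", "b12", "a5", "a6"], [141, 1192, 316, 469], 2118, 54_520_243),
    ("B", ["a7", "a8", "a9", "a10", "a11", "a12", "a13"],
     [821, 128, 246, 353, 656, 293], 2497, 54_558_285),
    ("C", ["a16", "b11"], [61], 61, 54_668_755),
    ("D", ["a19", "a18", "b36"], [36, 91], 127, 54_697_888),
    ("E", ["a21", "b2"], [222], 222, 54_738_501),
    ("F", ["a22", "a23", "b5", "b6", "a24", "a25", "a26"],
     [1, 41, 17, 34, 10, 265], 376, 54_748_976),
    ("G", ["a27", "a28"], [1823], 1823, 54_880_905),
    ("H", ["a29", "a30"], [244], 244, 54_928_591),
    ("I", ["a31", "a32", "a33"], [386, 921], 1307, 55_064_954),
    ("J", ["b15", "a34", "b8", "b4", "b3", "a35"],
     [22, 1792, 306, 108, 40], 2227, 55_123_258),
    ("K", ["b24", "b7"], [290], 290, 55_202_557),
    ("L", ["b14", "a36", "b17"], [66, 1461], 1527, 55_206_654),
    ("M", ["a37", "b13", "b9"], [30, 160], 190, 55_241_284),
    ("N", ["b23", "b33", "b35", "b21", "b26"], [331, 165, 885, 613], 1999, 55_257_873),
    ("O", ["b39", "b32", "b25", "a38", "a39"], [171, 5, 82, 126], 384, 55_262_169),
    ("P", ["b30", "b38", "b37"], [329, 505], 834, 55_268_502),
    ("Q", ["b10", "b29", "b31"], [348, 1133], 1481, 55_278_611),
]

# new chromosome-7 breakpoints at passage 4: single additions to existing
# clusters and four new clusters (cluster, labels, gaps, length, anchor);
# the Q additions are printed only as a position range
CLUSTERS_P4_ADDITIONS: List[Tuple[str, List[str], List[int], Optional[int], int]] = [
    ("B", ["a73"], [], None, 54_559_480),
    ("J", ["b83"], [], None, 55_125_302),
    ("O", ["a82"], [], None, 55_262_174),
    ("Q", ["a83", "b73", "b80"], [], None, 55_279_982),
]
CLUSTERS_P4_NEW: List[Tuple[str, List[str], List[int], int, int]] = [
    ("R", ["a78", "b77"], [35], 35, 54_957_228),
    ("S", ["b82", "a80"], [103], 103, 55_207_419),
    ("T", ["a67", "b68", "a69", "b75"], [209, 37, 1109], 1355, 54_438_342),
    ("U", ["a85", "b69", "b74"], [11, 19], 30, 55_292_438),
]


def cluster_positions(
    rows: List[Tuple[str, List[str], List[int], Optional[int], int]]
) -> List[Tuple[str, str, int]]:
    """Reconstruct (cluster, label, position) triples from anchor + gaps."""
    out = []
    for cluster, labels, gaps, _length, anchor in rows:
        pos = anchor
        cum = [0]
        for g in gaps:
            cum.append(cum[-1] + g)
        for label, off in zip(labels, cum):
            out.append((cluster, label, pos + off))
    return out


def table1_breakends(chrom: str = "7") -> List[Breakend]:
    """All passage-2 chromosome-7 breakpoints reconstructed from the printed
    cluster rows (anchor plus cumulative gaps).  Orientation is not printed;
    clustering ignores it, so LEFT_RETAINED is used throughout."""
    return [
        Breakend(chrom, pos, Orientation.LEFT_RETAINED, label=label)
        for _cluster, label, pos in cluster_positions(CLUSTERS_P2)
    ]


# printed bounds of the amplified regions at passage 2 (dmins): 40 kb in the
# 47.3 Mb region of chromosome 7 plus the 54.41-55.31 Mb segment, and two
# chromosome-8 regions, 127.70-129.73 and 130.15-132.82 Mb
AMPLIFIED_P2: List[Interval] = [
    Interval("7", 47_300_001, 47_340_000),
    Interval("7", 54_410_001, 55_310_000),
    Interval("8", 127_700_001, 129_730_000),
    Interval("8", 130_150_001, 132_820_000),
]


# contig table: (passage, contig number, junction arms, microhomology column
# (negative = insertion of that length), fragment lengths (bp), distances
# between fragments in the normal genome (kb; None where not printed))
CONTIGS: List[dict] = [
    dict(passage="p2", contig=1, junctions=["a11b", "a16b"], mh=[3, 0],
         fragment_lengths=[61], distances_kb=[170]),
    dict(passage="p2", contig=2, junctions=["a14b", "a36b"], mh=[0, 0],
         fragment_lengths=[66], distances_kb=[105]),
    dict(passage="p2", contig=3, junctions=["a15b", "a34b"], mh=[0, 0],
         fragment_lengths=[22], distances_kb=[60]),
    dict(passage="p2", contig=4, junctions=["a55b", "a47b"], mh=[0, 0],
         fragment_lengths=[28], distances_kb=[815]),
    dict(passage="p2", contig=5, junctions=["a2b", "a21b", "b23a"], mh=[0, 0, 0],
         fragment_lengths=[222, 1386], distances_kb=[782, 10]),
    dict(passage="p2", contig=6, junctions=["b18a", "a19b", "a53b"], mh=[6, 2, 1],
         fragment_lengths=[36, 64], distances_kb=[None, 1232]),
    dict(passage="p2", contig=7,
         junctions=["b8a", "a9b", "b13a", "a12b", "a5b", "a26b"],
         mh=[2, 1, 1, 0, 0, 0], fragment_lengths=[128, 160, 293, 316, 326],
         distances_kb=[116, 1.5, 719, 188, 737]),
    dict(passage="p2/p4", contig=8, junctions=["a24b", "b7a"], mh=[3, 0],
         fragment_lengths=[290], distances_kb=[190]),
    dict(passage="p2/p4", contig=9,
         junctions=["a4b", "b3a", "a6b", "a22b", "b31a", "a32b"],
         mh=[2, 1, 0, 4, -2, -2], fragment_lengths=[108, 2118, 67],
         distances_kb=[0.14, 376, 235]),
    dict(passage="p2/p4", contig=10,
         junctions=["b39a", "a38b", "b30a", "a29b", "b10a"],
         mh=[0, 0, 2, 0, -5], fragment_lengths=[386, 171, 126, 329, 244, 348],
         distances_kb=[17, 197, 6, 333, 10, 369]),
    dict(passage="p4", contig=11, junctions=["a73b", "a83b", "a35b"], mh=[2, 2, 3],
         fragment_lengths=[71, 224], distances_kb=[565, 21]),
    dict(passage="p4", contig=12, junctions=["a74b", "a85b"], mh=[0, 2],
         fragment_lengths=[30], distances_kb=[None]),
    dict(passage="p4", contig=13, junctions=["a75b", "a69b"], mh=[2, 1],
         fragment_lengths=[72], distances_kb=[621]),
    dict(passage="p4", contig=14, junctions=["a78b", "a77b"], mh=[2, 0],
         fragment_lengths=[35], distances_kb=[12]),
    dict(passage="p4", contig=15, junctions=["b92a", "b98a"], mh=[0, 0],
         fragment_lengths=[20], distances_kb=[91]),
    dict(passage="p4", contig=16, junctions=["a82b", "a80b"], mh=[0, 0],
         fragment_lengths=[109], distances_kb=[18]),
    dict(passage="p4", contig=17, junctions=["a88b", "b81a"], mh=[2, 2],
         fragment_lengths=[948], distances_kb=[None]),
    dict(passage="p4", contig=18,
         junctions=["b91a", "b99a", "b103a", "a102b", "a104b", "b94a",
                    "b101a", "b100a", "b87a"],
         mh=[2, 0, 2, 1, 0, 2, 0, 0],
         fragment_lengths=[257, 35_856, 14_115, 1_258, 1_168, 4_331,
                           21_471, 72_238],
         distances_kb=[2077, 3297, 998, 1000, 1956, 949, 2588, None]),
]


def printed_contigs():
    """Rebuild the printed contig table as Contig objects plus microhomology
    and insertion maps, for replay through the contig report.

    Junction entries are paired index-wise with the microhomology column;
    rows where the printed junction list is longer than the value list
    contribute only the junctions that carry a printed value.  Fragment
    intervals are placed on a dummy chromosome at the printed lengths.
    """
    from .contigs import Contig

    contigs = []
    mh_by_junction: Dict[str, Optional[int]] = {}
    ins_by_junction: Dict[str, int] = {}
    for row in CONTIGS:
        jids = []
        for arm, value in zip(row["junctions"], row["mh"]):
            jid = f"c{row['contig']}:{arm}"
            jids.append(jid)
            if value < 0:
                mh_by_junction[jid] = None
                ins_by_junction[jid] = -value
            else:
                mh_by_junction[jid] = value
        fragments = [
            Interval("printed", 1, length) for length in row["fragment_lengths"]
        ]
        contigs.append(Contig(junction_ids=jids, fragments=fragments))
    return contigs, mh_by_junction, ins_by_junction
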