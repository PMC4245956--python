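"""Per-junction sequence characterization.

A junction fuses two oriented breakends.  Read in "junction orientation", the
fused molecule is ``A + (insert) + B`` where ``A`` is the retained reference
ending at arm_a's breakend and ``B`` the retained reference starting at
arm_b's breakend (reverse complement applied when a retained side points the
other way along the reference).

Two-sided microhomology: the bases immediately after the seam may match the
reference continuation past arm_a (``mh_right``), and the bases immediately
before the seam may match the reference immediately preceding arm_b
(``mh_left``).  The total ``mh_left + mh_right`` is the number of alternative
seam placements, i.e. the length of sequence shared by the two normal
counterparts of the fusion and maintained as a single copy.  Microhomology
and untemplated insertion are mutually exclusive calls: a junction with
inserted bases has ``mh_len = 0`` by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align

from .model import Breakend, Interval, Junction, Orientation, revcomp

Genome = Dict[str, str]


# ---------------------------------------------------------------------------
# flank extraction


def arm_flanks(
    be: Breakend, genome: Genome, w: int, side: str
) -> Tuple[str, str, bool]:
    """Extract (kept, beyond, truncated) for a breakend in junction orientation.

    ``side`` is "left" for the arm whose retained sequence ends at the seam
    (arm_a) and "right" for the arm starting at the seam (arm_b).  ``kept``
    is the retained reference adjacent to the seam; ``beyond`` is the
    reference on the *other* side of the breakend, read in the same junction
    orientation (the continuation past the seam for a left arm, the bases
    preceding the seam for a right arm).  ``truncated`` flags a window cut
    short by a contig edge.
    """
    seq = genome.get(be.chrom)
    if seq is None:
        raise KeyError(f"breakend chrom {be.chrom!r} not in genome")
    n = len(seq)
    p = be.pos
    if not (1 <= p <= n):
        raise ValueError(f"breakend pos {p} outside contig {be.chrom} (1..{n})")
    if side == "left":
        if be.orient is Orientation.LEFT_RETAINED:
            kept = seq[max(0, p - w) : p]
            beyond = seq[p : p + w]
        else:  # RIGHT_RETAINED read toward decreasing coordinates
            kept = revcomp(seq[p - 1 : p - 1 + w])
            beyond = revcomp(seq[max(0, p - 1 - w) : p - 1])
    elif side == "right":
        if be.orient is Orientation.RIGHT_RETAINED:
            kept = seq[p - 1 : p - 1 + w]
            beyond = seq[max(0, p - 1 - w) : p - 1]
        else:
            kept = revcomp(seq[max(0, p - w) : p])
            beyond = revcomp(seq[p : p + w])
    else:
        raise ValueError("side must be 'left' or 'right'")
    truncated = len(kept) < w or len(beyond) < w
    return kept, beyond, truncated


def _common_prefix(a: str, b: str) -> int:
    k = 0
    for x, y in zip(a, b):
        if x != y:
            break
        k += 1
    return k


@dataclass(frozen=True)
class Microhomology:
    left: int
    right: int
    truncated: bool = False

    @property
    def total(self) -> int:
        return self.left + self.right


def microhomology_at(
    junction: Junction, genome: Genome, max_window: int = 50
) -> Microhomology:
    """Two-sided microhomology of a junction against the reference.

    ``mh_right`` extends the seam rightward: longest k such that the first k
    retained bases of arm_b equal the reference continuation past arm_a's
    breakend.  ``mh_left`` extends leftward: longest k such that the last k
    retained bases of arm_a equal the reference immediately preceding arm_b's
    breakend.  Both capped at ``max_window``; windows truncated by contig
    edges are flagged.
    """
    kept_a, cont_a, trunc_a = arm_flanks(junction.arm_a, genome, max_window, "left")
    kept_b, pre_b, trunc_b = arm_flanks(junction.arm_b, genome, max_window, "right")
    right = _common_prefix(cont_a, kept_b)
    left = _common_prefix(kept_a[::-1], pre_b[::-1])
    return Microhomology(left=left, right=right, truncated=trunc_a or trunc_b)


# ---------------------------------------------------------------------------
# filtering


def filter_junctions(
    raw: Sequence[Junction],
    min_support: int = 3,
    amplified: Optional[Sequence[Interval]] = None,
) -> List[Junction]:
    """Keep junctions with support >= min_support and, when amplified regions
    are given, at least one arm inside an amplified interval."""
    out = []
    for j in raw:
        if j.support < min_support:
            continue
        if amplified is not None:
            in_amp = any(
                iv.contains(arm.chrom, arm.pos)
                for arm in (j.arm_a, j.arm_b)
                for iv in amplified
            )
            if not in_amp:
                continue
        out.append(j)
    return out


def annotate_repeat_class(
    junctions: Sequence[Junction],
    annotations: Sequence[tuple],
) -> None:
    """Join a user-supplied repeat annotation onto junction arms.

    ``annotations`` are (Interval, class) pairs (e.g. from
    :func:`amprearr.io.read_bed_annotated`).  Each arm's class (or '') is
    stored in ``junction.extra['repeat_class_a'/'repeat_class_b']``; classes
    of overlapping annotations are joined with ','.  No repeat inference is
    performed — the annotation is taken as given.
    """

    def classes_at(chrom: str, pos: int) -> str:
        hits = sorted(
            {name for iv, name in annotations if name and iv.contains(chrom, pos)}
        )
        return ",".join(hits)

    for j in junctions:
        j.extra["repeat_class_a"] = classes_at(j.arm_a.chrom, j.arm_a.pos)
        j.extra["repeat_class_b"] = classes_at(j.arm_b.chrom, j.arm_b.pos)


# ---------------------------------------------------------------------------
# insertion calling from spanning sequence


class UnanchoredJunction(ValueError):
    """The spanning sequence could not be anchored to both reference flanks."""


def _anchor_left(span: str, kept_a: str, seed_len: int) -> int:
    """Index in span just past the last base attributable to arm_a's retained
    reference, found by exact seed + extension to the seam."""
    seed = span[:seed_len]
    if len(seed) < seed_len:
        raise UnanchoredJunction("spanning sequence shorter than seed")
    start = 0
    while True:
        i = kept_a.find(seed, start)
        if i < 0:
            raise UnanchoredJunction("left flank failed to anchor")
        a_part = kept_a[i:]
        if span[: len(a_part)] == a_part:
            return len(a_part)
        start = i + 1


def _anchor_right(span: str, kept_b: str, seed_len: int) -> int:
    """Index in span of the first base attributable to arm_b's retained
    reference."""
    seed = span[-seed_len:]
    if len(seed) < seed_len:
        raise UnanchoredJunction("spanning sequence shorter than seed")
    start = 0
    while True:
        m = kept_b.find(seed, start)
        if m < 0:
            raise UnanchoredJunction("right flank failed to anchor")
        t = m + seed_len
        if t <= len(span) and span[-t:] == kept_b[:t]:
            return len(span) - t
        start = m + 1


def call_insertion(
    junction: Junction, genome: Genome, seed_len: int = 15
) -> Tuple[int, str]:
    """Call the untemplated insertion at a junction from its spanning sequence.

    Anchors the span to both retained reference flanks with exact seeds of
    ``seed_len`` bases extended to the seam; the bases between the two
    anchored flanks, attributable to neither reference, are the insertion.
    Returns ``(0, "")`` for a flush seam.  Raises :class:`UnanchoredJunction`
    if either flank fails to anchor.
    """
    span = junction.span_seq
    if not span:
        raise UnanchoredJunction(f"junction {junction.id} has no spanning sequence")
    span = span.upper()
    w = len(span) + seed_len
    kept_a, _, _ = arm_flanks(junction.arm_a, genome, w, "left")
    kept_b, _, _ = arm_flanks(junction.arm_b, genome, w, "right")
    seam_a = _anchor_left(span, kept_a, seed_len)
    seam_b = _anchor_right(span, kept_b, seed_len)
    if seam_b < seam_a:
        # flanks overlap inside the span: the overlap is attributable to both
        # references (microhomology), not an insertion
        return 0, ""
    return seam_b - seam_a, span[seam_a:seam_b]


# ---------------------------------------------------------------------------
# templated-insert search in breakend flank windows


@dataclass(frozen=True)
class TemplateHit:
    chrom: str
    start: int  # 1-based start of the matched window in the reference
    end: int
    strand: str
    identity: float
    score: float


@dataclass
class TemplateSearchResult:
    searched: bool
    hits: List[TemplateHit] = field(default_factory=list)


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -0.5
    return a


def search_insert_template(
    inserted_seq: str,
    genome: Genome,
    junction: Junction,
    flank_window: int = 2000,
    min_identity: float = 0.9,
    min_len: int = 20,
) -> TemplateSearchResult:
    """Search both strands of the windows around both breakends for a
    (near-)copy of the inserted sequence.

    Inserts shorter than ``min_len`` are not searched (result flagged).  A hit
    is a local alignment whose matched bases cover at least ``min_identity``
    of the insert length.
    """
    insert = inserted_seq.upper()
    if len(insert) < min_len:
        return TemplateSearchResult(searched=False)
    aligner = _local_aligner()
    hits: List[TemplateHit] = []
    seen = set()
    for arm in (junction.arm_a, junction.arm_b):
        seq = genome[arm.chrom]
        lo = max(0, arm.pos - 1 - flank_window)
        hi = min(len(seq), arm.pos + flank_window)
        window = seq[lo:hi]
        if not window:
            continue
        for strand, query in (("+", insert), ("-", revcomp(insert))):
            alns = aligner.align(window, query)
            if len(alns) == 0:
                continue
            aln = alns[0]
            matches = sum(
                1
                for (ts, te), (qs, qe) in zip(*aln.aligned)
                for t, q in zip(window[ts:te], query[qs:qe])
                if t == q
            )
            identity = matches / len(insert)
            if identity >= min_identity:
                tstart = int(aln.aligned[0][0][0])
                tend = int(aln.aligned[0][-1][1])
                key = (arm.chrom, lo + tstart, strand)
                if key in seen:
                    continue
                seen.add(key)
                hits.append(
                    TemplateHit(
                        chrom=arm.chrom,
                        start=lo + tstart + 1,
                        end=lo + tend,
                        strand=strand,
                        identity=identity,
                        score=float(aln.score),
                    )
                )
    return TemplateSearchResult(searched=True, hits=hits)


# ---------------------------------------------------------------------------
# flank variant scan

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass(frozen=True)
class FlankVariant:
    kind: str  # "substitution" | "insertion" | "deletion"
    offset: int  # position relative to the seam: negative = a-side flank
    length: int
    ref: str
    obs: str
    klass: Optional[str] = None  # "transition" | "transversion" for substitutions


def classify_substitution(ref: str, obs: str) -> str:
    for b in (ref, obs):
        if b not in "ACGT":
            raise ValueError(f"ambiguity code {b!r} not supported")
    if (ref in _PURINES) == (obs in _PURINES):
        return "transition"
    return "transversion"


def _flank_aligner(free: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -3
    a.extend_gap_score = -0.5
    # let the observed sequence overhang on its seam-facing end
    if free == "right":
        a.open_right_deletion_score = 0
        a.extend_right_deletion_score = 0
    else:
        a.open_left_deletion_score = 0
        a.extend_left_deletion_score = 0
    return a


def _variants_from_alignment(
    ref: str, obs: str, aln, to_offset
) -> List[FlankVariant]:
    out: List[FlankVariant] = []
    taln, qaln = aln.aligned
    # substitutions inside aligned blocks
    for (ts, te), (qs, qe) in zip(taln, qaln):
        for k in range(te - ts):
            r, o = ref[ts + k], obs[qs + k]
            if r != o:
                out.append(
                    FlankVariant(
                        "substitution",
                        to_offset(ts + k),
                        1,
                        r,
                        o,
                        classify_substitution(r, o),
                    )
                )
    # gaps between consecutive blocks
    for (t0, t1), (q0, q1) in zip(
        zip([b[1] for b in taln[:-1]], [b[0] for b in taln[1:]]),
        zip([b[1] for b in qaln[:-1]], [b[0] for b in qaln[1:]]),
    ):
        if t1 > t0:  # bases of the reference missing from the observed flank
            out.append(
                FlankVariant("deletion", to_offset(t0), t1 - t0, ref[t0:t1], "")
            )
        if q1 > q0:  # extra observed bases
            out.append(
                FlankVariant("insertion", to_offset(t0), q1 - q0, "", obs[q0:q1])
            )
    return out


def scan_flank_variants(
    junction: Junction, genome: Genome, window: int = 50, seed_len: int = 15
) -> List[FlankVariant]:
    """Scan the spanning sequence's two flanks against the reference.

    Each flank of the spanning sequence (up to ``window`` bases each side of
    the seam, insertion excluded) is globally aligned to its reference
    counterpart; substitutions are classified transition/transversion and
    indels reported with their length.  Offsets are relative to the seam
    (negative on the arm_a side).  Raises :class:`UnanchoredJunction` when the
    span cannot be split at the seam.
    """
    span = junction.span_seq
    if not span:
        raise UnanchoredJunction(f"junction {junction.id} has no spanning sequence")
    span = span.upper()
    kept_a, _, _ = arm_flanks(junction.arm_a, genome, window, "left")
    kept_b, _, _ = arm_flanks(junction.arm_b, genome, window, "right")
    obs_a, obs_b = _split_span(span, junction, genome, seed_len, window)
    variants: List[FlankVariant] = []
    if obs_a and kept_a:
        aln = _flank_aligner("left").align(kept_a, obs_a)[0]
        variants.extend(
            _variants_from_alignment(
                kept_a, obs_a, aln, lambda t: t - len(kept_a)
            )
        )
    if obs_b and kept_b:
        aln = _flank_aligner("right").align(kept_b, obs_b)[0]
        variants.extend(
            _variants_from_alignment(kept_b, obs_b, aln, lambda t: t + 1)
        )
    return [v for v in variants if -window <= v.offset <= window]


def _split_span(
    span: str, junction: Junction, genome: Genome, seed_len: int, window: int
) -> Tuple[str, str]:
    """Split the spanning sequence into its two flank halves, excluding any
    called insertion.  Falls back to outer-seed anchoring when exact seam
    anchoring fails because of variants near the seam."""
    w = len(span) + seed_len
    kept_a, _, _ = arm_flanks(junction.arm_a, genome, w, "left")
    kept_b, _, _ = arm_flanks(junction.arm_b, genome, w, "right")
    try:
        seam_a = _anchor_left(span, kept_a, seed_len)
        seam_b = _anchor_right(span, kept_b, seed_len)
        if seam_b < seam_a:
            seam_b = seam_a
    except UnanchoredJunction:
        # anchor only the outer ends: locate the span's outermost seeds in the
        # reference and split at the expected flank lengths
        i = kept_a.find(span[:seed_len])
        m = kept_b.find(span[-seed_len:])
        if i < 0 or m < 0:
            raise
        seam_a = min(len(kept_a) - i, len(span))
        seam_b = max(len(span) - (m + seed_len), seam_a)
    return span[max(0, seam_a - window) : seam_a], span[seam_b : seam_b + window]


# ---------------------------------------------------------------------------
# characterization and summary


@dataclass
class JunctionCall:
    """A junction with its derived sequence characterization."""

    junction: Junction
    mh_left: int = 0
    mh_right: int = 0
    insertion_len: int = 0
    inserted_seq: str = ""
    truncated: bool = False
    template_hits: Optional[TemplateSearchResult] = None
    flank_variants: List[FlankVariant] = field(default_factory=list)

    @property
    def mh_len(self) -> int:
        return 0 if self.insertion_len > 0 else self.mh_left + self.mh_right

    @property
    def is_blunt(self) -> bool:
        return self.mh_len == 0 and self.insertion_len == 0


def characterize_junction(
    junction: Junction,
    genome: Genome,
    max_window: int = 50,
    search_templates: bool = False,
    scan_variants: bool = False,
) -> JunctionCall:
    """Full sequence characterization of one junction.

    If the junction carries a spanning sequence, the insertion is called from
    it; otherwise a caller-provided ``inserted_seq`` is trusted.  Junctions
    with an insertion get ``mh_len = 0``; the rest get the two-sided
    microhomology against the reference.
    """
    ins_len, ins_seq = 0, ""
    if junction.span_seq:
        ins_len, ins_seq = call_insertion(junction, genome)
    elif junction.inserted_seq:
        ins_seq = junction.inserted_seq
        ins_len = len(ins_seq)
    call = JunctionCall(junction=junction, insertion_len=ins_len, inserted_seq=ins_seq)
    if ins_len == 0:
        mh = microhomology_at(junction, genome, max_window=max_window)
        call.mh_left, call.mh_right = mh.left, mh.right
        call.truncated = mh.truncated
    if search_templates and ins_len > 0:
        call.template_hits = search_insert_template(ins_seq, genome, junction)
    if scan_variants and junction.span_seq:
        call.flank_variants = scan_flank_variants(junction, genome, window=max_window)
    return call


def junction_summary(calls: Sequence[JunctionCall]) -> dict:
    """Summary statistics over characterized junctions.

    Reports counts by microhomology length, the blunt fraction, the fraction
    with any microhomology among insertion-free junctions, the same fraction
    over all junctions (both denominators are reported explicitly), and the
    insertion fraction, plus a per-sample breakdown.
    """
    n = len(calls)
    by_mh: Dict[int, int] = {}
    n_ins = 0
    n_blunt = 0
    n_mh_pos = 0
    for c in calls:
        if c.insertion_len > 0:
            n_ins += 1
        else:
            by_mh[c.mh_len] = by_mh.get(c.mh_len, 0) + 1
            if c.mh_len >= 1:
                n_mh_pos += 1
        if c.is_blunt:
            n_blunt += 1
    n_free = n - n_ins
    per_sample: Dict[str, int] = {}
    for c in calls:
        for s in c.junction.samples:
            per_sample[s] = per_sample.get(s, 0) + 1
    return {
        "n_junctions": n,
        "n_insertion_free": n_free,
        "counts_by_mh": dict(sorted(by_mh.items())),
        "fraction_blunt": n_blunt / n if n else float("nan"),
        "fraction_with_insertion": n_ins / n if n else float("nan"),
        "fraction_mh_insertion_free": n_mh_pos / n_free if n_free else float("nan"),
        "fraction_mh_all": n_mh_pos / n if n else float("nan"),
        "per_sample": per_sample,
    }
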