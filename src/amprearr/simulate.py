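"""Synthetic amplicon rearrangement generator with full truth tables.

The generator emulates the architecture of a sequenced amplicon living either
extrachromosomally (double minutes, "dmin" mode: closed circles) or
intrachromosomally (homogeneously staining region, "hsr" mode: one linear
chain):

* amplified source regions with segment-level copy-number steps centred on
  ~15-fold (a fraction of fragments carries twice the copies, giving the two
  amplification levels seen in real read-depth profiles);
* breakpoints grouped in clusters of a few hundred to a few thousand bp
  (uniform spans 100-2500 bp, 2-7 breaks per cluster) separated by at least
  tens of kb, plus occasional singleton breaks;
* fragments between breakpoints joined with a tunable microhomology bias
  (join weight (1 + beta)^mh over candidate free ends) or, with probability
  ``p_insertion``, through a short untemplated insertion (i.i.d. uniform
  bases, geometric length of mean 8 capped at 42 bp) which forces the
  microhomology call to 0;
* a passage transition in which fragments are lost independently, new breaks
  cut the survivors, and the surviving blocks re-join, so that successive
  passages share, lose and gain junctions.

Every random draw flows from ``SimConfig.seed``; a fixed seed reproduces all
outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io import DepthTrack
from .junctions import microhomology_at
from .model import Breakend, Interval, Junction, Orientation

Genome = Dict[str, str]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_reference(
    length_by_chrom: Dict[str, int], gc_fraction: float = 0.5, seed: int = 0
) -> Genome:
    """I.i.d. random genome with the stated GC fraction, deterministic under
    ``seed``.  Chromosomes must be at least 1 kb long."""
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError(f"gc_fraction must be in (0, 1), got {gc_fraction}")
    rng = np.random.default_rng(seed)
    genome: Genome = {}
    for chrom, length in length_by_chrom.items():
        if length < 1000:
            raise ValueError(f"chromosome {chrom}: length {length} < 1 kb")
        if gc_fraction == 0.5:
            codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        else:
            at = (1.0 - gc_fraction) / 2.0
            gc = gc_fraction / 2.0
            cum = np.cumsum([at, gc, gc, at])
            codes = np.searchsorted(cum, rng.random(length)).astype(np.uint8)
        genome[chrom] = _BASES[codes].tobytes().decode("ascii")
    return genome


def _default_source_regions() -> List[Interval]:
    # two amplified regions per chromosome, a co-amplification layout at
    # roughly one tenth of genomic scale
    return [
        Interval("7", 100_001, 140_000),
        Interval("7", 300_001, 390_000),
        Interval("8", 100_001, 303_000),
        Interval("8", 400_001, 667_000),
    ]


@dataclass
class SimConfig:
    """Generator parameters; the defaults are the study conditions emulated."""

    genome_length: Dict[str, int] = field(
        default_factory=lambda: {"7": 1_000_000, "8": 1_000_000}
    )
    gc_fraction: float = 0.5
    source_regions: List[Interval] = field(default_factory=_default_source_regions)
    n_clusters: int = 17
    cluster_span: Tuple[int, int] = (100, 2500)
    breaks_per_cluster: Tuple[int, int] = (2, 7)
    inter_cluster_min_gap: int = 10_000
    singleton_break_rate: float = 1.0  # expected singletons per cluster
    mh_bias: float = 0.65  # join weight (1 + bias)^mh
    p_insertion: float = 0.3
    insertion_mean_len: float = 8.0
    insertion_max_len: int = 42
    cn_mean: float = 15.0
    cn_sd: float = 2.0
    p_cn_double: float = 0.3  # second amplification level (twice the copies)
    passage_loss_prob: float = 0.35
    passage_new_break_rate: float = 8.0  # Poisson mean of new cuts
    mode: str = "dmin"  # "dmin" (circles) or "hsr" (one chain)
    n_episomes: int = 3
    allow_inversion: bool = True
    candidate_pool: int = 40  # candidate ends scored per biased join
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "p_insertion", "p_cn_double", "passage_loss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mh_bias < 0:
            raise ValueError("mh_bias must be >= 0")
        if self.mode not in ("dmin", "hsr"):
            raise ValueError(f"mode must be 'dmin' or 'hsr', got {self.mode!r}")


@dataclass
class Fragment:
    id: str
    interval: Interval
    copy_number: int
    parent: Optional[str] = None  # fragment this piece was cut from

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class Join:
    """One realized junction between two oriented fragment ends."""

    id: str
    left_frag: str
    left_flip: bool
    right_frag: str
    right_flip: bool
    arm_a: Breakend
    arm_b: Breakend
    mh_len: int
    inserted_seq: str = ""
    fate: str = ""  # "retained" | "new" on a transitioned truth


@dataclass
class Structure:
    """A simulated amplicon molecule: a circle (dmin) or chain (hsr).

    ``join_ids[k]`` is the junction between ``elements[k]`` and
    ``elements[k+1]`` (modulo length for circles).
    """

    kind: str  # "circle" | "chain"
    elements: List[Tuple[str, bool]]  # (fragment id, flipped)
    join_ids: List[str]


@dataclass
class SimTruth:
    """Full generative record of a simulated amplicon."""

    genome: Genome
    config: SimConfig
    fragments: Dict[str, Fragment]
    structures: List[Structure]
    joins: List[Join]
    passage: int = 1
    fragment_fates: Dict[str, str] = field(default_factory=dict)
    junction_fates: Dict[str, str] = field(default_factory=dict)
    empty: bool = False

    def join_by_id(self, jid: str) -> Join:
        return next(j for j in self.joins if j.id == jid)

    def junction_objects(self, sample: str = "sim") -> List[Junction]:
        return [
            Junction(
                id=j.id,
                arm_a=j.arm_a,
                arm_b=j.arm_b,
                support=0,
                inserted_seq=j.inserted_seq,
                mh_len=0 if j.inserted_seq else j.mh_len,
                samples=frozenset([sample]),
            )
            for j in self.joins
        ]


# ---------------------------------------------------------------------------
# breakend arithmetic for oriented fragment ends


def trailing_end(frag: Fragment, flipped: bool) -> Breakend:
    """Breakend at the end of a fragment read in its chain orientation."""
    if flipped:
        return Breakend(
            frag.interval.chrom, frag.interval.start, Orientation.RIGHT_RETAINED
        )
    return Breakend(frag.interval.chrom, frag.interval.end, Orientation.LEFT_RETAINED)


def leading_end(frag: Fragment, flipped: bool) -> Breakend:
    """Breakend at the start of a fragment read in its chain orientation."""
    if flipped:
        return Breakend(
            frag.interval.chrom, frag.interval.end, Orientation.LEFT_RETAINED
        )
    return Breakend(frag.interval.chrom, frag.interval.start, Orientation.RIGHT_RETAINED)


def _reconstitutes_reference(a: Breakend, b: Breakend) -> bool:
    """True when fusing ``a`` (left arm) to ``b`` (right arm) rebuilds the
    contiguous reference, i.e. is not a junction at all."""
    if a.chrom != b.chrom:
        return False
    if a.orient is Orientation.LEFT_RETAINED and b.orient is Orientation.RIGHT_RETAINED:
        return b.pos == a.pos + 1
    if a.orient is Orientation.RIGHT_RETAINED and b.orient is Orientation.LEFT_RETAINED:
        return b.pos == a.pos - 1
    return False


# ---------------------------------------------------------------------------
# breakpoint placement


def _place_clusters(cfg: SimConfig, rng: np.random.Generator) -> Dict[str, List[int]]:
    """Cluster plus singleton breakpoint positions per chromosome.

    Cluster anchors are drawn uniformly within the source regions (no
    sequence determinant is modelled) with rejection sampling enforcing the
    inter-cluster minimum gap; breakpoints within a cluster are distinct
    offsets over the cluster span.
    """
    import bisect

    regions = cfg.source_regions
    weights = np.array([iv.length for iv in regions], dtype=float)
    weights /= weights.sum()
    attempts = 0
    max_attempts = 500 * max(cfg.n_clusters, 1)
    span_hi = cfg.cluster_span[1]
    placed: List[Tuple[str, int, Interval]] = []
    by_chrom_sorted: Dict[str, List[int]] = {}
    min_sep = cfg.inter_cluster_min_gap + span_hi
    while len(placed) < cfg.n_clusters:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "source regions too small for the requested number of "
                "breakpoint clusters at the configured inter-cluster gap"
            )
        region = regions[int(rng.choice(len(regions), p=weights))]
        if region.length <= span_hi + 2:
            continue
        pos = int(rng.integers(region.start, region.end - span_hi))
        taken = by_chrom_sorted.setdefault(region.chrom, [])
        i = bisect.bisect_left(taken, pos)
        if (i > 0 and pos - taken[i - 1] < min_sep) or (
            i < len(taken) and taken[i] - pos < min_sep
        ):
            continue
        taken.insert(i, pos)
        placed.append((region.chrom, pos, region))
    breaks: Dict[str, set] = {}
    for chrom, anchor, region in placed:
        span = int(rng.integers(cfg.cluster_span[0], cfg.cluster_span[1] + 1))
        k = int(
            rng.integers(cfg.breaks_per_cluster[0], cfg.breaks_per_cluster[1] + 1)
        )
        offsets = rng.choice(span + 1, size=min(k, span + 1), replace=False)
        for off in offsets:
            breaks.setdefault(chrom, set()).add(
                min(anchor + int(off), region.end - 1)
            )
    n_single = int(rng.poisson(cfg.singleton_break_rate * cfg.n_clusters))
    for _ in range(n_single):
        region = regions[int(rng.choice(len(regions), p=weights))]
        pos = int(rng.integers(region.start, region.end))
        breaks.setdefault(region.chrom, set()).add(pos)
    return {c: sorted(s) for c, s in breaks.items()}


def _cut_source_regions(
    cfg: SimConfig, breaks: Dict[str, List[int]], rng: np.random.Generator
) -> Dict[str, Fragment]:
    """Cut each source region at its breakpoints ("cut after position b")
    and draw a copy number per fragment."""
    fragments: Dict[str, Fragment] = {}
    counter = 0
    for region in cfg.source_regions:
        inside = [
            b for b in breaks.get(region.chrom, []) if region.start <= b < region.end
        ]
        bounds = [region.start - 1] + inside + [region.end]
        for lo, hi in zip(bounds, bounds[1:]):
            counter += 1
            cn = int(max(1, round(rng.normal(cfg.cn_mean, cfg.cn_sd))))
            if rng.random() < cfg.p_cn_double:
                cn *= 2
            fragments[f"f{counter}"] = Fragment(
                id=f"f{counter}",
                interval=Interval(region.chrom, lo + 1, hi),
                copy_number=cn,
            )
    return fragments


# ---------------------------------------------------------------------------
# microhomology-biased chaining

Block = List[Tuple[str, bool]]


def _flip_block(block: Block) -> Block:
    return [(fid, not flip) for fid, flip in reversed(block)]


class _JoinSampler:
    """Samples the partner of a free fragment end.

    With zero bias the choice among candidates is uniform and no
    microhomology is evaluated except for the realized join; with positive
    bias a capped random subset (``candidate_pool``) is scored with weight
    (1 + bias)^mh.  With probability ``p_insertion`` the join instead
    receives an untemplated insert and its microhomology is recorded as 0.
    """

    def __init__(
        self,
        cfg: SimConfig,
        genome: Genome,
        rng: np.random.Generator,
        start_index: int = 0,
    ):
        self.cfg = cfg
        self.genome = genome
        self.rng = rng
        self.counter = start_index

    def _mh(self, a: Breakend, b: Breakend) -> int:
        j = Junction(id="tmp", arm_a=a, arm_b=b)
        return microhomology_at(j, self.genome, max_window=50).total

    def _draw_insert(self) -> str:
        n = int(self.rng.geometric(1.0 / self.cfg.insertion_mean_len))
        n = min(n, self.cfg.insertion_max_len)
        codes = self.rng.choice(4, size=n)
        return _BASES[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")

    def pick_and_join(
        self, tail: Breakend, n_cand: int, lead_of, left: Tuple[str, bool]
    ) -> Tuple[int, Join]:
        """Choose among ``n_cand`` candidate leading ends (materialized lazily
        through ``lead_of``) and realize the join."""
        cfg = self.cfg
        insertion = self.rng.random() < cfg.p_insertion
        if insertion or cfg.mh_bias == 0 or n_cand == 1:
            chosen = int(self.rng.integers(n_cand))
            if n_cand > 1:
                # avoid rebuilding the contiguous reference; collisions are
                # rare, so a bounded redraw suffices
                for _ in range(20):
                    if not _reconstitutes_reference(tail, lead_of(chosen)):
                        break
                    chosen = int(self.rng.integers(n_cand))
        else:
            if n_cand > cfg.candidate_pool:
                sel = self.rng.choice(n_cand, size=cfg.candidate_pool, replace=False)
            else:
                sel = np.arange(n_cand)
            pool = [(int(i), lead_of(int(i))) for i in sel]
            usable = [
                (i, be) for i, be in pool if not _reconstitutes_reference(tail, be)
            ] or pool
            weights = np.array(
                [(1.0 + cfg.mh_bias) ** self._mh(tail, be) for _, be in usable]
            )
            weights /= weights.sum()
            chosen = usable[int(self.rng.choice(len(usable), p=weights))][0]
        lead = lead_of(chosen)
        self.counter += 1
        ins = self._draw_insert() if insertion else ""
        mh = 0 if insertion else self._mh(tail, lead)
        join = Join(
            id=f"j{self.counter}",
            left_frag=left[0],
            left_flip=left[1],
            right_frag="",
            right_flip=False,
            arm_a=tail,
            arm_b=lead,
            mh_len=mh,
            inserted_seq=ins,
        )
        return chosen, join


def _assemble(
    blocks: List[Tuple[Block, List[str]]],
    kind: str,
    frags: Dict[str, Fragment],
    sampler: _JoinSampler,
    rng: np.random.Generator,
    allow_inversion: bool,
) -> Tuple[Structure, List[Join]]:
    """Chain blocks into one structure, sampling a new join per boundary.

    Each block is a run of oriented fragments with its internal (already
    existing) join ids; blocks may be used in either orientation when
    inversions are allowed.
    """
    free = list(range(len(blocks)))
    start = free.pop(int(rng.integers(len(free))))
    chain: Block = list(blocks[start][0])
    join_ids: List[str] = list(blocks[start][1])
    new_joins: List[Join] = []
    per_block = 2 if allow_inversion else 1

    def lead_of(i: int) -> Breakend:
        b, _ = blocks[free[i // per_block]]
        if i % per_block == 0:
            fid, flip = b[0]
            return leading_end(frags[fid], flip)
        fid, flip = b[-1]  # block used in reverse orientation
        return leading_end(frags[fid], not flip)

    while free:
        tail_fid, tail_flip = chain[-1]
        tail = trailing_end(frags[tail_fid], tail_flip)
        chosen, join = sampler.pick_and_join(
            tail, len(free) * per_block, lead_of, (tail_fid, tail_flip)
        )
        b, ij = blocks[free[chosen // per_block]]
        if chosen % per_block == 1:
            b, ij = _flip_block(b), list(reversed(ij))
        join.right_frag, join.right_flip = b[0]
        new_joins.append(join)
        join_ids.append(join.id)
        join_ids.extend(ij)
        chain.extend(b)
        free.pop(chosen // per_block)
    if kind == "circle":
        tail_fid, tail_flip = chain[-1]
        lead_fid, lead_flip = chain[0]
        tail = trailing_end(frags[tail_fid], tail_flip)
        _, join = sampler.pick_and_join(
            tail,
            1,
            lambda _i: leading_end(frags[lead_fid], lead_flip),
            (tail_fid, tail_flip),
        )
        join.right_frag, join.right_flip = lead_fid, lead_flip
        new_joins.append(join)
        join_ids.append(join.id)
    return Structure(kind=kind, elements=chain, join_ids=join_ids), new_joins


def simulate_amplicon(config: SimConfig, genome: Optional[Genome] = None) -> SimTruth:
    """Generate a full amplicon: clustered breakpoints, fragments with copy
    numbers, and microhomology-biased joins arranged as circles (dmin mode)
    or one linear chain (hsr mode)."""
    rng = np.random.default_rng(config.seed)
    if genome is None:
        genome = simulate_reference(
            config.genome_length, config.gc_fraction, config.seed
        )
    for iv in config.source_regions:
        if iv.chrom not in genome or iv.end > len(genome[iv.chrom]):
            raise ValueError(f"source region {iv} outside the genome")
    breaks = _place_clusters(config, rng)
    frags = _cut_source_regions(config, breaks, rng)
    sampler = _JoinSampler(config, genome, rng)
    ids = list(frags)
    if config.mode == "hsr":
        groups = [ids]
        kind = "chain"
    else:
        n_groups = min(config.n_episomes, len(ids))
        assignment = rng.integers(n_groups, size=len(ids))
        for g in range(n_groups):
            if not np.any(assignment == g):
                assignment[int(rng.integers(len(ids)))] = g
        groups = [
            [fid for fid, a in zip(ids, assignment) if a == g] for g in range(n_groups)
        ]
        groups = [g for g in groups if g]
        kind = "circle"
    structures: List[Structure] = []
    joins: List[Join] = []
    for group in groups:
        blocks: List[Tuple[Block, List[str]]] = []
        for fid in group:
            flip = bool(rng.random() < 0.5) if config.allow_inversion else False
            blocks.append(([(fid, flip)], []))
        structure, new_joins = _assemble(
            blocks, kind, frags, sampler, rng, config.allow_inversion
        )
        structures.append(structure)
        joins.extend(new_joins)
    return SimTruth(
        genome=genome,
        config=config,
        fragments=frags,
        structures=structures,
        joins=joins,
        passage=1,
    )


# ---------------------------------------------------------------------------
# passage transition


def apply_passage_transition(
    truth: SimTruth, config: Optional[SimConfig] = None
) -> SimTruth:
    """Simulate one serial passage of the amplicon.

    Fragments are lost independently with ``passage_loss_prob``; a junction
    survives iff both its flanking fragments survive.  Poisson-many new
    breaks cut surviving fragments, and the resulting blocks (maximal runs
    still held together by surviving junctions) re-join in random order with
    freshly sampled junctions (fate "new").  Structures untouched by loss or
    cuts persist intact, so zero loss and zero new breaks leave the junction
    set identical.  A circle touched only by cuts is opened at its wrap-around
    join (that join is fated "lost").  An all-lost transition yields an
    empty amplicon, flagged.
    """
    cfg = config or truth.config
    rng = np.random.default_rng((cfg.seed, 104729))
    frag_fate: Dict[str, str] = {
        fid: "lost" if rng.random() < cfg.passage_loss_prob else "retained"
        for fid in truth.fragments
    }

    # new cuts on surviving fragments (recursively cuttable)
    leaves: Dict[str, Fragment] = {
        fid: f for fid, f in truth.fragments.items() if frag_fate[fid] == "retained"
    }
    all_frags: Dict[str, Fragment] = dict(truth.fragments)
    children: Dict[str, List[str]] = {}
    n_cuts = int(rng.poisson(cfg.passage_new_break_rate))
    for _ in range(n_cuts):
        cuttable = sorted(fid for fid, f in leaves.items() if f.length >= 2)
        if not cuttable:
            break
        fid = cuttable[int(rng.integers(len(cuttable)))]
        f = leaves.pop(fid)
        cut = int(rng.integers(f.interval.start, f.interval.end))
        p1 = Fragment(
            f"{fid}a",
            Interval(f.interval.chrom, f.interval.start, cut),
            f.copy_number,
            parent=fid,
        )
        p2 = Fragment(
            f"{fid}b",
            Interval(f.interval.chrom, cut + 1, f.interval.end),
            f.copy_number,
            parent=fid,
        )
        children[fid] = [p1.id, p2.id]
        leaves[p1.id] = p1
        leaves[p2.id] = p2
        all_frags[p1.id] = p1
        all_frags[p2.id] = p2

    def expand(fid: str, flip: bool) -> List[Block]:
        """Pieces of a fragment in chain order, one block per piece."""
        if fid in children:
            kids = children[fid][::-1] if flip else children[fid]
            out: List[Block] = []
            for k in kids:
                out.extend(expand(k, flip))
            return out
        return [[(fid, flip)]]

    blocks: List[Tuple[Block, List[str]]] = []
    kept_structures: List[Structure] = []

    for st in truth.structures:
        lost_any = any(frag_fate[fid] == "lost" for fid, _ in st.elements)
        cut_any = any(fid in children for fid, _ in st.elements)
        if not lost_any and not cut_any:
            kept_structures.append(st)
            continue
        elements = list(st.elements)
        jids = list(st.join_ids)
        if st.kind == "circle":
            n = len(elements)
            broken = [
                i
                for i in range(n)
                if frag_fate[elements[i][0]] == "lost"
                or frag_fate[elements[(i + 1) % n][0]] == "lost"
            ]
            k = (broken[0] + 1) % n if broken else 0
            elements = elements[k:] + elements[:k]
            jids = jids[k:] + jids[:k]
            jids = jids[:-1]  # the wrap join of the rotated order is dropped
        current: Block = []
        current_jids: List[str] = []

        def close() -> None:
            nonlocal current, current_jids
            if current:
                blocks.append((current, current_jids))
            current, current_jids = [], []

        for i, (fid, flip) in enumerate(elements):
            if frag_fate[fid] == "lost":
                close()
                continue
            pieces = expand(fid, flip)
            if len(pieces) > 1:
                current.extend(pieces[0])
                close()
                for p in pieces[1:-1]:
                    blocks.append((p, []))
                current = list(pieces[-1])
                current_jids = []
            else:
                current.extend(pieces[0])
            if i < len(jids) and frag_fate[elements[i + 1][0]] == "retained":
                current_jids.append(jids[i])
            else:
                close()
        close()

    structures = list(kept_structures)
    new_joins: List[Join] = []
    if blocks:
        max_jid = max((int(j.id[1:]) for j in truth.joins), default=0)
        sampler = _JoinSampler(cfg, truth.genome, rng, start_index=max_jid)
        order = rng.permutation(len(blocks))
        shuffled = [blocks[i] for i in order]
        if cfg.allow_inversion:
            shuffled = [
                ((_flip_block(b), list(reversed(ij))) if rng.random() < 0.5 else (b, ij))
                for b, ij in shuffled
            ]
        kind = "chain" if cfg.mode == "hsr" else "circle"
        st, new_joins = _assemble(
            shuffled, kind, all_frags, sampler, rng, cfg.allow_inversion
        )
        structures.append(st)

    # rebuild the join list from the final structures so fragment references
    # point at the actual (possibly cut) chain elements
    by_id = {j.id: j for j in truth.joins}
    by_id.update({j.id: j for j in new_joins})
    new_ids = {j.id for j in new_joins}
    final_joins: List[Join] = []
    retained_ids = set()
    for st in structures:
        m = len(st.elements)
        for k, jid in enumerate(st.join_ids):
            lf, lflip = st.elements[k]
            rf, rflip = st.elements[(k + 1) % m]
            fate = "new" if jid in new_ids else "retained"
            final_joins.append(
                dataclasses.replace(
                    by_id[jid],
                    left_frag=lf,
                    left_flip=lflip,
                    right_frag=rf,
                    right_flip=rflip,
                    fate=fate,
                )
            )
            if fate == "retained":
                retained_ids.add(jid)

    junction_fate = {
        j.id: ("retained" if j.id in retained_ids else "lost") for j in truth.joins
    }
    for jid in new_ids:
        junction_fate[jid] = "new"
    surviving = {fid for st in structures for fid, _ in st.elements}
    return SimTruth(
        genome=truth.genome,
        config=cfg,
        fragments={fid: all_frags[fid] for fid in surviving},
        structures=structures,
        joins=final_joins,
        passage=truth.passage + 1,
        fragment_fates=frag_fate,
        junction_fates=junction_fate,
        empty=len(surviving) == 0,
    )


# ---------------------------------------------------------------------------
# observables


@dataclass
class Observables:
    junctions: List[Junction]
    depth: DepthTrack
    spans: Dict[str, str]  # junction id -> spanning sequence


def emit_observables(
    truth: SimTruth,
    depth_per_copy: float = 0.67,
    baseline: float = 4.0,
    support_per_copy: float = 0.4,
    flank: int = 50,
    noise_seed: Optional[int] = None,
    sample: str = "sim",
) -> Observables:
    """Bridge a truth record to the pipeline's input formats.

    Depth per base is ``baseline + copy_number * depth_per_copy`` summed over
    covering fragments; junction read support is proportional to the mean
    copy number of its two fragments.  With ``noise_seed`` set both receive
    Poisson noise; in noiseless mode they are exact (support at least 1).
    Spanning sequences carry ``flank`` retained bases each side of the seam
    plus the realized insertion.
    """
    if depth_per_copy <= 0:
        raise ValueError("depth_per_copy must be > 0")
    from .junctions import arm_flanks

    rng = None if noise_seed is None else np.random.default_rng(noise_seed)
    arrays = {
        chrom: np.full(len(seq), float(baseline))
        for chrom, seq in truth.genome.items()
    }
    for frag in truth.fragments.values():
        iv = frag.interval
        arrays[iv.chrom][iv.start - 1 : iv.end] += frag.copy_number * depth_per_copy
    if rng is not None:
        arrays = {c: rng.poisson(a).astype(float) for c, a in arrays.items()}
    junctions: List[Junction] = []
    spans: Dict[str, str] = {}
    for j in truth.joins:
        kept_a, _, _ = arm_flanks(j.arm_a, truth.genome, flank, "left")
        kept_b, _, _ = arm_flanks(j.arm_b, truth.genome, flank, "right")
        span = kept_a + j.inserted_seq + kept_b
        cn = 0.5 * (
            truth.fragments[j.left_frag].copy_number
            + truth.fragments[j.right_frag].copy_number
        )
        mean_support = support_per_copy * cn
        if rng is None:
            support = max(1, int(round(mean_support)))
        else:
            support = int(rng.poisson(mean_support))
        junctions.append(
            Junction(
                id=j.id,
                arm_a=j.arm_a,
                arm_b=j.arm_b,
                support=support,
                inserted_seq=j.inserted_seq,
                span_seq=span,
                samples=frozenset([sample]),
            )
        )
        spans[j.id] = span
    return Observables(junctions=junctions, depth=DepthTrack(arrays), spans=spans)


def write_truth_tables(truth: SimTruth, fragments_path, joins_path) -> None:
    """Truth tables as TSV: fragments with copy numbers and fates; joins with
    realized microhomology, insertions and fates."""
    with open(fragments_path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\tcopy_number\tfate\n")
        for f in truth.fragments.values():
            fate = truth.fragment_fates.get(f.id, "")
            fh.write(
                f"{f.id}\t{f.interval.chrom}\t{f.interval.start}\t"
                f"{f.interval.end}\t{f.copy_number}\t{fate or '.'}\n"
            )
    with open(joins_path, "w") as fh:
        fh.write(
            "id\tchrom_a\tpos_a\torient_a\tchrom_b\tpos_b\torient_b\t"
            "mh_len\tinserted_seq\tfate\n"
        )
        for j in truth.joins:
            fh.write(
                f"{j.id}\t{j.arm_a.chrom}\t{j.arm_a.pos}\t{j.arm_a.orient.value}\t"
                f"{j.arm_b.chrom}\t{j.arm_b.pos}\t{j.arm_b.orient.value}\t"
                f"{j.mh_len}\t{j.inserted_seq or '.'}\t{j.fate or '.'}\n"
            )
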