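"""End-to-end orchestration: configuration, pipeline stages, fixtures.

The pipeline consumes junction calls (BEDPE-dialect TSV), a reference FASTA,
a per-base depth bedGraph and optionally a BED of amplified regions, and runs
the stage order: filter -> characterize -> null model / enrichment ->
breakpoint clustering -> contig assembly -> coordinated pairs -> (with two
samples) cross-passage comparison.  Every output is a plain TSV/BED and the
resolved configuration is echoed into the output directory for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import clustering, compare, contigs, coverage, io, junctions, nullmodel
from .model import Interval, Junction

log = logging.getLogger("amprearr")


@dataclass
class SampleConfig:
    name: str
    junctions: str
    depth: Optional[str] = None


@dataclass
class PipelineParams:
    bin_size: int = coverage.DEFAULT_BIN_SIZE
    min_fold: float = coverage.DEFAULT_MIN_FOLD
    baseline: Optional[float] = None  # estimated when None
    min_support: int = 3
    max_gap: int = clustering.DEFAULT_MAX_GAP
    max_link: int = contigs.DEFAULT_MAX_LINK
    tol: int = 0
    max_intra: int = 2000
    min_inter: int = 100_000
    null_composition: Optional[Dict[str, float]] = None


@dataclass
class PipelineConfig:
    reference: str
    samples: List[SampleConfig]
    output_dir: str
    amplified_bed: Optional[str] = None
    repeat_bed: Optional[str] = None  # optional repeat-class annotation
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        params_raw = raw.get("params", {}) or {}
        allowed_p = {f.name for f in dataclasses.fields(PipelineParams)}
        unknown_p = set(params_raw) - allowed_p
        if unknown_p:
            raise ValueError(f"unknown parameter keys: {sorted(unknown_p)}")
        samples = [SampleConfig(**s) for s in raw.get("samples", [])]
        return cls(
            reference=raw["reference"],
            samples=samples,
            output_dir=raw.get("output_dir", "amprearr_out"),
            amplified_bed=raw.get("amplified_bed"),
            repeat_bed=raw.get("repeat_bed"),
            params=PipelineParams(**params_raw),
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the summary dict also written to disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    ref_path = Path(config.reference)
    if not ref_path.exists():
        raise RuntimeError(f"pipeline stage 'inputs' failed: missing reference {ref_path}")
    genome = io.read_reference(ref_path)
    p = config.params
    summary: dict = {"samples": {}, "parameters": dataclasses.asdict(p)}
    per_sample_junctions: Dict[str, List[Junction]] = {}
    per_sample_amplified: Dict[str, List[Interval]] = {}
    for sample in config.samples:
        s = _run_sample(sample, genome, p, config, out)
        summary["samples"][sample.name] = s["summary"]
        per_sample_junctions[sample.name] = s["junctions"]
        per_sample_amplified[sample.name] = s["amplified"]
    if len(config.samples) == 2:
        a, b = config.samples[0].name, config.samples[1].name
        cmp = _stage("compare")(compare.match_junctions)(
            per_sample_junctions[a], per_sample_junctions[b], tol=p.tol
        )
        amp_cmp = coverage.compare_amplified(
            per_sample_amplified[a], per_sample_amplified[b]
        )
        csum = compare.comparison_summary(cmp, amp_cmp)
        _write_tsv(
            out / "junction_fates.tsv",
            ["id", "fate", "matched_id"],
            [[r["id"], r["fate"], r["matched_id"]] for r in compare.fate_table(cmp)],
        )
        summary["comparison"] = dataclasses.asdict(csum)
        log.info(
            "compare: %d shared, %d lost, %d gained, %d distinct",
            cmp.n_shared, cmp.n_lost, cmp.n_gained, cmp.n_union,
        )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary


def _run_sample(
    sample: SampleConfig,
    genome: Dict[str, str],
    p: PipelineParams,
    config: PipelineConfig,
    out: Path,
) -> dict:
    tag = sample.name
    raw = _stage("read_junctions")(io.read_junction_table)(sample.junctions)
    log.info("%s: %d raw junctions", tag, len(raw))

    amplified: Optional[List[Interval]] = None
    if config.amplified_bed:
        amplified = io.read_bed(config.amplified_bed)
    elif sample.depth:
        track = _stage("read_depth")(io.read_depth)(sample.depth)
        bins = coverage.bin_coverage(track, p.bin_size)
        baseline = (
            p.baseline
            if p.baseline is not None
            else coverage.estimate_baseline(bins)
        )
        segments = _stage("call_amplified")(coverage.call_amplified)(
            bins, baseline, min_fold=p.min_fold
        )
        amplified = [s.interval for s in segments]
        io.write_bed(amplified, out / f"{tag}.amplified.bed")
        log.info("%s: %d amplified segments (baseline %.2f)", tag, len(segments), baseline)

    kept = _stage("filter")(junctions.filter_junctions)(
        raw, min_support=p.min_support, amplified=amplified
    )
    log.info("%s: %d junctions pass filtering", tag, len(kept))
    if config.repeat_bed:
        junctions.annotate_repeat_class(kept, io.read_bed_annotated(config.repeat_bed))

    calls = [
        _stage("characterize")(junctions.characterize_junction)(j, genome)
        for j in kept
    ]
    _write_tsv(
        out / f"{tag}.junctions.tsv",
        ["id", "mh_left", "mh_right", "mh_len", "insertion_len", "inserted_seq"],
        [
            [c.junction.id, c.mh_left, c.mh_right, c.mh_len, c.insertion_len,
             c.inserted_seq or "."]
            for c in calls
        ],
    )
    jsum = junctions.junction_summary(calls)

    counts_vec = _mh_count_vector(calls)
    enr = None
    if counts_vec is not None:
        enr = _stage("enrichment")(nullmodel.enrichment_test)(
            counts_vec, composition=p.null_composition
        )
        _write_tsv(
            out / f"{tag}.mh_table.tsv",
            ["k", "observed", "expected"],
            [[int(k), int(o), f"{e:.3f}"] for k, o, e in enr.table],
        )

    breakends = [arm for j in kept for arm in (j.arm_a, j.arm_b)]
    clusters, singles = _stage("cluster")(clustering.cluster_breakpoints)(
        breakends, max_gap=p.max_gap
    )
    _write_tsv(
        out / f"{tag}.clusters.tsv",
        ["cluster", "chrom", "members", "n_breakpoints", "span", "anchor"],
        [
            [r["cluster"], r["chrom"], r["members"], r["n_breakpoints"],
             r["span"], r["anchor"]]
            for r in clustering.cluster_table(clusters)
        ],
    )

    links = contigs.build_arm_links(kept, max_link=p.max_link)
    contigs.write_link_graph(links, out / f"{tag}.links.tsv")
    asm = _stage("contigs")(contigs.assemble_contigs)(links, kept)
    mh_map = {c.junction.id: (None if c.insertion_len else c.mh_len) for c in calls}
    ins_map = {c.junction.id: c.insertion_len for c in calls}
    report = contigs.contig_report(asm, mh_map, ins_map)
    _write_tsv(
        out / f"{tag}.contigs.tsv",
        ["contig", "junctions", "microhomology", "fragment_lengths",
         "distances_kb", "circular"],
        [
            [r["contig"], r["junctions"], r["microhomology"],
             ",".join(str(x) for x in r["fragment_lengths"]),
             ",".join("na" if d is None else f"{d:g}" for d in r["distances_kb"]),
             r["circular"]]
            for r in report["rows"]
        ],
    )

    pairs = _stage("pairs")(contigs.detect_coordinated_pairs)(
        kept, max_intra=p.max_intra, min_inter=p.min_inter
    )

    return {
        "junctions": kept,
        "amplified": amplified or [],
        "summary": {
            "n_raw": len(raw),
            "n_filtered": len(kept),
            "junction_summary": jsum,
            "enrichment": None
            if enr is None
            else {
                "observed_fraction": enr.observed_fraction,
                "null_fraction": enr.null_fraction,
                "p_value": enr.p_value,
            },
            "n_clusters": len(clusters),
            "n_singletons": len(singles),
            "clustered_fraction": clustering.clustered_fraction(breakends, clusters),
            "n_contigs": len(report["rows"]),
            "contig_fraction_blunt": report["fraction_blunt"],
            "n_coordinated_pairs": len(pairs),
            "amplified_length": coverage.amplified_length_summary(amplified or []),
        },
    }


def _mh_count_vector(calls) -> Optional[List[int]]:
    mhs = [c.mh_len for c in calls if c.insertion_len == 0]
    if not mhs:
        return None
    vec = [0] * (max(mhs) + 1)
    for m in mhs:
        vec[m] += 1
    return vec


def _write_tsv(path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(seed: int = 0, outdir: str = "fixtures") -> dict:
    """Write a deterministic miniature dataset for tests and documentation.

    Two 1-Mb chromosomes, ~60 junctions, two passages (dmin-like circles at
    passage 2, one hsr-like chain at passage 4), plus the printed cluster and
    contig tables as TSV fixtures.  Returns the paths written.
    """
    from . import oda14, simulate

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = simulate.SimConfig(
        n_clusters=12,
        breaks_per_cluster=(2, 5),
        singleton_break_rate=0.5,
        seed=seed,
    )
    truth2 = simulate.simulate_amplicon(cfg)
    truth4 = simulate.apply_passage_transition(
        truth2, dataclasses.replace(cfg, mode="hsr")
    )
    io.write_reference(truth2.genome, out / "reference.fa")
    paths = {"reference": str(out / "reference.fa")}
    for name, truth in (("p2", truth2), ("p4", truth4)):
        obs = simulate.emit_observables(truth, noise_seed=seed + 1, sample=name)
        io.write_junction_table(obs.junctions, out / f"{name}.junctions.tsv")
        io.write_depth(obs.depth, out / f"{name}.depth.bedgraph")
        simulate.write_truth_tables(
            truth, out / f"{name}.truth_fragments.tsv", out / f"{name}.truth_joins.tsv"
        )
        paths[name] = str(out / f"{name}.junctions.tsv")
    _write_tsv(
        out / "printed_clusters_p2.tsv",
        ["cluster", "label", "position"],
        [list(row) for row in oda14.cluster_positions(oda14.CLUSTERS_P2)],
    )
    _write_tsv(
        out / "printed_contigs.tsv",
        ["passage", "contig", "junction", "mh"],
        [
            [row["passage"], row["contig"], arm, mh]
            for row in oda14.CONTIGS
            for arm, mh in zip(row["junctions"], row["mh"])
        ],
    )
    config = PipelineConfig(
        reference=str(out / "reference.fa"),
        samples=[
            SampleConfig("p2", str(out / "p2.junctions.tsv"), str(out / "p2.depth.bedgraph")),
            SampleConfig("p4", str(out / "p4.junctions.tsv"), str(out / "p4.depth.bedgraph")),
        ],
        output_dir=str(out / "pipeline_out"),
        seed=seed,
    )
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    paths["config"] = str(out / "config.yaml")
    return paths
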