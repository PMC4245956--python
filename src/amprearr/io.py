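"""Readers and writers for the external formats the pipeline touches.

Junction tables are a BEDPE dialect: tab-separated with a required header
line::

    chrom1 start1 end1 chrom2 start2 end2 id support orient1 orient2
    [inserted_seq] [span_seq] [samples]

Breakend intervals on disk are 0-based half-open single-base intervals
(``end = start + 1``); internally ``pos = start + 1`` (1-based).  Orientation
'+' means the reference upstream of the breakend is retained (LEFT_RETAINED),
'-' means downstream (RIGHT_RETAINED).  Optional columns may be omitted or
written as '.'.  Unknown columns are preserved as opaque string attributes in
``Junction.extra``.

Reference sequences are plain (optionally gzipped) FASTA; depth tracks are
bedGraph (0-based half-open); amplified regions and annotations are BED.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

from .model import Breakend, Interval, Junction, Orientation

PathLike = Union[str, Path]

REQUIRED_COLUMNS = (
    "chrom1",
    "start1",
    "end1",
    "chrom2",
    "start2",
    "end2",
    "id",
    "support",
    "orient1",
    "orient2",
)
OPTIONAL_COLUMNS = ("inserted_seq", "span_seq", "samples")


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# junction tables


def read_junction_table(
    path: PathLike, samples: Optional[Sequence[str]] = None
) -> List[Junction]:
    """Read a junction TSV, converting on-disk 0-based breakend intervals to
    internal 1-based positions.

    ``samples`` optionally declares the admissible sample names; a junction
    naming an undeclared sample is an error.
    """
    declared = None if samples is None else set(samples)
    junctions: List[Junction] = []
    with _open_text(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty file, header line required")
        header = header_line.lstrip("#").rstrip("\n").split("\t")
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: header missing columns {missing}")
        idx = {c: i for i, c in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            row = {c: fields[i] for c, i in idx.items()}
            try:
                junctions.append(_junction_from_row(row, header, declared))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return junctions


def _junction_from_row(row: dict, header: Sequence[str], declared) -> Junction:
    def breakend(which: str) -> Breakend:
        start = int(row[f"start{which}"])
        end = int(row[f"end{which}"])
        if end != start + 1:
            raise ValueError(
                f"breakend {which}: interval [{start},{end}) is not a "
                "single-base breakend"
            )
        orient = Orientation.from_symbol(row[f"orient{which}"])
        return Breakend(row[f"chrom{which}"], start + 1, orient)

    def opt(col: str) -> str:
        val = row.get(col, "")
        return "" if val == "." else val

    sample_field = opt("samples")
    sample_set = frozenset(s for s in sample_field.split(",") if s)
    if declared is not None:
        unknown = sample_set - declared
        if unknown:
            raise ValueError(f"undeclared sample names {sorted(unknown)}")
    span = opt("span_seq")
    extra = {
        c: row[c]
        for c in header
        if c not in REQUIRED_COLUMNS and c not in OPTIONAL_COLUMNS
    }
    return Junction(
        id=row["id"],
        arm_a=breakend("1"),
        arm_b=breakend("2"),
        support=int(row["support"]),
        inserted_seq=opt("inserted_seq").upper(),
        span_seq=span.upper() if span else None,
        samples=sample_set,
        extra=extra,
    )


def write_junction_table(
    junctions: Iterable[Junction], path: PathLike
) -> None:
    """Write a canonical junction TSV (all optional columns present, '.' for
    empty).  ``write(read(x))`` is byte-identical for canonical tables."""
    cols = REQUIRED_COLUMNS + OPTIONAL_COLUMNS
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(cols) + "\n")
        for j in junctions:
            fields = [
                j.arm_a.chrom,
                str(j.arm_a.pos - 1),
                str(j.arm_a.pos),
                j.arm_b.chrom,
                str(j.arm_b.pos - 1),
                str(j.arm_b.pos),
                j.id,
                str(j.support),
                j.arm_a.orient.value,
                j.arm_b.orient.value,
                j.inserted_seq or ".",
                j.span_seq or ".",
                ",".join(sorted(j.samples)) or ".",
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# reference FASTA


def read_reference(path: PathLike) -> Dict[str, str]:
    """Read a FASTA reference into a chrom -> upper-case sequence mapping."""
    genome: Dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in genome:
                raise ValueError(f"{path}: duplicate contig name {rec.id!r}")
            genome[rec.id] = str(rec.seq).upper()
    return genome


def write_reference(genome: Dict[str, str], path: PathLike, width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Alias used for spanning-sequence FASTA files."""
    return read_reference(path)


# ---------------------------------------------------------------------------
# depth tracks (bedGraph)


class DepthTrack:
    """Per-base depth with 1-based access; positions not covered are 0."""

    def __init__(self, arrays: Dict[str, np.ndarray]):
        self.arrays = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}

    def chroms(self) -> List[str]:
        return list(self.arrays)

    def depth(self, chrom: str, pos: int) -> float:
        arr = self.arrays.get(chrom)
        if arr is None or not (1 <= pos <= len(arr)):
            return 0.0
        return float(arr[pos - 1])

    def region(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Depth over the 1-based closed interval [start, end]."""
        arr = self.arrays.get(chrom)
        n = end - start + 1
        out = np.zeros(n)
        if arr is None:
            return out
        lo = max(start, 1)
        hi = min(end, len(arr))
        if hi >= lo:
            out[lo - start : hi - start + 1] = arr[lo - 1 : hi]
        return out


def read_depth(
    path: PathLike, chrom_lengths: Optional[Dict[str, int]] = None
) -> DepthTrack:
    """Read a bedGraph (0-based half-open) into a per-base :class:`DepthTrack`.

    Overlapping records are an error; gaps are depth 0.
    """
    records: Dict[str, list] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            records.setdefault(chrom, []).append((start, end, value))
    arrays: Dict[str, np.ndarray] = {}
    for chrom, recs in records.items():
        recs.sort()
        for (s1, e1, _), (s2, _, _) in zip(recs, recs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{path}: overlapping bedGraph records on {chrom} at {s2}"
                )
        length = recs[-1][1]
        if chrom_lengths and chrom in chrom_lengths:
            length = max(length, chrom_lengths[chrom])
        arr = np.zeros(length)
        for s, e, v in recs:
            arr[s:e] = v
        arrays[chrom] = arr
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            arrays.setdefault(chrom, np.zeros(length))
    return DepthTrack(arrays)


def write_depth(track: DepthTrack, path: PathLike) -> None:
    """Write a run-length-compressed bedGraph (zero runs skipped)."""
    with _open_text(path, "wt") as fh:
        for chrom, arr in track.arrays.items():
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")


# ---------------------------------------------------------------------------
# BED intervals


def read_bed(path: PathLike) -> List[Interval]:
    """Read BED (0-based half-open) into 1-based closed intervals."""
    out: List[Interval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty BED interval")
            out.append(Interval(chrom, start + 1, end))
    return out


def read_bed_annotated(path: PathLike) -> List[tuple]:
    """Read a BED with a name column (e.g. repeat class) into
    (Interval, name) pairs; rows without a name get ''."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            iv = Interval(parts[0], int(parts[1]) + 1, int(parts[2]))
            out.append((iv, parts[3] if len(parts) > 3 else ""))
    return out


def write_bed(intervals: Iterable[Interval], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")
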