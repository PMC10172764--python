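"""Sequence and interval data model plus FASTA/BED/bedGraph I/O.

Everything downstream works on three small containers: :class:`GenomeSequence`
(an upper-case ACGTN string), :class:`Interval` (BED-style, 0-based half-open)
and per-nucleotide tracks (:class:`LabelTrack`, :class:`ScoreTrack`).  A single
coordinate convention — 0-based half-open, as in BED — is used everywhere in
the toolkit; 1-based coordinates appear only in user-facing display strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "GenomeSequence",
    "Interval",
    "LabelTrack",
    "ScoreTrack",
    "read_fasta",
    "write_fasta",
    "intervals_from_bed",
    "intervals_to_bed",
    "track_from_intervals",
    "intervals_from_track",
    "merge_intervals",
    "intersect_intervals",
    "subtract_intervals",
    "interval_ops",
    "coverage_fraction",
    "write_bedgraph",
]


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"sequence {self.name!r} contains invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.seq)

    def revcomp(self) -> "GenomeSequence":
        return GenomeSequence(self.name, str(Seq(self.seq).reverse_complement()))


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class LabelTrack:
    """Per-nucleotide binary labels (1 = Z-prone) for one sequence."""

    chrom: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class ScoreTrack:
    """Per-nucleotide real-valued scores for one sequence."""

    chrom: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.isfinite(self.values).all():
            raise ValueError("score track must be finite")

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _sanitize(seq: str) -> str:
    s = seq.upper()
    return "".join(c if c in "ACGT" else "N" for c in s)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file; sequences are uppercased and non-ACGT mapped to N."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or malformed FASTA")
    return [GenomeSequence(r.id, _sanitize(str(r.seq))) for r in records]


def write_fasta(sequences: Iterable[GenomeSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.name, description="") for s in sequences]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def intervals_from_bed(path: str | Path) -> list[Interval]:
    """Parse a BED3+ file (0-based half-open) into intervals."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields, got {len(fields)}")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            score = None
            if len(fields) >= 5 and fields[4] not in {".", ""}:
                score = float(fields[4])
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(Interval(chrom, start, end, score=score, strand=strand))
    return out


def intervals_to_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write intervals to BED, sorted by (chrom, start)."""
    rows = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in rows:
            if iv.score is None and iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = "." if iv.score is None else f"{iv.score:g}"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{score}\t{iv.strand}\n")


def write_bedgraph(track: ScoreTrack, path: str | Path) -> None:
    """Write a ScoreTrack as bedGraph, run-length collapsing equal values."""
    vals = track.values
    with open(path, "w") as fh:
        if vals.size == 0:
            return
        change = np.flatnonzero(np.diff(vals) != 0)
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [vals.size]])
        for s, e in zip(starts, ends):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{vals[s]:g}\n")


# ---------------------------------------------------------------------------
# Interval <-> track conversions
# ---------------------------------------------------------------------------

def track_from_intervals(intervals: Sequence[Interval], seq_length: int, chrom: str | None = None) -> LabelTrack:
    """Binary per-nucleotide labels: 1 where covered by at least one interval."""
    if chrom is None:
        chrom = intervals[0].chrom if intervals else "chr"
    labels = np.zeros(seq_length, dtype=np.int8)
    for iv in intervals:
        if iv.start < 0 or iv.end > seq_length:
            raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} out of bounds for length {seq_length}")
        labels[iv.start : iv.end] = 1
    return LabelTrack(chrom, labels)


def intervals_from_track(track: LabelTrack, min_len: int = 1) -> list[Interval]:
    """Maximal runs of 1-labels as intervals (the inverse of track_from_intervals)."""
    lab = track.labels
    if lab.size == 0:
        return []
    padded = np.concatenate([[0], lab, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [Interval(track.chrom, int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


# ---------------------------------------------------------------------------
# Interval set algebra (bp semantics, per chromosome)
# ---------------------------------------------------------------------------

def _by_chrom(intervals: Iterable[Interval]) -> dict[str, list[tuple[int, int]]]:
    d: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        d.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom in d:
        d[chrom].sort()
    return d


def _merge_pairs(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in pairs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    out = []
    for chrom, pairs in sorted(_by_chrom(intervals).items()):
        out.extend(Interval(chrom, s, e) for s, e in _merge_pairs(pairs))
    return out


def intersect_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    da, db = _by_chrom(a), _by_chrom(b)
    missing = set(da) - set(db)
    if missing:
        log.warning("chromosomes %s absent from second interval set; treated as zero overlap", sorted(missing))
    out = []
    for chrom in sorted(da):
        pa = _merge_pairs(da[chrom])
        pb = _merge_pairs(db.get(chrom, []))
        i = j = 0
        while i < len(pa) and j < len(pb):
            s = max(pa[i][0], pb[j][0])
            e = min(pa[i][1], pb[j][1])
            if s < e:
                out.append(Interval(chrom, s, e))
            if pa[i][1] <= pb[j][1]:
                i += 1
            else:
                j += 1
    return out


def subtract_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    da, db = _by_chrom(a), _by_chrom(b)
    out = []
    for chrom in sorted(da):
        pb = _merge_pairs(db.get(chrom, []))
        for s, e in _merge_pairs(da[chrom]):
            cur = s
            for bs, be in pb:
                if be <= cur or bs >= e:
                    continue
                if bs > cur:
                    out.append(Interval(chrom, cur, bs))
                cur = max(cur, be)
                if cur >= e:
                    break
            if cur < e:
                out.append(Interval(chrom, cur, e))
    return out


def interval_ops(a: Iterable[Interval], b: Iterable[Interval], mode: str) -> list[Interval]:
    """Set algebra on interval lists; ``mode`` is intersect, subtract or merge."""
    if mode == "intersect":
        return intersect_intervals(a, b)
    if mode == "subtract":
        return subtract_intervals(a, b)
    if mode == "merge":
        return merge_intervals(list(a) + list(b))
    raise ValueError(f"unknown mode {mode!r}")


def total_bp(intervals: Iterable[Interval]) -> int:
    return sum(iv.length for iv in merge_intervals(intervals))


def coverage_fraction(a: Sequence[Interval], b: Sequence[Interval]) -> float:
    """Fraction of the bp of ``a`` covered by ``b`` (bp-level semantics)."""
    denom = total_bp(a)
    if denom == 0:
        return float("nan")
    return total_bp(intersect_intervals(a, b)) / denom
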