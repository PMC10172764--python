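"""Evaluation metrics and downstream genomic analytics.

Nucleotide-level confusion metrics and rank-based ROC AUC; classification of
intervals into the seven canonical genomic feature classes (promoter, 5'UTR,
exon, intron, 3'UTR, downstream, distal intergenic); segment-level overlap
recovery tables; enrichment (observed vs expected percentage) tables;
repeat-family base-score summaries; BZ-junction window extraction for motif
discovery; haplotype trait-direction scoring; and printed-precision
contingency ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genomeio import GenomeSequence, Interval, LabelTrack, ScoreTrack

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "FeatureAnnotation",
    "JunctionWindow",
    "Haplotype",
    "confusion_counts",
    "confusion_metrics",
    "roc_auc",
    "classify_feature",
    "overlap_recovery",
    "enrichment_table",
    "repeat_scores",
    "junction_windows",
    "junction_windows_to_fasta",
    "haplotype_score",
    "contingency_ratio",
]

FEATURE_CLASSES = (
    "Promoter (<=3 kb)",
    "5' UTR",
    "Exon",
    "Intron",
    "3' UTR",
    "Downstream (<=300)",
    "Distal Intergenic",
)


# ---------------------------------------------------------------------------
# Nucleotide-level evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def precision(self) -> float:
        d = self.TP + self.FP
        return self.TP / d if d else float("nan")

    @property
    def recall(self) -> float:
        d = self.TP + self.FN
        return self.TP / d if d else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if np.isnan(p) or np.isnan(r) or p + r == 0:
            return float("nan")
        return 2 * p * r / (p + r)


def confusion_counts(pred: np.ndarray, truth: np.ndarray, threshold: float = 0.5) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    call = pred >= threshold
    return ConfusionCounts(
        TP=int((call & truth).sum()),
        FP=int((call & ~truth).sum()),
        FN=int((~call & truth).sum()),
        TN=int((~call & ~truth).sum()),
    )


def confusion_metrics(pred, truth, threshold: float = 0.5) -> dict[str, float]:
    """Precision, recall and F1 at a probability threshold.

    Accepts arrays or PredictionTrack/LabelTrack objects.  Metrics with a
    zero denominator come back as NaN.
    """
    p = getattr(pred, "p", pred)
    t = getattr(truth, "labels", truth)
    cc = confusion_counts(p, t, threshold)
    return {"precision": cc.precision, "recall": cc.recall, "f1": cc.f1, "counts": cc}


def roc_auc(pred, truth) -> float:
    """Rank-based (Mann-Whitney) ROC AUC with midrank tie handling."""
    p = np.asarray(getattr(pred, "p", pred), dtype=np.float64)
    t = np.asarray(getattr(truth, "labels", truth)).astype(bool)
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(p)
    return float((ranks[t].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Genomic feature classification
# ---------------------------------------------------------------------------


@dataclass
class FeatureAnnotation:
    """A minimal gene model: TSS positions and feature intervals per class.

    ``promoter_window`` bp upstream of each TSS count as promoter;
    ``downstream_window`` bp past each gene end count as downstream.
    """

    tss: list[Interval] = field(default_factory=list)           # 1-bp TSS markers (strand-aware)
    utr5: list[Interval] = field(default_factory=list)
    exons: list[Interval] = field(default_factory=list)
    genes: list[Interval] = field(default_factory=list)          # gene bodies (introns = gene - exon)
    utr3: list[Interval] = field(default_factory=list)
    promoter_window: int = 3000
    downstream_window: int = 300

    def __post_init__(self) -> None:
        if self.promoter_window <= 0 or self.downstream_window <= 0:
            raise ValueError("annotation windows must be > 0")

    def chroms(self) -> set[str]:
        out = set()
        for group in (self.tss, self.utr5, self.exons, self.genes, self.utr3):
            out.update(iv.chrom for iv in group)
        return out


def _point_in(pos: int, chrom: str, intervals: Sequence[Interval]) -> bool:
    return any(iv.chrom == chrom and iv.start <= pos < iv.end for iv in intervals)


def classify_feature(interval: Interval, annotation: FeatureAnnotation) -> str:
    """Assign one of the seven feature classes to an interval's midpoint.

    Precedence: promoter > 5'UTR > exon > intron > 3'UTR > downstream >
    distal intergenic.  Intervals on unannotated chromosomes fall through to
    distal intergenic with a warning.
    """
    mid = interval.midpoint
    chrom = interval.chrom
    if chrom not in annotation.chroms():
        log.warning("chromosome %s not in annotation; classified as Distal Intergenic", chrom)
        return FEATURE_CLASSES[6]
    for t in annotation.tss:
        if t.chrom != chrom:
            continue
        if t.strand == "-":
            lo, hi = t.start + 1, t.start + 1 + annotation.promoter_window
        else:
            lo, hi = t.start - annotation.promoter_window, t.start
        if lo <= mid < hi:
            return FEATURE_CLASSES[0]
    if _point_in(mid, chrom, annotation.utr5):
        return FEATURE_CLASSES[1]
    if _point_in(mid, chrom, annotation.exons):
        return FEATURE_CLASSES[2]
    if _point_in(mid, chrom, annotation.genes):
        return FEATURE_CLASSES[3]  # in a gene but not exonic -> intron
    if _point_in(mid, chrom, annotation.utr3):
        return FEATURE_CLASSES[4]
    for g in annotation.genes:
        if g.chrom != chrom:
            continue
        if g.strand == "-":
            lo, hi = g.start - annotation.downstream_window, g.start
        else:
            lo, hi = g.end, g.end + annotation.downstream_window
        if lo <= mid < hi:
            return FEATURE_CLASSES[5]
    return FEATURE_CLASSES[6]


# ---------------------------------------------------------------------------
# Overlap and enrichment tables
# ---------------------------------------------------------------------------


def overlap_recovery(
    experimental: Sequence[Interval],
    predicted: Sequence[Interval],
    annotation: FeatureAnnotation | None = None,
) -> pd.DataFrame:
    """Per-feature-class recovery of experimental segments by predictions.

    Segment-level semantics: an experimental segment counts as shared when it
    intersects at least one predicted segment by >= 1 bp.  The percentage is
    shared / (shared + experimental-only) * 100.  Without an annotation a
    single "All" row is produced.
    """
    import bisect

    from .genomeio import merge_intervals

    pred_sorted: dict[str, list[tuple[int, int]]] = {}
    for iv in merge_intervals(predicted):
        pred_sorted.setdefault(iv.chrom, []).append((iv.start, iv.end))

    def is_shared(iv: Interval) -> bool:
        pairs = pred_sorted.get(iv.chrom, [])
        i = bisect.bisect_left(pairs, (iv.end, iv.end))
        # merged pairs are disjoint, so ends are sorted: scan back until clear
        for s, e in reversed(pairs[:i]):
            if e > iv.start:
                return True
            if e <= iv.start:
                return False
        return False

    rows: dict[str, dict[str, int]] = {}
    for iv in experimental:
        cls = classify_feature(iv, annotation) if annotation is not None else "All"
        row = rows.setdefault(cls, {"shared": 0, "experimental_only": 0})
        row["shared" if is_shared(iv) else "experimental_only"] += 1
    out = []
    order = list(FEATURE_CLASSES) if annotation is not None else ["All"]
    for cls in order:
        if cls not in rows:
            continue
        shared = rows[cls]["shared"]
        only = rows[cls]["experimental_only"]
        out.append(
            {
                "feature": cls,
                "shared": shared,
                "experimental_only": only,
                "percent": 100.0 * shared / (shared + only) if shared + only else float("nan"),
            }
        )
    return pd.DataFrame(out)


def enrichment_table(
    hits: Mapping[str, int], background: Mapping[str, int]
) -> pd.DataFrame:
    """Observed vs expected class percentages and their difference (pp).

    ``observed`` is each class's share of the hit counts, ``expected`` its
    share of the background counts; ``difference`` is observed − expected in
    percentage points.  Rows are sorted by observed share, descending.
    """
    tot_h = sum(hits.values())
    tot_b = sum(background.values())
    if tot_h == 0 or tot_b == 0:
        raise ValueError("hit and background totals must be positive")
    rows = []
    for cls in hits:
        obs = 100.0 * hits[cls] / tot_h
        exp = 100.0 * background.get(cls, 0) / tot_b
        rows.append({"class": cls, "count": hits[cls], "observed_pct": obs,
                     "expected_pct": exp, "difference_pp": obs - exp})
    return pd.DataFrame(rows).sort_values("observed_pct", ascending=False, ignore_index=True)


def repeat_scores(
    track: ScoreTrack, repeats: Mapping[str, Sequence[Interval]]
) -> pd.DataFrame:
    """Mean and max base score per repeat family over covered bases.

    Families with no covered bases are omitted with a warning.
    """
    rows = []
    for family, ivs in repeats.items():
        mask = np.zeros(len(track), dtype=bool)
        for iv in ivs:
            if iv.chrom != track.chrom:
                continue
            mask[iv.start : min(iv.end, len(track))] = True
        n = int(mask.sum())
        if n == 0:
            log.warning("repeat family %s covers no bases of %s; row omitted", family, track.chrom)
            continue
        vals = track.values[mask]
        rows.append(
            {
                "family": family,
                "bases_in_repeats": n,
                "mean_base_score": float(vals.mean()),
                "max_base_score": float(vals.max()),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("mean_base_score", ascending=False, ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# BZ junction windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JunctionWindow:
    """An 11-nt window centred on a segment boundary base (boundary ± 5)."""

    chrom: str
    start: int
    end: int
    side: str  # "start" or "end"
    seq: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq) or len(self.seq) != 11:
            raise ValueError("junction windows must be 11 nt")


def junction_windows(
    segments: Sequence[Interval],
    genome: Mapping[str, GenomeSequence] | GenomeSequence,
    flank: int = 5,
) -> list[JunctionWindow]:
    """Extract boundary windows (first base ± flank, last base ± flank).

    Windows that would run off a contig edge are dropped with a warning.
    The resulting 11-nt sequences are the standard input for external motif
    discovery (e.g. MEME).
    """
    if isinstance(genome, GenomeSequence):
        genome = {genome.name: genome}
    width = 2 * flank + 1
    out: list[JunctionWindow] = []
    dropped = 0
    for seg in segments:
        contig = genome.get(seg.chrom)
        if contig is None:
            log.warning("segment chrom %s absent from genome; skipped", seg.chrom)
            continue
        for side, center in (("start", seg.start), ("end", seg.end - 1)):
            lo, hi = center - flank, center + flank + 1
            if lo < 0 or hi > contig.length:
                dropped += 1
                continue
            out.append(JunctionWindow(seg.chrom, lo, hi, side, contig.seq[lo:hi]))
    if dropped:
        log.warning("%d junction window(s) clipped at contig edges and dropped", dropped)
    assert all(len(w.seq) == width for w in out)
    return out


def junction_windows_to_fasta(windows: Sequence[JunctionWindow], path) -> None:
    """FASTA export; headers declare the boundary convention used."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.chrom}:{w.start}-{w.end}|{w.side}|center=boundary_base\n{w.seq}\n")


# ---------------------------------------------------------------------------
# Haplotypes and contingency ratios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Haplotype:
    """An ordered set of SNP alleles with per-allele trait directions.

    Directions are +1 (allele increases the trait), −1 (decreases), or 0
    (no quantitative trait measure available for the SNP).
    """

    alleles: tuple
    directions: tuple

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.directions):
            raise ValueError("alleles and directions must align")
        if any(d not in (-1, 0, 1) for d in self.directions):
            raise ValueError("directions must be in {+1, -1, 0}")

    @property
    def score(self) -> int:
        return int(sum(self.directions))


def haplotype_score(directions: Sequence[int]) -> int:
    """Sum of {+1, −1, 0} trait directions over the haplotype's alleles."""
    if any(d not in (-1, 0, 1) for d in directions):
        raise ValueError("directions must be in {+1, -1, 0}")
    return int(sum(directions))


def contingency_ratio(
    numerator: int, denominator: int, decimals: int = 1, scale: float = 100.0
) -> float:
    """Percentage n/d rounded half-up to the printed precision."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    raw = Decimal(numerator) * Decimal(str(scale)) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(raw.quantize(q, rounding=ROUND_HALF_UP))
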