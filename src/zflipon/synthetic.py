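"""Seeded synthetic genomes with energetics-derived ground truth.

The generator emulates the statistical shape of chemically mapped Z-DNA
training data: short Z-prone segments (tens of bp) of alternating
purine-pyrimidine repeats — d(CG)n, d(CA)n/d(TG)n, d(CGGG)n and mixed CG/CA
runs — embedded sparsely in i.i.d. background sequence at realistic GC
content, optionally with an adenosine-rich d(TAAA) motif planted at the 5'
flank of each segment, mirroring the junction motif seen at experimental
segment boundaries.

Ground-truth labels are produced by running the energetics oracle on the
finished contig (not by echoing the planting plan), so background runs that
happen to be Z-prone are labelled consistently with the planted repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import EnergyModel, energy_label_track, energy_score_track
from .genomeio import GenomeSequence, Interval, LabelTrack, ScoreTrack, intervals_from_track

__all__ = ["SyntheticSpec", "SyntheticGenome", "generate", "generate_annotation_fixture", "AnnotationFixture"]

FAMILIES = ("CG", "CA", "CGGG", "mixed")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic contig.

    Defaults describe the benchmark condition used throughout the test
    suite: a 100 kb contig with 200 planted Z segments of 12-60 bp,
    separated by at least 50 bp, over a 41% GC background.
    """

    contig_length: int = 100_000
    n_z_segments: int = 200
    repeat_family_mix: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.4, "CA": 0.3, "CGGG": 0.15, "mixed": 0.15}
    )
    segment_length_range: tuple[int, int] = (12, 60)
    junction_motif_rate: float = 0.5
    background_gc: float = 0.41
    min_gap: int = 50
    seed: int = 0
    name: str = "synth1"

    def __post_init__(self) -> None:
        w = sum(self.repeat_family_mix.values())
        if not np.isclose(w, 1.0):
            raise ValueError("repeat family weights must sum to 1")
        lo, hi = self.segment_length_range
        if lo % 2 or hi % 2 or lo < 12 or hi < lo:
            raise ValueError("segment lengths must be even, >= 12, lo <= hi")
        if not (0.0 <= self.junction_motif_rate <= 1.0 and 0.0 < self.background_gc < 1.0):
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class SyntheticGenome:
    """A generated contig with its planting plan and oracle-derived truth."""

    sequence: GenomeSequence
    planted: list[Interval]          # the planting plan (family in .strand-free score slot)
    planted_families: list[str]
    truth: LabelTrack                # oracle labels of the finished contig
    truth_intervals: list[Interval]
    oracle_scores: ScoreTrack


def _repeat_unit(family: str, length: int, rng: np.random.Generator) -> str:
    if family == "CG":
        return ("CG" * (length // 2 + 1))[:length]
    if family == "CA":
        unit = rng.choice(["CA", "TG"])
        return (unit * (length // 2 + 1))[:length]
    if family == "CGGG":
        length -= length % 4  # whole units keep the repeat in register
        length = max(length, 16)
        return ("CGGG" * (length // 4 + 1))[:length]
    if family == "mixed":
        length = max(length, 24)
        half = (length // 2) - (length // 2) % 2
        return ("CG" * (half // 2 + 1))[:half] + ("CA" * ((length - half) // 2 + 1))[: length - half]
    raise ValueError(f"unknown repeat family {family!r}")


def generate(spec: SyntheticSpec | None = None, model: EnergyModel | None = None) -> SyntheticGenome:
    """Generate a contig, plant Z segments, and label it with the oracle.

    Deterministic given ``spec.seed``: the same spec yields byte-identical
    sequence, truth intervals and score track.
    """
    spec = spec or SyntheticSpec()
    model = model or EnergyModel()
    rng = np.random.default_rng(spec.seed)
    gc = spec.background_gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(list("ACGT"), size=spec.contig_length, p=probs)

    lo, hi = spec.segment_length_range
    families = list(spec.repeat_family_mix)
    weights = np.array([spec.repeat_family_mix[f] for f in families])
    lengths = (rng.integers(lo // 2, hi // 2, size=spec.n_z_segments, endpoint=True) * 2).astype(int)
    fam_draw = rng.choice(len(families), size=spec.n_z_segments, p=weights / weights.sum())
    units = [
        _repeat_unit(families[fam_draw[i]], int(lengths[i]), rng) for i in range(spec.n_z_segments)
    ]
    unit_lengths = np.array([len(u) for u in units])

    # place segments left-to-right with random gaps >= min_gap
    pad = 8  # room for the flank motif and junction clearance
    needed = int(unit_lengths.sum()) + (spec.n_z_segments + 1) * (spec.min_gap + pad)
    if needed > spec.contig_length:
        raise ValueError(
            f"cannot fit {spec.n_z_segments} segments (need ~{needed} bp) in {spec.contig_length} bp"
        )
    slack = spec.contig_length - int(unit_lengths.sum()) - spec.n_z_segments * (spec.min_gap + pad)
    cuts = np.sort(rng.integers(0, slack, size=spec.n_z_segments, endpoint=True))
    extra_gaps = np.diff(np.concatenate([[0], cuts]))

    planted: list[Interval] = []
    planted_families: list[str] = []
    cursor = 0
    for i in range(spec.n_z_segments):
        cursor += spec.min_gap + pad + int(extra_gaps[i])
        fam = families[fam_draw[i]]
        unit = units[i]
        start = cursor
        end = start + len(unit)
        seq[start:end] = list(unit)
        if rng.random() < spec.junction_motif_rate:
            seq[start - 4 : start] = list("TAAA")
        planted.append(Interval(spec.name, start, end))
        planted_families.append(fam)
        cursor = end
    contig = GenomeSequence(spec.name, "".join(seq))

    truth = energy_label_track(contig, model)
    return SyntheticGenome(
        sequence=contig,
        planted=planted,
        planted_families=planted_families,
        truth=truth,
        truth_intervals=intervals_from_track(truth),
        oracle_scores=energy_score_track(contig, model),
    )


# ---------------------------------------------------------------------------
# Annotation fixture
# ---------------------------------------------------------------------------


@dataclass
class AnnotationFixture:
    """Internally consistent gene models, repeat tracks and a SNP table."""

    tss: list[Interval]
    utr5: list[Interval]
    exons: list[Interval]
    genes: list[Interval]
    utr3: list[Interval]
    repeats: dict[str, list[Interval]]
    snps: pd.DataFrame  # columns: chrom, pos, ref, alt, trait_direction


def generate_annotation_fixture(
    genome: SyntheticGenome,
    n_genes: int = 20,
    n_snps: int = 60,
    seed: int = 1,
) -> AnnotationFixture:
    """Gene models, repeat-family intervals and a trait-direction SNP table.

    Genes are laid out on alternating strands with 5'UTR/exon/intron/3'UTR
    structure (every exon inside its gene); repeat intervals echo the planted
    segments grouped by family; SNP trait directions are drawn from
    {+1, -1, 0}.
    """
    rng = np.random.default_rng(seed)
    chrom = genome.sequence.name
    L = genome.sequence.length
    tss, utr5, exons, genes, utr3 = [], [], [], [], []
    gene_span = L // (n_genes + 1)
    for g in range(n_genes):
        strand = "+" if g % 2 == 0 else "-"
        body_len = int(rng.integers(gene_span // 3, gene_span - 200))
        start = g * gene_span + int(rng.integers(100, max(gene_span - body_len - 100, 101)))
        end = start + body_len
        genes.append(Interval(chrom, start, end, strand=strand))
        if strand == "+":
            tss.append(Interval(chrom, start, start + 1, strand=strand))
            utr5.append(Interval(chrom, start, start + 60, strand=strand))
            utr3.append(Interval(chrom, end - 60, end, strand=strand))
        else:
            tss.append(Interval(chrom, end - 1, end, strand=strand))
            utr5.append(Interval(chrom, end - 60, end, strand=strand))
            utr3.append(Interval(chrom, start, start + 60, strand=strand))
        n_ex = int(rng.integers(2, 5))
        ex_starts = np.sort(rng.choice(np.arange(start + 60, end - 120), size=n_ex, replace=False))
        for es in ex_starts:
            ee = min(int(es) + int(rng.integers(40, 120)), end - 60)
            if ee > es:
                exons.append(Interval(chrom, int(es), ee))
    repeats: dict[str, list[Interval]] = {}
    for iv, fam in zip(genome.planted, genome.planted_families):
        label = {"CG": "(CG)n", "CA": "(CA)n", "CGGG": "(CGGG)n", "mixed": "mixed"}[fam]
        repeats.setdefault(label, []).append(iv)
    positions = np.sort(rng.choice(L, size=n_snps, replace=False))
    bases = "ACGT"
    snp_rows = []
    for pos in positions:
        ref = genome.sequence.seq[int(pos)]
        if ref == "N":
            continue
        alt = rng.choice([b for b in bases if b != ref])
        snp_rows.append(
            {
                "chrom": chrom,
                "pos": int(pos),
                "ref": ref,
                "alt": str(alt),
                "trait_direction": int(rng.choice([-1, 0, 1])),
            }
        )
    return AnnotationFixture(
        tss=tss, utr5=utr5, exons=exons, genes=genes, utr3=utr3,
        repeats=repeats, snps=pd.DataFrame(snp_rows),
    )
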