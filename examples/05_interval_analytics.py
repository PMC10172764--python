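"""Downstream analytics: feature classes, enrichment, junctions, haplotypes.

Uses the synthetic annotation fixture to walk through the interval-level
machinery: classifying Z segments into genomic feature classes, building an
observed-vs-expected enrichment table, extracting 11-nt BZ-junction windows
for motif discovery, and scoring haplotypes from per-allele trait directions.
"""

from collections import Counter

from zflipon.annotate_eval import (
    FeatureAnnotation,
    classify_feature,
    contingency_ratio,
    enrichment_table,
    haplotype_score,
    junction_windows,
)
from zflipon.synthetic import SyntheticSpec, generate, generate_annotation_fixture

genome = generate(SyntheticSpec(contig_length=50_000, n_z_segments=100, seed=42))
fx = generate_annotation_fixture(genome, n_genes=15, n_snps=40, seed=7)
annotation = FeatureAnnotation(
    tss=fx.tss, utr5=fx.utr5, exons=fx.exons, genes=fx.genes, utr3=fx.utr3
)

# feature classification of predicted Z segments vs a uniform background
hits = Counter(classify_feature(iv, annotation) for iv in genome.truth_intervals)
from zflipon.genomeio import Interval

background = Counter(
    classify_feature(Interval(genome.sequence.name, p, p + 1), annotation)
    for p in range(0, genome.sequence.length - 1, 211)
)
table = enrichment_table(hits, background)
print(table.to_string(index=False, float_format=lambda x: f"{x:7.2f}"))

# BZ junction windows for motif discovery
windows = junction_windows(genome.truth_intervals, genome.sequence)
print(f"\n{len(windows)} junction windows of 11 nt extracted")

# haplotype scoring from the SNP table's trait directions
directions = fx.snps["trait_direction"].tolist()[:6]
print(f"haplotype {directions} scores {haplotype_score(directions)}")

# printed-precision contingency ratio, e.g. SNPs falling in Z regions
n_in = sum(genome.truth.labels[p] for p in fx.snps["pos"])
print(f"{n_in} of {len(fx.snps)} SNPs in Z regions = {contingency_ratio(int(n_in), len(fx.snps))}%")
# The enrichment table's difference column is observed minus expected
# percentage points per class; positive rows are over-represented among
# Z segments relative to the uniform background.
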