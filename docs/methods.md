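# Methods

`zflipon` implements a complete desk-scale pipeline for discovering
Z-flipons — genomic sequences that can flip from the right-handed B-DNA
helix to the left-handed Z conformation — from sequence alone: a
thermodynamic propensity model, a learned 6-mer transformer segmenter with
the cross-validation and ensembling protocol used for experimental Z-DNA
training data, in-silico saturation mutagenesis, attention-based
interpretability, and the interval/feature analytics needed downstream.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Energetics model

The B→Z transition is scored additively.  Every non-overlapping
dinucleotide step of a candidate helix pays a flipping cost (kcal/mol):

| step | cost |
|------|------|
| d(CG) | 0.6 |
| d(CA) = d(TG) | 1.34 |
| d(GG) = d(CC) | 2.4 |
| all other steps | 4.0 (configurable `default_cost`) |

The table is closed under reverse complement, reflecting the strand
symmetry of the double helix.  A Z helix additionally pays a
`junction_cost` of 5.0 kcal/mol at each of its two BZ junctions, where an
extruded base pair separates left- and right-handed helix.  The phrase "per
BZ junction" is ambiguous between per-junction and per-junction-dinucleotide
readings; we adopt 5.0 kcal/mol per junction (two per segment) and expose it
as a parameter.  Out-of-alternation steps are deliberately penalised rather
than forbidden (4.0 > d(GG) but ≪ a junction), which is what lets
d(CGGG)n-style repeats score as single helices instead of fragmenting.

A region is called Z-prone when an even-length window of at least
`min_helix_bp` = 12 bp (one helical turn of Z-DNA) has mean step cost at or
below `z_cutoff` = 1.5 kcal/mol per dinucleotide.  The cutoff is a tunable,
chosen so that (CG)n and (CA)n repeats qualify and random sequence does
not; it applies to the mean step cost *excluding* junctions (the closed
forms (CG)×6 → 13.6 and (CA)×6 → 18.04 kcal/mol include them).  There is no
supercoiling-dependent partition function: the score is raw energy, and the
segment caller is a deterministic scan, not a statistical-mechanics model.

### Segment calling

`best_z_segments` enumerates, in both dinucleotide phasings, every window of
6–256 steps whose mean cost is at or below the cutoff, ranks candidates by
mean cost (ties: longer, then leftmost), and accepts them greedily without
base-pair overlap.  Each accepted core is then extended stepwise while the
flanking step is itself Z-compatible (cost ≤ cutoff), so cheap alternating
flanks are absorbed but expensive background never is; segment boundaries
therefore stay within a couple of bp of an embedded repeat.  A segment's
reported `energy_per_dinuc` is the mean step cost of its minimal-energy
core, which provably equals the minimum over all even sub-windows — the
property the exhaustive-enumeration oracle test checks.  Ranking keys are
quantised to 9 decimals so uniform repeats are not split by last-ulp
prefix-sum noise.

One knock-on effect worth knowing: for d(CGGG)n runs the minimal-mean core
is the odd-step window that starts and ends on a CG step, and the flanking
GG steps (2.4 > 1.5) are not absorbed, so oracle labels shave roughly one
step off each end of such repeats.  (CG)n and (CA)n plants are recovered
exactly.

## Tokenisation

Sequences are encoded as overlapping 6-mers: token *i* is the hexamer
starting at base *i*, so an *n*-base sequence yields *n* − 5 tokens over a
lexicographic vocabulary of 4⁶ = 4096 k-mers plus PAD and UNK.  Any k-mer
containing N becomes UNK; UNK tokens are excluded from the training loss
and predict probability 0.  Token *i* inherits the label of base *i* (its
first base); a majority-vote projection is available as an option.
Predicted token probabilities are lifted back so base *i* receives token
*i*'s probability and the trailing five bases inherit the final token's
value — the simplest consistent extension.  Windows of 256 or 512 tokens
tile the token stream with PAD-padding on the final short window;
overlapping strides are supported, with per-token averaging of the
overlapped predictions.  A 261-nt categorical encoding (256 ordered 6-mer
ids centred on a target base) is provided for gradient-boosting baselines.

## Segmenter

The backbone is a from-scratch NumPy transformer encoder — pre-layer-norm
blocks of multi-head self-attention and a ReLU feed-forward, learned token
and positional embeddings, a per-token sigmoid head — with hand-derived
backpropagation, Adam, and a one-cycle learning-rate schedule (linear
warmup over the first 30% of steps from max_lr/25, cosine anneal to
max_lr/1000).  Training uses masked per-token binary cross-entropy with PAD
and UNK excluded; no dropout (runs are short and the task small) and no
class weighting (negatives are already downsampled).

The protocol follows the fine-tuning recipe for experimental Z-DNA data:
labelled regions are split into five stratified folds (regions shuffled,
stably sorted by positive-bp content, dealt serpentine-fashion so each fold
carries a near-equal share of positive bases; whole regions never straddle
folds); each of five members trains on the positive windows of the other
four folds plus twice as many negative windows sampled without replacement;
batch size is 24.  Windows that touch regions of several folds are excluded
from the training of every member whose fold they touch — including
negative windows whose trailing five bases contain held-out region
sequence, which carry content without labels.  `epochs=3` and the
fine-tuning learning rate 1e-5 remain the config defaults; training this
backbone *from scratch* on the benchmark uses 20 epochs at max_lr 3e-3, a
64-dimensional model, 2 layers, 4 heads and 256-token windows — sized so
the full five-member run trains in a few minutes on one CPU.  One master
seed fans out (via `numpy.random.SeedSequence`) to the fold split, each
member's negative sampling, weight initialisation and batch order, so runs
are bit-reproducible.

Prediction for novel sequence averages all five members; for held-out
regions the quoted rule — averaging the models that used data not seen
during training — resolves, under five-fold region-level CV, to the single
member whose folds exclude the region, and both modes are selectable.
Evaluation (`evaluate_heldout`) follows the protocol of assessing each
model on the ~20% of data it never saw: per member, the positive windows of
its held-out fold plus the negative windows outside its sampled training
set, scored at token level; precision, recall, F1 and rank-based ROC AUC
are computed per fold and macro-averaged.  Metrics are deliberately *not*
pooled across folds before ranking: members are separately calibrated
classifiers, and pooling their probabilities mixes calibration scales and
understates the ranking quality every individual member actually achieves.

Segments are called as maximal runs of per-base probability ≥ 0.5 (both
threshold and minimum length configurable).

### Attention maps

For a window, the per-(layer, head) attention received by token *t* is the
column sum of that head's attention matrix over real (non-PAD) queries.
The combined map is the mean over all layers and heads, min-max normalised
to [0, 1] within the window (a constant map normalises to zero), and a
binary mask is `combined > 0.2`.  The layer/head aggregation behind the
published combined-map figures is not specified anywhere we could verify,
so this column-sum + min-max choice is declared, not inferred.  In this
compact two-layer encoder the zebra-stripe enrichment over Z repeats is a
*head-level* phenomenon: first-layer heads concentrate attention received
on repeat tokens, while the second layer redistributes mass toward context
positions, so the all-layer mean can wash the signal out.  The per-head
tensors are exposed precisely so that analyses mirror the published
practice of inspecting individual heads.

## Saturation mutagenesis

A region's score is Σᵢ ln(1 + pᵢ) over a fixed scoring extent (the model
windows covering the region); adding 1 to p keeps zero probabilities
well-defined, and the natural log is an arbitrary but harmless choice since
effects are score *ratios* (variant / reference), which are log-base
invariant.  Every position is substituted with the three alternative bases;
each variant is re-tokenised and re-scored over the same extent, so ratios
are comparable across the region.  Raw differences are emitted alongside
ratios in the TSV; scores are not length-normalised (ratios make it moot).
If the reference score is zero the ratio is undefined and reported NaN with
a warning.  Heatmaps use a diverging scale centred at ratio 1 (red =
increased Z propensity, blue = decreased).

## Interval analytics

Coordinates are BED-style 0-based half-open throughout; Z segments are
strandless.  Interval algebra (merge/intersect/subtract, bp-level coverage
fractions) is implemented with sorted sweeps and property-tested against
per-base membership arrays.  Feature classification assigns an interval's
midpoint to one of seven classes with promoter-first precedence (promoter
≤ 3 kb upstream of a TSS > 5′UTR > exon > intron > 3′UTR > downstream
≤ 300 bp > distal intergenic); the precedence order and both window sizes
are configurable, since the convention behind published feature tables is
not stated.  Overlap-recovery tables use segment-level semantics (an
experimental segment is shared if it intersects any predicted segment by
≥ 1 bp), the convention that reproduces the published per-class recovery
percentages; bp-level coverage is available separately.  Contingency ratios
are computed exactly as 100·n/d and rounded half-up to the table's printed
precision.  BZ junction windows are 11 nt centred on a segment's first and
last base (boundary ± 5); windows clipped by a contig edge are dropped with
a warning, and the FASTA headers state the centring convention.  Haplotype
scores sum per-allele trait directions in {+1, −1, 0}, with 0 for alleles
lacking quantitative trait data.

## Synthetic benchmark

The generator emulates the statistical shape of chemically mapped Z-DNA
training data: short Z segments embedded sparsely in background.  Defaults
— the benchmark condition used by the test suite and the acceptance script
— are a 100 kb contig, 200 planted segments of 12–60 bp (even lengths)
separated by ≥ 50 bp, family mix 40% (CG)n, 30% (CA)n/(TG)n, 15% (CGGG)n,
15% mixed CG/CA, i.i.d. background at 41% GC (the human genome-wide value),
and a d(TAAA) motif planted at the 5′ flank of half the segments, mirroring
the adenosine-rich junction flanks seen at experimental segment boundaries.
Ground truth comes from running the energetics oracle on the *finished*
contig rather than echoing the planting plan, so chance Z-prone background
runs are labelled consistently — roughly 10–20% extra short truth segments
at these settings, which is also what makes the benchmark honest: the
segmenter must learn the oracle's rule, not the planting locations.

What passing does and does not show: the synthetic task establishes that
the full pipeline — tokenisation, fold hygiene, training, ensembling,
lifting, evaluation — can recover a deterministic sequence-local labelling
rule at nucleotide resolution.  Real chemical-mapping data differ in ways
the generator does not emulate: labels are noisy and incomplete,
Z-formation depends on supercoiling and transcription (context beyond
sequence), repeat families are correlated with other genomic features, and
background is not i.i.d.  Benchmark metrics therefore bound pipeline
correctness, not real-data performance.  Residual benchmark error is
concentrated in two places: narrow collars at segment boundaries, where the
oracle's hard label edges meet the model's smooth probability transitions,
and very short chance background segments, which must be recognised from
context rather than token identity alone.

## Degenerate inputs and numerical conventions

Sequences are uppercased on load with non-ACGT characters mapped to N; N
positions are always labelled 0, tokenise to UNK, and break the energetics
scan.  Metrics with zero denominators (no positive calls, single-class
labels) return NaN rather than raising.  ROC AUC uses midrank tie handling.
Empty repeat-family rows are omitted with a warning.  All percentages meant
to reproduce printed tables are rounded half-up at the table's precision;
everything else is reported at full precision.

## Known limitations

The energetics model omits supercoiling density, G4-quadruplex competition
and Z-RNA-specific energetics.  The transformer is desk-scale and trained
from scratch; a fine-tune mode accepts externally supplied weights but no
pretrained weights ship with the package.  Mutagenesis covers single-base
substitutions only.  Motif discovery itself (MEME) and GO/FDR enrichment
are out of scope — the toolkit prepares their inputs and consumes their
outputs as user-supplied tables.
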