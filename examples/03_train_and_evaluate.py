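"""Train the transformer segmenter and evaluate it at nucleotide level.

A small synthetic contig is tokenised into overlapping 6-mers; five
transformer members are trained, each holding out one stratified fold of the
labelled regions, with twice as many negative windows as positive ones.
Held-out regions are then scored only by the member that never saw them.
Printed metrics are per-nucleotide: precision and recall of Z calls at
p >= 0.5, their harmonic mean F1, and the ranking quality ROC AUC.

Runtime: a few minutes on one CPU.
"""

from zflipon.segmenter import SegmenterConfig, call_segments, evaluate_heldout, predict, train
from zflipon.synthetic import SyntheticSpec, generate

genome = generate(SyntheticSpec(contig_length=30_000, n_z_segments=60, seed=8))
config = SegmenterConfig(
    epochs=20, max_learning_rate=3e-3, n_folds=3, window=128, d_model=32, seed=1
)
ensemble = train(
    [genome.sequence], {genome.sequence.name: genome.truth}, genome.truth_intervals, config
)

ev = evaluate_heldout(ensemble, [genome.sequence], {genome.sequence.name: genome.truth})
print(f"precision {ev['precision']:.3f}  recall {ev['recall']:.3f}  F1 {ev['f1']:.3f}")
print(f"ROC AUC   {ev['roc_auc']:.3f}   ({ev['n_bases']} held-out bases)")

track = predict(ensemble, genome.sequence, mode="all")
called = call_segments(track, threshold=0.5, min_len=6)
print(f"called segments: {len(called)} (truth: {len(genome.truth_intervals)})")
# F1 near 0.9 means the model recovered the energetics oracle's labels from
# sequence alone; segments are maximal runs of p >= 0.5.
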