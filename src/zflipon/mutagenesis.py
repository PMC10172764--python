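"""In-silico saturation mutagenesis of Z-DNA propensity.

Every position of a region is substituted with the three alternative bases;
each variant is re-tokenised and re-scored by the trained ensemble over a
fixed scoring extent (the model windows covering the region), and the effect
of a substitution is the ratio of the variant score to the reference score,
where the score is the sum over the extent of log(1 + p) with p the predicted
per-nucleotide Z probability.  Adding 1 to p before the log keeps zero
probabilities well-defined; natural log is used (ratios are base-invariant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genomeio import GenomeSequence, Interval
from .segmenter import TrainedEnsemble, predict

log = logging.getLogger(__name__)

__all__ = ["MutagenesisMap", "z_score", "z_score_from_probs", "mutagenesis_map", "render_heatmap"]

BASES = "ACGT"


def z_score_from_probs(p: np.ndarray) -> float:
    """Sum of ln(1 + p_i) over a probability track."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty probability track")
    return float(np.log1p(p).sum())


def z_score(seq: GenomeSequence | str, ensemble: TrainedEnsemble) -> float:
    """Z-propensity score of a sequence: sum over positions of ln(1 + p)."""
    if isinstance(seq, str):
        seq = GenomeSequence("query", seq)
    if seq.length == 0:
        raise ValueError("empty sequence")
    track = predict(ensemble, seq, mode="all")
    return z_score_from_probs(track.p)


@dataclass
class MutagenesisMap:
    """Effect ratios of every single-base substitution in a region.

    ``ratio`` is (region length, 4) over columns A, C, G, T; the reference
    base's own entry is 1 by convention.  ``diff`` holds the score
    differences (variant − reference) on the same grid.
    """

    region: Interval
    ref_seq: str
    ref_score: float
    ratio: np.ndarray
    diff: np.ndarray

    @property
    def effect(self) -> np.ndarray:
        """(region length, 3) ratios for the three alternative bases only."""
        out = np.empty((len(self.ref_seq), 3))
        for i, ref in enumerate(self.ref_seq):
            out[i] = [self.ratio[i, j] for j, b in enumerate(BASES) if b != ref]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ref in enumerate(self.ref_seq):
            row = {"position": self.region.start + i, "ref": ref}
            for j, b in enumerate(BASES):
                row[f"ratio_{b}"] = self.ratio[i, j]
                row[f"diff_{b}"] = self.diff[i, j]
            rows.append(row)
        return pd.DataFrame(rows)


def _scoring_extent(seq_len: int, region: Interval, window_bp: int) -> tuple[int, int]:
    """The window-aligned bp extent used to score all variants of a region."""
    lo = (region.start // window_bp) * window_bp
    hi = min(seq_len, ((region.end - 1) // window_bp + 1) * window_bp)
    return max(0, lo), hi


def _score_sequence(ensemble: TrainedEnsemble, seq: str) -> float:
    track = predict(ensemble, GenomeSequence("v", seq), mode="all")
    return z_score_from_probs(track.p)


def mutagenesis_map(
    seq: GenomeSequence,
    ensemble: TrainedEnsemble,
    region: Interval,
    extent: tuple[int, int] | None = None,
) -> MutagenesisMap:
    """Saturation-mutagenesis effect map for ``region`` within ``seq``.

    The scoring extent (default: the model windows covering the region) is
    fixed across all variants so ratios are comparable.  If the reference
    score is zero the ratios are undefined and reported as NaN.
    """
    cfg = ensemble.config
    window_bp = cfg.window + cfg.k - 1
    if extent is None:
        extent = _scoring_extent(seq.length, region, window_bp)
    lo, hi = extent
    if not (lo <= region.start and region.end <= hi):
        raise ValueError("scoring extent must contain the region")
    ref_window = seq.seq[lo:hi]
    ref_score = _score_sequence(ensemble, ref_window)
    L = region.length
    ratio = np.ones((L, 4))
    diff = np.zeros((L, 4))
    undefined = ref_score == 0.0
    if undefined:
        log.warning("reference score is 0; effect ratios reported as NaN")
        ratio[:] = np.nan
    for i in range(L):
        pos = region.start + i
        ref_base = seq.seq[pos]
        for j, alt in enumerate(BASES):
            if alt == ref_base:
                ratio[i, j] = np.nan if undefined else 1.0
                diff[i, j] = 0.0
                continue
            variant = ref_window[: pos - lo] + alt + ref_window[pos - lo + 1 :]
            v_score = _score_sequence(ensemble, variant)
            diff[i, j] = v_score - ref_score
            if not undefined:
                ratio[i, j] = v_score / ref_score
    return MutagenesisMap(region=region, ref_seq=seq.seq[region.start : region.end],
                          ref_score=ref_score, ratio=ratio, diff=diff)


def render_heatmap(
    mmap: MutagenesisMap,
    tsv_path: str | Path | None = None,
    png_path: str | Path | None = None,
):
    """Write the machine-readable TSV twin and, optionally, a PNG heatmap.

    The colour scale diverges around effect = 1: red marks substitutions that
    increase Z propensity, blue marks substitutions that decrease it.
    """
    frame = mmap.to_frame()
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False)
    fig = None
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import TwoSlopeNorm

        data = mmap.ratio.T  # (4, L)
        finite = data[np.isfinite(data)]
        spread = max(np.abs(finite - 1.0).max(), 0.05) if finite.size else 0.05
        norm = TwoSlopeNorm(vcenter=1.0, vmin=1.0 - spread, vmax=1.0 + spread)
        fig, ax = plt.subplots(figsize=(max(6, mmap.region.length / 8), 2.5))
        im = ax.imshow(data, aspect="auto", cmap="RdBu_r", norm=norm, interpolation="nearest")
        ax.set_yticks(range(4), list(BASES))
        ax.set_xlabel(f"{mmap.region.chrom}:{mmap.region.start}-{mmap.region.end} (0-based)")
        fig.colorbar(im, ax=ax, label="score ratio vs reference")
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return frame
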