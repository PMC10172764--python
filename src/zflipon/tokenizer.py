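"""6-mer tokenisation, nucleotide<->token label projection, and windowing.

Each nucleotide position i is represented by the k-mer (default k = 6)
starting at i, so a sequence of n bases yields n - k + 1 tokens.  The
vocabulary enumerates all 4^k k-mers in lexicographic order (ids 0..4^k - 1)
plus two specials, PAD and UNK; any k-mer containing N maps to UNK.  Token i
inherits the label of its first base, and predicted token probabilities are
lifted back so nucleotide i receives token i's probability (the trailing
k - 1 bases inherit the final token's value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .genomeio import LabelTrack

__all__ = [
    "KmerVocabulary",
    "TokenSequence",
    "TokenLabelSet",
    "BoostRecord",
    "tokenize",
    "detokenize",
    "project_labels",
    "lift_predictions",
    "make_windows",
    "concat_windows",
    "encode_boost",
]

_BASE_ORD = {"A": 0, "C": 1, "G": 2, "T": 3}
_ORD_BASE = "ACGT"


class KmerVocabulary:
    """Lexicographic k-mer vocabulary with PAD/UNK specials."""

    def __init__(self, k: int = 6):
        self.k = k
        self.n_kmers = 4 ** k
        self.pad_id = self.n_kmers
        self.unk_id = self.n_kmers + 1

    def __len__(self) -> int:
        return self.n_kmers + 2

    def encode(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"expected {self.k}-mer, got {kmer!r}")
        idx = 0
        for c in kmer:
            o = _BASE_ORD.get(c)
            if o is None:
                return self.unk_id
            idx = idx * 4 + o
        return idx

    def decode(self, idx: int) -> str:
        if idx == self.pad_id:
            return "<PAD>"
        if idx == self.unk_id:
            return "<UNK>"
        out = []
        for _ in range(self.k):
            out.append(_ORD_BASE[idx % 4])
            idx //= 4
        return "".join(reversed(out))

    def write(self, path: str | Path) -> None:
        """Plain-text vocabulary file, one `kmer<TAB>id` line, lexicographic."""
        with open(path, "w") as fh:
            for i, kmer in enumerate("".join(p) for p in product(_ORD_BASE, repeat=self.k)):
                fh.write(f"{kmer}\t{i}\n")
            fh.write(f"<PAD>\t{self.pad_id}\n<UNK>\t{self.unk_id}\n")

    @classmethod
    def read(cls, path: str | Path) -> "KmerVocabulary":
        with open(path) as fh:
            first = fh.readline().split("\t")[0]
        vocab = cls(k=len(first))
        return vocab


@dataclass
class TokenSequence:
    """A k-mer token stream with its genomic origin."""

    tokens: np.ndarray
    k: int = 6
    origin: tuple[str, int] = ("chr", 0)

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens, dtype=np.int64)

    def __len__(self) -> int:
        return self.tokens.size


@dataclass
class TokenLabelSet:
    """Binary labels aligned one-to-one with a token stream."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)

    def __len__(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class BoostRecord:
    """A 256-feature categorical encoding of a 261-nt window for boosting models."""

    features: tuple
    label: int
    center: int

    def __post_init__(self) -> None:
        if len(self.features) != 256:
            raise ValueError("BoostRecord requires exactly 256 features")


def tokenize(seq: str, k: int = 6, origin: tuple[str, int] = ("chr", 0)) -> TokenSequence:
    """Sliding-window k-mer ids, stride 1; k-mers containing N become UNK."""
    n = len(seq)
    if n < k:
        raise ValueError(f"sequence length {n} < k = {k}")
    vocab = KmerVocabulary(k)
    codes = np.array([_BASE_ORD.get(c, -1) for c in seq], dtype=np.int64)
    m = n - k + 1
    ids = np.zeros(m, dtype=np.int64)
    bad = np.zeros(m, dtype=bool)
    for j in range(k):
        window = codes[j : j + m]
        bad |= window < 0
        ids = ids * 4 + np.where(window < 0, 0, window)
    ids[bad] = vocab.unk_id
    return TokenSequence(ids, k=k, origin=origin)


def detokenize(tokens: TokenSequence) -> str:
    """Reconstruct the sequence from overlapping k-mers (N-free streams only)."""
    vocab = KmerVocabulary(tokens.k)
    if tokens.tokens.size == 0:
        return ""
    if (tokens.tokens >= vocab.n_kmers).any():
        raise ValueError("cannot detokenize streams containing PAD/UNK")
    first = vocab.decode(int(tokens.tokens[0]))
    tail = "".join(vocab.decode(int(t))[-1] for t in tokens.tokens[1:])
    return first + tail


def project_labels(track: LabelTrack, k: int = 6) -> TokenLabelSet:
    """Token i inherits the label of nucleotide i (the k-mer's first base)."""
    n = len(track)
    if n < k:
        raise ValueError(f"track length {n} < k = {k}")
    return TokenLabelSet(track.labels[: n - k + 1])


def project_labels_majority(track: LabelTrack, k: int = 6) -> TokenLabelSet:
    """Alternative projection: majority vote over the k covered bases."""
    n = len(track)
    if n < k:
        raise ValueError(f"track length {n} < k = {k}")
    m = n - k + 1
    csum = np.concatenate([[0], np.cumsum(track.labels)])
    votes = csum[np.arange(m) + k] - csum[np.arange(m)]
    return TokenLabelSet((votes * 2 > k).astype(np.int8))


def lift_predictions(token_probs: np.ndarray, k: int, seq_length: int, chrom: str = "chr") -> np.ndarray:
    """Per-token probabilities -> per-nucleotide probabilities.

    Nucleotide i receives token i's probability; the trailing k - 1 bases
    receive the final token's probability.
    """
    token_probs = np.asarray(token_probs, dtype=np.float64)
    if token_probs.size != seq_length - k + 1:
        raise ValueError(
            f"token count {token_probs.size} inconsistent with sequence length {seq_length} and k = {k}"
        )
    out = np.empty(seq_length, dtype=np.float64)
    out[: token_probs.size] = token_probs
    out[token_probs.size :] = token_probs[-1] if token_probs.size else 0.0
    return out


def make_windows(
    tokens: TokenSequence,
    window: int = 512,
    stride: int | None = None,
    labels: TokenLabelSet | None = None,
):
    """Tile a token stream into fixed-length windows.

    Returns ``(ids, mask, starts, window_labels)`` where ``ids`` is
    (n_windows, window) with the final short window PAD-padded, ``mask`` is
    True on real (non-PAD) positions, and ``starts`` gives each window's
    offset in the token stream.  With the default stride (= window) the
    windows tile the stream without overlap.
    """
    stride = stride or window
    if stride <= 0 or window <= 0:
        raise ValueError("window and stride must be positive")
    vocab = KmerVocabulary(tokens.k)
    m = len(tokens)
    starts = list(range(0, max(m - window, 0) + 1, stride))
    while starts[-1] + window < m:  # short final window, PAD-padded below
        starts.append(starts[-1] + stride)
    n_w = len(starts)
    ids = np.full((n_w, window), vocab.pad_id, dtype=np.int64)
    mask = np.zeros((n_w, window), dtype=bool)
    labs = np.zeros((n_w, window), dtype=np.int8) if labels is not None else None
    for r, s in enumerate(starts):
        e = min(s + window, m)
        ids[r, : e - s] = tokens.tokens[s:e]
        mask[r, : e - s] = True
        if labs is not None:
            labs[r, : e - s] = labels.labels[s:e]
    return ids, mask, np.array(starts), labs


def concat_windows(ids: np.ndarray, mask: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Reassemble a non-overlapping tiling back into one token stream."""
    pieces = []
    expected = 0
    for r in range(ids.shape[0]):
        if starts[r] != expected:
            raise ValueError("windows do not tile the stream (overlap or gap)")
        row = ids[r][mask[r]]
        pieces.append(row)
        expected += row.size
    return np.concatenate(pieces) if pieces else np.empty(0, dtype=np.int64)


def average_window_probs(
    probs: np.ndarray, mask: np.ndarray, starts: np.ndarray, n_tokens: int
) -> np.ndarray:
    """Average per-token probabilities from (possibly overlapping) windows."""
    acc = np.zeros(n_tokens, dtype=np.float64)
    cnt = np.zeros(n_tokens, dtype=np.float64)
    for r, s in enumerate(starts):
        valid = mask[r]
        length = int(valid.sum())
        acc[s : s + length] += probs[r, :length]
        cnt[s : s + length] += 1.0
    cnt[cnt == 0] = 1.0
    return acc / cnt


def encode_boost(
    seq: str, center: int, k: int = 6, span: int = 256, track: LabelTrack | None = None
) -> BoostRecord | None:
    """Categorical window encoding for gradient-boosting baselines.

    A (span + k - 1)-nt window centred on ``center`` is decomposed into
    ``span`` ordered k-mer ids; feature j is the id of
    seq[start + j : start + j + k).  Windows running off the contig are
    skipped (returns None).
    """
    vocab = KmerVocabulary(k)
    start = center - span // 2
    end = start + span + k - 1
    if start < 0 or end > len(seq):
        import logging

        logging.getLogger(__name__).warning("boost window for center %d out of bounds; skipped", center)
        return None
    feats = tuple(vocab.encode(seq[start + j : start + j + k]) for j in range(span))
    label = int(track.labels[center]) if track is not None else 0
    return BoostRecord(features=feats, label=label, center=center)
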