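"""Thermodynamic B-to-Z transition propensity scoring.

The model assigns each dinucleotide step a flipping cost (kcal/mol) for
adopting the left-handed Z conformation, plus a fixed penalty for each of the
two BZ junctions that bound a Z helix.  Alternating purine-pyrimidine steps
are cheap — d(CG) 0.6, d(CA)/d(TG) 1.34, d(GG)/d(CC) 2.4 kcal/mol per
dinucleotide — while out-of-alternation steps carry a larger but finite
default cost, so they are penalised rather than forbidden.  A sequence region
is called Z-prone when its mean step cost (junctions excluded) stays at or
below a configurable cutoff over an even-length window of at least one helical
turn (12 bp).

This scorer plays two roles: an independent Z-propensity track, and the
ground-truth labeling oracle for the synthetic-genome generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .genomeio import GenomeSequence, Interval, LabelTrack, ScoreTrack

__all__ = ["EnergyModel", "ZSegment", "segment_energy", "best_z_segments", "energy_label_track", "energy_score_track"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# Published per-dinucleotide B->Z flipping costs (kcal/mol): d(CG) = 0.6,
# d(CA) = d(TG) = 1.34, d(GG) = d(CC) = 2.4.  The table is closed under
# reverse complement; steps without a published value get `default_cost`.
_PRINTED_COSTS = {"CG": 0.6, "CA": 1.34, "GG": 2.4}


def _complete_cost_table(base: dict[str, float], default_cost: float) -> dict[str, float]:
    table: dict[str, float] = {}
    for dinuc, cost in base.items():
        table[dinuc] = cost
        table[revcomp(dinuc)] = cost
    alphabet = "ACGT"
    for x in alphabet:
        for y in alphabet:
            table.setdefault(x + y, default_cost)
    return table


@dataclass(frozen=True)
class EnergyModel:
    """Dinucleotide B->Z costs, junction penalty, and segment-calling knobs.

    Parameters
    ----------
    dinucleotide_cost:
        kcal/mol per dinucleotide step in the Z conformation.  Closed under
        reverse complement.  Entries not given explicitly default to
        ``default_cost``.
    junction_cost:
        kcal/mol per BZ junction; every Z helix pays for two.
    min_helix_bp:
        Minimum helix length in bp (even; default 12, one Z turn).
    z_cutoff:
        Maximum mean step cost (kcal/mol per dinucleotide, junctions
        excluded) for a region to be called Z-prone.
    max_helix_bp:
        Scan bound for segment search; candidate windows longer than this
        are not enumerated directly (adjacent calls cover longer runs).
    """

    dinucleotide_cost: dict[str, float] = field(default_factory=dict)
    junction_cost: float = 5.0
    min_helix_bp: int = 12
    z_cutoff: float = 1.5
    default_cost: float = 4.0
    max_helix_bp: int = 512

    def __post_init__(self) -> None:
        base = dict(_PRINTED_COSTS)
        base.update(self.dinucleotide_cost)
        table = _complete_cost_table(base, self.default_cost)
        if any(not np.isfinite(c) or c <= 0 for c in table.values()):
            raise ValueError("all dinucleotide costs must be finite and > 0")
        if self.junction_cost <= 0:
            raise ValueError("junction_cost must be > 0")
        if self.min_helix_bp < 4 or self.min_helix_bp % 2:
            raise ValueError("min_helix_bp must be even and >= 4")
        object.__setattr__(self, "dinucleotide_cost", table)

    def cost(self, dinuc: str) -> float:
        return self.dinucleotide_cost[dinuc]

    @classmethod
    def from_yaml(cls, path: str) -> "EnergyModel":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)

    def to_yaml(self, path: str) -> None:
        cfg = {
            "dinucleotide_cost": {k: float(v) for k, v in sorted(self.dinucleotide_cost.items())},
            "junction_cost": self.junction_cost,
            "min_helix_bp": self.min_helix_bp,
            "z_cutoff": self.z_cutoff,
            "default_cost": self.default_cost,
            "max_helix_bp": self.max_helix_bp,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh)


@dataclass(frozen=True)
class ZSegment:
    """A called Z-prone segment with its energetic bookkeeping.

    ``energy_total`` is the full segment's step-cost sum plus the two BZ
    junction penalties.  ``energy_per_dinuc`` is the mean step cost of the
    most favorable helix core within the segment (the minimal-mean window
    found by the scan, junctions excluded); for uniform repeats it equals
    the full-segment mean.  The cutoff criterion applies to this value.
    """

    interval: Interval
    energy_total: float      # sum of step costs + 2 * junction_cost
    energy_per_dinuc: float  # mean step cost of the minimal-energy core
    phase: int               # parity of the first base of the dinucleotide grid

    def __post_init__(self) -> None:
        if self.interval.length % 2 or self.interval.length < 2:
            raise ValueError("Z segments must have even length >= 2")


def _step_costs(seq: str, model: EnergyModel, phase: int) -> np.ndarray:
    """Costs of the non-overlapping dinucleotide grid starting at ``phase``."""
    n = len(seq)
    stops = range(phase, n - 1, 2)
    return np.array([model.cost(seq[i : i + 2]) for i in stops], dtype=np.float64)


def segment_energy(seq: str, phase: int, model: EnergyModel | None = None) -> float:
    """Total flipping energy (kcal/mol) of an even-length Z helix.

    The helix is tiled by non-overlapping dinucleotide steps starting at
    offset ``phase`` (0 or 1; phase 1 leaves the first and last base at the
    junctions) and pays two BZ junction penalties.
    """
    model = model or EnergyModel()
    if len(seq) < 2 or len(seq) % 2:
        raise ValueError("segment length must be even and >= 2")
    if "N" in seq:
        raise ValueError("cannot score sequences containing N")
    if phase not in (0, 1):
        raise ValueError("phase must be 0 or 1")
    return float(_step_costs(seq, model, phase).sum() + 2.0 * model.junction_cost)


def _candidate_windows(costs: np.ndarray, min_d: int, max_d: int, cutoff: float):
    """All dinucleotide windows [i, i+L) with mean cost <= cutoff.

    Returns parallel arrays (start, length, mean) over the dinucleotide grid.
    """
    m = costs.size
    if m < min_d:
        return np.empty(0, int), np.empty(0, int), np.empty(0)
    prefix = np.concatenate([[0.0], np.cumsum(costs)])
    starts_all, lens_all, means_all = [], [], []
    for L in range(min_d, min(max_d, m) + 1):
        means = (prefix[L:] - prefix[:-L]) / L
        ok = np.flatnonzero(means <= cutoff)
        if ok.size:
            starts_all.append(ok)
            lens_all.append(np.full(ok.size, L))
            means_all.append(means[ok])
    if not starts_all:
        return np.empty(0, int), np.empty(0, int), np.empty(0)
    return np.concatenate(starts_all), np.concatenate(lens_all), np.concatenate(means_all)


def best_z_segments(seq: GenomeSequence | str, model: EnergyModel | None = None) -> list[ZSegment]:
    """Call maximal non-overlapping Z-prone segments in a sequence.

    Both dinucleotide phasings are scanned.  Candidate even-length windows of
    at least ``min_helix_bp`` whose mean step cost is at or below ``z_cutoff``
    are ranked by mean cost (ties: longer, then leftmost, then phase 0) and
    accepted greedily without bp overlap.  Each accepted core is then extended
    one step at a time while the flanking step's cost does not exceed the
    segment's current mean — so cheap alternating flanks are absorbed but
    expensive junction-adjacent sequence is not.  N-containing positions
    break the scan.
    """
    model = model or EnergyModel()
    if isinstance(seq, GenomeSequence):
        chrom, s = seq.name, seq.seq
    else:
        chrom, s = "chr", seq
    n = len(s)
    if n < model.min_helix_bp:
        return []

    min_d = model.min_helix_bp // 2
    max_d = max(min_d, model.max_helix_bp // 2)
    big = 1e9  # poisons N-containing and already-claimed steps

    cost_arrays: dict[int, np.ndarray] = {}
    for phase in (0, 1):
        stops = np.arange(phase, n - 1, 2)
        costs = np.full(stops.size, big)
        for j, i in enumerate(stops):
            d = s[i : i + 2]
            if "N" not in d:
                costs[j] = model.cost(d)
        cost_arrays[phase] = costs

    # enumerate candidates in both phases
    cand = []
    for phase in (0, 1):
        st, ln, mn = _candidate_windows(cost_arrays[phase], min_d, max_d, model.z_cutoff)
        for k in range(st.size):
            # quantize the ranking key so equal-cost windows tie exactly and
            # the longer window wins (prefix-sum rounding would otherwise
            # split uniform repeats at the last ulp)
            cand.append((round(mn[k], 9), -int(ln[k]), phase + 2 * int(st[k]), phase, int(st[k]), int(ln[k])))
    if not cand:
        return []
    cand.sort()

    claimed = np.zeros(n, dtype=bool)
    segments: list[ZSegment] = []
    tol = 1e-9
    for _mean_key, _negL, _bp, phase, di, dl in cand:
        bp_start, bp_end = phase + 2 * di, phase + 2 * (di + dl)
        if claimed[bp_start:bp_end].any():
            continue
        costs = cost_arrays[phase]
        lo, hi = di, di + dl  # dinucleotide-grid extent
        core_mean = float(costs[lo:hi].mean())
        total = float(costs[lo:hi].sum())
        # greedy extension: absorb flanking steps that are themselves
        # Z-compatible (cost <= cutoff); the mean then stays <= cutoff and
        # expensive out-of-alternation background is never swallowed
        while True:
            left_ok = lo > 0 and costs[lo - 1] <= model.z_cutoff + tol and not claimed[phase + 2 * (lo - 1) : phase + 2 * lo].any()
            right_ok = hi < costs.size and costs[hi] <= model.z_cutoff + tol and not claimed[phase + 2 * hi : phase + 2 * (hi + 1)].any()
            if left_ok and (not right_ok or costs[lo - 1] <= costs[hi]):
                lo -= 1
                total += costs[lo]
            elif right_ok:
                total += costs[hi]
                hi += 1
            else:
                break
        bp_start, bp_end = phase + 2 * lo, phase + 2 * hi
        claimed[bp_start:bp_end] = True
        segments.append(
            ZSegment(
                interval=Interval(chrom, bp_start, bp_end),
                energy_total=float(total + 2.0 * model.junction_cost),
                energy_per_dinuc=core_mean,
                phase=phase,
            )
        )
    segments.sort(key=lambda z: z.interval.start)
    return segments


def energy_label_track(seq: GenomeSequence, model: EnergyModel | None = None) -> LabelTrack:
    """Binary oracle labels: 1 inside best_z_segments calls."""
    labels = np.zeros(seq.length, dtype=np.int8)
    for z in best_z_segments(seq, model):
        labels[z.interval.start : z.interval.end] = 1
    return LabelTrack(seq.name, labels)


def energy_score_track(seq: GenomeSequence, model: EnergyModel | None = None) -> ScoreTrack:
    """Per-base Z propensity: cutoff minus the covering segment's mean step cost.

    Bases outside any called segment score 0; higher means more Z-prone.
    """
    model = model or EnergyModel()
    values = np.zeros(seq.length, dtype=np.float64)
    for z in best_z_segments(seq, model):
        values[z.interval.start : z.interval.end] = max(0.0, model.z_cutoff - z.energy_per_dinuc)
    return ScoreTrack(seq.name, values)
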