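"""ChIP signal per ITR, fidelity stratification, and critical motif positions.

Binding affinity is operationalized as the length-weighted mean of a
piecewise-constant coverage track (bedGraph semantics, uncovered bases score
0) over the 19-bp ITR hit.  Hits are stratified by mismatch group and
compared to a genomic background ("Total") of seeded random motif-length
intervals placed outside hit loci.  Group comparisons use a Wilcoxon rank-sum
test (exact enumeration for small samples, tie- and continuity-corrected
normal approximation otherwise).

The single-substitution analysis groups 1-mismatch solo ITRs by their
(position, from-base, to-base) change, drops rare substitutions
(frequency < 2% of the 1MM solo pool), and reports each group's median
score, fold change versus the 0MM solo median, and rank-sum p value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from statistics import median
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .element_annotation import SOLO, ItrElement
from .genome_scan import ItrHit
from .peak_analysis import Interval, IntervalIndex


class SignalTrack:
    """Piecewise-constant per-base signal with mean-over-interval queries.

    Stores sorted, non-overlapping scored intervals per chromosome; bases not
    covered by any interval score 0.  Means are computed from a cumulative
    integral, so queries are O(log n).
    """

    def __init__(self, intervals: Mapping[str, Sequence[Tuple[int, int, float]]]):
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        self._values: Dict[str, np.ndarray] = {}
        self._cum: Dict[str, np.ndarray] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            starts = np.array([i[0] for i in ivs], dtype=np.int64)
            ends = np.array([i[1] for i in ivs], dtype=np.int64)
            values = np.array([i[2] for i in ivs], dtype=float)
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping signal intervals on {chrom}")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite signal values on {chrom}")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = values
            self._cum[chrom] = np.concatenate(
                ([0.0], np.cumsum(values * (ends - starts)))
            )

    @property
    def chroms(self) -> List[str]:
        return list(self._starts)

    def _integral(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the signal over [0, pos) for each position."""
        starts, ends = self._starts[chrom], self._ends[chrom]
        values, cum = self._values[chrom], self._cum[chrom]
        idx = np.searchsorted(ends, pos, side="right")
        total = cum[idx]
        partial = idx < len(starts)
        pi = idx[partial]
        overlap = np.clip(pos[partial] - starts[pi], 0, None)
        total = total.astype(float)
        total[partial] += values[pi] * overlap
        return total

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean score over [start, end), zeros included."""
        return float(self.mean_over_many(chrom, np.array([start]), np.array([end]))[0])

    def mean_over_many(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        if chrom not in self._starts:
            raise KeyError(f"unknown chromosome: {chrom}")
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if np.any(ends <= starts):
            raise ValueError("empty interval")
        return (self._integral(chrom, ends) - self._integral(chrom, starts)) / (
            ends - starts
        )

    def to_intervals(self) -> Dict[str, List[Tuple[int, int, float]]]:
        return {
            c: list(zip(self._starts[c].tolist(), self._ends[c].tolist(), self._values[c].tolist()))
            for c in self._starts
        }


def mean_score_over_interval(track: SignalTrack, interval: Interval) -> float:
    chrom, start, end = interval
    return track.mean_over(chrom, start, end)


@dataclass
class GroupScore:
    """Per-group signal summary: member scores and their median."""

    label: str
    scores: np.ndarray

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def median(self) -> float:
        return float(np.median(self.scores)) if self.n else float("nan")


def hit_scores(track: SignalTrack, hits: Sequence[ItrHit]) -> np.ndarray:
    """Mean track score over each hit's motif-length interval."""
    out = np.empty(len(hits))
    by_chrom: Dict[str, List[int]] = {}
    for i, h in enumerate(hits):
        by_chrom.setdefault(h.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        s = np.array([hits[i].start for i in idxs])
        e = np.array([hits[i].end for i in idxs])
        out[idxs] = track.mean_over_many(chrom, s, e)
    return out


def random_background_intervals(
    chrom_sizes: Mapping[str, int],
    exclude: Iterable[Interval],
    n: int,
    length: int,
    seed: int,
) -> List[Interval]:
    """Seeded random fixed-length intervals avoiding the excluded loci."""
    rng = np.random.default_rng(seed)
    index = IntervalIndex(exclude)
    chroms = sorted(chrom_sizes)
    weights = np.array([max(0, chrom_sizes[c] - length) for c in chroms], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("no room for background intervals")
    weights /= weights.sum()
    out: List[Interval] = []
    while len(out) < n:
        batch = max(64, n - len(out))
        ci = rng.choice(len(chroms), size=batch, p=weights)
        for k in range(batch):
            chrom = chroms[ci[k]]
            start = int(rng.integers(0, chrom_sizes[chrom] - length + 1))
            if not index.overlaps(chrom, np.array([start]), np.array([start + length]))[0]:
                out.append((chrom, start, start + length))
                if len(out) == n:
                    break
    return out


def scores_by_group(
    track: SignalTrack,
    hits: Sequence[ItrHit],
    chrom_sizes: Mapping[str, int],
    background_n: int = 10_000,
    seed: int = 0,
    max_mismatch: int = 3,
    blacklist: Sequence[Interval] = (),
) -> Dict[str, GroupScore]:
    """Per-group mean-score distributions plus a 'Total' genomic background.

    'Total' is ``background_n`` seeded random motif-length intervals outside
    hit loci (and any blacklist), representing the genomic background.
    """
    scores = hit_scores(track, hits)
    groups: Dict[str, GroupScore] = {}
    for k in range(max_mismatch + 1):
        label = f"{k}MM"
        sel = np.array([h.mismatch_count == k for h in hits], dtype=bool)
        groups[label] = GroupScore(label, scores[sel] if len(hits) else np.array([]))
    length = len(hits[0].matched_seq) if hits else 19
    exclude = [(h.chrom, h.start, h.end) for h in hits] + list(blacklist)
    bg = random_background_intervals(chrom_sizes, exclude, background_n, length, seed)
    bg_scores = np.empty(background_n)
    by_chrom: Dict[str, List[int]] = {}
    for i, (chrom, s, e) in enumerate(bg):
        by_chrom.setdefault(chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        s = np.array([bg[i][1] for i in idxs])
        e = np.array([bg[i][2] for i in idxs])
        bg_scores[idxs] = track.mean_over_many(chrom, s, e)
    groups["Total"] = GroupScore("Total", bg_scores)
    return groups


# -- rank-sum test -------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first sample
    z: float
    pvalue: float
    method: str


EXACT_LIMIT = 12


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration of all rank assignments when len(x)+len(y) <= 12
    (ties get average ranks); otherwise the normal approximation with tie
    correction and a continuity correction.  ``method`` may force either
    branch ("exact" | "normal").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0

    use_exact = n <= EXACT_LIMIT if method == "auto" else method == "exact"
    if use_exact:
        dev = abs(w - mu)
        count = 0
        total = 0
        for idx in combinations(range(n), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12:
                count += 1
        return RankSumResult(w, 0.0, count / total, "exact")

    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all observations identical
        return RankSumResult(w, 0.0, 1.0, "normal")
    d = max(0.0, abs(w - mu) - 0.5)  # continuity correction
    z = d / math.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    signed_z = math.copysign(z, w - mu) if w != mu else 0.0
    return RankSumResult(w, signed_z, p, "normal")


# -- single-substitution analysis ---------------------------------------------

@dataclass
class SubstitutionEffect:
    """Effect of one single-nucleotide ITR change on binding signal."""

    position: int
    from_base: str
    to_base: str
    n: int
    frequency: float  # percent of all 1MM solo ITRs
    median_score: float
    fold_change: float  # (0MM solo median) / (group median)
    pvalue: float


def substitution_effects(
    track: SignalTrack,
    elements: Sequence[ItrElement],
    min_frequency: float = 2.0,
) -> List[SubstitutionEffect]:
    """Group 1MM solo ITRs by substitution and compare each to 0MM solos.

    ``min_frequency`` is in percent; groups strictly below it are excluded.
    Raises if there are no 0MM solo ITRs (no reference group).
    """
    solos = [e for e in elements if e.kind == SOLO]
    ref_hits = [e.hits[0] for e in solos if e.hits[0].mismatch_count == 0]
    if not ref_hits:
        raise ValueError("no 0MM solo ITRs: reference group is empty")
    ref_scores = hit_scores(track, ref_hits)
    ref_median = float(np.median(ref_scores))

    one_mm = [e.hits[0] for e in solos if e.hits[0].mismatch_count == 1]
    groups: Dict[Tuple[int, str, str], List[ItrHit]] = {}
    for h in one_mm:
        (entry,) = h.profile
        key = (entry.position, entry.motif_base, entry.observed_base)
        groups.setdefault(key, []).append(h)

    total = len(one_mm)
    out: List[SubstitutionEffect] = []
    for key in sorted(groups):
        members = groups[key]
        freq = 100.0 * len(members) / total
        if freq < min_frequency:
            continue
        scores = hit_scores(track, members)
        med = float(np.median(scores))
        fold = ref_median / med if med > 0 else math.inf
        p = rank_sum_test(scores, ref_scores).pvalue
        out.append(
            SubstitutionEffect(key[0], key[1], key[2], len(members), freq, med, fold, p)
        )
    out.sort(key=lambda e: (e.position, e.from_base, e.to_base))
    return out
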