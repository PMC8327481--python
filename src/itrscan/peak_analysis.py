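"""ChIP-peak / ITR intersection and enrichment against a randomized null.

Peaks are intersected with ITR hits after symmetric extension (default
+/- 500 bp).  Enrichment of peak counts in a genomic category is tested with
a pooled two-proportion z test against randomized peak sets that preserve
per-chromosome peak counts and lengths and avoid blacklisted regions
(placement is rejection-free, uniform over the allowed complement).

Peak summits are annotated into one of five genomic categories with a fixed
priority (TSS > TTS > exon > intron > intergenic), using strand-aware
promoter/terminator windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .genome_scan import ItrHit

Interval = Tuple[str, int, int]

TSS_WINDOW = (1000, 100)  # bases upstream, downstream of the TSS
TTS_WINDOW = (100, 1000)  # bases upstream, downstream of the TTS
CATEGORIES = ("TSS", "TTS", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class Peak:
    """A ChIP interval with its summit (absolute coordinate) and score."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside peak {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TTS and non-overlapping exon intervals."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        ex = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", ex)
        for (a0, a1), (b0, b1) in zip(ex, ex[1:]):
            if b0 < a1:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
        for a0, a1 in ex:
            if a0 < self.start or a1 > self.end:
                raise ValueError(f"exon outside gene span in {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    observed_count: int
    expected_count: float
    ratio: float
    z: float
    p: float


# -- interval utilities -------------------------------------------------------

def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge possibly-overlapping half-open intervals into a sorted disjoint set."""
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class IntervalIndex:
    """Per-chromosome merged intervals with vectorized overlap queries."""

    def __init__(self, intervals: Iterable[Interval]):
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            merged = merge_intervals(ivs)
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    def overlaps(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean array: does each half-open query intersect >=1 bp of the index?"""
        if chrom not in self._starts:
            return np.zeros(len(starts), dtype=bool)
        ms, me = self._starts[chrom], self._ends[chrom]
        # candidate merged interval: the last one starting before each query end
        idx = np.searchsorted(ms, ends, side="left") - 1
        ok = idx >= 0
        hit = np.zeros(len(starts), dtype=bool)
        hit[ok] = me[idx[ok]] > np.asarray(starts)[ok]
        return hit

    def contains(self, chrom: str, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points)
        return self.overlaps(chrom, pts, pts + 1)


# -- operations ---------------------------------------------------------------

def extend_intervals(
    intervals: Sequence[Interval],
    flank: int = 500,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> List[Interval]:
    """Grow each interval symmetrically, clipping at chromosome bounds."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out: List[Interval] = []
    for chrom, s, e in intervals:
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise KeyError(f"unknown chromosome: {chrom}")
            size = chrom_sizes[chrom]
        else:
            size = None
        ns = max(0, s - flank)
        ne = e + flank if size is None else min(size, e + flank)
        out.append((chrom, ns, ne))
    return out


@dataclass
class VennResult:
    n_peaks: int
    n_peaks_overlapping: int
    n_itrs: int
    n_itrs_covered: int
    peak_flags: List[bool] = field(default_factory=list)
    itr_flags: List[bool] = field(default_factory=list)


def overlap_peaks_itrs(
    peaks: Sequence[Peak],
    hits: Sequence[ItrHit],
    flank: int = 500,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> VennResult:
    """Symmetric overlap counts between flank-extended peaks and ITR hits.

    Overlap means >=1 bp intersection between the extended peak and the
    19-bp hit (half-open arithmetic).
    """
    extended = extend_intervals(
        [(p.chrom, p.start, p.end) for p in peaks], flank, chrom_sizes
    )
    peak_index = IntervalIndex(extended)
    hit_index = IntervalIndex((h.chrom, h.start, h.end) for h in hits)

    itr_flags: List[bool] = []
    by_chrom_hits: Dict[str, List[int]] = {}
    for i, h in enumerate(hits):
        by_chrom_hits.setdefault(h.chrom, []).append(i)
    flags = np.zeros(len(hits), dtype=bool)
    for chrom, idxs in by_chrom_hits.items():
        s = np.array([hits[i].start for i in idxs])
        e = np.array([hits[i].end for i in idxs])
        flags[idxs] = peak_index.overlaps(chrom, s, e)
    itr_flags = flags.tolist()

    pflags = np.zeros(len(peaks), dtype=bool)
    by_chrom_peaks: Dict[str, List[int]] = {}
    for i, (chrom, s, e) in enumerate(extended):
        by_chrom_peaks.setdefault(chrom, []).append(i)
    for chrom, idxs in by_chrom_peaks.items():
        s = np.array([extended[i][1] for i in idxs])
        e = np.array([extended[i][2] for i in idxs])
        pflags[idxs] = hit_index.overlaps(chrom, s, e)
    peak_flags = pflags.tolist()

    return VennResult(
        n_peaks=len(peaks),
        n_peaks_overlapping=int(sum(peak_flags)),
        n_itrs=len(hits),
        n_itrs_covered=int(sum(itr_flags)),
        peak_flags=peak_flags,
        itr_flags=itr_flags,
    )


def _category_indices(
    genes: Sequence[GeneModel],
    tss_window: Tuple[int, int] = TSS_WINDOW,
    tts_window: Tuple[int, int] = TTS_WINDOW,
) -> Dict[str, IntervalIndex]:
    tss_iv, tts_iv, exon_iv, body_iv = [], [], [], []
    for g in genes:
        up, down = tss_window
        if g.strand == "+":
            tss_iv.append((g.chrom, g.tss - up, g.tss + down + 1))
        else:
            tss_iv.append((g.chrom, g.tss - down, g.tss + up + 1))
        up, down = tts_window
        if g.strand == "+":
            tts_iv.append((g.chrom, g.tts - up, g.tts + down + 1))
        else:
            tts_iv.append((g.chrom, g.tts - down, g.tts + up + 1))
        exon_iv.extend((g.chrom, a, b) for a, b in g.exons)
        body_iv.append((g.chrom, g.start, g.end))
    return {
        "TSS": IntervalIndex(tss_iv),
        "TTS": IntervalIndex(tts_iv),
        "exon": IntervalIndex(exon_iv),
        "intron": IntervalIndex(body_iv),  # body minus exon, by priority order
    }


def annotate_summits(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    tss_window: Tuple[int, int] = TSS_WINDOW,
    tts_window: Tuple[int, int] = TTS_WINDOW,
) -> List[str]:
    """Assign each peak summit one category: TSS > TTS > exon > intron > intergenic.

    TSS/TTS windows are strand-aware (defaults: [TSS-1000, TSS+100] and
    [TTS-100, TTS+1000] in the direction of transcription).  'intron' is any
    summit inside a gene body that is not exonic and not in a TSS/TTS window.
    """
    indices = _category_indices(genes, tss_window, tts_window)
    out: List[str] = []
    for p in peaks:
        pt = np.array([p.summit])
        for cat in ("TSS", "TTS", "exon", "intron"):
            if indices[cat].contains(p.chrom, pt)[0]:
                out.append(cat)
                break
        else:
            out.append("intergenic")
    return out


def _allowed_gaps(
    size: int, blacklist: Sequence[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    gaps: List[Tuple[int, int]] = []
    pos = 0
    for s, e in merge_intervals(blacklist):
        s, e = max(0, s), min(size, e)
        if s > pos:
            gaps.append((pos, s))
        pos = max(pos, e)
    if pos < size:
        gaps.append((pos, size))
    return gaps


class PeakRandomizer:
    """Rejection-free uniform placement of peaks outside blacklisted regions.

    For each (chromosome, peak length) the allowed start positions form the
    union of blacklist-complement gaps at least as long as the peak; a
    cumulative table maps one uniform integer to a start position.
    """

    def __init__(
        self,
        chrom_sizes: Mapping[str, int],
        blacklist: Sequence[Interval] = (),
    ):
        self.chrom_sizes = dict(chrom_sizes)
        bl: Dict[str, List[Tuple[int, int]]] = {c: [] for c in self.chrom_sizes}
        for chrom, s, e in blacklist:
            if chrom in bl:
                bl[chrom].append((s, e))
        self._gaps = {
            c: _allowed_gaps(self.chrom_sizes[c], bl[c]) for c in self.chrom_sizes
        }
        self._tables: Dict[Tuple[str, int], Tuple[np.ndarray, np.ndarray, int]] = {}

    def _table(self, chrom: str, length: int):
        key = (chrom, length)
        if key not in self._tables:
            gaps = [(s, e) for s, e in self._gaps[chrom] if e - s >= length]
            counts = np.array([e - s - length + 1 for s, e in gaps], dtype=np.int64)
            starts = np.array([s for s, _ in gaps], dtype=np.int64)
            cum = np.concatenate(([0], np.cumsum(counts)))
            self._tables[key] = (starts, cum, int(cum[-1]))
        return self._tables[key]

    def sample_starts(self, chrom: str, length: int, n: int, rng: np.random.Generator) -> np.ndarray:
        starts, cum, total = self._table(chrom, length)
        if total <= 0:
            raise ValueError(
                f"no allowed placement for a {length}-bp peak on {chrom}"
            )
        u = rng.integers(0, total, size=n)
        gi = np.searchsorted(cum, u, side="right") - 1
        return starts[gi] + (u - cum[gi])


def randomize_peaks(
    peaks: Sequence[Peak],
    chrom_sizes: Mapping[str, int],
    blacklist: Sequence[Interval] = (),
    n_sets: int = 100,
    seed: int = 0,
) -> List[List[Peak]]:
    """Generate ``n_sets`` randomized peak sets as a null model.

    Each set preserves per-chromosome peak counts and exact lengths; starts
    are uniform over the blacklist complement; reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    randomizer = PeakRandomizer(chrom_sizes, blacklist)
    # group peaks by (chrom, length) so each group is sampled in one call
    groups: Dict[Tuple[str, int], int] = {}
    for p in peaks:
        if p.chrom not in chrom_sizes:
            raise KeyError(f"unknown chromosome: {p.chrom}")
        groups[(p.chrom, p.length)] = groups.get((p.chrom, p.length), 0) + 1
    sets: List[List[Peak]] = []
    for _ in range(n_sets):
        out: List[Peak] = []
        for (chrom, length), n in sorted(groups.items()):
            starts = randomizer.sample_starts(chrom, length, n, rng)
            out.extend(
                Peak(chrom, int(s), int(s) + length, int(s) + length // 2)
                for s in starts
            )
        sets.append(out)
    return sets


def enrichment_test(
    observed_hits: int,
    n_obs: int,
    random_hits: int,
    n_rand: int,
    category: str = "",
) -> EnrichmentResult:
    """Pooled two-proportion z test of observed vs randomized hit rates.

    Two-sided p from the normal approximation; z**2 equals the 2x2 chi-square
    statistic without continuity correction.
    """
    if n_obs <= 0 or n_rand <= 0:
        raise ValueError("totals must be positive")
    if observed_hits > n_obs or random_hits > n_rand:
        raise ValueError("hit counts cannot exceed totals")
    p1 = observed_hits / n_obs
    p2 = random_hits / n_rand
    pooled = (observed_hits + random_hits) / (n_obs + n_rand)
    denom = pooled * (1.0 - pooled) * (1.0 / n_obs + 1.0 / n_rand)
    z = 0.0 if denom == 0 else (p1 - p2) / math.sqrt(denom)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    expected = random_hits * n_obs / n_rand
    if expected > 0:
        ratio = observed_hits / expected
    else:
        ratio = math.inf if observed_hits > 0 else 1.0
    return EnrichmentResult(category, observed_hits, expected, ratio, float(z), float(p))


def category_enrichment(
    observed_categories: Sequence[str],
    random_categories: Sequence[str],
    categories: Sequence[str] = CATEGORIES,
) -> List[EnrichmentResult]:
    """Per-category enrichment of observed vs pooled randomized annotations.

    Each category is tested independently; no multiple-testing correction is
    applied (raw p values are reported).
    """
    n_obs, n_rand = len(observed_categories), len(random_categories)
    results = []
    for cat in categories:
        o = sum(1 for c in observed_categories if c == cat)
        r = sum(1 for c in random_categories if c == cat)
        results.append(enrichment_test(o, n_obs, r, n_rand, category=cat))
    return results


def chromosome_correlation(
    hits: Sequence[ItrHit],
    peaks: Sequence[Peak],
    chrom_lengths: Mapping[str, int],
) -> Dict[str, Tuple[float, float]]:
    """Spearman correlations over chromosomes: ITRs vs length, peaks vs length,
    peaks vs ITRs.  Ties are handled by average ranks."""
    chroms = sorted(chrom_lengths)
    if len(chroms) < 3:
        raise ValueError("need >=3 chromosomes for a correlation")
    n_hits = {c: 0 for c in chroms}
    n_peaks = {c: 0 for c in chroms}
    for h in hits:
        if h.chrom in n_hits:
            n_hits[h.chrom] += 1
    for p in peaks:
        if p.chrom in n_peaks:
            n_peaks[p.chrom] += 1
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    hv = np.array([n_hits[c] for c in chroms], dtype=float)
    pv = np.array([n_peaks[c] for c in chroms], dtype=float)
    out = {}
    for name, (x, y) in {
        "itrs_vs_length": (hv, lengths),
        "peaks_vs_length": (pv, lengths),
        "peaks_vs_itrs": (pv, hv),
    }.items():
        rho, p = stats.spearmanr(x, y)
        out[name] = (float(rho), float(p))
    return out
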