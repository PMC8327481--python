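"""Fidelity-stratified gene-expression comparison.

Genes are associated with ITRs over their TSS-window / exon / intron /
TTS-window span and stratified by the best (minimum) mismatch count among
their associated ITRs.  Each fidelity group's FPKM distribution is compared
to a seeded random group of non-associated genes with a Wilcoxon rank-sum
test, mirroring the expectation that high-fidelity binding sites mark
transcriptionally repressed loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .affinity_analysis import rank_sum_test
from .genome_scan import ItrHit
from .peak_analysis import TSS_WINDOW, TTS_WINDOW, GeneModel, Peak


def _association_span(
    gene: GeneModel,
    tss_window: Tuple[int, int] = TSS_WINDOW,
    tts_window: Tuple[int, int] = TTS_WINDOW,
) -> Tuple[int, int]:
    """Union of TSS window, gene body and TTS window (one contiguous interval)."""
    up_tss, down_tss = tss_window
    up_tts, down_tts = tts_window
    if gene.strand == "+":
        lo = min(gene.start, gene.tss - up_tss)
        hi = max(gene.end, gene.tts + down_tts + 1)
    else:
        lo = min(gene.start, gene.tts - down_tts)
        hi = max(gene.end, gene.tss + up_tss + 1)
    return max(0, lo), hi


def associate_genes(
    hits: Sequence[ItrHit],
    genes: Sequence[GeneModel],
    tss_window: Tuple[int, int] = TSS_WINDOW,
    tts_window: Tuple[int, int] = TTS_WINDOW,
) -> Dict[str, int]:
    """Map gene_id -> minimum mismatch count among ITR hits in its span.

    A gene is associated when >=1 hit interval intersects the union of its
    TSS window, exons, introns and TTS window.  Only associated genes appear
    in the result.
    """
    out: Dict[str, int] = {}
    by_chrom: Dict[str, List[ItrHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    arrays: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, hs in by_chrom.items():
        hs.sort(key=lambda h: h.start)
        arrays[chrom] = (
            np.array([h.start for h in hs]),
            np.array([h.end for h in hs]),
            np.array([h.mismatch_count for h in hs]),
        )
    for g in genes:
        if g.chrom not in arrays:
            continue
        lo, hi = _association_span(g, tss_window, tts_window)
        starts, ends, mms = arrays[g.chrom]
        # hits are non-overlapping and sorted, so ends are sorted too
        i0 = int(np.searchsorted(ends, lo, side="right"))
        i1 = int(np.searchsorted(starts, hi, side="left"))
        if i1 > i0:
            out[g.gene_id] = int(mms[i0:i1].min())
    return out


def associate_genes_by_peaks(
    peaks: Sequence[Peak],
    hits: Sequence[ItrHit],
    genes: Sequence[GeneModel],
    flank: int = 500,
    tss_window: Tuple[int, int] = TSS_WINDOW,
    tts_window: Tuple[int, int] = TTS_WINDOW,
) -> Dict[str, int]:
    """Peak-summit variant: genes whose span contains a peak summit, graded by
    the minimum mismatch among ITRs within the flank-extended peak."""
    peak_mm: List[Optional[int]] = []
    for p in peaks:
        best = None
        for h in hits:
            if h.chrom == p.chrom and h.start < p.end + flank and h.end > p.start - flank:
                best = h.mismatch_count if best is None else min(best, h.mismatch_count)
        peak_mm.append(best)
    out: Dict[str, int] = {}
    for g in genes:
        lo, hi = _association_span(g, tss_window, tts_window)
        for p, mm in zip(peaks, peak_mm):
            if mm is None or p.chrom != g.chrom:
                continue
            if lo <= p.summit < hi:
                cur = out.get(g.gene_id)
                out[g.gene_id] = mm if cur is None else min(cur, mm)
    return out


@dataclass
class GroupComparison:
    group: str
    n: int
    median_fpkm: float
    pvalue: Optional[float]  # vs the random group; None for the random group


@dataclass
class ExpressionCompareResult:
    groups: Dict[str, np.ndarray]
    comparisons: List[GroupComparison]
    n_missing_expression: int
    random_gene_ids: List[str] = field(default_factory=list)


def expression_compare(
    gene_groups: Mapping[str, int],
    expression: Mapping[str, float],
    random_n: Optional[int] = None,
    seed: int = 0,
    max_mismatch: int = 3,
    mode: str = "all",
) -> ExpressionCompareResult:
    """Compare per-fidelity-group FPKM distributions to a random gene group.

    The random group is sampled (seeded, without replacement) from genes in
    the expression table that are not associated with any ITR; ``mode`` is
    "all" or "expressed" (FPKM > 0 only).  ``random_n`` defaults to the total
    number of grouped genes.  Genes missing from the expression table are
    dropped and counted.
    """
    groups: Dict[str, List[float]] = {f"MM{k}": [] for k in range(max_mismatch + 1)}
    missing = 0
    for gid, mm in gene_groups.items():
        if gid in expression:
            groups[f"MM{mm}"].append(float(expression[gid]))
        else:
            missing += 1
    if not groups["MM0"]:
        raise ValueError("empty MM0 group: nothing to compare")

    pool = [g for g in sorted(expression) if g not in gene_groups]
    if mode == "expressed":
        pool = [g for g in pool if expression[g] > 0]
    elif mode != "all":
        raise ValueError(f"unknown mode: {mode}")
    n_grouped = sum(len(v) for v in groups.values())
    k = random_n if random_n is not None else n_grouped
    if k > len(pool):
        raise ValueError(f"cannot sample {k} random genes from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    random_ids = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
    random_fpkm = np.array([expression[g] for g in random_ids], dtype=float)

    arrays = {g: np.array(v, dtype=float) for g, v in groups.items()}
    arrays["random"] = random_fpkm
    comparisons = []
    for g in sorted(groups):
        vals = arrays[g]
        if len(vals) == 0:
            comparisons.append(GroupComparison(g, 0, float("nan"), None))
            continue
        p = rank_sum_test(vals, random_fpkm).pvalue
        comparisons.append(GroupComparison(g, len(vals), float(np.median(vals)), p))
    comparisons.append(
        GroupComparison("random", len(random_fpkm), float(np.median(random_fpkm)), None)
    )
    return ExpressionCompareResult(arrays, comparisons, missing, random_ids)
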