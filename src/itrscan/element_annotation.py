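"""Classification of ITR hits into MITE-like paired elements and solo ITRs.

A miniature inverted-repeat transposable element (MITE) is annotated when two
ITR hits lie on the same chromosome with an inner gap of at most ``max_gap``
bases (default 500); every other hit is a solo ITR.  Pairing is greedy
left-to-right: each unpaired hit pairs with its nearest eligible downstream
neighbour, so chains of nearby hits resolve first-come.  Pairing does not
require inverted (+/-) orientation unless ``require_inverted`` is set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from statistics import median
from typing import Dict, Iterable, List, Sequence, Tuple

from .genome_scan import ItrHit

MITE = "MITE"
SOLO = "solo"


@dataclass(frozen=True)
class ItrElement:
    """A classified element: a MITE (two paired hits) or a solo ITR."""

    kind: str
    hits: Tuple[ItrHit, ...]
    chrom: str
    span_start: int
    span_end: int

    @property
    def length(self) -> int:
        return self.span_end - self.span_start

    @property
    def min_mismatch(self) -> int:
        return min(h.mismatch_count for h in self.hits)

    @property
    def group(self) -> str:
        return f"{self.min_mismatch}MM"


def pair_itrs(
    hits: Sequence[ItrHit],
    max_gap: int = 500,
    require_inverted: bool = False,
) -> List[ItrElement]:
    """Partition non-overlapping hits into MITEs and solo ITRs.

    The inner gap (downstream hit start minus upstream hit end) must be at
    most ``max_gap`` for a pair.  Overlapping input hits are rejected.
    """
    ordered = sorted(hits, key=lambda h: (h.chrom, h.start))
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(
                f"overlapping hits: {a.chrom}:{a.start}-{a.end} and "
                f"{b.chrom}:{b.start}-{b.end}"
            )
    paired = [False] * len(ordered)
    elements: List[ItrElement] = []
    for i, h in enumerate(ordered):
        if paired[i]:
            continue
        partner = None
        for j in range(i + 1, len(ordered)):
            nxt = ordered[j]
            if nxt.chrom != h.chrom:
                break
            gap = nxt.start - h.end
            if gap > max_gap:
                break
            if paired[j]:
                continue
            if require_inverted and nxt.strand == h.strand:
                continue
            partner = j
            break
        if partner is not None:
            p = ordered[partner]
            paired[i] = paired[partner] = True
            elements.append(ItrElement(MITE, (h, p), h.chrom, h.start, p.end))
        else:
            paired[i] = True
            elements.append(ItrElement(SOLO, (h,), h.chrom, h.start, h.end))
    return elements


def element_length_summary(elements: Iterable[ItrElement]) -> Dict[str, object]:
    """Length histogram (1-bp bins) and median over MITE elements."""
    lengths = sorted(e.length for e in elements if e.kind == MITE)
    if not lengths:
        return {"n": 0, "median": None, "histogram": {}, "empty": True}
    return {
        "n": len(lengths),
        "median": median(lengths),
        "histogram": dict(Counter(lengths)),
        "empty": False,
    }


def solo_itrs_by_group(
    elements: Iterable[ItrElement], max_mismatch: int = 3
) -> Dict[str, int]:
    """Counts of solo ITRs per mismatch group, keyed '0MM'..'<k>MM'."""
    counts = {f"{k}MM": 0 for k in range(max_mismatch + 1)}
    for e in elements:
        if e.kind == SOLO:
            counts[e.hits[0].group] = counts.get(e.hits[0].group, 0) + 1
    return counts
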