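"""Degenerate scanning of a short motif across a genome with Hamming mismatches.

The target motif is the 19-nt core of the *Hsmar1* inverted terminal repeat
(ITR), 5'-GGTGCAAAAGTAATTGCGG-3', the binding site of the SETMAR transposase
domain.  Both strands are scanned; every window within ``max_mismatch``
substitutions of the motif is a raw match.  Overlapping raw matches are
resolved greedily (lowest mismatch count wins, then ``+`` strand, then the
leftmost start) so the returned hit set annotates each locus exactly once.

Coordinates are 0-based half-open throughout; mismatch positions inside a
motif are reported 1-based in motif (5'->3') orientation, matching the
conventional "C17"-style naming of ITR positions.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

#: 19-nt core of the Hsmar1 ITR consensus.
CORE_MOTIF = "GGTGCAAAAGTAATTGCGG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_MOTIF = frozenset("ACGT")
_VALID_GENOME = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """A query motif and the maximum Hamming distance allowed for a hit."""

    sequence: str = CORE_MOTIF
    max_mismatch: int = 3

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("motif sequence must be non-empty")
        bad = set(seq) - _VALID_MOTIF
        if bad:
            raise ValueError(f"motif contains invalid bases: {sorted(bad)}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be non-negative")
        if self.max_mismatch >= len(seq):
            raise ValueError("max_mismatch must be < motif length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MismatchEntry:
    """One substitution relative to the motif, in 1-based motif coordinates."""

    position: int
    motif_base: str
    observed_base: str

    def __str__(self) -> str:
        return f"{self.position}:{self.motif_base}>{self.observed_base}"


MismatchProfile = Tuple[MismatchEntry, ...]


@dataclass(frozen=True)
class ItrHit:
    """A single genomic match of the ITR core motif.

    ``matched_seq`` is oriented: for a minus-strand hit it is the reverse
    complement of the genomic window, so its Hamming distance to the motif
    always equals ``mismatch_count``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    mismatch_count: int
    profile: MismatchProfile
    matched_seq: str

    @property
    def group(self) -> str:
        return f"{self.mismatch_count}MM"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def profile_string(self) -> str:
        return ",".join(str(e) for e in self.profile) if self.profile else "."


def normalize_genome(genome: Mapping[str, object]) -> Dict[str, str]:
    """Uppercase chromosome sequences and validate the A/C/G/T/N alphabet.

    Accepts any mapping of name -> sequence-like (str, pyfaidx record, ...).
    Soft-masked (lowercase) bases are treated as normal bases.
    """
    out: Dict[str, str] = {}
    for name, seq in genome.items():
        s = str(seq).upper()
        bad = set(s) - _VALID_GENOME
        if bad:
            raise ValueError(f"chromosome {name!r} contains invalid bases: {sorted(bad)}")
        out[str(name)] = s
    return out


def mismatch_profile(window: str, motif: MotifSpec | str) -> MismatchProfile:
    """Per-position differences between an oriented window and the motif."""
    motif_seq = motif.sequence if isinstance(motif, MotifSpec) else motif.upper()
    window = window.upper()
    if len(window) != len(motif_seq):
        raise ValueError(
            f"window length {len(window)} != motif length {len(motif_seq)}"
        )
    return tuple(
        MismatchEntry(i + 1, m, w)
        for i, (m, w) in enumerate(zip(motif_seq, window))
        if m != w
    )


# -- raw matching ------------------------------------------------------------

def _window_has_n(arr: np.ndarray, k: int) -> np.ndarray:
    is_n = (arr == ord("N")).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(is_n)))
    return (cs[k:] - cs[:-k]) > 0


def _mismatch_counts(arr: np.ndarray, pattern: bytes) -> np.ndarray:
    """Hamming distance of every window of ``len(pattern)`` to the pattern."""
    k = len(pattern)
    n_win = len(arr) - k + 1
    mm = np.zeros(n_win, dtype=np.int16)
    for i, b in enumerate(pattern):
        mm += arr[i : i + n_win] != b
    return mm


def _raw_matches(chrom: str, seq: str, motif: MotifSpec) -> List[Tuple[str, int, str, int]]:
    """All (chrom, start, strand, mismatch_count) raw matches, vectorized."""
    k = len(motif)
    if len(seq) < k:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    has_n = _window_has_n(arr, k)
    out: List[Tuple[str, int, str, int]] = []
    for strand, pattern in (("+", motif.sequence), ("-", revcomp(motif.sequence))):
        mm = _mismatch_counts(arr, pattern.encode("ascii"))
        keep = np.nonzero((mm <= motif.max_mismatch) & ~has_n)[0]
        out.extend((chrom, int(s), strand, int(mm[s])) for s in keep)
    return out


def _raw_matches_naive(chrom: str, seq: str, motif: MotifSpec) -> List[Tuple[str, int, str, int]]:
    """Reference enumeration: every window on both strands, direct Hamming."""
    k = len(motif)
    kmax = motif.max_mismatch
    patterns = (("+", motif.sequence), ("-", revcomp(motif.sequence)))
    out: List[Tuple[str, int, str, int]] = []
    for start in range(len(seq) - k + 1):
        window = seq[start : start + k]
        if "N" in window:
            continue
        for strand, pattern in patterns:
            mm = 0
            for a, b in zip(window, pattern):
                if a != b:
                    mm += 1
                    if mm > kmax:
                        break
            if mm <= kmax:
                out.append((chrom, start, strand, mm))
    return out


def resolve_overlaps(
    raw: Sequence[Tuple[str, int, str, int]], motif_length: int
) -> List[Tuple[str, int, str, int]]:
    """Greedy per-chromosome resolution of overlapping raw matches.

    Priority: lowest mismatch count, then ``+`` over ``-``, then leftmost
    start.  A window matching on both strands keeps the higher-priority
    orientation.  The kept set is mutually non-overlapping.
    """
    by_chrom: Dict[str, List[Tuple[str, int, str, int]]] = {}
    for m in raw:
        by_chrom.setdefault(m[0], []).append(m)
    kept: List[Tuple[str, int, str, int]] = []
    for chrom in by_chrom:
        candidates = sorted(
            by_chrom[chrom], key=lambda m: (m[3], 0 if m[2] == "+" else 1, m[1])
        )
        starts: List[int] = []  # sorted starts of kept hits on this chromosome
        for m in candidates:
            s = m[1]
            i = bisect_left(starts, s)
            if i > 0 and s - starts[i - 1] < motif_length:
                continue
            if i < len(starts) and starts[i] - s < motif_length:
                continue
            insort(starts, s)
            kept.append(m)
    kept.sort(key=lambda m: (m[0], m[1]))
    return kept


def _build_hits(
    genome: Mapping[str, str],
    raw: Sequence[Tuple[str, int, str, int]],
    motif: MotifSpec,
) -> List[ItrHit]:
    k = len(motif)
    hits = []
    for chrom, start, strand, mm in raw:
        window = genome[chrom][start : start + k]
        oriented = window if strand == "+" else revcomp(window)
        profile = mismatch_profile(oriented, motif)
        assert len(profile) == mm
        hits.append(ItrHit(chrom, start, start + k, strand, mm, profile, oriented))
    return hits


def scan_motif(genome: Mapping[str, object], motif: MotifSpec | None = None) -> List[ItrHit]:
    """Scan a genome on both strands for the motif, up to ``max_mismatch``.

    Returns non-overlapping hits sorted by (chrom, start).  Windows
    containing N are skipped.
    """
    motif = motif or MotifSpec()
    norm = normalize_genome(genome)
    raw: List[Tuple[str, int, str, int]] = []
    for chrom in norm:
        raw.extend(_raw_matches(chrom, norm[chrom], motif))
    return _build_hits(norm, resolve_overlaps(raw, len(motif)), motif)


def scan_motif_naive(genome: Mapping[str, object], motif: MotifSpec | None = None) -> List[ItrHit]:
    """Naive all-window reference scanner (same contract as :func:`scan_motif`).

    Enumerates every window on both strands and computes Hamming distance
    directly; used as the independent ground-truth oracle.
    """
    motif = motif or MotifSpec()
    norm = normalize_genome(genome)
    raw: List[Tuple[str, int, str, int]] = []
    for chrom in norm:
        raw.extend(_raw_matches_naive(chrom, norm[chrom], motif))
    return _build_hits(norm, resolve_overlaps(raw, len(motif)), motif)


def group_by_mismatch(hits: Iterable[ItrHit], max_mismatch: int = 3) -> Dict[str, int]:
    """Counts of hits per mismatch group, keyed '0MM'..'<k>MM'."""
    counts = {f"{k}MM": 0 for k in range(max_mismatch + 1)}
    for h in hits:
        counts[h.group] = counts.get(h.group, 0) + 1
    return counts
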