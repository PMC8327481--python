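"""Synthetic genomes, ChIP data and expression tables with planted truth.

The generator emulates the statistical structure of the ITR/SETMAR analysis:
a multi-chromosome uniform-random genome with planted ITR loci at controlled
mismatch counts (0-3), planted inverted-repeat pairs (MITEs), a blacklist,
peaks preferentially placed on high-fidelity ITRs, a piecewise-constant ChIP
signal whose amplitude decays with mismatch count plus noise, and gene models
whose FPKM values are log-normally distributed with a per-group repression
shift.  Every planted object is recorded in a truth table; background windows
that happen to fall within the mismatch threshold are enumerated after
generation and added to the truth with source="background".

One master seed drives everything; each artifact (genome, ChIP, expression)
derives its own child stream so modules can be regenerated independently.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .affinity_analysis import SignalTrack
from .element_annotation import ItrElement, pair_itrs
from .genome_scan import (
    CORE_MOTIF,
    ItrHit,
    MotifSpec,
    mismatch_profile,
    revcomp,
    scan_motif,
)
from .peak_analysis import GeneModel, Interval, IntervalIndex, Peak, PeakRandomizer

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults plant 100 solo ITRs split (20, 30, 25, 25) across mismatch
    groups 0-3 plus 200 exact inverted-repeat pairs (MITEs) with inner gaps
    uniform in 20-80 bp, on a 2.4-Mb three-chromosome genome.  Peaks cover a
    decreasing fraction of ITRs per group; signal amplitude is S0 * f^mm with
    Gaussian noise; gene expression is log-normal with a per-group
    repression shift strongest for the high-fidelity group.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 800_000, "chr3": 600_000}
    )
    motif: str = CORE_MOTIF
    max_mismatch: int = 3
    solo_counts: Tuple[int, ...] = (20, 30, 25, 25)
    mite_pairs: int = 200
    mite_gap_range: Tuple[int, int] = (20, 80)  # inner gap, uniform inclusive
    element_spacing: int = 2500  # min distance between planted elements
    blacklist_fraction: float = 0.05
    blacklist_chunk: int = 2000
    peak_fraction: Tuple[float, ...] = (0.9, 0.6, 0.4, 0.2)
    n_background_peaks: int = 100
    peak_halfwidth: int = 200
    signal_halfwidth: int = 150
    s0: float = 100.0
    decay: float = 0.5  # per-mismatch amplitude factor, in (0, 1]
    noise_sigma: float = 5.0
    bin_size: int = 100
    gene_fraction: float = 0.7
    gene_length: int = 1500
    n_null_genes: int = 300
    log_mu: float = 1.0
    log_sigma: float = 1.0
    expression_shift: Tuple[float, ...] = (-1.0, -0.5, -0.25, 0.0)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.solo_counts) or self.mite_pairs < 0:
            raise ValueError("planted counts must be >= 0")
        if not (0 < self.decay <= 1):
            raise ValueError("decay factor must be in (0, 1]")
        if len(self.solo_counts) != self.max_mismatch + 1:
            raise ValueError("solo_counts must have max_mismatch+1 entries")

    @property
    def motif_spec(self) -> MotifSpec:
        return MotifSpec(self.motif, self.max_mismatch)


HIT_COLUMNS = [
    "chrom", "start", "end", "strand", "mismatch_count",
    "kind", "element_id", "source", "matched_seq", "peaked",
]


@dataclass
class TruthTable:
    """Planted (and oracle-enumerated background) loci with their labels."""

    hits: pd.DataFrame
    blacklist: List[Interval]
    chrom_sizes: Dict[str, int]
    genes: Optional[pd.DataFrame] = None

    def hit_objects(self, motif: MotifSpec) -> List[ItrHit]:
        """Reconstruct ItrHit objects from the truth rows (geometry only)."""
        out = []
        for r in self.hits.itertuples(index=False):
            profile = mismatch_profile(r.matched_seq, motif)
            out.append(
                ItrHit(r.chrom, int(r.start), int(r.end), r.strand,
                       int(r.mismatch_count), profile, r.matched_seq)
            )
        return sorted(out, key=lambda h: (h.chrom, h.start))

    def expected_elements(self, motif: MotifSpec, max_gap: int = 500) -> List[ItrElement]:
        """Element classification implied by the truth coordinates alone."""
        return pair_itrs(self.hit_objects(motif), max_gap=max_gap)

    def planted_group_counts(self, max_mismatch: int = 3) -> Dict[str, int]:
        planted = self.hits[self.hits["source"] == "planted"]
        return {
            f"{k}MM": int((planted["mismatch_count"] == k).sum())
            for k in range(max_mismatch + 1)
        }


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _mutate_motif(motif: str, k: int, rng: np.random.Generator) -> str:
    """The motif with exactly k substitutions at distinct random positions."""
    seq = list(motif)
    positions = rng.choice(len(seq), size=k, replace=False)
    for p in positions:
        choices = [b for b in "ACGT" if b != seq[p]]
        seq[p] = choices[int(rng.integers(0, 3))]
    return "".join(seq)


def _place_elements(
    lengths: Mapping[str, int],
    widths: Sequence[int],
    spacing: int,
    rng: np.random.Generator,
) -> List[Tuple[str, int]]:
    """Assign each element a chromosome and start so neighbours are >= spacing apart."""
    chroms = sorted(lengths)
    total_len = sum(lengths.values())
    # deterministic proportional allocation (largest remainder)
    quotas = {c: len(widths) * lengths[c] / total_len for c in chroms}
    counts = {c: int(quotas[c]) for c in chroms}
    rem = len(widths) - sum(counts.values())
    for c in sorted(chroms, key=lambda c: quotas[c] - int(quotas[c]), reverse=True)[:rem]:
        counts[c] += 1
    order = rng.permutation(len(widths))
    placements: List[Tuple[str, int]] = [None] * len(widths)  # type: ignore
    cursor = 0
    for c in chroms:
        k = counts[c]
        idxs = order[cursor : cursor + k]
        cursor += k
        w = [widths[i] for i in idxs]
        slack = lengths[c] - sum(w) - spacing * (k + 1)
        if slack < 0:
            raise ValueError(
                f"infeasible packing: {k} elements do not fit on {c} "
                f"({lengths[c]} bp) with spacing {spacing}"
            )
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        offset = spacing
        acc = 0
        for j, i in enumerate(idxs):
            start = int(cuts[j]) + offset + acc
            placements[i] = (c, start)
            acc += w[j]
            offset += spacing
    return placements


def generate_genome(config: SimulationConfig, seed: int = 0) -> Tuple[Dict[str, str], TruthTable]:
    """Build the genome FASTA content and its truth table.

    Background is uniform-random ACGT; planted loci overwrite it.  After
    assembly the whole genome is rescanned and any background window within
    the mismatch threshold is appended to the truth (source="background").
    """
    rng = _child_rng(seed, 0)
    motif = config.motif_spec
    mlen = len(motif)

    # element plan: solos per group, then MITE pairs
    plan: List[Tuple[str, int, object]] = []  # (kind, width, payload)
    for k, n in enumerate(config.solo_counts):
        for _ in range(n):
            plan.append(("solo", mlen, k))
    lo, hi = config.mite_gap_range
    for _ in range(config.mite_pairs):
        gap = int(rng.integers(lo, hi + 1))
        plan.append(("mite", 2 * mlen + gap, gap))

    placements = _place_elements(
        config.chrom_lengths, [w for _, w, _ in plan], config.element_spacing, rng
    )

    # background sequence
    genome_arr: Dict[str, np.ndarray] = {}
    for chrom in sorted(config.chrom_lengths):
        idx = rng.integers(0, 4, size=config.chrom_lengths[chrom])
        genome_arr[chrom] = _BASES[idx]

    rows = []
    element_intervals: List[Interval] = []
    for eid, ((kind, width, payload), (chrom, start)) in enumerate(zip(plan, placements)):
        if kind == "solo":
            k = int(payload)
            mutated = _mutate_motif(config.motif, k, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = mutated if strand == "+" else revcomp(mutated)
            genome_arr[chrom][start : start + mlen] = np.frombuffer(
                inserted.encode(), dtype=np.uint8
            )
            rows.append((chrom, start, start + mlen, strand, k, "solo",
                         eid, "planted", mutated, False))
        else:
            gap = int(payload)
            left = config.motif
            right = revcomp(config.motif)
            seq = left + "".join("ACGT"[i] for i in rng.integers(0, 4, size=gap)) + right
            genome_arr[chrom][start : start + len(seq)] = np.frombuffer(
                seq.encode(), dtype=np.uint8
            )
            rows.append((chrom, start, start + mlen, "+", 0, "mite",
                         eid, "planted", config.motif, False))
            rstart = start + mlen + gap
            rows.append((chrom, rstart, rstart + mlen, "-", 0, "mite",
                         eid, "planted", config.motif, False))
        element_intervals.append((chrom, start, start + width))

    genome = {c: arr.tobytes().decode("ascii") for c, arr in genome_arr.items()}

    # blacklist: chunks carved from inter-element gaps, away from elements
    blacklist = _make_blacklist(config, element_intervals, rng)

    hits_df = pd.DataFrame(rows, columns=HIT_COLUMNS)

    # enumerate accidental background matches over the assembled genome
    planted_index = IntervalIndex(
        (r[0], r[1], r[2]) for r in rows
    )
    extra = []
    for h in scan_motif(genome, motif):
        if not planted_index.overlaps(h.chrom, np.array([h.start]), np.array([h.end]))[0]:
            extra.append((h.chrom, h.start, h.end, h.strand, h.mismatch_count,
                          "background", -1, "background", h.matched_seq, False))
    if extra:
        hits_df = pd.concat(
            [hits_df, pd.DataFrame(extra, columns=HIT_COLUMNS)], ignore_index=True
        )
    hits_df = hits_df.sort_values(["chrom", "start"], ignore_index=True)
    truth = TruthTable(hits_df, blacklist, dict(config.chrom_lengths))
    return genome, truth


def _make_blacklist(
    config: SimulationConfig,
    element_intervals: Sequence[Interval],
    rng: np.random.Generator,
) -> List[Interval]:
    margin = 600  # keep blacklist away from planted loci and their flanks
    out: List[Interval] = []
    by_chrom: Dict[str, List[Tuple[int, int]]] = {c: [] for c in config.chrom_lengths}
    for chrom, s, e in element_intervals:
        by_chrom[chrom].append((s, e))
    for chrom in sorted(config.chrom_lengths):
        size = config.chrom_lengths[chrom]
        target = int(config.blacklist_fraction * size)
        gaps = []
        pos = 0
        for s, e in sorted(by_chrom[chrom]):
            if s - margin > pos + margin:
                gaps.append((pos + margin, s - margin))
            pos = max(pos, e)
        if pos + margin < size:
            gaps.append((pos + margin, size))
        order = rng.permutation(len(gaps))
        placed = 0
        for gi in order:
            if placed >= target:
                break
            g0, g1 = gaps[gi]
            room = g1 - g0
            if room < config.blacklist_chunk:
                continue
            chunk = min(config.blacklist_chunk, target - placed)
            start = g0 + int(rng.integers(0, room - chunk + 1))
            out.append((chrom, start, start + chunk))
            placed += chunk
    return sorted(out)


@dataclass
class ChipData:
    peaks: List[Peak]
    track: SignalTrack
    truth: TruthTable  # with the 'peaked' column filled in


def generate_chip(config: SimulationConfig, truth: TruthTable, seed: int = 0) -> ChipData:
    """Place peaks on a per-group fraction of ITRs and build the signal track.

    Per-base signal over a peaked ITR (+/- signal_halfwidth) is
    S0 * decay^mm plus one Gaussian noise draw per locus; elsewhere the track
    holds non-negative noise binned at ``bin_size``.  Background peaks are
    placed uniformly outside the blacklist.  With noise_sigma = 0 the track
    is exact: the mean over a peaked k-MM ITR equals S0 * decay^k.
    """
    rng = _child_rng(seed, 1)
    hits = truth.hits.copy()
    peaked = np.array([
        rng.random() < config.peak_fraction[int(mm)]
        for mm in hits["mismatch_count"]
    ])
    hits["peaked"] = peaked

    peaks: List[Peak] = []
    elevated: Dict[str, List[Tuple[int, int, float]]] = {
        c: [] for c in truth.chrom_sizes
    }
    for r in hits[hits["peaked"]].itertuples(index=False):
        mid = (int(r.start) + int(r.end)) // 2
        size = truth.chrom_sizes[r.chrom]
        ps = max(0, mid - config.peak_halfwidth)
        pe = min(size, mid + config.peak_halfwidth)
        amp = config.s0 * config.decay ** int(r.mismatch_count)
        peaks.append(Peak(r.chrom, ps, pe, mid, amp))
        value = amp if config.noise_sigma == 0 else max(
            0.0, amp + rng.normal(0.0, config.noise_sigma)
        )
        a = max(0, mid - config.signal_halfwidth)
        b = min(size, mid + config.signal_halfwidth)
        elevated[r.chrom].append((a, b, value))

    # background peaks, uniform over the blacklist complement
    if config.n_background_peaks > 0:
        randomizer = PeakRandomizer(truth.chrom_sizes, truth.blacklist)
        chroms = sorted(truth.chrom_sizes)
        weights = np.array([truth.chrom_sizes[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        length = 2 * config.peak_halfwidth
        counts = rng.multinomial(config.n_background_peaks, weights)
        for c, n in zip(chroms, counts):
            if n == 0:
                continue
            starts = randomizer.sample_starts(c, length, int(n), rng)
            peaks.extend(
                Peak(c, int(s), int(s) + length, int(s) + length // 2)
                for s in starts
            )
    peaks.sort(key=lambda p: (p.chrom, p.start))

    track_intervals: Dict[str, List[Tuple[int, int, float]]] = {}
    for chrom in sorted(truth.chrom_sizes):
        size = truth.chrom_sizes[chrom]
        n_bins = (size + config.bin_size - 1) // config.bin_size
        if config.noise_sigma == 0:
            bin_vals = np.zeros(n_bins)
        else:
            bin_vals = np.clip(rng.normal(0.0, config.noise_sigma, size=n_bins), 0.0, None)
        track_intervals[chrom] = _overlay(
            size, config.bin_size, bin_vals, elevated[chrom]
        )
    return ChipData(peaks, SignalTrack(track_intervals),
                    TruthTable(hits, truth.blacklist, dict(truth.chrom_sizes), truth.genes))


def _overlay(
    size: int,
    bin_size: int,
    bin_vals: np.ndarray,
    elevated: Sequence[Tuple[int, int, float]],
) -> List[Tuple[int, int, float]]:
    """Splice elevated intervals into the binned background track."""
    merged: List[Tuple[int, int, float]] = []
    for a, b, v in sorted(elevated):
        if merged and a <= merged[-1][1]:
            pa, pb, pv = merged[-1]
            merged[-1] = (pa, max(pb, b), max(pv, v))
        else:
            merged.append((a, b, v))

    out: List[Tuple[int, int, float]] = []

    def emit_background(x: int, y: int) -> None:
        while x < y:
            b_idx = x // bin_size
            b_end = min(y, (b_idx + 1) * bin_size)
            v = float(bin_vals[b_idx])
            if v != 0.0:
                out.append((x, b_end, v))
            x = b_end

    pos = 0
    for a, b, v in merged:
        emit_background(pos, a)
        out.append((a, b, float(v)))
        pos = b
    emit_background(pos, size)
    return out


@dataclass
class ExpressionData:
    genes: List[GeneModel]
    fpkm: Dict[str, float]
    gene_truth: pd.DataFrame


def generate_expression(
    config: SimulationConfig, truth: TruthTable, seed: int = 0
) -> ExpressionData:
    """Place genes over a fraction of planted solo ITRs plus null genes.

    FPKM ~ LogNormal(log_mu + shift(group), log_sigma); null genes (placed in
    ITR-free regions) carry no shift.  The truth records each gene's group.
    """
    rng = _child_rng(seed, 2)
    genes: List[GeneModel] = []
    records = []
    solo = truth.hits[(truth.hits["kind"] == "solo") & (truth.hits["source"] == "planted")]
    for r in solo.itertuples(index=False):
        if rng.random() >= config.gene_fraction:
            continue
        mm = int(r.mismatch_count)
        gstart = max(0, int(r.start) - 100)
        gend = gstart + config.gene_length
        gid = f"GENE_{r.chrom}_{gstart}"
        exons = ((gstart, gstart + 200), (gend - 300, gend))
        genes.append(GeneModel(gid, r.chrom, "+", gstart, gend, exons))
        shift = config.expression_shift[mm]
        fpkm = float(np.exp(rng.normal(config.log_mu + shift, config.log_sigma)))
        records.append((gid, r.chrom, gstart, gend, mm, shift, fpkm))

    # null genes in element-free regions (association windows included)
    buffer = 1100  # TSS window + 100 so no ITR can associate
    exclusion = IntervalIndex(
        (r.chrom, int(r.start) - buffer, int(r.end) + buffer)
        for r in truth.hits.itertuples(index=False)
    )
    chroms = sorted(truth.chrom_sizes)
    weights = np.array([truth.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    taken: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    placed = 0
    attempts = 0
    max_attempts = config.n_null_genes * 200
    while placed < config.n_null_genes and attempts < max_attempts:
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        size = truth.chrom_sizes[chrom]
        gstart = int(rng.integers(buffer, size - config.gene_length - buffer))
        gend = gstart + config.gene_length
        if exclusion.overlaps(chrom, np.array([gstart]), np.array([gend]))[0]:
            continue
        if any(gstart < e + buffer and gend + buffer > s for s, e in taken[chrom]):
            continue
        taken[chrom].append((gstart, gend))
        gid = f"NULL_{chrom}_{gstart}"
        exons = ((gstart, gstart + 200), (gend - 300, gend))
        genes.append(GeneModel(gid, chrom, "+", gstart, gend, exons))
        fpkm = float(np.exp(rng.normal(config.log_mu, config.log_sigma)))
        records.append((gid, chrom, gstart, gend, -1, 0.0, fpkm))
        placed += 1
    if placed < config.n_null_genes:
        raise ValueError("could not place the requested number of null genes")

    gene_truth = pd.DataFrame(
        records, columns=["gene_id", "chrom", "start", "end", "group", "shift", "fpkm"]
    )
    fpkm = dict(zip(gene_truth["gene_id"], gene_truth["fpkm"]))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return ExpressionData(genes, fpkm, gene_truth)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: Dict[str, str]
    truth: TruthTable
    peaks: List[Peak]
    track: SignalTrack
    genes: List[GeneModel]
    fpkm: Dict[str, float]


def simulate_dataset(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedDataset:
    """Run the full generator: genome, ChIP peaks + signal, genes + FPKM."""
    config = config or SimulationConfig()
    genome, truth = generate_genome(config, seed)
    chip = generate_chip(config, truth, seed)
    expr = generate_expression(config, chip.truth, seed)
    truth = chip.truth
    truth.genes = expr.gene_truth
    return SimulatedDataset(
        config, genome, truth, chip.peaks, chip.track, expr.genes, expr.fpkm
    )


def write_dataset(ds: SimulatedDataset, outdir: str) -> Dict[str, str]:
    """Write the dataset as plain-text files re-parseable by the package readers."""
    from . import io as iomod

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "chrom_sizes": os.path.join(outdir, "chrom.sizes"),
        "blacklist": os.path.join(outdir, "blacklist.bed"),
        "peaks": os.path.join(outdir, "peaks.narrowPeak"),
        "signal": os.path.join(outdir, "chip.bedgraph"),
        "genes": os.path.join(outdir, "genes.gtf"),
        "fpkm": os.path.join(outdir, "fpkm.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "gene_truth": os.path.join(outdir, "truth_genes.tsv"),
    }
    iomod.write_fasta(ds.genome, paths["genome"])
    iomod.write_chrom_sizes(ds.truth.chrom_sizes, paths["chrom_sizes"])
    iomod.write_bed(ds.truth.blacklist, paths["blacklist"])
    iomod.write_narrowpeak(ds.peaks, paths["peaks"])
    iomod.write_bedgraph(ds.track, paths["signal"])
    iomod.write_gtf(ds.genes, paths["genes"])
    iomod.write_fpkm(ds.fpkm, paths["fpkm"])
    ds.truth.hits.to_csv(paths["truth"], sep="\t", index=False)
    if ds.truth.genes is not None:
        ds.truth.genes.to_csv(paths["gene_truth"], sep="\t", index=False)
    return paths
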