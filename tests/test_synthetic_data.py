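"""Generator determinism, planted truth, signal exactness, and file round-trips."""

import numpy as np
import pytest

from itrscan import (
    SimulationConfig,
    group_by_mismatch,
    pair_itrs,
    scan_motif,
    simulate_dataset,
    write_dataset,
)
from itrscan import io as iomod
from itrscan.synthetic_data import generate_chip, generate_expression, generate_genome


SMALL = SimulationConfig(
    chrom_lengths={"chr1": 300_000, "chr2": 200_000},
    solo_counts=(5, 8, 6, 6),
    mite_pairs=20,
    n_null_genes=40,
)


def test_generate_genome_is_deterministic():
    g1, t1 = generate_genome(SMALL, seed=5)
    g2, t2 = generate_genome(SMALL, seed=5)
    assert g1 == g2
    assert t1.hits.equals(t2.hits)
    assert t1.blacklist == t2.blacklist
    g3, _ = generate_genome(SMALL, seed=6)
    assert g3 != g1


def test_zero_planted_objects_only_background():
    config = SimulationConfig(
        chrom_lengths={"chr1": 100_000}, solo_counts=(0, 0, 0, 0),
        mite_pairs=0, n_null_genes=5,
    )
    genome, truth = generate_genome(config, seed=3)
    hits = scan_motif(genome, config.motif_spec)
    background = truth.hits[truth.hits["source"] == "background"]
    assert len(hits) == len(background)
    assert (truth.hits["source"] == "planted").sum() == 0


def test_planted_counts_recovered_above_background():
    genome, truth = generate_genome(SMALL, seed=2)
    hits = scan_motif(genome, SMALL.motif_spec)
    counts = group_by_mismatch(hits)
    background = truth.hits[truth.hits["source"] == "background"]
    for k in range(4):
        planted = int((truth.hits["mismatch_count"][truth.hits["source"] == "planted"] == k).sum())
        bg = int((background["mismatch_count"] == k).sum())
        assert counts[f"{k}MM"] == planted + bg


def test_scan_reproduces_truth_coordinates_exactly():
    genome, truth = generate_genome(SMALL, seed=4)
    hits = scan_motif(genome, SMALL.motif_spec)
    got = [(h.chrom, h.start, h.strand, h.mismatch_count) for h in hits]
    want = sorted(
        (r.chrom, int(r.start), r.strand, int(r.mismatch_count))
        for r in truth.hits.itertuples(index=False)
    )
    assert got == sorted(want)


def test_infeasible_packing_errors():
    config = SimulationConfig(chrom_lengths={"chr1": 10_000},
                              solo_counts=(50, 0, 0, 0), mite_pairs=0)
    with pytest.raises(ValueError, match="infeasible"):
        generate_genome(config, seed=0)


def test_noise_free_signal_is_exact():
    """With sigma=0, f=0.5, S0=100 the mean over a peaked 2MM ITR is 25 exactly."""
    config = SimulationConfig(
        chrom_lengths={"chr1": 300_000}, solo_counts=(4, 4, 4, 4), mite_pairs=0,
        peak_fraction=(1.0, 1.0, 1.0, 1.0), s0=100.0, decay=0.5, noise_sigma=0.0,
        n_background_peaks=0, n_null_genes=2,
    )
    genome, truth = generate_genome(config, seed=9)
    chip = generate_chip(config, truth, seed=9)
    for r in chip.truth.hits.itertuples(index=False):
        if r.source != "planted":
            continue
        expected = 100.0 * 0.5 ** int(r.mismatch_count)
        got = chip.track.mean_over(r.chrom, int(r.start), int(r.end))
        assert got == pytest.approx(expected, abs=1e-12)


def test_peak_fraction_zero_places_only_background_peaks():
    config = SimulationConfig(
        chrom_lengths={"chr1": 300_000}, solo_counts=(5, 5, 5, 5), mite_pairs=5,
        peak_fraction=(0.0, 0.0, 0.0, 0.0), n_background_peaks=7, n_null_genes=2,
    )
    genome, truth = generate_genome(config, seed=1)
    chip = generate_chip(config, truth, seed=1)
    assert len(chip.peaks) == 7
    assert not chip.truth.hits["peaked"].any()


def test_expression_truth_consistency():
    genome, truth = generate_genome(SMALL, seed=6)
    expr = generate_expression(SMALL, truth, seed=6)
    assert len(expr.genes) == len(expr.gene_truth)
    solos = truth.hits[(truth.hits["kind"] == "solo")]
    planted_genes = expr.gene_truth[expr.gene_truth["group"] >= 0]
    assert len(planted_genes) <= len(solos)
    assert (expr.gene_truth[expr.gene_truth["group"] < 0]["shift"] == 0).all()
    assert set(expr.fpkm) == set(expr.gene_truth["gene_id"])
    assert all(v >= 0 for v in expr.fpkm.values())


def test_dataset_files_round_trip(tmp_path, default_dataset):
    """Every emitted file re-parses through the package readers without loss."""
    ds = default_dataset
    paths = write_dataset(ds, str(tmp_path))

    genome = iomod.read_fasta(paths["genome"])
    assert genome == ds.genome

    sizes = iomod.read_chrom_sizes(paths["chrom_sizes"])
    assert sizes == ds.truth.chrom_sizes

    assert iomod.read_bed(paths["blacklist"]) == ds.truth.blacklist

    peaks = iomod.read_narrowpeak(paths["peaks"])
    assert [(p.chrom, p.start, p.end, p.summit) for p in peaks] == [
        (p.chrom, p.start, p.end, p.summit) for p in ds.peaks
    ]

    track = iomod.read_bedgraph(paths["signal"])
    rng = np.random.default_rng(0)
    for chrom, size in sizes.items():
        starts = rng.integers(0, size - 100, size=20)
        for s in starts:
            assert track.mean_over(chrom, int(s), int(s) + 100) == pytest.approx(
                ds.track.mean_over(chrom, int(s), int(s) + 100), rel=1e-4, abs=1e-4
            )

    genes = iomod.read_gtf(paths["genes"])
    assert [(g.gene_id, g.chrom, g.start, g.end, g.exons) for g in genes] == [
        (g.gene_id, g.chrom, g.start, g.end, g.exons) for g in ds.genes
    ]

    fpkm = iomod.read_fpkm(paths["fpkm"])
    assert set(fpkm) == set(ds.fpkm)
    for gid in fpkm:
        assert fpkm[gid] == pytest.approx(ds.fpkm[gid], rel=1e-4)


def test_hits_bed_round_trip(tmp_path, default_dataset):
    hits = scan_motif(default_dataset.genome)
    path = str(tmp_path / "itrs.bed")
    iomod.write_hits_bed(hits, path)
    assert iomod.read_hits_bed(path) == hits


def test_full_loop_recovers_planted_structure(default_dataset):
    """Simulate -> scan -> classify recovers the planted element structure."""
    ds = default_dataset
    hits = scan_motif(ds.genome, ds.config.motif_spec)
    elements = pair_itrs(hits)
    expected = ds.truth.expected_elements(ds.config.motif_spec)
    assert elements == expected
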