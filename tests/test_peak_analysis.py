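"""Peak/ITR overlap, summit annotation, randomized null and enrichment test."""

import numpy as np
import pytest
from scipy import stats

from itrscan.peak_analysis import (
    GeneModel,
    Peak,
    annotate_summits,
    chromosome_correlation,
    enrichment_test,
    extend_intervals,
    overlap_peaks_itrs,
    randomize_peaks,
)

from conftest import make_hit

SIZES = {"c": 10_000}


def test_extend_intervals():
    assert extend_intervals([("c", 1000, 1100)], 500, SIZES) == [("c", 500, 1600)]
    assert extend_intervals([("c", 100, 200)], 500, SIZES) == [("c", 0, 700)]
    assert extend_intervals([("c", 100, 200)], 0, SIZES) == [("c", 100, 200)]
    with pytest.raises(KeyError):
        extend_intervals([("nope", 0, 10)], 500, SIZES)
    with pytest.raises(ValueError):
        extend_intervals([("c", 0, 10)], -1, SIZES)


def test_overlap_summit_on_itr():
    hit = make_hit("c", 5000)
    peak = Peak("c", 4900, 5100, 5009)
    venn = overlap_peaks_itrs([peak], [hit], flank=500, chrom_sizes=SIZES)
    assert (venn.n_peaks_overlapping, venn.n_itrs_covered) == (1, 1)


def test_overlap_boundary_one_bp_short():
    # extended peak spans [0, 1500); an ITR starting at 1500 does not overlap
    peak = Peak("c", 500, 1000, 700)
    assert overlap_peaks_itrs([peak], [make_hit("c", 1500)], 500, SIZES).n_itrs_covered == 0
    assert overlap_peaks_itrs([peak], [make_hit("c", 1499)], 500, SIZES).n_itrs_covered == 1


def test_overlap_planted_counts():
    """Peaks on 80 of 100 ITRs plus 5 off-target peaks give (80/85, 80/100)."""
    sizes = {"c": 2_000_000}
    hits = [make_hit("c", 10_000 * i + 5000) for i in range(100)]
    peaks = [Peak("c", h.start - 50, h.end + 50, h.midpoint) for h in hits[:80]]
    peaks += [Peak("c", 1_900_000 + 3000 * i, 1_900_000 + 3000 * i + 200,
                   1_900_000 + 3000 * i + 100) for i in range(5)]
    venn = overlap_peaks_itrs(peaks, hits, flank=500, chrom_sizes=sizes)
    assert (venn.n_peaks, venn.n_peaks_overlapping) == (85, 80)
    assert (venn.n_itrs, venn.n_itrs_covered) == (100, 80)


GENE = GeneModel("g1", "c", "+", 5000, 8000, ((5000, 5400), (7000, 8000)))


@pytest.mark.parametrize(
    "summit,category",
    [
        (5200, "exon"),        # inside exon 1, past the TSS window [4000, 5100]
        (6000, "intron"),
        (7950, "TTS"),         # TTS window [7900, 8999]
        (2000, "intergenic"),
        (4800, "TSS"),         # 200 bp upstream of the + strand TSS
    ],
)
def test_annotate_summit_categories(summit, category):
    peak = Peak("c", summit - 10, summit + 10, summit)
    assert annotate_summits([peak], [GENE]) == [category]


def test_annotate_priority_and_order_independence():
    # 5050 is both in the TSS window [4000, 5100] and in exon 1: TSS wins
    peak = Peak("c", 5040, 5060, 5050)
    other = GeneModel("g2", "c", "-", 1000, 3000, ((1000, 3000),))
    assert annotate_summits([peak], [GENE, other]) == ["TSS"]
    assert annotate_summits([peak], [other, GENE]) == ["TSS"]


def test_annotate_is_total(default_dataset):
    ds = default_dataset
    cats = annotate_summits(ds.peaks, ds.genes)
    assert len(cats) == len(ds.peaks)
    assert set(cats) <= {"TSS", "TTS", "exon", "intron", "intergenic"}


def test_randomize_forced_placement():
    # blacklist everything except one exactly-peak-sized gap
    blacklist = [("c", 0, 4000), ("c", 4100, 10_000)]
    peak = Peak("c", 0, 100, 50)
    sets = randomize_peaks([peak], SIZES, blacklist, n_sets=5, seed=1)
    for s in sets:
        assert len(s) == 1 and (s[0].start, s[0].end) == (4000, 4100)


def test_randomize_peak_too_long_errors():
    blacklist = [("c", 50, 10_000)]
    with pytest.raises(ValueError, match="100-bp"):
        randomize_peaks([Peak("c", 0, 100, 50)], SIZES, blacklist, n_sets=1, seed=0)


def test_randomize_uniform_over_allowed_starts():
    """10,000 placements of one 100-bp peak are uniform (chi-square GOF p > 0.01)."""
    peak = Peak("c", 0, 100, 50)
    sets = randomize_peaks([peak] * 10_000, SIZES, [], n_sets=1, seed=3)
    starts = np.array([p.start for p in sets[0]])
    assert starts.min() >= 0 and starts.max() <= 10_000 - 100
    counts, _ = np.histogram(starts, bins=20, range=(0, 9901))
    p = stats.chisquare(counts).pvalue
    assert p > 0.01


def test_randomize_preserves_lengths_avoids_blacklist_and_is_deterministic():
    rng = np.random.default_rng(4)
    peaks = [Peak("c", int(s), int(s) + int(l), int(s) + int(l) // 2)
             for s, l in zip(rng.integers(0, 9000, 30), rng.integers(50, 400, 30))]
    blacklist = [("c", 2000, 3000), ("c", 6000, 6500)]
    sets = randomize_peaks(peaks, SIZES, blacklist, n_sets=10, seed=9)
    for s in sets:
        assert sorted(p.length for p in s) == sorted(p.length for p in peaks)
        for p in s:
            assert not (p.start < 3000 and p.end > 2000)
            assert not (p.start < 6500 and p.end > 6000)
    again = randomize_peaks(peaks, SIZES, blacklist, n_sets=10, seed=9)
    assert again == sets


def test_enrichment_identical_proportions_is_null():
    res = enrichment_test(30, 100, 30, 100)
    assert res.z == 0 and res.p == 1 and res.ratio == 1


def test_enrichment_example_and_chi2_identity():
    res = enrichment_test(30, 100, 10, 100)
    assert res.z == pytest.approx(3.5355, abs=5e-4)
    assert res.p == pytest.approx(4.06e-4, rel=0.01)
    assert res.ratio == pytest.approx(3.0)
    chi2 = stats.chi2_contingency([[30, 70], [10, 90]], correction=False)[0]
    assert res.z**2 == pytest.approx(chi2, rel=1e-9)


def test_enrichment_swap_negates_z():
    a = enrichment_test(30, 100, 10, 100)
    b = enrichment_test(10, 100, 30, 100)
    assert a.z == pytest.approx(-b.z)
    assert a.p == pytest.approx(b.p)


def test_enrichment_input_validation():
    with pytest.raises(ValueError):
        enrichment_test(1, 0, 1, 10)
    with pytest.raises(ValueError):
        enrichment_test(11, 10, 1, 10)


def test_correlation_examples():
    lengths = {"c1": 2000, "c2": 1000, "c3": 4000, "c4": 3000}
    hits = [make_hit(c, 100 + 30 * i) for j, c in enumerate(lengths) for i in range(j + 1)]
    peaks = [Peak(c, 0, 10, 5) for j, c in enumerate(lengths) for _ in range(j + 1)]
    out = chromosome_correlation(hits, peaks, lengths)
    # counts (1,2,3,4) vs lengths (2,1,4,3): Spearman rho = 0.6
    assert out["itrs_vs_length"][0] == pytest.approx(0.6)
    assert out["peaks_vs_itrs"][0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        chromosome_correlation(hits, peaks, {"c1": 1000, "c2": 2000})
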