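"""Signal means, fidelity stratification, rank-sum test and substitution effects."""

import numpy as np
import pytest
from scipy import stats

from itrscan import SimulationConfig, scan_motif
from itrscan.affinity_analysis import (
    SignalTrack,
    rank_sum_test,
    scores_by_group,
    substitution_effects,
)
from itrscan.element_annotation import pair_itrs
from itrscan.genome_scan import CORE_MOTIF
from itrscan.synthetic_data import generate_chip, generate_genome

from conftest import make_hit


def test_mean_constant_track():
    track = SignalTrack({"c": [(0, 100, 5.0)]})
    assert track.mean_over("c", 10, 60) == 5.0


def test_mean_across_segments():
    track = SignalTrack({"c": [(0, 10, 2.0), (10, 20, 4.0)]})
    assert track.mean_over("c", 5, 15) == pytest.approx(3.0)


def test_mean_counts_uncovered_bases_as_zero():
    track = SignalTrack({"c": [(10, 20, 10.0)]})
    assert track.mean_over("c", 0, 40) == pytest.approx(2.5)


def test_mean_matches_per_base_oracle():
    rng = np.random.default_rng(8)
    edges = np.sort(rng.choice(np.arange(1, 1000), size=40, replace=False))
    intervals, pos = [], 0
    per_base = np.zeros(1000)
    for e in edges:
        if rng.random() < 0.6:
            v = float(rng.normal(5, 2))
            intervals.append((pos, int(e), v))
            per_base[pos:e] = v
        pos = int(e)
    track = SignalTrack({"c": intervals})
    for a, b in [(0, 1000), (3, 17), (500, 501), (123, 999)]:
        assert track.mean_over("c", a, b) == pytest.approx(per_base[a:b].mean(), abs=1e-9)


def test_mean_input_validation():
    track = SignalTrack({"c": [(0, 10, 1.0)]})
    with pytest.raises(ValueError):
        track.mean_over("c", 5, 5)
    with pytest.raises(KeyError):
        track.mean_over("nope", 0, 5)
    with pytest.raises(ValueError):
        SignalTrack({"c": [(0, 10, 1.0), (5, 15, 2.0)]})


def test_scores_by_group_zero_track():
    track = SignalTrack({"c": [(0, 100_000, 0.0)]})
    hits = [make_hit("c", 1000 * (i + 1)) for i in range(8)]
    groups = scores_by_group(track, hits, {"c": 100_000}, background_n=50, seed=1)
    assert all(g.median == 0 for g in groups.values() if g.n)


def test_scores_by_group_monotone_decreasing():
    """Planted amplitude S0 * 2^-mm (S0=100, sigma=5) gives decreasing medians."""
    config = SimulationConfig(
        solo_counts=(100, 100, 100, 100), mite_pairs=0,
        peak_fraction=(1.0, 1.0, 1.0, 1.0), s0=100.0, decay=0.5, noise_sigma=5.0,
    )
    genome, truth = generate_genome(config, seed=13)
    chip = generate_chip(config, truth, seed=13)
    hits = scan_motif(genome, config.motif_spec)
    groups = scores_by_group(chip.track, hits, truth.chrom_sizes,
                             background_n=500, seed=13)
    medians = [groups[f"{k}MM"].median for k in range(4)]
    assert medians == sorted(medians, reverse=True)
    assert groups["Total"].median < medians[3]
    for k in range(3):
        p = rank_sum_test(groups[f"{k}MM"].scores, groups[f"{k + 1}MM"].scores).pvalue
        assert p < 0.01


def test_rank_sum_exact_example():
    res = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert res.method == "exact"
    assert res.pvalue == pytest.approx(0.1)


def test_rank_sum_identical_samples():
    res = rank_sum_test([1.0, 2.0, 3.0] * 6, [1.0, 2.0, 3.0] * 6)
    assert res.pvalue == 1.0 and res.z == 0.0


def test_rank_sum_ties_average_ranks():
    res = rank_sum_test([1, 2], [1, 2])
    assert res.pvalue == 1.0


def test_rank_sum_empty_sample_errors():
    with pytest.raises(ValueError):
        rank_sum_test([], [1.0])


@pytest.mark.parametrize("seed,n1,n2", [(0, 15, 20), (1, 30, 30), (2, 8, 40)])
def test_rank_sum_matches_scipy_asymptotic(seed, n1, n2):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n1)
    y = rng.normal(0.5, 1, n2)
    ours = rank_sum_test(x, y, method="normal")
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_rank_sum_exact_close_to_normal_at_boundary(seed):
    """At n1+n2 = 12 the exact and approximate branches agree within 0.05."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, 6)
    y = rng.normal(0.8, 1, 6)
    exact = rank_sum_test(x, y, method="exact").pvalue
    approx = rank_sum_test(x, y, method="normal").pvalue
    assert abs(exact - approx) <= 0.05


def _mutant(pos: int, base: str) -> str:
    s = list(CORE_MOTIF)
    s[pos - 1] = base
    return "".join(s)


def _solo_elements(hits):
    return pair_itrs(hits, max_gap=500)


def test_substitution_effects_single_substitution_is_total():
    hits = [make_hit("c", 10_000 * i) for i in range(5)]
    hits += [make_hit("c", 10_000 * (i + 5)) for i in range(4)]
    one_mm = [make_hit("c", 10_000 * (i + 9), seq=_mutant(17, "T")) for i in range(6)]
    track = SignalTrack({"c": [(0, 10_000 * 20, 1.0)]})
    effects = substitution_effects(track, _solo_elements(hits + one_mm))
    assert len(effects) == 1
    e = effects[0]
    assert (e.position, e.from_base, e.to_base) == (17, "C", "T")
    assert e.frequency == pytest.approx(100.0)


def test_substitution_effects_requires_reference_group():
    one_mm = [make_hit("c", 10_000 * i, seq=_mutant(5, "A")) for i in range(3)]
    track = SignalTrack({"c": [(0, 100_000, 1.0)]})
    with pytest.raises(ValueError):
        substitution_effects(track, _solo_elements(one_mm))


def test_substitution_effects_planted_fold_change_recovered():
    """A planted 6-fold signal drop at position 17 dominates the fold changes."""
    rng = np.random.default_rng(21)
    intervals, hits = [], []
    pos = 1000
    ref_amp, low_amp = 60.0, 10.0

    def add(seq, amp):
        nonlocal pos
        hits.append(make_hit("c", pos, seq=seq))
        intervals.append((pos, pos + 19, max(0.1, amp + rng.normal(0, 1))))
        pos += 2000

    for _ in range(50):
        add(CORE_MOTIF, ref_amp)
    for _ in range(50):
        add(_mutant(17, "T"), low_amp)     # planted 6x reduction
    for _ in range(50):
        add(_mutant(8, "C"), ref_amp)      # neutral substitution
    track = SignalTrack({"c": intervals})
    effects = substitution_effects(track, _solo_elements(hits))
    by_key = {(e.position, e.to_base): e for e in effects}
    planted = by_key[(17, "T")]
    neutral = by_key[(8, "C")]
    assert planted.fold_change == max(e.fold_change for e in effects)
    assert planted.fold_change == pytest.approx(6.0, rel=0.2)
    assert planted.pvalue < 1e-6
    assert neutral.fold_change == pytest.approx(1.0, rel=0.2)


def test_substitution_effects_rare_groups_filtered():
    hits = [make_hit("c", 10_000 * i) for i in range(3)]
    common = [make_hit("c", 10_000 * (i + 3), seq=_mutant(2, "A")) for i in range(59)]
    rare = [make_hit("c", 10_000 * 62, seq=_mutant(9, "T"))]  # 1/60 < 2%
    track = SignalTrack({"c": [(0, 10_000 * 70, 1.0)]})
    effects = substitution_effects(track, _solo_elements(hits + common + rare))
    assert [(e.position, e.to_base) for e in effects] == [(2, "A")]
    assert effects[0].frequency == pytest.approx(100 * 59 / 60)
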