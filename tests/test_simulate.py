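"""Synthetic Repli-seq generator: tiling, truth construction, count law."""

import numpy as np
import pytest
from scipy import stats

from replikit import (
    BinGrid,
    Condition,
    DomainClass,
    GenomeSpec,
    SwitchDirection,
    SyntheticTruth,
    plan_genome_and_domains,
    simulate_counts,
    truth_from_plan,
)
from replikit.tracks import cpm_normalize

GENOME = GenomeSpec([("chr1", 10_000_000)])


def test_plan_tiles_exactly_without_gaps():
    plan = plan_genome_and_domains(GENOME, 1_000_000, 0.0, seed=3)
    pos = 0
    for chrom, start, end, _ in plan.domains:
        assert chrom == "chr1" and start == pos and end > start
        pos = end
    assert pos == 10_000_000
    assert plan.differential == ()


def test_plan_differential_fraction_within_one_domain():
    g = GenomeSpec([("chr1", 25_000_000), ("chr2", 25_000_000)])
    plan = plan_genome_and_domains(g, 1_000_000, 0.2, seed=9)
    total = sum(e - s for _, s, e, _ in plan.differential)
    max_dom = max(e - s for _, s, e, _ in plan.domains)
    assert abs(total - 0.2 * 50_000_000) <= max_dom
    # differential regions are whole domains
    domain_keys = {(c, s, e) for c, s, e, _ in plan.domains}
    for c, s, e, _ in plan.differential:
        assert (c, s, e) in domain_keys


def test_plan_no_noop_switch_directions():
    plan = plan_genome_and_domains(GENOME, 1_000_000, 0.3, seed=5)
    klass_of = {(c, s): k for c, s, e, k in plan.domains}
    for c, s, e, direction in plan.differential:
        k = klass_of[(c, s)]
        if k is DomainClass.EARLY:
            assert direction is SwitchDirection.DELAYED
        if k is DomainClass.LATE:
            assert direction is SwitchDirection.ADVANCED


def test_plan_rejects_bad_params():
    with pytest.raises(ValueError):
        plan_genome_and_domains(GENOME, 50_000, 0.0, seed=0)  # < 5 bins
    with pytest.raises(ValueError):
        plan_genome_and_domains(GENOME, 1_000_000, 1.0, seed=0)


def test_plan_deterministic_under_seed():
    a = plan_genome_and_domains(GENOME, 1_000_000, 0.2, seed=4)
    b = plan_genome_and_domains(GENOME, 1_000_000, 0.2, seed=4)
    assert a == b


def test_truth_piecewise_constant_idealized():
    """class_jitter=0, edge_softness=0 reproduces the 3-level truth exactly."""
    plan = plan_genome_and_domains(GENOME, 1_000_000, 0.0, seed=3)
    truth = truth_from_plan(plan, p_early=1.0, p_late=0.0, edge_softness=0,
                            class_jitter=0.0)
    wt = truth.p_rep[Condition.WT]
    assert set(np.unique(wt)) == {0.0, 0.5, 1.0}
    for chrom, start, end, klass in plan.domains:
        sl = slice(start // 20_000, end // 20_000)
        level = {"EARLY": 1.0, "MID": 0.5, "LATE": 0.0}[klass.value]
        assert (wt[sl] == level).all()


def test_truth_rescue_equals_wt_and_ko_differs_only_in_planted_regions():
    plan = plan_genome_and_domains(GENOME, 1_000_000, 0.25, seed=8)
    truth = truth_from_plan(plan, edge_softness=0, seed=2)
    wt, ko = truth.p_rep[Condition.WT], truth.p_rep[Condition.KO]
    np.testing.assert_array_equal(wt, truth.p_rep[Condition.RESCUE])
    diff_bins = np.zeros(truth.grid.n_bins, dtype=bool)
    for c, s, e, _ in plan.differential:
        off = truth.grid.chrom_offset[c]
        diff_bins[off + s // 20_000 : off + e // 20_000] = True
    assert (wt[~diff_bins] == ko[~diff_bins]).all()
    assert (wt[diff_bins] != ko[diff_bins]).any()


def test_truth_delayed_early_domain_hits_p_late():
    plan = plan_genome_and_domains(GENOME, 1_000_000, 0.3, seed=5)
    klass_of = {(c, s): k for c, s, e, k in plan.domains}
    truth = truth_from_plan(plan, p_early=0.9, p_late=0.1, edge_softness=0,
                            class_jitter=0.0)
    ko = truth.p_rep[Condition.KO]
    checked = False
    for c, s, e, direction in plan.differential:
        if klass_of[(c, s)] is DomainClass.EARLY:
            assert direction is SwitchDirection.DELAYED
            sl = slice(s // 20_000, e // 20_000)
            assert (ko[sl] == 0.1).all()
            checked = True
    assert checked


def test_truth_rejects_inverted_levels():
    plan = plan_genome_and_domains(GENOME, 1_000_000, 0.0, seed=3)
    with pytest.raises(ValueError):
        truth_from_plan(plan, p_early=0.2, p_late=0.5)


def _flat_truth(p: float, n_bins=200) -> SyntheticTruth:
    g = GenomeSpec([("chr1", n_bins * 20_000)])
    plan = plan_genome_and_domains(g, 1_000_000, 0.0, seed=0)
    grid = BinGrid(g, 20_000)
    arr = np.full(grid.n_bins, p)
    return SyntheticTruth(
        grid=grid,
        p_rep={c: arr.copy() for c in Condition},
        plan=plan,
    )


@pytest.mark.parametrize("p", [0.0, 1.0])
def test_uniform_p_rep_gives_unit_cpm_ratio(p):
    """Uniform copy number cancels after CPM scaling: expected S/G1 CPM
    ratio is 1 in every bin."""
    truth = _flat_truth(p)
    ratios = []
    for seed in range(40):
        s, g1 = simulate_counts(truth, Condition.WT, 1, depth_per_bin=500, seed=seed)
        ratios.append(cpm_normalize(s).values / np.maximum(cpm_normalize(g1).values, 1e-9))
    assert abs(np.mean(ratios) - 1.0) < 0.01


def test_expected_count_ratio_tracks_copy_number():
    """Mean raw S/G1 ratio over 1000 draws is proportional to 1 + p_rep
    within 2%."""
    g = GenomeSpec([("chr1", 100 * 20_000)])
    plan = plan_genome_and_domains(g, 1_000_000, 0.0, seed=0)
    grid = BinGrid(g, 20_000)
    rng = np.random.default_rng(0)
    p = rng.uniform(0, 1, grid.n_bins)
    truth = SyntheticTruth(grid=grid, p_rep={c: p.copy() for c in Condition}, plan=plan)
    s_sum = np.zeros(grid.n_bins)
    g_sum = np.zeros(grid.n_bins)
    for seed in range(1000):
        s, g1 = simulate_counts(truth, Condition.WT, 1, depth_per_bin=100, seed=seed)
        s_sum += s.counts
        g_sum += g1.counts
    ratio = s_sum / g_sum
    expected = 1.0 + p
    scaled = ratio / ratio.mean() * expected.mean()
    assert np.max(np.abs(scaled - expected) / expected) < 0.02


def test_wt_and_rescue_counts_are_exchangeable():
    """WT and RESCUE are draws from the same law: two-sample KS on CPM
    values does not reject at alpha = 0.01 (n = 5000 bins)."""
    g = GenomeSpec([("chr1", 5000 * 20_000)])
    plan = plan_genome_and_domains(g, 1_000_000, 0.0, seed=1)
    truth = truth_from_plan(plan, seed=1)
    s_wt, _ = simulate_counts(truth, Condition.WT, 1, seed=11)
    s_res, _ = simulate_counts(truth, Condition.RESCUE, 1, seed=22)
    ks = stats.ks_2samp(cpm_normalize(s_wt).values, cpm_normalize(s_res).values)
    assert ks.pvalue > 0.01


def test_counts_deterministic_and_negative_binomial_overdisperses():
    truth = _flat_truth(0.5)
    a = simulate_counts(truth, Condition.KO, 1, seed=9)
    b = simulate_counts(truth, Condition.KO, 1, seed=9)
    np.testing.assert_array_equal(a[0].counts, b[0].counts)
    np.testing.assert_array_equal(a[1].counts, b[1].counts)
    nb, _ = simulate_counts(truth, Condition.KO, 1, noise=0.5, seed=9,
                            depth_per_bin=200)
    po, _ = simulate_counts(truth, Condition.KO, 1, noise=0.0, seed=9,
                            depth_per_bin=200)
    assert nb.counts.var() > 2 * po.counts.var()
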