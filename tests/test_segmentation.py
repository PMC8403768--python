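"""HMM domain segmentation: merging, fitting, decoding, statistics."""

import numpy as np
import pytest

from replikit import (
    BinGrid,
    GenomeSpec,
    SignalTrack,
    Stage,
    decode_domains,
    domain_stats,
    fit_segmentation,
    merge_replicates,
)
from replikit.segmentation import RDClass, _absorb_flickers


@pytest.fixture()
def grid():
    return BinGrid(GenomeSpec([("chr1", 12_000_000)]), 20_000)


def three_level_track(grid, levels=(1.5, 0.0, -1.5), block=100, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    v = np.empty(grid.n_bins)
    for i in range(0, grid.n_bins, 3 * block):
        for j, lvl in enumerate(levels):
            v[i + j * block : i + (j + 1) * block] = lvl
    v = v[: grid.n_bins]
    if noise:
        v = v + rng.normal(0, noise, grid.n_bins)
    v = (v - v.mean()) / v.std(ddof=1)
    return SignalTrack(grid, v, Stage.ZSCORE)


# --------------------------------------------------------------- merging

def test_merge_replicates_identity_and_nan_rule(grid):
    rng = np.random.default_rng(0)
    v = rng.normal(size=grid.n_bins)
    t = SignalTrack(grid, v, Stage.ZSCORE)
    np.testing.assert_allclose(merge_replicates([t, t]).values, v)
    v2 = v.copy()
    v2[0] = np.nan
    m = merge_replicates([t, SignalTrack(grid, v2, Stage.ZSCORE)])
    assert m.values[0] == v[0]  # {x, NaN} -> x
    v3 = v.copy()
    v3[1] = np.nan
    v4 = v.copy()
    v4[1] = np.nan
    m2 = merge_replicates([SignalTrack(grid, v3, Stage.ZSCORE),
                           SignalTrack(grid, v4, Stage.ZSCORE)])
    assert np.isnan(m2.values[1])  # NaN only where all replicates NaN


def test_merge_matches_bruteforce_mean(grid):
    rng = np.random.default_rng(1)
    tracks = [SignalTrack(grid, rng.normal(size=grid.n_bins), Stage.ZSCORE)
              for _ in range(4)]
    m = merge_replicates(tracks)
    oracle = np.mean([t.values for t in tracks], axis=0)
    np.testing.assert_allclose(m.values, oracle)
    with pytest.raises(ValueError):
        merge_replicates([])


# --------------------------------------------------------------- fitting

def test_fit_recovers_noiseless_three_levels(grid):
    t = three_level_track(grid)
    model = fit_segmentation(t, seed=0)
    levels = np.sort(np.unique(t.values))[::-1]
    np.testing.assert_allclose(model.means, levels, atol=1e-3)
    assert model.means[0] > model.means[1] > model.means[2]
    np.testing.assert_allclose(model.transmat.sum(axis=1), 1.0, atol=1e-9)


def test_fit_loglik_nondecreasing_in_iterations(grid):
    t = three_level_track(grid, noise=0.5, seed=3)
    lls = [
        fit_segmentation(t, n_init=1, max_iter=k, tol=0).log_likelihood
        for k in (1, 2, 5, 10, 20)
    ]
    assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))


def test_fit_requires_enough_bins():
    grid = BinGrid(GenomeSpec([("chr1", 200_000)]), 20_000)
    t = SignalTrack(grid, np.random.default_rng(0).normal(size=grid.n_bins),
                    Stage.ZSCORE)
    with pytest.raises(ValueError):
        fit_segmentation(t)


# -------------------------------------------------------------- decoding

def test_decode_noiseless_blocks_exactly(grid):
    g = BinGrid(GenomeSpec([("chr1", 6_000_000)]), 20_000)  # 300 bins
    v = np.r_[np.full(100, 1.5), np.full(100, 0.0), np.full(100, -1.5)]
    v = (v - v.mean()) / v.std(ddof=1)
    t = SignalTrack(g, v, Stage.ZSCORE)
    model = fit_segmentation(t, seed=0)
    rds = decode_domains(model, t)
    assert [d.klass for d in rds.domains] == [RDClass.ERD, RDClass.MRD, RDClass.LRD]
    assert [(d.start, d.end) for d in rds.domains] == [
        (0, 2_000_000), (2_000_000, 4_000_000), (4_000_000, 6_000_000)
    ]


def test_negated_track_swaps_erd_and_lrd(grid):
    t = three_level_track(grid, noise=0.4, seed=5)
    neg = SignalTrack(grid, -t.values, Stage.ZSCORE)
    rds = decode_domains(fit_segmentation(t, seed=0), t)
    rds_neg = decode_domains(fit_segmentation(neg, seed=0), neg)
    swap = {RDClass.ERD: RDClass.LRD, RDClass.MRD: RDClass.MRD,
            RDClass.LRD: RDClass.ERD}
    assert [(d.chrom, d.start, d.end, swap[d.klass]) for d in rds.domains] == [
        (d.chrom, d.start, d.end, d.klass) for d in rds_neg.domains
    ]


def test_decode_partitions_unmasked_bins(grid):
    rng = np.random.default_rng(6)
    t = three_level_track(grid, noise=0.4, seed=6)
    v = t.values.copy()
    v[rng.choice(grid.n_bins, 30, replace=False)] = np.nan
    # a long masked gap must split domains
    v[250:260] = np.nan
    t = SignalTrack(grid, v, Stage.ZSCORE)
    model = fit_segmentation(t, seed=0)
    rds = decode_domains(model, t, gap_tolerance=2)
    covered = np.zeros(grid.n_bins, dtype=int)
    for d in rds.domains:
        covered[d.start // 20_000 : d.end // 20_000] += 1
    ok = np.isfinite(v)
    assert (covered[ok] == 1).all()  # every unmasked bin exactly once
    assert not any(d.start <= 250 * 20_000 < d.end for d in rds.domains)


def test_flicker_absorber_merges_short_runs():
    lab = np.array([0] * 10 + [1] + [0] * 10 + [2] * 6)
    out = _absorb_flickers(lab, min_bins=2)
    np.testing.assert_array_equal(out, [0] * 21 + [2] * 6)
    # already-clean labels unchanged
    clean = np.array([0] * 5 + [1] * 5)
    np.testing.assert_array_equal(_absorb_flickers(clean, 2), clean)


# ------------------------------------------------------------ statistics

def test_domain_stats_coverage_and_counts(grid):
    g = BinGrid(GenomeSpec([("chr1", 10_000_000)]), 20_000)
    v = np.r_[np.full(100, 2.0), np.full(250, 0.0), np.full(150, -2.0)]
    v = (v - v.mean()) / v.std(ddof=1)
    t = SignalTrack(g, v, Stage.ZSCORE)
    rds = decode_domains(fit_segmentation(t, seed=0), t)
    stats = domain_stats(rds).set_index("class")
    assert stats.loc["ERD", "coverage_pct"] == pytest.approx(20.0)
    assert stats.loc["MRD", "coverage_pct"] == pytest.approx(50.0)
    assert stats.loc["LRD", "coverage_pct"] == pytest.approx(30.0)
    assert stats["coverage_pct"].sum() == pytest.approx(100.0, abs=1e-9)
    # counts match run-length encoding of the label vector
    assert stats["count"].tolist() == [1, 1, 1]


def test_class_rt_ordering_on_noisy_data(grid):
    """Mean Z-RT over decoded ERD bins > MRD bins > LRD bins."""
    t = three_level_track(grid, noise=0.5, seed=9)
    rds = decode_domains(fit_segmentation(t, seed=0), t)
    means = {}
    for klass in RDClass:
        sel = np.zeros(grid.n_bins, dtype=bool)
        for d in rds.domains:
            if d.klass is klass:
                sel[d.start // 20_000 : d.end // 20_000] = True
        means[klass] = t.values[sel].mean()
    assert means[RDClass.ERD] > means[RDClass.MRD] > means[RDClass.LRD]
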