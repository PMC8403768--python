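"""RT track pipeline: binning, CPM, log2 ratio, quantile norm, Loess,
Z-score, correlation and density."""

import numpy as np
import pytest

from replikit import (
    BinGrid,
    GenomeSpec,
    Phase,
    SignalTrack,
    Stage,
    bin_reads,
    cpm_normalize,
    log2_ratio,
    loess_smooth,
    quantile_normalize,
    replicate_correlation,
    rt_density,
    zscore,
)
from replikit.tracks import BinnedCounts


@pytest.fixture()
def grid():
    return BinGrid(GenomeSpec([("chr1", 1_000_000)]), 20_000)


def _track(grid, values, stage=Stage.RAW_LOG2):
    v = np.full(grid.n_bins, np.nan)
    v[: len(values)] = values
    return SignalTrack(grid, v, stage)


# ------------------------------------------------------------- bin_reads

def test_bin_reads_half_open_boundaries():
    grid = BinGrid(GenomeSpec([("chr1", 40_000)]), 20_000)
    counts = bin_reads([("chr1", 0), ("chr1", 19_999), ("chr1", 20_000)], grid)
    np.testing.assert_array_equal(counts.counts, [2, 1])


def test_bin_reads_empty_and_partial_bin_dropped():
    grid = BinGrid(GenomeSpec([("chr1", 50_000)]), 20_000)
    assert grid.n_bins == 2  # trailing 10 kb dropped
    counts = bin_reads([], grid)
    assert counts.counts.sum() == 0
    # a read in the dropped tail is discarded, not an error
    counts = bin_reads([("chr1", 45_000)], grid)
    assert counts.counts.sum() == 0


def test_bin_reads_conserves_kept_positions(grid):
    rng = np.random.default_rng(0)
    pos = rng.integers(0, 1_000_000, 10_000)
    counts = bin_reads([("chr1", int(p)) for p in pos], grid)
    assert counts.counts.sum() == 10_000


def test_bin_reads_unknown_chromosome_named_in_error(grid):
    with pytest.raises(KeyError, match="chrX"):
        bin_reads([("chrX", 100)], grid)


# ------------------------------------------------------------------- CPM

def test_cpm_examples_and_scale_invariance(grid):
    g2 = BinGrid(GenomeSpec([("chr1", 60_000)]), 20_000)
    c = BinnedCounts("s", Phase.S, g2, [1, 1, 2])
    np.testing.assert_allclose(cpm_normalize(c).values, [250_000, 250_000, 500_000])
    c7 = BinnedCounts("s", Phase.S, g2, [7, 7, 14])
    np.testing.assert_allclose(cpm_normalize(c7).values, cpm_normalize(c).values)
    rng = np.random.default_rng(1)
    rand = BinnedCounts("s", Phase.S, grid, rng.integers(0, 50, grid.n_bins))
    assert cpm_normalize(rand).values.sum() == pytest.approx(1e6)
    with pytest.raises(ValueError):
        cpm_normalize(BinnedCounts("s", Phase.S, g2, [0, 0, 0]))


# ------------------------------------------------------------ log2 ratio

def test_log2_ratio_values_and_masking(grid):
    rng = np.random.default_rng(2)
    base = rng.integers(50, 150, grid.n_bins)
    s = cpm_normalize(BinnedCounts("s", Phase.S, grid, base))
    g1 = cpm_normalize(BinnedCounts("g", Phase.G1, grid, base))
    np.testing.assert_allclose(log2_ratio(s, g1, min_g1_cpm=0).values, 0.0, atol=1e-12)
    s2 = SignalTrack(grid, 2.0 * g1.values, Stage.CPM)  # S CPM = 2 × G1 CPM
    np.testing.assert_allclose(log2_ratio(s2, g1, min_g1_cpm=0).values, 1.0, atol=1e-12)
    # low-G1 bins become NaN and stay NaN downstream
    low = rng.integers(50, 150, grid.n_bins)
    low[0] = 1
    s_var = cpm_normalize(
        BinnedCounts("s", Phase.S, grid, rng.integers(50, 300, grid.n_bins))
    )
    g1_low = cpm_normalize(BinnedCounts("g", Phase.G1, grid, low))
    r = log2_ratio(s_var, g1_low)
    assert np.isnan(r.values[0]) and np.isfinite(r.values[1:]).all()
    sm = loess_smooth(r, span_bp=100_000)
    assert np.isnan(sm.values[0])
    z = zscore(sm)
    assert np.isnan(z.values[0])
    assert abs(np.nanmean(z.values)) < 1e-9


# --------------------------------------------------------- quantile norm

def test_quantile_normalize_rankwise_mean():
    grid = BinGrid(GenomeSpec([("chr1", 60_000)]), 20_000)
    a = SignalTrack(grid, [1.0, 2.0, 3.0], Stage.RAW_LOG2)
    b = SignalTrack(grid, [4.0, 5.0, 6.0], Stage.RAW_LOG2)
    qa, qb = quantile_normalize([a, b])
    np.testing.assert_allclose(qa.values, [2.5, 3.5, 4.5])
    np.testing.assert_allclose(qb.values, [2.5, 3.5, 4.5])


def test_quantile_normalize_identical_tracks_unchanged(grid):
    rng = np.random.default_rng(3)
    v = rng.normal(size=grid.n_bins)
    tracks = [SignalTrack(grid, v.copy(), Stage.RAW_LOG2) for _ in range(3)]
    for q in quantile_normalize(tracks):
        np.testing.assert_allclose(q.values, v)


def test_quantile_normalize_sorted_vectors_identical_and_masks_preserved(grid):
    rng = np.random.default_rng(4)
    tracks = []
    for i in range(4):
        v = rng.normal(size=grid.n_bins)
        v[rng.choice(grid.n_bins, 5, replace=False)] = np.nan
        tracks.append(SignalTrack(grid, v, Stage.RAW_LOG2))
    out = quantile_normalize(tracks)
    common = np.logical_and.reduce([t.mask for t in tracks])
    ref = np.sort(out[0].values[common])
    for t, q in zip(tracks, out):
        np.testing.assert_array_equal(t.mask, q.mask)  # NaN positions kept
        np.testing.assert_allclose(np.sort(q.values[common]), ref)


def test_quantile_normalize_ties_average_dialect():
    grid = BinGrid(GenomeSpec([("chr1", 80_000)]), 20_000)
    a = SignalTrack(grid, [1.0, 1.0, 2.0, 3.0], Stage.RAW_LOG2)
    b = SignalTrack(grid, [10.0, 20.0, 30.0, 40.0], Stage.RAW_LOG2)
    qa, _ = quantile_normalize([a, b], ties="average")
    ref = (np.sort(a.values) + np.sort(b.values)) / 2  # [5.5, 10.5, 16, 21.5]
    np.testing.assert_allclose(qa.values[:2], np.mean(ref[:2]))
    np.testing.assert_allclose(qa.values[2:], ref[2:])


def test_quantile_normalize_stable_ties_keep_sorted_vectors_identical():
    """Default tie handling ranks tied values by position, so every output
    is an exact permutation of the reference even with heavy ties."""
    grid = BinGrid(GenomeSpec([("chr1", 2_000_000)]), 20_000)
    rng = np.random.default_rng(9)
    tracks = [
        SignalTrack(grid, rng.integers(0, 8, grid.n_bins).astype(float),
                    Stage.RAW_LOG2)
        for _ in range(3)
    ]
    out = quantile_normalize(tracks)
    ref = np.sort(out[0].values)
    for q in out[1:]:
        np.testing.assert_array_equal(np.sort(q.values), ref)


def test_quantile_normalize_needs_two_tracks(grid):
    with pytest.raises(ValueError):
        quantile_normalize([SignalTrack(grid, np.ones(grid.n_bins), Stage.RAW_LOG2)])


# ------------------------------------------------------------------ Loess

def test_loess_reproduces_constants_and_lines(grid):
    const = SignalTrack(grid, np.full(grid.n_bins, 2.5), Stage.QNORM)
    np.testing.assert_allclose(
        loess_smooth(const, 300_000).values, 2.5, atol=1e-9
    )
    x = np.arange(grid.n_bins, dtype=float)
    line = SignalTrack(grid, 0.3 * x - 4.0, Stage.QNORM)
    np.testing.assert_allclose(
        loess_smooth(line, 300_000).values, line.values, atol=1e-6
    )


def test_loess_denoises_step_signal(grid):
    rng = np.random.default_rng(5)
    clean = np.where(np.arange(grid.n_bins) < grid.n_bins // 2, 1.0, -1.0)
    noisy = clean + rng.normal(0, 0.3, grid.n_bins)
    sm = loess_smooth(SignalTrack(grid, noisy, Stage.QNORM), 300_000)
    rmse_in = np.sqrt(np.mean((noisy - clean) ** 2))
    rmse_out = np.sqrt(np.mean((sm.values - clean) ** 2))
    assert rmse_out < rmse_in


def test_loess_chromosomes_do_not_share_information():
    g = GenomeSpec([("chr1", 400_000), ("chr2", 400_000)])
    grid = BinGrid(g, 20_000)
    v = np.r_[np.zeros(20), np.ones(20)]
    a = loess_smooth(SignalTrack(grid, v, Stage.QNORM), 300_000)
    v2 = np.r_[np.zeros(20), 5 * np.ones(20)]
    b = loess_smooth(SignalTrack(grid, v2, Stage.QNORM), 300_000)
    np.testing.assert_allclose(a.values[:20], b.values[:20])


def test_loess_span_precondition(grid):
    t = SignalTrack(grid, np.zeros(grid.n_bins), Stage.QNORM)
    with pytest.raises(ValueError):
        loess_smooth(t, 40_000)


# ----------------------------------------------------------------- zscore

def test_zscore_symmetric_case_and_properties(grid):
    g3 = BinGrid(GenomeSpec([("chr1", 60_000)]), 20_000)
    z = zscore(SignalTrack(g3, [0.0, 1.0, 2.0], Stage.SMOOTHED))
    np.testing.assert_allclose(z.values, [-1.0, 0.0, 1.0])  # sample SD = 1
    rng = np.random.default_rng(6)
    v = rng.normal(3, 2, grid.n_bins)
    z1 = zscore(SignalTrack(grid, v, Stage.SMOOTHED))
    assert abs(z1.values.mean()) < 1e-9
    assert abs(z1.values.std(ddof=1) - 1) < 1e-9
    z2 = zscore(SignalTrack(grid, 5 * v + 11, Stage.SMOOTHED))
    np.testing.assert_allclose(z1.values, z2.values, atol=1e-9)


def test_zscore_zero_sd_errors(grid):
    with pytest.raises(ValueError):
        zscore(SignalTrack(grid, np.ones(grid.n_bins), Stage.SMOOTHED))


def test_stage_order_is_enforced(grid):
    raw = SignalTrack(grid, np.zeros(grid.n_bins), Stage.RAW_LOG2)
    with pytest.raises(ValueError, match="stage"):
        zscore(raw)
    smoothed = SignalTrack(grid, np.zeros(grid.n_bins), Stage.SMOOTHED)
    with pytest.raises(ValueError, match="stage"):
        loess_smooth(smoothed, 300_000)


# ----------------------------------------------- correlation and density

def test_replicate_correlation_limits(grid):
    rng = np.random.default_rng(7)
    v = rng.normal(size=grid.n_bins)
    t = SignalTrack(grid, v, Stage.SMOOTHED)
    neg = SignalTrack(grid, -v, Stage.SMOOTHED)
    r = replicate_correlation([t, t, neg])
    np.testing.assert_allclose(np.diag(r), 1.0)
    assert r[0, 1] == pytest.approx(1.0)
    assert r[0, 2] == pytest.approx(-1.0)
    np.testing.assert_allclose(r, r.T)


def test_rt_density_normalizes_and_locates_median(grid):
    rng = np.random.default_rng(8)
    v = rng.normal(0, 1, grid.n_bins)
    z = SignalTrack(grid, (v - v.mean()) / v.std(ddof=1), Stage.ZSCORE)
    med, lattice, dens = rt_density(z)
    assert abs(med) < 0.2
    assert np.trapezoid(dens, lattice) == pytest.approx(1.0, abs=1e-3)
    with pytest.raises(KeyError):
        rt_density(z, ["chrX"])
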