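"""From binned S/G1 read counts to normalized, smoothed, Z-scored RT tracks.

The pipeline stage order is fixed and enforced by stage tags:

    counts -> CPM -> log2(S/G1) [RAW_LOG2] -> quantile norm [QNORM]
           -> Loess smooth [SMOOTHED] -> Z-score [ZSCORE]

Replication timing (RT) is the per-window S/G1 copy-number ratio: loci
replicated early in S phase are present in two copies in more S-phase cells,
so a higher ratio means earlier replication. Windows are fixed 20 kb by
default. Masked (NaN) bins are contagious: they never contribute to any
downstream statistic.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import gaussian_kde
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .genome import BinGrid

log = logging.getLogger(__name__)

DEFAULT_SPAN_BP = 300_000


class Stage(enum.Enum):
    CPM = "CPM"
    RAW_LOG2 = "RAW_LOG2"
    QNORM = "QNORM"
    SMOOTHED = "SMOOTHED"
    ZSCORE = "ZSCORE"


class Phase(enum.Enum):
    S = "S"
    G1 = "G1"


@dataclass(frozen=True)
class BinnedCounts:
    """Non-negative integer read counts aligned to a bin grid."""

    sample: str
    phase: Phase
    grid: BinGrid
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (self.grid.n_bins,):
            raise ValueError(
                f"counts length {c.shape} != grid bins {self.grid.n_bins}"
            )
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class SignalTrack:
    """One float per bin (NaN = masked) plus a pipeline stage tag."""

    grid: BinGrid
    values: np.ndarray
    stage: Stage
    sample: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (self.grid.n_bins,):
            raise ValueError(
                f"values length {v.shape} != grid bins {self.grid.n_bins}"
            )
        object.__setattr__(self, "values", v)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the bin is unmasked (finite)."""
        return np.isfinite(self.values)


def _require_stage(track: SignalTrack, allowed: tuple[Stage, ...], op: str) -> None:
    if track.stage not in allowed:
        raise ValueError(
            f"{op} expects stage in {[s.value for s in allowed]}, "
            f"got {track.stage.value}"
        )


def bin_reads(
    read_positions, grid: BinGrid, sample: str = "", phase: Phase = Phase.S
) -> BinnedCounts:
    """Count read start positions into fixed bins.

    ``read_positions`` is an iterable of ``(chrom, pos)``. Positions falling
    in a chromosome's dropped partial terminal bin are discarded; an unknown
    chromosome raises ``KeyError`` naming it.
    """
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    for chrom, pos in read_positions:
        if chrom not in grid.chrom_offset:
            raise KeyError(f"read on unknown chromosome {chrom!r}")
        if pos < 0 or pos >= grid.genome.lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        idx = grid.bin_index(chrom, pos)
        if idx >= 0:
            counts[idx] += 1
    return BinnedCounts(sample=sample, phase=phase, grid=grid, counts=counts)


def cpm_normalize(counts: BinnedCounts) -> SignalTrack:
    """Counts-per-million library-size scaling; values sum to 1e6."""
    total = counts.counts.sum()
    if total <= 0:
        raise ValueError(f"sample {counts.sample!r}: zero total count")
    vals = counts.counts * (1e6 / total)
    return SignalTrack(counts.grid, vals, Stage.CPM, sample=counts.sample)


def log2_ratio(
    s: SignalTrack, g1: SignalTrack, min_g1_cpm: float | None = None
) -> SignalTrack:
    """log2(S_cpm / G1_cpm) per bin, the raw RT signal.

    Bins with G1 CPM below ``min_g1_cpm`` or with zero S CPM are masked (NaN)
    rather than pseudocounted. Default threshold: 25% of the median G1 CPM.
    """
    _require_stage(s, (Stage.CPM,), "log2_ratio")
    _require_stage(g1, (Stage.CPM,), "log2_ratio")
    if s.grid != g1.grid:
        raise ValueError("S and G1 tracks are on different grids")
    if min_g1_cpm is None:
        min_g1_cpm = 0.25 * float(np.median(g1.values))
    bad = (g1.values < min_g1_cpm) | (s.values <= 0) | ~np.isfinite(g1.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log2(s.values / g1.values)
    vals[bad] = np.nan
    return SignalTrack(s.grid, vals, Stage.RAW_LOG2, sample=s.sample)


def _qnorm_map(values: np.ndarray, reference: np.ndarray, ties: str) -> np.ndarray:
    """Map sorted-rank positions of ``values`` onto ``reference`` (sorted).

    ``ties="stable"`` assigns tied input values consecutive reference values
    in genomic-position order, so the output is an exact permutation of the
    reference. ``ties="average"`` gives every tied input the mean of the
    tied reference values instead.
    """
    order = np.argsort(values, kind="mergesort")
    out = np.empty_like(values)
    out[order] = reference
    if ties == "average":
        sv = values[order]
        tie_starts = np.flatnonzero(np.r_[True, sv[1:] != sv[:-1]])
        if len(tie_starts) < len(sv):
            sums = np.add.reduceat(reference, tie_starts)
            lens = np.diff(np.r_[tie_starts, len(sv)])
            out[order] = np.repeat(sums / lens, lens)
    elif ties != "stable":
        raise ValueError(f"unknown ties mode {ties!r}")
    return out


def quantile_normalize(
    tracks: list[SignalTrack], ties: str = "stable"
) -> list[SignalTrack]:
    """Force all tracks onto a common value distribution.

    The reference distribution is the rank-wise mean of sorted values over
    bins unmasked in *all* tracks. With the default ``ties="stable"`` every
    output is an exact permutation of the reference (tied values are ranked
    by genomic position), so the sorted value vectors of all outputs are
    bit-identical; ``ties="average"`` instead gives tied inputs the mean of
    the tied reference values. Bins a track has unmasked but some other
    track masks are mapped through a monotone interpolation of that track's
    common-bin→reference map, so per-track NaN positions are preserved.
    """
    if len(tracks) < 2:
        raise ValueError("quantile normalization needs >= 2 tracks")
    grid = tracks[0].grid
    for t in tracks:
        _require_stage(t, (Stage.RAW_LOG2,), "quantile_normalize")
        if t.grid != grid:
            raise ValueError("tracks on different grids")
    common = np.logical_and.reduce([t.mask for t in tracks])
    n = int(common.sum())
    if n < 2:
        raise ValueError("fewer than 2 bins unmasked in all tracks")
    mat = np.stack([t.values[common] for t in tracks])  # (k, n)
    reference = np.sort(mat, axis=1).mean(axis=0)
    out = []
    for t, row in zip(tracks, mat):
        vals = np.full(grid.n_bins, np.nan)
        mapped = _qnorm_map(row, reference, ties)
        vals[common] = mapped
        extra = t.mask & ~common
        if extra.any():
            # interpolation map: one target per unique value (mean over ties)
            xs, inv = np.unique(row, return_inverse=True)
            ys = np.zeros_like(xs)
            np.add.at(ys, inv, mapped)
            ys /= np.bincount(inv)
            vals[extra] = np.interp(t.values[extra], xs, ys)
        out.append(replace(t, values=vals, stage=Stage.QNORM))
    return out


def loess_smooth(track: SignalTrack, span_bp: int = DEFAULT_SPAN_BP) -> SignalTrack:
    """Per-chromosome Loess (degree-1, tricube) smoothing of the RT signal.

    The span is given in bp and converted to a nearest-neighbour fraction per
    chromosome; chromosomes never share information. NaN bins are excluded
    from the fit and stay NaN. A chromosome with < 3 unmasked bins is left
    unsmoothed with a warning.
    """
    _require_stage(track, (Stage.QNORM, Stage.RAW_LOG2), "loess_smooth")
    bs = track.grid.bin_size
    if span_bp < 3 * bs:
        raise ValueError(f"span_bp must be >= 3 x bin_size ({3 * bs})")
    vals = track.values.copy()
    for chrom in track.grid.genome.names:
        sl = track.grid.chrom_slice(chrom)
        v = track.values[sl]
        ok = np.isfinite(v)
        n_ok = int(ok.sum())
        if n_ok == 0:
            continue
        if n_ok < 3:
            warnings.warn(
                f"chromosome {chrom}: only {n_ok} unmasked bins, left unsmoothed"
            )
            continue
        x = (np.flatnonzero(ok) * bs + bs / 2.0).astype(float)
        frac = min(1.0, (span_bp / bs) / n_ok)
        # it=0: robustness reweighting divides by the median |residual|,
        # which is zero on locally constant signal and yields NaN
        sm = _sm_lowess(v[ok], x, frac=frac, it=0, xvals=x)
        out = vals[sl]
        out[ok] = sm
        vals[sl] = out
    return replace(track, values=vals, stage=Stage.SMOOTHED)


def zscore(track: SignalTrack) -> SignalTrack:
    """Genome-wide standardization to mean 0, SD 1 (sample SD, n-1)."""
    _require_stage(track, (Stage.SMOOTHED,), "zscore")
    ok = track.mask
    if ok.sum() < 2:
        raise ValueError("need >= 2 unmasked bins to Z-score")
    v = track.values[ok]
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation; cannot Z-score")
    vals = (track.values - float(np.mean(v))) / sd
    return replace(track, values=vals, stage=Stage.ZSCORE)


def replicate_correlation(tracks: list[SignalTrack]) -> np.ndarray:
    """Pairwise-complete Pearson correlation matrix of smoothed RT tracks."""
    for t in tracks:
        _require_stage(t, (Stage.SMOOTHED, Stage.ZSCORE), "replicate_correlation")
        if t.grid != tracks[0].grid:
            raise ValueError("tracks on different grids")
    k = len(tracks)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            ok = tracks[i].mask & tracks[j].mask
            if ok.sum() < 10:
                raise ValueError(
                    f"tracks {i},{j}: fewer than 10 pairwise-complete bins"
                )
            c = np.corrcoef(tracks[i].values[ok], tracks[j].values[ok])[0, 1]
            r[i, j] = r[j, i] = c
    return r


def rt_density(
    track: SignalTrack,
    chrom_subset: list[str] | None = None,
    n_points: int = 512,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Median and Gaussian-kernel density of RT values over a chromosome subset.

    Returns ``(median, lattice, density)``; the density is evaluated on a
    fixed lattice spanning the data range padded by three bandwidths and
    integrates to ~1 there.
    """
    if chrom_subset is None:
        sel = np.ones(track.grid.n_bins, dtype=bool)
    else:
        sel = np.zeros(track.grid.n_bins, dtype=bool)
        for chrom in chrom_subset:
            if chrom not in track.grid.chrom_offset:
                raise KeyError(f"unknown chromosome {chrom!r}")
            sel[track.grid.chrom_slice(chrom)] = True
    v = track.values[sel]
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise ValueError("need >= 10 unmasked bins in the subset")
    kde = gaussian_kde(v)
    bw = kde.factor * v.std(ddof=1)
    lattice = np.linspace(v.min() - 3 * bw, v.max() + 3 * bw, n_points)
    return float(np.median(v)), lattice, kde(lattice)
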