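"""Three-state segmentation of Z-scored RT into ERD/MRD/LRD domains.

A 3-state Gaussian hidden Markov model is fit by EM on the merged-replicate
Z-scored smoothed RT track and decoded by Viterbi. States are relabeled
after fitting so that mean(ERD) > mean(MRD) > mean(LRD): the label is the
RT level, not the fit order. Restarts use deterministic spread-scaled
initializations around tercile means, which makes the whole fit reproducible
and exactly equivariant under sign flips of the input (negating the track
swaps ERD and LRD).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .genome import GenomeSpec
from .intervals import IntervalSet
from .tracks import SignalTrack, Stage, _require_stage

N_INIT = 5
MAX_ITER = 500
TOL = 1e-4
_ALPHAS = (1.0, 0.6, 0.8, 1.2, 1.4)  # deterministic spread scalings
_SELF_TRANS = 0.98


class RDClass(enum.Enum):
    ERD = "ERD"
    MRD = "MRD"
    LRD = "LRD"


@dataclass(frozen=True)
class RDomain:
    chrom: str
    start: int
    end: int
    klass: RDClass

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty domain {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class RDSet:
    """Non-overlapping, sorted replication domains for one sample/condition."""

    label: str
    domains: tuple[RDomain, ...]

    def __post_init__(self):
        doms = tuple(
            sorted(self.domains, key=lambda d: (d.chrom, d.start))
        )
        prev: RDomain | None = None
        for d in doms:
            if prev and prev.chrom == d.chrom and d.start < prev.end:
                raise ValueError(f"overlapping domains at {d.chrom}:{d.start}")
            prev = d
        object.__setattr__(self, "domains", doms)

    def class_intervals(self, klass: RDClass) -> IntervalSet:
        return IntervalSet(
            [(d.chrom, d.start, d.end) for d in self.domains if d.klass is klass]
        )

    @property
    def total_length(self) -> int:
        return sum(d.end - d.start for d in self.domains)


@dataclass(frozen=True)
class SegmentationModel:
    """Fitted 3-state Gaussian HMM, states ordered ERD, MRD, LRD by mean."""

    means: np.ndarray          # (n_states,), descending
    variances: np.ndarray      # (n_states,)
    transmat: np.ndarray       # (n_states, n_states), rows sum to 1
    startprob: np.ndarray
    log_likelihood: float
    converged: bool
    n_states: int = 3
    seed: int = 0

    def state_class(self, state: int) -> RDClass:
        return [RDClass.ERD, RDClass.MRD, RDClass.LRD][state]

    def to_hmm(self) -> GaussianHMM:
        m = GaussianHMM(
            n_components=self.n_states, covariance_type="diag", init_params=""
        )
        m.startprob_ = self.startprob.copy()
        m.transmat_ = self.transmat.copy()
        m.means_ = self.means.reshape(-1, 1).copy()
        m.covars_ = self.variances.reshape(-1, 1).copy()
        return m


def merge_replicates(tracks: list[SignalTrack]) -> SignalTrack:
    """Per-bin mean of replicate tracks; a bin is NaN only if all replicates
    mask it."""
    if not tracks:
        raise ValueError("no tracks to merge")
    for t in tracks:
        _require_stage(t, (Stage.ZSCORE,), "merge_replicates")
        if t.grid != tracks[0].grid:
            raise ValueError("tracks on different grids")
    stack = np.stack([t.values for t in tracks])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        merged = np.nanmean(stack, axis=0)
    return replace(tracks[0], values=merged, sample="merged")


def _unmasked_runs(track: SignalTrack) -> list[tuple[str, int, int]]:
    """Maximal contiguous unmasked runs as (chrom, start_bin, end_bin),
    bin indices local to the chromosome."""
    runs = []
    for chrom in track.grid.genome.names:
        sl = track.grid.chrom_slice(chrom)
        ok = np.isfinite(track.values[sl])
        if not ok.any():
            continue
        d = np.diff(ok.astype(int))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if ok[0]:
            starts.insert(0, 0)
        if ok[-1]:
            ends.append(len(ok))
        runs.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return runs


def _tercile_init(values: np.ndarray, n_states: int) -> tuple[np.ndarray, np.ndarray]:
    sv = np.sort(values)
    chunks = np.array_split(sv, n_states)
    means = np.array([c.mean() for c in chunks])[::-1]  # descending
    variances = np.array([max(c.var(), 1e-4) for c in chunks])[::-1]
    return means, variances


def fit_segmentation(
    track: SignalTrack,
    n_states: int = 3,
    seed: int = 0,
    n_init: int = N_INIT,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> SegmentationModel:
    """EM-fit the segmentation HMM on all unmasked runs of the track.

    Initialization: state means at tercile means of the data, spread-scaled
    around their center across ``n_init`` restarts; the restart with the
    best log-likelihood wins. Non-convergence returns the best iterate with
    the ``converged`` flag unset (a warning is emitted).
    """
    _require_stage(track, (Stage.ZSCORE,), "fit_segmentation")
    runs = _unmasked_runs(track)
    values = track.values[np.isfinite(track.values)]
    if values.size < 100:
        raise ValueError("need >= 100 unmasked bins to fit a segmentation")
    X = values.reshape(-1, 1)
    lengths = []
    for chrom, s, e in runs:
        lengths.append(e - s)
    base_means, base_vars = _tercile_init(values, n_states)
    center = base_means.mean()
    trans = np.full((n_states, n_states), (1 - _SELF_TRANS) / (n_states - 1))
    np.fill_diagonal(trans, _SELF_TRANS)
    best = None
    for alpha in _ALPHAS[:n_init]:
        m = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            init_params="",
            params="stmc",
            n_iter=max_iter,
            tol=tol,
        )
        m.startprob_ = np.full(n_states, 1.0 / n_states)
        m.transmat_ = trans.copy()
        m.means_ = (center + alpha * (base_means - center)).reshape(-1, 1)
        m.covars_ = base_vars.reshape(-1, 1).copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(X, lengths)
            ll = float(m.score(X, lengths))
        if best is None or ll > best[0] + 1e-9:
            best = (ll, m)
    ll, m = best
    if not m.monitor_.converged:
        warnings.warn("EM did not converge within max_iter; best iterate kept")
    order = np.argsort(-m.means_.ravel(), kind="stable")
    return SegmentationModel(
        means=m.means_.ravel()[order],
        variances=np.asarray(m.covars_).reshape(n_states, -1)[:, 0][order],
        transmat=m.transmat_[np.ix_(order, order)],
        startprob=m.startprob_[order],
        log_likelihood=ll,
        converged=bool(m.monitor_.converged),
        n_states=n_states,
        seed=seed,
    )


def _absorb_flickers(labels: np.ndarray, min_bins: int) -> np.ndarray:
    """Merge runs shorter than min_bins into the larger flanking run."""
    lab = labels.copy()
    while True:
        # run-length encode
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.r_[0, change]
        ends = np.r_[change, len(lab)]
        sizes = ends - starts
        short = np.flatnonzero(sizes < min_bins)
        if len(short) == 0 or len(starts) == 1:
            return lab
        i = int(short[np.argmin(sizes[short])])  # smallest flicker first
        left = sizes[i - 1] if i > 0 else -1
        right = sizes[i + 1] if i < len(starts) - 1 else -1
        src = i - 1 if left >= right else i + 1
        lab[starts[i] : ends[i]] = lab[starts[src]]


def decode_domains(
    model: SegmentationModel,
    track: SignalTrack,
    gap_tolerance: int = 2,
    min_domain_bins: int = 2,
    label: str = "",
) -> RDSet:
    """Viterbi-decode the track and merge equal-label bins into domains.

    Runs of one label shorter than ``min_domain_bins`` are absorbed into the
    larger flanking run. Domains continue across masked gaps of at most
    ``gap_tolerance`` bins when the flanking labels agree; longer gaps and
    chromosome boundaries split domains.
    """
    hmm = model.to_hmm()
    bs = track.grid.bin_size
    domains: list[RDomain] = []
    # decode each unmasked run, then stitch runs per chromosome
    per_chrom: dict[str, list[tuple[int, int, np.ndarray]]] = {}
    for chrom, s, e in _unmasked_runs(track):
        sl = track.grid.chrom_slice(chrom)
        v = track.values[sl][s:e]
        states = hmm.predict(v.reshape(-1, 1))
        states = _absorb_flickers(states, min_domain_bins)
        per_chrom.setdefault(chrom, []).append((s, e, states))
    for chrom, runs in per_chrom.items():
        segs: list[list] = []  # [start_bin, end_bin, state]
        for s, e, states in runs:
            change = np.flatnonzero(np.diff(states)) + 1
            starts = np.r_[0, change] + s
            ends = np.r_[change, len(states)] + s
            for a, b in zip(starts, ends):
                st = int(states[a - s])
                prev = segs[-1] if segs else None
                if (
                    prev is not None
                    and prev[2] == st
                    and a - prev[1] <= gap_tolerance
                ):
                    prev[1] = int(b)
                else:
                    segs.append([int(a), int(b), st])
        for a, b, st in segs:
            domains.append(
                RDomain(chrom, a * bs, b * bs, model.state_class(st))
            )
    return RDSet(label=label, domains=tuple(domains))


def domain_stats(rds: RDSet, genome: GenomeSpec | None = None) -> pd.DataFrame:
    """Per-class domain count, genome coverage % (of segmented length) and
    size summary."""
    rows = []
    total = rds.total_length
    for klass in RDClass:
        sizes = np.array(
            [d.end - d.start for d in rds.domains if d.klass is klass], dtype=float
        )
        rows.append(
            {
                "class": klass.value,
                "count": int(sizes.size),
                "total_bp": int(sizes.sum()),
                "coverage_pct": 100.0 * sizes.sum() / total if total else 0.0,
                "mean_size_bp": float(sizes.mean()) if sizes.size else np.nan,
                "median_size_bp": float(np.median(sizes)) if sizes.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def domain_sizes(rds: RDSet) -> pd.DataFrame:
    """One row per domain (class, chrom, start, end, size_bp)."""
    return pd.DataFrame(
        [
            {
                "class": d.klass.value,
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "size_bp": d.end - d.start,
            }
            for d in rds.domains
        ]
    )
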