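"""RT-signal enrichment matrices around domain midpoints and gene anchors.

A ProfileMatrix is the computeMatrix-style reference-point view: one row per
anchor, one column per bin offset across a symmetric flank (default
±0.5 Mb at the track's 20 kb bin size, 50 columns). Signal lookup is
nearest-bin with no interpolation; minus-strand anchors are reported 5'→3'
(their rows are reversed). Out-of-chromosome cells are NaN and column means
ignore them.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import GeneAnnotation
from .intervals import IntervalSet
from .tracks import SignalTrack

log = logging.getLogger(__name__)

DEFAULT_FLANK = 500_000


class AnchorKind(enum.Enum):
    DOMAIN_MIDPOINT = "DOMAIN_MIDPOINT"
    TSS = "TSS"
    TES = "TES"
    GENE_CENTER = "GENE_CENTER"


@dataclass(frozen=True)
class AnchorSet:
    kind: AnchorKind
    anchors: tuple[tuple[str, int, str], ...]  # (chrom, pos, strand)

    def __post_init__(self):
        for chrom, pos, strand in self.anchors:
            if strand not in "+-.":
                raise ValueError(f"bad strand {strand!r}")
            if strand == "." and self.kind in (AnchorKind.TSS, AnchorKind.TES):
                raise ValueError(
                    f"{self.kind.value} anchors require a strand ({chrom}:{pos})"
                )


@dataclass(frozen=True)
class ProfileMatrix:
    kind: AnchorKind
    flank: int
    bin_size: int
    matrix: np.ndarray       # (n_anchors, 2*flank/bin_size)
    anchors: AnchorSet

    @property
    def offsets(self) -> np.ndarray:
        """Column center offsets in bp relative to the anchor."""
        n = self.matrix.shape[1] // 2
        return (np.arange(-n, n) + 0.5) * self.bin_size

    def column_mean(self) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return np.nanmean(self.matrix, axis=0)

    def column_ci(self, z: float = 1.96) -> np.ndarray:
        """Half-width of a normal-approximation CI of each column mean."""
        n = np.isfinite(self.matrix).sum(axis=0)
        sd = np.nanstd(self.matrix, axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return z * sd / np.sqrt(n)

    def sorted_rows(self) -> np.ndarray:
        """Rows sorted by row mean, descending (heat-map order)."""
        key = np.nan_to_num(np.nanmean(self.matrix, axis=1), nan=-np.inf)
        return self.matrix[np.argsort(-key, kind="stable")]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{int(o)}" for o in self.offsets - 0.5 * self.bin_size]
        return pd.DataFrame(self.matrix, columns=cols)


def midpoints(domains: IntervalSet) -> AnchorSet:
    """Floor midpoints of every interval, unstranded."""
    if not domains:
        raise ValueError("empty interval set")
    return AnchorSet(
        AnchorKind.DOMAIN_MIDPOINT,
        tuple((c, (s + e) // 2, ".") for c, s, e in domains),
    )


def matrix_around(
    track: SignalTrack, anchors: AnchorSet, flank: int = DEFAULT_FLANK
) -> ProfileMatrix:
    """Signal matrix across ±flank around each anchor, nearest-bin lookup."""
    bs = track.grid.bin_size
    if flank % bs:
        raise ValueError(f"flank must be a multiple of bin_size {bs}")
    n_flank = flank // bs
    offsets = np.arange(-n_flank, n_flank) * bs
    rows, kept = [], []
    for chrom, pos, strand in anchors.anchors:
        if chrom not in track.grid.chrom_offset:
            log.warning("anchor on unknown chromosome %s dropped", chrom)
            continue
        n_bins = track.grid.chrom_n_bins[chrom]
        off = track.grid.chrom_offset[chrom]
        bins = (pos + offsets) // bs
        valid = (pos + offsets >= 0) & (bins < n_bins)
        row = np.full(2 * n_flank, np.nan)
        row[valid] = track.values[off + bins[valid]]
        if strand == "-":
            row = row[::-1]
        rows.append(row)
        kept.append((chrom, pos, strand))
    if not rows:
        raise ValueError("no anchors on the track's genome")
    return ProfileMatrix(
        kind=anchors.kind,
        flank=flank,
        bin_size=bs,
        matrix=np.vstack(rows),
        anchors=AnchorSet(anchors.kind, tuple(kept)),
    )


def gene_anchors(
    annotation: GeneAnnotation,
    kind: AnchorKind,
    gene_subset: list[str] | None = None,
) -> AnchorSet:
    """TSS / TES / center anchors for a gene subset (None or empty = all).

    TSS is the 5' end by strand (minus strand: span end − 1), TES the 3'
    end, center the floor midpoint. Unstranded genes are skipped for
    TSS/TES and reported.
    """
    tab = annotation.table
    if gene_subset:
        tab = annotation.subset(gene_subset).table
    anchors, skipped = [], []
    for row in tab.itertuples(index=False):
        strand = str(row.strand)
        if kind is AnchorKind.GENE_CENTER:
            anchors.append((row.chrom, (int(row.start) + int(row.end)) // 2, strand))
            continue
        if strand not in "+-":
            skipped.append(str(row.gene_id))
            continue
        five = int(row.start) if strand == "+" else int(row.end) - 1
        three = int(row.end) - 1 if strand == "+" else int(row.start)
        anchors.append(
            (row.chrom, five if kind is AnchorKind.TSS else three, strand)
        )
    if skipped:
        log.warning("%d unstranded genes skipped for %s: %s",
                    len(skipped), kind.value, skipped[:10])
    if not anchors:
        raise ValueError(f"no usable anchors for {kind.value}")
    return AnchorSet(kind, tuple(anchors))


def gene_anchor_profiles(
    track: SignalTrack,
    annotation: GeneAnnotation,
    gene_subset: list[str] | None = None,
    kinds: tuple[AnchorKind, ...] = (
        AnchorKind.TSS,
        AnchorKind.TES,
        AnchorKind.GENE_CENTER,
    ),
    flank: int = DEFAULT_FLANK,
) -> dict[AnchorKind, ProfileMatrix]:
    """One ProfileMatrix per requested anchor kind for the gene subset."""
    return {
        kind: matrix_around(track, gene_anchors(annotation, kind, gene_subset), flank)
        for kind in kinds
    }
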