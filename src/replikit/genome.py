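"""Toy-genome description and the fixed-window bin grid.

Replication timing is quantified on a fixed grid of non-overlapping windows
(default 20 kb) tiling each chromosome; a trailing partial window is dropped.
All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_BIN_SIZE = 20_000


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes of a (toy) genome.

    Parameters
    ----------
    chroms
        Ordered ``(name, length_bp)`` pairs. Names must be unique and lengths
        positive.
    """

    chroms: tuple[tuple[str, int], ...]

    def __init__(self, chroms) -> None:
        chroms = tuple((str(n), int(l)) for n, l in chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate chromosome names: {names}")
        for n, l in chroms:
            if l <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length {l}")
        object.__setattr__(self, "chroms", chroms)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chroms]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chroms)


@dataclass(frozen=True)
class BinGrid:
    """Fixed windows tiling a genome; the coordinate system of every track.

    Bins are ``[start, start + bin_size)`` laid consecutively per chromosome,
    in genome order; a final partial bin is dropped.
    """

    genome: GenomeSpec
    bin_size: int = DEFAULT_BIN_SIZE
    # derived, filled in __post_init__
    chrom_n_bins: dict[str, int] = field(init=False, repr=False)
    chrom_offset: dict[str, int] = field(init=False, repr=False)
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        n_bins = {n: l // self.bin_size for n, l in self.genome.chroms}
        offsets, off = {}, 0
        for name, _ in self.genome.chroms:
            offsets[name] = off
            off += n_bins[name]
        object.__setattr__(self, "chrom_n_bins", n_bins)
        object.__setattr__(self, "chrom_offset", offsets)
        object.__setattr__(self, "n_bins", off)

    def chrom_slice(self, chrom: str) -> slice:
        off = self.chrom_offset[chrom]
        return slice(off, off + self.chrom_n_bins[chrom])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Flat index of the bin containing ``pos``; -1 if in the dropped tail."""
        if chrom not in self.chrom_offset:
            raise KeyError(f"unknown chromosome {chrom!r}")
        b = pos // self.bin_size
        if b >= self.chrom_n_bins[chrom] or pos < 0:
            return -1
        return self.chrom_offset[chrom] + b

    def bin_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-bin ``(chrom_codes, starts)`` arrays; codes index genome order."""
        codes = np.empty(self.n_bins, dtype=np.int64)
        starts = np.empty(self.n_bins, dtype=np.int64)
        for ci, (name, _) in enumerate(self.genome.chroms):
            sl = self.chrom_slice(name)
            codes[sl] = ci
            starts[sl] = np.arange(self.chrom_n_bins[name]) * self.bin_size
        return codes, starts

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinGrid)
            and self.genome == other.genome
            and self.bin_size == other.bin_size
        )

    def __hash__(self) -> int:
        return hash((self.genome, self.bin_size))
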