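"""bedtools-style base-level interval algebra on sorted, merged interval sets.

All intervals are 0-based half-open. An :class:`IntervalSet` is canonical:
sorted by (chrom, start), non-overlapping, and with touching intervals merged,
so set operations are exact at base resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeSpec


def _canonicalize(ivs: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(ivs):
        start, end = int(start), int(end)
        if end <= start:
            raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out


@dataclass(frozen=True)
class IntervalSet:
    intervals: tuple[tuple[str, int, int], ...]

    def __init__(self, intervals=()) -> None:
        object.__setattr__(self, "intervals", tuple(_canonicalize(list(intervals))))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome ``(n, 2)`` start/end arrays."""
        out: dict[str, list[list[int]]] = {}
        for c, s, e in self.intervals:
            out.setdefault(c, []).append([s, e])
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


def _pair_op(a: IntervalSet, b: IntervalSet, keep_b: bool) -> IntervalSet:
    """Sweep-line intersection (keep_b=True) or subtraction (keep_b=False)."""
    a_by, b_by = a.by_chrom(), b.by_chrom()
    result: list[tuple[str, int, int]] = []
    for chrom, aa in a_by.items():
        bb = b_by.get(chrom)
        if bb is None or not len(bb):
            if not keep_b:
                result.extend((chrom, int(s), int(e)) for s, e in aa)
            continue
        j = 0
        for s, e in aa:
            cursor = s
            # advance past b-intervals entirely left of [s, e)
            while j < len(bb) and bb[j, 1] <= s:
                j += 1
            k = j
            while k < len(bb) and bb[k, 0] < e:
                bs, be = int(bb[k, 0]), int(bb[k, 1])
                if keep_b:
                    result.append((chrom, max(s, bs), min(e, be)))
                else:
                    if bs > cursor:
                        result.append((chrom, cursor, bs))
                    cursor = max(cursor, be)
                k += 1
            if not keep_b and cursor < e:
                result.append((chrom, int(cursor), int(e)))
    return IntervalSet(result)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-level intersection ``a ∩ b``, merged."""
    return _pair_op(a, b, keep_b=True)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases of ``a`` not covered by ``b``, merged."""
    return _pair_op(a, b, keep_b=False)


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return IntervalSet(list(a) + list(b))


def extend(s: IntervalSet, pad: int, genome: GenomeSpec) -> IntervalSet:
    """Grow every interval by ``pad`` bp on both sides, clip to chromosome
    bounds, and re-merge."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    lengths = genome.lengths
    grown = []
    for chrom, start, end in s:
        limit = lengths.get(chrom)
        if limit is None:
            raise KeyError(f"interval on unknown chromosome {chrom!r}")
        grown.append((chrom, max(0, start - pad), min(limit, end + pad)))
    return IntervalSet(grown)


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Base-level Jaccard index |a ∩ b| / |a ∪ b| (0 when both empty)."""
    inter = intersect(a, b).total_length
    uni = union(a, b).total_length
    return inter / uni if uni else 0.0
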