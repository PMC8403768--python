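"""Condition-dependent replication domains by intersect-then-subtract.

For each domain class C, the class-matched wildtype and rescue domains are
intersected (the FUS-independent core: present without FUS only if present
both with endogenous and re-expressed FUS) and subtracted from the
knockout's class-C domains. What remains is the class-C genome whose RT
state exists in the knockout but is not shared by wildtype and rescue —
the FUS-dependent replication domains (ERD-FUS, MRD-FUS, LRD-FUS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .genome import GenomeSpec
from .intervals import IntervalSet, extend, intersect, subtract
from .segmentation import RDClass, RDSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DependentRDs:
    """Per-class FUS-dependent intervals with coverage summaries."""

    regions: dict[RDClass, IntervalSet]
    percent_of_class: dict[RDClass, float]
    percent_of_genome: dict[RDClass, float]
    segmented_length: int = 0

    def union(self) -> IntervalSet:
        out = IntervalSet()
        for s in self.regions.values():
            out = IntervalSet(list(out) + list(s))
        return out

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "class": k.value,
                    "dependent_bp": self.regions[k].total_length,
                    "percent_of_class": self.percent_of_class[k],
                    "percent_of_genome": self.percent_of_genome[k],
                }
                for k in RDClass
            ]
        )


def call_dependent_domains(
    ko: RDSet,
    wt: RDSet,
    rescue: RDSet,
    subtract_from_ko: bool = True,
) -> DependentRDs:
    """Per class C: ``dep_C = KO_C − (WT_C ∩ RESCUE_C)``.

    ``percent_of_class`` is relative to the KO class length and
    ``percent_of_genome`` to the total KO segmented length. With
    ``subtract_from_ko=False`` the opposite orientation
    ``(WT_C ∩ RESCUE_C) − KO_C`` is computed instead.
    """
    regions: dict[RDClass, IntervalSet] = {}
    pct_class: dict[RDClass, float] = {}
    pct_genome: dict[RDClass, float] = {}
    seg_len = ko.total_length
    for klass in RDClass:
        ko_c = ko.class_intervals(klass)
        core = intersect(wt.class_intervals(klass), rescue.class_intervals(klass))
        if not ko_c or not wt.class_intervals(klass) or not rescue.class_intervals(klass):
            if not (ko_c and core):
                log.warning("class %s absent from at least one set", klass.value)
        dep = subtract(ko_c, core) if subtract_from_ko else subtract(core, ko_c)
        regions[klass] = dep
        denom = ko_c.total_length if subtract_from_ko else core.total_length
        pct_class[klass] = 100.0 * dep.total_length / denom if denom else 0.0
        pct_genome[klass] = 100.0 * dep.total_length / seg_len if seg_len else 0.0
    return DependentRDs(
        regions=regions,
        percent_of_class=pct_class,
        percent_of_genome=pct_genome,
        segmented_length=seg_len,
    )


def extend_domains(s: IntervalSet, pad: int, genome: GenomeSpec) -> IntervalSet:
    """Grow intervals by ``pad`` bp both sides (default use: 3000 bp before
    gene extraction), clipped to chromosome ends and re-merged."""
    return extend(s, pad, genome)


@dataclass
class GeneAnnotation:
    """Gene spans: DataFrame with chrom, start, end, gene_id, strand."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("chrom", "start", "end", "gene_id", "strand")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns {missing}")

    def subset(self, gene_ids) -> "GeneAnnotation":
        ids = set(gene_ids)
        absent = sorted(ids - set(self.table["gene_id"]))
        if absent:
            log.warning("%d gene ids absent from annotation: %s",
                        len(absent), absent[:10])
        return GeneAnnotation(self.table[self.table["gene_id"].isin(ids)].copy())


def genes_in_regions(s: IntervalSet, annotation: GeneAnnotation) -> list[str]:
    """Gene ids whose span overlaps at least one base of ``s`` (half-open
    semantics: touching does not overlap); deduplicated and sorted."""
    by_chrom = s.by_chrom()
    hits: set[str] = set()
    for row in annotation.table.itertuples(index=False):
        ivs = by_chrom.get(row.chrom)
        if ivs is None:
            continue
        overlap = (ivs[:, 0] < row.end) & (ivs[:, 1] > row.start)
        if overlap.any():
            hits.add(str(row.gene_id))
    return sorted(hits)
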