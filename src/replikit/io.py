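"""Plain-text genomic I/O: bedGraph tracks, BED domains, design tables,
gene annotation (BED6+ or GFF3 gene rows), and YAML config snapshots.

All coordinates on disk are 0-based half-open (GFF3 start is converted from
its 1-based convention on read).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import CohortDesign, Condition, SampleSpec
from .genome import BinGrid, GenomeSpec
from .intervals import IntervalSet
from .segmentation import RDClass, RDomain, RDSet
from .simulate import DomainPlan
from .tracks import BinnedCounts, Phase, SignalTrack

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- bedGraph

def write_bedgraph(path, grid: BinGrid, values: np.ndarray, *, fmt="%.6g") -> None:
    """Write one value per bin as 4-column bedGraph; NaN bins are skipped."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        for chrom in grid.genome.names:
            sl = grid.chrom_slice(chrom)
            v = values[sl]
            for i, val in enumerate(v):
                if isinstance(val, float) and np.isnan(val):
                    continue
                start = i * grid.bin_size
                fh.write(
                    f"{chrom}\t{start}\t{start + grid.bin_size}\t{fmt % val}\n"
                )


def write_track(path, track: SignalTrack) -> None:
    write_bedgraph(path, track.grid, track.values)


def write_counts(path, counts: BinnedCounts) -> None:
    write_bedgraph(path, counts.grid, counts.counts, fmt="%d")


def read_bedgraph(path, grid: BinGrid) -> np.ndarray:
    """Read a bedGraph onto the grid; bins absent from the file are NaN.

    Intervals must align exactly to grid bins.
    """
    vals = np.full(grid.n_bins, np.nan)
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    for row in df.itertuples(index=False):
        if row.chrom not in grid.chrom_offset:
            raise KeyError(f"{path}: unknown chromosome {row.chrom!r}")
        if row.start % grid.bin_size or row.end - row.start != grid.bin_size:
            raise ValueError(
                f"{path}: interval {row.chrom}:{row.start}-{row.end} does not "
                f"align to the {grid.bin_size} bp grid"
            )
        idx = grid.bin_index(row.chrom, row.start)
        if idx < 0:
            raise ValueError(f"{path}: interval beyond grid at {row.chrom}:{row.start}")
        vals[idx] = row.value
    return vals


def infer_grid_from_bedgraph(path) -> BinGrid:
    """Reconstruct the bin grid from a per-bin bedGraph: bin size from the
    first interval, chromosome lengths from the maximal end per chromosome."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    if df.empty:
        raise ValueError(f"{path}: empty bedGraph")
    bin_size = int(df.iloc[0]["end"] - df.iloc[0]["start"])
    ends = df.groupby("chrom", sort=False)["end"].max()
    genome = GenomeSpec([(c, int(e)) for c, e in ends.items()])
    return BinGrid(genome, bin_size)


def read_counts(path, grid: BinGrid, sample: str, phase: Phase) -> BinnedCounts:
    vals = read_bedgraph(path, grid)
    vals = np.nan_to_num(vals, nan=0.0)
    return BinnedCounts(sample, phase, grid, vals.astype(np.int64))


# --------------------------------------------------------------------- BED

def write_domains_bed(path, rds: RDSet, track: SignalTrack | None = None) -> None:
    """BED6 with the domain class in the name column; score is the mean
    Z-scored RT over the domain ×1000, truncated, when a track is given."""
    with open(path, "w") as fh:
        for d in rds.domains:
            score = 0
            if track is not None:
                sl = track.grid.chrom_slice(d.chrom)
                b0, b1 = d.start // track.grid.bin_size, d.end // track.grid.bin_size
                v = track.values[sl][b0:b1]
                v = v[np.isfinite(v)]
                if v.size:
                    score = int(np.trunc(float(v.mean()) * 1000))
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.klass.value}\t{score}\t.\n")


def read_domains_bed(path, label: str = "") -> RDSet:
    doms = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            doms.append(RDomain(f[0], int(f[1]), int(f[2]), RDClass[f[3]]))
    return RDSet(label=label or Path(path).stem, domains=tuple(doms))


def write_intervals_bed(path, s: IntervalSet, name: str = ".") -> None:
    with open(path, "w") as fh:
        for chrom, start, end in s:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t.\n")


def write_truth_bed(path, plan: DomainPlan) -> None:
    """Domain tiling as BED6 (name = class); differential regions carry
    DIFF_<direction> names."""
    with open(path, "w") as fh:
        for chrom, start, end, klass in plan.domains:
            fh.write(f"{chrom}\t{start}\t{end}\t{klass.value}\t0\t.\n")
        for chrom, start, end, direction in plan.differential:
            fh.write(f"{chrom}\t{start}\t{end}\tDIFF_{direction.value}\t0\t.\n")


# -------------------------------------------------------------- annotation

def read_gene_bed(path):
    """Genes from BED6+ (chrom, start, end, name, score, strand)."""
    from .differential import GeneAnnotation

    rows, skipped = [], 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                rows.append(
                    {
                        "chrom": f[0],
                        "start": int(f[1]),
                        "end": int(f[2]),
                        "gene_id": f[3],
                        "strand": f[5] if len(f) > 5 else ".",
                    }
                )
            except (IndexError, ValueError):
                skipped += 1
    if skipped:
        log.warning("%s: skipped %d malformed rows", path, skipped)
    return GeneAnnotation(pd.DataFrame(rows))


def read_gene_gff3(path):
    """Gene feature rows from GFF3; gene_id from ID= (or gene_id=)."""
    from .differential import GeneAnnotation

    rows, skipped = [], 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                skipped += 1
                continue
            if f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                skipped += 1
                continue
            try:
                rows.append(
                    {
                        "chrom": f[0],
                        "start": int(f[3]) - 1,  # GFF3 is 1-based
                        "end": int(f[4]),
                        "gene_id": gid,
                        "strand": f[6] if f[6] in "+-" else ".",
                    }
                )
            except ValueError:
                skipped += 1
    if skipped:
        log.warning("%s: skipped %d malformed rows", path, skipped)
    return GeneAnnotation(pd.DataFrame(rows))


def read_annotation(path):
    p = str(path)
    if p.endswith((".gff", ".gff3")):
        return read_gene_gff3(path)
    return read_gene_bed(path)


# ------------------------------------------------------------------ design

def read_design(path) -> CohortDesign:
    """TSV with columns sample, condition, replicate, phase, path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition", "replicate", "phase", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design file missing columns {sorted(missing)}")
    samples = [
        SampleSpec(
            sample_id=r["sample"],
            condition=Condition[r["condition"].upper()],
            replicate=int(r["replicate"]),
            phase=Phase[r["phase"].upper()],
            path=r["path"],
        )
        for _, r in df.iterrows()
    ]
    return CohortDesign(samples)


def write_design(path, design: CohortDesign) -> None:
    pd.DataFrame(
        [
            {
                "sample": s.sample_id,
                "condition": s.condition.value,
                "replicate": s.replicate,
                "phase": s.phase.value,
                "path": s.path,
            }
            for s in design.samples
        ]
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ config

def write_config_snapshot(path, params: dict) -> None:
    """YAML snapshot of all parameters and seeds of a run."""
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def genome_to_dict(genome: GenomeSpec) -> dict:
    return {"chroms": [[n, l] for n, l in genome.chroms]}


def genome_from_dict(d: dict) -> GenomeSpec:
    return GenomeSpec([(n, int(l)) for n, l in d["chroms"]])
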