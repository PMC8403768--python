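"""End-to-end orchestration: counts -> RT tracks -> domains -> differential
calls -> profiles, with a config snapshot and a manifest for reproducibility.

A single global seed fans out to per-stage seeds by stable hashing of stage
names, so any stage can be re-run in isolation with the same randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .design import CohortDesign, Condition
from .differential import call_dependent_domains
from .genome import BinGrid
from .profiles import matrix_around, midpoints
from .segmentation import (
    RDClass,
    RDSet,
    SegmentationModel,
    decode_domains,
    domain_stats,
    fit_segmentation,
    merge_replicates,
)
from .genome import GenomeSpec
from .simulate import (
    DEFAULT_DEPTH,
    DEFAULT_EDGE_SOFTNESS,
    DEFAULT_P_EARLY,
    DEFAULT_P_LATE,
    SyntheticTruth,
    plan_genome_and_domains,
    simulate_cohort,
    stable_seed,
    truth_from_plan,
)
from .tracks import (
    BinnedCounts,
    SignalTrack,
    Stage,
    cpm_normalize,
    log2_ratio,
    loess_smooth,
    quantile_normalize,
    replicate_correlation,
    zscore,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters of a run; defaults follow the RT workflow's
    published constants where one exists (20 kb windows, ±0.5 Mb flank,
    3000 bp extension, 3 segmentation states)."""

    bin_size: int = 20_000
    span_bp: int = 300_000
    min_g1_cpm: float | None = None
    n_states: int = 3
    n_init: int = 5
    gap_tolerance: int = 2
    min_domain_bins: int = 2
    pad: int = 3000
    flank: int = 500_000
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return stable_seed(stage, base=self.seed)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RTResult:
    """Per-(condition, replicate) stage tracks plus the replicate-correlation
    matrix over smoothed tracks."""

    tracks: dict[tuple[Condition, int], dict[Stage, SignalTrack]]
    correlation: np.ndarray
    order: list[tuple[Condition, int]]


def rt_tracks_from_counts(
    counts: dict[tuple[Condition, int], tuple[BinnedCounts, BinnedCounts]],
    config: RunConfig,
) -> RTResult:
    """Run the fixed normalization chain over every S/G1 pair.

    CPM -> log2(S/G1) -> joint quantile normalization over all pairs ->
    per-chromosome Loess -> genome-wide Z-score.
    """
    order = sorted(counts, key=lambda k: (k[0].value, k[1]))
    raw: dict[tuple[Condition, int], SignalTrack] = {}
    for key in order:
        s, g1 = counts[key]
        raw[key] = log2_ratio(
            cpm_normalize(s), cpm_normalize(g1), min_g1_cpm=config.min_g1_cpm
        )
    qnormed = quantile_normalize([raw[k] for k in order])
    tracks: dict[tuple[Condition, int], dict[Stage, SignalTrack]] = {}
    smoothed = []
    for key, q in zip(order, qnormed):
        sm = loess_smooth(q, span_bp=config.span_bp)
        z = zscore(sm)
        tracks[key] = {
            Stage.RAW_LOG2: raw[key],
            Stage.QNORM: q,
            Stage.SMOOTHED: sm,
            Stage.ZSCORE: z,
        }
        smoothed.append(sm)
    corr = replicate_correlation(smoothed)
    return RTResult(tracks=tracks, correlation=corr, order=order)


def segment_conditions(
    rt: RTResult, config: RunConfig
) -> dict[Condition, tuple[SignalTrack, SegmentationModel, RDSet]]:
    """Merge replicates per condition, fit and decode the 3-state HMM."""
    out = {}
    conditions = sorted({k[0] for k in rt.order}, key=lambda c: c.value)
    for cond in conditions:
        reps = [rt.tracks[k][Stage.ZSCORE] for k in rt.order if k[0] is cond]
        merged = merge_replicates(reps)
        model = fit_segmentation(
            merged,
            n_states=config.n_states,
            seed=config.stage_seed(f"segment/{cond.value}"),
            n_init=config.n_init,
        )
        rds = decode_domains(
            model,
            merged,
            gap_tolerance=config.gap_tolerance,
            min_domain_bins=config.min_domain_bins,
            label=cond.value,
        )
        out[cond] = (merged, model, rds)
    return out


def run_pipeline(
    config: RunConfig, design: CohortDesign, outdir, grid: BinGrid | None = None
) -> Path:
    """Execute the full analysis for a design whose sample paths point at
    binned-count bedGraphs; writes every stage product plus a manifest.

    Idempotent: re-running with the same config and inputs reproduces
    byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def _stage(name):
        log.info("stage: %s", name)
        return name

    stage = _stage("load_counts")
    try:
        if grid is None:
            grid = rio.infer_grid_from_bedgraph(design.pairs()[0][2].path)
        counts = {}
        for cond, rep, s_spec, g1_spec in design.pairs():
            counts[(cond, rep)] = (
                rio.read_counts(s_spec.path, grid, s_spec.sample_id, s_spec.phase),
                rio.read_counts(g1_spec.path, grid, g1_spec.sample_id, g1_spec.phase),
            )
        stage = _stage("quantify")
        rt = rt_tracks_from_counts(counts, config)
        for (cond, rep), stages in rt.tracks.items():
            for st, track in stages.items():
                p = outdir / f"{cond.value}_rep{rep}.{st.value.lower()}.bedgraph"
                rio.write_track(p, track)
                outputs.append(p.name)
        corr_path = outdir / "replicate_correlation.tsv"
        _write_corr(corr_path, rt)
        outputs.append(corr_path.name)

        stage = _stage("segment")
        segs = segment_conditions(rt, config)
        for cond, (merged, model, rds) in segs.items():
            p = outdir / f"{cond.value}.domains.bed"
            rio.write_domains_bed(p, rds, merged)
            outputs.append(p.name)
            sp = outdir / f"{cond.value}.domain_stats.tsv"
            domain_stats(rds).to_csv(sp, sep="\t", index=False)
            outputs.append(sp.name)
            mp = outdir / f"{cond.value}.model.json"
            _write_model(mp, model)
            outputs.append(mp.name)
            tp = outdir / f"{cond.value}.merged.zscore.bedgraph"
            rio.write_track(tp, merged)
            outputs.append(tp.name)

        dep = None
        if {Condition.KO, Condition.WT, Condition.RESCUE} <= set(segs):
            stage = _stage("diffdomains")
            dep = call_dependent_domains(
                segs[Condition.KO][2], segs[Condition.WT][2], segs[Condition.RESCUE][2]
            )
            for klass, regions in dep.regions.items():
                p = outdir / f"dependent_{klass.value}.bed"
                rio.write_intervals_bed(p, regions, name=f"{klass.value}-FUS")
                outputs.append(p.name)
            sp = outdir / "dependent_summary.tsv"
            dep.summary().to_csv(sp, sep="\t", index=False)
            outputs.append(sp.name)

            stage = _stage("profiles")
            ko_track = segs[Condition.KO][0]
            for klass in RDClass:
                regions = dep.regions[klass]
                if not regions:
                    continue
                pm = matrix_around(ko_track, midpoints(regions), flank=config.flank)
                p = outdir / f"profile_{klass.value}_midpoint.tsv"
                pm.to_frame().to_csv(p, sep="\t", index=False)
                outputs.append(p.name)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "stage_seeds": {
            f"segment/{c.value}": config.stage_seed(f"segment/{c.value}")
            for c in sorted({k[0] for k in rt.order}, key=lambda c: c.value)
        },
        "samples": [s.sample_id for s in design.samples],
        "outputs": sorted(outputs),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    rio.write_config_snapshot(outdir / "config.yaml", asdict(config))
    return outdir


def simulate_to_dir(
    outdir,
    genome: GenomeSpec,
    seed: int,
    bin_size: int = 20_000,
    mean_domain_len: int = 1_000_000,
    differential_fraction: float = 0.2,
    depth_per_bin: float = DEFAULT_DEPTH,
    noise: float = 0.0,
    n_replicates: int = 2,
    p_early: float = DEFAULT_P_EARLY,
    p_late: float = DEFAULT_P_LATE,
    edge_softness: int = DEFAULT_EDGE_SOFTNESS,
) -> tuple[CohortDesign, SyntheticTruth]:
    """Simulate a full synthetic cohort to disk: per-sample count bedGraphs,
    the ground-truth BED, a design table, and a config snapshot."""
    from .design import SampleSpec
    from .tracks import Phase

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan = plan_genome_and_domains(
        genome,
        mean_domain_len,
        differential_fraction,
        seed=stable_seed("plan", base=seed),
        bin_size=bin_size,
    )
    truth = truth_from_plan(
        plan,
        p_early=p_early,
        p_late=p_late,
        edge_softness=edge_softness,
        seed=stable_seed("truth", base=seed),
    )
    counts = simulate_cohort(
        truth,
        n_replicates=n_replicates,
        depth_per_bin=depth_per_bin,
        noise=noise,
        seed=seed,
    )
    samples = []
    for (cond, rep), (s, g1) in sorted(
        counts.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
    ):
        for bc in (s, g1):
            path = outdir / f"{bc.sample}.counts.bedgraph"
            rio.write_counts(path, bc)
            samples.append(
                SampleSpec(bc.sample, cond, rep, bc.phase, str(path))
            )
    design = CohortDesign(samples)
    rio.write_design(outdir / "design.tsv", design)
    rio.write_truth_bed(outdir / "truth.bed", plan)
    rio.write_config_snapshot(
        outdir / "simulation.yaml",
        {
            "genome": rio.genome_to_dict(genome),
            "bin_size": bin_size,
            "mean_domain_len": mean_domain_len,
            "differential_fraction": differential_fraction,
            "depth_per_bin": depth_per_bin,
            "noise": noise,
            "n_replicates": n_replicates,
            "p_early": p_early,
            "p_late": p_late,
            "edge_softness": edge_softness,
            "seed": seed,
        },
    )
    return design, truth


def _write_corr(path, rt: RTResult) -> None:
    names = [f"{c.value}_rep{r}" for c, r in rt.order]
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(names) + "\n")
        for name, row in zip(names, rt.correlation):
            fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def _write_model(path, model: SegmentationModel) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "means": model.means.tolist(),
                "variances": model.variances.tolist(),
                "transmat": model.transmat.tolist(),
                "startprob": model.startprob.tolist(),
                "log_likelihood": model.log_likelihood,
                "converged": model.converged,
                "n_states": model.n_states,
                "seed": model.seed,
            },
            fh,
            indent=2,
        )
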