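import numpy as np
import pytest

from replikit import (
    BinGrid,
    GenomeSpec,
    RunConfig,
    plan_genome_and_domains,
    simulate_cohort,
    truth_from_plan,
)
from replikit.pipeline import rt_tracks_from_counts, segment_conditions

# canonical desk-scale study: 50 Mb over three chromosomes, 20 kb bins,
# ~1 Mb domains, 20% of the genome planted as KO-only RT switches
GENOME_50MB = GenomeSpec(
    [("chr1", 20_000_000), ("chr2", 16_000_000), ("chr3", 14_000_000)]
)
SEED = 1


@pytest.fixture(scope="session")
def grid_small():
    return BinGrid(GenomeSpec([("chr1", 1_000_000), ("chr2", 600_000)]), 20_000)


@pytest.fixture(scope="session")
def cohort():
    """Full synthetic study: plan, truth, counts, RT tracks, segmentations."""
    plan = plan_genome_and_domains(GENOME_50MB, 1_000_000, 0.2, seed=SEED)
    truth = truth_from_plan(plan, seed=SEED)
    counts = simulate_cohort(truth, seed=SEED)
    config = RunConfig(seed=SEED)
    rt = rt_tracks_from_counts(counts, config)
    segs = segment_conditions(rt, config)
    return {
        "plan": plan,
        "truth": truth,
        "counts": counts,
        "config": config,
        "rt": rt,
        "segs": segs,
    }


@pytest.fixture(scope="session")
def null_cohort():
    """Same study with no planted differences (KO truth ≡ WT truth)."""
    plan = plan_genome_and_domains(GENOME_50MB, 1_000_000, 0.0, seed=SEED)
    truth = truth_from_plan(plan, seed=SEED)
    counts = simulate_cohort(truth, seed=SEED)
    config = RunConfig(seed=SEED)
    rt = rt_tracks_from_counts(counts, config)
    segs = segment_conditions(rt, config)
    return {"plan": plan, "truth": truth, "rt": rt, "segs": segs}


def predicted_labels(rds, grid):
    """Per-bin 0/1/2 (ERD/MRD/LRD) codes from a decoded domain set."""
    order = {"ERD": 0, "MRD": 1, "LRD": 2}
    pred = np.full(grid.n_bins, -1)
    for d in rds.domains:
        sl = grid.chrom_slice(d.chrom)
        b0 = sl.start + d.start // grid.bin_size
        b1 = sl.start + d.end // grid.bin_size
        pred[b0:b1] = order[d.klass.value]
    return pred


def boundary_recovery(true_labels, pred_labels, grid, tol_bins=2):
    """Fraction of true class boundaries with a predicted boundary within
    tol_bins."""
    hits = total = 0
    for chrom in grid.genome.names:
        sl = grid.chrom_slice(chrom)
        tb = np.flatnonzero(np.diff(true_labels[sl])) + 1
        pb = np.flatnonzero(np.diff(pred_labels[sl])) + 1
        for b in tb:
            total += 1
            if len(pb) and np.min(np.abs(pb - b)) <= tol_bins:
                hits += 1
    return hits / total if total else 1.0
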