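"""Shared study definition for the numbered analysis scripts.

One canonical synthetic study: a 50 Mb three-chromosome genome binned at
20 kb, ~1 Mb replication domains, knockout/wildtype/rescue × two biological
replicates, and 20% of the genome planted as KO-only RT switches.
"""

from pathlib import Path

from replikit import (
    GenomeSpec,
    RunConfig,
    plan_genome_and_domains,
    simulate_cohort,
    truth_from_plan,
)
from replikit.pipeline import rt_tracks_from_counts, segment_conditions

STUDY_SEED = 1
GENOME = GenomeSpec([("chr1", 20_000_000), ("chr2", 16_000_000), ("chr3", 14_000_000)])
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study(differential_fraction: float = 0.2, seed: int = STUDY_SEED):
    """Simulate and analyze the canonical cohort; returns every stage."""
    plan = plan_genome_and_domains(GENOME, 1_000_000, differential_fraction, seed=seed)
    truth = truth_from_plan(plan, seed=seed)
    counts = simulate_cohort(truth, seed=seed)
    config = RunConfig(seed=seed)
    rt = rt_tracks_from_counts(counts, config)
    segs = segment_conditions(rt, config)
    RESULTS.mkdir(exist_ok=True)
    return {"plan": plan, "truth": truth, "counts": counts, "config": config,
            "rt": rt, "segs": segs}
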