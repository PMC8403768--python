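"""Simulate the synthetic Repli-seq cohort and summarize its ground truth.

Writes the planned domain structure and the planted differential regions to
results/, and a full on-disk run (count bedGraphs, design table, truth BED)
under scratch/ for ad-hoc inspection.
"""

import sys
from collections import Counter
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import GENOME, RESULTS, STUDY_SEED, study

from replikit.pipeline import simulate_to_dir


def main() -> None:
    st = study()
    plan = st["plan"]
    classes = Counter(k.value for _, _, _, k in plan.domains)
    sizes = pd.DataFrame(
        [{"chrom": c, "start": s, "end": e, "class": k.value, "size_bp": e - s}
         for c, s, e, k in plan.domains]
    )
    sizes.to_csv(RESULTS / "01_planned_domains.tsv", sep="\t", index=False)
    diff = pd.DataFrame(
        [{"chrom": c, "start": s, "end": e, "direction": d.value}
         for c, s, e, d in plan.differential]
    )
    diff.to_csv(RESULTS / "01_planted_differential.tsv", sep="\t", index=False)
    frac = plan.differential_set().total_length / GENOME.total_length
    print(f"planned {len(plan.domains)} domains over {GENOME.total_length/1e6:.0f} Mb "
          f"({dict(classes)})")
    print(f"planted {len(plan.differential)} differential domains = "
          f"{100*frac:.1f}% of the genome (target 20%)")
    scratch = Path(__file__).resolve().parent.parent / "scratch" / "sim"
    simulate_to_dir(scratch, GENOME, seed=STUDY_SEED)
    print(f"on-disk cohort (counts bedGraphs, design.tsv, truth.bed) -> {scratch}")


if __name__ == "__main__":
    main()
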