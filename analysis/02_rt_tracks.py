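"""Quantify replication timing: normalized, smoothed, Z-scored RT tracks.

Reports how well the estimated RT recovers the simulated truth, the
replicate concordance (Pearson on smoothed RT), and per-chromosome RT
density medians per condition.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import GENOME, RESULTS, study

from replikit import Condition, Stage, rt_density


def main() -> None:
    st = study()
    rt, truth = st["rt"], st["truth"]

    rows = []
    for (cond, rep), stages in rt.tracks.items():
        z = stages[Stage.ZSCORE]
        ok = z.mask
        rows.append(
            {
                "condition": cond.value,
                "replicate": rep,
                "spearman_vs_truth": stats.spearmanr(
                    truth.p_rep[cond][ok], z.values[ok]
                ).statistic,
                "pearson_vs_truth": stats.pearsonr(
                    truth.p_rep[cond][ok], z.values[ok]
                ).statistic,
            }
        )
    rec = pd.DataFrame(rows)
    rec.to_csv(RESULTS / "02_rt_recovery.tsv", sep="\t", index=False)
    print("RT recovery vs simulated truth (per track):")
    print(rec.to_string(index=False))

    names = [f"{c.value}_rep{r}" for c, r in rt.order]
    corr = pd.DataFrame(rt.correlation, index=names, columns=names)
    corr.to_csv(RESULTS / "02_replicate_correlation.tsv", sep="\t")
    within = [
        corr.loc[f"{c.value}_rep1", f"{c.value}_rep2"]
        for c in (Condition.KO, Condition.WT, Condition.RESCUE)
    ]
    print(f"\nwithin-condition replicate Pearson r: "
          f"{', '.join(f'{v:.3f}' for v in within)} (min {min(within):.3f})")

    dens = []
    for cond in (Condition.KO, Condition.WT, Condition.RESCUE):
        z = st["segs"][cond][0]
        for chrom in [None] + GENOME.names:
            med, _, _ = rt_density(z, None if chrom is None else [chrom])
            dens.append({"condition": cond.value,
                         "chromosome": chrom or "all", "median_z_rt": med})
    dd = pd.DataFrame(dens)
    dd.to_csv(RESULTS / "02_rt_density_medians.tsv", sep="\t", index=False)
    print("\nper-chromosome RT density medians (merged tracks):")
    print(dd.pivot(index="chromosome", columns="condition",
                   values="median_z_rt").round(3).to_string())


if __name__ == "__main__":
    main()
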