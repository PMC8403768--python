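"""Chromatin-IP MS enrichment on a synthetic spectral-count table.

330 proteins × {WT, KO} × 3 biological × 2 technical replicates; 30 planted
interactors are enriched in the WT IP (the KO IP is the negative control).
Pipeline: technical-replicate means -> WT mean-PSM ≥ 5 filter -> fold change
(≥1.3) + Welch t test (p < 0.05) hit classification.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, STUDY_SEED

from replikit.chipms import collapse_technical, enrichment_table, filter_low_psm

N_BACKGROUND, N_INTERACTORS = 300, 30


def main() -> None:
    rng = np.random.default_rng(STUDY_SEED)
    rows = []
    for i in range(N_BACKGROUND + N_INTERACTORS):
        interactor = i >= N_BACKGROUND
        lam_wt = rng.uniform(15, 40) if interactor else rng.uniform(1, 12)
        lam_ko = rng.uniform(1, 5) if interactor else lam_wt
        row = {"protein_id": ("interactor" if interactor else "background") + f"_{i}"}
        for geno, lam in (("WT", lam_wt), ("KO", lam_ko)):
            for b in (1, 2, 3):
                for t in (1, 2):
                    row[f"{geno}_b{b}_t{t}"] = float(rng.poisson(lam))
        rows.append(row)
    raw = pd.DataFrame(rows)

    collapsed = collapse_technical(raw)
    kept = filter_low_psm(collapsed)
    result = enrichment_table(kept)
    result.to_csv(RESULTS / "07_chipms_volcano.tsv", sep="\t", index=False)

    hits = result[result.hit]
    true_pos = hits.protein_id.str.startswith("interactor").sum()
    print(f"{len(raw)} proteins -> {len(kept)} pass the mean-PSM ≥ 5 filter")
    print(f"{len(hits)} hits at fold ≥ 1.3 and p < 0.05; "
          f"{true_pos} are planted interactors, "
          f"{len(hits) - true_pos} background false positives")
    surviving_interactors = kept.protein_id.str.startswith("interactor").sum()
    print(f"planted interactors surviving the abundance filter: "
          f"{surviving_interactors}/{N_INTERACTORS}")
    print("volcano-ready table -> results/07_chipms_volcano.tsv")


if __name__ == "__main__":
    main()
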