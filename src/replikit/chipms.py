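"""Chromatin-IP MS spectral-count filtering and enrichment classification.

The quantification table carries, per protein, PSM counts (or label-free
intensities) for WT and KO genotypes × three biological replicates × two
technical replicates; the KO IP is the negative control. Processing:
technical replicates are averaged per biological replicate, proteins with a
WT biological-replicate mean below 5 PSMs are dropped, and enrichment is
fold change mean(WT)/mean(KO) with a Welch t test across the three
biological replicates; a hit needs fold ≥ 1.3 and p < 0.05.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

MIN_AVG_PSM = 5.0
FOLD_THRESHOLD = 1.3
P_THRESHOLD = 0.05
ZERO_OFFSET = 0.5

_TECH_COL = re.compile(r"^(WT|KO)_b([0-9]+)_t([0-9]+)$")
_BIO_COL = re.compile(r"^(WT|KO)_b([0-9]+)$")


def collapse_technical(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates per (genotype, biological replicate).

    Input columns: ``protein_id`` plus ``{WT|KO}_b{i}_t{j}``. A missing
    technical value falls back to the present one (flagged in the log);
    both missing marks the cell NaN.
    """
    if "protein_id" not in table.columns:
        raise ValueError("table needs a protein_id column")
    cells: dict[str, list[str]] = {}
    for col in table.columns:
        m = _TECH_COL.match(col)
        if m:
            cells.setdefault(f"{m.group(1)}_b{m.group(2)}", []).append(col)
    if not cells:
        raise ValueError("no {WT|KO}_b{i}_t{j} technical-replicate columns found")
    out = table[["protein_id"]].copy()
    for cell, cols in sorted(cells.items()):
        vals = table[cols].astype(float)
        n_present = vals.notna().sum(axis=1)
        if (n_present == 1).any():
            log.warning(
                "%s: %d proteins with a single technical value",
                cell, int((n_present == 1).sum()),
            )
        out[cell] = vals.mean(axis=1, skipna=True)
    return out


def _bio_cols(table: pd.DataFrame, genotype: str) -> list[str]:
    cols = [c for c in table.columns if _BIO_COL.match(c) and c.startswith(genotype)]
    if not cols:
        raise ValueError(f"no biological-replicate columns for {genotype}")
    return sorted(cols)


def filter_low_psm(table: pd.DataFrame, min_avg: float = MIN_AVG_PSM) -> pd.DataFrame:
    """Keep proteins whose mean over the WT biological replicates is >= min_avg."""
    wt = table[_bio_cols(table, "WT")].mean(axis=1, skipna=True)
    return table[wt >= min_avg].reset_index(drop=True)


def enrichment_table(
    table: pd.DataFrame,
    fold_threshold: float = FOLD_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-protein fold change (WT/KO), t-test p value, and hit flag.

    Fold change adds a 0.5 count offset to both genotype means (the KO
    negative control is expected near zero for true interactors); the t test
    runs on the raw biological-replicate values. Proteins with all-zero
    counts are dropped; zero-variance cases get p = NaN and are never hits.
    """
    wt_cols, ko_cols = _bio_cols(table, "WT"), _bio_cols(table, "KO")
    wt = table[wt_cols].to_numpy(float)
    ko = table[ko_cols].to_numpy(float)
    keep = ~((np.nansum(wt, axis=1) == 0) & (np.nansum(ko, axis=1) == 0))
    if (~keep).any():
        log.info("dropping %d all-zero proteins", int((~keep).sum()))
    wt, ko = wt[keep], ko[keep]
    fold = (np.nanmean(wt, axis=1) + ZERO_OFFSET) / (np.nanmean(ko, axis=1) + ZERO_OFFSET)
    degenerate = (np.nanstd(wt, axis=1) == 0) & (np.nanstd(ko, axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(
            wt, ko, axis=1, equal_var=equal_var, nan_policy="omit"
        )
    p = np.where(degenerate, np.nan, res.pvalue)
    hit = (fold >= fold_threshold) & (p < p_threshold)
    out = pd.DataFrame(
        {
            "protein_id": table.loc[keep, "protein_id"].to_numpy(),
            "mean_wt": np.nanmean(wt, axis=1),
            "mean_ko": np.nanmean(ko, axis=1),
            "fold_change": fold,
            "log2_fold_change": np.log2(fold),
            "p_value": p,
            "hit": hit,
        }
    )
    return out
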