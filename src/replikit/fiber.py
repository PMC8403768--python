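"""DNA-fiber assay arithmetic: fork speed and restart fraction.

Second-pulse (CldU) track lengths measured in μm convert to kb with a
1 μm = 2.59 kb stretching factor and to speed by dividing by the 20 min
pulse. Groups are compared with Welch's unequal-variance t test; the
statistical unit is the per-experiment mean (three biological replicates of
≥150 fibers each in the assay this mirrors).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

KB_PER_UM = 2.59
PULSE_MIN = 20.0


class FiberClass(enum.Enum):
    RESTARTED = "RESTARTED"
    STALLED = "STALLED"
    NEW_ORIGIN = "NEW_ORIGIN"


@dataclass(frozen=True)
class FiberRecord:
    fiber_id: str
    first_label_um: float
    second_label_um: float
    classification: FiberClass

    def __post_init__(self):
        if self.first_label_um < 0 or self.second_label_um < 0:
            raise ValueError("fiber track lengths must be >= 0")


def fork_speed(
    track_len_um, kb_per_um: float = KB_PER_UM, pulse_min: float = PULSE_MIN
):
    """Fork speed in kb/min: ``track_len_um × kb_per_um / pulse_min``.

    Accepts a scalar or array of track lengths; all inputs must be positive.
    """
    arr = np.asarray(track_len_um, dtype=float)
    if (arr <= 0).any() or kb_per_um <= 0 or pulse_min <= 0:
        raise ValueError("fork_speed inputs must be positive")
    out = arr * kb_per_um / pulse_min
    return float(out) if np.isscalar(track_len_um) else out


def restart_fraction(records: list[FiberRecord]) -> float:
    """Percent of stalled forks that restarted: 100 × RESTARTED /
    (RESTARTED + STALLED). New origins are excluded from the denominator."""
    if not records:
        raise ValueError("no fiber records")
    restarted = sum(r.classification is FiberClass.RESTARTED for r in records)
    stalled = sum(r.classification is FiberClass.STALLED for r in records)
    if restarted + stalled == 0:
        raise ValueError("no restarted or stalled fibers (empty denominator)")
    return 100.0 * restarted / (restarted + stalled)


def compare_groups(a, b) -> dict:
    """Welch's two-sided t test between two groups of speeds.

    Returns t statistic, p value, Welch degrees of freedom, and the mean
    difference (a − b). Each group needs ≥3 values with nonzero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "df": float(res.df),
        "mean_difference": float(a.mean() - b.mean()),
    }


def read_fiber_table(path) -> list[FiberRecord]:
    """TSV with columns fiber_id, first_label_um, second_label_um, class."""
    df = pd.read_csv(path, sep="\t")
    return [
        FiberRecord(
            str(r["fiber_id"]),
            float(r["first_label_um"]),
            float(r["second_label_um"]),
            FiberClass[str(r["classification"])],
        )
        for _, r in df.iterrows()
    ]


def speed_summary(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-sample fork-speed distribution summary from second-label lengths."""
    rows = []
    for name, lengths in samples.items():
        v = fork_speed(np.asarray(lengths, float))
        rows.append(
            {
                "sample": name,
                "n_fibers": len(v),
                "mean_kb_per_min": float(np.mean(v)),
                "sd_kb_per_min": float(np.std(v, ddof=1)),
                "median_kb_per_min": float(np.median(v)),
            }
        )
    return pd.DataFrame(rows)
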