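"""Cohort design: samples mapped to condition x replicate x cell-cycle phase."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .tracks import Phase


class Condition(enum.Enum):
    KO = "KO"
    WT = "WT"
    RESCUE = "RESCUE"


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    condition: Condition
    replicate: int
    phase: Phase
    path: str = ""


@dataclass(frozen=True)
class CohortDesign:
    """Knockout / wildtype / rescue design with biological replicates.

    Every (condition, replicate) pair must contribute exactly one S-phase and
    one G1-phase sample.
    """

    samples: tuple[SampleSpec, ...] = field(default_factory=tuple)

    def __init__(self, samples) -> None:
        object.__setattr__(self, "samples", tuple(samples))
        self.validate()

    def validate(self) -> None:
        seen: dict[tuple[Condition, int], set[Phase]] = {}
        ids = set()
        for s in self.samples:
            if s.sample_id in ids:
                raise ValueError(f"duplicate sample id {s.sample_id!r}")
            ids.add(s.sample_id)
            phases = seen.setdefault((s.condition, s.replicate), set())
            if s.phase in phases:
                raise ValueError(
                    f"duplicate {s.phase.value} sample for "
                    f"({s.condition.value}, rep {s.replicate})"
                )
            phases.add(s.phase)
        for (cond, rep), phases in seen.items():
            missing = {Phase.S, Phase.G1} - phases
            if missing:
                raise ValueError(
                    f"({cond.value}, rep {rep}) is missing "
                    f"{sorted(p.value for p in missing)} sample(s)"
                )

    def pairs(self) -> list[tuple[Condition, int, SampleSpec, SampleSpec]]:
        """(condition, replicate, S sample, G1 sample) tuples in stable order."""
        by_key: dict[tuple[Condition, int], dict[Phase, SampleSpec]] = {}
        for s in self.samples:
            by_key.setdefault((s.condition, s.replicate), {})[s.phase] = s
        out = []
        for (cond, rep), d in sorted(
            by_key.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
        ):
            out.append((cond, rep, d[Phase.S], d[Phase.G1]))
        return out

    @property
    def conditions(self) -> list[Condition]:
        seen = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen
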