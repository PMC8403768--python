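"""Synthetic Repli-seq generator: parametric RT truth over a toy genome.

The model: each bin has a true replication fraction ``p_rep`` — the fraction
of S-phase cells in which that bin has already been replicated (cells are
assumed uniformly distributed through S phase, so early loci have high
``p_rep``). G1-phase coverage is flat (single copy everywhere, modulo
mappability); S-phase coverage is proportional to ``1 + p_rep`` because a
replicated bin is present in two copies. The expected raw S/G1 count ratio
in a bin is therefore proportional to ``1 + p_rep``, the copy-number basis
of Sort-Seq RT.

Condition-dependent biology is planted as whole domains whose RT switches in
the knockout only (ADVANCED toward early, DELAYED toward late); wildtype and
rescue share one truth, so the rescue restores the wildtype RT program
exactly.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass

import numpy as np

from .design import Condition
from .genome import BinGrid, GenomeSpec
from .intervals import IntervalSet
from .tracks import BinnedCounts, Phase

DEFAULT_DEPTH = 200.0
DEFAULT_P_EARLY = 0.9
DEFAULT_P_LATE = 0.1
DEFAULT_EDGE_SOFTNESS = 1
DEFAULT_CLASS_JITTER = 0.15
DEFAULT_LIBRARY_ASYMMETRY = 0.2
_MIN_DOMAIN_BINS = 3


class DomainClass(enum.Enum):
    EARLY = "EARLY"
    MID = "MID"
    LATE = "LATE"


class SwitchDirection(enum.Enum):
    ADVANCED = "ADVANCED"
    DELAYED = "DELAYED"


@dataclass(frozen=True)
class DomainPlan:
    """Ground-truth domain tiling plus planted differential regions (KO only)."""

    genome: GenomeSpec
    bin_size: int
    domains: tuple[tuple[str, int, int, DomainClass], ...]
    differential: tuple[tuple[str, int, int, SwitchDirection], ...]

    def differential_set(self) -> IntervalSet:
        return IntervalSet([(c, s, e) for c, s, e, _ in self.differential])


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-condition, per-bin true replication fraction with its plan."""

    grid: BinGrid
    p_rep: dict[Condition, np.ndarray]
    plan: DomainPlan

    def true_labels(self, condition: Condition) -> np.ndarray:
        """Per-bin EARLY/MID/LATE class codes (0/1/2) implied by p_rep terciles
        of the planted levels: the class whose level is nearest."""
        p = self.p_rep[condition]
        levels = np.array(
            [p.max(), (p.max() + p.min()) / 2.0, p.min()]
        )  # EARLY, MID, LATE
        return np.argmin(np.abs(p[:, None] - levels[None, :]), axis=1)


def stable_seed(*parts, base: int = 0) -> int:
    """Derive a sub-2^31 seed from a base seed and a sequence of labels."""
    h = hashlib.sha256(("/".join(str(p) for p in parts) + f"#{base}").encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def plan_genome_and_domains(
    genome: GenomeSpec,
    mean_domain_len: int,
    differential_fraction: float,
    seed: int,
    bin_size: int = 20_000,
) -> DomainPlan:
    """Tile each chromosome with alternating-class domains and mark a subset
    as differential.

    Domain lengths are geometric around ``mean_domain_len`` (floor 3 bins),
    aligned to bin boundaries. The class sequence cycles EARLY, MID, LATE,
    MID so mid domains sit at early/late transitions. Whole domains are
    drawn at random until the differential target length is reached; the
    total matches ``differential_fraction`` of the genome to within one
    domain's length. Switch direction is sampled 50/50, except that a
    direction that would leave the domain's RT unchanged is flipped.
    """
    mean_bins = mean_domain_len / bin_size
    if mean_bins < 5:
        raise ValueError("mean_domain_len must be >= 5 bins")
    if not 0 <= differential_fraction < 1:
        raise ValueError("differential_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cycle = [
        DomainClass.EARLY,
        DomainClass.MID,
        DomainClass.LATE,
        DomainClass.MID,
    ]
    domains: list[tuple[str, int, int, DomainClass]] = []
    for chrom, length in genome.chroms:
        n_bins = length // bin_size
        phase = int(rng.integers(len(cycle)))
        pos = 0
        while pos < n_bins:
            draw = _MIN_DOMAIN_BINS + rng.geometric(
                1.0 / max(1.0, mean_bins - _MIN_DOMAIN_BINS)
            ) - 1
            end = min(n_bins, pos + int(draw))
            if n_bins - end < _MIN_DOMAIN_BINS:
                end = n_bins  # absorb a too-short remainder
            domains.append(
                (chrom, pos * bin_size, end * bin_size, cycle[phase % len(cycle)])
            )
            phase += 1
            pos = end
    target = differential_fraction * genome.total_length
    differential: list[tuple[str, int, int, SwitchDirection]] = []
    if target > 0:
        order = rng.permutation(len(domains))
        total = 0
        chosen = []
        for i in order:
            length = domains[i][2] - domains[i][1]
            # take a domain only if it moves the total closer to the target
            if abs(total + length - target) < abs(total - target):
                chosen.append(i)
                total += length
        if abs(total - target) > max(
            (e - s for _, s, e, _ in domains), default=0
        ):
            raise ValueError(
                f"differential_fraction {differential_fraction} cannot be met "
                f"with whole domains (got {total} of {target:.0f} bp)"
            )
        for i in chosen:
            chrom, start, end, klass = domains[i]
            direction = (
                SwitchDirection.ADVANCED
                if rng.random() < 0.5
                else SwitchDirection.DELAYED
            )
            # a no-op switch is not a planted switch: flip it
            if klass is DomainClass.EARLY:
                direction = SwitchDirection.DELAYED
            elif klass is DomainClass.LATE:
                direction = SwitchDirection.ADVANCED
            differential.append((chrom, start, end, direction))
    differential.sort()
    return DomainPlan(
        genome=genome,
        bin_size=bin_size,
        domains=tuple(domains),
        differential=tuple(differential),
    )


_CLASS_LEVEL = {
    DomainClass.EARLY: 1.0,
    DomainClass.MID: 0.5,
    DomainClass.LATE: 0.0,
}


def truth_from_plan(
    plan: DomainPlan,
    p_early: float = DEFAULT_P_EARLY,
    p_late: float = DEFAULT_P_LATE,
    edge_softness: int = DEFAULT_EDGE_SOFTNESS,
    class_jitter: float = DEFAULT_CLASS_JITTER,
    seed: int = 0,
) -> SyntheticTruth:
    """Per-bin replication fractions for WT/RESCUE and KO.

    Each domain's timing is drawn from its class band: EARLY domains sit in
    ``[p_early - class_jitter·gap, p_early]``, LATE domains in
    ``[p_late, p_late + class_jitter·gap]`` and MID domains symmetrically
    around the midpoint, with ``gap = p_early - p_late`` — replication
    timing is continuous in real genomes, and domains within one class do
    not share one exact timing. ``class_jitter=0`` gives the idealized
    three-level truth. The knockout truth moves planted differential
    domains into the EARLY band (ADVANCED) or the LATE band (DELAYED)
    before edge ramping, reusing each domain's own band draw so the planted
    switch is the only KO/WT difference. Domain transitions are linearly
    ramped over ``edge_softness`` bins.
    """
    if not (0 <= p_late < p_early <= 1):
        raise ValueError("need 0 <= p_late < p_early <= 1")
    if edge_softness < 0:
        raise ValueError("edge_softness must be >= 0")
    if not 0 <= class_jitter <= 0.25:
        raise ValueError("class_jitter must be in [0, 0.25]")
    rng = np.random.default_rng(seed)
    gap = p_early - p_late
    mid = (p_early + p_late) / 2.0

    def level(klass: DomainClass, u: float) -> float:
        if klass is DomainClass.EARLY:
            return p_early - u * class_jitter * gap
        if klass is DomainClass.LATE:
            return p_late + u * class_jitter * gap
        return mid + (u - 0.5) * class_jitter * gap

    grid = BinGrid(plan.genome, plan.bin_size)
    base = np.empty(grid.n_bins, dtype=float)
    domain_u: dict[tuple[str, int], float] = {}
    for chrom, start, end, klass in plan.domains:
        u = float(rng.random())
        domain_u[(chrom, start)] = u
        off = grid.chrom_offset[chrom]
        sl = slice(off + start // plan.bin_size, off + end // plan.bin_size)
        base[sl] = level(klass, u)
    ko = base.copy()
    for chrom, start, end, direction in plan.differential:
        off = grid.chrom_offset[chrom]
        sl = slice(off + start // plan.bin_size, off + end // plan.bin_size)
        target = (
            DomainClass.EARLY
            if direction is SwitchDirection.ADVANCED
            else DomainClass.LATE
        )
        ko[sl] = level(target, domain_u[(chrom, start)])

    def ramp(v: np.ndarray) -> np.ndarray:
        if edge_softness == 0:
            return v
        w = edge_softness + 1
        kern = np.ones(w) / w
        out = v.copy()
        for chrom in grid.genome.names:
            sl = grid.chrom_slice(chrom)
            padded = np.pad(v[sl], (w, w), mode="edge")
            out[sl] = np.convolve(padded, kern, mode="same")[w:-w]
        return out

    wt = ramp(base)
    return SyntheticTruth(
        grid=grid,
        p_rep={Condition.WT: wt, Condition.RESCUE: wt.copy(), Condition.KO: ramp(ko)},
        plan=plan,
    )


def simulate_counts(
    truth: SyntheticTruth,
    condition: Condition,
    replicate: int,
    depth_per_bin: float = DEFAULT_DEPTH,
    noise: float = 0.0,
    seed: int = 0,
    library_asymmetry: float = DEFAULT_LIBRARY_ASYMMETRY,
    mappability: np.ndarray | None = None,
) -> tuple[BinnedCounts, BinnedCounts]:
    """Draw one (S, G1) sample pair of per-bin read counts.

    G1 counts are Poisson around ``depth_per_bin``; S counts are Poisson
    around ``depth_per_bin * (1 + p_rep) / c`` with ``c`` the genome-mean
    copy number, so S and G1 library sizes are comparable. ``noise > 0``
    switches to negative-binomial draws with variance ``mu + noise * mu^2``.
    S and G1 library sizes are independently perturbed by up to
    ``library_asymmetry`` (±20% by default) so CPM scaling is load-bearing.
    Deterministic under a fixed seed.
    """
    if depth_per_bin <= 0:
        raise ValueError("depth_per_bin must be positive")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    p = truth.p_rep[condition]
    rng = np.random.default_rng(seed)
    m = np.ones_like(p) if mappability is None else np.asarray(mappability, float)
    if m.shape != p.shape or (m < 0).any():
        raise ValueError("mappability must be non-negative, one value per bin")
    lib_s, lib_g1 = 1.0 + library_asymmetry * rng.uniform(-1, 1, size=2)
    copy = 1.0 + p
    c = float(np.mean(copy * m) / np.mean(m))
    mu_g1 = depth_per_bin * lib_g1 * m
    mu_s = depth_per_bin * lib_s * m * copy / c

    def draw(mu: np.ndarray) -> np.ndarray:
        if noise == 0:
            return rng.poisson(mu)
        r = 1.0 / noise
        return rng.negative_binomial(r, r / (r + mu))

    sid = f"{condition.value}_rep{replicate}"
    s = BinnedCounts(f"{sid}_S", Phase.S, truth.grid, draw(mu_s))
    g1 = BinnedCounts(f"{sid}_G1", Phase.G1, truth.grid, draw(mu_g1))
    return s, g1


def toy_gene_annotation(plan: DomainPlan, gene_fraction: float = 0.5):
    """One synthetic gene per planned domain, centered in it, spanning
    ``gene_fraction`` of the domain, with alternating strand.

    Gene ids encode the host domain (``gene_<chrom>_<start>``) so planted
    differential domains map directly to their genes.
    """
    import pandas as pd

    from .differential import GeneAnnotation

    rows = []
    for i, (chrom, start, end, klass) in enumerate(plan.domains):
        mid = (start + end) // 2
        half = max(1, int((end - start) * gene_fraction / 2))
        rows.append(
            {
                "chrom": chrom,
                "start": mid - half,
                "end": mid + half,
                "gene_id": f"gene_{chrom}_{start}",
                "strand": "+" if i % 2 == 0 else "-",
            }
        )
    return GeneAnnotation(pd.DataFrame(rows))


def simulate_cohort(
    truth: SyntheticTruth,
    n_replicates: int = 2,
    conditions: tuple[Condition, ...] = (Condition.KO, Condition.WT, Condition.RESCUE),
    depth_per_bin: float = DEFAULT_DEPTH,
    noise: float = 0.0,
    seed: int = 0,
    library_asymmetry: float = DEFAULT_LIBRARY_ASYMMETRY,
) -> dict[tuple[Condition, int], tuple[BinnedCounts, BinnedCounts]]:
    """Simulate the full cohort; per-sample seeds are derived stably from the
    global seed so any sample can be regenerated in isolation."""
    out = {}
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            out[(cond, rep)] = simulate_counts(
                truth,
                cond,
                rep,
                depth_per_bin=depth_per_bin,
                noise=noise,
                seed=stable_seed("counts", cond.value, rep, base=seed),
                library_asymmetry=library_asymmetry,
            )
    return out
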