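# replikit

Replication-timing (RT) analysis for Repli-seq / Sort-Seq experiments, built
around a knockout / wildtype / rescue design. The package turns sorted
S-phase and G1-phase read counts into normalized RT tracks, segments them
into early / mid / late replication domains (ERD/MRD/LRD), calls the
domains whose replication program depends on the perturbed factor, and
computes RT-signal profiles around domains and genes. A synthetic Repli-seq
generator with planted ground truth makes every stage testable at desk
scale. Two small companion modules cover DNA-fiber fork-speed arithmetic
and chromatin-IP mass-spectrometry enrichment filtering.

It is written for genomicists who have binned S/G1 read counts (bedGraph)
and want a reproducible, scriptable version of the standard copy-number RT
workflow, and for methodologists who want a simulation sandbox in which the
whole pipeline can be validated against known truth.

## The model

In an asynchronous population, a locus replicated early in S phase is
present in two copies in most S-phase cells, a late locus in one, so the
per-window read-depth ratio between sorted S and G1 fractions encodes
replication timing (higher ratio ⇒ earlier replication). With p(x) the
fraction of S-phase cells in which window x has replicated,

    E[S(x)] / E[G1(x)]  ∝  1 + p(x)

The pipeline, on a fixed 20 kb grid:

    counts → CPM → log2(S/G1) → quantile normalization (all samples jointly)
           → per-chromosome Loess (span 300 kb, degree-1 tricube)
           → genome-wide Z-score

Low-coverage windows are masked (NaN), never pseudocounted, and masking is
contagious through every stage. Replicates are merged per condition and the
Z-scored RT profile is segmented by a 3-state Gaussian hidden Markov model
(EM + Viterbi, states relabeled so mean(ERD) > mean(MRD) > mean(LRD)).
Condition-dependent domains are called per class C by bedtools-style
base-level set algebra:

    dep_C = KO_C − (WT_C ∩ RESCUE_C)

reported as a percent of each KO class and of the segmented genome.
Profiles around domain midpoints (±0.5 Mb) and strand-oriented TSS / TES /
gene-center anchors are computed computeMatrix-style at bin resolution.

Fork speed from fiber assays uses the printed constants: second-pulse track
length (μm) × 2.59 kb/μm ÷ 20 min. IP-MS spectral counts are averaged over
technical replicates, filtered at mean WT PSM ≥ 5, and classified as
enriched at fold change ≥ 1.3 (WT/KO) with Welch-t p < 0.05.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
50 Mb genome (three chromosomes, ~1 Mb domains, two replicates per
condition, 20% of the genome planted as KO-only RT switches) and write
their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_rt_tracks.py
python analysis/03_segment_domains.py
python analysis/04_differential_domains.py
```

`02_rt_tracks.py` prints, among other things:

```
within-condition replicate Pearson r: 0.975, 0.975, 0.972 (min 0.972)
```

smoothed RT is highly reproducible between biological replicates, and each
track correlates with the simulated truth at Pearson r ≈ 0.98.
`04_differential_domains.py` prints:

```
class  dependent_bp  percent_of_class  percent_of_genome
  ERD       7160000             32.84              14.32
  MRD        560000              5.16               1.12
  LRD       4580000             26.41               9.16

planted differential genome: 22.5%  |  called: 24.6%  |  Jaccard = 0.897
```

the intersect-then-subtract calls recover the planted 22.5% differential
genome with base-level Jaccard 0.90; a matched null cohort (no planted
switches) yields ~3% called coverage, the boundary-jitter floor of the
procedure.

The same stages are available as a CLI (`replikit simulate | quantify |
segment | diffdomains | profile | fiber | chipms | demo`), e.g.
`replikit demo --out demo_run --seed 1`.

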