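# Methods

## Replication-timing model and quantification

Replication timing is measured as relative DNA copy number between sorted
S- and G1-phase fractions. For a window x, let p(x) ∈ [0, 1] be the
fraction of S-phase cells in which x has replicated (cells assumed
uniformly distributed through S phase). G1 coverage is flat; S coverage is
proportional to 1 + p(x); the expected raw S/G1 count ratio is proportional
to 1 + p(x). The pipeline estimates a monotone transform of p:

1. **Binning** — read start positions counted into fixed windows
   (`bin_size`, default 20,000 bp, 0-based half-open; a trailing partial
   window is dropped).
2. **CPM** — per-sample library-size scaling to counts per million.
3. **log2 ratio** — log2(S_cpm / G1_cpm). Windows with G1 CPM below
   `min_g1_cpm` (default 25% of the median G1 CPM) or zero S CPM are masked
   NaN. No pseudocount is used: a pseudocount biases exactly the
   domain-boundary windows the segmentation cares about, whereas masking
   removes them honestly. Masked windows never contribute to any later
   statistic.
4. **Quantile normalization** — jointly over all samples of all conditions,
   on windows unmasked in every track, so inter-condition RT distributions
   are directly comparable. The reference is the rank-wise mean of sorted
   values. Tied values are ranked stably by genomic position, which makes
   every output an exact permutation of the reference (sorted value
   vectors of all samples are bit-identical); `ties="average"` switches to
   the tie-averaging dialect. Windows unmasked in one sample but masked in
   another are mapped through a monotone interpolation of that sample's
   value→reference map, preserving per-sample masks exactly. Normalization
   is applied to the log2 ratios (whether to normalize before or after the
   ratio is a genuinely open choice; the ratio scale is where
   cross-sample comparability matters, and the choice is recorded in the
   config snapshot).
5. **Loess smoothing** — per chromosome, degree-1 local regression with
   tricube weights (statsmodels `lowess`), evaluated at unmasked window
   midpoints. The span is expressed in bp (`span_bp`, default 300,000 ⇒ 15
   windows) and converted to a nearest-neighbour fraction per chromosome,
   keeping the smoothing scale independent of chromosome length.
   Robustness iterations are disabled (`it=0`): they divide by the median
   absolute residual, which vanishes on locally constant signal. A
   chromosome with fewer than 3 unmasked windows is left unsmoothed with a
   warning. Local linear fits reproduce constants and straight lines to
   numerical precision, which the tests assert at 1e-6.
6. **Z-score** — genome-wide (not per-chromosome) standardization with
   sample SD (n−1), so profiles are comparable across chromosomes and
   samples.

Replicate concordance is pairwise-complete Pearson correlation on smoothed
tracks; RT density summaries (per-chromosome median + Gaussian-kernel
density on a fixed lattice) use the merged Z-scored tracks.

## Domain segmentation

The two biological replicates are merged (per-window mean over unmasked
values) and the merged Z-scored smoothed track is segmented by a 3-state
Gaussian HMM (hmmlearn), one emission per 20 kb window — the native
resolution of the RT signal; nothing below the window size is informative.
Fitting: EM over all maximal unmasked runs, initialized at the data's
tercile means with self-transition 0.98, `n_init = 5` restarts that scale
the spread of the initial means by {1.0, 0.6, 0.8, 1.2, 1.4} around their
center, best log-likelihood wins, `max_iter = 500`, `tol = 1e-4`. The
deterministic spread-scaled restarts make the fit exactly reproducible and
sign-equivariant: segmenting the negated track swaps ERD and LRD labels
exactly. States are relabeled post-fit by descending mean: ERD > MRD > LRD,
so the label is the RT level, not the fit order. Decoding is Viterbi per
unmasked run; label runs shorter than `min_domain_bins` (default 2) are
absorbed into the larger flanking run (single-window flickers are almost
always emission noise at this SNR); domains continue across masked gaps of
at most `gap_tolerance` (default 2) windows when the flanking labels agree,
and split at chromosome boundaries and longer gaps. Non-convergence
returns the best iterate with a warning flag rather than failing.

## Condition-dependent domains

For each class C, dependent regions are `KO_C − (WT_C ∩ RESCUE_C)` at base
resolution (sorted-array sweep algebra, validated exactly against a
per-base bitmap oracle). The subtraction runs in this orientation because
the result is meant to live in the knockout's segmentation — RT states that
exist without the factor and are not shared by both wildtype and rescue;
the opposite orientation is available via `subtract_from_ko=False`.
Class correspondence is by identical label only. Percent-of-class uses the
KO class length as denominator and percent-of-genome the total KO segmented
length, making the two summary rings self-consistent. For gene extraction
the dependent regions are extended 3,000 bp on both ends (clipped,
re-merged) and genes overlapping ≥1 base are reported (half-open
semantics: touching is not overlapping).

## Signal profiles

Reference-point matrices: one row per anchor, one column per window offset
across ±`flank` (default 500,000 bp ⇒ 50 columns at 20 kb). Lookup is
nearest-window with no interpolation, matching binned-track practice.
Minus-strand anchors are reported 5′→3′ (rows reversed); strand-oriented
averaging can be disabled by passing unstranded anchors. Out-of-chromosome
cells are NaN; column means ignore NaN. Heat-map row order is by row mean,
descending. TSS is the 5′ end by strand (minus strand: span end − 1), TES
the 3′ end, gene center the floor midpoint.

## Synthetic Repli-seq generator

The generator emulates the study conditions the analysis is designed for:
a 50 Mb toy genome (three chromosomes), domains tiled with geometric
lengths around `mean_domain_len` (default 1 Mb, floor 3 windows) cycling
EARLY, MID, LATE, MID so mid domains sit at the early/late transitions;
two biological replicates for each of KO, WT and RESCUE.

- **Truth**: EARLY windows get `p_early` (default 0.9), LATE `p_late`
  (default 0.1), MID the midpoint. Each domain's level is drawn from a
  band below/above its class level (`class_jitter`, default 0.15 of the
  early−late gap): replication timing is continuous in real genomes and
  same-class domains do not share one exact timing; `class_jitter=0`
  recovers the idealized three-level truth. Transitions are linearly
  ramped over `edge_softness` windows (default 1 — sharp-ish boundaries).
- **Planted differences**: whole domains totalling `differential_fraction`
  of the genome (default 0.2, met to within one domain) switch in KO only:
  ADVANCED moves the domain into the EARLY band, DELAYED into the LATE
  band, reusing the domain's own band draw so the switch is the only
  KO/WT difference. Directions are sampled 50/50, except that a direction
  leaving the domain unchanged (DELAYED on LATE, ADVANCED on EARLY) is
  flipped — a no-op is not a planted switch. RESCUE truth is identical to
  WT.
- **Counts**: G1 ~ Poisson(depth × lib), S ~ Poisson(depth × lib ×
  (1+p)/c) with c the genome-mean copy number so library sizes are
  comparable; `noise > 0` switches to negative binomial with variance
  μ + noise·μ². Per-sample library sizes are perturbed by ±20% by default
  so the CPM step is load-bearing. Default depth is 200 reads per 20 kb
  window (≈30M mapped reads scaled to a human genome — the depth class of
  a typical Sort-Seq run; the real study does not publish a per-window
  depth, so this is a package choice, not a calibration). An optional
  per-window mappability multiplier exists to stress quantile
  normalization; it is uniform by default.

What the generator does **not** emulate: GC/mappability bias structure,
read-level artifacts (it draws binned counts directly), S-phase substages,
chromosome-scale copy-number aberrations, and cell-cycle sorting impurity.
Passing tests therefore demonstrate correctness of the estimators under
the copy-number model, not robustness to every artifact of real libraries.

Seeds: a single global seed fans out to per-stage and per-sample seeds by
stable SHA-256 hashing of stage names (all below 2^31), so any sample or
stage can be regenerated in isolation and whole runs are byte-identical
under a fixed seed.

## Side modules

- **Fiber**: speed = track μm × 2.59 kb/μm ÷ 20 min (strictly monotone,
  homogeneous of degree 1). Restart fraction = 100 × restarted /
  (restarted + stalled); new origins excluded. Group comparison is Welch's
  unequal-variance two-sided t test on per-experiment means (three
  experiments of ≥150 fibers), reporting t, p, Welch df and the mean
  difference. Fiber classification is taken as input; image analysis is
  out of scope.
- **IP-MS**: technical replicates averaged per biological replicate (a
  single present value is used as-is and flagged); proteins kept when the
  WT biological-replicate mean PSM is ≥ 5; fold change =
  (mean WT + 0.5)/(mean KO + 0.5) — the offset keeps fold changes finite
  when the knockout negative control is zero and is **not** applied to the
  t test, which runs on the raw replicate values (unequal-variance by
  default, `equal_var` exposed). Hits need fold ≥ 1.3 and p < 0.05;
  zero-variance proteins get p = NaN and are never hits. The module
  operates on whichever quantification column layout the user provides
  (PSM counts by default).

## Numerical choices and degenerate inputs

- Stage tags on tracks enforce the fixed pipeline order; out-of-order
  calls raise.
- Quantile normalization requires ≥2 tracks and ≥2 jointly unmasked
  windows; Z-scoring requires ≥2 unmasked windows and nonzero SD; CPM
  requires a nonzero library.
- The HMM requires ≥100 unmasked windows; emission variances are floored
  by hmmlearn's `min_covar`, so noiseless block inputs fit cleanly and are
  decoded exactly.
- Interval algebra is closed over canonical sets (sorted, merged,
  half-open); empty sets behave as identities/annihilators; Jaccard of two
  empty sets is defined as 0.

## Known limitations

- Spearman correlation between the *discrete-ish* simulated truth and the
  continuous smoothed RT estimate is structurally depressed by ties and by
  smoothing bleed at domain boundaries: with a noiseless input the spec'd
  300 kb span caps it at ≈0.97, and at the default depth the pipeline
  reaches ≈0.93 while Pearson r is ≈0.98. This is a property of the
  statistic on piecewise-constant-plus-band truth, not an estimator
  defect; the acceptance script reports both.
- With three independently segmented conditions, Viterbi boundary jitter
  (~1 window sd) leaves ~2–3% of the genome as spurious dependent-call
  slivers in a null cohort with no true differences. The set-algebra
  procedure deliberately applies no minimum-size filter, so this floor is
  reported rather than hidden; differences below it are not interpretable.
- Segmentation operates at window resolution; boundaries are never refined
  below 20 kb.
- The differential caller uses the merged-track segmentation per
  condition; replicate-level domain reproducibility is not enforced.
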