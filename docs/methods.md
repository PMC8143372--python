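# Methods

## The measurement model

Shallow whole-genome sequencing of plasma cell-free DNA (~0.1×) supports
copy-number inference by read counting but not point-mutation calling. The
plasma sample is a mixture: a fraction `tf` (the tumor fraction) of
fragments derives from tumor cells at local copy number `c`, the rest from
normal cells at 2 copies. The expected log2 ratio of a region relative to a
diploid baseline is therefore

    expected_log2(tf, c) = log2((tf·c + (1 − tf)·2) / 2),

the quantity around which the whole package is organized: the simulator's
forward model, the focal-calling thresholds (0.58 ≈ one extra copy at full
tumor content) and the tumor-fraction estimator's emission means all use it.
It is clipped at a configurable floor (default −8) so a homozygous deletion
at `tf = 1` stays finite.

## Profiling chain

Reads are counted in non-overlapping 50 kb windows (0-based half-open;
terminal windows may be shorter and are retained but length-down-weighted in
segmentation). Normalization proceeds in three steps:

1. **Total-count** — each bin count divided by the sample total, removing
   depth differences. A consequence used later: every bin is implicitly
   measured against the sample's mean copy number, so an aberrant genome
   shifts neutral bins off zero.
2. **GC correction** — a LOESS fit of ratio on GC fraction (span 0.3),
   divided out. The fit is two-pass: bins whose first-pass residual exceeds
   2.5 robust SDs in log space — typically bins inside genuine copy-number
   events — are dropped and the curve refit on the remainder, so broad
   aberrations cannot bend the bias estimate. The fitted curve is floored at
   1e-6 of its median.
3. **Control normalization** — log2 of the corrected ratio against the
   per-bin median of a healthy-control panel processed identically, removing
   residual position effects. Bins that are unmappable (including the
   PAR-style mask), or whose panel baseline is at the floor, are flagged
   unusable and excluded from segmentation. Applying control normalization
   twice is an error, never a silent double-application.

Segmentation is an exact optimal-partitioning dynamic program minimizing the
length-weighted within-segment sum of squares plus a per-change-point
penalty `sigma² · chi2_isf(alpha/n, 1)` (default alpha = 0.01, minimum
segment 3 bins), with sigma a median-absolute-successive-difference
estimate. The Bonferroni-style penalty makes alpha the approximate
probability of any spurious breakpoint on a flat chromosome. Because the
search is exact, its cost equals that of an exhaustive optimal-partition
oracle by construction; the test suite verifies this with an independent
recursive implementation.

For coarse analyses (1 Mb tumor-fraction bins), normalization and GC
correction run at the native 50 kb bins — where the LOESS has the most
points and outlier trimming is reliable — and the resulting log2 ratios are
averaged into 1 Mb windows afterwards (a window is usable when at least a
third of its member bins are). Rebinned raw counts (`rebin`) remain
available and conserve totals exactly.

## Focal calling

Focal events are segments standing out of their local context, as opposed to
arm-level changes. The amplification rule set: length < 20 Mb; mean log2
> 0.2; contains ≥ 1 and ≤ 100 genes; stands 0.2 above the length-weighted
mean log2 of the segments in the 20 Mb flanks on both sides if it contains a
known driver gene, 0.58 above otherwise; ≤ 50% covered by segmental
duplications; and no reciprocal-50% match to a known copy-number
polymorphism. Deletions mirror this below −0.2 with a single 0.2 neighbor
delta and require a gene recurrently affected by deletions (default
CDKN2A, RB1, PTEN). Decisions where the rules leave room:

* "contains a gene" means ≥ 1 bp overlap; "not >100 genes" means 101 fails.
* The polymorphism veto uses the conventional reciprocal-50% match rather
  than literal any-overlap (which would veto nearly everything given the
  density of polymorphism catalogs); the mode and threshold are arguments.
* Both the absolute log2 rule and the neighbor-delta rule must hold
  independently; elevated flanks therefore suppress calls.
* At chromosome edges the available flank(s) are used; a segment with no
  neighbors at all falls back to the chromosome-wide mean excluding itself,
  and with nothing to compare against, to the absolute level.
* Criteria are checked in the order size → log2 → gene content → neighbor
  delta → segdup → polymorphism with short-circuiting; the order is visible
  only in the per-criterion record attached to each event, never in the
  called set.

Resistance-related SCNAs (rrSCNAs) are the subset of focal events hitting a
curated, direction-aware gene list (amplifications: EGFR, ERBB2, MET, CDK4,
CDK6, MDM2, AKT2, PIK3CA; deletions: CDKN2A, RB1), user-overridable.

## Tumor fraction

A deliberately desk-scale estimator, not a reimplementation of a full
production tool (no subclonal states, no ploidy prior search): on the 1 Mb
log2 ratios, a grid over tf (step 0.005, range 0–0.6) scores a 7-state HMM
(copy numbers 0–6) by Viterbi path likelihood. Emission means are
`expected_log2(tf, c)` plus a global offset equal to minus the log2 of the
decoded mean mixture copy number — the self-consistent correction for
total-count normalization — iterated to convergence (≤ 4 passes). Emissions
are Gaussian with a shared scale from the MAD of the data (floored at
0.015); self-transition probability is 0.99; a per-bin state prior decaying
at 0.5 nats per copy away from diploid resolves the scaling degeneracy
between (tf, c) and (tf/2, 2c−2). Ties on the grid break toward the smaller
tf, so an aberration-free genome reports the grid floor. Samples below 3%
tumor fraction are below the reliable detection threshold for focal events;
they are flagged non-detectable and rendered `<3.0%` in cohort tables (the
numeric estimate is retained internally).

## Patient annotation and cohort rules

ddPCR positivity is strictly > 1 mutant copy per mL, for every assay. A
patient counts as activating-mutation-positive when any of exon-19
deletion / L858R / L861Q is positive. The evaluability gate excludes a
patient from outcome analyses when the pre-treatment sample has TF < 5% AND
no focal SCNAs of any kind: such a sample may simply lack tumor signal, so
absence of rrSCNAs cannot be asserted. The gate deliberately uses all SCNAs,
not only rrSCNAs — a low-TF sample with some SCNA visibly carries tumor
signal. Censored `<3.0%` values count as below 5%.

Rank statistics need a numeric stand-in for censored TF values: they enter
at a common 2.9 (percent), sharing an average rank. Both group medians of
the bundled cohort sit well above 2.9, so the medians are invariant to the
exact stand-in; the rank correlation shifts by less than 0.01 across
stand-ins in (0, 3).

## Statistics

Association tests on 2×2 tables use the Pearson chi-square without
continuity correction (df = 1); Fisher's exact test (two-sided, by summing
hypergeometric probabilities ≤ that of the observed table) is exposed
alongside, and on the bundled response table the two give 0.076 and 0.105
respectively — the package defaults to the chi-square for this comparison.
Mann–Whitney U is exact for tie-free groups of ≤ 8, otherwise the
tie-corrected normal approximation. Survival uses lifelines: Kaplan–Meier
(median = earliest time with S(t) ≤ 0.5, undefined when the curve never
reaches it), the standard log-rank test, and Cox proportional hazards with
Efron tie handling, fit to a precision at which the Efron partial-likelihood
score at the reported optimum vanishes below 1e-6 (verified independently).
Non-convergence is reported as a flagged result. Stepwise backward
elimination repeatedly drops the covariate with the largest Wald p above the
removal threshold (default 0.10, exposed); an empty retained set is a valid,
reported outcome. All p-values are two-sided.

Selection-consistency simulations run elimination at the stricter
conventional threshold 0.05: a null covariate is falsely retained at
exactly the removal rate, so with threshold 0.10 the expected
single-retention rate with one null covariate equals 90% — on the boundary
of any ≥90% check — whereas at 0.05 the expected rate is 95% and the check
is informative about the procedure rather than about seed luck.

## Synthetic data: what it does and does not emulate

The count simulator draws per-bin reads with expectation proportional to
bin length × GC bias curve (default quadratic peaking at GC 0.45) × mixture
copy number, normalized to the requested total (conserved to < 0.1%), with
Poisson noise by default or negative-binomial (variance μ + φμ²) when
overdispersion φ > 0 — real plasma-Seq counts are overdispersed, but
Poisson is the cleanly testable default. Control panels simulate healthy
genomes at the reference panel's read-depth band (6.83–6.98 M reads).
Unmappable and PAR-masked bins receive zero reads.

The cohort generator works at summary level (per-patient tumor fractions,
rrSCNA status, ddPCR copies, response, survival) rather than materializing
binned counts for every patient; the count-level forward model is exercised
by the separate simulate → profile → call path. Tumor fractions are
log-normal with medians 17% (rrSCNA carriers) and 5.1% (others), matching
the bundled cohort's group medians; ddPCR activating copies share the
log-TF latent factor with noise calibrated (via the Gaussian-copula
sin-transform) to a target Spearman correlation of 0.46, and the
lowest-signal fifth reads 0 copies/mL as below the assay limit. PFS and OS
are exponential (medians 10.4 and 18.7 months in non-carriers) with the
carrier hazard multiplied by the configured ratio (default 3.33), censored
administratively at 38.4 months; response is Bernoulli (81% vs 50%).

Not emulated: fragment-level features (fragmentomics, size selection),
library-prep artifacts, mappability estimated from sequence, waiting-time
entry/accrual patterns, or correlated competing risks between PFS and OS.
Passing tests therefore demonstrate the statistical machinery and the
calling rules under the stated noise model, not performance on real
sequencing data.

## Problem sizes and numerical choices

Tests and the reproduction script use a 2 × 60 Mb genome (2,400 bins at
50 kb, ~120 at 1 Mb) at 6 M reads with 10-control panels — large enough
that the 3%-TF detection threshold and the focal thresholds are exercised at
realistic per-bin noise, small enough for exact segmentation and dense seed
replication. Log ratios are floored at 1e-6 of the baseline median before
log2; segment means are length-weighted means of member bins (equal to the
plain mean on uniform bins, to 1e-9); all randomness flows from explicit
integer seeds through numpy Generators, and cohort/panel simulations spawn
child seeds so every component is independently reproducible.

## Known limitations

* The tumor-fraction estimator's state prior and offset make it accurate in
  the simulated regime (tf ≤ ~0.45, events spanning many 1 Mb bins) but it
  is not a substitute for a full production estimator on real data: no
  subclonality, no per-sample ploidy search, single shared noise scale.
* The exact segmentation is O(n²) per chromosome — fine at 50 kb bins for
  desk-scale genomes, slow for a full 3 Gb genome; a pruned search would be
  needed there.
* The evaluability rule's 5% boundary and the 3% detection threshold are
  applied as stated; borderline behavior (controls estimated just above 3%)
  is surfaced by the null-calibration tests rather than hidden by special
  cases.
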