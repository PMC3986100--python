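# Methods

`metsig` re-implements, as a tested reusable pipeline, an analysis design for
matched primary/omental-metastasis serous ovarian tumors: paired differential
expression, a median-vote prognostic gene signature evaluated by survival
analysis against a random gene-set null, copy-number segmentation with
gene-level scoring and metastasis-specific aberration calls, and staining
statistics. Every stage runs end-to-end on synthetic cohorts generated by the
package itself, so all statistical claims made by the test suite are claims
about data whose generating process is known exactly.

## Paired differential expression

Input is a log2 gene x sample matrix with matched primary and metastasis
samples per case. The stage applies, in order:

1. **Quantile normalization.** Every sample's sorted value vector is replaced
   by the across-sample mean of sorted vectors. Ties within a sample receive
   the mean of the reference values over the tied rank span, which makes the
   operation idempotent.
2. **Low-signal filter.** A gene is removed when it lies strictly below the
   25th percentile of *all* matrix values in every sample (the strictest
   reading of "consistently low"; the all-samples fraction is configurable).
   Percentiles use linear interpolation between order statistics so removal
   counts are reproducible.
3. **Paired t-test.** Per gene, differences d_i = met_i − primary_i over n
   cases give t = mean(d)/(sd(d)/√n) with the n−1 sample SD and a two-sided p
   from the t distribution with n−1 df. Genes with zero-variance differences
   get p = 1 and *stay in the Benjamini–Hochberg family*, so the
   multiple-testing denominator is never silently shrunk. Sidedness is
   two-sided by choice; q-values are BH step-up.
4. **Candidate filter.** A gene passes when |mean log2 FC| > 0.9, p < 0.05 and
   q < 0.25 (each threshold independently configurable). Both the q and p
   thresholds are applied because the two commonly quoted variants of this
   filter differ; applying all three is the conservative intersection.

## The median-vote signature

A signature is an ordered set of k genes, each with a direction of change in
metastases (up/down), plus an integer high-risk threshold. Scoring a cohort:
for each gene the *cohort's own* median expression is the cutpoint — cutpoints
are never transferred between cohorts, so the score is invariant to any
per-gene monotone transform (platform rescaling, log base, probe affinity). A
patient gains one point per up-gene strictly above its median and per
down-gene strictly below it; ties at the median contribute nothing. Patients
with score > threshold (default floor(k/2); > 3 for the canonical six-gene
set) form the high-risk group.

The packaged canonical signature is the published six-gene set (CALB2, CYP1B1,
EFTUD1, IL7R, RARRES2, TIMP3) with the > 3-point cut. The published gene table
does not state per-gene directions, so `canonical_signature()` requires the
caller to supply them (normally from the paired-DE stage).

**Direction convention.** Points are keyed to the metastasis direction of
change (the default). An alternative reading orients each gene by the sign of
its training-cohort Cox coefficient; that mode is available in the
empirical-null machinery (`direction_mode="fixed"`), and results metadata
records which mode produced them.

## Signature derivation

Candidates are first screened by univariate Cox proportional hazards on
continuous expression (partial likelihood, Efron ties; lifelines), keeping
genes with Wald p < 0.05 in the training dataset. How a screened candidate
list is reduced to a final k-gene set is genuinely open; the reconstruction
here scores every size-k subset of the retained genes by the *maximum*
log-rank p over all provided datasets of the high-vs-low comparison under
vote scoring, and returns the subset minimising that maximum — i.e. the set
that is simultaneously prognostic everywhere. The search is exhaustive while
C(n, k) is below a configurable cap (default 5000) and greedy-forward beyond
it; ties break on lexicographic gene order so runs are reproducible. With
fewer than k retained genes, all retained genes are returned with a warning.

## Survival analysis

Kaplan–Meier estimation, Greenwood variance, and median survival with 95%
confidence bounds come from lifelines; the median CI inverts log-log
transformed pointwise bands (the paper-era convention closest to
Brookmeyer–Crowley; the original analysis does not state its CI method). The
median is the smallest t with S(t) ≤ 0.5 and is reported as not-reached when
the curve never gets there.

The two-group log-rank test is implemented in-package as a vectorised
O(n log n) routine: at each distinct event time, observed events in one group
minus the hypergeometric expectation, summed over times and divided by the
summed hypergeometric variance, with a 1-df chi-square reference. Patients
censored at t remain at risk for events at t (censored-after-events
convention). The hand-rolled routine exists because the specificity null
evaluates tens of thousands of log-rank tests per run and per-call overhead
dominates otherwise; tests verify exact agreement with both a textbook
2×2-table oracle and lifelines.

`evaluate_signature` applies, in order: the treatment filter (a boolean
clinical column), vote scoring (medians computed on the treatment-filtered
cohort), then the residual-disease stratum filter, then KM + log-rank per
stratum and endpoint (OS or PFS). Scoring precedes stratum filtering because
the analysis design scores all treated patients and then examines
residual-disease subsets; strata with fewer than two patients in a risk group
are skipped with a warning.

## Random gene-set specificity null

The null asks: how often does a random same-size gene set, pushed through the
*identical* scoring and log-rank machinery, beat the observed signature's p?
Random sets draw k distinct genes uniformly without replacement from a
configurable universe (default: all non-signature genes in the matrix). The
empirical p is the fraction of random sets with *strictly* lower p; an
add-one ((n_lower+1)/(n_random+1)) variant is available for users who dislike
exact zeros. Random sets producing a degenerate grouping (every patient in
one risk group) are recorded with p = 1 — they cannot beat the signature but
still count in the denominator, keeping the accounting honest.

Direction assignment for random genes is not specified by the design being
reproduced; the default draws each gene's direction uniformly at random, and
a fixed-direction mode (orienting by supplied signs, e.g. training Cox
coefficients) is exposed. Output metadata records the mode.

## Copy number

Probe-level log10 tumor/reference ratios are smoothed and segmented:

- **Outlier smoothing.** A probe deviating more than 3 SDs from the median of
  its ±10-probe window is clamped to the window median ± 3 SDs (windows
  truncate at chromosome ends). The SD is estimated robustly as
  MAD(successive differences)/√2 so genuine segment steps do not inflate it.
  The exact trim constants of the reference R implementation are not public
  in the design being reproduced; this rule is a documented stand-in with the
  same intent (single-probe spikes pulled in, real steps preserved).
- **Circular binary segmentation.** Each segment is treated as a circle; the
  arc maximising a two-sample t-like statistic against its complement is the
  candidate split, accepted when a within-segment permutation test (default
  1000 permutations, reduced in tests) puts the observed maximum below
  alpha = 0.05. Accepted splits recurse; segments under 4 probes never split.
  Interior arcs suffice because wrap-around arcs are complements under a
  group-symmetric statistic.
- **Gene scoring.** Each probe inherits its segment mean; a gene's log10
  score is the average over probes overlapping the gene interval (0-based
  half-open, any overlap counts), and genes with fewer than 3 probes are
  dropped.
- **Metastasis-specific recurrent calls.** A gene is amplified above +0.1
  log10 and lost below −0.1 (the threshold is not stated in the reproduced
  design; 0.1 log10 ≈ 1.26-fold is the conventional aCGH cut and is recorded
  in output metadata). Tissue specificity is evaluated within-case (called in
  one tissue, not the other), recurrence across cases (≥ 2), and reported
  genes must show expression–copy-number Pearson r > 0.7 across samples;
  genes without expression are flagged uncorrelatable rather than dropped.
- **Clustering.** Samples cluster by 1 − Pearson correlation of gene-level
  profiles, average linkage. A case's primary and metastasis "co-cluster"
  when the linkage merges them while both are still singletons — each is the
  other's nearest neighbour in the dendrogram.

## Staining statistics

Percent-positive staining is treated as log-normal: Shapiro–Wilk p-values are
reported for raw and log-scale paired differences, and the paired t-test runs
on natural-log percentages (results are base-invariant). Zeros are replaced
by half the smallest positive observed value before the transform, flagged in
the result. The Ki-67 correlation ranking computes, per gene, the Pearson r
across cases between the paired log2 expression change and the paired Ki-67
percent change (raw percent scale by default, log-delta mode available;
signed r is ranked, not |r|), returning the top 250 by default.

## Synthetic data generators

One global integer seed governs every generator through fixed named
sub-streams, so a whole study is reproducible from one number and stages can
be regenerated independently.

- **Paired expression.** Gene baselines ~ N(7, 1.5²) log2 with a per-case
  N(0, 0.5²) offset shared by both tissues of a pair — this shared baseline is
  exactly what the paired t-test exploits. Planted genes shift the metastasis
  sample by ±1.2 log2 (77 up, 10 down by default, matching the candidate-list
  scale of the reproduced design); each tissue measurement adds N(0, 0.4²)
  noise, so per-pair differences have SD √2·0.4. Defaults: 9 cases, 2000
  genes (a desk-scale stand-in for a genome-wide array; recall/FDR properties
  depend on per-gene power and the BH family size, both preserved).
- **Survival.** Event times are exponential under proportional hazards
  (baseline 0.02 events/month ≈ 35-month median at score 0, in the range of
  advanced serous cohorts). Two hazard designs: hazard on the integer vote
  score (0.4 log HR/point default) emulates evaluating an established
  signature; hazard linear in direction-signed standardized expression (used
  for the gene-selection recovery experiment, 0.35 log HR per gene SD) makes
  each signature gene independently prognostic — the premise of a per-gene
  Cox screen, without which screen-then-combine selection is underpowered by
  construction. Censoring is independent exponential with per-patient rate
  proportional to the event hazard, making the expected censored fraction
  exactly the configured rate (default 0.3). An option confines the score
  effect to patients without residual disease to mirror designs where
  residual tumor burden dominates outcome.
- **Probe tracks.** Piecewise-constant per chromosome: breakpoints at random
  interior positions (segments ≥ 10 probes), level stepping ±0.3 log10 at
  each breakpoint, N(0, 0.05²) probe noise, and a 2% fraction of single-probe
  sign-symmetric spikes of 5–8 noise SDs (the target of the smoothing rule).

**What the generators do not emulate:** probe-level hybridization chemistry,
batch effects, tumor purity below the >70%-cancer-cell selection, inter-gene
correlation structure, platform-specific probe-to-gene mapping, or
non-proportional hazards. Passing tests therefore demonstrate correctness of
the machinery and calibration under the assumed model, not robustness to
real-array artefacts.

## Numerical choices and degenerate inputs

- Zero-variance paired differences: p = 1, kept in the BH family.
- Ties at the median: no point (strict inequalities).
- Log-rank with zero variance (no events, or an empty group at every event
  time): statistic 0, p 1; empty groups are an error.
- Degenerate random-set groupings in the null: p = 1, counted in n_random.
- Cox non-convergence or monotone likelihood: gene flagged, excluded from the
  significant set, kept in the output table.
- Constant-profile samples in correlation clustering: excluded with a warning
  (correlation undefined).
- Zero staining percentages: replaced by half the minimum positive value.
- Subset-search ties: lexicographic gene order (first candidate wins).

## Problem sizes used by the test suite and acceptance script

Simulation experiments run at the design points above with replicate counts
chosen for stable pass/fail behaviour at suite scale: 100 replicates for Cox
coverage and CBS breakpoint localisation (30 in the acceptance script), 10
replicates for signature-selection recovery, 2000 random sets for the
specificity null (50,000 for the Monte-Carlo-vs-enumeration check on the
6-gene toy universe), CBS permutations reduced to 100–200 in tests from the
1000 default. The KM-median closed-form check averages 10 replicates of
n = 1000 because a single sample median at that n carries ~4.6% relative SE.

## Known limitations

- The six-gene subset search is a reconstruction; the original reduction from
  twelve screened genes to six is not described in the reproduced design.
- CBS here follows the published algorithm outline, not the reference R
  implementation's exact pruning/ternary-split refinements; localisation
  accuracy is validated empirically instead.
- The empirical null's direction convention for random genes is a modelling
  choice (uniform random by default) and materially defines the null being
  sampled.
- External cohort benchmarks (public expression archives) require downloads
  and are out of scope for the packaged tests; readers can apply the DE and
  staining stages to those tables via the documented TSV formats.
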