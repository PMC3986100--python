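# metsig

Analysis pipeline for matched primary / omental-metastasis ovarian tumor
studies. In serous epithelial ovarian cancer the disease that kills patients
is the peritoneal metastasis left behind after debulking surgery, yet most
molecular profiling looks only at primary tumors. When primary and metastatic
tumors from the same patients are profiled together, the genes that change on
the way to the omentum become candidate markers of aggressive disease — and a
small panel of them, scored against cohort medians, stratifies survival in
independent primary-tumor cohorts.

`metsig` packages that whole analysis as reusable, tested components:

- **Paired differential expression** — quantile normalization, removal of
  genes consistently below the global lowest quartile, per-gene paired
  t-tests on metastasis-minus-primary log2 differences with
  Benjamini–Hochberg FDR, and the candidate filter |log2 FC| > 0.9, p < 0.05,
  q < 0.25.
- **Median-vote signature scoring** — for a k-gene signature, a patient gains
  a point per up-in-metastasis gene expressed strictly above the cohort
  median and per down-gene strictly below it; score > 3 (for k = 6) defines
  the high-risk group. The score S = Σ_g 1[x_g ≷ median_g] uses only order
  statistics, so it transfers across platforms without renormalization.
- **Survival analysis** — Kaplan–Meier curves with median survival and 95%
  CIs, a fast two-group log-rank test, univariate Cox per-gene screening,
  and treatment/residual-disease-stratified evaluation over multiple
  datasets and endpoints (OS, PFS).
- **Random gene-set specificity null** — the empirical p of a signature is
  the fraction of random same-size gene sets, run through the identical
  scoring + log-rank machinery, that achieve a strictly lower p.
- **Copy number** — outlier smoothing, circular binary segmentation of
  aCGH log10 ratios, gene-level scores (mean segmented ratio over ≥ 3
  overlapping probes), recurrent metastasis-specific amplification/loss
  calls gated on expression–copy-number correlation (Pearson r > 0.7), and
  CNA-profile clustering with matched-pair co-clustering reports.
- **Staining statistics** — Shapiro–Wilk log-normality checks and paired
  t-tests on log-transformed Ki-67 / TUNEL percent-positive staining, plus
  ranking of genes whose expression changes track the Ki-67 change.
- **Synthetic data generators** — matched-pair expression cohorts with
  planted differential genes, proportional-hazards survival cohorts driven
  by the vote score, and piecewise-constant probe tracks with outlier
  spikes; everything downstream is testable offline from one seed.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate a 9-pair cohort with 87 planted metastasis genes, run the paired DE
stage, build a six-gene signature from the top candidates, and evaluate it on
a simulated 400-patient treated cohort:

```python
from metsig import (SimConfig, Signature, SignatureGene, simulate_paired_cohort,
                    PairedDifferentialExpression, simulate_survival_cohort,
                    evaluate_signature, empirical_null)

cfg = SimConfig(n_cases=9, n_genes=2000, n_de_up=77, n_de_down=10, seed=1)
sim = simulate_paired_cohort(cfg)
de = PairedDifferentialExpression(sim.cohort).fit()
print(de.summary())
```

```
Paired differential expression (metastasis vs primary)
========================================================
genes tested:            1846
genes removed (low sig): 154
thresholds:              |log2FC| > 0.9, p < 0.05, q < 0.25
up-regulated in mets:    67
down-regulated in mets:  9
```

Of the 87 planted genes, 76 clear the candidate filter (the remainder fall
below one of the thresholds by noise at n = 9 pairs, the expected behaviour
at this effect size). Continuing:

```python
cand = de.candidates()  # passing genes, ascending p, with met directions
sig = Signature(
    [SignatureGene(g, d) for g, d in cand["met_direction"].head(6).items()],
    high_risk_threshold=3,
)
surv = simulate_survival_cohort(cfg, sig, n_extra_genes=200)
ev = evaluate_signature({"synthetic": (surv.cohort.expression, surv.cohort)}, sig)
print(ev.summary())
```

```
Signature survival evaluation
========================================================================
  dataset stratum endpoint  n_high  n_low  median_high  median_high_lo  median_high_hi  median_low  median_low_lo  median_low_hi    logrank_p
synthetic     all       OS     137    263     5.415004        4.661462         6.40581   14.180397      12.318683      16.764926 2.038163e-13
```

High-scoring patients (137/400) have a median survival of 5.4 months against
14.2 for the low-score group — the planted 0.4 log hazard ratio per signature
point, recovered through the median-vote scoring. The specificity null shows
no random six-gene set from 200 null genes does better:

```python
res = empirical_null(surv.cohort.expression, surv.cohort, sig,
                     n_random=2000, seed=1)
print(res.summary())
```

```
Random gene-set specificity null
========================================
observed log-rank p:   2.038e-13
random sets evaluated: 2000
sets with lower p:     0
empirical p:           0
direction mode:        random
```

The same stages are available from the shell (`metsig run --seed 1 --out
out/` for the full synthetic pipeline; `metsig de`, `metsig score`, `metsig
null`, `metsig cnv-segment`, `metsig phenotype`, ... for individual stages on
your own TSV inputs — see `metsig --help`).

The published six-gene panel (CALB2, CYP1B1, EFTUD1, IL7R, RARRES2, TIMP3) is
packaged as `canonical_signature(directions)`; supply per-gene metastasis
directions from your own paired cohort before scoring.

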