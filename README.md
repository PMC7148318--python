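# egfr-impact

Transcriptomic scoring of EGFR pathway dependence in lung adenocarcinoma.

A single hotspot mutation (EGFR exon 19 del, L858R) is an imperfect readout
of how much a tumour actually depends on EGFR signalling: some mutant tumours
have lost pure pathway dependence (and respond poorly to EGFR tyrosine-kinase
inhibitors), while some wild-type or variant-of-uncertain-significance tumours
behave like pathway-driven disease. `egfr-impact` implements a diagnostic
score that reads pathway dependence from the expression profile instead:

```
EGFR impact score = (es_up + 1) / (es_down + 1)
```

where `es_up` and `es_down` are a sample's single-sample GSEA (ssGSEA)
enrichment scores for a pair of signatures — genes coordinately up- and
downregulated in EGFR-mutant tumours. Samples above a ROC-calibrated cutoff
form the high-impact class **EI-H** (pathway-dependent, TKI-responsive,
better prognosis); the rest form **EI-L**.

The package is for computational biologists who want to derive such paired
signatures from their own mutant/wild-type cohort, score external cohorts
with a fixed signature and threshold, and evaluate the resulting classes
against drug response and survival endpoints.

## The pipeline

1. **Differential expression** (`diffexp`): moderated t-statistic between
   EGFR-mutant and wild-type samples (KRAS-mutant samples excluded first,
   since KRAS lies downstream of EGFR). Empirical-Bayes variance shrinkage
   with method-of-moments hyperparameters; DEGs are genes with
   `p < 0.01` and linear fold change `> 1.2` or `< 1/1.2`.
2. **Signature selection** (`signature`): random-forest Gini importance of
   the DEGs for the mutant/wild-type classification; zero-importance genes
   dropped, genes strictly above the third quartile of the remaining
   importances kept, partitioned into up/down sets by DEG direction, with
   ALK appended to the down set.
3. **ssGSEA** (`ssgsea`): per-sample rank-weighted random-walk enrichment,
   `ES = Σ_i [P_in(i) − P_out(i)]` over all gene positions, rank weight
   exponent `alpha = 0.25`, scores divided by the cohort-wide score range.
4. **Impact scoring** (`scoring`): the ratio above, ROC sweep with Youden's
   J for the EI-H/EI-L cutoff (2.2 in the original derivation cohort), ties
   at the threshold assigned to EI-L.
5. **Evaluation** (`evaluation`): Welch's t for group contrasts, Pearson's r
   for IC50/tumour-shrinkage association, Kaplan–Meier + log-rank and Cox
   proportional hazards (Efron ties) for RFS/OS.
6. **Synthetic cohorts** (`simulate`): Gaussian log2-intensity cohorts with
   planted up/down genes and class-dependent exponential survival, so the
   whole pipeline is testable without any download.

## Worked example

Simulate a derivation cohort (100 samples, 20% EGFR-mutant, 10 planted up-
and 10 planted down-genes at a 2.0 log2 effect) and run the whole pipeline:

```bash
$ egfr-impact simulate --seed 11 --out-dir cohort
cohort: 200 genes x 100 samples -> cohort/

$ egfr-impact deg --expr cohort/expr.tsv --meta cohort/meta.tsv --out degs.tsv
21 DEGs (of 200 genes) -> degs.tsv

$ egfr-impact derive-signature --expr cohort/expr.tsv --meta cohort/meta.tsv \
      --seed 1 --out signature.gmt
signature: 2 up / 4 down genes -> signature.gmt

$ egfr-impact calibrate --expr cohort/expr.tsv --gmt signature.gmt \
      --meta cohort/meta.tsv --out roc.tsv
chosen threshold 2.493 (Youden J 1.000, AUC 1.000) -> roc.tsv

$ egfr-impact score --expr cohort/expr.tsv --gmt signature.gmt \
      --threshold 2.493 --out impact.tsv
20/100 samples EI-H at threshold 2.493 -> impact.tsv

$ egfr-impact evaluate --impact impact.tsv --meta cohort/meta.tsv \
      --endpoint rfs --out report.tsv
endpoint        RFS
logrank_stat    7.51085
logrank_p       0.00613283
cox_hr_ei_low   2.3362
cox_hr_ci       [1.25172, 4.36026]
cox_p           0.00769522
```

Reading the output: the differential stage finds 21 DEGs (the planted genes
plus the occasional false positive); the quartile importance filter keeps a
compact subset of them as the signature; the calibrated impact-score cutoff
separates mutant from wild-type samples perfectly (Youden J = 1) and lands
near the published 2.2; and the EI-L class carries roughly twice the
recurrence hazard of EI-H (Cox HR 2.34, log-rank p = 0.006) — the planted
hazard ratio was 2.

The same stages are available as library functions
(`egfr_impact.moderated_t_test`, `derive_signature`, `ssgsea`,
`score_cohort`, `calibrate_threshold`, `km_logrank`, ...) operating on
pandas DataFrames.

To score a real cohort with a fixed published signature and threshold,
skip derivation and calibration:

```bash
egfr-impact score --expr external.tsv --gmt published_signature.gmt \
    --threshold 2.2 --out impact.tsv
```

## File formats

- Expression: TSV, first column `gene_id`, one column per sample, log2
  values (a heuristic warns when values look linear-scale). Duplicate
  probe rows are collapsed to the probe with the highest mean.
- Gene sets: standard GMT.
- Metadata: TSV keyed by `sample_id` with `egfr_status`
  (`wild_type | hotspot_mutant | vus | other_mutant | unknown`),
  `kras_status` (`wild_type | mutant | unknown`), optional
  `rfs_time`/`rfs_event`, `os_time`/`os_event`, `shrinkage_rate`, `ic50`;
  extra columns pass through untouched.
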