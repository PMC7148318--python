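# Methods

This note documents the models, estimators and numerical choices behind
`egfr-impact`, and what its synthetic cohorts do and do not establish.

## Differential expression

For gene *g* with group sizes *n₁* (mutant) and *n₂* (wild-type) the pooled
two-sample variance *s²_g* has *d_g = n₁ + n₂ − 2* degrees of freedom. A
scaled inverse-chi-square prior with hyperparameters (*d₀*, *s₀²*) shrinks it
to

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),

and the moderated statistic is t̃_g = (x̄₁ − x̄₂) / (s̃_g √(1/n₁ + 1/n₂)),
referred to a t distribution with *d₀ + d_g* degrees of freedom. The
hyperparameters are estimated by matching the mean and variance of
log s²_g against their theoretical values under the prior (digamma/trigamma
moments of the log chi-square), with the trigamma inverse solved by Newton
iteration. When the observed spread of log s²_g does not exceed pure
sampling noise, *d₀ = ∞* and every gene shares *s₀²*. Genes with zero sample
variance are excluded from the fit but still shrunk, so zero-variance genes
never produce undefined statistics. The suite cross-checks the whole stage
against the Bioconductor `limma` implementation on a small fixture.

Choices worth flagging:

- **Raw p-values in the DEG filter.** The filter is `p < 0.01` AND linear
  fold change strictly `> 1.2` or `< 1/1.2`; both inequalities strict. A
  Benjamini–Hochberg column is emitted for information but does not gate.
- **Fold change** is 2^(difference of log2 group means); inputs are assumed
  log2 (a loader heuristic flags matrices whose maximum exceeds 50 as
  probably linear-scale).
- **KRAS exclusion** precedes everything: KRAS-mutant samples are removed
  because KRAS activation mimics downstream EGFR activation and would blur
  the contrast.
- `--no-moderation` gives the ordinary pooled-variance t (the *d₀ = 0*
  limit) for sensitivity analysis.

## Signature selection

A random forest (500 trees, impurity-based Gini importance, fixed seed
recorded in the signature provenance) classifies mutant vs wild-type using
only the DEGs. Genes with importance exactly 0 are dropped; the third
quartile of the remaining importances is computed with the
linear-interpolation (type-7) quantile convention; genes **strictly** above
it are kept and partitioned into up/down sets by their DEG direction. ALK is
appended to the down set: ALK-rearranged tumours form a mutually exclusive
driver class, so high ALK expression argues against EGFR dependence.

Two boundary behaviours are deliberate errors rather than fallbacks: all
importances zero ("no informative genes") and a selection emptied by the
strict inequality (all nonzero importances equal). Permutation importance
was considered and rejected as the default: at cohort sizes of tens of
samples single-run permutation scores are too noisy to support a quartile
cutoff.

**Structural note.** The quartile rule retains at most a quarter of the
informative genes by construction. When the differential stage is highly
specific — as on synthetic cohorts where essentially only planted genes pass
the filter — the derived signature is therefore a compact, high-precision
subset of the truly shifted genes (~25% recall, ~100% precision), not their
full recovery. On real cohorts the DEG list is much larger and more
heterogeneous (hundreds of genes), which is the regime the rule was designed
for. Occasionally the selected subset is entirely one-directional; the
signature constructor then fails loudly rather than emit an unusable
one-sided signature.

## Single-sample GSEA

Within one sample all *N* genes are ranked ascending (highest expression →
rank *N*; ties averaged). Visiting genes in decreasing-rank order, the
in-set cumulative distribution weights gene *g* by rank_g^α, the out-set
distribution is uniform, and the enrichment score is the sum of their
differences over all *N* positions (an integrated random walk, not the
maximum-deviation statistic of two-group GSEA). Defaults: α = 0.25 and
division of the whole score matrix by its global max − min.

- **Visit order among tied ranks** is fixed by gene id, making scores
  invariant to input row order; ranks themselves are tie-averaged.
- **Normalization is cohort-dependent**: a sample's normalized score changes
  when the cohort changes. This matters for threshold portability — a cutoff
  calibrated on one cohort only transfers to another under comparable
  normalization. `normalize=False` gives cohort-independent raw scores.
- A gene set must intersect the matrix genes and leave a non-empty
  complement; members absent from the matrix are pruned with a warning.
- The implementation is validated to 1e-12 against a quadratic-time oracle
  that recomputes both cumulative distributions from scratch at every step.

## Impact score and classification

`impact_score = (es_up + 1)/(es_down + 1)` — strictly increasing in the
up-signature score, strictly decreasing in the down-signature score, and 1
when the two agree. The +1 offsets assume range-normalized ssGSEA scores
(which live in an interval of width 1); a denominator ≤ 0 is treated as a
normalization fault and raised.

The EI-H/EI-L threshold comes from a full ROC sweep: candidate cutoffs are
midpoints between consecutive distinct scores plus ∓∞ sentinels, a sample is
called positive when its score is strictly above the cutoff, and the chosen
threshold maximizes Youden's J = TPR − FPR (ties broken toward the smallest
qualifying threshold; AUC by trapezoid over the sweep, which equals the
Mann–Whitney statistic). Calibration truth defaults to EGFR mutant vs
wild-type in the derivation cohort, and is an explicit, overridable input.
Scores exactly at the threshold are assigned to EI-L, since the original
classes are defined by "higher/lower than" the cutoff with equality left
open. A pre-calibrated threshold can be supplied directly for external
cohorts.

## Outcome evaluation

- **Welch's t** (unequal variances, Satterthwaite df) for all two-group
  quantitative contrasts — impact score between sensitive/resistant lines,
  PD-L1 expression and mutation burden between EI classes are the same
  operation applied to different per-sample columns.
- **Pearson's r** with the t-transform p-value (n − 2 df) for associations
  with IC50 and tumour shrinkage; constant inputs are rejected.
- **Kaplan–Meier / log-rank** for two-group survival comparisons (every
  comparison in the intended analyses is two-group or pairwise); with no
  censoring the KM estimate equals the empirical survival function, which
  the suite asserts.
- **Cox proportional hazards** via lifelines with Efron tie handling
  (months-resolution follow-up ties heavily). The fit requires events ≥
  covariates + 1 and a full-rank design; collinearity and non-convergence
  raise explicit errors rather than returning unstable estimates.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, at the
study's scale: `n = 100` samples with a 20% mutant fraction, 200 genes of
which 10 are planted up and 10 down at a 2.0 log2 effect, i.i.d. Gaussian
noise with σ = 0.5 log2 units around a 7.0 baseline — the magnitude regime
of RMA-normalized arrays. Survival is exponential with per-class monthly
hazards 0.02 (mutant/EI-H-like) vs 0.04 (wild-type/EI-L-like), i.e. a
planted hazard ratio of 2 with medians near 35 vs 17 months; censoring is an
independent exponential whose rate h·c/(1−c) makes the expected censored
fraction equal the requested c (default 0.2). The sensitive/resistant pair
generator gives every sample the signature shift and attenuates it by a
stated factor in the resistant cohort, emulating loss of pathway dependence
under long-term drug exposure.

What the generator does **not** emulate: gene–gene correlation, batch
structure, heavy-tailed intensities, probe-level redundancy, or the identity
of any real signature gene (ALK is absent from synthetic matrices and is
pruned from the down set with a warning at scoring time). Passing tests on
these cohorts therefore establish the correctness and statistical behaviour
of the machinery — not that any particular real-cohort gene list or cutoff
will be reproduced.

## Problem sizes and determinism

Every stochastic check fixes its seeds. Monte-Carlo assertions state their
replicate counts explicitly: the ssGSEA oracle runs 1,000 random instances;
signature/classifier recovery uses 20 independent cohorts; the
sensitive/resistant contrast 100 cohort pairs; the survival pipeline 100
seeds in the test (50 in the acceptance script), with the ≥0.9 detection
probability judged by a one-sided binomial rule (fail only when the observed
rate is significantly below the bar at the 5% level) — the measured
detection rate sits near 0.91, close enough to the bar that a naive
proportion check would flicker. Random-forest runs are seeded through
scikit-learn's `random_state`; cohort generation uses `numpy`'s PCG64
generator, so identical specs give bit-identical cohorts.

## Known limitations

- Two-group designs only: no paired-sample modelling, covariate adjustment
  in the DEG stage, or k-group log-rank.
- Threshold portability across cohorts rests on comparable ssGSEA
  normalization; the package records the raw score range in provenance but
  cannot verify comparability for an external cohort.
- The importance filter's seed sensitivity is real: different seeds can
  select boundary genes differently. The seed is part of the signature
  provenance for exactly this reason.
- Probe-to-gene collapsing keeps the highest-mean probe; alternatives
  (median, summing) are not offered.
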