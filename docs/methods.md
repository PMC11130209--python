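# Methods

## Overview

`psilc` implements a pathway-centric discovery–validation workflow for
transcriptomic survival biomarkers, motivated by invasive lobular breast
cancer (ILC): a morphologically distinct, mostly ER-positive subtype with
poor long-term outcome for which subtype-specific prognostic tools are
scarce.  The workflow has five stages:

1. **Dysregulation screen.** Tumour vs normal differential expression and
   differential variance on log2 abundance; the union of the two
   significant sets is the dysregulated-gene resource.
2. **Pathway clusters (CPs).** Over-representation of that resource in a
   pathway database, collapse of redundant enriched pathways into clusters
   by overlap-coefficient similarity, and a non-redundant gene→CP
   assignment by a relevance score.
3. **Per-CP risk models.** For each CP, genes univariably associated with
   outcome in the discovery cohort are combined into a per-patient score;
   discovery cut-offs dichotomise/trichotomise validation patients into
   risk groups, evaluated with Cox models (prognosis and risk-group ×
   chemotherapy interaction).
4. **Multivariable model.** A random survival forest over all per-CP
   scores, tuned by a hyperparameter sweep with out-of-bag model
   selection.
5. **Contextual synthetic lethality.** Cell lines are scored with the
   multivariable model and split at the discovery cut-off; CRISPR
   gene-effect profiles are compared between groups to find knockouts that
   selectively reduce fitness in the high-score context.

Every stage is exercisable end-to-end on synthetic cohorts with known
ground truth (`psilc.synthetic_data`), because the real cohorts the design
emulates are controlled-access.

## Statistical detail and defaults

### Dysregulation

Differential expression uses a two-group t-test with empirical-Bayes
variance moderation.  Gene-wise pooled variances `s_g^2` (df `d`) are
shrunk towards a common prior: under the standard hierarchical model they
are marginally `s0^2 F(d, d0)`-distributed, and `(d0, s0^2)` are estimated
by matching the observed mean and variance of `s_g^2` (see
`moderation_prior`); the moderated statistic has `d + d0` df.  A plain
Welch test is available (`moderated=False`).  Defaults: significant when
`|log2FC| > 1` and BH `q < 0.001`.

Differential variance is the two-sided F ratio test on
`var_tumour / var_normal`; significance additionally requires
`sigma_tumour > sigma_normal` and `sigma_tumour > 0.5` log2 units, at BH
`q < 1e-15`.  The F test (rather than, say, Levene) is the conventional
two-sample variance test; the directional filters make the choice of
two-sided p-value immaterial for selection.  Standard deviations use the
n−1 denominator throughout.

### Pathway clustering

Enrichment is the hypergeometric upper tail with the universe defaulting
to the genes surviving expression filters (configurable).  Enriched
pathways need ≥ 3 query genes and BH `q < 0.1`.  Pathway similarity is the
overlap coefficient `|A∩B|/min(|A|,|B|)`; clustering is agglomerative
(average linkage by default — the linkage for this step was an open
choice; average linkage is the least shape-biased for similarity data) on
`1 − similarity`.  The number of clusters maximises "silhouette and k"
jointly: among all k whose average silhouette is within 0.01 of the
maximum, the largest k is chosen, favouring resolution when it is free.
Singleton-cluster silhouettes are 0 (standard convention).

The relevance score for de-redundancy is
`R = (#co-members with |Spearman rho| > 0.3) / (#co-members)`, computed on
the discovery cohort with the gene itself excluded from both numerator and
denominator (self-correlation is trivially 1).  Ties on `R` prefer the
larger correlated count, then the earlier CP id — deterministic and
size-bias-free.

### Per-CP risk models

Cox fits use lifelines (Efron tie handling).  Monotone-likelihood
separation is flagged and `|beta|` capped at 10; flagged genes are not
selected into CP models (their Wald p is meaningless).  The CP score is
the node-only linear combination `sum(beta_g z_g)` over genes with
discovery Wald `p < 0.05`; selected genes missing from a validation cohort
contribute 0 (mean imputation on the z scale) with a coverage warning.
Risk groups: score strictly above the discovery median is "high" (the
cutoff value itself is "low", keeping the discovery split balanced);
tertile mode uses the 33rd/66th percentiles with the analogous boundary
rule.  z-scores are computed within each cohort separately by default (a
flagged alternative reusing discovery moments is deliberately not the
default: cohort-internal standardization absorbs platform shifts).
Survival is truncated at 10 years by default; an event exactly at the
horizon remains an event.

Prognostic evaluation fits the group indicator(s) with "low" as reference,
reports a trend test (Wald on the ordinal coding) in tertile mode,
attaches the Schoenfeld zero-slope p per term, and falls back to the
log-rank test (HR suppressed) when a group has no events.  The adjusted
model adds age > 55, T-stage factors (T1 reference), nodal status and
continuous purity.  The interaction model is
`group + chemo + group:chemo (+ covariates)`; with an empty
group × treatment cell the design is collinear and the interaction is
reported as not estimable rather than silently dropped.

### Multivariable model

Features are the per-CP scores (CP-id-sorted columns; non-informative CPs
excluded consistently between training and prediction).  The discovery
cohort is split 66/34 (stratified by event status, which stabilises small
synthetic cohorts); each sweep candidate fits a log-rank-splitting random
survival forest (scikit-survival), records OOB error = 1 − OOB concordance
of ensemble mortality, and the Cox coefficient of the standardized
predicted score on the held-out third.  Selection: within the
lowest-OOB-error decile (≥ 1 candidate), the largest held-out coefficient
wins — a deterministic reading of "lowest OOB error and highest beta".
The full sweep is ntrees 501–1001 (step 100), nodesize 10–15, mtry 5–10
(216 candidates).  For the small simulated cohorts used in tests and in
`scripts/acceptance.py` a reduced sweep (`small_grid`) takes the corners
of the nodesize/mtry ranges with 101 trees; tree count beyond ~100 changes
OOB concordance on these cohorts by less than its sampling noise, while
the full sweep would dominate runtime without changing the measured
properties.  Risk scores are ensemble mortality; any monotone transform
would give identical groups since cut-offs are derived on the same scale.

### CRISPR screen

Lines are split at the discovery-derived score cut-off.  A gene passes the
effect-size filter iff mean GE(high) < −0.5, mean GE(low) > −0.75 and
mean GE(high) < mean GE(low), all strict.  The one-sided Welch test
(alternative: high < low) is computed only when both groups have ≥ 3
lines; undefined p propagates as missing, never as 1.  "ERBB2 altered"
means amplified or mutant.  Commonly essential genes (full-panel median
GE < −1, computed before any ERBB2 exclusion) are annotated post hoc;
they are removed from the significant list only on request
(`exclude_essential=True`).  Annotation-only is the default because a
contextual dependency concentrated in a majority high group can drag the
panel median below −1 while still being a genuine selective hit, and
essentiality is informative rather than disqualifying.  The overlap of two
screens is tested with the hypergeometric upper tail over the genes tested
in both, and the agreement of their effect sizes with Spearman rho over
the overlap (undefined below 3 genes).

### Comparison statistics

Cohen's kappa uses marginal-product expected agreement.  The weighted
Stouffer combination treats inputs as one-sided p-values oriented in the
direction of harm; weights default to equal, with `sqrt(n)` per cohort the
recommended choice for unbalanced validation sets.  The concordance index
counts event-anchored comparable pairs with ties at 1/2
(scikit-survival).  Kaplan–Meier survival at a time point is the step
value at the largest event time not exceeding it.

## The synthetic-data generator

The generator emulates the statistical structure the estimators assume,
not the technology that produced the real data.  Per gene, log2 abundance
is Gaussian with mean ~N(7, 1.5²) and a common within-group sd of 0.5;
tumours add planted log2 fold-changes and sd multipliers; each cohort gets
gene-wise additive shifts (sd 0.3 log2 units) emulating platform
differences.  Survival is exponential proportional hazards — hazard
`0.08/yr × exp(eta)` with `eta` the planted linear predictor over
prognostic-pathway genes — with independent exponential censoring
(0.04/yr) and an administrative cut at 15 years; these rates give roughly
half the cohort an event within the 10-year modelling horizon, typical of
long-follow-up breast cancer series.  The planted "high-risk" truth label
is `eta` above its cohort median, matching the median-dichotomisation
convention downstream.  Treated samples in that stratum have hazard
multiplied by `exp(−0.69)` (HR ≈ 0.5) by default.  Gene-effect screens
plant group-selective dependency means against N(0, noise_sd) background.

What the generator does **not** emulate: probe structure, count noise,
FFPE artefacts, correlated co-expression beyond what planted effects
induce, informative censoring, competing risks, or cohort-specific
treatment policies.  Passing tests therefore demonstrate that the
estimators recover the structure they model, under that model — not
performance on real cohorts.

## Problem sizes

Simulated studies use a discovery cohort of 150 tumours (with up to 100
normals), three validation cohorts of 100, 2000 genes and 25 pathways for
end-to-end checks; 500-sample feature matrices for forest sanity checks;
600-sample cohorts for interaction recovery; and a 100-gene × 14-line
panel (8 high / 6 low) for the screen.  These sizes are large enough that
the planted effects dominate sampling noise at the stated thresholds while
keeping a full run of the suite and of `scripts/acceptance.py` in the
minutes range.

## Known limitations

* The marginal interaction coefficient recovered from dichotomised groups
  is attenuated relative to the planted conditional log-HR (risk
  heterogeneity within groups plus the non-collapsibility of hazard
  ratios); the acceptance script reports the fitted value without
  correction.
* The moderated DE test estimates its prior by moment matching, which is
  coarser than profile-likelihood estimation; with very few genes the
  prior df estimate is unstable (a Welch fallback is provided).
* `evaluate_interaction` models two risk groups; tertile-mode interaction
  testing is not implemented.
* Forest persistence uses Python pickling; models are not portable across
  scikit-survival versions.
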