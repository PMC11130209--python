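# psilc

Pathway-cluster survival signatures for invasive lobular breast cancer
(ILC), with a contextual CRISPR synthetic-lethality screen.

ILC is the second most common histological subtype of breast cancer;
despite poorer long-term outcome than invasive breast carcinoma of no
special type, it lacks subtype-specific prognostic tools.  `psilc`
implements a pathway-centric discovery–validation workflow for this
problem, aimed at computational biologists who want to build, validate and
stress-test such signatures on data with known ground truth:

1. **Dysregulated genes** — tumour-vs-normal differential expression
   (moderated t, significant at |log2FC| > 1, FDR q < 0.001) and
   differential variance (F test, σ_tumour > σ_normal, σ_tumour > 0.5,
   q < 1e-15), combined by union.
2. **Clusters of pathways (CPs)** — hypergeometric over-representation
   (≥ 3 query genes, q < 0.1), collapse of redundant pathways by
   hierarchical clustering on 1 − overlap coefficient with
   silhouette-guided choice of k, and a non-redundant gene→CP assignment
   by the relevance score R = (#co-members with |Spearman ρ| > 0.3)/CP size.
3. **Per-CP risk models** — for each CP, genes with discovery Cox Wald
   p < 0.05 enter the per-patient score
   `score_s = Σ_g β_g · z_{g,s}`;
   discovery median (or tertiles) define validation risk groups, tested
   with (optionally covariate-adjusted) Cox models, including a
   risk-group × chemotherapy interaction.
4. **Multivariable model** — a random survival forest over all CP scores,
   tuned by a sweep (ntrees 501–1001, nodesize 10–15, mtry 5–10; 216
   candidates) selecting the lowest out-of-bag error / highest held-out β.
5. **Synthetic lethality** — cell lines are scored and split at the
   discovery cut-off; genes with mean gene-effect < −0.5 in the high
   group, > −0.75 in the low group, high < low, and one-sided Welch
   p < 0.05 are contextual dependency candidates (commonly essential
   genes, panel median < −1, are annotated).

Because the real cohorts this design targets are controlled-access, the
package ships a first-class simulator (`psilc.synthetic_data`) that plants
differential means/variances, pathway-structured proportional-hazards
survival, multi-cohort shifts, a treatment-by-risk-group interaction and
group-selective CRISPR dependencies — every downstream stage is testable
against known truth.  See `docs/methods.md` for the statistical detail.

## Worked example

```python
from psilc import pipeline, synthetic_data as sd
from psilc.pathway_clusters import cps_from_pathways
from psilc.psilc_model import build_feature_matrix, predict_psilc, small_grid, train_psilc
from psilc.cp_risk import evaluate_prognosis
from psilc.evaluation_stats import concordance_index

# a discovery cohort (n=150) + 3 validation cohorts (n=100), 2000 genes,
# 25 pathways, with one planted prognostic pathway (per-gene beta 0.5)
cfg = sd.SimConfig(prognostic_cps=[(0, 0.5)], seed=11)
db = sd.generate_pathway_db(cfg)
cohorts, truth = sd.generate_cohorts(cfg, db)

cps = cps_from_pathways(db)                       # one CP per pathway
models = pipeline.fit_cp_models(cps, cohorts[0])  # discovery Cox models
print(pipeline.combined_validation_ranking(models, cohorts[1:])
      .sort_values("wald_p").head(3).round(4))
```

```
       wald_p      hr  n_genes
cp_id
CP01   0.0000  3.0719       12
CP16   0.0119  1.5377        1
CP24   0.0488  0.7142        2
```

CP01 — the planted prognostic pathway (`truth.prognostic_pathways[0]` is
`PW001`, which CP01 wraps) — tops the combined-validation ranking with a
pooled high-vs-low hazard ratio of 3.07; the runner-up CPs are chance
findings near the 0.05 selection threshold.  Aggregating all CPs:

```python
disc = pipeline.prepare_cohort(cohorts[0])        # truncate at 10y, z-score
feats = build_feature_matrix(models, disc)
model = train_psilc(feats, disc.clinical, grid=small_grid(), seed=11)

val = pipeline.prepare_cohort(cohorts[1])
rs = predict_psilc(model, build_feature_matrix(models, val))
fit = evaluate_prognosis(rs.group, val.clinical).fits[0]
print(f"validation HR = {fit.hr:.2f} "
      f"(95% CI {fit.ci95[0]:.2f}-{fit.ci95[1]:.2f}), p = {fit.wald_p:.2g}")
print("c-index =", round(concordance_index(
    rs.score, val.clinical['time'], val.clinical['event'].astype(bool)), 3))
```

```
validation HR = 2.32 (95% CI 1.31-4.10), p = 0.0038
c-index = 0.660
```

Patients the forest places above the discovery median risk score die at
2.3 times the rate of the low group in an independent cohort, and the
continuous score orders survival times with concordance 0.66 — in the
range expected for a single-modality transcriptomic signature.

A command-line surface wraps the same stages
(`psilc simulate | preprocess | dysregulate | build-cps | fit-cp | score |
evaluate | fit-psilc | predict-psilc | sl-screen | stats`); run
`psilc --help`.

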