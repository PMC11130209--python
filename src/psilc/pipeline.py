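"""Convenience orchestration of the discovery -> validation workflow.

These helpers wire the per-module operations together in the order the
analysis runs them: truncate follow-up, z-score within each cohort, fit
per-CP models on discovery, score and group each validation cohort with
discovery cut-offs, and evaluate prognosis on the pooled validation risk
groups.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort_io import ExpressionCohort, truncate_survival, zscore_genes
from .cp_risk import (
    CPModel,
    assign_risk_groups,
    build_cp_model,
    evaluate_prognosis,
    score_patients,
)

__all__ = ["prepare_cohort", "fit_cp_models", "combined_validation_ranking"]


def prepare_cohort(cohort: ExpressionCohort, horizon: float = 10.0) -> ExpressionCohort:
    """Tumour samples only, survival truncated at ``horizon``, per-gene
    z-scores within the cohort."""
    tumour, _ = cohort.split_tumour_normal()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return zscore_genes(truncate_survival(tumour, horizon))


def fit_cp_models(
    cps, discovery: ExpressionCohort, p_select: float = 0.05, horizon: float = 10.0
) -> list[CPModel]:
    """Per-CP discovery models (the discovery cohort is prepared here)."""
    prepared = discovery if discovery.standardized else prepare_cohort(discovery, horizon)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [
            build_cp_model(cp, prepared, p_select=p_select, horizon=horizon)
            for cp in cps.cps
        ]


def combined_validation_ranking(
    cp_models: list[CPModel],
    validation_cohorts: list[ExpressionCohort],
    horizon: float = 10.0,
    n_groups: int = 2,
) -> pd.DataFrame:
    """Pool risk groups over all validation cohorts per CP and test them.

    Returns one row per informative CP with the combined-validation Wald
    p-value and hazard ratio of the high-vs-low contrast (NaN where the
    evaluation is degenerate, e.g. one group absent).
    """
    prepared = [prepare_cohort(c, horizon) for c in validation_cohorts]
    rows = []
    for model in cp_models:
        if model.non_informative:
            rows.append({"cp_id": model.cp_id, "wald_p": np.nan, "hr": np.nan,
                         "n_genes": 0})
            continue
        groups, clin = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for cohort in prepared:
                rs = assign_risk_groups(
                    score_patients(model, cohort), model.cutoffs, n_groups=n_groups
                )
                groups.append(rs.group)
                clin.append(cohort.clinical)
        pooled_groups = pd.concat(groups)
        pooled_clin = pd.concat(clin)
        try:
            res = evaluate_prognosis(pooled_groups, pooled_clin)
            if res.fallback or not res.fits:
                rows.append({"cp_id": model.cp_id, "wald_p": np.nan,
                             "hr": np.nan, "n_genes": len(model.betas)})
            else:
                high = [f for f in res.fits if f.term == "group_high"][0]
                rows.append({"cp_id": model.cp_id, "wald_p": high.wald_p,
                             "hr": high.hr, "n_genes": len(model.betas)})
        except ValueError:
            rows.append({"cp_id": model.cp_id, "wald_p": np.nan, "hr": np.nan,
                         "n_genes": len(model.betas)})
    return pd.DataFrame(rows).set_index("cp_id")
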