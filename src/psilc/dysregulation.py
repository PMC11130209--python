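"""Differentially expressed and differentially variable genes.

Two complementary screens of tumour-vs-normal dysregulation on log2
abundance:

* **Differential expression** — a per-gene two-group test with
  empirical-Bayes variance moderation.  Per-gene pooled variances are
  shrunk towards a common prior ``s0^2`` with prior degrees of freedom
  ``d0``, both estimated by moment matching of the gene-wise variance
  distribution against its scaled-F marginal; the moderated t statistic has
  ``d + d0`` degrees of freedom.  A plain Welch t-test is available via
  ``moderated=False``.
* **Differential variance** — the two-sided F ratio test
  ``sigma_tumour^2 / sigma_normal^2``, with directionality and a minimum
  tumour-sd filter applied on top of the FDR threshold.

Default significance rules: |log2FC| > 1 with BH q < 0.001 for expression;
sigma_tumour > sigma_normal, sigma_tumour > 0.5 and BH q < 1e-15 for
variance.  The union of the two significant sets is the dysregulated-gene
resource fed to pathway mapping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import ExpressionCohort

__all__ = [
    "differential_expression",
    "differential_variance",
    "dysregulated_union",
    "moderation_prior",
]


def _check_groups(tumour: ExpressionCohort, normal: ExpressionCohort) -> None:
    if tumour.standardized or normal.standardized:
        raise ValueError("dysregulation tests need unstandardized log2 values")
    if not tumour.genes.equals(normal.genes):
        raise ValueError("tumour and normal cohorts must share the gene index")
    if tumour.n_samples < 2 or normal.n_samples < 2:
        raise ValueError("need at least 2 samples per group")


def moderation_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-matched prior (d0, s0^2) for variance shrinkage.

    Under the hierarchical model the gene-wise sample variances are
    marginally ``s0^2 * F(d, d0)``-distributed.  Matching the observed mean
    ``m`` and variance ``v`` of the variances gives::

        v / m^2 = 2 (d + d0 - 2) / (d (d0 - 4))

    solved for ``d0``, then ``s0^2 = m (d0 - 2) / d0``.  Overdispersion too
    small to be consistent with finite ``d0`` (near-constant variances)
    yields a very large ``d0``, i.e. near-complete pooling.
    """
    s2 = np.asarray(s2, dtype=float)
    m = s2.mean()
    v = s2.var(ddof=1)
    if m <= 0:
        raise ValueError("all variances are zero")
    c = v / m**2
    denom = c * d - 2.0
    if denom <= 1e-12:
        d0 = 1e6
    else:
        d0 = (2.0 * d - 4.0 + 4.0 * c * d) / denom
        d0 = float(np.clip(d0, 1.0, 1e6))
    s0_sq = m * (d0 - 2.0) / d0 if d0 > 2.0 else m
    return d0, float(s0_sq)


def differential_expression(
    tumour: ExpressionCohort,
    normal: ExpressionCohort,
    abs_log2fc_min: float = 1.0,
    q_max: float = 0.001,
    moderated: bool = True,
) -> tuple[pd.DataFrame, set[str]]:
    """Per-gene two-group test of mean log2 abundance, tumour vs normal.

    Returns the per-gene table (mean_tumour, mean_normal, log2fc,
    t_statistic, p, q) and the significant set
    ``{|log2fc| > abs_log2fc_min and q < q_max}``.
    """
    _check_groups(tumour, normal)
    x = tumour.values.to_numpy()
    y = normal.values.to_numpy()
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    log2fc = m1 - m2

    if moderated:
        d = n1 + n2 - 2
        s2 = (x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)) / d
        d0, s0_sq = moderation_prior(s2, d)
        s2_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
        se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
        df = min(d + d0, 1e6)
        t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
        t, p = res.statistic, res.pvalue
        t = np.nan_to_num(t)
        p = np.where(np.isnan(p), 1.0, p)

    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": tumour.genes,
            "mean_tumour": m1,
            "mean_normal": m2,
            "log2fc": log2fc,
            "t_statistic": t,
            "p": p,
            "q": q,
        }
    ).reset_index(drop=True)
    sig = set(table.loc[(table.log2fc.abs() > abs_log2fc_min) & (table.q < q_max), "gene"])
    return table, sig


def differential_variance(
    tumour: ExpressionCohort,
    normal: ExpressionCohort,
    sigma_min: float = 0.5,
    q_max: float = 1e-15,
) -> tuple[pd.DataFrame, set[str]]:
    """Two-sided F-test of the tumour/normal variance ratio per gene.

    Significant genes additionally require sigma_tumour > sigma_normal and
    sigma_tumour > ``sigma_min`` (log2 units).  Genes with zero variance in
    either group are skipped (``skipped`` flag; no p-value).
    """
    _check_groups(tumour, normal)
    x = tumour.values.to_numpy()
    y = normal.values.to_numpy()
    n1, n2 = x.shape[1], y.shape[1]
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    skipped = (v1 == 0) | (v2 == 0)
    f = np.where(skipped, np.nan, v1 / np.where(v2 > 0, v2, 1.0))
    sf = stats.f.sf(f, n1 - 1, n2 - 1)
    cdf = stats.f.cdf(f, n1 - 1, n2 - 1)
    p = np.minimum(2.0 * np.minimum(sf, cdf), 1.0)
    tested = ~skipped
    q = np.full(len(p), np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": tumour.genes,
            "sigma_tumour": np.sqrt(v1),
            "sigma_normal": np.sqrt(v2),
            "f_statistic": f,
            "p": p,
            "q": q,
            "skipped": skipped,
        }
    ).reset_index(drop=True)
    sig_mask = (
        ~table.skipped
        & (table.sigma_tumour > table.sigma_normal)
        & (table.sigma_tumour > sigma_min)
        & (table.q < q_max)
    )
    return table, set(table.loc[sig_mask, "gene"])


def dysregulated_union(
    de_set: set[str], dv_set: set[str]
) -> tuple[list[str], dict[str, int]]:
    """Union of the two significant sets in deterministic lexicographic
    order, with the sizes of the inputs and their overlap."""
    union = sorted(set(de_set) | set(dv_set))
    sizes = {
        "n_de": len(set(de_set)),
        "n_dv": len(set(dv_set)),
        "n_overlap": len(set(de_set) & set(dv_set)),
        "n_union": len(union),
    }
    return union, sizes
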