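"""Contextual synthetic-lethality screening on CRISPR gene-effect profiles.

Cell lines are classified into high- and low-risk groups by the trained
multivariable survival model, and per-gene knockout fitness effects (GE
scores; more negative = stronger dependency) are compared between groups.
A gene is a candidate contextual synthetic-lethal dependency of the
high-risk state when its mean GE score is clearly essential-range in the
high group (< -0.5), clearly tolerated in the low group (> -0.75), lower in
high than low, and the one-sided Welch test on the two groups is
significant.  Genes commonly essential across the whole panel (median GE
score < -1) are annotated and, by default, excluded post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneEffectScreen",
    "OverlapResult",
    "classify_lines",
    "sl_screen",
    "overlap_analysis",
    "load_ge_screen",
    "write_ge_screen",
]

SL_COLUMNS = [
    "gene",
    "mean_high",
    "mean_low",
    "delta",
    "p",
    "passes_filter",
    "essential",
    "n_high",
    "n_low",
    "significant",
]


@dataclass
class GeneEffectScreen:
    """Gene x cell-line CRISPR gene-effect matrix with line annotations.

    ``annotations`` is indexed by cell line and carries at least
    ``psilc_group`` ({"high", "low"}) plus driver-status columns such as
    ``erbb2_status`` ({"amplified", "mutant", "wildtype"}).
    """

    ge: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.ge.columns.equals(self.annotations.index):
            self.annotations = self.annotations.reindex(self.ge.columns)
            if self.annotations.isna().all(axis=1).any():
                raise ValueError("cell line missing from annotations")

    @property
    def essential(self) -> pd.Series:
        """Commonly essential genes: median GE score across ALL lines < -1."""
        return self.ge.median(axis=1) < -1.0

    def lines_in_group(self, group: str) -> pd.Index:
        return self.annotations.index[self.annotations["psilc_group"] == group]


@dataclass
class OverlapResult:
    n_list_all: int
    n_list_wt: int
    n_overlap: int
    n_universe: int
    fisher_p: float
    spearman_rho: float | None
    overlap_genes: list[str] = field(default_factory=list)


def classify_lines(model, cp_models, line_expression, cutoff: float) -> pd.DataFrame:
    """Score a cell-line expression panel with the trained multivariable
    model and split lines at ``cutoff`` (score > cutoff -> "high").

    ``line_expression`` must already be standardized within the panel.
    Returns a per-line annotation frame (psilc_score, psilc_group).
    """
    from .cp_risk import assign_risk_groups
    from .psilc_model import build_feature_matrix, predict_psilc

    if line_expression.n_samples < 6:
        import warnings

        warnings.warn(
            "fewer than 6 cell lines: group-wise tests may be under-powered",
            stacklevel=2,
        )
    features = build_feature_matrix(cp_models, line_expression)
    scores = predict_psilc(model, features, assign_groups=False).score
    groups = assign_risk_groups(
        scores, {"median": cutoff}, n_groups=2
    ).group.map({"low": "low", "high": "high"})
    return pd.DataFrame({"psilc_score": scores, "psilc_group": groups})


def _welch_one_sided(high: np.ndarray, low: np.ndarray) -> float:
    """One-sided Welch t-test P(mean_high < mean_low)."""
    res = stats.ttest_ind(high, low, equal_var=False, alternative="less")
    return float(res.pvalue)


def sl_screen(
    screen: GeneEffectScreen,
    exclude_erbb2_altered: bool = False,
    high_mean_max: float = -0.5,
    low_mean_min: float = -0.75,
    min_group: int = 3,
    alpha: float = 0.05,
    exclude_essential: bool = False,
) -> pd.DataFrame:
    """Per-gene contextual dependency screen between high and low lines.

    A gene ``passes_filter`` iff mean(GE | high) < ``high_mean_max`` AND
    mean(GE | low) > ``low_mean_min`` AND mean(GE | high) < mean(GE | low)
    (strict inequalities).  The one-sided Welch p (alternative:
    mean_high < mean_low) is computed only when both groups retain at least
    ``min_group`` lines; otherwise p is missing and nothing is significant.
    ``significant = passes_filter AND p < alpha``; commonly essential genes
    are annotated post hoc (full-panel flag, computed before any ERBB2
    exclusion) and dropped from the significant list only when
    ``exclude_essential`` is set, since a contextual dependency strong
    enough to drag the panel median below -1 is still a real selective hit.
    """
    essential = screen.essential
    annotations = screen.annotations
    ge = screen.ge
    if exclude_erbb2_altered:
        keep = annotations["erbb2_status"] == "wildtype"
        ge = ge.loc[:, keep.values]
        annotations = annotations.loc[keep.values]

    high_lines = annotations.index[annotations["psilc_group"] == "high"]
    low_lines = annotations.index[annotations["psilc_group"] == "low"]
    high = ge[high_lines].to_numpy()
    low = ge[low_lines].to_numpy()
    mean_high = high.mean(axis=1) if high.shape[1] else np.full(len(ge), np.nan)
    mean_low = low.mean(axis=1) if low.shape[1] else np.full(len(ge), np.nan)
    passes = (
        (mean_high < high_mean_max)
        & (mean_low > low_mean_min)
        & (mean_high < mean_low)
    )

    testable = len(high_lines) >= min_group and len(low_lines) >= min_group
    if testable:
        p = stats.ttest_ind(
            high, low, axis=1, equal_var=False, alternative="less"
        ).pvalue
    else:
        p = np.full(len(ge), np.nan)

    res = pd.DataFrame(
        {
            "gene": ge.index,
            "mean_high": mean_high,
            "mean_low": mean_low,
            "delta": mean_high - mean_low,
            "p": p,
            "passes_filter": passes,
            "essential": essential.values,
            "n_high": len(high_lines),
            "n_low": len(low_lines),
        }
    )
    significant = res["passes_filter"] & (res["p"] < alpha)
    if exclude_essential:
        significant &= ~res["essential"]
    res["significant"] = significant.fillna(False)
    return res.reset_index(drop=True)


def overlap_analysis(
    res_all: pd.DataFrame, res_wt: pd.DataFrame, universe
) -> OverlapResult:
    """Overlap of the significant gene lists of two screens.

    The Fisher (hypergeometric upper-tail) p asks how surprising the overlap
    is given the two list sizes within ``universe`` (the genes tested in
    both analyses); the Spearman rho correlates the two mean-difference
    (delta) vectors over the overlap genes (undefined below 3 genes).
    """
    universe = set(universe)
    list_all = set(res_all.loc[res_all["significant"], "gene"])
    list_wt = set(res_wt.loc[res_wt["significant"], "gene"])
    if len(universe) < max(len(list_all), len(list_wt)):
        raise ValueError("universe smaller than a significant list")
    overlap = sorted(list_all & list_wt)
    n, k = len(list_wt), len(overlap)
    big_n, big_k = len(universe), len(list_all)
    fisher_p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
    rho = None
    if len(overlap) >= 3:
        d_all = res_all.set_index("gene").loc[overlap, "delta"]
        d_wt = res_wt.set_index("gene").loc[overlap, "delta"]
        rho = float(stats.spearmanr(d_all, d_wt).statistic)
    return OverlapResult(
        n_list_all=len(list_all),
        n_list_wt=len(list_wt),
        n_overlap=k,
        n_universe=big_n,
        fisher_p=fisher_p,
        spearman_rho=rho,
        overlap_genes=overlap,
    )


def load_ge_screen(ge_tsv, annotation_tsv) -> GeneEffectScreen:
    ge = pd.read_csv(ge_tsv, sep="\t", index_col=0)
    annotations = pd.read_csv(annotation_tsv, sep="\t", index_col=0)
    return GeneEffectScreen(ge=ge, annotations=annotations)


def write_ge_screen(screen: GeneEffectScreen, ge_tsv, annotation_tsv) -> None:
    out = screen.ge.copy()
    out.index.name = "gene_id"
    out.to_csv(ge_tsv, sep="\t")
    ann = screen.annotations.copy()
    ann.index.name = "line"
    ann.to_csv(annotation_tsv, sep="\t")
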