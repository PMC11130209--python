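"""From dysregulated genes to a non-redundant database of pathway clusters.

The mapping proceeds in four steps:

1. hypergeometric over-representation of the dysregulated gene list in a
   pathway database (enriched: >= 3 query genes and BH q < 0.1);
2. pairwise similarity of enriched pathways by the overlap coefficient
   |A∩B| / min(|A|,|B|), hierarchical clustering on 1 - similarity, and
   selection of the cluster number k by average silhouette — among k whose
   average silhouette is within a tolerance of the maximum, the largest k
   wins (favouring resolution when it costs nothing);
3. pooling each cluster's pathways into a "cluster of pathways" (CP) whose
   member genes are the dysregulated genes of its pathways, plus a leftover
   CP for dysregulated genes hitting no enriched pathway;
4. de-redundancy: a gene appearing in several CPs is assigned to the CP
   where it is most *relevant* — R = (number of CP co-members whose
   expression correlates with it, |Spearman rho| > 0.3) / (CP size).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .cohort_io import ExpressionCohort, PathwayDB

__all__ = [
    "CP",
    "CPSet",
    "ClusterSolution",
    "GeneRelevance",
    "over_representation",
    "overlap_coefficient",
    "cluster_pathways",
    "build_cps",
    "deredundant_cps",
    "cps_from_pathways",
]


@dataclass
class CP:
    """A cluster of pathways: the unit of risk modelling."""

    cp_id: str
    pathways: list[str]
    genes: frozenset
    leftover: bool = False


@dataclass
class CPSet:
    cps: list[CP]
    redundant: bool = True
    leftover_cp_id: str | None = None
    assignment: dict[str, str] = field(default_factory=dict)  # gene -> cp_id

    def __getitem__(self, cp_id: str) -> CP:
        for cp in self.cps:
            if cp.cp_id == cp_id:
                return cp
        raise KeyError(cp_id)

    @property
    def cp_ids(self) -> list[str]:
        return [cp.cp_id for cp in self.cps]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for cp in self.cps:
            out |= cp.genes
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "redundant": self.redundant,
                "leftover_cp_id": self.leftover_cp_id,
                "cps": [
                    {
                        "cp_id": cp.cp_id,
                        "pathways": cp.pathways,
                        "genes": sorted(cp.genes),
                        "leftover": cp.leftover,
                    }
                    for cp in self.cps
                ],
                "assignment": self.assignment,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CPSet":
        obj = json.loads(text)
        return cls(
            cps=[
                CP(c["cp_id"], c["pathways"], frozenset(c["genes"]), c["leftover"])
                for c in obj["cps"]
            ],
            redundant=obj["redundant"],
            leftover_cp_id=obj["leftover_cp_id"],
            assignment=obj.get("assignment", {}),
        )


@dataclass
class ClusterSolution:
    silhouette_by_k: dict[int, float]
    chosen_k: int
    labels: dict[str, int]  # pathway -> cluster label
    linkage: str
    tolerance: float


@dataclass
class GeneRelevance:
    gene: str
    cp_id: str
    correlated_count: int
    cp_size: int
    r: float
    rho_threshold: float


# ---------------------------------------------------------------------------


def over_representation(
    query_genes,
    db: PathwayDB,
    universe,
    min_overlap: int = 3,
    q_max: float = 0.1,
) -> tuple[pd.DataFrame, set[str]]:
    """Hypergeometric upper-tail enrichment of ``query_genes`` in each
    pathway, intersected with ``universe`` before testing; BH adjustment
    across tested pathways.  Enriched pathways need at least ``min_overlap``
    query genes and q < ``q_max``."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    rows = []
    for name, genes in db.sets.items():
        in_universe = genes & universe
        if not in_universe:
            continue
        k = len(in_universe & query)
        rows.append(
            {
                "pathway": name,
                "k_overlap": k,
                "K_pathway": len(in_universe),
                "n_query": len(query),
                "N_universe": len(universe),
                "p": float(
                    stats.hypergeom.sf(k - 1, len(universe), len(in_universe), len(query))
                ),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["q"] = pd.Series(dtype=float)
    enriched = set(
        table.loc[(table.k_overlap >= min_overlap) & (table.q < q_max), "pathway"]
    )
    return table, enriched


def overlap_coefficient(a, b) -> float:
    """|a ∩ b| / min(|a|, |b|); 1 iff one set contains the other."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def _overlap_distance_matrix(pathway_sets: dict[str, frozenset]) -> np.ndarray:
    names = list(pathway_sets)
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - overlap_coefficient(
                pathway_sets[names[i]], pathway_sets[names[j]]
            )
    return d


def cluster_pathways(
    pathway_sets: dict[str, frozenset],
    k_min: int = 2,
    method: str = "average",
    tolerance: float = 0.01,
) -> ClusterSolution:
    """Agglomerative clustering of pathways on 1 - overlap coefficient.

    For every k in [k_min, n-1] the tree is cut and the average silhouette
    computed on the same distance matrix; the chosen k is the largest one
    whose average silhouette is within ``tolerance`` of the maximum.
    """
    names = list(pathway_sets)
    n = len(names)
    if n < 3:
        raise ValueError("need at least 3 pathways to cluster")
    dist = _overlap_distance_matrix(pathway_sets)
    if not dist.any():
        raise ValueError("all pathways identical: distance matrix is zero")
    z = linkage(squareform(dist, checks=False), method=method)
    cuts = cut_tree(z, n_clusters=list(range(k_min, n)))
    sil: dict[int, float] = {}
    for col, k in enumerate(range(k_min, n)):
        labels = cuts[:, col]
        sil[k] = float(silhouette_score(dist, labels, metric="precomputed"))
    best = max(sil.values())
    chosen_k = max(k for k, s in sil.items() if s >= best - tolerance)
    labels = cuts[:, chosen_k - k_min]
    return ClusterSolution(
        silhouette_by_k=sil,
        chosen_k=chosen_k,
        labels={name: int(lab) for name, lab in zip(names, labels)},
        linkage=method,
        tolerance=tolerance,
    )


def build_cps(
    solution: ClusterSolution,
    pathway_sets: dict[str, frozenset],
    all_dysregulated_genes,
) -> CPSet:
    """Pool each cluster's pathways into a CP whose member genes are the
    dysregulated genes of its pathways; dysregulated genes hitting no
    enriched pathway form a leftover CP of their own."""
    missing = set(pathway_sets) - set(solution.labels)
    if missing:
        raise ValueError(f"pathways without cluster label: {sorted(missing)[:5]}")
    dysregulated = set(all_dysregulated_genes)
    by_label: dict[int, list[str]] = {}
    for name in pathway_sets:
        by_label.setdefault(solution.labels[name], []).append(name)
    cps = []
    for i, label in enumerate(sorted(by_label), start=1):
        members = sorted(by_label[label])
        genes = frozenset().union(*(pathway_sets[m] for m in members)) & dysregulated
        cps.append(CP(cp_id=f"CP{i:02d}", pathways=members, genes=genes))
    cps = [cp for cp in cps if cp.genes]
    mapped = frozenset().union(*(cp.genes for cp in cps)) if cps else frozenset()
    leftover_genes = dysregulated - mapped
    leftover_id = None
    if leftover_genes:
        leftover_id = f"CP{len(cps) + 1:02d}"
        cps.append(
            CP(cp_id=leftover_id, pathways=[], genes=frozenset(leftover_genes),
               leftover=True)
        )
    return CPSet(cps=cps, redundant=True, leftover_cp_id=leftover_id)


def cps_from_pathways(db: PathwayDB, gene_filter=None) -> CPSet:
    """One CP per pathway (identity collapse), optionally restricted to a
    gene filter — convenient when redundancy removal is not wanted."""
    keep = None if gene_filter is None else set(gene_filter)
    cps = []
    for i, (name, genes) in enumerate(db.sets.items(), start=1):
        members = genes if keep is None else frozenset(genes & keep)
        if members:
            cps.append(CP(cp_id=f"CP{i:02d}", pathways=[name], genes=members))
    return CPSet(cps=cps, redundant=True)


def deredundant_cps(
    cps: CPSet,
    expression: ExpressionCohort,
    rho_threshold: float = 0.3,
) -> tuple[CPSet, list[GeneRelevance]]:
    """Assign every multi-CP gene to its most relevant CP.

    For each candidate CP, ``correlated_count`` is the number of co-member
    genes whose discovery-cohort Spearman |rho| with the gene exceeds
    ``rho_threshold`` (self excluded); relevance R = correlated_count /
    cp_size, where cp_size counts co-members (the gene itself excluded).
    Ties on R prefer the larger correlated_count, then the earlier CP.
    The result has every gene in exactly one CP.
    """
    if not cps.redundant:
        raise ValueError("CP set is already non-redundant")
    all_genes = sorted(cps.all_genes())
    missing = [g for g in all_genes if g not in expression.genes]
    if missing:
        raise ValueError(f"gene(s) absent from expression: {missing[:5]}")

    membership: dict[str, list[str]] = {g: [] for g in all_genes}
    cp_order = {cp.cp_id: i for i, cp in enumerate(cps.cps)}
    for cp in cps.cps:
        for g in cp.genes:
            membership[g].append(cp.cp_id)

    # Spearman = Pearson on ranks (average ranks for ties); one matrix pass
    expr = expression.values.loc[all_genes]
    ranks = expr.rank(axis=1, method="average").to_numpy()
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    norms[norms == 0] = 1.0
    ranks /= norms[:, None]
    rho = ranks @ ranks.T
    gi = {g: i for i, g in enumerate(all_genes)}

    relevances: list[GeneRelevance] = []
    assignment: dict[str, str] = {}
    for g in all_genes:
        cands = membership[g]
        if len(cands) == 1:
            assignment[g] = cands[0]
            continue
        best = None
        for cp_id in sorted(cands, key=lambda c: cp_order[c]):
            co = [m for m in cps[cp_id].genes if m != g]
            if co:
                idx = [gi[m] for m in co]
                count = int((np.abs(rho[gi[g], idx]) > rho_threshold).sum())
                r = count / len(co)
            else:
                count, r = 0, 0.0
            rec = GeneRelevance(g, cp_id, count, len(co), r, rho_threshold)
            relevances.append(rec)
            if best is None or (rec.r, rec.correlated_count) > (
                best.r, best.correlated_count
            ):
                best = rec
        assignment[g] = best.cp_id

    new_cps = []
    for cp in cps.cps:
        genes = frozenset(g for g in cp.genes if assignment[g] == cp.cp_id)
        if genes:
            new_cps.append(CP(cp.cp_id, cp.pathways, genes, leftover=cp.leftover))
    return (
        CPSet(
            cps=new_cps,
            redundant=False,
            leftover_cp_id=cps.leftover_cp_id,
            assignment=assignment,
        ),
        relevances,
    )
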