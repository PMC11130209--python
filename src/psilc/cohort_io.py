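"""Cohort data model, TSV/GMT readers and writers, and pre-modelling transforms.

An :class:`ExpressionCohort` couples a log2 gene x sample abundance matrix
with per-sample clinical outcome records (survival time in years, event
indicator, endpoint type and the covariates used for adjusted models).
The transforms here are the standard preprocessing applied before any
survival modelling: removal of unexpressed genes against a reference-set
floor, removal of mostly-zero count rows, per-gene z-scoring, and
truncation of follow-up at a fixed horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionCohort",
    "PathwayDB",
    "CLINICAL_COLUMNS",
    "load_expression",
    "write_expression",
    "load_gmt",
    "write_gmt",
    "filter_unexpressed",
    "filter_zero_fraction",
    "zscore_genes",
    "truncate_survival",
]

#: Clinical columns carried per sample.  ``time`` is in years, ``event`` is
#: 0/1, ``endpoint`` one of OS/MFS/DFS, ``purity`` in [0, 1]; ``chemo`` and
#: ``tnbc_or_her2`` may be NaN where unknown.
CLINICAL_COLUMNS = [
    "time",
    "event",
    "endpoint",
    "age",
    "t_stage",
    "nodal",
    "purity",
    "chemo",
    "tnbc_or_her2",
    "is_normal",
]


@dataclass
class ExpressionCohort:
    """A gene x sample log2 expression matrix with aligned clinical metadata.

    Parameters
    ----------
    cohort_id : str
        Label for the cohort (e.g. ``"discovery"``).
    values : pandas.DataFrame
        Genes as rows, samples as columns, log2 abundance.
    clinical : pandas.DataFrame
        One row per sample (index = sample id) with `CLINICAL_COLUMNS`.
    role : {"discovery", "validation"}
    standardized : bool
        True once per-gene z-scoring has been applied.
    """

    cohort_id: str
    values: pd.DataFrame
    clinical: pd.DataFrame
    role: str = "validation"
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if not self.values.columns.equals(self.clinical.index):
            # align, adding unknown-metadata rows for samples missing from
            # the clinical table (they are flagged via missing_clinical)
            missing = self.values.columns.difference(self.clinical.index)
            self.clinical = self.clinical.reindex(self.values.columns)
            if len(missing):
                warnings.warn(
                    f"{len(missing)} sample(s) missing clinical metadata: "
                    f"{list(missing)[:5]}",
                    stacklevel=2,
                )
        if "missing_clinical" not in self.clinical.columns:
            self.clinical = self.clinical.assign(
                missing_clinical=self.clinical["time"].isna()
                & self.clinical["event"].isna()
            )
        t = self.clinical["time"]
        if (t.dropna() < 0).any():
            raise ValueError("negative survival times")
        has_event = self.clinical["event"].notna()
        if (has_event & t.isna()).any():
            raise ValueError("event recorded without survival time")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples) -> "ExpressionCohort":
        samples = pd.Index(samples)
        return replace(
            self,
            values=self.values.loc[:, samples],
            clinical=self.clinical.loc[samples],
        )

    def subset_genes(self, genes) -> "ExpressionCohort":
        return replace(self, values=self.values.loc[pd.Index(genes)])

    def split_tumour_normal(self) -> tuple["ExpressionCohort", "ExpressionCohort"]:
        """Split into (tumour, normal) cohorts on the ``is_normal`` flag."""
        flag = self.clinical["is_normal"].fillna(False).astype(bool)
        return (
            self.subset_samples(self.samples[~flag.values]),
            self.subset_samples(self.samples[flag.values]),
        )

    def copy(self) -> "ExpressionCohort":
        return replace(self, values=self.values.copy(), clinical=self.clinical.copy())


@dataclass
class PathwayDB:
    """Named gene sets (e.g. from a GMT file)."""

    sets: dict[str, frozenset]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"pathway {name!r} is empty")
            self.sets[name] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers


def load_expression(
    tsv_path,
    clinical_tsv_path,
    cohort_id: str = "cohort",
    role: str = "validation",
    drop_denovo_metastatic: bool = True,
) -> ExpressionCohort:
    """Read an expression TSV (rows = genes, first column ``gene_id``) and a
    clinical TSV (one row per sample) into an :class:`ExpressionCohort`.

    Samples present in the expression matrix but absent from the clinical
    table are kept with unknown metadata and flagged.  De-novo metastatic
    records (time = 0, event = 1) are excluded by default.
    """
    raw = pd.read_csv(tsv_path, sep="\t", index_col=0)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique()
        raise ValueError(f"duplicate gene row(s): {list(dupes)[:5]}")
    for j, col in enumerate(raw.columns):
        bad = pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.values)[0])
            raise ValueError(
                f"non-numeric expression value at gene {raw.index[i]!r}, "
                f"sample {col!r}"
            )
    values = raw.astype(float)
    values.index.name = None
    values.columns.name = None

    clinical = pd.read_csv(clinical_tsv_path, sep="\t", index_col=0)
    clinical.index.name = None
    clinical = clinical.reindex(columns=CLINICAL_COLUMNS)
    absent = values.columns.difference(clinical.index)
    if len(absent):
        warnings.warn(
            f"{len(absent)} sample(s) missing clinical metadata: "
            f"{list(absent)[:5]}",
            stacklevel=2,
        )
    if drop_denovo_metastatic:
        denovo = (clinical["time"] == 0) & (clinical["event"] == 1)
        if denovo.any():
            warnings.warn(
                f"excluding {int(denovo.sum())} de-novo metastatic sample(s) "
                "(time = 0, event = 1)",
                stacklevel=2,
            )
            drop = clinical.index[denovo]
            clinical = clinical.drop(index=drop)
            values = values.drop(columns=[s for s in drop if s in values.columns])
    clinical = clinical.reindex(values.columns)
    return ExpressionCohort(cohort_id, values, clinical, role=role)


def write_expression(cohort: ExpressionCohort, tsv_path, clinical_tsv_path) -> None:
    """Write the expression matrix and clinical table as TSV files that
    round-trip through :func:`load_expression`."""
    out = cohort.values.copy()
    out.index.name = "gene_id"
    out.to_csv(tsv_path, sep="\t")
    clin = cohort.clinical[CLINICAL_COLUMNS].copy()
    clin.index.name = "sample_id"
    clin.to_csv(clinical_tsv_path, sep="\t")


def load_gmt(path, source: str = "") -> PathwayDB:
    """Parse a GMT file (name, description, genes...); the description column
    is discarded and duplicate genes within a set are collapsed."""
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    if not sets:
        warnings.warn("empty GMT file", stacklevel=2)
    return PathwayDB(sets, source=source or str(path))


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for name, genes in db.sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# transforms


def filter_unexpressed(
    tumour: ExpressionCohort,
    normal: ExpressionCohort,
    reference_genes,
) -> tuple[ExpressionCohort, ExpressionCohort, float]:
    """Remove genes unexpressed in both cohorts.

    The expression floor is the median, over ``reference_genes`` (e.g.
    Y-chromosome genes in a female cancer cohort, where they mark background
    signal), of each reference gene's mean expression computed on the pooled
    tumour+normal sample set.  A gene is removed only when its mean falls
    below the floor in the tumour cohort AND in the normal cohort.

    Returns the filtered cohorts and the floor used (log2 units).
    """
    reference_genes = pd.Index(sorted(set(reference_genes)))
    if len(reference_genes) == 0:
        raise ValueError("empty reference gene set")
    missing = reference_genes.difference(tumour.genes)
    if len(missing):
        raise ValueError(f"reference genes not measured: {list(missing)[:5]}")
    pooled = pd.concat([tumour.values, normal.values], axis=1)
    floor = float(pooled.loc[reference_genes].mean(axis=1).median())
    mean_t = tumour.values.mean(axis=1)
    mean_n = normal.values.mean(axis=1)
    keep = ~((mean_t < floor) & (mean_n < floor))
    kept = tumour.genes[keep.values]
    return tumour.subset_genes(kept), normal.subset_genes(kept), floor


def filter_zero_fraction(counts: pd.DataFrame, max_zero_fraction: float = 0.75) -> pd.DataFrame:
    """Drop rows whose fraction of zero entries strictly exceeds
    ``max_zero_fraction`` (default: genes with >75% zero counts)."""
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")
    zero_frac = (counts == 0).mean(axis=1)
    return counts.loc[zero_frac <= max_zero_fraction]


def zscore_genes(cohort: ExpressionCohort) -> ExpressionCohort:
    """Per-gene z-scores within the cohort (mean 0, sd 1, n-1 denominator).

    Constant genes are dropped with a warning; a cohort already standardized
    or with fewer than two samples is rejected.
    """
    if cohort.standardized:
        raise ValueError("cohort is already standardized")
    if cohort.n_samples < 2:
        raise ValueError("need at least 2 samples to z-score")
    mu = cohort.values.mean(axis=1)
    sd = cohort.values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant gene(s) during z-scoring",
            stacklevel=2,
        )
    vals = cohort.values.loc[~constant.values]
    z = vals.sub(mu[~constant], axis=0).div(sd[~constant], axis=0)
    return replace(cohort, values=z, standardized=True)


def truncate_survival(cohort: ExpressionCohort, horizon: float) -> ExpressionCohort:
    """Administratively censor follow-up strictly beyond ``horizon`` years:
    time > horizon becomes (horizon, event = 0); an event exactly at the
    horizon is kept as an event."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    clin = cohort.clinical.copy()
    if (clin["time"].dropna() < 0).any():
        raise ValueError("negative survival times")
    over = clin["time"] > horizon
    clin.loc[over, "time"] = horizon
    clin.loc[over, "event"] = 0
    return replace(cohort, clinical=clin)
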