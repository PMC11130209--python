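"""Synthetic cohorts with known ground truth.

This module generates the three kinds of input the pipeline consumes —
pathway gene-set databases, multi-cohort tumour/normal expression with
proportional-hazards survival outcomes, and CRISPR gene-effect screens —
with every planted effect recorded in a :class:`TruthRecord` so that each
downstream stage can be tested against known truth.

The generative model is deliberately the simplest one consistent with what
the downstream estimators assume: Gaussian log2 abundance per gene, additive
log2 fold-change shifts and standard-deviation inflation in tumours,
exponential event times with hazard ``baseline_hazard * exp(eta)`` where
``eta`` is a linear predictor over planted prognostic genes, independent
exponential censoring plus an administrative follow-up cut, and a
treatment-by-risk-group hazard multiplier confined to the planted high-risk
stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import CLINICAL_COLUMNS, ExpressionCohort, PathwayDB
from .crispr_sl import GeneEffectScreen

__all__ = [
    "SimConfig",
    "TruthRecord",
    "gene_ids",
    "generate_pathway_db",
    "generate_block_pathway_db",
    "generate_cohorts",
    "generate_ge_screen",
]


def gene_ids(n: int) -> list[str]:
    """Deterministic gene identifiers G0001, G0002, ..."""
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


@dataclass
class SimConfig:
    """Configuration of the cohort simulator.

    The defaults describe the study conditions exercised throughout the test
    suite: a discovery cohort of 150 tumours with matched normals, three
    validation cohorts of 100 tumours, 2000 genes, 25 pathways, ~10 years of
    follow-up with moderate censoring, and a protective chemotherapy effect
    (log-HR ``interaction_loghr``) confined to the planted high-risk half.
    """

    n_genes: int = 2000
    n_pathways: int = 25
    pathway_size_range: tuple[int, int] = (10, 30)
    nesting_fraction: float = 0.0
    n_tumour: int | tuple[int, ...] = (150, 100, 100, 100)
    n_normal: int | tuple[int, ...] = (100, 0, 0, 0)
    n_cohorts: int = 4
    cohort_shift_sd: float = 0.3  # log2 units, gene-wise additive per cohort
    gene_sd: float = 0.5  # within-group log2 sd of every background gene
    de_genes: list[tuple[str, float]] = field(default_factory=list)
    dv_genes: list[tuple[str, float]] = field(default_factory=list)
    prognostic_cps: list[tuple[int, float]] = field(default_factory=list)
    baseline_hazard: float = 0.08  # events / year
    censoring_rate: float = 0.04  # events / year
    followup_horizon: float = 15.0  # years, administrative cut
    chemo_assignment_prob: float = 0.5
    interaction_loghr: float = -0.69  # treatment log-HR in planted high-risk
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.pathway_size_range
        if min(self.n_genes, self.n_pathways, self.n_cohorts) <= 0:
            raise ValueError("counts must be positive")
        if lo < 3:
            raise ValueError("pathway_size_range.min must be >= 3")
        if hi > self.n_genes:
            raise ValueError("pathway_size_range.max exceeds n_genes")
        if not 0 <= self.nesting_fraction <= 1:
            raise ValueError("nesting_fraction must be in [0, 1]")
        if not 0 <= self.chemo_assignment_prob <= 1:
            raise ValueError("chemo_assignment_prob must be in [0, 1]")
        if self.followup_horizon <= 0:
            raise ValueError("followup_horizon must be positive")
        if self.baseline_hazard <= 0 or self.censoring_rate < 0:
            raise ValueError("hazard rates must be nonnegative (baseline > 0)")
        for counts in (self.per_cohort("n_tumour"), self.per_cohort("n_normal")):
            if len(counts) != self.n_cohorts:
                raise ValueError("per-cohort counts must match n_cohorts")
            if any(c < 0 for c in counts):
                raise ValueError("sample counts must be nonnegative")
        if all(c == 0 for c in self.per_cohort("n_tumour")):
            raise ValueError("at least one tumour sample required")

    def per_cohort(self, attr: str) -> tuple[int, ...]:
        v = getattr(self, attr)
        if isinstance(v, int):
            return (v,) * self.n_cohorts
        return tuple(v)


@dataclass
class TruthRecord:
    """Every planted effect of one simulation run."""

    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> log2FC
    dv_genes: dict[str, float] = field(default_factory=dict)  # gene -> sd ratio
    prognostic_genes: dict[str, float] = field(default_factory=dict)  # gene -> beta
    prognostic_pathways: list[str] = field(default_factory=list)
    high_risk: dict[str, list[str]] = field(default_factory=dict)  # cohort -> samples
    interaction_loghr: float = 0.0
    sl_genes: dict[str, tuple[float, float]] = field(default_factory=dict)
    essential_genes: dict[str, float] = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# pathway databases


def generate_pathway_db(config: SimConfig) -> PathwayDB:
    """Draw named gene sets from the gene universe.

    ``nesting_fraction`` of the pathways are built as strict subsets (or,
    when the parent is minimal, strict supersets) of another pathway, so the
    overlap-coefficient collapse downstream has genuine redundancy to remove.
    Non-nested pathways are carved from a shuffled universe without
    replacement while it lasts, so that when their sizes sum to at most
    ``n_genes`` they are pairwise disjoint.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    universe = np.array(gene_ids(config.n_genes))
    lo, hi = config.pathway_size_range
    n_nested = min(int(round(config.nesting_fraction * config.n_pathways)),
                   config.n_pathways - 1)
    n_base = config.n_pathways - n_nested

    shuffled = rng.permutation(universe)
    pos = 0
    sets: dict[str, frozenset] = {}
    for i in range(n_base):
        size = int(rng.integers(lo, hi + 1))
        if pos + size <= len(shuffled):
            members = shuffled[pos : pos + size]
            pos += size
        else:  # universe exhausted: fall back to independent draws
            members = rng.choice(universe, size=size, replace=False)
        sets[f"PW{i + 1:03d}"] = frozenset(members)

    base_names = list(sets)
    for j in range(n_nested):
        parent = sets[base_names[int(rng.integers(0, len(base_names)))]]
        parent_genes = np.array(sorted(parent))
        if len(parent_genes) > 3:
            size = int(rng.integers(3, len(parent_genes)))
            members = rng.choice(parent_genes, size=size, replace=False)
        else:  # parent minimal: build a strict superset instead
            extra = rng.choice(
                np.array(sorted(set(universe) - parent)),
                size=int(rng.integers(1, 4)),
                replace=False,
            )
            members = np.concatenate([parent_genes, extra])
        sets[f"PW{n_base + j + 1:03d}"] = frozenset(members)
    return PathwayDB(sets, source="synthetic")


def generate_block_pathway_db(
    n_blocks: int,
    pathways_per_block: int = 4,
    core_size: int = 10,
    pool_extra: int = 5,
    n_genes: int | None = None,
    seed: int = 0,
) -> tuple[PathwayDB, dict[str, int]]:
    """Block-structured database for cluster-number recovery checks.

    Pathways within a block share a core of ``core_size`` genes and carry
    ``pool_extra`` pathway-private extras, so every within-block pair has
    the same high overlap coefficient core/(core+extra); blocks draw from
    disjoint gene pools, so between-block coefficients are zero.  Returns
    the database and the true pathway -> block map.
    """
    rng = np.random.default_rng(seed)
    pool_size = core_size + pathways_per_block * pool_extra
    need = n_blocks * pool_size
    n_genes = need if n_genes is None else n_genes
    if n_genes < need:
        raise ValueError("gene universe too small for requested blocks")
    universe = rng.permutation(np.array(gene_ids(n_genes)))
    sets: dict[str, frozenset] = {}
    truth: dict[str, int] = {}
    idx = 0
    for b in range(n_blocks):
        pool = universe[b * pool_size : (b + 1) * pool_size]
        core = pool[:core_size]
        for p in range(pathways_per_block):
            start = core_size + p * pool_extra
            extra = pool[start : start + pool_extra]
            idx += 1
            name = f"PW{idx:03d}"
            sets[name] = frozenset(np.concatenate([core, extra]))
            truth[name] = b
    return PathwayDB(sets, source="synthetic-blocks"), truth


# ---------------------------------------------------------------------------
# expression + survival cohorts


def _clinical_frame(
    rng: np.random.Generator,
    samples: list[str],
    time: np.ndarray,
    event: np.ndarray,
    chemo: np.ndarray,
    is_normal: np.ndarray,
) -> pd.DataFrame:
    n = len(samples)
    clin = pd.DataFrame(index=pd.Index(samples), columns=CLINICAL_COLUMNS,
                        dtype=object)
    clin["time"] = time
    clin["event"] = event
    clin["endpoint"] = "OS"
    clin["age"] = np.round(rng.normal(60.0, 10.0, n), 1)
    clin["t_stage"] = rng.choice(["T1", "T2", "T3"], size=n, p=[0.3, 0.5, 0.2])
    clin["nodal"] = rng.binomial(1, 0.4, n)
    clin["purity"] = np.round(rng.beta(5.0, 2.0, n), 3)
    clin["chemo"] = chemo
    clin["tnbc_or_her2"] = rng.binomial(1, 0.05, n)
    clin["is_normal"] = is_normal
    clin.loc[is_normal.astype(bool), ["time", "event", "chemo", "tnbc_or_her2"]] = np.nan
    return clin


def generate_cohorts(
    config: SimConfig, db: PathwayDB
) -> tuple[list[ExpressionCohort], TruthRecord]:
    """Simulate expression + survival for every cohort.

    Normals are Gaussian per gene on the log2 scale; tumours add the planted
    log2 fold-changes (``de_genes``) and inflate the sd of ``dv_genes``.
    Each tumour's hazard is ``baseline_hazard * exp(eta)`` with
    ``eta = sum(beta_g * z_g)`` over planted prognostic genes (z-scores
    within the cohort's tumours); treated samples of the planted high-risk
    half (eta above its cohort median) have hazard further multiplied by
    ``exp(interaction_loghr)``.  Cohort 1 is labelled discovery.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = gene_ids(config.n_genes)
    gene_index = pd.Index(genes)
    for g, _ in [*config.de_genes, *config.dv_genes]:
        if g not in gene_index:
            raise ValueError(f"planted gene {g!r} not in universe")

    pathway_names = db.names
    prognostic_beta = pd.Series(0.0, index=gene_index)
    prognostic_pathways = []
    for cp_index, beta in config.prognostic_cps:
        name = pathway_names[cp_index]
        prognostic_pathways.append(name)
        for g in db[name]:
            prognostic_beta[g] = beta

    base_mean = rng.normal(7.0, 1.5, config.n_genes)
    sd = np.full(config.n_genes, config.gene_sd)
    de_shift = pd.Series(0.0, index=gene_index)
    for g, lfc in config.de_genes:
        de_shift[g] = lfc
    dv_mult = pd.Series(1.0, index=gene_index)
    for g, ratio in config.dv_genes:
        if ratio <= 1:
            raise ValueError("dv sd multipliers must exceed 1")
        dv_mult[g] = ratio

    truth = TruthRecord(
        de_genes=dict(config.de_genes),
        dv_genes=dict(config.dv_genes),
        prognostic_genes={
            g: float(b) for g, b in prognostic_beta.items() if b != 0.0
        },
        prognostic_pathways=prognostic_pathways,
        interaction_loghr=config.interaction_loghr,
        seed=config.seed,
    )

    cohorts: list[ExpressionCohort] = []
    n_tumours = config.per_cohort("n_tumour")
    n_normals = config.per_cohort("n_normal")
    for c in range(config.n_cohorts):
        cid = "discovery" if c == 0 else f"validation{c}"
        nt, nn = n_tumours[c], n_normals[c]
        n = nt + nn
        samples = [f"{cid}_S{i + 1:04d}" for i in range(n)]
        is_normal = np.zeros(n, dtype=bool)
        is_normal[nt:] = True

        shift = rng.normal(0.0, config.cohort_shift_sd, config.n_genes)
        x = rng.normal(0.0, 1.0, (config.n_genes, n)) * sd[:, None]
        x += (base_mean + shift)[:, None]
        # tumour-only planted effects
        x[:, :nt] = (
            (x[:, :nt] - (base_mean + shift)[:, None]) * dv_mult.values[:, None]
            + (base_mean + shift + de_shift.values)[:, None]
        )
        values = pd.DataFrame(x, index=gene_index, columns=samples)

        time = np.full(n, np.nan)
        event = np.full(n, np.nan)
        chemo = np.full(n, np.nan)
        if nt:
            tum = values.iloc[:, :nt]
            if truth.prognostic_genes:
                z = tum.sub(tum.mean(axis=1), axis=0).div(
                    tum.std(axis=1, ddof=1), axis=0
                )
                eta = (z.mul(prognostic_beta, axis=0)).sum(axis=0).values
            else:
                eta = np.zeros(nt)
            high = eta > np.median(eta)
            truth.high_risk[cid] = [samples[i] for i in range(nt) if high[i]]
            chemo_t = rng.binomial(1, config.chemo_assignment_prob, nt)
            loghr = eta + config.interaction_loghr * chemo_t * high
            rate = config.baseline_hazard * np.exp(loghr)
            t_event = rng.exponential(1.0 / rate)
            if config.censoring_rate > 0:
                t_cens = rng.exponential(1.0 / config.censoring_rate, nt)
            else:
                t_cens = np.full(nt, np.inf)
            t_cens = np.minimum(t_cens, config.followup_horizon)
            time[:nt] = np.minimum(t_event, t_cens)
            event[:nt] = (t_event <= t_cens).astype(float)
            chemo[:nt] = chemo_t

        clin = _clinical_frame(rng, samples, time, event, chemo, is_normal)
        cohorts.append(
            ExpressionCohort(
                cid, values, clin,
                role="discovery" if c == 0 else "validation",
            )
        )
    return cohorts, truth


# ---------------------------------------------------------------------------
# CRISPR gene-effect screens


def generate_ge_screen(
    n_genes: int,
    n_lines: int,
    sl_spec: list[tuple[str, float, float]],
    essential_spec: list[tuple[str, float]] | None = None,
    noise_sd: float = 0.05,
    n_high: int | None = None,
    erbb2_altered_high: int = 0,
    seed: int = 0,
) -> tuple[GeneEffectScreen, TruthRecord]:
    """Simulate a gene x cell-line CRISPR gene-effect matrix.

    Background genes are ``Normal(0, noise_sd)`` in every line; each
    ``sl_spec`` entry ``(gene, mean_high, mean_low)`` plants a group-selective
    dependency; each ``essential_spec`` entry plants a commonly essential
    gene (``mean_all`` below -1 in all lines).  Lines are split into
    ``n_high`` high-score and the remaining low-score lines, and the first
    ``erbb2_altered_high`` high lines are marked ERBB2-amplified.
    """
    if n_lines < 6:
        raise ValueError("need at least 6 cell lines (3 per group)")
    essential_spec = essential_spec or []
    sl_names = [g for g, *_ in sl_spec]
    ess_names = [g for g, _ in essential_spec]
    clash = set(sl_names) & set(ess_names)
    if clash:
        raise ValueError(f"gene(s) in both sl_spec and essential_spec: {sorted(clash)}")
    if len(set(sl_names)) != len(sl_names) or len(set(ess_names)) != len(ess_names):
        raise ValueError("duplicate gene in planted spec")

    rng = np.random.default_rng(seed)
    n_high = n_lines // 2 + 1 if n_high is None else n_high
    if not 3 <= n_high <= n_lines - 3:
        raise ValueError("each group needs at least 3 lines")
    genes = gene_ids(n_genes)
    planted = sl_names + ess_names
    for g in planted:
        if g not in genes:
            raise ValueError(f"planted gene {g!r} not in universe")
    lines = [f"LINE{i + 1:03d}" for i in range(n_lines)]
    group = np.array(["high"] * n_high + ["low"] * (n_lines - n_high))

    mean = np.zeros((n_genes, n_lines))
    gi = {g: i for i, g in enumerate(genes)}
    for g, mu_high, mu_low in sl_spec:
        mean[gi[g]] = np.where(group == "high", mu_high, mu_low)
    for g, mu_all in essential_spec:
        mean[gi[g]] = mu_all
    ge = mean + rng.normal(0.0, noise_sd, (n_genes, n_lines)) if noise_sd > 0 else mean
    ge = pd.DataFrame(ge, index=pd.Index(genes, name="gene_id"), columns=lines)

    erbb2 = np.array(["wildtype"] * n_lines, dtype=object)
    erbb2[:erbb2_altered_high] = "amplified"
    score = rng.normal(0.0, 1.0, n_lines) + np.where(group == "high", 2.0, -2.0)
    annotations = pd.DataFrame(
        {
            "psilc_score": score,
            "psilc_group": group,
            "erbb2_status": erbb2,
            "pten_status": rng.choice(
                ["wildtype", "mutant", "deleted"], size=n_lines, p=[0.7, 0.2, 0.1]
            ),
            "tp53_status": rng.choice(["wildtype", "mutant"], size=n_lines, p=[0.3, 0.7]),
        },
        index=pd.Index(lines, name="line"),
    )
    screen = GeneEffectScreen(ge=ge, annotations=annotations)
    truth = TruthRecord(
        sl_genes={g: (mh, ml) for g, mh, ml in sl_spec},
        essential_genes=dict(essential_spec),
        seed=seed,
    )
    return screen, truth
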