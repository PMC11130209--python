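"""Per-pathway-cluster survival risk models.

For each cluster of pathways (CP), genes univariably associated with
outcome in the discovery cohort (Cox Wald p < 0.05 on per-gene z-scores)
are retained with their log-hazard coefficients, and each patient receives
the module risk score

    score_s = sum_{g in selected} beta_g * z_{g,s}

Scores are dichotomised at the discovery median (or trichotomised at the
discovery 33rd/66th percentiles) and the resulting risk groups are tested
for prognostic association — and, where treatment flags exist, for a
risk-group x chemotherapy interaction — with Cox proportional-hazards
models, optionally adjusted for age (>55), T-stage, nodal status and
tumour purity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test

from .cohort_io import ExpressionCohort

__all__ = [
    "CoxFit",
    "CPModel",
    "RiskScores",
    "PrognosisResult",
    "InteractionResult",
    "fit_univariable_cox",
    "build_cp_model",
    "score_patients",
    "assign_risk_groups",
    "build_covariates",
    "evaluate_prognosis",
    "evaluate_interaction",
]

BETA_CAP = 10.0  # |beta| cap under monotone-likelihood separation


@dataclass
class CoxFit:
    """One term of a fitted Cox proportional-hazards model."""

    term: str
    beta: float
    se: float
    hr: float
    ci95: tuple[float, float]
    wald_p: float
    n: int
    n_events: int
    trend_p: float | None = None
    schoenfeld_p: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class CPModel:
    """Discovery-fitted risk model of one CP: selected genes with their
    univariable Cox coefficients and the discovery score cut-offs."""

    cp_id: str
    betas: dict[str, float]
    cutoffs: dict[str, float]
    endpoint: str = "OS"
    horizon: float = 10.0
    p_select: float = 0.05
    non_informative: bool = False

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CPModel":
        return cls(**json.loads(text))


@dataclass
class RiskScores:
    """Continuous per-sample risk scores, optionally with group labels."""

    score: pd.Series
    cutoffs: dict[str, float]
    source: str = ""
    group: pd.Series | None = None
    n_groups: int | None = None


@dataclass
class PrognosisResult:
    fits: list[CoxFit]
    logrank_p: float | None = None
    fallback: bool = False  # True when a zero-event group suppressed the HR


@dataclass
class InteractionResult:
    interaction: CoxFit
    within_group: dict[str, CoxFit | None]
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# fitting


def _cox_frame_fit(df: pd.DataFrame) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    return cph


def _term_fit(cph: CoxPHFitter, term: str, n: int, n_events: int) -> CoxFit:
    s = cph.summary.loc[term]
    beta = float(s["coef"])
    flags = []
    if abs(beta) > BETA_CAP:
        beta = float(np.sign(beta) * BETA_CAP)
        flags.append("separation")
    with np.errstate(over="ignore"):
        return CoxFit(
        term=term,
        beta=beta,
        se=float(s["se(coef)"]),
        hr=float(np.exp(beta)),
        ci95=(float(np.exp(s["coef lower 95%"])), float(np.exp(s["coef upper 95%"]))),
        wald_p=float(s["p"]),
        n=n,
        n_events=n_events,
        flags=flags,
    )


def fit_univariable_cox(x, time, event, term: str = "x") -> CoxFit:
    """Single-covariate Cox fit (Efron tie handling, as in lifelines).

    Monotone-likelihood separation is flagged and |beta| capped at 10.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    df = pd.DataFrame({"time": time, "event": event, term: x})
    try:
        cph = _cox_frame_fit(df)
        fit = _term_fit(cph, term, len(df), int(event.sum()))
    except ConvergenceError:
        # complete separation: report the capped direction of effect
        direction = 1.0 if np.corrcoef(x, -time)[0, 1] > 0 else -1.0
        fit = CoxFit(
            term=term,
            beta=direction * BETA_CAP,
            se=float("inf"),
            hr=float(np.exp(direction * BETA_CAP)),
            ci95=(0.0, float("inf")),
            wald_p=1.0,
            n=len(df),
            n_events=int(event.sum()),
            flags=["separation", "no-convergence"],
        )
    return fit


def _outcome_samples(cohort: ExpressionCohort) -> pd.Index:
    clin = cohort.clinical
    ok = clin["time"].notna() & clin["event"].notna()
    return cohort.samples[ok.to_numpy()]


def build_cp_model(
    cp,
    discovery: ExpressionCohort,
    p_select: float = 0.05,
    horizon: float = 10.0,
) -> CPModel:
    """Select the CP's prognostic genes in the discovery cohort and store
    their coefficients together with the discovery score cut-offs.

    Requires a standardized discovery cohort whose survival has already
    been truncated at the model horizon.  A CP where no gene reaches
    ``p_select`` is flagged non-informative (and excluded downstream).
    """
    if not discovery.standardized:
        raise ValueError("discovery cohort must be standardized (z-scores)")
    samples = _outcome_samples(discovery)
    clin = discovery.clinical.loc[samples]
    time = clin["time"].to_numpy(dtype=float)
    event = clin["event"].to_numpy(dtype=float)
    genes = sorted(set(cp.genes) & set(discovery.genes))
    betas: dict[str, float] = {}
    for g in genes:
        x = discovery.values.loc[g, samples].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        fit = fit_univariable_cox(x, time, event, term=g)
        if fit.wald_p < p_select and "separation" not in fit.flags:
            betas[g] = fit.beta
    model = CPModel(
        cp_id=cp.cp_id,
        betas=betas,
        cutoffs={},
        endpoint=str(clin["endpoint"].iloc[0]) if len(clin) else "OS",
        horizon=horizon,
        p_select=p_select,
    )
    if not betas:
        model.non_informative = True
        warnings.warn(f"{cp.cp_id}: no gene selected; CP is non-informative",
                      stacklevel=2)
        return model
    scores = score_patients(model, discovery.subset_samples(samples)).score
    model.cutoffs = {
        "median": float(np.median(scores)),
        "q33": float(np.quantile(scores, 1 / 3)),
        "q66": float(np.quantile(scores, 2 / 3)),
    }
    return model


def score_patients(model: CPModel, cohort: ExpressionCohort) -> RiskScores:
    """Beta-weighted sum of z-scores over the model's selected genes.

    Selected genes missing from the cohort contribute zero (mean
    imputation on the z scale) with a coverage warning.
    """
    if not cohort.standardized:
        raise ValueError("cohort must be standardized before scoring")
    if model.non_informative:
        raise ValueError(f"{model.cp_id} is non-informative")
    present = [g for g in model.betas if g in cohort.genes]
    if not present:
        raise ValueError(f"{model.cp_id}: no selected gene measured in cohort")
    if len(present) < len(model.betas):
        warnings.warn(
            f"{model.cp_id}: {len(model.betas) - len(present)} selected gene(s) "
            f"missing in {cohort.cohort_id}; they contribute 0 to the score",
            stacklevel=2,
        )
    beta = pd.Series({g: model.betas[g] for g in present})
    score = cohort.values.loc[present].mul(beta, axis=0).sum(axis=0)
    score.name = model.cp_id
    return RiskScores(score=score, cutoffs=dict(model.cutoffs), source=model.cp_id)


def assign_risk_groups(scores, cutoffs: dict, n_groups: int = 2) -> RiskScores:
    """Label samples low/(intermediate)/high with discovery-derived
    cut-offs; the cutoff value itself falls in the lower group."""
    if isinstance(scores, RiskScores):
        rs = scores
    else:
        rs = RiskScores(score=pd.Series(scores), cutoffs=dict(cutoffs))
    s = rs.score
    if n_groups == 2:
        group = pd.Series(np.where(s > cutoffs["median"], "high", "low"),
                          index=s.index)
    elif n_groups == 3:
        q33, q66 = cutoffs["q33"], cutoffs["q66"]
        if q33 > q66:
            raise ValueError("q33 cutoff exceeds q66")
        group = pd.Series(
            np.select([s <= q33, s > q66], ["low", "high"], default="intermediate"),
            index=s.index,
        )
    else:
        raise ValueError("n_groups must be 2 or 3")
    return RiskScores(score=s, cutoffs=dict(cutoffs), source=rs.source,
                      group=group, n_groups=n_groups)


# ---------------------------------------------------------------------------
# evaluation


def build_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    """Clinical adjustment covariates: age dichotomised at 55 years,
    T-stage as factors (T1 reference), nodal status dichotomous, purity
    continuous."""
    cov = pd.DataFrame(index=clinical.index)
    cov["age_gt55"] = (clinical["age"].astype(float) > 55).astype(float)
    stage = clinical["t_stage"].astype(str)
    cov["t_stage_T2"] = (stage == "T2").astype(float)
    cov["t_stage_T3"] = (stage == "T3").astype(float)
    cov["nodal"] = clinical["nodal"].astype(float)
    cov["purity"] = clinical["purity"].astype(float)
    return cov


GROUP_ORDER = {"low": 0, "intermediate": 1, "high": 2}


def _prepare_outcome_frame(groups: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame({"group": groups})
    df["time"] = clinical["time"].astype(float)
    df["event"] = clinical["event"].astype(float)
    df = df.dropna(subset=["time", "event", "group"])
    present = set(df["group"].unique())
    if len(present) < 2:
        raise ValueError(f"fewer than 2 risk groups represented: {sorted(present)}")
    return df


def evaluate_prognosis(
    groups: pd.Series,
    clinical: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> PrognosisResult:
    """Cox PH association of risk groups with outcome (reference: low).

    Three-group mode additionally reports a trend test (Wald on the ordinal
    low<intermediate<high coding).  A Schoenfeld zero-slope p-value is
    attached per term.  When a group has no events, the Wald HR is
    unreliable and a log-rank p is reported instead (fits suppressed).
    """
    df = _prepare_outcome_frame(groups, clinical)
    labels = sorted(df["group"].unique(), key=GROUP_ORDER.get)
    n, n_events = len(df), int(df["event"].sum())

    events_by_group = df.groupby("group", observed=True)["event"].sum()
    logrank = multivariate_logrank_test(df["time"], df["group"], df["event"])
    if (events_by_group == 0).any():
        return PrognosisResult(fits=[], logrank_p=float(logrank.p_value),
                               fallback=True)

    design = pd.DataFrame({"time": df["time"], "event": df["event"]})
    terms = []
    for lab in labels[1:]:
        col = f"group_{lab}"
        design[col] = (df["group"] == lab).astype(float)
        terms.append(col)
    if covariates is not None:
        cov = covariates.loc[df.index].astype(float)
        design = design.join(cov)
    design = design.dropna()
    cph = _cox_frame_fit(design)
    try:
        ph = proportional_hazard_test(cph, design, time_transform="km")
        sch = ph.summary["p"]
    except Exception:  # degenerate designs
        sch = pd.Series(dtype=float)

    fits = []
    for term in terms:
        fit = _term_fit(cph, term, n, n_events)
        if term in sch.index:
            fit.schoenfeld_p = float(sch.loc[term])
        fits.append(fit)

    if len(labels) == 3:
        trend = design.drop(columns=terms)
        trend["group_trend"] = df["group"].map(GROUP_ORDER).astype(float)
        trend_fit = _term_fit(_cox_frame_fit(trend.dropna()), "group_trend",
                              n, n_events)
        for fit in fits:
            fit.trend_p = trend_fit.wald_p
    return PrognosisResult(fits=fits, logrank_p=float(logrank.p_value))


def evaluate_interaction(
    groups: pd.Series,
    chemo: pd.Series,
    clinical: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> InteractionResult:
    """Risk-group x chemotherapy interaction (two risk groups).

    Fits ``group + chemo + group:chemo`` (+ covariates) and reports the
    interaction term, plus stratified treatment effects within each risk
    group (suppressed for empty group x treatment cells).
    """
    df = _prepare_outcome_frame(groups, clinical)
    df["chemo"] = chemo.reindex(df.index).astype(float)
    df = df.dropna(subset=["chemo"])
    if df["chemo"].nunique() < 2:
        raise ValueError("both treatment arms must be present")

    design = pd.DataFrame(
        {
            "time": df["time"],
            "event": df["event"],
            "group_high": (df["group"] == "high").astype(float),
            "chemo": df["chemo"],
        }
    )
    design["group_high:chemo"] = design["group_high"] * design["chemo"]
    if covariates is not None:
        design = design.join(covariates.loc[df.index].astype(float))
    design = design.dropna()
    flags: list[str] = []
    try:
        cph = _cox_frame_fit(design)
        interaction = _term_fit(
            cph, "group_high:chemo", len(design), int(design["event"].sum())
        )
    except (ConvergenceError, np.linalg.LinAlgError):
        # e.g. an empty group x treatment cell makes the design collinear
        interaction = CoxFit(
            term="group_high:chemo", beta=float("nan"), se=float("nan"),
            hr=float("nan"), ci95=(float("nan"), float("nan")),
            wald_p=float("nan"), n=len(design),
            n_events=int(design["event"].sum()), flags=["not-estimable"],
        )
        flags.append("interaction not estimable (degenerate design)")
    within: dict[str, CoxFit | None] = {}
    for lab in sorted(df["group"].unique(), key=GROUP_ORDER.get):
        sub = df[df["group"] == lab]
        cells = sub.groupby("chemo", observed=True).size()
        if len(cells) < 2 or (cells == 0).any() or sub["event"].sum() < 2:
            within[lab] = None
            flags.append(f"{lab}: stratified HR suppressed (empty/degenerate cell)")
            continue
        try:
            within[lab] = fit_univariable_cox(
                sub["chemo"], sub["time"], sub["event"], term="chemo"
            )
        except ValueError:
            within[lab] = None
            flags.append(f"{lab}: stratified HR suppressed")
    return InteractionResult(interaction=interaction, within_group=within, flags=flags)
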