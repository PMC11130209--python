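"""The multivariable pathway signature: a random survival forest over
per-CP risk scores.

The discovery cohort's sample x CP score matrix (one column per informative
CP, from :func:`psilc.cp_risk.score_patients`) is split 66/34 into training
and internal validation.  A hyperparameter sweep over tree count, terminal
node size and the per-split feature draw fits one log-rank-splitting
survival forest per grid point, recording the out-of-bag error (1 - OOB
concordance of ensemble mortality) and the Cox coefficient of the
(standardized) predicted score on the held-out third.  The winning
candidate is the one with the largest internal coefficient among the
lowest-OOB-error decile.  Discovery cut-offs (median and tertiles of the
selected forest's scores on the full discovery cohort) travel with the
model so validation cohorts can be grouped without refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from .cohort_io import ExpressionCohort
from .cp_risk import CPModel, RiskScores, assign_risk_groups, fit_univariable_cox, score_patients

__all__ = [
    "PSILCCandidate",
    "PSILCModel",
    "default_grid",
    "build_feature_matrix",
    "train_psilc",
    "predict_psilc",
]


@dataclass
class PSILCCandidate:
    ntrees: int
    nodesize: int
    mtry: int
    oob_error: float
    internal_beta: float


@dataclass
class PSILCModel:
    hyperparameters: dict
    forest: RandomSurvivalForest
    feature_order: list[str]
    cutoffs: dict[str, float]
    seed: int
    endpoint: str = "OS"
    horizon: float = 10.0
    candidates: list[PSILCCandidate] = field(default_factory=list)


def default_grid() -> list[dict]:
    """The full sweep: ntrees 501..1001 step 100, nodesize 10..15,
    mtry 5..10 — 6 x 6 x 6 = 216 candidates."""
    return [
        {"ntrees": nt, "nodesize": ns, "mtry": mt}
        for nt in range(501, 1002, 100)
        for ns in range(10, 16)
        for mt in range(5, 11)
    ]


def small_grid() -> list[dict]:
    """A reduced sweep for small synthetic cohorts: the corners of the
    nodesize/mtry ranges with a short ensemble (see docs/methods.md)."""
    return [
        {"ntrees": 101, "nodesize": ns, "mtry": mt}
        for ns in (10, 15)
        for mt in (5, 10)
    ]


def build_feature_matrix(
    cp_models: list[CPModel], cohort: ExpressionCohort
) -> pd.DataFrame:
    """Sample x CP score table; columns sorted by CP id.  Non-informative
    CPs are skipped; a CP whose genes are all missing from the cohort
    yields a zero column with a warning."""
    cols = {}
    for model in sorted(cp_models, key=lambda m: m.cp_id):
        if model.non_informative:
            continue
        try:
            cols[model.cp_id] = score_patients(model, cohort).score
        except ValueError:
            warnings.warn(
                f"{model.cp_id}: no selected gene measured in "
                f"{cohort.cohort_id}; scoring as zero",
                stacklevel=2,
            )
            cols[model.cp_id] = pd.Series(0.0, index=cohort.samples)
    if not cols:
        raise ValueError("no usable CP produces a feature column")
    return pd.DataFrame(cols)


def _fit_forest(params: dict, x: np.ndarray, y, seed: int, oob: bool) -> RandomSurvivalForest:
    mtry = min(params["mtry"], x.shape[1])
    forest = RandomSurvivalForest(
        n_estimators=params["ntrees"],
        min_samples_leaf=params["nodesize"],
        max_features=mtry,
        oob_score=oob,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forest.fit(x, y)
    return forest


def train_psilc(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    split_fraction: float = 0.66,
    grid: list[dict] | None = None,
    seed: int = 0,
    decile: float = 0.1,
) -> PSILCModel:
    """Sweep the hyperparameter grid and keep the selected forest.

    ``features`` is the discovery sample x CP matrix; ``clinical`` supplies
    ``time``/``event`` (already truncated at the model horizon).  The split
    into training and internal validation is stratified by event status.
    Selection: sort candidates by OOB error ascending; within the best
    ``decile`` (at least one candidate) take the largest internal Cox beta.
    """
    grid = default_grid() if grid is None else list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    clin = clinical.loc[features.index]
    time = clin["time"].astype(float)
    event = clin["event"].astype(float)
    ok = time.notna() & event.notna()
    features, time, event = features[ok], time[ok], event[ok]
    if len(features) < 30:
        raise ValueError("need at least 30 samples with outcome")
    if event.sum() < 5:
        raise ValueError("need at least 5 events")

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    for stratum in (0.0, 1.0):
        members = np.flatnonzero(event.to_numpy() == stratum)
        n_train = int(round(split_fraction * len(members)))
        train_idx.extend(rng.permutation(members)[:n_train])
    train_mask = np.zeros(len(features), dtype=bool)
    train_mask[train_idx] = True

    x = features.to_numpy(dtype=float)
    y = Surv.from_arrays(event=event.to_numpy().astype(bool), time=time.to_numpy())
    x_tr, y_tr = x[train_mask], y[train_mask]
    x_ho = x[~train_mask]
    time_ho = time.to_numpy()[~train_mask]
    event_ho = event.to_numpy()[~train_mask]

    candidates: list[PSILCCandidate] = []
    forests: list[RandomSurvivalForest] = []
    for params in grid:
        forest = _fit_forest(params, x_tr, y_tr, seed=seed, oob=True)
        oob_error = 1.0 - float(forest.oob_score_)
        pred = forest.predict(x_ho)
        if np.ptp(pred) == 0 or event_ho.sum() < 2:
            beta = 0.0
        else:
            z = (pred - pred.mean()) / pred.std(ddof=1)
            beta = fit_univariable_cox(z, time_ho, event_ho, term="score").beta
        candidates.append(
            PSILCCandidate(
                ntrees=params["ntrees"],
                nodesize=params["nodesize"],
                mtry=params["mtry"],
                oob_error=oob_error,
                internal_beta=beta,
            )
        )
        forests.append(forest)

    order = np.argsort([c.oob_error for c in candidates], kind="stable")
    n_best = max(1, int(np.ceil(decile * len(candidates))))
    shortlist = order[:n_best]
    best = max(shortlist, key=lambda i: candidates[i].internal_beta)
    chosen, forest = candidates[best], forests[best]

    scores = forest.predict(x)
    cutoffs = {
        "median": float(np.median(scores)),
        "q33": float(np.quantile(scores, 1 / 3)),
        "q66": float(np.quantile(scores, 2 / 3)),
    }
    return PSILCModel(
        hyperparameters={
            "ntrees": chosen.ntrees,
            "nodesize": chosen.nodesize,
            "mtry": chosen.mtry,
        },
        forest=forest,
        feature_order=list(features.columns),
        cutoffs=cutoffs,
        seed=seed,
        candidates=candidates,
    )


def predict_psilc(
    model: PSILCModel, features: pd.DataFrame, n_groups: int = 2,
    assign_groups: bool = True,
) -> RiskScores:
    """Ensemble-mortality risk scores for new samples, grouped with the
    model's discovery cut-offs.  Feature columns must match the stored
    order exactly."""
    if list(features.columns) != model.feature_order:
        extra = [c for c in features.columns if c not in model.feature_order]
        missing = [c for c in model.feature_order if c not in features.columns]
        raise ValueError(
            "feature columns do not match the trained model "
            f"(missing: {missing}, unexpected: {extra}, order must match)"
        )
    scores = pd.Series(
        model.forest.predict(features.to_numpy(dtype=float)),
        index=features.index,
        name="psilc",
    )
    rs = RiskScores(score=scores, cutoffs=dict(model.cutoffs), source="psilc")
    if assign_groups:
        rs = assign_risk_groups(rs, model.cutoffs, n_groups=n_groups)
    return rs
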