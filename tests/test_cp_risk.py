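import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from psilc.cp_risk import (
    CPModel,
    assign_risk_groups,
    build_covariates,
    build_cp_model,
    evaluate_interaction,
    evaluate_prognosis,
    fit_univariable_cox,
    score_patients,
)
from psilc.pathway_clusters import CP

from conftest import make_cohort


def efron_partial_loglik(beta, x, time, event):
    """Partial log-likelihood with Efron tie handling, by definition."""
    ll = 0.0
    eta = beta * np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    for t in sorted(set(time[event == 1])):
        tied = (time == t) & (event == 1)
        d = int(tied.sum())
        risk = time >= t
        sum_risk = np.exp(eta[risk]).sum()
        sum_tied = np.exp(eta[tied]).sum()
        ll += eta[tied].sum()
        for l in range(d):
            ll -= np.log(sum_risk - (l / d) * sum_tied)
    return ll


def grid_search_beta(x, time, event, lo=-5, hi=5, n=20001):
    grid = np.linspace(lo, hi, n)
    ll = [efron_partial_loglik(b, x, time, event) for b in grid]
    return grid[int(np.argmax(ll))]


class TestUnivariableCox:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_univariable_cox([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 0, 1])

    def test_sign_follows_risk_ordering(self):
        # high x values fail early -> positive log-hazard
        x = [3.0, 2.5, 2.0, 0.5, 0.2, 0.1]
        fit = fit_univariable_cox(x, [1, 2, 3, 10, 11, 12], [1, 1, 1, 1, 1, 1])
        assert fit.beta > 0
        assert fit.ci95[0] <= fit.hr <= fit.ci95[1]

    @pytest.mark.parametrize(
        "x, time, event",
        [
            ([0.5, 1.5, 0.2, 2.0, 1.0, 0.1], [2, 1, 5, 3, 4, 6], [1, 1, 0, 1, 1, 1]),
            ([1, 0, 1, 0, 1, 0, 1, 0], [1, 1, 2, 2, 3, 3, 4, 4], [1, 1, 1, 0, 1, 1, 0, 1]),
            ([2.0, 0.1, 1.4, 0.6, 0.9, 1.1, 0.3], [3, 9, 1, 6, 4, 2, 8],
             [1, 1, 1, 1, 0, 1, 1]),
        ],
    )
    def test_beta_matches_grid_search_oracle(self, x, time, event):
        fit = fit_univariable_cox(x, time, event)
        oracle = grid_search_beta(x, time, event)
        assert fit.beta == pytest.approx(oracle, abs=1e-3)

    def test_separable_toy_saturates_grid_bound_and_is_flagged(self):
        # all x=1 subjects fail before all x=0: monotone partial likelihood,
        # so the dense-grid maximiser sits at the upper bound
        x, time, event = [1, 1, 1, 0, 0, 0], [1, 2, 3, 4, 5, 6], [1] * 6
        oracle = grid_search_beta(x, time, event)
        assert oracle == pytest.approx(5.0, abs=1e-3)
        fit = fit_univariable_cox(x, time, event)
        assert "separation" in fit.flags
        assert min(fit.beta, 5.0) == pytest.approx(oracle, abs=1e-3)


def _survival_cohort(rng, betas, n=150, n_genes=10, horizon=None):
    """Standardized cohort whose hazards follow the planted betas."""
    z = rng.standard_normal((n_genes, n))
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
    eta = (np.asarray(betas)[:, None] * z).sum(axis=0)
    t_event = rng.exponential(1.0 / (0.1 * np.exp(eta)))
    t_cens = rng.exponential(1.0 / 0.05, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return make_cohort(z, time=time, event=event, standardized=True)


class TestBuildCPModel:
    def test_null_selection_rate_near_alpha(self):
        picked = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            cohort = _survival_cohort(rng, np.zeros(10))
            cp = CP("CP01", ["P1"], frozenset(cohort.genes))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = build_cp_model(cp, cohort)
            picked.append(len(model.betas) / 10)
        assert 0.02 <= np.mean(picked) <= 0.08

    def test_planted_gene_usually_selected(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            betas = np.zeros(10)
            betas[0] = 1.0
            cohort = _survival_cohort(rng, betas)
            cp = CP("CP01", ["P1"], frozenset(cohort.genes))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = build_cp_model(cp, cohort)
            hits += "g1" in model.betas
        assert hits >= 45

    def test_no_selected_genes_flags_non_informative(self):
        rng = np.random.default_rng(0)
        cohort = _survival_cohort(rng, np.zeros(3), n=40, n_genes=3)
        cp = CP("CP01", ["P1"], frozenset(cohort.genes))
        with warnings.catch_warnings(record=True):
            warnings.simplefilter("always")
            models = [
                build_cp_model(cp, cohort, p_select=1e-12) for _ in range(1)
            ]
        assert models[0].non_informative

    def test_requires_standardized_cohort(self):
        cohort = make_cohort([[1.0, 2.0, 3.0]], time=[1, 2, 3], event=[1, 1, 1])
        with pytest.raises(ValueError, match="standardized"):
            build_cp_model(CP("CP01", [], frozenset({"g1"})), cohort)


class TestScoring:
    def _model(self, betas):
        return CPModel("CP01", betas, {"median": 0.0, "q33": -0.5, "q66": 0.5})

    def test_weighted_sum_arithmetic(self):
        model = self._model({"g1": 0.5, "g2": -1.0})
        cohort = make_cohort([[1.0], [0.5]], standardized=True)
        rs = score_patients(model, cohort)
        assert rs.score.iloc[0] == pytest.approx(0.0)

    def test_gene_order_invariance(self):
        cohort = make_cohort([[1.0, -0.2], [0.3, 0.7]], standardized=True)
        a = score_patients(self._model({"g1": 0.5, "g2": 1.2}), cohort)
        b = score_patients(self._model({"g2": 1.2, "g1": 0.5}), cohort)
        pd.testing.assert_series_equal(a.score, b.score)

    def test_linearity_in_profiles(self):
        model = self._model({"g1": 0.7, "g2": -0.3})
        x = make_cohort([[1.0], [2.0]], standardized=True)
        y = make_cohort([[0.5], [-1.0]], standardized=True)
        s = make_cohort([[1.5], [1.0]], standardized=True)
        assert score_patients(model, s).score.iloc[0] == pytest.approx(
            score_patients(model, x).score.iloc[0]
            + score_patients(model, y).score.iloc[0]
        )

    def test_missing_gene_contributes_zero_with_warning(self):
        model = self._model({"g1": 1.0, "ghost": 5.0})
        cohort = make_cohort([[2.0]], standardized=True)
        with pytest.warns(UserWarning, match="missing"):
            rs = score_patients(model, cohort)
        assert rs.score.iloc[0] == pytest.approx(2.0)

    def test_all_genes_missing_errors(self):
        model = self._model({"ghost": 1.0})
        cohort = make_cohort([[2.0]], standardized=True)
        with pytest.raises(ValueError, match="no selected gene"):
            score_patients(model, cohort)


class TestRiskGroups:
    def test_two_group_boundary_is_low(self):
        scores = pd.Series([0.1, 0.5, 0.9], index=list("abc"))
        rs = assign_risk_groups(scores, {"median": 0.5}, n_groups=2)
        assert list(rs.group) == ["low", "low", "high"]

    def test_three_group_boundaries(self):
        scores = pd.Series([-1.0, 0.0, 0.5, 1.0], index=list("abcd"))
        rs = assign_risk_groups(scores, {"q33": 0.0, "q66": 0.5}, n_groups=3)
        assert list(rs.group) == ["low", "low", "intermediate", "high"]

    def test_all_below_q33(self):
        scores = pd.Series([-3.0, -2.0], index=list("ab"))
        rs = assign_risk_groups(scores, {"q33": 0.0, "q66": 0.5}, n_groups=3)
        assert set(rs.group) == {"low"}

    def test_inverted_cutoffs_rejected(self):
        with pytest.raises(ValueError, match="q33"):
            assign_risk_groups(pd.Series([0.0]), {"q33": 1.0, "q66": 0.0}, 3)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=40,
                    unique=True))
    def test_own_median_split_is_balanced(self, values):
        scores = pd.Series(values)
        rs = assign_risk_groups(scores, {"median": float(np.median(values))}, 2)
        counts = rs.group.value_counts()
        assert abs(counts.get("low", 0) - counts.get("high", 0)) <= 1


class TestEvaluatePrognosis:
    def test_separable_toy_strongly_prognostic(self):
        time = np.array([1.0, 1.5, 2.0, 2.5, 10.0, 11.0, 12.0, 13.0])
        event = np.array([1, 1, 1, 1, 1, 0, 1, 1])
        groups = pd.Series(["high"] * 4 + ["low"] * 4)
        clin = pd.DataFrame({"time": time, "event": event}, index=groups.index)
        res = evaluate_prognosis(groups, clin)
        assert res.fits[0].beta > 0
        assert res.logrank_p < 0.01

    def test_null_wald_p_approximately_uniform(self):
        ps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 80
            time = rng.exponential(5, n)
            event = rng.integers(0, 2, n)
            groups = pd.Series(np.where(rng.random(n) < 0.5, "low", "high"))
            clin = pd.DataFrame({"time": time, "event": event},
                                index=groups.index)
            try:
                ps.append(evaluate_prognosis(groups, clin).fits[0].wald_p)
            except ValueError:
                pass
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.15

    def test_zero_event_group_falls_back_to_logrank(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        groups = pd.Series(["high"] * 3 + ["low"] * 3)
        clin = pd.DataFrame({"time": time, "event": event}, index=groups.index)
        res = evaluate_prognosis(groups, clin)
        assert res.fallback
        assert res.fits == []
        assert res.logrank_p is not None

    def test_single_group_errors(self):
        clin = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]})
        with pytest.raises(ValueError, match="fewer than 2"):
            evaluate_prognosis(pd.Series(["high", "high"]), clin)

    def test_three_group_trend_reported(self):
        rng = np.random.default_rng(2)
        n = 120
        g = rng.integers(0, 3, n)
        time = rng.exponential(1.0 / (0.1 * np.exp(0.8 * g)))
        clin = pd.DataFrame({"time": time, "event": np.ones(n)})
        groups = pd.Series(pd.Categorical.from_codes(
            g, categories=["low", "intermediate", "high"]).astype(str))
        res = evaluate_prognosis(groups, clin)
        assert all(f.trend_p is not None for f in res.fits)
        assert res.fits[-1].trend_p < 0.01


class TestEvaluateInteraction:
    def _simulate(self, rng, n, benefit_high, benefit_low):
        group = np.where(rng.random(n) < 0.5, "high", "low")
        chemo = rng.integers(0, 2, n)
        loghr = np.where(group == "high", 0.7, 0.0)
        loghr = loghr + chemo * np.where(group == "high", benefit_high, benefit_low)
        t_event = rng.exponential(1.0 / (0.1 * np.exp(loghr)))
        t_cens = rng.exponential(20.0, n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        clin = pd.DataFrame({"time": time, "event": event})
        return pd.Series(group), pd.Series(chemo, dtype=float), clin

    def test_equal_benefit_gives_null_interaction(self):
        # average over replicates: the interaction coefficient centres on 0
        betas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            groups, chemo, clin = self._simulate(rng, 2000, -0.5, -0.5)
            res = evaluate_interaction(groups, chemo, clin)
            betas.append(res.interaction.beta)
        assert abs(np.mean(betas)) < 0.15
        assert set(res.within_group) == {"low", "high"}

    def test_high_only_benefit_detected(self):
        rng = np.random.default_rng(1)
        groups, chemo, clin = self._simulate(rng, 1500, -0.8, 0.0)
        res = evaluate_interaction(groups, chemo, clin)
        assert res.interaction.beta < 0
        assert res.within_group["high"].hr < 1.0

    def test_empty_cell_suppresses_stratified_hr(self):
        groups = pd.Series(["high"] * 6 + ["low"] * 6)
        chemo = pd.Series([1, 1, 1, 0, 0, 0] + [1] * 6, dtype=float)
        rng = np.random.default_rng(3)
        clin = pd.DataFrame({"time": rng.exponential(5, 12),
                             "event": np.ones(12)}, index=groups.index)
        res = evaluate_interaction(groups, chemo, clin)
        assert res.within_group["low"] is None
        assert any("low" in f for f in res.flags)
        # with an empty cell the full interaction design is collinear
        assert np.isnan(res.interaction.beta)
        assert "not-estimable" in res.interaction.flags

    def test_missing_treatment_arm_rejected(self):
        groups = pd.Series(["high", "low", "high", "low"])
        chemo = pd.Series([1.0, 1.0, 1.0, 1.0])
        clin = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="treatment"):
            evaluate_interaction(groups, chemo, clin)


class TestCovariates:
    def test_encoding(self):
        clin = pd.DataFrame(
            {"age": [50.0, 60.0], "t_stage": ["T1", "T3"], "nodal": [0, 1],
             "purity": [0.5, 0.9]}
        )
        cov = build_covariates(clin)
        assert list(cov.loc[0]) == [0.0, 0.0, 0.0, 0.0, 0.5]
        assert list(cov.loc[1]) == [1.0, 0.0, 1.0, 1.0, 0.9]
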