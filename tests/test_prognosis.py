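"""Hub selection, Cox modelling, optimal cutoff and Kaplan–Meier tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from uvrsig import synthdata
from uvrsig.core import ExpressionMatrix, GeneSet
from uvrsig.prognosis import (
    SELECTOR_REGISTRY,
    CoxModel,
    SelectorResult,
    SurvivalTable,
    consensus_hub,
    fit_cox,
    km_logrank,
    optimal_cutoff,
    risk_scores,
    run_selector,
)


def labeled_matrix(rng, n=60, n_noise=7):
    """One perfectly separating gene plus noise genes."""
    y = np.array([0, 1] * (n // 2))
    perf = y * 4.0 + rng.normal(0, 0.3, n)
    noise = rng.normal(size=(n_noise, n))
    genes = ["PERF"] + [f"N{i}" for i in range(n_noise)]
    m = ExpressionMatrix(genes, [f"S{i}" for i in range(n)],
                         np.vstack([perf, noise]))
    return m, y, GeneSet("cand", frozenset(genes))


class TestSelectors:
    @pytest.mark.parametrize("selector", sorted(SELECTOR_REGISTRY))
    def test_perfect_separator_selected(self, selector):
        rng = np.random.default_rng(1)
        m, y, cand = labeled_matrix(rng)
        res = run_selector(m, y, cand, selector, seed=1)
        assert "PERF" in res.selected
        assert res.selector_name == selector

    def test_unknown_selector_lists_registry(self):
        rng = np.random.default_rng(0)
        m, y, cand = labeled_matrix(rng)
        with pytest.raises(ValueError, match="lasso"):
            run_selector(m, y, cand, "nope")

    def test_lasso_recovers_planted_effect_genes(self):
        cohort, truth = synthdata.make_ici_cohort(
            n_samples=150, n_genes=40, n_effect=8, effect_size=2.0, seed=5
        )
        res = run_selector(
            cohort.matrix, cohort.labels(),
            GeneSet("cand", frozenset(cohort.matrix.gene_ids)), "lasso", seed=5,
        )
        recall = len(res.selected & truth.effect_genes.genes) / 8
        assert recall >= 0.8

    def test_null_candidates_rarely_selected(self):
        """False-selection rate stays low on pure-noise candidates."""
        rates = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 200)
            y[:2] = [0, 1]
            m = ExpressionMatrix(
                [f"N{i}" for i in range(20)], [f"S{i}" for i in range(200)],
                rng.normal(size=(20, 200)),
            )
            res = run_selector(m, y, GeneSet("c", frozenset(m.gene_ids)),
                               "univariate_auc", seed=seed)
            rates.append(len(res.selected) / 20)
        assert np.mean(rates) <= 0.10


class TestConsensusHub:
    def make_results(self, memberships):
        return [
            SelectorResult(f"sel{i}", frozenset(s), pd.Series(dtype=float), 0)
            for i, s in enumerate(memberships)
        ]

    def test_vote_threshold(self):
        results = self.make_results(
            [{"A", "B"}, {"A", "B"}, {"A", "B"}, {"A"}, {"C"}, {"C"}]
        )
        hub, votes = consensus_hub(results, min_votes=4)
        assert hub.genes == {"A"}
        assert votes.loc["B", "votes"] == 3 and votes.loc["A", "votes"] == 4

    def test_identical_selectors_return_their_set(self):
        results = self.make_results([{"X", "Y"}] * 6)
        hub, _ = consensus_hub(results)
        assert hub.genes == {"X", "Y"}

    def test_adding_a_selector_never_removes_genes(self):
        base = self.make_results([{"A"}, {"A"}, {"A", "B"}, {"A", "B"}, {"B"}])
        hub1, _ = consensus_hub(base, min_votes=2)
        hub2, _ = consensus_hub(
            base + self.make_results([{"B", "C"}]), min_votes=2
        )
        assert hub1.genes <= hub2.genes

    def test_too_few_results_rejected(self):
        with pytest.raises(ValueError):
            consensus_hub(self.make_results([{"A"}] * 3), min_votes=4)


def oracle_partial_loglik(beta, x, time, event):
    """Independent Cox partial log-likelihood (no tied event times)."""
    ll = 0.0
    for i in np.where(event == 1)[0]:
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_matches_manual_partial_likelihood(self):
        """Fitted log-likelihood and coefficient agree with a hand oracle."""
        time = np.array([2.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0, 23.0,
                         29.0, 31.0, 37.0, 41.0])
        event = np.array([1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1])
        x = np.array([0.5, -1.0, 0.3, 1.2, -0.7, 0.9, -0.2, 0.4,
                      -1.3, 0.8, 0.1, -0.5])
        ids = [f"S{i}" for i in range(12)]
        m = ExpressionMatrix(["G"], ids, x[None, :])
        surv = SurvivalTable(ids, time, event)
        model = fit_cox(m, surv, GeneSet("s", frozenset({"G"})))
        beta_hat = float(model.coef[0])
        assert model.log_likelihood == pytest.approx(
            oracle_partial_loglik(beta_hat, x, time, event), abs=1e-6
        )
        opt = minimize_scalar(
            lambda b: -oracle_partial_loglik(b, x, time, event),
            bounds=(-5, 5), method="bounded",
        )
        assert beta_hat == pytest.approx(opt.x, abs=1e-4)

    def test_null_covariates_rarely_significant(self):
        hits = 0
        for seed in range(10):
            matrix, surv, _ = synthdata.make_survival_cohort(
                n_samples=300, betas=(0.0, 0.0), seed=seed
            )
            model = fit_cox(
                matrix, SurvivalTable(surv.sample_ids, surv.time, surv.event),
                GeneSet("s", frozenset(matrix.gene_ids)),
            )
            hits += int(np.all(np.abs(model.coef / model.se) < 2))
        assert hits >= 8

    def test_too_few_events_rejected(self):
        matrix, surv, _ = synthdata.make_survival_cohort(n_samples=30, seed=0)
        surv.event[:] = 0
        surv.event[:5] = 1
        with pytest.raises(ValueError, match="10 events"):
            fit_cox(matrix, SurvivalTable(surv.sample_ids, surv.time, surv.event),
                    GeneSet("s", frozenset(matrix.gene_ids)))


class TestRiskScores:
    def test_linear_predictor(self):
        model = CoxModel(["A", "B"], np.array([1.0, -2.0]), np.array([0.1, 0.1]),
                         0.0, True)
        m = ExpressionMatrix(["A", "B"], ["S0", "S1"], [[1.0, 2.0], [3.0, 4.0]])
        s = risk_scores(model, m)
        np.testing.assert_allclose(s.to_numpy(), [1 - 6, 2 - 8])

    def test_zero_coefficients_zero_scores(self):
        model = CoxModel(["A"], np.array([0.0]), np.array([0.1]), 0.0, True)
        m = ExpressionMatrix(["A"], ["S0"], [[7.0]])
        assert risk_scores(model, m)["S0"] == 0.0

    def test_score_differences_invariant_to_covariate_shift(self, rng):
        model = CoxModel(["A", "B"], np.array([0.7, -0.3]), np.array([0.1, 0.1]),
                         0.0, True)
        X = rng.normal(size=(2, 5))
        m1 = ExpressionMatrix(["A", "B"], [f"S{i}" for i in range(5)], X)
        m2 = ExpressionMatrix(["A", "B"], [f"S{i}" for i in range(5)], X + 10.0)
        d1 = np.diff(risk_scores(model, m1).to_numpy())
        d2 = np.diff(risk_scores(model, m2).to_numpy())
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_missing_gene_rejected(self):
        model = CoxModel(["A"], np.array([1.0]), np.array([0.1]), 0.0, True)
        m = ExpressionMatrix(["B"], ["S0"], [[1.0]])
        with pytest.raises(ValueError):
            risk_scores(model, m)


class TestOptimalCutoff:
    def test_separates_two_risk_clusters(self):
        rng = np.random.default_rng(3)
        n = 100
        scores = np.concatenate([rng.normal(0, 0.3, n // 2),
                                 rng.normal(5, 0.3, n // 2)])
        # high cluster has much higher hazard
        time = np.concatenate([rng.exponential(100, n // 2),
                               rng.exponential(5, n // 2)])
        surv = SurvivalTable([f"S{i}" for i in range(n)], np.maximum(time, 0.01),
                             np.ones(n, dtype=int))
        s = pd.Series(scores, index=surv.sample_ids)
        cutoff, groups = optimal_cutoff(s, surv)
        # the cutpoint must fall between the clusters: groups = clusters
        assert (groups.to_numpy() == np.where(scores > 2.5, "high", "low")).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        n = 40
        scores = rng.normal(size=n)
        time = rng.exponential(10, n)
        ids = [f"S{i}" for i in range(n)]
        surv = SurvivalTable(ids, time, np.ones(n, dtype=int))
        s = pd.Series(scores, index=ids)
        cut1, _ = optimal_cutoff(s, surv)
        perm = rng.permutation(n)
        surv2 = SurvivalTable([ids[i] for i in perm], time[perm],
                              np.ones(n, dtype=int))
        cut2, _ = optimal_cutoff(s, surv2)
        assert cut1 == pytest.approx(cut2)

    def test_degenerate_candidates_fall_back_to_median(self, caplog):
        ids = [f"S{i}" for i in range(10)]
        surv = SurvivalTable(ids, np.arange(1.0, 11.0), np.ones(10, dtype=int))
        s = pd.Series([1.0] * 9 + [2.0], index=ids)
        with caplog.at_level("WARNING", logger="uvrsig"):
            cutoff, groups = optimal_cutoff(s, surv)
        assert set(groups.unique()) == {"high", "low"}


def oracle_logrank(time, event, group):
    """Independent log-rank chi-square via the O-E / V sums."""
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKmLogrank:
    def test_matches_manual_logrank(self):
        time = np.array([3.0, 5.0, 8.0, 10.0, 2.0, 4.0, 6.0, 12.0])
        event = np.array([1, 1, 0, 1, 1, 1, 1, 0])
        group = np.array([True] * 4 + [False] * 4)
        ids = [f"S{i}" for i in range(8)]
        surv = SurvivalTable(ids, time, event)
        groups = pd.Series(np.where(group, "high", "low"), index=ids)
        res = km_logrank(groups, surv)
        assert res.statistic == pytest.approx(
            oracle_logrank(time, event, group), rel=1e-6
        )

    def test_km_curve_matches_empirical_survival_without_censoring(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 3.5, 4.5])
        event = np.ones(8, dtype=int)
        ids = [f"S{i}" for i in range(8)]
        surv = SurvivalTable(ids, time, event)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=ids)
        res = km_logrank(groups, surv)
        curve = res.curves["a"].iloc[:, 0]
        # no censoring: KM equals the empirical survival function
        assert curve.loc[2.0] == pytest.approx(0.5)
        assert curve.loc[4.0] == pytest.approx(0.0)
        assert (curve.diff().dropna() <= 1e-12).all()

    def test_no_events_degenerate(self):
        ids = [f"S{i}" for i in range(6)]
        surv = SurvivalTable(ids, np.arange(1.0, 7.0), np.zeros(6, dtype=int))
        groups = pd.Series(["a", "a", "a", "b", "b", "b"], index=ids)
        res = km_logrank(groups, surv)
        assert res.degenerate and res.p == 1.0
        assert (res.curves["a"].iloc[:, 0] == 1.0).all()

    def test_identical_groups_not_significant(self):
        time = np.tile(np.array([2.0, 4.0, 6.0, 8.0]), 2)
        event = np.tile(np.array([1, 0, 1, 1]), 2)
        ids = [f"S{i}" for i in range(8)]
        surv = SurvivalTable(ids, time, event)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=ids)
        res = km_logrank(groups, surv)
        assert res.p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        ids = ["S0", "S1"]
        surv = SurvivalTable(ids, np.array([1.0, 2.0]), np.array([1, 1]))
        with pytest.raises(ValueError, match="2 non-empty groups"):
            km_logrank(pd.Series(["a", "a"], index=ids), surv)

    def test_high_risk_group_has_worse_survival_on_planted_data(self):
        matrix, surv_data, betas = synthdata.make_survival_cohort(
            n_samples=300, betas=(1.0, -0.8), seed=9
        )
        surv = SurvivalTable(surv_data.sample_ids, surv_data.time, surv_data.event)
        model = fit_cox(matrix, surv, GeneSet("s", frozenset(matrix.gene_ids)))
        scores = risk_scores(model, matrix)
        cutoff, groups = optimal_cutoff(scores, surv)
        res = km_logrank(groups, surv, cutoff_optimized=True)
        assert res.p < 0.01 and res.cutoff_optimized
        high = groups == "high"
        assert scores[high].min() > scores[~high].max()
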