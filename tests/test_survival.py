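"""Eigengene, Kaplan-Meier, log-rank and Cox evaluation."""

import numpy as np
import pandas as pd
import pytest

from oracles import cox_grid_fit, km_survival_by_hand, logrank_exact_permutation_p
from survmod.cohort import SurvivalCohort
from survmod.survival import (
    apply_eigengene,
    assign_risk_groups,
    cox_model,
    evaluate_module,
    fit_eigengene,
    kaplan_meier,
    log_rank_test,
)


class TestEigengene:
    def test_rank_one_matrix_reproduces_shared_profile(self):
        profile = np.array([1.0, -0.5, 2.0, 0.3, -1.2])
        expr = pd.DataFrame(
            np.vstack([2 * profile + 1, 3 * profile - 2, 0.5 * profile]),
            index=["g1", "g2", "g3"],
            columns=[f"P{i}" for i in range(5)],
        )
        model, em = fit_eigengene(expr)
        corr = np.corrcoef(em, profile)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(model.loadings) == pytest.approx(1.0)

    def test_matches_dense_eigendecomposition(self):
        """EM equals the first-PC projection from an independent
        eigendecomposition of the gene-gene covariance matrix."""
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.standard_normal((3, 4)), index=["a", "b", "c"],
            columns=[f"P{i}" for i in range(4)],
        )
        model, em = fit_eigengene(expr)
        z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=1)).T.to_numpy()
        evals, evecs = np.linalg.eigh(z @ z.T)
        lead = evecs[:, np.argmax(evals)]
        expected = lead @ z
        if np.dot(expected, em) < 0:
            expected = -expected
        assert np.allclose(em, expected, atol=1e-9)

    def test_application_to_training_is_identity(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.standard_normal((5, 30)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"P{i}" for i in range(30)],
        )
        model, em_fit = fit_eigengene(expr)
        em_applied = apply_eigengene(model, expr)
        assert np.allclose(em_fit, em_applied, atol=1e-12)

    def test_orientation_follows_mean_profile(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(40)
        expr = pd.DataFrame(
            np.vstack([base + 0.1 * rng.standard_normal(40) for _ in range(4)]),
            index=[f"g{i}" for i in range(4)],
            columns=[f"P{i}" for i in range(40)],
        )
        _, em = fit_eigengene(expr)
        z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=1)).T
        assert np.corrcoef(em, z.mean(axis=0))[0, 1] > 0

    def test_missing_gene_is_named(self):
        expr = pd.DataFrame(
            np.random.default_rng(3).standard_normal((3, 10)),
            index=["a", "b", "c"], columns=[f"P{i}" for i in range(10)],
        )
        model, _ = fit_eigengene(expr)
        with pytest.raises(KeyError, match="b"):
            apply_eigengene(model, expr.drop(index="b"))

    def test_external_em_tracks_module_activity(self, planted_bundle):
        """An eigengene fitted on training correlates with mean planted
        expression in the external cohort drawn from the same truth."""
        genes = planted_bundle.planted_module
        model, _ = fit_eigengene(
            planted_bundle.cohorts["training"].expression.loc[genes]
        )
        ext = planted_bundle.cohorts["external"].expression
        em = apply_eigengene(model, ext)
        r = np.corrcoef(em, ext.loc[genes].mean(axis=0))[0, 1]
        assert abs(r) > 0.5


class TestKaplanMeier:
    def test_no_censoring_matches_hand_product_limit(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        est = kaplan_meier(times, [1] * 5)
        hand = dict(km_survival_by_hand(times, [1] * 5))
        for t, s in hand.items():
            assert est.survival[np.searchsorted(est.times, t)] == pytest.approx(s)
        assert est.median == 3.0

    def test_all_censored_never_reaches_median(self):
        est = kaplan_meier([5.0, 10.0, 15.0], [0, 0, 0])
        assert np.all(est.survival == 1.0)
        assert np.isinf(est.median)

    def test_single_event_drops_to_zero(self):
        est = kaplan_meier([7.0], [1])
        assert est.survival[-1] == 0.0
        assert est.median == 7.0


class TestLogRank:
    def test_identical_groups_give_null_statistic(self):
        t = np.tile([2.0, 5.0, 9.0, 14.0], 2)
        e = np.ones(8, int)
        g = np.repeat([0, 1], 4)
        # both groups see the same survival pattern
        chi2, p = log_rank_test(g, t, e)
        assert chi2 < 0.5 and p > 0.4

    def test_chi2_p_consistent_with_exact_permutation(self):
        """On an 8-patient toy the chi-square approximation lands within
        the exact permutation distribution's neighbourhood."""
        t = np.array([1.0, 3.0, 4.0, 6.0, 8.0, 11.0, 13.0, 16.0])
        e = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        g = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        chi2, p = log_rank_test(g, t, e)
        p_exact = logrank_exact_permutation_p(t, e, g)
        assert abs(p - p_exact) < 0.1

    def test_power_against_planted_separation(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            x = rng.integers(0, 2, size=200)
            t = rng.exponential(np.exp(-0.7 * x))
            _, p = log_rank_test(x, t, np.ones(200, int))
            if p < 0.01:
                hits += 1
        assert hits >= 18

    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="2 groups"):
            log_rank_test([1, 1, 1], [1.0, 2.0, 3.0], [1, 1, 1])


class TestCoxModel:
    def test_binary_covariate_matches_grid_oracle(self):
        x = np.array([0, 1, 0, 1, 0, 1.0])
        t = np.arange(1.0, 7.0)
        e = np.ones(6, int)
        beta_o, _, p_o = cox_grid_fit(x, t, e)
        res = cox_model(pd.DataFrame({"grp": x}), t, e)
        assert res.loc["grp", "hr"] == pytest.approx(np.exp(beta_o), rel=1e-3)
        assert res.loc["grp", "p"] == pytest.approx(p_o, rel=1e-2)
        assert res.loc["grp", "ci_low"] <= res.loc["grp", "hr"] <= res.loc["grp", "ci_high"]

    def test_null_coefficient_ci_covers_one(self):
        """A no-effect covariate's 95% CI contains HR=1 in about 95% of
        replicates (here checked loosely over 40)."""
        rng = np.random.default_rng(4)
        covered = 0
        for _ in range(40):
            x = rng.standard_normal(150)
            t = rng.exponential(1.0, 150)
            res = cox_model(pd.DataFrame({"x": x}), t, np.ones(150, int))
            if res.loc["x", "ci_low"] <= 1.0 <= res.loc["x", "ci_high"]:
                covered += 1
        assert covered >= 33

    def test_constant_and_collinear_covariates_rejected(self):
        t = np.arange(1.0, 11.0)
        e = np.ones(10, int)
        with pytest.raises(ValueError, match="constant"):
            cox_model(pd.DataFrame({"c": np.ones(10)}), t, e)
        x = np.random.default_rng(5).standard_normal(10)
        with pytest.raises(ValueError, match="collinear"):
            cox_model(pd.DataFrame({"a": x, "b": 2 * x}), t, e)


class TestRiskGroupsAndEvaluation:
    def test_split_partitions_and_is_deterministic(self):
        em = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("wxyz"))
        labels = assign_risk_groups(em, 2.5)
        assert set(labels) == {"high", "low"}
        assert (labels == assign_risk_groups(em, 2.5)).all()
        groups = labels.groupby(labels).size()
        assert tuple(groups) == (2, 2)

    def test_high_risk_group_has_shorter_median_survival(self):
        em = pd.Series(np.arange(20.0), index=[f"P{i}" for i in range(20)])
        t = np.where(em >= 10, 60.0, 10.0)  # high EM lives longer
        labels = assign_risk_groups(em, 9.5, t, np.ones(20, int))
        assert (labels[em >= 10] == "low").all()

    def test_identical_em_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            assign_risk_groups(pd.Series([1.0, 1.0, 1.0]), 1.0)

    def test_planted_module_evaluation_end_to_end(self, planted_bundle):
        rep = evaluate_module(
            planted_bundle.planted_module,
            planted_bundle.cohorts["training"],
            planted_bundle.cohorts["test"],
            planted_bundle.cohorts["external"],
        )
        assert rep.screen_passed
        tr = rep.cohorts["training"]
        assert tr.logrank_p < 0.01
        # positive node_effect makes high module expression hazardous
        assert tr.cox_univariate["hr"] > 1.0
        assert tr.cox_multivariate.loc["em_high", "p"] < 0.05
        assert rep.cohorts["external"].logrank_p < 0.05
        # high-risk group dies sooner wherever both medians are defined
        km = tr.km_median
        assert km["high"] <= km["low"]

    def test_protective_module_reports_hr_below_one(self):
        from survmod.simulate import SimulationConfig, generate_bundle

        bundle = generate_bundle(
            SimulationConfig(n_genes=80, n_celldeath=20, node_effect=-0.7, seed=21)
        )
        rep = evaluate_module(
            bundle.planted_module, bundle.cohorts["training"], adjust_covariates=False
        )
        assert rep.cohorts["training"].cox_univariate["hr"] < 1.0

    def test_missing_external_cohort_is_allowed(self, planted_bundle):
        rep = evaluate_module(
            planted_bundle.planted_module,
            planted_bundle.cohorts["training"],
            adjust_covariates=False,
        )
        assert "external" not in rep.cohorts

    def test_null_screen_rate_tracks_alpha(self, null_bundle):
        """Random 12-gene modules in a null bundle pass the 0.1 screen at
        roughly the nominal rate (loose bound over 40 replicates)."""
        rng = np.random.default_rng(6)
        genes = null_bundle.cohorts["training"].genes
        passes = 0
        for _ in range(40):
            module = list(rng.choice(genes, size=12, replace=False))
            rep = evaluate_module(
                module, null_bundle.cohorts["training"], adjust_covariates=False
            )
            passes += rep.screen_passed
        assert passes <= 12
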