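"""Hybrid OLR DIF machinery: fits, pseudo-R², flag rules, purification."""

import numpy as np
import pytest

from gradedif import (
    DIFConfig,
    DIFInjection,
    SimulationSpec,
    dif_analysis,
    dif_single_item,
    eap_score,
    fit_grm,
    fit_proportional_odds,
    pseudo_r2,
    simulate_responses,
)


def _hybrid_inputs(bank, n, seed, dif_spec=(), theta_means=None):
    d = simulate_responses(
        SimulationSpec(
            n_persons=n, item_bank=bank, seed=seed,
            dif_spec=dif_spec, theta_means=theta_means or {},
        )
    )
    fit = fit_grm(d, compute_se=False)
    theta = eap_score(d.scores, fit.bank).theta
    group = (d.gender == "F").astype(int)
    return d, theta, group


class TestProportionalOdds:
    def test_null_model_is_observed_cumulative_logits(self):
        y = np.repeat([0, 1, 2, 3], [10, 20, 30, 40])
        fit = fit_proportional_odds(y)
        emp = np.array([0.1, 0.3, 0.6])
        assert np.allclose(fit.intercepts, np.log(emp / (1 - emp)), atol=1e-6)
        saturated = sum(c * np.log(c / 100) for c in (10, 20, 30, 40))
        assert fit.loglik == pytest.approx(saturated, abs=1e-8)

    def test_matches_brute_force_grid(self):
        """Binary-outcome fit agrees with an exhaustive (intercept, slope)
        grid search to 1e-3 in log-likelihood."""
        rng = np.random.default_rng(5)
        n = 50
        x = rng.standard_normal(n)
        y = (x + rng.logistic(size=n) > 0.3).astype(int)
        fit = fit_proportional_odds(y, x)

        a_grid = np.linspace(-2.5, 2.5, 801)
        b_grid = np.linspace(-3.0, 3.0, 801)
        A, B = np.meshgrid(a_grid, b_grid, indexing="ij")
        # P(y<=0) = sigmoid(a - b x); loglik summed over persons
        ll = np.zeros_like(A)
        for xi, yi in zip(x, y):
            F = 1.0 / (1.0 + np.exp(-(A - B * xi)))
            ll += np.log(np.clip(F if yi == 0 else 1 - F, 1e-300, None))
        grid_best = ll.max()
        assert fit.loglik >= grid_best - 1e-9
        assert fit.loglik - grid_best < 1e-3

    def test_adding_predictors_never_decreases_loglik(self):
        rng = np.random.default_rng(11)
        n = 400
        theta = rng.standard_normal(n)
        g = rng.integers(0, 2, n)
        y = np.digitize(theta + 0.4 * g + rng.logistic(size=n), [-0.5, 0.8, 1.8])
        lls = [
            fit_proportional_odds(y, X).loglik
            for X in (None, theta, np.column_stack([theta, g]),
                      np.column_stack([theta, g, theta * g]))
        ]
        assert np.all(np.diff(lls) >= -1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="categories"):
            fit_proportional_odds(np.zeros(20, dtype=int))
        with pytest.raises(ValueError, match="consecutive"):
            fit_proportional_odds(np.array([0, 2, 0, 2]))
        with pytest.raises(ValueError, match="finite"):
            fit_proportional_odds(np.array([0, 1, 0, 1]), np.array([1.0, np.inf, 0, 1]))


class TestPseudoR2:
    def test_self_comparison_is_zero(self):
        y = np.repeat([0, 1, 2], [5, 7, 9])
        fit = fit_proportional_odds(y)
        r2 = pseudo_r2(fit, fit)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in r2.values())

    def test_closed_forms(self):
        from gradedif.dif import OLRFit

        fit = OLRFit(np.zeros(1), np.zeros(0), loglik=-90.0, n_params=1,
                     n_obs=100, converged=True)
        null = OLRFit(np.zeros(1), np.zeros(0), loglik=-100.0, n_params=1,
                      n_obs=100, converged=True)
        r2 = pseudo_r2(fit, null, 100)
        assert r2["mcfadden"] == pytest.approx(0.1)
        assert r2["coxsnell"] == pytest.approx(1 - np.exp(-0.2))
        assert r2["nagelkerke"] == pytest.approx(
            (1 - np.exp(-0.2)) / (1 - np.exp(-2.0))
        )

    def test_improvement_gives_positive_values(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(300)
        y = (x + rng.logistic(size=300) > 0).astype(int)
        f1 = fit_proportional_odds(y, x)
        f0 = fit_proportional_odds(y)
        assert all(v > 0 for v in pseudo_r2(f1, f0).values())


class TestSingleItem:
    def test_permuted_group_null_has_tiny_deltas(self, bank):
        d, theta, group = _hybrid_inputs(bank, 4000, seed=31)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(group)
            res = dif_single_item(d.scores[:, 9], theta, perm, item=10)
            assert not res.flagged
            assert res.delta("1v3") < 0.01
            for comp in ("1v2", "1v3", "2v3"):
                assert res.lr[comp][0] >= 0
                assert res.delta(comp) >= -1e-12

    def test_injected_uniform_dif_flagged_and_classified(self, bank):
        inj = DIFInjection(10, "F", threshold_shift=0.75)
        d, theta, group = _hybrid_inputs(bank, 12_677, seed=32, dif_spec=(inj,))
        res = dif_single_item(d.scores[:, 9], theta, group, item=10)
        assert res.flagged
        assert res.dif_type == "uniform"
        assert res.delta("1v2") > 0.02
        assert res.delta("2v3") < 0.02

    def test_flag_follows_threshold_rule(self, bank):
        """An item flags exactly when its 1-vs-3 pseudo-R² change clears
        the configured threshold."""
        inj = DIFInjection(10, "F", threshold_shift=0.75)
        d, theta, group = _hybrid_inputs(bank, 12_677, seed=32, dif_spec=(inj,))
        res = dif_single_item(d.scores[:, 9], theta, group, item=10)
        delta = res.delta("1v3")
        tight = dif_single_item(
            d.scores[:, 9], theta, group, item=10,
            config=DIFConfig(threshold=delta + 0.001),
        )
        assert not tight.flagged

    def test_flag_invariant_to_group_swap(self, bank):
        inj = DIFInjection(10, "F", threshold_shift=0.75)
        d, theta, group = _hybrid_inputs(bank, 6000, seed=33, dif_spec=(inj,))
        res = dif_single_item(d.scores[:, 9], theta, group, item=10)
        res_swap = dif_single_item(d.scores[:, 9], theta, 1 - group, item=10)
        assert res.flagged == res_swap.flagged
        assert res.delta("1v3") == pytest.approx(res_swap.delta("1v3"), abs=1e-6)

    def test_sparse_categories_collapsed(self):
        rng = np.random.default_rng(8)
        n = 400
        theta = rng.standard_normal(n)
        group = rng.integers(0, 2, n)
        y = np.digitize(theta + rng.logistic(size=n), [0.0, 3.5, 4.0])
        res = dif_single_item(y, theta, group, item=1, config=DIFConfig(min_cell=5))
        assert res.collapsed


class TestAnalysis:
    def test_no_dif_keeps_all_anchors(self, bank):
        d = simulate_responses(
            SimulationSpec(n_persons=4000, item_bank=bank, seed=41)
        )
        rep = dif_analysis(d, "gender")
        assert rep.flagged_items == []
        assert rep.anchor_set == list(range(1, 22))
        assert rep.n_purification_iters == 1
        assert rep.converged

    def test_single_injection_flags_only_that_item(self, bank):
        d = simulate_responses(
            SimulationSpec(
                n_persons=12_677, item_bank=bank, seed=42,
                dif_spec=(DIFInjection(10, "F", threshold_shift=0.75),),
            )
        )
        rep = dif_analysis(d, "gender")
        assert rep.flagged_items == [10]
        assert rep.anchor_set == [j for j in range(1, 22) if j != 10]
        assert rep.results[9].dif_type == "uniform"
        assert rep.converged

    def test_impact_without_dif_not_flagged(self, bank):
        """A pure trait-mean shift between groups (impact) must not be
        mistaken for DIF by the trait-conditioned scan."""
        d = simulate_responses(
            SimulationSpec(
                n_persons=8000, item_bank=bank, seed=43,
                theta_means={"F": 0.25, "M": -0.25},
            )
        )
        rep = dif_analysis(d, "gender")
        assert rep.flagged_items == []

    def test_purification_terminates(self, bank):
        d = simulate_responses(
            SimulationSpec(
                n_persons=6000, item_bank=bank, seed=44,
                dif_spec=(
                    DIFInjection(10, "F", threshold_shift=0.9),
                    DIFInjection(16, "F", discrimination_ratio=2.2),
                ),
            )
        )
        rep = dif_analysis(d, "gender")
        assert rep.n_purification_iters <= 10
        assert 10 in rep.flagged_items
        assert len(rep.trace) == rep.n_purification_iters

    def test_single_level_grouping_rejected(self, bank):
        d = simulate_responses(
            SimulationSpec(
                n_persons=200, item_bank=bank, seed=1,
                gender_fractions={"F": 1.0},
            )
        )
        with pytest.raises(ValueError, match="single level"):
            dif_analysis(d, "gender")
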