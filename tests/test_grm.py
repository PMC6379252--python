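"""Graded response model: probabilities, implied quantities, EM, EAP."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gradedif import (
    GRMItem,
    SimulationSpec,
    boundary_prob,
    category_prob,
    default_grid,
    eap_score,
    fit_grm,
    implied_marginals,
    implied_moments,
    simulate_responses,
)

item_strategy = st.builds(
    lambda a, b1, g2, g3: GRMItem(a=a, b=(b1, b1 + g2, b1 + g2 + g3)),
    a=st.floats(0.2, 4.0),
    b1=st.floats(-3.0, 3.0),
    g2=st.floats(0.05, 2.0),
    g3=st.floats(0.05, 2.0),
)


class TestProbabilities:
    def test_boundary_at_threshold_is_half(self):
        item = GRMItem(a=1.58, b=(0.03, 1.69, 3.04), label="sleep")
        assert boundary_prob(item, 1, 0.03) == pytest.approx(0.5)

    def test_boundary_closed_form(self):
        # a=2.38, b1=1.10 at theta=0: 1/(1+e^{2.618})
        item = GRMItem(a=2.38, b=(1.10, 2.75, 3.13))
        assert boundary_prob(item, 1, 0.0) == pytest.approx(0.0680, abs=5e-4)

    def test_boundary_limits_and_conventions(self):
        item = GRMItem(a=1.0, b=(0.0, 1.0, 2.0))
        assert boundary_prob(item, 1, -50.0) < 1e-15
        assert boundary_prob(item, 0, 3.0) == 1.0
        assert boundary_prob(item, 4, 3.0) == 0.0
        with pytest.raises(IndexError):
            boundary_prob(item, 7, 0.0)

    def test_category_prob_closed_form(self):
        item = GRMItem(a=1.0, b=(0.0, 1.0, 2.0))
        assert category_prob(item, 0.0)[0] == pytest.approx(0.5)
        item21 = GRMItem(a=1.32, b=(1.91, 3.26, 4.44))
        assert category_prob(item21, 2.0)[0] == pytest.approx(0.4703, abs=5e-4)

    @given(item=item_strategy, theta=st.floats(-6, 6))
    def test_category_probs_sum_to_one(self, item, theta):
        p = category_prob(item, theta)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-10

    def test_sum_to_one_on_dense_grid_all_items(self, bank):
        grid = np.linspace(-8, 8, 1000)
        for item in bank.items:
            p = category_prob(item, grid)
            assert np.max(np.abs(p.sum(axis=1) - 1.0)) < 1e-10

    @given(item=item_strategy, theta=st.floats(-5, 5))
    def test_boundary_probs_decreasing_in_k(self, item, theta):
        vals = [boundary_prob(item, k, theta) for k in range(1, item.n_categories)]
        assert np.all(np.diff(vals) < 0)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            GRMItem(a=1.0, b=(1.0, 0.5, 2.0))
        with pytest.raises(ValueError):
            GRMItem(a=-0.5, b=(0.0, 1.0))


class TestImpliedQuantities:
    def test_marginals_match_observed_score0_rates(self, bank):
        """Population score-0 rates from the bank reproduce the published
        response-category proportions of the calibration sample."""
        m = implied_marginals(bank)
        expected = {1: 0.813, 5: 0.699, 10: 0.776, 21: 0.880}
        for item, p0 in expected.items():
            assert m[item - 1, 0] == pytest.approx(p0, abs=0.015)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_single_threshold_symmetry(self):
        item = GRMItem(a=1.7, b=(0.0,))
        m = implied_marginals(_one_item_bank(item))
        assert m[0, 0] == pytest.approx(0.5, abs=1e-9)

    def test_implied_moments_match_observed(self, bank):
        mo = implied_moments(bank)
        assert mo["expected_total"] == pytest.approx(6.99, abs=0.3)
        assert mo["item_means"][0] == pytest.approx(0.21, abs=0.03)

    def test_quadrature_stability(self, bank):
        m61 = implied_marginals(bank, default_grid(61))
        m41 = implied_marginals(bank, default_grid(41))
        assert np.max(np.abs(m61 - m41)) < 1e-6


def _one_item_bank(item):
    from gradedif import ItemBank

    return ItemBank(items=[item])


class TestFitGRM:
    def test_em_loglik_monotone_and_recovery_small(self, toy_bank):
        data = simulate_responses(
            SimulationSpec(n_persons=5000, item_bank=toy_bank, seed=9)
        )
        fit = fit_grm(data, compute_se=True)
        assert fit.converged
        path = np.array(fit.loglik_path)
        assert np.all(np.diff(path) >= -1e-6)
        # recovery within 3 * (OPG SE + MC slack)
        for est, true in zip(fit.bank.items, toy_bank.items):
            assert abs(est.a - true.a) < 3 * (est.se_a + 0.02)
            for bk_e, bk_t, se in zip(est.b, true.b, est.se_b):
                assert abs(bk_e - bk_t) < 3 * (se + 0.02)

    def test_em_beats_random_search_oracle(self):
        """On a 2-item, K=3, N=30 toy, EM's marginal log-likelihood must
        be at least the best found by independent random search."""
        from gradedif import GRMItem, ItemBank

        truth = ItemBank(
            items=[GRMItem(a=1.5, b=(-0.5, 0.7)), GRMItem(a=1.0, b=(0.0, 1.0))]
        )
        data = simulate_responses(
            SimulationSpec(n_persons=30, item_bank=truth, seed=4)
        )
        fit = fit_grm(data, compute_se=False)

        # independent marginal log-likelihood evaluator (plain quadrature)
        nodes = np.linspace(-5, 5, 61)
        w = np.exp(-0.5 * nodes**2)
        w /= w.sum()

        def marginal_ll(params):
            ll = 0.0
            for row in data.scores:
                like = np.ones_like(nodes)
                for (a, b1, b2), x in zip(params, row):
                    s1 = 1 / (1 + np.exp(-a * (nodes - b1)))
                    s2 = 1 / (1 + np.exp(-a * (nodes - b2)))
                    p = [1 - s1, s1 - s2, s2][int(x)]
                    like = like * p
                ll += np.log(np.sum(w * like))
            return ll

        rng = np.random.default_rng(0)
        best = -np.inf
        for _ in range(8000):
            cand = []
            for _j in range(2):
                a = rng.uniform(0.2, 3.0)
                b1 = rng.uniform(-2, 2)
                b2 = b1 + rng.uniform(0.05, 2.5)
                cand.append((a, b1, b2))
            best = max(best, marginal_ll(cand))
        em_ll = marginal_ll(
            [(it.a, it.b[0], it.b[1]) for it in fit.bank.items]
        )
        assert em_ll >= best - 1e-3
        assert fit.loglik == pytest.approx(em_ll, abs=1e-6)

    def test_degenerate_item_rejected(self):
        scores = np.column_stack(
            [np.zeros(50), np.tile([0, 1, 2, 3], 13)[:50]]
        )
        with pytest.raises(ValueError, match="item 1"):
            fit_grm(scores)

    def test_empty_category_collapse_or_fail(self):
        rng = np.random.default_rng(3)
        col_ok = rng.integers(0, 4, 300)
        col_gap = rng.choice([0, 1, 3], 300)  # category 2 never observed
        scores = np.column_stack([col_ok, col_gap, rng.integers(0, 4, 300)])
        with pytest.raises(ValueError, match="item 2"):
            fit_grm(scores, on_empty="fail")
        fit = fit_grm(scores, on_empty="collapse", compute_se=False)
        assert 1 in fit.collapsed_items
        assert fit.bank.items[1].n_categories == 3


class TestEAP:
    def test_extreme_patterns_order(self, bank):
        lo = np.zeros((1, bank.n_items))
        hi = np.full((1, bank.n_items), 3.0)
        est = eap_score(np.vstack([lo, hi]), bank)
        assert est.theta[0] < 0 < est.theta[1]
        assert np.all(est.psd > 0)

    def test_monotone_in_single_response(self, bank):
        base = np.tile(np.array([1.0] * bank.n_items), (4, 1))
        for k, row in enumerate(base):
            row[5] = k
        est = eap_score(base, bank)
        assert np.all(np.diff(est.theta) > 0)

    def test_all_missing_falls_back_to_prior(self, bank):
        row = np.full((1, bank.n_items), np.nan)
        est = eap_score(row, bank)
        assert est.all_missing[0]
        assert est.theta[0] == pytest.approx(0.0, abs=1e-9)
        assert est.psd[0] == pytest.approx(1.0, abs=1e-3)

    def test_shrinkage_and_correlation(self, bank):
        data = simulate_responses(
            SimulationSpec(n_persons=5000, item_bank=bank, seed=17)
        )
        est = eap_score(data.scores, bank)
        slope = np.polyfit(data.theta_true, est.theta, 1)[0]
        corr = np.corrcoef(data.theta_true, est.theta)[0, 1]
        assert 0 < slope <= 1.0
        assert corr > 0.9
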