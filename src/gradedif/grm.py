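"""Graded response model: probabilities, implied population quantities, EAP scoring.

All probability functions use the logistic metric without the 1.702
scaling constant.  The boundary ("operating characteristic") probability
of scoring in category k or above is

    P*_k(theta) = 1 / (1 + exp(-a (theta - b_k))),   k = 1..K-1,

with the conventions P*_0 = 1 and P*_K = 0, so the probability of
scoring exactly k is the telescoping difference P_k = P*_k - P*_{k+1}.

Population ("implied") quantities integrate these probabilities over the
latent-trait distribution with a fixed quadrature grid; they are what a
very large sample drawn from the model would show, and are used both to
check a calibrated bank against observed marginals and to calibrate
group trait means in the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bank import GRMItem, ItemBank, QuadratureGrid, default_grid

__all__ = [
    "boundary_prob",
    "category_prob",
    "bank_category_probs",
    "implied_marginals",
    "implied_moments",
    "implied_alpha",
    "ThetaEstimates",
    "eap_score",
    "pattern_log_likelihood",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def boundary_prob(item: GRMItem, k: int, theta) -> np.ndarray | float:
    """P*_k(theta), probability of responding in category >= k.

    ``k`` runs from 1 to K-1; by convention k=0 gives 1 and k=K gives 0.
    """
    K = item.n_categories
    if k < 0 or k > K:
        raise IndexError(f"boundary index k={k} outside 0..{K}")
    theta_arr = np.asarray(theta, dtype=float)
    if k == 0:
        res = np.ones_like(theta_arr)
    elif k == K:
        res = np.zeros_like(theta_arr)
    else:
        res = _sigmoid(item.a * (theta_arr - item.b[k - 1]))
    return res if np.ndim(theta) else float(res)


def category_prob(item: GRMItem, theta) -> np.ndarray:
    """Category probability vector P_0..P_{K-1} at theta.

    For array theta of shape S, returns shape S + (K,).
    """
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    K = item.n_categories
    bstar = np.empty(theta_arr.shape + (K + 1,))
    bstar[..., 0] = 1.0
    bstar[..., K] = 0.0
    for k in range(1, K):
        bstar[..., k] = _sigmoid(item.a * (theta_arr - item.b[k - 1]))
    probs = bstar[..., :-1] - bstar[..., 1:]
    if np.ndim(theta) == 0:
        return probs[0]
    return probs


def bank_category_probs(bank: ItemBank, thetas: np.ndarray) -> np.ndarray:
    """(J, Q, K) array of category probabilities over a theta vector.

    K is the bank-wide maximum; items with fewer categories get zero
    probability in the categories they cannot produce.
    """
    thetas = np.asarray(thetas, dtype=float)
    K = bank.n_categories
    out = np.zeros((bank.n_items, thetas.size, K))
    for j, it in enumerate(bank.items):
        out[j, :, : it.n_categories] = category_prob(it, thetas)
    return out


def implied_marginals(bank: ItemBank, grid: QuadratureGrid | None = None) -> np.ndarray:
    """Population category probabilities, one K-vector per item.

    Integrates each item's category probabilities over the grid's trait
    distribution; rows sum to one.
    """
    grid = grid or default_grid()
    probs = bank_category_probs(bank, grid.nodes)  # (J, Q, K)
    return np.einsum("jqk,q->jk", probs, grid.weights)


def implied_moments(
    bank: ItemBank, grid: QuadratureGrid | None = None
) -> dict[str, np.ndarray | float]:
    """Model-implied item means, expected total score, and total variance.

    The total-score variance decomposes, by local independence, into the
    variance of the conditional mean E[T|theta] plus the mean of the
    conditional variance sum_j Var[X_j|theta].
    """
    grid = grid or default_grid()
    probs = bank_category_probs(bank, grid.nodes)  # (J, Q, K)
    k = np.arange(bank.n_categories)
    cond_mean = probs @ k  # (J, Q) E[X_j | theta_q]
    cond_second = probs @ (k**2)
    cond_var = cond_second - cond_mean**2
    item_means = cond_mean @ grid.weights
    total_cond_mean = cond_mean.sum(axis=0)  # E[T | theta_q]
    expected_total = float(total_cond_mean @ grid.weights)
    var_between = float(((total_cond_mean - expected_total) ** 2) @ grid.weights)
    var_within = float(cond_var.sum(axis=0) @ grid.weights)
    item_vars = (cond_var @ grid.weights) + (
        ((cond_mean - item_means[:, None]) ** 2) @ grid.weights
    )
    return {
        "item_means": item_means,
        "item_vars": item_vars,
        "expected_total": expected_total,
        "total_var": var_between + var_within,
    }


def implied_alpha(bank: ItemBank, grid: QuadratureGrid | None = None) -> float:
    """Cronbach's alpha a model-generated infinite sample would show."""
    m = implied_moments(bank, grid)
    J = bank.n_items
    return J / (J - 1) * (1.0 - float(np.sum(m["item_vars"])) / m["total_var"])


def pattern_log_likelihood(
    scores: np.ndarray, bank: ItemBank, thetas: np.ndarray
) -> np.ndarray:
    """(N, Q) log-likelihood of each response row at each theta node.

    ``scores`` is an (N, J) float array; NaN entries (missing responses)
    are skipped, so an all-missing row has log-likelihood zero.
    """
    scores = np.asarray(scores, dtype=float)
    n, J = scores.shape
    if J != bank.n_items:
        raise ValueError(f"data has {J} columns but bank has {bank.n_items} items")
    probs = bank_category_probs(bank, thetas)  # (J, Q, K)
    logp = np.log(np.clip(probs, 1e-300, None))
    ll = np.zeros((n, thetas.size))
    for j in range(J):
        obs = ~np.isnan(scores[:, j])
        cats = scores[obs, j].astype(int)
        ll[obs] += logp[j][:, cats].T
    return ll


@dataclass
class ThetaEstimates:
    """EAP latent-trait point estimates with posterior standard deviations."""

    theta: np.ndarray
    psd: np.ndarray
    all_missing: np.ndarray  # flag: row had no observed responses


def eap_score(
    scores: np.ndarray, bank: ItemBank, grid: QuadratureGrid | None = None
) -> ThetaEstimates:
    """Expected-a-posteriori trait scores under the grid's normal prior.

    Missing responses are skipped in the pattern likelihood; a fully
    missing row falls back to the prior (mean 0, SD 1) and is flagged.
    """
    grid = grid or default_grid()
    if hasattr(scores, "scores"):  # ResponseData
        scores = scores.scores
    scores = np.asarray(scores, dtype=float)
    ll = pattern_log_likelihood(scores, bank, grid.nodes)
    ll -= ll.max(axis=1, keepdims=True)
    post = np.exp(ll) * grid.weights
    post /= post.sum(axis=1, keepdims=True)
    theta = post @ grid.nodes
    second = post @ grid.nodes**2
    psd = np.sqrt(np.maximum(second - theta**2, 1e-12))
    all_missing = np.all(np.isnan(scores), axis=1)
    return ThetaEstimates(theta=theta, psd=psd, all_missing=all_missing)
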