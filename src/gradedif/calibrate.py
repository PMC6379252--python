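"""Marginal-maximum-likelihood EM calibration of the graded response model.

The latent trait is integrated out over a fixed quadrature grid with a
standard-normal prior (which also identifies the scale — no post-hoc
standardization).  The E-step computes each response pattern's posterior
weights over the grid nodes; the M-step maximizes each item's expected
complete-data log-likelihood by quasi-Newton search in a reparameterized
space (log discrimination; first threshold plus log-gaps) that enforces
threshold ordering by construction.  Standard errors come from the
outer-product-of-gradients (empirical cross-product) approximation of
the information matrix and should be read as approximate.

Response patterns are deduplicated before the E-step, so the cost per
iteration scales with the number of distinct patterns rather than the
number of persons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .bank import GRMItem, ItemBank, QuadratureGrid, default_grid
from .simulate import ResponseData

__all__ = ["FitResult", "fit_grm"]

log = logging.getLogger(__name__)

_MISSING = -1  # internal integer code for a missing response


@dataclass
class FitResult:
    """Calibrated bank with convergence diagnostics."""

    bank: ItemBank
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: list[float] = field(default_factory=list)
    collapsed_items: dict[int, list[int]] = field(default_factory=dict)


def _encode(scores: np.ndarray, on_empty: str):
    """Integer-code responses, collapsing unobserved categories if allowed.

    Returns (coded int matrix with -1 missing, per-item category count,
    per-item list of original category values retained).
    """
    scores = np.asarray(scores, dtype=float)
    n, J = scores.shape
    coded = np.full((n, J), _MISSING, dtype=np.int64)
    n_cats = np.zeros(J, dtype=int)
    kept: dict[int, list[int]] = {}
    for j in range(J):
        col = scores[:, j]
        obs = ~np.isnan(col)
        values = np.unique(col[obs]).astype(int)
        if values.size < 2:
            raise ValueError(
                f"item {j + 1} is degenerate: only {values.size} observed "
                "category; cannot calibrate"
            )
        full = np.arange(values.min(), values.max() + 1)
        if values.size != full.size or values.min() != 0:
            if on_empty == "fail":
                raise ValueError(
                    f"item {j + 1} has unobserved categories "
                    f"(observed {values.tolist()}); pass on_empty='collapse' "
                    "to merge them into the adjacent lower category"
                )
            log.warning(
                "item %d: collapsing to %d observed categories %s",
                j + 1, values.size, values.tolist(),
            )
        kept[j] = values.tolist()
        remap = {v: i for i, v in enumerate(values)}
        coded[obs, j] = np.vectorize(remap.get)(col[obs].astype(int))
        n_cats[j] = values.size
    return coded, n_cats, kept


def _item_neg_ll(z: np.ndarray, theta: np.ndarray, r: np.ndarray):
    """Expected negative log-likelihood of one item and its gradient.

    ``z`` = (log a, b1, log gap_2, ..., log gap_{K-1}); ``r`` is the
    (Q, K) table of expected counts per node and category.
    """
    K = r.shape[1]
    a = np.exp(z[0])
    gaps = np.exp(z[2:])
    b = z[1] + np.concatenate([[0.0], np.cumsum(gaps)])
    # boundary probabilities S_k, k=0..K
    S = np.ones((theta.size, K + 1))
    S[:, K] = 0.0
    x = a * (theta[:, None] - b[None, :])
    S[:, 1:K] = 1.0 / (1.0 + np.exp(-x))
    P = np.clip(S[:, :-1] - S[:, 1:], 1e-12, None)
    f = float(np.sum(r * np.log(P)))

    D = r / P  # (Q, K)
    Sint = S[:, 1:K]
    sprime = Sint * (1.0 - Sint)  # (Q, K-1)
    # d f / d S_k for interior k: S_k enters P_{k-1} with -1 and P_k with +1
    dd = D[:, 1:] - D[:, :-1]
    df_da = np.sum(dd * (theta[:, None] - b[None, :]) * sprime)
    df_db = np.sum(dd * (-a) * sprime, axis=0)  # per threshold
    grad = np.empty_like(z)
    grad[0] = a * df_da
    grad[1] = df_db.sum()
    csum = np.cumsum(df_db[::-1])[::-1]  # sum_{k>=m} df_db_k
    grad[2:] = gaps * csum[1:]
    return -f, -grad


def _z_from_item(a: float, b: np.ndarray) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    return np.concatenate([[np.log(a), b[0]], np.log(np.diff(b))])


def _params_from_z(z: np.ndarray):
    a = float(np.exp(z[0]))
    b = z[1] + np.concatenate([[0.0], np.cumsum(np.exp(z[2:]))])
    return a, b


def _log_prob_tables(params, nodes: np.ndarray) -> list[np.ndarray]:
    """Per-item (Q, K_j) log category-probability tables."""
    tables = []
    for a, b in params:
        K = b.size + 1
        S = np.ones((nodes.size, K + 1))
        S[:, K] = 0.0
        S[:, 1:K] = 1.0 / (1.0 + np.exp(-a * (nodes[:, None] - b[None, :])))
        tables.append(np.log(np.clip(S[:, :-1] - S[:, 1:], 1e-300, None)))
    return tables


def _pattern_loglik(coded: np.ndarray, tables) -> np.ndarray:
    """(P, Q) log-likelihood of each coded pattern at each node."""
    P, J = coded.shape
    Q = tables[0].shape[0]
    ll = np.zeros((P, Q))
    for j in range(J):
        resp = coded[:, j]
        obs = resp != _MISSING
        ll[obs] += tables[j][:, resp[obs]].T
    return ll


def fit_grm(
    data: ResponseData | np.ndarray,
    grid: QuadratureGrid | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
    on_empty: str = "fail",
    compute_se: bool = True,
    labels: list[str] | None = None,
) -> FitResult:
    """Calibrate GRM item parameters by MML-EM under a N(0,1) trait prior.

    Iterates until the largest absolute parameter change falls below
    ``tol`` or ``max_iter`` is reached.  The marginal log-likelihood is
    guaranteed non-decreasing across iterations and is checked at every
    step.  Items whose interior categories were never observed are
    collapsed (``on_empty='collapse'``) or rejected (default).
    """
    scores = data.scores if isinstance(data, ResponseData) else np.asarray(data, float)
    if scores.shape[0] < 10:
        raise ValueError("too few persons to calibrate (need at least 10)")
    grid = grid or default_grid()
    nodes, weights = grid.nodes, grid.weights

    coded, n_cats, kept = _encode(scores, on_empty)
    J = coded.shape[1]
    if labels is None:
        labels = [f"item{j + 1:02d}" for j in range(J)]

    patterns, counts = np.unique(coded, axis=0, return_counts=True)
    counts = counts.astype(float)

    # Starting values: a = 1, thresholds at inverse-logits of observed
    # cumulative endorsement proportions, forced strictly increasing.
    params = []
    for j in range(J):
        col = coded[:, j]
        obs = col != _MISSING
        K = n_cats[j]
        prop_ge = np.array([(col[obs] >= k).mean() for k in range(1, K)])
        prop_ge = np.clip(prop_ge, 1e-3, 1 - 1e-3)
        b = -np.log(prop_ge / (1 - prop_ge))
        for k in range(1, b.size):
            b[k] = max(b[k], b[k - 1] + 1e-3)
        params.append((1.0, b))

    loglik_path: list[float] = []
    prev_loglik = -np.inf
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        tables = _log_prob_tables(params, nodes)
        ll = _pattern_loglik(patterns, tables)  # (P, Q)
        ll_w = ll + np.log(weights)[None, :]
        m = ll_w.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(ll_w - m).sum(axis=1))
        loglik = float(counts @ lse)
        if loglik < prev_loglik - 1e-6 * max(1.0, abs(prev_loglik)):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: "
                f"{prev_loglik} -> {loglik}"
            )
        loglik_path.append(loglik)
        prev_loglik = loglik

        post = np.exp(ll_w - lse[:, None])  # (P, Q), rows sum to 1
        W = post * counts[:, None]

        new_params = []
        delta = 0.0
        for j in range(J):
            K = n_cats[j]
            resp = patterns[:, j]
            r = np.zeros((nodes.size, K))
            for k in range(K):
                mask = resp == k
                if mask.any():
                    r[:, k] = W[mask].sum(axis=0)
            a0, b0 = params[j]
            z0 = _z_from_item(a0, b0)
            res = minimize(
                _item_neg_ll, z0, args=(nodes, r), jac=True,
                method="L-BFGS-B", options={"maxiter": 100, "ftol": 1e-12},
            )
            a1, b1 = _params_from_z(res.x)
            delta = max(delta, abs(a1 - a0), float(np.max(np.abs(b1 - b0))))
            new_params.append((a1, np.asarray(b1)))
        params = new_params
        if delta < tol:
            converged = True
            break

    if not converged:
        log.warning("EM reached max_iter=%d without converging (delta=%g)", max_iter, delta)

    # marginal log-likelihood at the returned (post-M-step) parameters
    tables = _log_prob_tables(params, nodes)
    ll_w = _pattern_loglik(patterns, tables) + np.log(weights)[None, :]
    m = ll_w.max(axis=1, keepdims=True)
    final_loglik = float(
        counts @ (m[:, 0] + np.log(np.exp(ll_w - m).sum(axis=1)))
    )
    loglik_path.append(final_loglik)
    prev_loglik = final_loglik

    se_a, se_b = _opg_standard_errors(params, patterns, counts, nodes, weights) if compute_se else (
        [None] * J, [None] * J
    )

    items = []
    collapsed = {}
    for j in range(J):
        a, b = params[j]
        if kept[j] != list(range(len(kept[j]))):
            collapsed[j] = kept[j]
        items.append(
            GRMItem(
                a=a, b=tuple(b),
                se_a=se_a[j],
                se_b=tuple(se_b[j]) if se_b[j] is not None else None,
                label=labels[j],
            )
        )
    bank = ItemBank(items=items, metadata={"estimator": "MML-EM", "n_iter": n_iter})
    return FitResult(
        bank=bank, loglik=prev_loglik, n_iter=n_iter, converged=converged,
        loglik_path=loglik_path, collapsed_items=collapsed,
    )


def _opg_standard_errors(params, patterns, counts, nodes, weights):
    """Outer-product-of-gradients SEs in the natural (a, b) metric.

    The gradient of each pattern's marginal log-likelihood with respect
    to every item parameter is the posterior-weighted complete-data
    score; summing count-weighted outer products approximates the
    information matrix.
    """
    J = patterns.shape[1]
    P = patterns.shape[0]
    tables = _log_prob_tables(params, nodes)
    ll = _pattern_loglik(patterns, tables)
    ll_w = ll + np.log(weights)[None, :]
    m = ll_w.max(axis=1, keepdims=True)
    post = np.exp(ll_w - m)
    post /= post.sum(axis=1, keepdims=True)  # (P, Q)

    n_par = sum(b.size + 1 for _, b in params)
    G = np.zeros((P, n_par))
    offset = 0
    for j in range(J):
        a, b = params[j]
        K = b.size + 1
        S = np.ones((nodes.size, K + 1))
        S[:, K] = 0.0
        S[:, 1:K] = 1.0 / (1.0 + np.exp(-a * (nodes[:, None] - b[None, :])))
        Pk = np.clip(S[:, :-1] - S[:, 1:], 1e-12, None)  # (Q, K)
        sprime = S[:, 1:K] * (1 - S[:, 1:K])  # (Q, K-1)
        # d log P_k / da and / db_m at each node, for each category k
        dlogp_da = np.zeros((nodes.size, K))
        dlogp_db = np.zeros((nodes.size, K, K - 1))
        for k in range(K):
            # P_k = S_k - S_{k+1}; S_k has threshold b[k-1], S_{k+1} has b[k]
            d_lower = (nodes - b[k - 1]) * sprime[:, k - 1] if k >= 1 else 0.0
            d_upper = (nodes - b[k]) * sprime[:, k] if k <= K - 2 else 0.0
            dlogp_da[:, k] = (d_lower - d_upper) / Pk[:, k]
            if k >= 1:
                dlogp_db[:, k, k - 1] += -a * sprime[:, k - 1] / Pk[:, k]
            if k <= K - 2:
                dlogp_db[:, k, k] -= -a * sprime[:, k] / Pk[:, k]
        resp = patterns[:, j]
        obs = resp != _MISSING
        G[obs, offset] = np.einsum("pq,qp->p", post[obs], dlogp_da[:, resp[obs]])
        for mth in range(K - 1):
            G[obs, offset + 1 + mth] = np.einsum(
                "pq,qp->p", post[obs], dlogp_db[:, resp[obs], mth]
            )
        offset += K
    info = G.T @ (G * counts[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        log.warning("information matrix singular; standard errors unavailable")
        return [None] * J, [None] * J
    se_a, se_b = [], []
    offset = 0
    for j in range(J):
        K = params[j][1].size + 1
        se_a.append(float(se[offset]))
        se_b.append(se[offset + 1 : offset + K].tolist())
        offset += K
    return se_a, se_b
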