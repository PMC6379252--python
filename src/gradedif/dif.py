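"""Iterative hybrid ordinal-logistic-regression DIF detection.

For each item, four nested cumulative-logit (proportional-odds) models
of the item response are fitted by maximum likelihood:

    model 0: intercepts only
    model 1: intercepts + trait score theta
    model 2: intercepts + theta + group
    model 3: intercepts + theta + group + theta x group

The conditioning trait score is the EAP estimate from a GRM calibration
("hybrid": an IRT score rather than the raw sum score).  An item is
flagged for DIF when the pseudo-R² change between models 1 and 3
exceeds a threshold (default 0.02); the change between models 1 and 2
signals uniform DIF (constant group effect) and between 2 and 3
non-uniform DIF (group effect varying with the trait).  Likelihood-ratio
chi-square statistics for the same comparisons are reported, and an
LR-based significance flag rule is available as an alternative.

Purification: items flagged on a pass are given group-specific item
parameters in a recalibration (the unflagged anchors keep shared
parameters and fix the trait metric), trait scores are re-estimated,
and the scan repeats until the flagged set stabilizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .bank import ItemBank, QuadratureGrid, default_grid
from .calibrate import fit_grm
from .grm import eap_score
from .simulate import ResponseData

__all__ = [
    "OLRFit",
    "DIFItemResult",
    "DIFReport",
    "DIFConfig",
    "fit_proportional_odds",
    "pseudo_r2",
    "dif_single_item",
    "dif_analysis",
]

log = logging.getLogger(__name__)

R2_FLAVORS = ("mcfadden", "coxsnell", "nagelkerke")


@dataclass
class OLRFit:
    """Maximum-likelihood proportional-odds fit."""

    intercepts: np.ndarray  # ordered cumulative-logit cutpoints, length K-1
    beta: np.ndarray  # slopes, one per predictor column (may be empty)
    loglik: float
    n_params: int
    n_obs: int
    converged: bool


def _po_neg_ll(z: np.ndarray, y: np.ndarray, X: np.ndarray, K: int):
    """Negative log-likelihood and gradient, cutpoints as (c1, log-gaps).

    P(Y <= k) = sigmoid(alpha_{k+1} - X beta); the log-gap
    parameterization keeps the cutpoints ordered during the search.
    """
    ncut = K - 1
    alpha = z[0] + np.concatenate([[0.0], np.cumsum(np.exp(z[1:ncut]))])
    beta = z[ncut:]
    eta = X @ beta if X.size else np.zeros(y.size)
    # cumulative probs F_k = P(Y<=k), k=0..K-1; F_{K-1}=1
    lin_u = np.where(y < ncut, alpha[np.minimum(y, ncut - 1)] - eta, np.inf)
    lin_l = np.where(y > 0, alpha[np.maximum(y - 1, 0)] - eta, -np.inf)
    Fu = np.where(np.isinf(lin_u), 1.0, 1.0 / (1.0 + np.exp(-np.clip(lin_u, -700, 700))))
    Fl = np.where(np.isinf(lin_l), 0.0, 1.0 / (1.0 + np.exp(-np.clip(lin_l, -700, 700))))
    p = np.clip(Fu - Fl, 1e-300, None)
    nll = -float(np.log(p).sum())

    fu = np.where(np.isinf(lin_u), 0.0, Fu * (1 - Fu))  # logistic density at upper
    fl = np.where(np.isinf(lin_l), 0.0, Fl * (1 - Fl))
    inv_p = 1.0 / p
    # d ll / d alpha_j accumulated over persons
    dalpha = np.zeros(ncut)
    np.add.at(dalpha, np.minimum(y, ncut - 1), np.where(y < ncut, fu * inv_p, 0.0))
    np.add.at(dalpha, np.maximum(y - 1, 0), np.where(y > 0, -fl * inv_p, 0.0))
    dbeta = -X.T @ ((fu - fl) * inv_p) if X.size else np.zeros(0)
    grad = np.empty_like(z)
    grad[0] = dalpha.sum()
    gaps = np.exp(z[1:ncut])
    csum = np.cumsum(dalpha[::-1])[::-1]  # sum_{j>=m} dalpha_j
    grad[1:ncut] = gaps * csum[1:]
    grad[ncut:] = dbeta
    return nll, -grad


def fit_proportional_odds(y: np.ndarray, X: np.ndarray | None = None) -> OLRFit:
    """Fit a cumulative-logit proportional-odds model by ML.

    ``y`` holds consecutive integer categories 0..K-1 (each observed at
    least once); ``X`` is an (n, p) design of slope predictors, or None
    for the intercept-only model.  Deterministic given the data.
    """
    y = np.asarray(y, dtype=np.int64)
    if X is None:
        X = np.empty((y.size, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors must be finite")
    cats = np.unique(y)
    K = cats.size
    if K < 2:
        raise ValueError("response must have at least 2 observed categories")
    if not np.array_equal(cats, np.arange(K)):
        raise ValueError(f"response categories must be consecutive 0..K-1, got {cats}")

    # start at the empirical cumulative logits, zero slopes
    cum = np.cumsum(np.bincount(y, minlength=K))[:-1] / y.size
    cum = np.clip(cum, 1e-10, 1 - 1e-10)
    alpha0 = np.log(cum / (1 - cum))
    for k in range(1, alpha0.size):
        alpha0[k] = max(alpha0[k], alpha0[k - 1] + 1e-6)
    z0 = np.concatenate(
        [[alpha0[0]], np.log(np.diff(alpha0) + 1e-10), np.zeros(X.shape[1])]
    )
    res = minimize(
        _po_neg_ll, z0, args=(y, X, K), jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"proportional-odds fit failed: {res.message}")
    ncut = K - 1
    alpha = res.x[0] + np.concatenate([[0.0], np.cumsum(np.exp(res.x[1:ncut]))])
    return OLRFit(
        intercepts=alpha,
        beta=res.x[ncut:].copy(),
        loglik=-float(res.fun),
        n_params=ncut + X.shape[1],
        n_obs=y.size,
        converged=bool(res.success),
    )


def pseudo_r2(fit: OLRFit, null_fit: OLRFit, n: int | None = None) -> dict[str, float]:
    """McFadden, Cox-Snell and Nagelkerke pseudo-R² of ``fit`` against a null.

    McFadden = 1 - ll/ll0; Cox-Snell = 1 - exp(2 (ll0 - ll)/n);
    Nagelkerke rescales Cox-Snell by its maximum 1 - exp(2 ll0 / n).
    """
    n = n or fit.n_obs
    ll, ll0 = fit.loglik, null_fit.loglik
    mcfadden = 1.0 - ll / ll0 if ll0 != 0 else np.nan
    coxsnell = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
    denom = 1.0 - np.exp(2.0 * ll0 / n)
    nagelkerke = coxsnell / denom if denom > 0 else np.nan
    return {"mcfadden": mcfadden, "coxsnell": coxsnell, "nagelkerke": nagelkerke}


@dataclass
class DIFConfig:
    """Tuning knobs of the DIF scan."""

    flavor: str = "mcfadden"
    threshold: float = 0.02
    min_cell: int = 5
    max_purification_iters: int = 10
    flag_rule: str = "r2"  # 'r2' (pseudo-R² change) or 'lrt' (Bonferroni LR test)
    lrt_alpha: float = 0.01
    anchor_mode: str = "group_specific"  # or 'anchors_only'

    def __post_init__(self) -> None:
        if self.flavor not in R2_FLAVORS:
            raise ValueError(f"flavor must be one of {R2_FLAVORS}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.flag_rule not in ("r2", "lrt"):
            raise ValueError("flag_rule must be 'r2' or 'lrt'")


@dataclass
class DIFItemResult:
    """Nested-model comparison summary for one item."""

    item: int  # 1-based
    loglik: dict[str, float]  # keys m0..m3
    lr: dict[str, tuple[float, int]]  # comparison -> (chi2, df)
    r2_delta: dict[str, dict[str, float]]  # comparison -> flavor -> delta
    flagged: bool
    dif_type: str  # none / uniform / nonuniform / mixed
    collapsed: bool = False

    def delta(self, comparison: str, flavor: str = "mcfadden") -> float:
        return self.r2_delta[comparison][flavor]


def _collapse_sparse(y: np.ndarray, group01: np.ndarray, min_cell: int):
    """Merge categories with < min_cell observations in either group downward.

    Returns the recoded response and whether any merge happened.
    """
    y = y.copy()
    collapsed = False
    while True:
        cats = np.unique(y)
        if cats.size <= 2:
            break
        counts = np.array(
            [[np.sum((y == c) & (group01 == g)) for g in (0, 1)] for c in cats]
        )
        sparse = np.where(counts.min(axis=1) < min_cell)[0]
        if sparse.size == 0:
            break
        i = sparse[-1]  # merge the highest sparse category downward
        target = cats[i - 1] if i > 0 else cats[i + 1]
        y[y == cats[i]] = target
        collapsed = True
    # recode to consecutive 0..K-1
    cats = np.unique(y)
    remap = np.zeros(cats.max() + 1, dtype=np.int64)
    remap[cats] = np.arange(cats.size)
    return remap[y], collapsed


def dif_single_item(
    y: np.ndarray,
    theta: np.ndarray,
    group: np.ndarray,
    item: int = 0,
    config: DIFConfig | None = None,
) -> DIFItemResult:
    """Run the four nested OLR models for one item and apply the flag rules.

    ``group`` is binary (0 = reference, 1 = focal).  Flag: pseudo-R²
    change of models 1 vs 3 above the threshold (or, under the 'lrt'
    rule, a significant 2-df likelihood-ratio test).  Classification:
    uniform if the 1-vs-2 change exceeds the threshold, non-uniform if
    2-vs-3 does, mixed if both.
    """
    config = config or DIFConfig()
    y = np.asarray(y)
    obs = ~np.isnan(np.asarray(y, dtype=float))
    y = np.asarray(y, dtype=float)[obs].astype(np.int64)
    theta = np.asarray(theta, dtype=float)[obs]
    g = np.asarray(group)[obs].astype(np.int64)
    y, collapsed = _collapse_sparse(y, g, config.min_cell)
    if collapsed:
        log.info("item %d: sparse categories collapsed before OLR", item)

    n = y.size
    interaction = theta * g
    designs = {
        "m0": None,
        "m1": theta[:, None],
        "m2": np.column_stack([theta, g]),
        "m3": np.column_stack([theta, g, interaction]),
    }
    fits = {name: fit_proportional_odds(y, X) for name, X in designs.items()}
    ll = {name: fit.loglik for name, fit in fits.items()}

    comparisons = {"1v2": ("m1", "m2"), "1v3": ("m1", "m3"), "2v3": ("m2", "m3")}
    lr = {}
    r2_delta = {}
    for comp, (lo, hi) in comparisons.items():
        chi2 = max(0.0, 2.0 * (ll[hi] - ll[lo]))
        df = fits[hi].n_params - fits[lo].n_params
        lr[comp] = (chi2, df)
        r2_lo = pseudo_r2(fits[lo], fits["m0"], n)
        r2_hi = pseudo_r2(fits[hi], fits["m0"], n)
        r2_delta[comp] = {f: r2_hi[f] - r2_lo[f] for f in R2_FLAVORS}

    fl = config.flavor
    if config.flag_rule == "r2":
        flagged = r2_delta["1v3"][fl] > config.threshold
    else:
        from scipy.stats import chi2 as chi2_dist

        n_items_for_bonf = 21
        crit = config.lrt_alpha / n_items_for_bonf
        flagged = chi2_dist.sf(lr["1v3"][0], lr["1v3"][1]) < crit
    uniform = r2_delta["1v2"][fl] > config.threshold
    nonuniform = r2_delta["2v3"][fl] > config.threshold
    dif_type = (
        "mixed" if (uniform and nonuniform)
        else "uniform" if uniform
        else "nonuniform" if nonuniform
        else "none"
    )
    return DIFItemResult(
        item=item, loglik=ll, lr=lr, r2_delta=r2_delta,
        flagged=flagged, dif_type=dif_type, collapsed=collapsed,
    )


@dataclass
class DIFReport:
    """Per-item DIF results plus the purification trace."""

    results: list[DIFItemResult]
    anchor_set: list[int]  # 1-based indices of final non-DIF items
    n_purification_iters: int
    converged: bool
    theta_source: str
    trace: list[list[int]] = field(default_factory=list)  # flagged sets per pass
    bank: ItemBank | None = None

    @property
    def flagged_items(self) -> list[int]:
        return [r.item for r in self.results if r.flagged]

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.results:
            row = {"item": r.item, "flagged": r.flagged, "dif_type": r.dif_type}
            row.update({f"loglik_{m}": r.loglik[m] for m in ("m0", "m1", "m2", "m3")})
            for comp in ("1v2", "1v3", "2v3"):
                row[f"lr_{comp}"] = r.lr[comp][0]
                row[f"df_{comp}"] = r.lr[comp][1]
                for f in R2_FLAVORS:
                    row[f"dr2_{comp}_{f}"] = r.r2_delta[comp][f]
            rows.append(row)
        return pd.DataFrame(rows)


def _group_specific_scores(
    data: ResponseData, group01: np.ndarray, flagged: list[int],
    grid: QuadratureGrid,
):
    """EAP trait scores with flagged items split into group-specific columns.

    Anchors keep one shared column; each flagged item becomes two
    columns, observed only in its group, so its parameters are
    estimated per group while the anchors pin the theta metric.
    """
    scores = data.scores
    n, J = scores.shape
    cols = []
    labels = []
    for j in range(J):
        if (j + 1) in flagged:
            for g in (0, 1):
                col = np.where(group01 == g, scores[:, j], np.nan)
                cols.append(col)
                labels.append(f"item{j + 1:02d}_g{g}")
        else:
            cols.append(scores[:, j])
            labels.append(f"item{j + 1:02d}")
    aug = np.column_stack(cols)
    fit = fit_grm(aug, grid=grid, compute_se=False, labels=labels, on_empty="collapse")
    est = eap_score(aug, fit.bank, grid)
    return est.theta, fit


def dif_analysis(
    data: ResponseData,
    grouping: str = "gender",
    config: DIFConfig | None = None,
    grid: QuadratureGrid | None = None,
) -> DIFReport:
    """Full iterative hybrid OLR DIF scan with purification.

    1. Calibrate the GRM on all persons pooled and score everyone by
       EAP.  2. Scan every item with :func:`dif_single_item`.  3. If any
       item is flagged, re-estimate trait scores treating flagged items
       as group-specific (or dropping them, per config) and rescan.
       Stops when the flagged set repeats or the iteration cap is hit.
    """
    config = config or DIFConfig()
    grid = grid or default_grid()
    labels = data.group_labels(grouping)
    ref = {"gender": "M", "age": "younger"}[grouping]
    group01 = (labels != ref).astype(np.int64)
    if group01.min() == group01.max():
        raise ValueError(f"grouping {grouping!r} has a single level in the data")

    fit = fit_grm(data, grid=grid, compute_se=False, on_empty="collapse")
    theta = eap_score(data.scores, fit.bank, grid).theta
    theta_source = "EAP from pooled calibration"

    J = data.n_items
    trace: list[list[int]] = []
    flagged: list[int] = []
    converged = False
    results: list[DIFItemResult] = []
    n_iter = 0
    for n_iter in range(1, config.max_purification_iters + 1):
        results = [
            dif_single_item(data.scores[:, j], theta, group01, item=j + 1, config=config)
            for j in range(J)
        ]
        flagged = [r.item for r in results if r.flagged]
        trace.append(flagged)
        if len(flagged) == J:
            raise RuntimeError("all items flagged for DIF; no anchors remain")
        if len(trace) >= 2 and flagged == trace[-2]:
            converged = True
            break
        if not flagged and len(trace) == 1:
            converged = True
            break
        if config.anchor_mode == "group_specific":
            theta, _ = _group_specific_scores(data, group01, flagged, grid)
            theta_source = "EAP, flagged items group-specific"
        else:
            anchors = [j for j in range(J) if (j + 1) not in flagged]
            sub = data.scores[:, anchors]
            sub_fit = fit_grm(sub, grid=grid, compute_se=False, on_empty="collapse")
            theta = eap_score(sub, sub_fit.bank, grid).theta
            theta_source = "EAP from anchor items only"
    else:
        log.warning("purification did not stabilize in %d passes", n_iter)

    anchor_set = [j + 1 for j in range(J) if (j + 1) not in flagged]
    return DIFReport(
        results=results,
        anchor_set=anchor_set,
        n_purification_iters=n_iter,
        converged=converged,
        theta_source=theta_source,
        trace=trace,
        bank=fit.bank,
    )
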