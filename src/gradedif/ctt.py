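"""Classical-test-theory descriptives for ordinal scales.

Cronbach's alpha, alpha-if-item-deleted, item and total-score means,
SDs and coefficients of variation, cut-off classification rates, and
simple two-group comparisons of total scores.  Rows with any missing
response are dropped (listwise deletion) before reliability statistics;
all variances use the N-1 denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ResponseData

__all__ = [
    "CTTReport",
    "cronbach_alpha",
    "item_descriptives",
    "classify_cutoff",
    "compare_groups",
]

log = logging.getLogger(__name__)


def _complete_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    complete = ~np.isnan(scores).any(axis=1)
    n_dropped = scores.shape[0] - int(complete.sum())
    if n_dropped:
        log.info("listwise deletion dropped %d incomplete rows", n_dropped)
    return scores[complete]


def _alpha(scores: np.ndarray) -> float:
    J = scores.shape[1]
    if J < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    total_var = scores.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    item_var = scores.var(axis=0, ddof=1).sum()
    return J / (J - 1) * (1.0 - item_var / total_var)


def cronbach_alpha(data: ResponseData | np.ndarray) -> float:
    """Cronbach's alpha of the scale, after listwise deletion."""
    scores = data.scores if isinstance(data, ResponseData) else np.asarray(data, float)
    return _alpha(_complete_scores(scores))


@dataclass
class CTTReport:
    """Item/total descriptives in the layout of a scale-characteristics table."""

    item_mean: np.ndarray
    item_sd: np.ndarray
    item_cv: np.ndarray
    alpha_if_deleted: np.ndarray
    total_mean: float
    total_sd: float
    total_cv: float
    alpha: float
    labels: list[str]
    n_used: int
    degenerate_items: list[int]  # 0-based indices of zero-variance items

    def to_frame(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            {
                "item": self.labels,
                "M": self.item_mean,
                "SD": self.item_sd,
                "CV": self.item_cv,
                "alpha_if_deleted": self.alpha_if_deleted,
            }
        )
        total = pd.DataFrame(
            {
                "item": ["Total"],
                "M": [self.total_mean],
                "SD": [self.total_sd],
                "CV": [self.total_cv],
                "alpha_if_deleted": [self.alpha],
            }
        )
        return pd.concat([rows, total], ignore_index=True)


def item_descriptives(data: ResponseData, labels: list[str] | None = None) -> CTTReport:
    """Per-item and total M, SD, CV (= SD/M) plus alpha-if-item-deleted.

    CV is reported as 0 and the item flagged when its mean or SD is 0.
    """
    scores = _complete_scores(data.scores)
    n, J = scores.shape
    if n == 0 or J == 0:
        raise ValueError("no complete rows / no items")
    labels = labels or [f"item{j + 1:02d}" for j in range(J)]
    mean = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=1)
    degenerate = [int(j) for j in np.where(sd == 0)[0]]
    if degenerate:
        log.warning("items with zero variance: %s", degenerate)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    if J >= 3:
        aid = np.array(
            [_alpha(np.delete(scores, j, axis=1)) for j in range(J)]
        )
    else:
        aid = np.full(J, np.nan)
        log.warning("alpha-if-deleted undefined for a %d-item scale", J)
    total = scores.sum(axis=1)
    tm, ts = float(total.mean()), float(total.std(ddof=1))
    return CTTReport(
        item_mean=mean,
        item_sd=sd,
        item_cv=cv,
        alpha_if_deleted=aid,
        total_mean=tm,
        total_sd=ts,
        total_cv=ts / tm if tm > 0 else 0.0,
        alpha=_alpha(scores),
        labels=labels,
        n_used=n,
        degenerate_items=degenerate,
    )


def classify_cutoff(data: ResponseData, cutoff: int = 13) -> dict[str, float]:
    """Proportion with total score strictly above the cut-off, by group.

    The default 13 matches the conventional BDI-II banding where totals
    of 0-13 are "minimal"; a person is classified probable-depression
    when total > cutoff, i.e. >= cutoff + 1.
    """
    total = data.total_scores()
    above = total > cutoff
    out = {"overall": float(above.mean())}
    for grouping in ("gender", "age"):
        labels = data.group_labels(grouping)
        for g in np.unique(labels):
            out[str(g)] = float(above[labels == g].mean())
    return out


def compare_groups(
    data: ResponseData, grouping: str = "gender", cutoff: int = 13
) -> dict[str, float]:
    """Welch comparison of total scores plus a 2x2 chi-square on the cut-off.

    Group order follows the reference/focal convention (men before
    women, younger before older); ``mean_diff`` is focal minus
    reference.
    """
    labels = data.group_labels(grouping)
    order = ["M", "F"] if grouping == "gender" else ["younger", "older"]
    groups = [g for g in order if g in labels] + [
        str(g) for g in np.unique(labels) if g not in order
    ]
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    total = data.total_scores()
    x0, x1 = total[labels == groups[0]], total[labels == groups[1]]
    if min(x0.size, x1.size) < 2:
        raise ValueError("each group needs at least 2 members")
    t_stat, p_val = stats.ttest_ind(x1, x0, equal_var=False)
    above = total > cutoff
    table = np.array(
        [
            [(above & (labels == g)).sum(), ((~above) & (labels == g)).sum()]
            for g in groups
        ]
    )
    if table.min() > 0:
        chi2, p_chi2, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        chi2, p_chi2 = np.nan, np.nan
    return {
        "reference": groups[0],
        "focal": groups[1],
        "mean_diff": float(x1.mean() - x0.mean()),
        "t_stat": float(t_stat),
        "p_value": float(p_val),
        "prop_reference": float(above[labels == groups[0]].mean()),
        "prop_focal": float(above[labels == groups[1]].mean()),
        "chi2": float(chi2),
        "p_chi2": float(p_chi2),
    }
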