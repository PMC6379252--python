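"""Item and test characteristic curves, and DIF impact on the total score.

The item characteristic curve (ICC) is the expected item score
E[X|theta] = sum_k k P_k(theta) together with the per-category
probability curves; the test characteristic curve (TCC) sums the item
ICCs and maps the latent trait to the expected raw total (0 to J*(K-1)).
Comparing the TCCs implied by a reference-group and a focal-group bank
quantifies, in raw-score points, how much flagged DIF items actually
move the total score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bank import GRMItem, ItemBank
from .grm import bank_category_probs, category_prob

__all__ = ["CurveTable", "curve_grid", "icc", "tcc", "dif_impact"]


def curve_grid(lo: float = -4.0, hi: float = 4.0, n: int = 201) -> np.ndarray:
    """Default plotting grid for characteristic curves."""
    return np.linspace(lo, hi, n)


@dataclass
class CurveTable:
    """Gridded curve values: one row per theta, labelled columns."""

    theta_grid: np.ndarray
    values: pd.DataFrame  # indexed like theta_grid
    kind: str  # ICC_expected / ICC_categories / TCC
    group: str | None = None
    item: int | None = None  # 1-based, for per-item curves

    def __post_init__(self) -> None:
        if np.any(np.diff(self.theta_grid) <= 0):
            raise ValueError("theta grid must be strictly increasing")

    def to_long(self) -> pd.DataFrame:
        """Long format: kind,group,item,theta,value_label,value."""
        df = self.values.copy()
        df.insert(0, "theta", self.theta_grid)
        long = df.melt(id_vars="theta", var_name="value_label", value_name="value")
        long.insert(0, "kind", self.kind)
        long.insert(1, "group", self.group or "")
        long.insert(2, "item", self.item if self.item is not None else "")
        return long


def icc(
    item: GRMItem,
    grid: np.ndarray | None = None,
    group: str | None = None,
    item_number: int | None = None,
) -> CurveTable:
    """Expected-score and category-probability curves for one item."""
    grid = curve_grid() if grid is None else np.asarray(grid, dtype=float)
    probs = category_prob(item, grid)  # (Q, K)
    k = np.arange(item.n_categories)
    values = pd.DataFrame(
        {"expected": probs @ k,
         **{f"P{int(c)}": probs[:, int(c)] for c in k}}
    )
    return CurveTable(
        theta_grid=grid, values=values, kind="ICC", group=group, item=item_number
    )


def tcc(bank: ItemBank, grid: np.ndarray | None = None, group: str | None = None) -> CurveTable:
    """Test characteristic curve: expected total score over the grid."""
    grid = curve_grid() if grid is None else np.asarray(grid, dtype=float)
    probs = bank_category_probs(bank, grid)  # (J, Q, K)
    k = np.arange(bank.n_categories)
    expected = (probs @ k).sum(axis=0)
    values = pd.DataFrame({"expected_total": expected})
    return CurveTable(theta_grid=grid, values=values, kind="TCC", group=group)


def dif_impact(
    bank_ref: ItemBank,
    bank_focal: ItemBank,
    dif_items: list[int],
    grid: np.ndarray | None = None,
    atol: float = 1e-9,
) -> dict:
    """DIF impact on the expected total, all items and DIF items only.

    ``dif_items`` are 1-based indices of the flagged items; every other
    item must carry identical parameters in both banks (the anchors).
    Returns the per-theta TCC difference (focal - reference) over all
    items and restricted to the DIF items, with the maximum absolute
    difference and where it occurs.
    """
    grid = curve_grid() if grid is None else np.asarray(grid, dtype=float)
    if bank_ref.n_items != bank_focal.n_items:
        raise ValueError("banks must have the same number of items")
    for j in range(bank_ref.n_items):
        if (j + 1) in dif_items:
            continue
        r, f = bank_ref.items[j], bank_focal.items[j]
        if abs(r.a - f.a) > atol or np.max(np.abs(np.array(r.b) - np.array(f.b))) > atol:
            raise ValueError(f"anchor item {j + 1} differs between banks")

    k = np.arange(bank_ref.n_categories)
    exp_ref = bank_category_probs(bank_ref, grid) @ k  # (J, Q)
    exp_foc = bank_category_probs(bank_focal, grid) @ k
    delta = exp_foc - exp_ref
    all_diff = delta.sum(axis=0)
    dif_idx = [j - 1 for j in dif_items]
    dif_diff = delta[dif_idx].sum(axis=0) if dif_idx else np.zeros(grid.size)
    i_max = int(np.argmax(np.abs(all_diff)))
    return {
        "theta": grid,
        "delta_tcc_all": all_diff,
        "delta_tcc_dif_items": dif_diff,
        "max_abs_delta": float(np.abs(all_diff)[i_max]),
        "theta_at_max": float(grid[i_max]),
    }
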