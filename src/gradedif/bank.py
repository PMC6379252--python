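"""Item banks and quadrature grids for the graded response model.

An :class:`ItemBank` holds the per-item parameters of Samejima's graded
response model (GRM) in the logistic metric *without* the D = 1.702
scaling constant: the boundary probability of responding in category k
or above is ``1 / (1 + exp(-a * (theta - b_k)))``.  Each item has one
discrimination ``a`` and K-1 strictly ordered thresholds ``b_1 < ... <
b_{K-1}`` on the latent-trait (theta) scale.

The packaged bank :func:`load_bdi2_bank` is the published calibration of
the 21-item Beck Depression Inventory-II (four response categories
scored 0-3) in a large Brazilian college-student sample; it drives the
synthetic-data generator and serves as a reference truth for parameter
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRMItem",
    "ItemBank",
    "QuadratureGrid",
    "default_grid",
    "load_bdi2_bank",
    "read_bank_csv",
    "write_bank_csv",
]


@dataclass(frozen=True)
class GRMItem:
    """One graded-response item: discrimination ``a`` and ordered thresholds ``b``."""

    a: float
    b: tuple[float, ...]
    se_a: float | None = None
    se_b: tuple[float, ...] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"discrimination must be positive, got a={self.a}")
        b = np.asarray(self.b, dtype=float)
        if b.ndim != 1 or b.size < 1:
            raise ValueError("b must be a non-empty 1-d sequence")
        if np.any(np.diff(b) <= 0):
            raise ValueError(f"thresholds must be strictly increasing, got b={self.b}")
        object.__setattr__(self, "b", tuple(float(x) for x in b))
        if self.se_b is not None:
            object.__setattr__(self, "se_b", tuple(float(x) for x in self.se_b))

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


@dataclass
class ItemBank:
    """Ordered collection of GRM items.

    Items normally share one category count K; an item calibrated after
    collapsing an unobserved category may carry fewer.  ``n_categories``
    reports the maximum, and probability arrays are padded with zeros
    for categories an item cannot produce.
    """

    items: list[GRMItem]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("item bank must contain at least one item")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_categories(self) -> int:
        return max(it.n_categories for it in self.items)

    @property
    def max_total(self) -> int:
        """Maximum attainable total score, sum of per-item K - 1."""
        return sum(it.n_categories - 1 for it in self.items)

    def discriminations(self) -> np.ndarray:
        return np.array([it.a for it in self.items])

    def thresholds(self) -> np.ndarray:
        """(J, K-1) threshold matrix, NaN-padded for collapsed items."""
        km1 = self.n_categories - 1
        out = np.full((self.n_items, km1), np.nan)
        for j, it in enumerate(self.items):
            out[j, : len(it.b)] = it.b
        return out

    def labels(self) -> list[str]:
        return [it.label for it in self.items]

    def to_frame(self) -> pd.DataFrame:
        km1 = self.n_categories - 1
        rows = []
        for j, it in enumerate(self.items, start=1):
            row: dict = {"item": j, "label": it.label, "a": it.a, "se_a": it.se_a}
            for k in range(km1):
                row[f"b{k + 1}"] = it.b[k] if k < len(it.b) else None
                row[f"se_b{k + 1}"] = (
                    it.se_b[k] if it.se_b is not None and k < len(it.se_b) else None
                )
            rows.append(row)
        return pd.DataFrame(rows)


def read_bank_csv(path: str | Path) -> ItemBank:
    """Read an item bank from ``item,label,a,se_a,b1,se_b1,...`` CSV."""
    df = pd.read_csv(path)
    return _bank_from_frame(df, metadata={"source": str(path)})


def _bank_from_frame(df: pd.DataFrame, metadata: dict | None = None) -> ItemBank:
    b_cols = sorted(
        (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not b_cols:
        raise ValueError("no threshold columns (b1, b2, ...) found")
    items = []
    for _, row in df.iterrows():
        se_b = None
        if all(f"se_{c}" in df.columns for c in b_cols):
            vals = [row[f"se_{c}"] for c in b_cols]
            if not any(pd.isna(v) for v in vals):
                se_b = tuple(float(v) for v in vals)
        se_a = None if "se_a" not in df.columns or pd.isna(row.get("se_a")) else float(row["se_a"])
        items.append(
            GRMItem(
                a=float(row["a"]),
                b=tuple(float(row[c]) for c in b_cols),
                se_a=se_a,
                se_b=se_b,
                label=str(row.get("label", "")),
            )
        )
    return ItemBank(items=items, metadata=metadata or {})


def write_bank_csv(bank: ItemBank, path: str | Path) -> None:
    bank.to_frame().to_csv(path, index=False)


def load_bdi2_bank() -> ItemBank:
    """Packaged GRM calibration of the 21-item BDI-II (college-student sample)."""
    ref = resources.files("gradedif.data") / "bdi2_college_bank.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    bank = _bank_from_frame(df, metadata={"source": "bdi2_college_bank"})
    bank.metadata["description"] = (
        "GRM parameters of the Brazilian-Portuguese BDI-II calibrated on "
        "12,677 college students; logistic metric (no 1.702 constant)."
    )
    return bank


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed quadrature nodes with weights proportional to the N(0,1) density.

    Weights are renormalized to sum to one, so expectations over the grid
    approximate expectations under a standard-normal latent trait.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.shape != weights.shape or nodes.ndim != 1:
            raise ValueError("nodes and weights must be 1-d arrays of equal length")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        total = weights.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("weights must have positive finite sum")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights / total)

    def __len__(self) -> int:
        return self.nodes.size

    def shifted(self, mu: float, sigma: float = 1.0) -> "QuadratureGrid":
        """Grid representing theta ~ N(mu, sigma^2) via node relocation."""
        return QuadratureGrid(mu + sigma * self.nodes, self.weights.copy())


def default_grid(n_nodes: int = 61, bound: float = 5.0) -> QuadratureGrid:
    """Equally spaced nodes on [-bound, bound] with normal-density weights."""
    if n_nodes < 11:
        raise ValueError("need at least 11 quadrature nodes")
    nodes = np.linspace(-bound, bound, n_nodes)
    weights = np.exp(-0.5 * nodes**2)
    return QuadratureGrid(nodes, weights)
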