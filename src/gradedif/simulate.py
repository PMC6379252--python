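"""Synthetic response-data generator for the graded response model.

Generates BDI-II-like datasets with the statistical structure the
downstream analyses assume: ordinal responses drawn category-wise from
the GRM at each person's latent trait, binary demographic groups
(gender, age group) with configurable composition, group trait-mean
shifts ("impact"), and optionally injected differential item
functioning (DIF) on chosen items.

The study fixture :func:`make_study_fixture` reproduces the design of a
large college-student survey: 12,677 respondents, 44.9% men / 55.1%
women, 85.9% younger (16-30 y) / 14.1% older (31+ y), with group trait
means calibrated so the model-implied expected total scores match the
observed group means (women 7.85, men 5.92, younger 7.17, older 5.83 on
the 0-63 scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bank import GRMItem, ItemBank, QuadratureGrid, default_grid, load_bdi2_bank
from .grm import bank_category_probs, implied_moments

__all__ = [
    "DIFInjection",
    "SimulationSpec",
    "ResponseData",
    "simulate_responses",
    "make_study_fixture",
    "calibrate_group_mean",
    "study_theta_means",
    "save_spec",
    "load_spec",
    "apply_dif",
    "STUDY_N",
    "STUDY_GENDER_FRACTIONS",
    "STUDY_AGE_FRACTIONS",
    "STUDY_GROUP_TOTALS",
]

# Survey composition and observed group mean totals the fixture emulates.
STUDY_N = 12_677
STUDY_GENDER_FRACTIONS = {"M": 0.449, "F": 0.551}
STUDY_AGE_FRACTIONS = {"younger": 0.859, "older": 0.141}
STUDY_GROUP_TOTALS = {"M": 5.92, "F": 7.85, "younger": 7.17, "older": 5.83}


@dataclass(frozen=True)
class DIFInjection:
    """Injected DIF on one item for one focal group.

    ``threshold_shift`` is subtracted from every threshold of the item
    for the focal group (lower thresholds = easier endorsement), giving
    uniform DIF.  ``discrimination_ratio`` multiplies the item's ``a``
    for the focal group, giving non-uniform DIF.  The identity values
    (0, 1) inject nothing.
    """

    item_index: int  # 1-based
    focal_group: str
    threshold_shift: float = 0.0
    discrimination_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.discrimination_ratio <= 0:
            raise ValueError("discrimination_ratio must be positive")
        if self.item_index < 1:
            raise ValueError("item_index is 1-based and must be >= 1")

    @property
    def is_null(self) -> bool:
        return self.threshold_shift == 0.0 and self.discrimination_ratio == 1.0


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic dataset."""

    n_persons: int
    item_bank: ItemBank
    gender_fractions: dict = field(default_factory=lambda: dict(STUDY_GENDER_FRACTIONS))
    age_fractions: dict = field(default_factory=lambda: dict(STUDY_AGE_FRACTIONS))
    theta_means: dict = field(default_factory=dict)  # label -> mean shift contribution
    theta_sd: float = 1.0
    dif_spec: tuple[DIFInjection, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if self.theta_sd <= 0:
            raise ValueError("theta_sd must be positive")
        for name, frac in (("gender", self.gender_fractions), ("age", self.age_fractions)):
            if abs(sum(frac.values()) - 1.0) > 1e-8:
                raise ValueError(f"{name} fractions must sum to 1")
        for inj in self.dif_spec:
            if inj.item_index > self.item_bank.n_items:
                raise ValueError(
                    f"DIF injection on item {inj.item_index} but bank has "
                    f"{self.item_bank.n_items} items"
                )
        object.__setattr__(self, "dif_spec", tuple(self.dif_spec))


@dataclass
class ResponseData:
    """N x J ordinal response matrix with per-person binary group labels.

    ``scores`` is float to allow NaN for missing responses; observed
    entries are integers 0..K-1.
    """

    scores: np.ndarray
    gender: np.ndarray  # 'M' / 'F'
    age_group: np.ndarray  # 'younger' / 'older'
    person_id: np.ndarray | None = None
    theta_true: np.ndarray | None = None  # populated by the simulator

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-d")
        n = self.scores.shape[0]
        if self.person_id is None:
            self.person_id = np.arange(1, n + 1)
        for name in ("gender", "age_group", "person_id"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    def total_scores(self) -> np.ndarray:
        return np.nansum(self.scores, axis=1)

    def group_labels(self, grouping: str) -> np.ndarray:
        if grouping == "gender":
            return self.gender
        if grouping == "age":
            return self.age_group
        raise KeyError(f"unknown grouping {grouping!r}; use 'gender' or 'age'")

    def to_frame(self) -> pd.DataFrame:
        J = self.n_items
        cols = {f"item{j + 1:02d}": self.scores[:, j] for j in range(J)}
        return pd.DataFrame(
            {"person_id": self.person_id, "gender": self.gender,
             "age_group": self.age_group, **cols}
        )


def save_spec(spec: SimulationSpec, path, bank_ref: str = "packaged") -> None:
    """Write a SimulationSpec as a flat ``key = value`` config file.

    ``bank_ref`` names the item-bank source ("packaged" or a CSV path);
    the bank itself is not embedded.
    """
    lines = [
        f"bank = {bank_ref}",
        f"n_persons = {spec.n_persons}",
        f"seed = {spec.seed}",
        f"theta_sd = {spec.theta_sd}",
    ]
    for g, frac in spec.gender_fractions.items():
        lines.append(f"gender_fraction_{g} = {frac}")
    for g, frac in spec.age_fractions.items():
        lines.append(f"age_fraction_{g} = {frac}")
    for label, shift in spec.theta_means.items():
        lines.append(f"theta_mean_{label} = {shift}")
    for i, inj in enumerate(spec.dif_spec, start=1):
        lines.append(f"dif{i}_item = {inj.item_index}")
        lines.append(f"dif{i}_focal = {inj.focal_group}")
        lines.append(f"dif{i}_threshold_shift = {inj.threshold_shift}")
        lines.append(f"dif{i}_discrimination_ratio = {inj.discrimination_ratio}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_spec(path) -> SimulationSpec:
    """Read a SimulationSpec from a flat ``key = value`` config file."""
    from .bank import read_bank_csv

    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    bank_ref = kv.pop("bank", "packaged")
    bank = load_bdi2_bank() if bank_ref == "packaged" else read_bank_csv(bank_ref)
    gender = {k[len("gender_fraction_"):]: float(v) for k, v in kv.items()
              if k.startswith("gender_fraction_")}
    age = {k[len("age_fraction_"):]: float(v) for k, v in kv.items()
           if k.startswith("age_fraction_")}
    means = {k[len("theta_mean_"):]: float(v) for k, v in kv.items()
             if k.startswith("theta_mean_")}
    dif = []
    i = 1
    while f"dif{i}_item" in kv:
        dif.append(
            DIFInjection(
                item_index=int(kv[f"dif{i}_item"]),
                focal_group=kv[f"dif{i}_focal"],
                threshold_shift=float(kv.get(f"dif{i}_threshold_shift", 0.0)),
                discrimination_ratio=float(kv.get(f"dif{i}_discrimination_ratio", 1.0)),
            )
        )
        i += 1
    return SimulationSpec(
        n_persons=int(kv["n_persons"]),
        item_bank=bank,
        gender_fractions=gender or dict(STUDY_GENDER_FRACTIONS),
        age_fractions=age or dict(STUDY_AGE_FRACTIONS),
        theta_means=means,
        theta_sd=float(kv.get("theta_sd", 1.0)),
        dif_spec=tuple(dif),
        seed=int(kv.get("seed", 0)),
    )


def apply_dif(bank: ItemBank, dif_spec, focal_of_grouping: dict | None = None) -> ItemBank:
    """Return the focal-group bank implied by a set of DIF injections.

    Each injection shifts all thresholds of its item down by
    ``threshold_shift`` and scales the discrimination by
    ``discrimination_ratio``.  Items not named keep their parameters
    (they are the anchors).
    """
    items = list(bank.items)
    for inj in dif_spec:
        j = inj.item_index - 1
        it = items[j]
        items[j] = GRMItem(
            a=it.a * inj.discrimination_ratio,
            b=tuple(bk - inj.threshold_shift for bk in it.b),
            label=it.label,
        )
    return ItemBank(items=items, metadata=dict(bank.metadata))


def _draw_groups(rng, n, fractions: dict) -> np.ndarray:
    labels = list(fractions)
    probs = np.array([fractions[g] for g in labels])
    return rng.choice(np.array(labels, dtype=object), size=n, p=probs).astype(str)


def simulate_responses(spec: SimulationSpec) -> ResponseData:
    """Draw an ordinal response matrix from the GRM.

    A single seeded random stream draws, in order: gender labels, age
    labels, per-person latent traits, then item responses left to
    right.  Each person's trait mean is the sum of their group
    contributions in ``theta_means`` (absent labels contribute 0).
    Responses are sampled category-wise from the GRM probabilities at
    the person's trait, using the focal-group bank for persons in a DIF
    injection's focal group.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_persons
    bank = spec.item_bank
    gender = _draw_groups(rng, n, spec.gender_fractions)
    age = _draw_groups(rng, n, spec.age_fractions)

    mu = np.zeros(n)
    for label, shift in spec.theta_means.items():
        mu += np.where((gender == label) | (age == label), shift, 0.0)
    theta = mu + spec.theta_sd * rng.standard_normal(n)

    # One uniform per person-item, drawn before any partitioning so the
    # random stream does not depend on the DIF configuration.
    u = rng.random((n, bank.n_items))

    # Partition persons by which injections apply, so each subset is
    # scored under a single (possibly DIF-shifted) bank.
    applied = np.zeros((n, len(spec.dif_spec)), dtype=bool)
    for i, inj in enumerate(spec.dif_spec):
        applied[:, i] = (gender == inj.focal_group) | (age == inj.focal_group)

    scores = np.empty((n, bank.n_items))
    patterns = sorted({tuple(row) for row in applied}) if spec.dif_spec else [()]
    for pat in patterns:
        if spec.dif_spec:
            mask = np.all(applied == np.array(pat, dtype=bool), axis=1)
            active = [inj for inj, on in zip(spec.dif_spec, pat) if on]
            sub_bank = apply_dif(bank, active) if active else bank
        else:
            mask = np.ones(n, dtype=bool)
            sub_bank = bank
        probs = bank_category_probs(sub_bank, theta[mask])  # (J, n_sub, K)
        cum = np.cumsum(probs, axis=2)
        for j in range(bank.n_items):
            scores[mask, j] = (u[mask, j][:, None] > cum[j, :, :-1]).sum(axis=1)

    return ResponseData(
        scores=scores, gender=gender, age_group=age, theta_true=theta
    )


def calibrate_group_mean(
    bank: ItemBank,
    target_total: float,
    grid: QuadratureGrid | None = None,
    tol: float = 1e-6,
) -> float:
    """Trait mean mu such that E[total | theta ~ N(mu, 1)] = target_total.

    Inverts the population expected total score by monotone root
    finding; the target must lie strictly inside (0, J*(K-1)).
    """
    grid = grid or default_grid()
    if not 0.0 < target_total < bank.max_total:
        raise ValueError(
            f"target_total must be in (0, {bank.max_total}), got {target_total}"
        )

    def expected_total(mu: float) -> float:
        return implied_moments(bank, grid.shifted(mu))["expected_total"]

    lo, hi = -10.0, 10.0
    return brentq(lambda mu: expected_total(mu) - target_total, lo, hi, xtol=tol)


def study_theta_means(bank: ItemBank | None = None) -> dict[str, float]:
    """Per-group trait-mean contributions matching the survey's group totals.

    Gender carries the group location (mu calibrated to each gender's
    mean total); age enters as a deviation from the overall calibrated
    mean, so gender and age contributions add per person.
    """
    bank = bank or load_bdi2_bank()
    mu_overall = calibrate_group_mean(bank, 6.99)
    means = {
        g: calibrate_group_mean(bank, t) for g, t in STUDY_GROUP_TOTALS.items() if g in ("M", "F")
    }
    for g in ("younger", "older"):
        means[g] = calibrate_group_mean(bank, STUDY_GROUP_TOTALS[g]) - mu_overall
    return means


def make_study_fixture(seed: int, dif_spec: tuple = ()) -> ResponseData:
    """Synthetic stand-in for the college-student survey dataset.

    12,677 persons x 21 items from the packaged BDI-II bank, survey
    group composition, and trait means calibrated to the observed group
    mean totals.  Optional DIF injections are passed through to the
    simulator.
    """
    bank = load_bdi2_bank()
    spec = SimulationSpec(
        n_persons=STUDY_N,
        item_bank=bank,
        theta_means=study_theta_means(bank),
        dif_spec=tuple(dif_spec),
        seed=seed,
    )
    return simulate_responses(spec)
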