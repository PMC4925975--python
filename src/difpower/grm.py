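"""Synthetic data generation: graded response model, item banks, latent traits.

The graded response model (GRM) describes the probability that a subject
with latent trait :math:`\\theta` scores in or above category :math:`j` of
item :math:`i` as a two-parameter logistic,

.. math::

    P^*_{ij}(\\theta) = \\frac{e^{a_i(\\theta - b_{ij})}}
                             {1 + e^{a_i(\\theta - b_{ij})}},

with discrimination :math:`a_i` and thresholds :math:`b_{i2} < \\dots <
b_{iJ}`.  Category probabilities are differences of consecutive cumulative
probabilities, with :math:`P^*_{i1} \\equiv 1` and :math:`P^*_{i,J+1}
\\equiv 0`.  A J-category item therefore carries J-1 free thresholds.

Uniform DIF is created by shifting every threshold of one item by a
constant in the focal group; the shift is the same at every trait level,
which is what makes the DIF "uniform".

Latent traits are drawn either from N(0, 1) or from a Beta(alpha, beta)
distribution standardized to mean 0 and variance 1.  Standardization is
affine, so the skewness of the beta shape is preserved while the trait is
placed on the same scale as the N(0, 1) thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.special import expit


class InvalidScenarioError(ValueError):
    """Raised for structurally impossible simulation settings."""


# ---------------------------------------------------------------------------
# Item bank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemBank:
    """GRM parameters for a set of items.

    Parameters
    ----------
    discrimination
        Array of shape ``(n_items,)`` with item slopes :math:`a_i`.
    thresholds
        Array of shape ``(n_items, J - 1)``; each row is strictly
        ascending.
    """

    discrimination: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.discrimination, dtype=float))
        b = np.atleast_2d(np.asarray(self.thresholds, dtype=float))
        if a.ndim != 1 or b.ndim != 2 or a.shape[0] != b.shape[0]:
            raise InvalidScenarioError(
                f"discrimination {a.shape} and thresholds {b.shape} disagree"
            )
        if b.shape[1] < 1:
            raise InvalidScenarioError("need at least one threshold per item")
        if not np.all(np.diff(b, axis=1) > 0) and b.shape[1] > 1:
            raise InvalidScenarioError("thresholds must be strictly ascending")
        object.__setattr__(self, "discrimination", a)
        object.__setattr__(self, "thresholds", b)

    @property
    def n_items(self) -> int:
        return self.discrimination.shape[0]

    @property
    def n_categories(self) -> int:
        return self.thresholds.shape[1] + 1

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the bank as a plain CSV (item, a, b_1..b_{J-1})."""
        cols = {"item": np.arange(1, self.n_items + 1), "a": self.discrimination}
        for j in range(self.n_categories - 1):
            cols[f"b_{j + 1}"] = self.thresholds[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ItemBank":
        df = pd.read_csv(path)
        bcols = sorted(
            (c for c in df.columns if c.startswith("b_")),
            key=lambda c: int(c.split("_")[1]),
        )
        return cls(df["a"].to_numpy(), df[bcols].to_numpy())


def sample_item_parameters(
    n_items: int, n_categories: int, rng: np.random.Generator
) -> ItemBank:
    """Draw a random item bank.

    Discriminations are i.i.d. Uniform(0.5, 1.5).  For each item, J-1
    independent N(0, 1) draws sorted ascending form the thresholds; sorting
    is the minimal way to enforce the ordering the GRM requires while
    keeping the marginal distribution of the threshold set standard normal.
    """
    if n_categories < 2:
        raise InvalidScenarioError(f"n_categories must be >= 2, got {n_categories}")
    if n_items < 1:
        raise InvalidScenarioError(f"n_items must be >= 1, got {n_items}")
    a = rng.uniform(0.5, 1.5, size=n_items)
    b = np.sort(rng.standard_normal((n_items, n_categories - 1)), axis=1)
    return ItemBank(a, b)


def inject_uniform_dif(bank: ItemBank, item: int, delta: float) -> ItemBank:
    """Return a focal-group bank with every threshold of ``item`` shifted by ``delta``.

    A uniform shift preserves the threshold ordering; all other items and
    all discriminations are unchanged.  ``delta > 0`` makes the item harder
    for the focal group (mass moves to lower categories).
    """
    if not 0 <= item < bank.n_items:
        raise IndexError(f"item {item} out of range for {bank.n_items} items")
    b = bank.thresholds.copy()
    b[item] = b[item] + delta
    return ItemBank(bank.discrimination.copy(), b)


# ---------------------------------------------------------------------------
# Latent trait distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitDistribution:
    """Latent-trait distribution: N(0,1) or a standardized Beta(alpha, beta).

    A standardized beta variate is ``(x - mu) / sigma`` with ``mu =
    alpha/(alpha+beta)`` and ``sigma^2 = alpha*beta / ((alpha+beta)^2 *
    (alpha+beta+1))``, so it has mean 0 and variance 1 but keeps the
    skewness of the beta shape.
    """

    kind: str  # "normal" | "beta"
    alpha: float = math.nan
    beta: float = math.nan

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "beta"):
            raise InvalidScenarioError(f"unknown trait distribution kind {self.kind!r}")
        if self.kind == "beta" and not (self.alpha > 0 and self.beta > 0):
            raise InvalidScenarioError("beta parameters must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "normal":
            return rng.standard_normal(n)
        a, b = self.alpha, self.beta
        mu = a / (a + b)
        sigma = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        return (rng.beta(a, b, size=n) - mu) / sigma

    @property
    def skewness(self) -> float:
        """Population skewness (invariant under standardization)."""
        if self.kind == "normal":
            return 0.0
        a, b = self.alpha, self.beta
        return 2 * (b - a) * math.sqrt(a + b + 1) / ((a + b + 2) * math.sqrt(a * b))

    def __str__(self) -> str:
        if self.kind == "normal":
            return "N(0,1)"
        return f"stdBeta({self.alpha:g},{self.beta:g})"


@dataclass(frozen=True)
class TraitCondition:
    """A (reference, focal) pair of latent-trait distributions."""

    condition_id: int
    reference_dist: TraitDistribution
    focal_dist: TraitDistribution


def _normal() -> TraitDistribution:
    return TraitDistribution("normal")


def _beta(a: float, b: float) -> TraitDistribution:
    return TraitDistribution("beta", a, b)


#: The nine study conditions.  Conditions 1-3 use identical distributions in
#: both groups (normal, moderately skewed, highly skewed); 4-7 pair a normal
#: reference with increasingly skewed focal groups; 8 and 9 skew the two
#: groups in opposite directions (moderately and highly).
TRAIT_CONDITIONS: dict[int, TraitCondition] = {
    1: TraitCondition(1, _normal(), _normal()),
    2: TraitCondition(2, _beta(1, 4), _beta(1, 4)),
    3: TraitCondition(3, _beta(0.5, 4), _beta(0.5, 4)),
    4: TraitCondition(4, _normal(), _beta(4, 1)),
    5: TraitCondition(5, _normal(), _beta(1, 4)),
    6: TraitCondition(6, _normal(), _beta(4, 0.5)),
    7: TraitCondition(7, _normal(), _beta(0.5, 4)),
    8: TraitCondition(8, _beta(4, 1), _beta(1, 4)),
    9: TraitCondition(9, _beta(4, 0.5), _beta(0.5, 4)),
}


def sample_latent_traits(
    condition: Union[TraitCondition, int],
    n_ref: int,
    n_focal: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw latent traits for the reference and focal groups."""
    if isinstance(condition, int):
        try:
            condition = TRAIT_CONDITIONS[condition]
        except KeyError:
            raise InvalidScenarioError(
                f"unknown trait condition {condition}; valid ids are 1..9"
            ) from None
    if n_ref < 1 or n_focal < 1:
        raise InvalidScenarioError("both groups need at least one subject")
    return (
        condition.reference_dist.sample(n_ref, rng),
        condition.focal_dist.sample(n_focal, rng),
    )


# ---------------------------------------------------------------------------
# Response generation
# ---------------------------------------------------------------------------


def grm_category_probabilities(
    theta: Union[float, np.ndarray], a: float, thresholds: np.ndarray
) -> np.ndarray:
    """Category probabilities of a GRM item at trait level(s) ``theta``.

    Returns an array of shape ``(J,)`` for scalar ``theta`` or
    ``theta.shape + (J,)`` otherwise.  The vector is nonnegative and sums
    to 1: it is a telescoping difference of the cumulative probabilities,
    which decrease in the category index and are bounded by 1 and 0.
    """
    b = np.asarray(thresholds, dtype=float)
    if b.ndim != 1 or (b.size > 1 and not np.all(np.diff(b) > 0)):
        raise InvalidScenarioError("thresholds must be a strictly ascending vector")
    th = np.asarray(theta, dtype=float)
    # cumulative P(Y >= j+1) for j = 1..J-1, padded with 1 and 0
    cum = expit(a * (th[..., None] - b))
    ones = np.ones(th.shape + (1,))
    zeros = np.zeros(th.shape + (1,))
    star = np.concatenate([ones, cum, zeros], axis=-1)
    return star[..., :-1] - star[..., 1:]


@dataclass(frozen=True)
class ResponseData:
    """Ordinal responses for one simulated sample.

    ``responses`` holds codes 1..J, ``group`` is 0 for the reference and 1
    for the focal group, and ``total_score`` is the per-subject sum over
    all items — the observed proxy for the latent trait used as the
    matching variable in the regression models.
    """

    responses: np.ndarray  # (n_subjects, n_items), int, 1..J
    group: np.ndarray  # (n_subjects,), 0/1
    total_score: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        r = np.asarray(self.responses)
        g = np.asarray(self.group)
        if r.shape[0] != g.shape[0]:
            raise InvalidScenarioError("responses and group lengths disagree")
        object.__setattr__(self, "responses", r)
        object.__setattr__(self, "group", g)
        if self.total_score is None:
            object.__setattr__(self, "total_score", r.sum(axis=1))

    @property
    def n_subjects(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def to_csv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame(
            self.responses,
            columns=[f"item_{i + 1}" for i in range(self.n_items)],
        )
        df.insert(0, "group", self.group)
        df["total_score"] = self.total_score
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ResponseData":
        df = pd.read_csv(path)
        items = [c for c in df.columns if c.startswith("item_")]
        return cls(df[items].to_numpy(), df["group"].to_numpy())


def _draw_responses(
    theta: np.ndarray, bank: ItemBank, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized categorical draws: one uniform per (subject, item).

    With cumulative probabilities C_j = P(Y >= j+1) decreasing in j, the
    response 1 + sum_j 1{u < C_j} has exactly the GRM category
    distribution.
    """
    # (n, items, J-1)
    cum = expit(
        bank.discrimination[None, :, None]
        * (theta[:, None, None] - bank.thresholds[None, :, :])
    )
    u = rng.random((theta.shape[0], bank.n_items, 1))
    return 1 + (u < cum).sum(axis=2)


def generate_responses(
    theta_ref: np.ndarray,
    theta_focal: np.ndarray,
    reference_bank: ItemBank,
    focal_bank: ItemBank,
    rng: np.random.Generator,
) -> ResponseData:
    """Generate GRM responses for both groups.

    Reference subjects respond according to ``reference_bank`` and focal
    subjects according to ``focal_bank`` (which may carry a DIF shift on
    one item); the two banks must describe the same instrument.
    """
    if (
        reference_bank.n_items != focal_bank.n_items
        or reference_bank.n_categories != focal_bank.n_categories
    ):
        raise InvalidScenarioError("reference and focal banks disagree on shape")
    resp_ref = _draw_responses(np.asarray(theta_ref, dtype=float), reference_bank, rng)
    resp_foc = _draw_responses(np.asarray(theta_focal, dtype=float), focal_bank, rng)
    responses = np.vstack([resp_ref, resp_foc])
    group = np.concatenate(
        [np.zeros(len(resp_ref), dtype=int), np.ones(len(resp_foc), dtype=int)]
    )
    return ResponseData(responses, group)
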