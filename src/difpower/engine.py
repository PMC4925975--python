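"""Scenario grid driver: Monte-Carlo power and type-I error estimation.

A scenario is one cell of the study grid: number of response categories J
in {3, 4, 5}, total sample size N in {600, 1000}, reference:focal ratio R
in {1, 2, 3}, signed uniform-DIF magnitude, and one of nine latent-trait
distribution conditions.  The full grid has 3 x 2 x 3 x 2 x 9 = 324
cells; each cell is replicated (1000 times in the reference study) and
summarized by the rejection rate of the uniform-DIF likelihood-ratio test
for the DIF item (power) and, pooled over the nine DIF-free items, for
the null items (type-I error).

Reproducibility: every replication draws from a child random stream keyed
by (master seed, scenario, replication index), so the whole grid is a
pure function of the configuration and the master seed, and cells or
replications can be recomputed independently and in any order.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .dif import classify_replication, test_item_dif
from .grm import (
    InvalidScenarioError,
    ItemBank,
    TRAIT_CONDITIONS,
    TraitCondition,
    generate_responses,
    inject_uniform_dif,
    sample_item_parameters,
    sample_latent_traits,
)
from .olr import DegenerateDataError

logger = logging.getLogger(__name__)

#: (N, R) -> (n_reference, n_focal)
GROUP_SIZES: dict[tuple[int, int], tuple[int, int]] = {
    (600, 1): (300, 300),
    (600, 2): (400, 200),
    (600, 3): (450, 150),
    (1000, 1): (500, 500),
    (1000, 2): (667, 333),
    (1000, 3): (750, 250),
}

N_ITEMS = 10


class ConfigError(ValueError):
    """Raised for malformed grid configurations."""


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid."""

    n_categories: int
    total_n: int
    ratio: int
    dif_magnitude: float
    condition: TraitCondition
    dif_item: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if (self.total_n, self.ratio) not in GROUP_SIZES:
            raise InvalidScenarioError(
                f"unsupported (N, R) = ({self.total_n}, {self.ratio})"
            )
        if self.n_categories < 2:
            raise InvalidScenarioError("n_categories must be >= 2")
        if not 0 <= self.dif_item < N_ITEMS:
            raise InvalidScenarioError(f"dif_item {self.dif_item} out of range")
        if isinstance(self.condition, int):
            object.__setattr__(self, "condition", TRAIT_CONDITIONS[self.condition])

    @property
    def group_sizes(self) -> tuple[int, int]:
        return GROUP_SIZES[(self.total_n, self.ratio)]

    def _seed_key(self) -> tuple[int, ...]:
        # nonnegative integers identifying the cell for child-stream spawning
        return (
            self.n_categories,
            self.total_n,
            self.ratio,
            int(round(self.dif_magnitude * 10)) + 1000,
            self.condition.condition_id,
        )


@dataclass(frozen=True)
class ReplicationOutcome:
    """Result of one replication; ``dif_detected`` is None if the DIF-item
    test was invalid (a convergence failure) and the replication should be
    excluded from the power denominator."""

    dif_detected: Optional[bool]
    false_positives: int
    n_valid_null_items: int


@dataclass(frozen=True)
class ScenarioSummary:
    """Monte-Carlo summary of one scenario."""

    scenario: Scenario
    n_reps: int
    power: float
    power_mc_se: float
    type1: float
    type1_mc_se: float
    n_convergence_failures: int


def _item_bank_for(
    scenario: Scenario, master_seed: int, rep: Optional[int] = None
) -> ItemBank:
    """Draw the reference item bank for a scenario.

    With ``rep=None`` (lifetime "fixed") the bank depends only on the
    master seed and J, so every cell sharing a category count reuses the
    same instrument.  With a replication index (lifetime
    "per_replication") a fresh bank is drawn for each replication, which
    marginalizes the power estimate over the item-parameter distribution.
    """
    key: tuple[int, ...] = (master_seed, 7001, scenario.n_categories)
    if rep is not None:
        key = key + scenario._seed_key() + (rep,)
    rng = np.random.default_rng(np.random.SeedSequence(key))
    return sample_item_parameters(N_ITEMS, scenario.n_categories, rng)


def run_replication(
    scenario: Scenario,
    reference_bank: ItemBank,
    rng: np.random.Generator,
    items: str = "all",
    matching: str = "total",
) -> ReplicationOutcome:
    """Simulate one dataset and test it.

    Draws latent traits, builds the focal bank by shifting the DIF item's
    thresholds, generates responses, and runs the likelihood-ratio DIF
    test.  ``items="all"`` tests all 10 items (needed for type-I error);
    ``items="dif_only"`` tests only the DIF item, which leaves the power
    estimate untouched while skipping nine-tenths of the model fits.
    """
    n_ref, n_focal = scenario.group_sizes
    theta_ref, theta_focal = sample_latent_traits(
        scenario.condition, n_ref, n_focal, rng
    )
    focal_bank = inject_uniform_dif(
        reference_bank, scenario.dif_item, scenario.dif_magnitude
    )
    data = generate_responses(theta_ref, theta_focal, reference_bank, focal_bank, rng)

    if items == "dif_only":
        test_set = [scenario.dif_item]
    elif items == "all":
        test_set = list(range(data.n_items))
    else:
        raise ConfigError(f"unknown items mode {items!r}")

    results = []
    for i in test_set:
        results.append(test_item_dif(i, data, matching=matching))
    dif_res = next(r for r in results if r.item == scenario.dif_item)
    detected, fp, n_valid = classify_replication(
        results, scenario.dif_item, scenario.alpha
    )
    return ReplicationOutcome(
        dif_detected=detected if dif_res.valid else None,
        false_positives=fp,
        n_valid_null_items=n_valid,
    )


def run_scenario(
    scenario: Scenario,
    n_reps: int,
    master_seed: int,
    bank: Optional[ItemBank] = None,
    bank_lifetime: str = "per_replication",
    items: str = "all",
    matching: str = "total",
) -> ScenarioSummary:
    """Estimate power and type-I error for one scenario.

    Power is the fraction of replications in which the DIF item is
    rejected at ``scenario.alpha``; type-I error pools rejections of the
    nine DIF-free items over all replications.  Monte-Carlo standard
    errors are ``sqrt(p(1-p)/n)`` on the respective denominators.

    Each replication that raises a degenerate-data condition (e.g. an
    item with a single observed category in a highly skewed cell) is
    redrawn once from a follow-up stream and dropped if it degenerates
    again; drops and invalid fits are counted in
    ``n_convergence_failures``.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    if bank_lifetime not in ("fixed", "per_replication"):
        raise ConfigError(f"unknown bank_lifetime {bank_lifetime!r}")
    key = scenario._seed_key()
    fixed_bank = bank
    if fixed_bank is None and bank_lifetime == "fixed":
        fixed_bank = _item_bank_for(scenario, master_seed)

    n_detect = 0
    n_power_denom = 0
    n_fp = 0
    n_null_denom = 0
    n_failures = 0
    for rep in range(n_reps):
        outcome = None
        for attempt in range(2):
            rng = np.random.default_rng(
                np.random.SeedSequence((master_seed,) + key + (rep, attempt))
            )
            rbank = (
                fixed_bank
                if fixed_bank is not None
                else _item_bank_for(scenario, master_seed, rep)
            )
            try:
                outcome = run_replication(
                    scenario, rbank, rng, items=items, matching=matching
                )
                break
            except DegenerateDataError as exc:
                logger.debug("replication %d attempt %d degenerate: %s", rep, attempt, exc)
        if outcome is None:
            n_failures += 1
            continue
        if outcome.dif_detected is None:
            n_failures += 1
        else:
            n_power_denom += 1
            n_detect += int(outcome.dif_detected)
        n_fp += outcome.false_positives
        n_null_denom += outcome.n_valid_null_items

    if n_power_denom == 0:
        raise RuntimeError("all replications failed; no valid DIF-item tests")
    power = n_detect / n_power_denom
    type1 = n_fp / n_null_denom if n_null_denom else float("nan")
    return ScenarioSummary(
        scenario=scenario,
        n_reps=n_power_denom,
        power=power,
        power_mc_se=math.sqrt(power * (1 - power) / n_power_denom),
        type1=type1,
        type1_mc_se=(
            math.sqrt(type1 * (1 - type1) / n_null_denom) if n_null_denom else float("nan")
        ),
        n_convergence_failures=n_failures,
    )


# ---------------------------------------------------------------------------
# Grid configuration and execution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridConfig:
    """Declarative description of a (sub-)grid of scenarios."""

    categories: tuple[int, ...] = (3, 4, 5)
    sample_sizes: tuple[int, ...] = (600, 1000)
    ratios: tuple[int, ...] = (1, 2, 3)
    dif_magnitudes: tuple[float, ...] = (0.5, 1.0)
    conditions: tuple[int, ...] = tuple(range(1, 10))
    n_reps: int = 1000
    seed: int = 0
    alpha: float = 0.05
    dif_item: int = 0
    matching: str = "total"
    bank_lifetime: str = "per_replication"
    items: str = "all"

    _KEYS = (
        "categories sample_sizes ratios dif_magnitudes conditions "
        "n_reps seed alpha dif_item matching bank_lifetime items"
    ).split()

    @classmethod
    def from_dict(cls, d: dict) -> "GridConfig":
        unknown = set(d) - set(cls._KEYS)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(d)
        for k in ("categories", "sample_sizes", "ratios", "dif_magnitudes", "conditions"):
            if k in kwargs:
                v = kwargs[k]
                kwargs[k] = tuple(v) if isinstance(v, (list, tuple)) else (v,)
        try:
            cfg = cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        for c in cfg.conditions:
            if c not in TRAIT_CONDITIONS:
                raise ConfigError(f"unknown condition id {c}")
        return cfg

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "GridConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(d)

    def scenarios(self) -> list[Scenario]:
        """Cells ordered (condition, ratio, J) within (N, DIF) to mirror the
        published table layout."""
        out = []
        for n in self.sample_sizes:
            for dif in self.dif_magnitudes:
                for cond in self.conditions:
                    for r in self.ratios:
                        for j in self.categories:
                            out.append(
                                Scenario(
                                    n_categories=j,
                                    total_n=n,
                                    ratio=r,
                                    dif_magnitude=dif,
                                    condition=TRAIT_CONDITIONS[cond],
                                    dif_item=self.dif_item,
                                    alpha=self.alpha,
                                )
                            )
        return out


def run_grid(
    config: GridConfig, progress: bool = False
) -> pd.DataFrame:
    """Run every cell of the grid and return a long-format table.

    One row per scenario with the estimated power, pooled type-I error,
    Monte-Carlo standard errors and failure counts.  The output is a pure
    function of (config, seed).
    """
    rows = []
    cells = config.scenarios()
    for i, sc in enumerate(cells):
        summ = run_scenario(
            sc,
            config.n_reps,
            config.seed,
            bank_lifetime=config.bank_lifetime,
            items=config.items,
            matching=config.matching,
        )
        rows.append(_summary_row(summ))
        if progress:
            logger.info(
                "cell %d/%d J=%d N=%d R=%d DIF=%+.1f cond=%d: power=%.3f type1=%s",
                i + 1, len(cells), sc.n_categories, sc.total_n, sc.ratio,
                sc.dif_magnitude, sc.condition.condition_id, summ.power,
                f"{summ.type1:.3f}" if not math.isnan(summ.type1) else "n/a",
            )
    return pd.DataFrame(rows)


def _summary_row(s: ScenarioSummary) -> dict:
    sc = s.scenario
    return {
        "condition": sc.condition.condition_id,
        "ratio": sc.ratio,
        "n_categories": sc.n_categories,
        "total_n": sc.total_n,
        "dif_magnitude": sc.dif_magnitude,
        "alpha": sc.alpha,
        "n_reps": s.n_reps,
        "power": s.power,
        "power_mc_se": s.power_mc_se,
        "type1": s.type1,
        "type1_mc_se": s.type1_mc_se,
        "n_convergence_failures": s.n_convergence_failures,
    }


def format_results_table(
    summaries: Union[pd.DataFrame, list[ScenarioSummary]],
    sample_size: int,
    metric: str = "power",
) -> pd.DataFrame:
    """Pivot a long-format result table into the published wide layout.

    One row per (condition, ratio); one column per (DIF magnitude, J),
    rounded half-even to 2 decimals.  Missing cells of a ragged sub-grid
    appear as NaN rather than being silently dropped.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = pd.DataFrame([_summary_row(s) for s in summaries])
    if metric not in ("power", "type1"):
        raise ConfigError(f"unknown metric {metric!r}")
    df = summaries[summaries["total_n"] == sample_size]
    if df.empty:
        raise ConfigError(f"no results for N={sample_size}")
    wide = df.pivot_table(
        index=["condition", "ratio"],
        columns=["dif_magnitude", "n_categories"],
        values=metric,
    )
    wide.columns = [f"DIF={d:g} J={j}" for d, j in wide.columns]
    return wide.round(2)


def write_run_outputs(
    results: pd.DataFrame, config: GridConfig, out_dir: Union[str, Path]
) -> None:
    """Write long CSV, wide per-(N, metric) CSVs, and a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "results_long.csv", index=False)
    for n in sorted(results["total_n"].unique()):
        for metric in ("power", "type1"):
            format_results_table(results, n, metric).to_csv(
                out / f"{metric}_N{n}.csv"
            )
    manifest = {
        "seed": config.seed,
        "n_reps": config.n_reps,
        "n_cells": int(len(results)),
        "config": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in vars(config).items()  # dataclass fields only
            if not k.startswith("_")
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
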