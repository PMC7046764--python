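"""Monte Carlo propagation of parameter uncertainty.

Parameters get independent distributions — normal with an absolute SD,
normal with a relative SD (the convention used for measured NEE: 5% of
the value), or lognormal with a geometric SD obtained from pedigree-style
data-quality scores — and are drawn ``n_iterations`` times through an
arbitrary model callable. Results are summarized as mean, median and
the 25th/75th percentiles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Distribution",
    "normal",
    "normal_rel",
    "lognormal",
    "UncertaintySpec",
    "PedigreeScores",
    "pedigree_factor",
    "run_mc",
    "MCSummary",
]

PEDIGREE_INDICATORS = (
    "reliability",
    "completeness",
    "temporal",
    "geographical",
    "technological",
    "sample_size",
)


@dataclass(frozen=True)
class Distribution:
    """One parameter's sampling rule around its central value."""

    kind: str  # normal | normal_rel | lognormal
    scale: float  # sd, sd fraction, or geometric sd

    def sample(self, center: float, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "normal":
            return rng.normal(center, self.scale, size)
        if self.kind == "normal_rel":
            return rng.normal(center, abs(center) * self.scale, size)
        if self.kind == "lognormal":
            if center <= 0:
                raise ValueError("lognormal requires a positive central value")
            if self.scale < 1.0:
                raise ValueError("geometric sd must be >= 1")
            return center * rng.lognormal(0.0, math.log(self.scale), size)
        raise ValueError(f"unknown distribution kind {self.kind!r}")


def normal(sd: float) -> Distribution:
    return Distribution("normal", sd)


def normal_rel(sd_fraction: float) -> Distribution:
    return Distribution("normal_rel", sd_fraction)


def lognormal(gsd: float) -> Distribution:
    return Distribution("lognormal", gsd)


@dataclass(frozen=True)
class UncertaintySpec:
    """Which parameters vary, how, and how the ensemble is summarized."""

    distributions: Mapping[str, Distribution]
    n_iterations: int = 1000
    seed: int = 0
    report_percentiles: tuple = (25.0, 75.0)
    max_failure_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        lo, hi = self.report_percentiles
        if not (0.0 < lo < hi < 100.0):
            raise ValueError("percentiles must be ordered and inside (0, 100)")


@dataclass(frozen=True)
class PedigreeScores:
    """Six ordinal data-quality scores, each 1 (best) to 5 (worst)."""

    reliability: int = 1
    completeness: int = 1
    temporal: int = 1
    geographical: int = 1
    technological: int = 1
    sample_size: int = 1

    def __post_init__(self) -> None:
        for name in PEDIGREE_INDICATORS:
            s = getattr(self, name)
            if not 1 <= s <= 5:
                raise ValueError(f"{name} score must be in 1..5, got {s}")


def _load_pedigree_table() -> dict[str, list[float]]:
    text = resources.files("palmghg.data").joinpath("pedigree_factors.json").read_text()
    table = json.loads(text)
    return {k: v for k, v in table.items() if not k.startswith("_")}


def pedigree_factor(scores: PedigreeScores) -> float:
    """Combined geometric standard deviation from pedigree scores.

    Each indicator score maps to a lognormal uncertainty factor f_i via
    the shipped lookup table; the combined multiplier is
    ``exp(sqrt(sum(ln f_i ^ 2)))`` — 1.0 when every score is 1.
    """
    table = _load_pedigree_table()
    ssq = 0.0
    for name in PEDIGREE_INDICATORS:
        f = table[name][getattr(scores, name) - 1]
        ssq += math.log(f) ** 2
    return math.exp(math.sqrt(ssq))


@dataclass(frozen=True)
class MCSummary:
    """Percentile summary of a Monte Carlo ensemble, one row per output."""

    table: pd.DataFrame
    n_evaluated: int
    n_failed: int

    def row(self, output: str) -> pd.Series:
        return self.table.loc[output]


def run_mc(
    model: Callable[[Mapping[str, float]], Mapping[str, float] | float],
    center: Mapping[str, float],
    uspec: UncertaintySpec,
) -> MCSummary:
    """Propagate parameter draws through ``model``.

    ``model`` receives a full parameter dict (center values overridden
    by the current draw for every parameter with a distribution) and
    returns a number or a dict of named outputs. Draw failures are
    recorded and excluded; more than ``max_failure_fraction`` failures
    aborts.
    """
    rng = np.random.default_rng(uspec.seed)
    n = uspec.n_iterations
    draws = {
        name: dist.sample(float(center[name]), rng, n)
        for name, dist in uspec.distributions.items()
    }

    results: dict[str, list[float]] = {}
    n_failed = 0
    for i in range(n):
        params = dict(center)
        for name, values in draws.items():
            params[name] = float(values[i])
        try:
            out = model(params)
        except Exception:
            n_failed += 1
            continue
        if not isinstance(out, Mapping):
            out = {"value": float(out)}
        for key, val in out.items():
            results.setdefault(key, []).append(float(val))

    if n_failed > uspec.max_failure_fraction * n:
        raise RuntimeError(
            f"{n_failed}/{n} model evaluations failed "
            f"(> {uspec.max_failure_fraction:.0%} allowed)"
        )

    lo, hi = uspec.report_percentiles
    rows = {}
    for key, vals in results.items():
        arr = np.asarray(vals)
        rows[key] = {
            "mean": arr.mean(),
            "median": float(np.median(arr)),
            f"p{lo:g}": float(np.percentile(arr, lo)),
            f"p{hi:g}": float(np.percentile(arr, hi)),
            "sd": arr.std(ddof=1) if len(arr) > 1 else 0.0,
        }
    table = pd.DataFrame(rows).T
    return MCSummary(table=table, n_evaluated=n - n_failed, n_failed=n_failed)
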