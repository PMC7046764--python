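"""Year-indexed life-cycle trajectories for plantation management scenarios.

A plantation rotation cycle is described by per-age annual values of
NEE, fresh-fruit-bunch (FFB) yield, fertilizer and herbicide inputs.
Management follows a common ramp rule: constant "young" level during an
establishment plateau (first 3 years), linear increase to the "mature"
level by year 8, constant thereafter. Yield ramps from zero in the year
before first production to the maximum at the maturity year.

Scenarios:

=========  ===========  ====================================
name       cycle (yr)   change vs business-as-usual
=========  ===========  ====================================
BAU        25           none (Indonesian standard rotation)
A          30           longer rotation
B          40           longer rotation
C          30           earlier-yielding variety (first
                        fruit at age 3, max yield at age 6)
=========  ===========  ====================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AnnualTrajectory",
    "ScenarioSpec",
    "scenario",
    "SCENARIOS",
    "ramp_trajectory",
    "yield_trajectory",
    "nee_trajectory",
    "input_trajectories",
    "running_mean_and_cumulative",
]

#: default per-substance (young, mature) application levels
#: N/K/P in kg ha-1 yr-1, glyphosate in ml ha-1 yr-1
DEFAULT_INPUT_LEVELS = {
    "N": (88.0, 196.0),
    "K": (73.0, 220.0),
    "P": (38.0, 50.0),
    "glyphosate": (0.0, 2250.0),
}

INPUT_UNITS = {
    "N": "kg ha-1 yr-1",
    "K": "kg ha-1 yr-1",
    "P": "kg ha-1 yr-1",
    "glyphosate": "ml ha-1 yr-1",
}


@dataclass(frozen=True)
class AnnualTrajectory:
    """Ordered annual values for plantation ages 1..cycle_length."""

    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).reshape(-1)
        )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(1, len(self.values) + 1)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class ScenarioSpec:
    """Management scenario for one rotation cycle.

    ``nee_young``/``nee_mature`` are annual NEE levels (gC m-2 yr-1,
    positive = source) for the establishment plateau and mature phase;
    ``max_yield`` is the plateau FFB yield in Mg ha-1 yr-1.
    """

    name: str
    cycle_length: int = 25
    yield_start_year: int = 4
    yield_max_year: int = 8
    rotation: str = "first"
    nee_young: float = 1012.0
    nee_mature: float = -754.0
    max_yield: float = 26.5
    ramp_plateau_end: int = 3
    ramp_mature_year: int = 8
    input_levels: dict = field(default_factory=lambda: dict(DEFAULT_INPUT_LEVELS))

    def __post_init__(self) -> None:
        if not self.yield_start_year < self.yield_max_year <= self.cycle_length:
            raise ValueError(
                "need yield_start_year < yield_max_year <= cycle_length"
            )
        if self.rotation not in ("first", "second"):
            raise ValueError("rotation must be 'first' or 'second'")


SCENARIOS = {
    "BAU": ScenarioSpec(name="BAU", cycle_length=25),
    "A": ScenarioSpec(name="A", cycle_length=30),
    "B": ScenarioSpec(name="B", cycle_length=40),
    "C": ScenarioSpec(name="C", cycle_length=30, yield_start_year=3, yield_max_year=6),
}


def scenario(name: str, rotation: str = "first") -> ScenarioSpec:
    """Look up a named scenario, optionally switched to second rotation."""
    try:
        spec = SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        ) from None
    return replace(spec, rotation=rotation)


def ramp_trajectory(
    young_value: float,
    mature_value: float,
    plateau_end: int,
    mature_year: int,
    cycle_length: int,
    unit: str = "",
) -> AnnualTrajectory:
    """Plateau-ramp-plateau annual trajectory.

    ``value(y) = young`` for ``y <= plateau_end``; linear interpolation
    up to ``mature`` at ``mature_year``; ``mature`` for all later ages.
    This piecewise-linear reading reproduces the conventional life-cycle
    mean input rates exactly (e.g. N 88->196 over a 25-yr cycle averages
    174.4 kg ha-1 yr-1).
    """
    if not (0 < plateau_end < mature_year <= cycle_length):
        raise ValueError("need 0 < plateau_end < mature_year <= cycle_length")
    ages = np.arange(1, cycle_length + 1, dtype=float)
    frac = np.clip((ages - plateau_end) / (mature_year - plateau_end), 0.0, 1.0)
    values = young_value + (mature_value - young_value) * frac
    return AnnualTrajectory(values=values, unit=unit)


def yield_trajectory(spec: ScenarioSpec) -> AnnualTrajectory:
    """Annual FFB yield over the cycle, Mg ha-1 yr-1.

    Zero before ``yield_start_year``, then linear from zero (anchored in
    the year before first production) to ``max_yield`` at
    ``yield_max_year``, constant afterwards.
    """
    ages = np.arange(1, spec.cycle_length + 1, dtype=float)
    anchor = spec.yield_start_year - 1
    frac = np.clip((ages - anchor) / (spec.yield_max_year - anchor), 0.0, 1.0)
    return AnnualTrajectory(values=spec.max_yield * frac, unit="Mg ha-1 yr-1")


def nee_trajectory(
    spec: ScenarioSpec,
    decay_curve=None,
    sr_anchor_flux: float = 133.9,
    sr_anchor_age: float = 1.0,
    second_rotation_start: float | None = None,
) -> AnnualTrajectory:
    """Annual NEE over the cycle, gC m-2 yr-1 (positive = source).

    First rotation: the plateau-ramp-plateau rule between the young
    (source) and mature (sink) NEE levels. Second rotation: the
    first-rotation trajectory corrected per-age by substituting the
    first-rotation soil respiration with the (near-equilibrium)
    second-rotation one from the calibrated decay curve; this requires
    ``decay_curve`` and the hourly soil-respiration anchor.
    """
    first = ramp_trajectory(
        spec.nee_young,
        spec.nee_mature,
        spec.ramp_plateau_end,
        spec.ramp_mature_year,
        spec.cycle_length,
        unit="gC m-2 yr-1",
    )
    if spec.rotation == "first":
        return first
    if decay_curve is None:
        raise ValueError("second-rotation NEE requires a calibrated decay curve")
    from .decay import HOURLY_TO_ANNUAL_SR, respiration_from_anchor
    from .fluxes import nee_second_rotation

    if second_rotation_start is None:
        second_rotation_start = float(spec.cycle_length)
    ages = np.arange(1, spec.cycle_length + 1, dtype=float)
    sr_first = (
        np.asarray(
            respiration_from_anchor(decay_curve, sr_anchor_flux, sr_anchor_age, ages)
        )
        * HOURLY_TO_ANNUAL_SR
    )
    sr_second = (
        np.asarray(
            respiration_from_anchor(
                decay_curve, sr_anchor_flux, sr_anchor_age, second_rotation_start + ages
            )
        )
        * HOURLY_TO_ANNUAL_SR
    )
    values = [
        nee_second_rotation(n, s1, s2)
        for n, s1, s2 in zip(first.values, sr_first, sr_second)
    ]
    return AnnualTrajectory(values=np.array(values), unit="gC m-2 yr-1")


def input_trajectories(spec: ScenarioSpec) -> dict[str, AnnualTrajectory]:
    """Fertilizer and herbicide trajectories for every configured substance."""
    return {
        name: ramp_trajectory(
            young,
            mature,
            spec.ramp_plateau_end,
            spec.ramp_mature_year,
            spec.cycle_length,
            unit=INPUT_UNITS.get(name, ""),
        )
        for name, (young, mature) in spec.input_levels.items()
    }


def running_mean_and_cumulative(
    traj: AnnualTrajectory,
) -> tuple[AnnualTrajectory, AnnualTrajectory]:
    """Running annual mean and cumulative sum along the cycle.

    The running mean at age y is the mean of all years up to and
    including y; the cumulative value is their sum.
    """
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    csum = np.cumsum(traj.values)
    rmean = csum / np.arange(1, len(traj) + 1)
    return (
        AnnualTrajectory(values=rmean, unit=traj.unit),
        AnnualTrajectory(values=csum, unit=traj.unit),
    )
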