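"""Synthetic flux measurements and fixture inventories.

Generates half-hourly net-ecosystem-exchange (NEE) series and soil
chamber campaigns with the statistical structure the downstream budget
and LCA stages assume: a diurnal CO2 cycle with random gaps, replicated
chamber campaigns with a peat/mineral soil-respiration contrast, and
fertilization-driven N2O pulses. All generators are deterministic under
a fixed seed, so the full pipeline is testable without any measurement
downloads.

The simulated magnitudes default to the study conditions of a young
(1-yr, strong C source) and a mature (12-yr, strong C sink) Indonesian
oil-palm plantation on mineral soil, with peat soil respiration 2.6
times the mineral one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fluxes import (
    HALFHOUR_SECONDS,
    MOLAR_MASS_C,
    UNIT_UMOL,
    ChamberCampaignSet,
    FluxSeries,
)

__all__ = [
    "NEESimParams",
    "ChamberSimParams",
    "gen_halfhourly_nee",
    "gen_chamber_campaigns",
    "make_fixture_inventory",
]

#: nominal (non-leap) simulation year
SIM_YEAR = 2015


@dataclass(frozen=True)
class NEESimParams:
    """Parameters of the half-hourly NEE simulator.

    ``annual_total`` is the signed annual NEE in gC m-2 yr-1 (positive
    = source); ``diurnal_amplitude`` the peak daytime uptake added on
    top of the base level, in µmol CO2 m-2 s-1; ``noise_sd`` the
    relative SD of multiplicative measurement noise.
    """

    annual_total: float
    diurnal_amplitude: float = 10.0
    months_covered: int = 12
    gap_fraction: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.months_covered <= 12:
            raise ValueError("months_covered must be in 1..12")
        if not 0.0 <= self.gap_fraction < 0.5:
            raise ValueError("gap_fraction must be in [0, 0.5)")
        if self.diurnal_amplitude < 0:
            raise ValueError("diurnal_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ChamberSimParams:
    """Parameters of the chamber-campaign simulator.

    Soil respiration (SR) is lognormal with mean ``mean_sr_mineral``
    (mgC m-2 h-1) on mineral soil and ``mean_sr_mineral * peat_ratio``
    on peat. CH4 (µgC m-2 h-1, typically negative = uptake) and N2O
    (µgN m-2 h-1) are normal; N2O campaigns within ``pulse_window_days``
    after a fertilization date are elevated by an exponentially decaying
    pulse of initial amplitude ``n2o_pulse_amplitude``. ``dispersion``
    is the coefficient of variation shared by all gases.
    """

    n_replicates_mineral: int = 4
    n_replicates_peat: int = 2
    n_campaigns: int = 45
    n_campaigns_peat: int | None = None
    mean_sr_mineral: float = 91.7
    peat_ratio: float = 2.6
    mean_ch4: float = -15.0
    n2o_baseline: float = 35.0
    n2o_pulse_amplitude: float = 100.0
    fertilization_dates: tuple = ()
    pulse_window_days: float = 14.0
    dispersion: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_campaigns < 2:
            raise ValueError("need at least 2 campaigns for annualization")
        if self.peat_ratio <= 0:
            raise ValueError("peat_ratio must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def gen_halfhourly_nee(params: NEESimParams) -> FluxSeries:
    """Simulate a half-hourly NEE series over the covered months.

    Shape: constant nocturnal respiration plus a daytime (06:00-18:00)
    half-sinusoid uptake of the configured amplitude; a constant offset
    is solved so that the noise-free, gap-free series integrates exactly
    to ``annual_total * months_covered / 12``. Gaps are placed uniformly
    at random over whole half-hour slots (flux set to NaN).
    """
    rng = np.random.default_rng(params.seed)
    start = pd.Timestamp(SIM_YEAR, 1, 1)
    if params.months_covered == 12:
        end = pd.Timestamp(SIM_YEAR + 1, 1, 1)
    else:
        end = pd.Timestamp(SIM_YEAR, params.months_covered + 1, 1)
    ts = pd.date_range(start, end, freq="30min", inclusive="left")
    n = len(ts)

    hours = ts.hour + ts.minute / 60.0
    day = (hours >= 6.0) & (hours < 18.0)
    shape = np.where(
        day, -params.diurnal_amplitude * np.sin(np.pi * (hours - 6.0) / 12.0), 0.0
    )

    # offset (µmol m-2 s-1) so the discrete sum hits the target exactly
    per_halfhour = HALFHOUR_SECONDS * MOLAR_MASS_C * 1e-6  # gC per unit flux
    target_gc = params.annual_total * params.months_covered / 12.0
    offset = (target_gc / per_halfhour - shape.sum()) / n
    flux = shape + offset

    if params.noise_sd > 0:
        flux = flux * (1.0 + params.noise_sd * rng.standard_normal(n))

    is_gap = np.zeros(n, dtype=bool)
    n_gaps = int(round(params.gap_fraction * n))
    if n_gaps:
        is_gap[rng.choice(n, size=n_gaps, replace=False)] = True
        flux = np.where(is_gap, np.nan, flux)

    df = pd.DataFrame({"timestamp": ts, "flux": flux, "is_gap": is_gap})
    return FluxSeries(df, unit=UNIT_UMOL)


def _campaign_dates(n: int, rng_free_year: int = SIM_YEAR) -> pd.DatetimeIndex:
    """Evenly spaced campaign dates spanning one plantation year."""
    days = np.linspace(0, 364, n).round().astype(int)
    return pd.Timestamp(rng_free_year, 1, 1) + pd.to_timedelta(days, unit="D")


def _lognormal_mean(rng, mean: float, cv: float, size) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def gen_chamber_campaigns(params: ChamberSimParams) -> ChamberCampaignSet:
    """Simulate dated chamber campaigns for CO2, CH4 and N2O.

    Produces one flux per replicate x campaign x gas on mineral soil
    and additionally CO2 (soil respiration) on peat. SR is lognormal
    (strictly positive); CH4 and N2O are normal, since CH4 uptake makes
    those fluxes signed. N2O means are elevated after each
    fertilization date by ``n2o_pulse_amplitude * exp(-dt / (window/3))``
    within the pulse window.
    """
    rng = np.random.default_rng(params.seed)
    rows = []

    min_dates = _campaign_dates(params.n_campaigns)
    n_peat_campaigns = params.n_campaigns_peat or params.n_campaigns
    peat_dates = _campaign_dates(n_peat_campaigns)
    fert = pd.to_datetime(list(params.fertilization_dates))

    def n2o_mean(date) -> float:
        mean = params.n2o_baseline
        for f in fert:
            dt = (date - f).days
            if 0 <= dt <= params.pulse_window_days:
                mean += params.n2o_pulse_amplitude * np.exp(
                    -dt / (params.pulse_window_days / 3.0)
                )
        return mean

    cv = params.dispersion
    for date in min_dates:
        for rep in range(1, params.n_replicates_mineral + 1):
            sr = _lognormal_mean(rng, params.mean_sr_mineral, cv, 1)[0]
            ch4 = params.mean_ch4 * (1.0 + cv * rng.standard_normal()) if cv else params.mean_ch4
            mu_n2o = n2o_mean(date)
            n2o = mu_n2o * (1.0 + cv * rng.standard_normal()) if cv else mu_n2o
            rows += [
                (date, f"M{rep}", "mineral", "CO2", sr),
                (date, f"M{rep}", "mineral", "CH4", ch4),
                (date, f"M{rep}", "mineral", "N2O", n2o),
            ]
    mean_sr_peat = params.mean_sr_mineral * params.peat_ratio
    for date in peat_dates:
        for rep in range(1, params.n_replicates_peat + 1):
            sr = _lognormal_mean(rng, mean_sr_peat, cv, 1)[0]
            rows.append((date, f"P{rep}", "peat", "CO2", sr))

    df = pd.DataFrame(
        rows, columns=["date", "replicate", "soil_type", "gas", "flux"]
    )
    return ChamberCampaignSet(df)


# ---------------------------------------------------------------------------
# fixture foreground inventories

#: background emission factors and activity data for the LCA foreground.
#: Synthetic stand-ins on the order of typical published life-cycle
#: inventory values; absolute LCA totals are therefore
#: inventory-dependent and only component structure is meaningful.
_PAPER_DEFAULT_BACKGROUND = {
    # fertilizer & herbicide production + regional transport
    "ef_n_fertilizer": 3500.0,  # gCO2-eq per kg N applied
    "ef_k_fertilizer": 600.0,  # gCO2-eq per kg K
    "ef_p_fertilizer": 1500.0,  # gCO2-eq per kg P
    "ef_glyphosate": 10.0,  # gCO2-eq per ml
    "ef_transport": 0.1,  # gCO2-eq per kg km (truck)
    "ef_mill": 15.0,  # gCO2-eq per kg FFB processed (fossil share)
    "ef_transesterification": 250.0,  # gCO2-eq per kg biodiesel (MeOH, NaOH, grid)
    "ef_nursery": 2.0e5,  # gCO2-eq per ha cycle (establishment)
    # POME methane inventory, calibrated so the closed-capture route
    # emits 1.8 gCO2 MJ-1 after combustion to CO2
    "pome_ch4_per_mj": 1.8 / (44.0 / 16.0),  # g CH4 per MJ biodiesel
}


def make_fixture_inventory(profile: str = "paper_defaults"):
    """Build a complete foreground inventory for the LCA engine.

    Profiles: ``paper_defaults`` (study process parameters plus
    synthetic background emission factors of realistic magnitude) and
    ``zero_background`` (same process parameters, all background
    factors zero — useful for conservation tests).
    """
    from .lca import ForegroundInventory, ProcessParams

    if profile == "paper_defaults":
        return ForegroundInventory(
            process=ProcessParams(),
            background=dict(_PAPER_DEFAULT_BACKGROUND),
            pome_mode="closed",
            fossil_reference=94.0,
        )
    if profile == "zero_background":
        return ForegroundInventory(
            process=ProcessParams(),
            background={k: 0.0 for k in _PAPER_DEFAULT_BACKGROUND},
            pome_mode="closed",
            fossil_reference=94.0,
        )
    raise KeyError(f"unknown inventory profile {profile!r}")
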