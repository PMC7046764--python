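"""Annual ecosystem greenhouse-gas budgets from flux measurements.

Turns half-hourly eddy-covariance CO2 records and dated soil-chamber
campaigns into annual budgets (NEE, NEP, GWPnet, GHGI) for an oil-palm
plantation year.

Sign convention throughout: positive = flux from the ecosystem to the
atmosphere (emission), negative = uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FluxSeries",
    "ChamberCampaignSet",
    "AnnualBudget",
    "GWPConstants",
    "gapfill_diurnal",
    "integrate_annual_nee",
    "trapezoid_annual",
    "nep",
    "nee_peat",
    "nee_second_rotation",
    "gwp_net",
    "ghgi",
]

HOURS_PER_YEAR = 8760.0
DAYS_PER_YEAR = 365.0
HALFHOUR_SECONDS = 1800.0
#: g C per mol C; used to convert µmol CO2 m-2 s-1 to mass-of-carbon flux.
MOLAR_MASS_C = 12.011

#: admissible per-record units of a FluxSeries
UNIT_UMOL = "umol_co2_m-2_s-1"
UNIT_GC_HH = "gC_m-2_halfhour-1"

GASES = ("CO2", "CH4", "N2O")
SOIL_TYPES = ("mineral", "peat")


class QualityError(ValueError):
    """Raised when a series is too gappy or otherwise unusable."""


class FormatError(ValueError):
    """Raised on malformed series/campaign tables (step, units, columns)."""


@dataclass(frozen=True)
class GWPConstants:
    """100-year global-warming-potential factors and mass conversions.

    ``c_to_co2`` is the conventional printed factor 3.664, kept as such
    rather than recomputed from atomic masses.
    """

    gwp_ch4: float = 25.0
    gwp_n2o: float = 298.0
    c_to_co2: float = 3.664
    n2o_n_to_n2o: float = 44.0 / 28.0
    ch4_c_to_ch4: float = 16.0 / 12.0


#: module-wide default constants
GWP100 = GWPConstants()


@dataclass
class FluxSeries:
    """Half-hourly ecosystem CO2 flux record with gap flags.

    Parameters
    ----------
    data
        DataFrame with columns ``timestamp`` (datetime64), ``flux``
        (float; NaN allowed only where ``is_gap``) and ``is_gap`` (bool).
    unit
        Either µmol CO2 m-2 s-1 (``umol_co2_m-2_s-1``) or g C m-2 per
        half-hour (``gC_m-2_halfhour-1``).
    """

    data: pd.DataFrame
    unit: str = UNIT_UMOL

    def __post_init__(self) -> None:
        required = {"timestamp", "flux", "is_gap"}
        if not required.issubset(self.data.columns):
            raise FormatError(f"FluxSeries needs columns {sorted(required)}")
        if self.unit not in (UNIT_UMOL, UNIT_GC_HH):
            raise FormatError(f"unknown flux unit {self.unit!r}")
        ts = pd.to_datetime(self.data["timestamp"])
        if len(ts) > 1:
            steps = ts.diff().dropna()
            if (steps <= pd.Timedelta(0)).any():
                raise FormatError("timestamps must be strictly increasing")
            if steps.nunique() > 1 or steps.iloc[0] != pd.Timedelta(minutes=30):
                raise FormatError("FluxSeries must be on a uniform half-hour step")
        self.data = self.data.assign(timestamp=ts).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gap_fraction(self) -> float:
        if len(self.data) == 0:
            return 0.0
        return float(self.data["is_gap"].mean())

    def to_csv(self, path) -> None:
        """Write as delimited text with a unit header line."""
        with open(path, "w") as fh:
            fh.write(f"# unit: {self.unit}\n")
            fh.write("# columns: timestamp (ISO-8601), flux, is_gap (0/1)\n")
            out = self.data.assign(is_gap=self.data["is_gap"].astype(int))
            out.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "FluxSeries":
        unit = UNIT_UMOL
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                if "unit:" in line:
                    unit = line.split("unit:", 1)[1].strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, parse_dates=["timestamp"])
        df["is_gap"] = df["is_gap"].astype(bool)
        return cls(df, unit=unit)


@dataclass
class ChamberCampaignSet:
    """Dated spot fluxes from vented static chambers.

    One row per (date, replicate, soil type, gas). Per-gas units are
    fixed: mg C m-2 h-1 for CO2 (soil respiration), µg C m-2 h-1 for
    CH4, µg N m-2 h-1 for N2O.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"date", "replicate", "soil_type", "gas", "flux"}
        if not required.issubset(self.entries.columns):
            raise FormatError(f"ChamberCampaignSet needs columns {sorted(required)}")
        bad_gas = set(self.entries["gas"]) - set(GASES)
        if bad_gas:
            raise FormatError(f"unknown gases {sorted(bad_gas)}")
        bad_soil = set(self.entries["soil_type"]) - set(SOIL_TYPES)
        if bad_soil:
            raise FormatError(f"unknown soil types {sorted(bad_soil)}")
        self.entries = self.entries.assign(
            date=pd.to_datetime(self.entries["date"])
        ).reset_index(drop=True)

    def subset(self, gas: str, soil_type: str) -> pd.DataFrame:
        m = (self.entries["gas"] == gas) & (self.entries["soil_type"] == soil_type)
        return self.entries.loc[m]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# columns: date (ISO-8601), replicate, soil_type, gas, flux\n"
                "# units: CO2 mgC m-2 h-1; CH4 ugC m-2 h-1; N2O ugN m-2 h-1\n"
            )
            self.entries.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ChamberCampaignSet":
        df = pd.read_csv(path, comment="#", parse_dates=["date"])
        return cls(df)


@dataclass(frozen=True)
class AnnualBudget:
    """Per-year ecosystem GHG budget of one plantation site.

    All CO2 terms are carbon-mass based (gC m-2 yr-1), N2O is N-mass
    based (gN m-2 yr-1); ``gwp_net`` is in g CO2-eq m-2 yr-1 and
    ``ghgi`` in g CO2-eq per g fresh-fruit-bunch yield (None when there
    is no yield).
    """

    nee: float
    cyield: float
    ch4: float
    n2o: float
    nep: float = field(init=False)
    gwp_net: float = field(init=False)
    ghgi: float | None = None
    yield_ffb: float | None = None  # Mg ha-1 yr-1, kept for provenance

    def __post_init__(self) -> None:
        object.__setattr__(self, "nep", nep(self.nee, self.cyield))
        object.__setattr__(self, "gwp_net", gwp_net(self.nep, self.ch4, self.n2o))
        if self.yield_ffb is not None and self.yield_ffb > 0:
            object.__setattr__(self, "ghgi", ghgi(self.gwp_net, self.yield_ffb))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "nee_gC_m2_yr": self.nee,
                    "cyield_gC_m2_yr": self.cyield,
                    "nep_gC_m2_yr": self.nep,
                    "ch4_gC_m2_yr": self.ch4,
                    "n2o_gN_m2_yr": self.n2o,
                    "gwp_net_gCO2eq_m2_yr": self.gwp_net,
                    "ghgi_gCO2eq_gyield": self.ghgi,
                }
            ]
        )


# ---------------------------------------------------------------------------
# gap filling and annual integration


def gapfill_diurnal(series: FluxSeries, window_days: int = 7) -> FluxSeries:
    """Fill flagged gaps with a mean-diurnal-variation estimate.

    Each gap is replaced by the mean of non-gap values at the same time
    of day within a moving ±``window_days`` window; the window is
    widened until at least three donor values exist. Original values
    are never modified. A stand-in for full meteorological gap-filling:
    it exploits only the diurnal cycle and temporal autocorrelation.
    """
    if series.gap_fraction >= 0.5:
        raise QualityError(
            f"refusing to gap-fill a series with {series.gap_fraction:.0%} gaps (>= 50%)"
        )
    df = series.data.copy()
    gaps = df.index[df["is_gap"]]
    if len(gaps) == 0:
        return series

    ts = df["timestamp"]
    tod = ts.dt.hour * 60 + ts.dt.minute  # minutes since midnight
    day = (ts - ts.iloc[0]).dt.days.to_numpy()
    flux = df["flux"].to_numpy(dtype=float).copy()
    is_gap = df["is_gap"].to_numpy()

    # group candidate donors by time-of-day once
    donors_by_tod: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for t in np.unique(tod[is_gap]):
        m = (tod == t).to_numpy() & ~is_gap
        donors_by_tod[int(t)] = (day[m], flux[m])

    max_span = int(day.max() - day.min()) + 1
    filled = flux.copy()
    for i in gaps:
        ddays, dflux = donors_by_tod[int(tod.iloc[i])]
        w = window_days
        while w <= max_span:
            sel = np.abs(ddays - day[i]) <= w
            if sel.sum() >= 3:
                filled[i] = dflux[sel].mean()
                break
            w *= 2
        else:
            if len(dflux) == 0:
                raise QualityError("no donor values at this time of day")
            filled[i] = dflux.mean()

    out = df.assign(flux=filled, is_gap=False)
    return FluxSeries(out, unit=series.unit)


def _months_covered(ts: pd.Series) -> int:
    return int(ts.dt.to_period("M").nunique())


def integrate_annual_nee(series: FluxSeries) -> float:
    """Annualize a gap-free half-hourly CO2 series to gC m-2 yr-1.

    Sums the record to a period total (converting µmol CO2 m-2 s-1 to
    gC per half-hour when needed) and linearly extrapolates an
    m-month record to 12 months as ``total * 12 / m``.
    """
    if len(series) == 0:
        raise FormatError("cannot integrate an empty series")
    if series.data["is_gap"].any():
        raise QualityError("series contains gaps; gap-fill before integrating")
    flux = series.data["flux"].to_numpy(dtype=float)
    if series.unit == UNIT_UMOL:
        per_halfhour = flux * HALFHOUR_SECONDS * MOLAR_MASS_C * 1e-6  # gC m-2
    else:
        per_halfhour = flux
    total = float(per_halfhour.sum())
    m = _months_covered(series.data["timestamp"])
    return total * 12.0 / m


def trapezoid_annual(campaigns: ChamberCampaignSet, gas: str, soil_type: str) -> float:
    """Annual soil flux by trapezoidal integration of campaign means.

    Replicate fluxes are averaged per campaign date first; the campaign
    means are integrated trapezoidally over a 365-day (8760 h) year,
    with the first and last campaign values extended as constants to
    the year boundaries. Returns gC m-2 yr-1 for CO2/CH4 and
    gN m-2 yr-1 for N2O.
    """
    if gas not in GASES:
        raise FormatError(f"unknown gas {gas!r}")
    sub = campaigns.subset(gas, soil_type)
    means = sub.groupby("date")["flux"].mean().sort_index()
    if len(means) < 2:
        raise ValueError(
            f"need >= 2 campaigns for {gas}/{soil_type}, got {len(means)}"
        )
    first = means.index.min()
    if means.index.max().year == first.year:
        year_start = first.normalize().replace(month=1, day=1)
    else:
        # plantation-year window spanning a calendar boundary: anchor on
        # the first campaign instead of Jan 1
        year_start = first.normalize()
    hours = (means.index - year_start).total_seconds() / 3600.0
    hours = np.clip(np.asarray(hours, dtype=float), 0.0, HOURS_PER_YEAR)
    vals = means.to_numpy(dtype=float)
    # constant extension to the year boundaries
    if hours[0] > 0.0:
        hours = np.concatenate([[0.0], hours])
        vals = np.concatenate([[vals[0]], vals])
    if hours[-1] < HOURS_PER_YEAR:
        hours = np.concatenate([hours, [HOURS_PER_YEAR]])
        vals = np.concatenate([vals, [vals[-1]]])
    hourly_integral = float(np.trapezoid(vals, hours))  # (mg or µg) m-2
    return hourly_integral * (1e-3 if gas == "CO2" else 1e-6)


# ---------------------------------------------------------------------------
# budget equations


def nep(nee: float, cyield: float) -> float:
    """Net ecosystem productivity: NEE plus harvest carbon export.

    Positive = carbon removed from the system (net source once harvest
    is counted). ``cyield`` is the carbon exported in harvested fruit
    bunches, gC m-2 yr-1, and must be non-negative.
    """
    if cyield < 0:
        raise ValueError("harvest carbon export (cyield) must be >= 0")
    return nee + cyield


def nee_peat(nee_mineral: float, sr_mineral: float, sr_peat: float) -> float:
    """NEE over peat soil inferred from the mineral-soil tower record.

    Replaces the mineral-soil soil-respiration contribution with the
    peat-soil one: ``NEE_peat = NEE_mineral - SR_mineral + SR_peat``.
    """
    if sr_mineral < 0 or sr_peat < 0:
        raise ValueError("soil respiration must be >= 0")
    return nee_mineral - sr_mineral + sr_peat


def nee_second_rotation(nee_mineral: float, sr_mineral: float, sr_2nd: float) -> float:
    """NEE of a second-rotation plantation by soil-respiration substitution.

    ``NEE_2nd = NEE_mineral - SR_mineral + SR_2nd`` with the
    second-rotation soil respiration from the calibrated decay curve.
    """
    if sr_mineral < 0 or sr_2nd < 0:
        raise ValueError("soil respiration must be >= 0")
    return nee_mineral - sr_mineral + sr_2nd


def gwp_net(nep_c: float, ch4_c: float, n2o_n: float, k: GWPConstants = GWP100) -> float:
    """Net global warming potential in g CO2-eq m-2 yr-1.

    Converts the carbon-based NEP to CO2, CH4-C to CH4 and N2O-N to
    N2O, weights the non-CO2 gases by their 100-yr GWP, and sums.
    Positive = net emission.
    """
    return (
        nep_c * k.c_to_co2
        + ch4_c * k.ch4_c_to_ch4 * k.gwp_ch4
        + n2o_n * k.n2o_n_to_n2o * k.gwp_n2o
    )


def ghgi(gwp: float, yield_ffb: float) -> float:
    """Greenhouse-gas intensity: GWPnet per gram of fresh-fruit-bunch yield.

    ``yield_ffb`` is in Mg ha-1 yr-1 (1 Mg ha-1 = 100 g m-2); result in
    g CO2-eq per g yield.
    """
    if yield_ffb <= 0:
        raise ZeroDivisionError("GHGI is undefined for zero or negative yield")
    return gwp / (yield_ffb * 100.0)
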