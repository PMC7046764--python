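"""Soil organic carbon decay after forest-to-plantation conversion.

After a rainforest is cleared for oil palm, the soil carbon stock
declines from the forest reference towards a lower equilibrium reached
roughly three decades after conversion. We model the *relative* stock as
an exponential relaxation towards an asymptote,

    r(t) = f + (1 - f) * exp(-k * t),

where ``f`` is the equilibrium fraction of the forest stock and the rate
``k`` is fixed by requiring that at ``equilibrium_time`` only 1% of the
initial excess (1 - f) remains. Soil respiration is assumed to follow
the same relative curve, anchored on a measured flux at a known
plantation age; this yields the soil-respiration trajectory needed for
second-rotation analyses, where decomposition of forest-derived soil
carbon has largely ceased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .scenarios import AnnualTrajectory

__all__ = [
    "DecayCurve",
    "calibrate_decay",
    "stock_at",
    "respiration_from_anchor",
    "second_rotation_sr_trajectory",
    "HOURLY_TO_ANNUAL_SR",
]

#: mgC m-2 h-1 -> gC m-2 yr-1 (8760 h per year, mg -> g)
HOURLY_TO_ANNUAL_SR = 8.760

#: fraction of the initial stock excess remaining at equilibrium_time
RESIDUAL_EXCESS = 0.01


@dataclass(frozen=True)
class DecayCurve:
    """Calibrated relative soil-carbon decay curve.

    ``reference_stock`` is the forest (100%) stock in kgC m-2;
    ``equilibrium_fraction`` the asymptotic fraction retained under oil
    palm; ``rate`` the relaxation constant in yr-1; ``equilibrium_time``
    the age at which the remaining excess is down to 1%.
    """

    reference_stock: float
    equilibrium_fraction: float
    rate: float
    equilibrium_time: float

    def relative(self, t) -> np.ndarray | float:
        """Relative stock r(t) with r(0) = 1 and r(t >= equilibrium_time) = f.

        Past the equilibrium age the residual 1% excess is dropped and
        the curve sits exactly on the asymptote.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time since conversion must be >= 0")
        f = self.equilibrium_fraction
        out = np.where(
            t >= self.equilibrium_time,
            f,
            f + (1.0 - f) * np.exp(-self.rate * t),
        )
        return out if out.ndim else float(out)

    @property
    def equilibrium_stock(self) -> float:
        """Asymptotic soil C stock under oil palm, kgC m-2."""
        return self.reference_stock * self.equilibrium_fraction


def calibrate_decay(
    reference_stock: float,
    equilibrium_fraction: float = 0.60,
    equilibrium_time: float = 32.5,
) -> DecayCurve:
    """Calibrate the decay curve to a regional forest reference stock.

    Parameters
    ----------
    reference_stock
        Forest soil C stock taken as the 100% reference, kgC m-2.
    equilibrium_fraction
        Fraction of the reference retained at equilibrium, in (0, 1).
    equilibrium_time
        Years after conversion at which equilibrium is considered
        reached (1% residual excess). Default 32.5 yr, the midpoint of
        the 30-35 yr range over which the equilibrium establishes.
    """
    if not 0.0 < equilibrium_fraction < 1.0:
        raise ValueError("equilibrium_fraction must lie strictly in (0, 1)")
    if equilibrium_time <= 0:
        raise ValueError("equilibrium_time must be > 0")
    if reference_stock <= 0:
        raise ValueError("reference_stock must be > 0")
    rate = -math.log(RESIDUAL_EXCESS) / equilibrium_time
    return DecayCurve(reference_stock, equilibrium_fraction, rate, equilibrium_time)


def stock_at(curve: DecayCurve, t) -> np.ndarray | float:
    """Soil C stock at ``t`` years after conversion, kgC m-2."""
    return curve.reference_stock * curve.relative(t)


def respiration_from_anchor(
    curve: DecayCurve, anchor_flux: float, anchor_age: float, t
) -> np.ndarray | float:
    """Soil respiration at age ``t`` scaled along the decay curve.

    The relative magnitude of soil respiration after conversion is
    assumed to follow the same curve as the relative soil C stock, so a
    single measured flux (``anchor_flux`` at ``anchor_age``, same unit
    in = same unit out) fixes the whole trajectory:
    ``SR(t) = anchor_flux * r(t) / r(anchor_age)``.
    """
    if anchor_flux <= 0:
        raise ValueError("anchor_flux must be > 0")
    return anchor_flux * curve.relative(t) / curve.relative(anchor_age)


def second_rotation_sr_trajectory(
    curve: DecayCurve,
    anchor_flux: float,
    anchor_age: float,
    start_year: float,
    cycle_length: int,
) -> AnnualTrajectory:
    """Annual soil respiration over a second-rotation cycle.

    The second rotation begins ``start_year`` years after the original
    forest conversion, so a palm of age ``a`` sits at
    ``start_year + a`` on the decay curve — essentially flat at the
    equilibrium respiration. ``anchor_flux`` is hourly
    (mgC m-2 h-1); the returned trajectory is annual (gC m-2 yr-1).
    """
    ages = np.arange(1, cycle_length + 1, dtype=float)
    hourly = respiration_from_anchor(curve, anchor_flux, anchor_age, start_year + ages)
    values = np.asarray(hourly, dtype=float) * HOURLY_TO_ANNUAL_SR
    return AnnualTrajectory(values=values, unit="gC m-2 yr-1")
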