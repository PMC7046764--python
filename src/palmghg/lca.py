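"""Per-MJ life-cycle greenhouse-gas assembly for palm-oil biodiesel.

The functional unit is 1 MJ of biodiesel. Cycle-total emissions per
hectare are assembled from the plantation trajectories (NEE, yield,
inputs), the processing chain (mill, transesterification, transport),
land-use-change terms and a foreground inventory of background emission
factors, then divided by the cycle-total biodiesel energy and allocated
between biodiesel and glycerol.

Two analysis modes:

* ``traditional`` — the conventional carbon-neutrality assumption: the
  ecosystem CO2 sink and the biogenic CO2 released on use cancel and
  both are dropped.
* ``enhanced`` — measured ecosystem fluxes enter as a (negative) sink
  component and biogenic combustion CO2 (biodiesel use, fibre/shell
  boiler) is counted on the emission side.

Second-rotation cycles carry no land-use-change emissions and no
foregone sequestration: the forest was cleared one rotation earlier.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import yaml

from .fluxes import GWP100, GWPConstants
from .scenarios import (
    AnnualTrajectory,
    ScenarioSpec,
    input_trajectories,
    nee_trajectory,
    yield_trajectory,
)

__all__ = [
    "ProcessParams",
    "LUCParams",
    "ForegroundInventory",
    "LCAResult",
    "luc_annualized",
    "foregone_sequestration",
    "energy_chain",
    "allocation_factor",
    "biogenic_combustion",
    "pome_emissions",
    "assemble_lca",
]

M2_PER_HA = 1.0e4
KG_PER_MG = 1.0e3

#: background-inventory keys assemble_lca requires
REQUIRED_BACKGROUND = (
    "ef_n_fertilizer",
    "ef_k_fertilizer",
    "ef_p_fertilizer",
    "ef_glyphosate",
    "ef_transport",
    "ef_mill",
    "ef_transesterification",
    "ef_nursery",
    "pome_ch4_per_mj",
)


@dataclass(frozen=True)
class ProcessParams:
    """Processing-chain parameters of the palm-oil biodiesel route.

    Defaults are the study values: 5.18 kg fresh fruit bunches (FFB)
    per kg crude palm oil (CPO), 95% biodiesel yield from CPO, heating
    values 37.5 / 16 MJ kg-1 for biodiesel / glycerol, biodiesel carbon
    content 76.35%, fibre and shell water/carbon contents for the mill
    boiler, and transport distances of 25 km (FFB to mill) and 250 km
    (CPO to the biodiesel plant).
    """

    ffb_per_cpo: float = 5.18
    biodiesel_fraction_of_cpo: float = 0.95
    hv_biodiesel: float = 37.5
    hv_glycerol: float = 16.0
    biodiesel_c_content: float = 0.7635
    fibre_water: float = 0.40
    shell_water: float = 0.35
    fibre_c: float = 0.472
    shell_c: float = 0.524
    fibre_per_ffb: float = 0.13
    shell_per_ffb: float = 0.065
    cpo_transport_km: float = 250.0
    mill_distance_km: float = 25.0

    def __post_init__(self) -> None:
        for name in (
            "biodiesel_fraction_of_cpo",
            "biodiesel_c_content",
            "fibre_water",
            "shell_water",
            "fibre_c",
            "shell_c",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if self.hv_biodiesel <= 0 or self.hv_glycerol <= 0:
            raise ValueError("heating values must be > 0")


@dataclass(frozen=True)
class LUCParams:
    """Land-use-change carbon stocks and foregone-sequestration basis.

    ``cs_r``/``cs_a`` are total (vegetation + soil) carbon stocks of the
    reference land use (forest) and the plantation, MgC ha-1; ``t_years``
    the amortization period (= rotation length); ``forest_nee`` the
    annual NEE the forest would have sustained, gC m-2 yr-1.
    """

    cs_r: float = 283.5
    cs_a: float = 109.9
    t_years: float = 25.0
    forest_nee: float = -124.0

    def __post_init__(self) -> None:
        if self.t_years <= 0:
            raise ValueError("amortization period t_years must be > 0")


@dataclass
class ForegroundInventory:
    """Process parameters plus per-stage background emission factors."""

    process: ProcessParams
    background: dict
    pome_mode: str = "closed"
    fossil_reference: float = 94.0  # gCO2-eq MJ-1
    mill_allocation_to_cpo: float = 1.0

    def require(self, keys=REQUIRED_BACKGROUND) -> None:
        missing = [k for k in keys if k not in self.background]
        if missing:
            raise KeyError(f"inventory is missing background factors: {missing}")

    def to_yaml(self, path) -> None:
        payload = {
            "process": {f.name: getattr(self.process, f.name) for f in fields(ProcessParams)},
            "background": dict(self.background),
            "pome_mode": self.pome_mode,
            "fossil_reference": self.fossil_reference,
            "mill_allocation_to_cpo": self.mill_allocation_to_cpo,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ForegroundInventory":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            process=ProcessParams(**payload["process"]),
            background=dict(payload["background"]),
            pome_mode=payload.get("pome_mode", "closed"),
            fossil_reference=float(payload.get("fossil_reference", 94.0)),
            mill_allocation_to_cpo=float(payload.get("mill_allocation_to_cpo", 1.0)),
        )


COMPONENT_NAMES = (
    "ecosystem_sink",
    "cultivation",
    "milling",
    "biodiesel_production",
    "biogenic_use",
    "pome",
    "luc",
    "foregone_sequestration",
)


@dataclass(frozen=True)
class LCAResult:
    """Per-MJ emission components (gCO2-eq MJ-1) and their net sum."""

    components: dict
    net: float
    allocation_factor: float
    mode: str
    scenario: str
    rotation: str
    savings_vs_fossil: float
    total_mj_per_ha: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": name, "gCO2eq_per_MJ": self.components[name]}
            for name in COMPONENT_NAMES
        ]
        rows.append({"component": "net", "gCO2eq_per_MJ": self.net})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# elementary operations


def luc_annualized(p: LUCParams, k: GWPConstants = GWP100) -> tuple[float, float]:
    """Annualized land-use-change CO2 emissions.

    ``(CS_R - CS_A) / T * 3.664``, returned both in gCO2-eq m-2 yr-1
    and MgCO2 ha-1 yr-1.
    """
    mg_per_ha_yr = (p.cs_r - p.cs_a) / p.t_years * k.c_to_co2
    g_per_m2_yr = mg_per_ha_yr * 1.0e6 / M2_PER_HA
    return g_per_m2_yr, mg_per_ha_yr


def foregone_sequestration(forest_nee: float, k: GWPConstants = GWP100) -> float:
    """CO2 uptake the uncleared forest would have provided, as a charge.

    A forest sink (negative NEE) becomes a positive emission charge in
    gCO2-eq m-2 yr-1; a forest source would yield a negative charge.
    """
    return -forest_nee * k.c_to_co2


def energy_chain(yield_traj: AnnualTrajectory, p: ProcessParams) -> pd.DataFrame:
    """Per-ha annual product masses and energies along the cycle.

    From FFB (Mg ha-1 yr-1) to CPO (1/5.18), biodiesel (95% of CPO),
    glycerol (the 5% remainder) and their energy contents.
    """
    ffb_kg = np.asarray(yield_traj.values) * KG_PER_MG
    if np.any(ffb_kg < 0):
        raise ValueError("FFB yield must be >= 0")
    cpo_kg = ffb_kg / p.ffb_per_cpo
    biodiesel_kg = cpo_kg * p.biodiesel_fraction_of_cpo
    glycerol_kg = cpo_kg * (1.0 - p.biodiesel_fraction_of_cpo)
    return pd.DataFrame(
        {
            "age": yield_traj.ages,
            "ffb_kg": ffb_kg,
            "cpo_kg": cpo_kg,
            "biodiesel_kg": biodiesel_kg,
            "glycerol_kg": glycerol_kg,
            "biodiesel_mj": biodiesel_kg * p.hv_biodiesel,
            "glycerol_mj": glycerol_kg * p.hv_glycerol,
        }
    )


def allocation_factor(
    method: str, outputs: dict, prices: dict | None = None
) -> dict:
    """Allocation of chain emissions among co-products.

    ``outputs`` maps product name to energy content (MJ) for the energy
    method, or to mass/amount for the economic method (combined with
    per-unit ``prices``). Factors sum to one.
    """
    if not outputs:
        raise ValueError("need at least one co-product")
    if method == "energy":
        weights = {k: float(v) for k, v in outputs.items()}
    elif method == "economic":
        if prices is None:
            raise ValueError("economic allocation requires prices")
        missing = sorted(set(outputs) - set(prices))
        if missing:
            raise ValueError(f"missing prices for {missing}")
        weights = {k: float(v) * float(prices[k]) for k, v in outputs.items()}
    else:
        raise ValueError(f"unknown allocation method {method!r}")
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("co-product weights must sum to a positive total")
    return {k: w / total for k, w in weights.items()}


def biogenic_combustion(
    mass_kg: float,
    c_content: float,
    water_content: float = 0.0,
    k: GWPConstants = GWP100,
) -> float:
    """CO2 (g) released by fully combusting biogenic material.

    ``mass * (1 - water) * C-content * 3.664``; pass ``water_content=0``
    for biodiesel, the as-received water fractions for fibre and shell.
    """
    if not 0.0 <= c_content <= 1.0 or not 0.0 <= water_content <= 1.0:
        raise ValueError("fractions must be in [0, 1]")
    return mass_kg * (1.0 - water_content) * c_content * k.c_to_co2 * 1.0e3


def pome_emissions(
    mode: str, ch4_inventory: float, k: GWPConstants = GWP100
) -> float:
    """Palm-oil-mill-effluent emissions per MJ biodiesel.

    ``ch4_inventory`` is the CH4 generated by anaerobic POME
    degradation, g CH4 per MJ. Closed systems capture and combust it
    (CH4 -> CO2, factor 44/16); open lagoons vent it at its full GWP
    (factor 25) — a ~9-fold penalty.
    """
    if ch4_inventory < 0:
        raise ValueError("ch4_inventory must be >= 0")
    if mode == "closed":
        return ch4_inventory * 44.0 / 16.0
    if mode == "open":
        return ch4_inventory * k.gwp_ch4
    raise ValueError(f"unknown POME mode {mode!r}")


# ---------------------------------------------------------------------------
# assembly


def assemble_lca(
    spec: ScenarioSpec,
    inventory: ForegroundInventory,
    mode: str = "enhanced",
    luc: LUCParams | None = None,
    decay_curve=None,
    soil_ch4_annual: float = -0.13,  # gC m-2 yr-1 (mineral-soil uptake)
    soil_n2o_annual: float = 0.33,  # gN m-2 yr-1 (field emission)
    k: GWPConstants = GWP100,
) -> LCAResult:
    """Assemble the per-MJ life-cycle GHG result for one scenario.

    Sums cycle-total component emissions per hectare, divides by the
    cycle-total biodiesel energy, and allocates chain emissions between
    biodiesel and glycerol by energy content (biodiesel's own
    combustion CO2 is not allocated away — it belongs entirely to the
    functional unit). See the module docstring for the mode and
    rotation contracts.
    """
    if mode not in ("traditional", "enhanced"):
        raise ValueError(f"unknown LCA mode {mode!r}")
    inventory.require()
    p = inventory.process
    bg = inventory.background
    if luc is None:
        luc = LUCParams(t_years=float(spec.cycle_length))

    yields = yield_trajectory(spec)
    nee = nee_trajectory(spec, decay_curve=decay_curve)
    inputs = input_trajectories(spec)
    chain = energy_chain(yields, p)

    total_mj = float(chain["biodiesel_mj"].sum())
    if total_mj <= 0:
        raise ValueError("cycle produces no biodiesel energy")
    total_glycerol_mj = float(chain["glycerol_mj"].sum())
    alloc = allocation_factor(
        "energy", {"biodiesel": total_mj, "glycerol": total_glycerol_mj}
    )["biodiesel"]

    total_ffb_kg = float(chain["ffb_kg"].sum())
    total_cpo_kg = float(chain["cpo_kg"].sum())
    total_biodiesel_kg = float(chain["biodiesel_kg"].sum())
    years = spec.cycle_length

    # --- per-ha cycle totals, gCO2-eq -------------------------------------
    # ecosystem sink: cumulative NEE plus soil CH4, as CO2-eq
    sink = (
        nee.total * k.c_to_co2
        + soil_ch4_annual * years * k.ch4_c_to_ch4 * k.gwp_ch4
    ) * M2_PER_HA

    cultivation = (
        inputs["N"].total * bg["ef_n_fertilizer"]
        + inputs["K"].total * bg["ef_k_fertilizer"]
        + inputs["P"].total * bg["ef_p_fertilizer"]
        + inputs["glyphosate"].total * bg["ef_glyphosate"]
        + bg["ef_nursery"]
        # field N2O from fertilized soil
        + soil_n2o_annual * years * k.n2o_n_to_n2o * k.gwp_n2o * M2_PER_HA
    )

    milling = (
        total_ffb_kg * bg["ef_mill"]
        + total_ffb_kg * p.mill_distance_km * bg["ef_transport"]
    ) * inventory.mill_allocation_to_cpo

    production = (
        total_biodiesel_kg * bg["ef_transesterification"]
        + total_cpo_kg * p.cpo_transport_km * bg["ef_transport"]
    )

    fibre_kg = total_ffb_kg * p.fibre_per_ffb
    shell_kg = total_ffb_kg * p.shell_per_ffb
    fuel_combustion = biogenic_combustion(
        total_biodiesel_kg, p.biodiesel_c_content, 0.0, k
    )
    boiler_combustion = biogenic_combustion(
        fibre_kg, p.fibre_c, p.fibre_water, k
    ) + biogenic_combustion(shell_kg, p.shell_c, p.shell_water, k)

    pome_per_mj = pome_emissions(inventory.pome_mode, bg["pome_ch4_per_mj"], k)

    luc_g_m2_yr, _ = luc_annualized(luc, k)
    luc_total = luc_g_m2_yr * years * M2_PER_HA
    foregone_total = foregone_sequestration(luc.forest_nee, k) * years * M2_PER_HA

    # --- mode and rotation contracts --------------------------------------
    if mode == "traditional":
        sink = 0.0
        fuel_combustion = 0.0
        boiler_combustion = 0.0
    if spec.rotation == "second":
        luc_total = 0.0
        foregone_total = 0.0

    # --- to the functional unit -------------------------------------------
    components = {
        "ecosystem_sink": sink / total_mj * alloc,
        "cultivation": cultivation / total_mj * alloc,
        "milling": milling / total_mj * alloc,
        "biodiesel_production": production / total_mj * alloc,
        # biodiesel's own combustion is unallocated; boiler CO2 is chain
        "biogenic_use": (fuel_combustion + boiler_combustion * alloc) / total_mj,
        "pome": pome_per_mj * alloc,
        "luc": luc_total / total_mj * alloc,
        "foregone_sequestration": foregone_total / total_mj * alloc,
    }
    net = float(sum(components.values()))
    savings = 1.0 - net / inventory.fossil_reference

    return LCAResult(
        components=components,
        net=net,
        allocation_factor=alloc,
        mode=mode,
        scenario=spec.name,
        rotation=spec.rotation,
        savings_vs_fossil=savings,
        total_mj_per_ha=total_mj,
    )
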