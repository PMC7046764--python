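# Methods

## Scope and sign conventions

`palmghg` models the greenhouse-gas balance of oil-palm cultivation on
mineral soil from flux measurement to per-MJ biodiesel life-cycle
result. Everywhere, positive fluxes are emissions from the ecosystem to
the atmosphere and negative fluxes are uptake. Carbon-based quantities
(NEE, NEP, soil respiration, CH₄-C) are converted to CO₂ with the
conventional factor 3.664 (kept as the printed constant, not recomputed
from atomic masses); CH₄ and N₂O are weighted with 100-yr global
warming potentials of 25 and 298 after mass conversion by 16/12 and
44/28.

## Ecosystem budgets

**Gap-filling.** Gaps in the half-hourly NEE record are replaced by the
mean of same-time-of-day values within a moving ±7-day window, widened
(doubling) until at least three donors exist. This is deliberately a
mean-diurnal-variation filler: it exploits only the diurnal cycle and
temporal autocorrelation, not meteorological covariates, which is
sufficient for the synthetic series it is applied to. Series with ≥50%
gaps are refused rather than filled.

**Annualization.** Half-hourly fluxes in µmol CO₂ m⁻² s⁻¹ are converted
to gC per half-hour (×1800 s ×12.011 µg µmol⁻¹), summed, and a record
covering m whole months is extrapolated linearly to the year as
total × 12/m. Chamber campaigns are first averaged across replicates
per campaign date, then integrated trapezoidally over a 365-day
(8760 h) year; the first and last campaign values are extended as
constants to the year boundaries, an edge rule chosen because it makes
the integral of a constant flux exactly flux × 8760 h for any campaign
schedule. Leap years are out of scope. If campaigns span a calendar
boundary the year window is anchored on the first campaign instead of
January 1.

**Budget identities.** NEP = NEE + Cyield (harvest carbon export is an
input in gC m⁻² yr⁻¹, not derived from fruit composition); peat-soil
and second-rotation NEE substitute the corresponding soil respiration
into the mineral-soil NEE; GWPnet and GHGI follow the formulas in the
README. All four are exact arithmetic, and the substitution identities
reduce to the identity map when the replacement respiration equals the
measured one.

## Soil-carbon decay

The relative stock after forest conversion is r(t) = f + (1−f)e^(−kt)
with r(0) = 1. Two parameters calibrate it: the equilibrium fraction
f (default 0.60, the ratio of the equilibrium stock 3.26 kgC m⁻² to
the forest reference 5.43 kgC m⁻²) and the equilibrium time (default
32.5 yr, midpoint of the 30–35 yr range over which the new equilibrium
establishes), at which the remaining excess is defined to be 1%:
k = ln(100)/t_eq ≈ 0.1417 yr⁻¹. An exponential relaxation was chosen
because the multi-site source curve is not available in closed form;
the two calibration parameters are exposed rather than hard-coded. For
ages at or beyond the equilibrium time the curve returns the asymptote
exactly (the ≤1%-of-excess residual, at most 0.4% of the stock with the
defaults, is dropped); this matches the contract that second-rotation
respiration is flat at equilibrium, at the cost of a correspondingly
tiny discontinuity at the equilibrium age.

Soil respiration is assumed to follow the same relative curve, anchored
on the measured young-plantation flux (133.9 mgC m⁻² h⁻¹ at age 1),
giving an equilibrium respiration of 84.8 mgC m⁻² h⁻¹. The annual
equivalent by pure unit conversion is 743 gC m⁻² yr⁻¹; an independently
reported annual figure of 825 gC m⁻² yr⁻¹ rests on annual-scale anchors
that are not public, so this package derives the annual scale from the
hourly one and documents the difference rather than reproducing it.

## Scenario trajectories

Plantation age is an integer 1..cycle_length with values constant
within a year. Fluxes and inputs follow a plateau–ramp–plateau rule:
constant "young" level through year 3, linear to the "mature" level at
year 8, constant thereafter. This is the unique piecewise-linear
reading that reproduces all four published life-cycle input means
exactly (N 174.4, K 190.6, P 47.6 kg ha⁻¹ yr⁻¹; glyphosate
1800 ml ha⁻¹ yr⁻¹ over 25 years). Yield is zero before the first
productive year and ramps linearly from zero — anchored in the year
before first production, for consistency with the input-ramp convention
— to the maximum (26.5 Mg ha⁻¹ yr⁻¹ fresh fruit bunches) at the
maturity year. Under this rule the 25-yr mean FFB yield is
21.2 Mg ha⁻¹ yr⁻¹, slightly below the 21.9 reported from unpublished
yield-by-age values; a user-supplied explicit yield table can replace
the ramp if those values surface. Scenarios: BAU 25 yr; A 30 yr;
B 40 yr; C 30 yr with first yield at age 3 and maximum at age 6.
Second-rotation cycles reuse all first-rotation parameters but correct
NEE per age via the respiration substitution, with first-rotation
respiration evaluated at t = age and second-rotation respiration at
t = start_year + age on the decay curve (start_year defaults to the
cycle length of the preceding rotation).

## Life-cycle assembly

The functional unit is 1 MJ biodiesel. Cycle totals per hectare are
divided by the cycle-total biodiesel energy. The processing chain is
5.18 kg FFB → 1 kg crude palm oil (CPO); 95% of CPO mass becomes
biodiesel (37.5 MJ kg⁻¹) and 5% glycerol (16 MJ kg⁻¹), giving an
energy-allocation factor of 0.978 to biodiesel. Allocation is applied
to all chain components; the CO₂ from combusting the biodiesel itself
(76.35% C → 74.6 gCO₂ MJ⁻¹) belongs entirely to the functional unit
and is not allocated away. Economic allocation is available as a
sensitivity alternative.

Components: the ecosystem sink (cumulative NEE plus soil CH₄ uptake as
CO₂-eq); cultivation (fertilizer/herbicide production and transport,
nursery establishment, and field N₂O at the measured 0.33 gN m⁻² yr⁻¹);
milling (fossil mill energy and 25-km FFB transport, with a
configurable mill allocation factor defaulting to 1.0 to CPO because
kernel-product heating values are not published); biodiesel production
(transesterification inputs and 250-km CPO transport); biogenic use
(biodiesel combustion plus the fibre/shell mill boiler, using 40/35%
water and 47.2/52.4% C contents; fibre and shell masses per kg FFB,
0.13 and 0.065, are typical mill values, not measurements); POME
(methane from effluent digestion — combusted to CO₂ in the closed
default, calibrated to 1.8 gCO₂ MJ⁻¹, or vented at GWP 25 in the open
mode, a 25/(44/16) ≈ 9.1-fold penalty); land-use change
((CS_R − CS_A)/T × 3.664 with stocks 283.5 and 109.9 MgC ha⁻¹,
amortized over the rotation); and foregone sequestration (the −124
gC m⁻² yr⁻¹ forest sink charged as an emission, kept as a separate
component from land-use change). Traditional mode zeroes the sink and
biogenic components (carbon neutrality); second rotations zero
land-use change and foregone sequestration. The net is the exact sum
of components and savings = 1 − net/94 gCO₂-eq MJ⁻¹ (a configurable
fossil-fuel reference consistent with EU biofuel-directive values).

The background emission factors shipped in the `paper_defaults`
inventory are synthetic stand-ins of realistic magnitude for a
commercial background database; absolute per-MJ totals are therefore
inventory-dependent, and only component structure, mode contracts,
rotation contrasts and scenario orderings are treated as results.

## Uncertainty propagation

Parameters vary independently (no correlation structure, no Latin
hypercube — plain Monte Carlo) as normal with absolute SD, normal with
relative SD (measured NEE uses 5% of the value), or lognormal with a
geometric SD. Pedigree-style data-quality scores (six indicators, each
1–5) map through a shipped lookup table to lognormal factors combined
as exp(√Σ(ln fᵢ)²); two undefined cells of the published table
(geographical score 4, technological score 2) are filled monotonically.
Ensembles default to 1000 iterations summarized by mean, median and
the 25th/75th percentiles. Evaluations that raise are excluded and
counted; more than 1% failures aborts the run.

## Synthetic data

The NEE generator produces a half-hourly series with constant nocturnal
respiration and a 06:00–18:00 half-sinusoid daytime uptake of
configurable amplitude (10 µmol CO₂ m⁻² s⁻¹ default), offset so the
noise-free series integrates *exactly* to annual_total × months/12;
multiplicative Gaussian noise (relative SD) and uniformly placed
half-hour gaps are added on top. The chamber generator draws lognormal
soil respiration (strictly positive; arithmetic mean preserved for any
CV) and normal CH₄/N₂O (signed fluxes — CH₄ uptake rules out a
positive-support law), with peat respiration at peat_ratio × the
mineral mean (2.6 default) and N₂O elevated after fertilization dates
by an exponentially decaying pulse over a 14-day window (the pulse
duration is not reported; 14 days with a 1/3-window e-folding time is
this package's choice). Default structure mirrors the study design:
4 mineral replicates × 45 campaigns, 2 peat replicates × 37 campaigns,
CV 0.4, mineral mean 91.7 mgC m⁻² h⁻¹.

What the generators do *not* emulate: meteorological covariation (so
gap-filling skill on real data is not demonstrated), storm/drought
anomalies, within-day chamber variability, spatial autocorrelation
among replicates, and instrument drift. Passing recovery tests shows
the integration and estimation machinery is unbiased under the assumed
statistical structure, not that the structure matches any particular
field campaign.

## Problem sizes and determinism

All analyses run in seconds on one CPU: a full synthetic year is 17,520
half-hours, chamber simulations are a few hundred draws, and a
1000-iteration Monte Carlo of a full scenario LCA takes well under a
minute. Every stochastic component takes an explicit integer seed and
is bit-reproducible under it.

## Known limitations

- No raw eddy-covariance processing (coordinate rotation, WPL, u*
  filtering, footprints) — the pipeline starts at quality-flagged
  half-hourly fluxes.
- Peat-soil budgets are supported at the flux level (the peat NEE
  substitution), but no full peat LCA is assembled.
- Annualization assumes a 365-day year; leap days are ignored.
- The LCA background is a fixture, not a licensed inventory database;
  absolute totals should not be quoted against published totals.
- Statistical site comparisons (mixed-effects models, rank tests) are
  out of scope; the peat/mineral contrast is a ratio estimator.
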