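# rhodolith

Analysis pipeline for rhodolith (free-living coralline algae) ecophysiology:
from raw microsensor depth profiles, acid titrations, sealed-chamber
incubations and micro-CT volumes to diffusive-boundary-layer (DBL)
thickness, O₂ fluxes, surface-pH anomalies, total alkalinity, calcification
rates and surface-area/volume morphometrics — plus the regression/ANOVA
layer that compares species, thallus locations and seawater-pH treatments.

It is written for benthic ecophysiologists who measure microscale chemistry
at algal (or coral) surfaces and relate it to whole-organism metabolic and
calcification rates, e.g. in ocean-acidification experiments.

## What it computes

**Boundary layer and fluxes.** An O₂ or pH microprofile `C(z)` measured from
the thallus surface (z = 0) into the water column is fitted linearly over a
near-surface window; the effective DBL thickness is where the extrapolated
gradient meets the bulk concentration,

    δ = (C_bulk − C_0) / (dC/dz),

and the diffusive flux follows Fick's first law, `J = −D · dC/dz` with
D = 2.01 × 10⁻⁹ m² s⁻¹ for O₂ in seawater (positive J = efflux). Surface pH
anomalies are `ΔpH = pH_S − pH_B`.

**Alkalinity and the CO₂ system.** Total alkalinity comes from HCl
titrations via the Gran function `F(v) = (V₀ + v)·10^(−pH)`, refined with a
bicarbonate-compensated second pass, so `A_T = C_acid·v_eq / m_sample`.
Calcification uses the alkalinity anomaly (2 mol A_T per mol CaCO₃):

    G = −ΔA_T/2 · (V·ρ) / (SA·Δt),
    G_net = h_light·G_light + h_dark·G_dark   (14 h : 10 h photoperiod).

A CO₂-system solver speciates (pH, A_T) into HCO₃⁻/CO₃²⁻/CO₂/B(OH)₄⁻ and the
calcite saturation state `Ω_calc = [Ca²⁺][CO₃²⁻]/K_sp`.

**Morphometrics.** Micro-CT-style volumes are median-filtered,
unsharp-masked, threshold-segmented (Otsu or fixed, largest connected
component kept) and measured: volume by voxel counting, surface area from a
marching-cubes isosurface (voxel-face counting overestimates curved
surfaces by ~1.5× and is deliberately avoided), giving SA, V, SA/V, SA/DW.

**Statistics.** OLS regression with 95 % confidence bands, one/two-way
fixed-effects ANOVA, Newman–Keuls post hoc with compact-letter displays
(studentized-range quantiles evaluated numerically), Shapiro–Wilk and
Levene assumption checks.

**Synthetic data.** Every input kind can be generated with known ground
truth (seeded): steady-state microprofiles on the 25 µm/100 µm sampling
grid, forward-simulated closed-system titrations, chamber endpoint records,
and branched-rhodolith voxel phantoms for the three studied species
(*Lithothamnion crispatum*, *Lithophyllum atlanticum*, *Melyvonnea
erubescens*) with closed-form surface area and volume.

## Worked example

```python
import rhodolith as rh
from rhodolith.incubation import Photoperiod

# a noisy O2 microprofile with a 500-um DBL and a known efflux
p, truth = rh.simulate_microprofile(bulk=250.0, dbl_thickness=500.0,
                                    flux=0.0724, noise_sd=1.0, seed=42)
dbl = rh.estimate_dbl(p, bulk=250.0)
print(dbl.summary())
flux = rh.fick_flux(dbl)
print(f"J = {flux.flux:+.4f} umol O2 cm^-2 h^-1 ({flux.direction})")

curve, _ = rh.simulate_titration(at_true=2378.0, noise_sd_ph=0.003, seed=7)
print(rh.gran_alkalinity(curve).summary())

state = rh.solve_from_ph_alk(ph=8.12, at=2378.0, temp=24.0, salinity=35.0)
print(state.summary())

g_net = rh.daily_net_calcification(0.12, 0.04, Photoperiod(14, 10))
print(f"G_net = {g_net:.2f} umol CaCO3 cm^-2 day^-1")
```

prints

```
Effective DBL fit
-----------------
analyte:          oxygen
DBL thickness:    456.8 um
surface value:    300.3
surface gradient: -0.1102 per um
bulk value:       250
fit R^2:          0.9314  (n = 5)
J = +0.0797 umol O2 cm^-2 h^-1 (efflux)
Gran titration fit
------------------
A_T:              2379.2 umol/kg
equivalence vol.: 0.2923 mL
Gran fit R^2:     0.99986  (n = 8)
CO2-system solution
-------------------
pH (as given):   8.120
A_T:             2378.0 umol/kg
DIC:             2028.8 umol/kg
CO2*:            9.4 umol/kg
HCO3-:           1770.1 umol/kg
CO3 2-:          249.4 umol/kg
Omega_calcite:   5.99
T = 24.0 C, S = 35.0
G_net = 2.08 umol CaCO3 cm^-2 day^-1
```

Reading: electrode noise of 1 µmol/L pulls the fitted DBL thickness ~9 %
below the imposed 500 µm for this seed (the estimator is unbiased across
seeds); the titration recovers the true alkalinity (2378) within
1.2 µmol/kg; ambient seawater at pH 8.12 and A_T 2378 µmol/kg is
six-fold supersaturated with respect to calcite; and 14 h of light
calcification at 0.12 plus 10 h of dark calcification at
0.04 µmol CaCO₃ cm⁻² h⁻¹ integrate to 2.08 µmol cm⁻² day⁻¹.

## Command line

`rhodolith simulate --seed 1 --out study/` writes a complete synthetic study
(profile/titration CSVs, an incubation table, TIFF volumes, `truth.json`);
`rhodolith pipeline study/ --out results/` runs every applicable stage and
writes tidy result tables. Single-stage subcommands: `dbl`, `flux`,
`titrate`, `carbsys`, `calcify`, `morpho`, `stats`.

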