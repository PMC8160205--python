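# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical choices a maintainer would want to know about. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Boundary-layer analysis

A microsensor profile `C(z)` is measured from the thallus surface (z = 0,
µm, increasing into the water column; profiles recorded in the opposite
direction are re-indexed on read). The effective diffusive-boundary-layer
(DBL) model assumes steady state and no reaction inside the DBL, so the
concentration is linear between the surface and the bulk value and constant
beyond. The estimator fits an ordinary straight line to the points within a
fixed near-surface window (default 100 µm — five points on a 25-µm in-DBL
sampling grid; configurable) and defines

    δ = (C_bulk − intercept) / slope .

A fixed window was preferred over iterative window growth because it is
deterministic and matches the sampling design; it trades a little bias on
strongly curved profiles (see the generator's `curvature` knob) for
reproducibility.

*Bulk value.* Mean of the outermost three points, with a stationarity check
(slope t-test over those points at α = 0.05). A non-stationary tail sets a
flag rather than failing: bulk drift is information the analyst should see,
not an error.

*Degenerate gradients.* If the within-window slope is statistically
indistinguishable from zero (t-test p > 0.05, or an exactly constant
window), no DBL is definable and the fit raises rather than returning a
huge δ. A δ extrapolating beyond the deepest measured point also raises.

*Fick flux.* `J = −D · dC/dz` with D = 2.01 × 10⁻⁹ m² s⁻¹ (O₂ in seawater,
configurable). Gradients in µmol L⁻¹ µm⁻¹ convert to µmol cm⁻² h⁻¹ by the
factor 3.6 × 10⁸. Sign convention: positive = efflux from the thallus;
dark respiratory influx is negative; reporting layers may print |J| with a
direction label. Replicate ("two consecutive") profiles at a spot are
averaged point-wise after checking the grids match.

The surface pH anomaly is read directly: ΔpH = pH(z=0) − pH_bulk, and the
diel swing is ΔpH_light − ΔpH_dark. The pipeline does not assume dark
ΔpH ≤ 0 — small positive dark anomalies at protuberance tips are a real
observation.

## Gran alkalinity

Total alkalinity is estimated from an HCl titration via the Gran function
F(v) = (V₀ + v)·10^(−pH), fitted linearly over the acid-side region
(default: points with pH in [3.0, 3.5]; if fewer than five points fall
there, the contiguous five-point window with the smallest fit residual is
used). The x-intercept gives the equivalence volume and
A_T = C_acid·v_eq/m_sample.

The plain Gran function is slightly curved in that window because residual
bicarbonate still carries ~10⁻⁶ mol/kg of buffering; on simulated curves
this biases A_T about −10 µmol/kg (≈0.4 %). The fit is therefore refined
with a compensated Gran function,

    F = (V₀ + v) · ([H⁺] − [HCO₃⁻] − [B(OH)₄⁻] − [OH⁻]) ,

which is exactly linear for a closed-system carbonate sample. The DIC
needed for the correction is speciated from the sample's initial pH and the
previous pass's A_T; two passes converge. `correction_passes=0` restores
the textbook estimator. On noise-free synthetic curves the compensated fit
recovers A_T within 0.1 µmol/kg; at 0.003 pH electrode noise the mean
absolute error is ≈3.6 µmol/kg over 50 curves (the acceptance script
recomputes this), comparable to certified-reference-material performance.

Duplicate tubes are fitted independently and averaged by a thin wrapper.
Litre-to-kilogram conversions use the one-atmosphere equation of state
ρ(S, T) (Millero & Poisson 1981).

## CO₂-system solver

Speciation from (pH, A_T) at given T, S: h = 10^(−pH−offset); borate, OH
and H are subtracted from A_T; the carbonate alkalinity is split between
HCO₃⁻ and CO₃²⁻ by K2; Ω_calc = CaT·[CO₃²⁻]/Ksp. Sulfate and fluoride are
not carried — above pH 6 their alkalinity contributions are negligible at
the solver's 0.1 % closure tolerance.

Constants: K1/K2 from the Dickson & Millero (1987) refit of Mehrbach
(default) or Lueker et al. (2000) via `k1k2="lueker"`; KB Dickson (1990);
Kw Millero (1995); Ksp(calcite) Mucci (1983); BT Uppström (1974);
CaT = 0.010282·S/35. Each formulation is pinned in tests to its published
check value at (25 °C, S 35).

Two deliberate calibrations, both configurable: the measured pH is inserted
against the constants as given (`ph_scale_offset = 0`), and salinity
defaults to 35 (open-shelf value; the source data report none). With these
defaults and the DM87 K1/K2 the solver reproduces the two treatment
saturation states (Ω ≈ 6.0 at pH 8.12 / A_T 2378; Ω ≈ 2.7 at pH 7.698 /
A_T 2377) — the Lueker set yields ≈5.88/2.64, about 2 % lower, which is why
DM87 is the default. The ambient/low-pH Ω *ratio* is robust to the scale
offset (it moves ~5 % across offsets 0–0.15 while the individual Ω values
move ~20 %).

## Incubation rates

With chamber endpoints (V = 0.150 L, 0.5 h phases, n = 5 specimens per
species by default):

    O₂ rate  = ((ΔO₂) − ΔO₂_control) · V / (SA·Δt)            [µmol cm⁻² h⁻¹]
    P_max    = net light rate + dark-respiration magnitude
    G        = −(ΔA_T − ΔA_T_control)/2 · (V·ρ) / (SA·Δt)     [µmol CaCO₃ cm⁻² h⁻¹]
    G_net    = h_light·G_light + h_dark·G_dark                 [µmol cm⁻² day⁻¹]

P_max as net-plus-respiration is the standard light/dark-bottle
construction (no formula is given in the source tables). Alkalinity
controls default to zero (controls are typically run for oxygen only);
oxygen controls are required unless explicitly waived. The photoperiod
defaults to 14 h light : 10 h dark. G_net is computed per replicate and
then averaged — this reproduces table entries that rounded-mean arithmetic
misses — with a mean-of-means variant available
(`summarize_rates(..., g_net_from_means=True)`).

The species × treatment comparison runs a two-way ANOVA per response plus
per-species one-way contrasts with Newman–Keuls letters; assumption-check
failures are reported, never fatal.

## Morphometrics

Volumes are median-filtered (cubic neighbourhood, reflective edges),
unsharp-masked (out = in + amount·(in − blur), clipped to the input range),
segmented by Otsu or a fixed threshold, and cleaned by keeping the largest
26-connected component. Interior voids are kept — and therefore counted as
surface — unless `fill_holes` is set, because how internal porosity should
be treated is a genuine analysis decision.

Volume is the voxel count × voxel volume. Surface area is the area of a
marching-cubes isosurface at level 0.5; voxel-face counting is rejected
because it overestimates curved surfaces by up to ~1.5×. A binary
isosurface still inflates curved areas by staircase bumps (+8.7 % on a
25-voxel digitized sphere), so the mask is lightly Gaussian-smoothed
(σ = 0.8 voxels) before triangulation, which brings the sphere error under
1 % (the acceptance script recomputes it). The trade-off: smoothing rounds
genuinely sharp edges over about a voxel, shaving ~σ/n off the relative
area of an n-voxel sharp-edged object — set `smooth_sigma=0` when measuring
such calibration geometry (a 32-voxel cube then lands within 2 % of 6n²).
Objects so small that the smoothed field never reaches the 0.5 level fall
back to the raw binary isosurface. Anisotropic inputs are resampled to
isotropic with a warning.

## Statistics

One-way ANOVA is computed directly from the between/within sums of squares
(and is fast enough for thousands of null simulations — its empirical size
at α = 0.05 is checked over 2000 simulations). The two-way crossed design
is delegated to statsmodels OLS/anova_lm behind the same result type; types
coincide for balanced designs, and imbalance triggers a warning with
type-II sums of squares. OLS regression reports slope, R², the two-sided
slope test and a pointwise 95 % confidence band.

Newman–Keuls: means are sorted; the largest stretch is tested first with
the studentized-range quantile at that span (evaluated numerically from
scipy's distribution, so any error df works — no lookup tables); a
significant stretch recurses into its two sub-stretches, a non-significant
one closes all pairs inside it (containment). Unequal n uses the
Tukey–Kramer style standard error. When the residual mean square is exactly
zero (degenerate data), any difference in means separates groups. Letters
come from the standard insert-and-absorb compact-letter-display algorithm
and are assigned in group input order (the first group takes "a"), matching
how rate tables print superscripts column by column; ties in means keep
input order.

## Synthetic data

Every generator inverts the corresponding estimator's forward model and
records its ground truth, so each stage has a recovery test. All randomness
flows from one seed; equal seeds give identical bundles.

* **Microprofiles** — steady-state, no-reaction DBL shape (linear inside δ,
  constant outside), sampled at 25 µm inside / 100 µm outside to ≥600 µm,
  with additive Gaussian noise. A `curvature` knob bends the in-DBL segment
  (zero value and slope at the surface, zero at δ) to stress the linear
  estimator. Not emulated: profile curvature from within-DBL
  photosynthesis/respiration, sensor drift, stirring artefacts.
* **Titrations** — closed-system carbonate equilibrium after each acid
  increment, dilution tracked by mass, pH solved by root-finding from the
  charge balance, Gaussian electrode noise. Not emulated: CO₂ degassing
  during the titration (open-cell behaviour), electrode calibration error —
  so passing tests show estimator correctness, not bench accuracy.
* **Incubations** — endpoints from inverting the rate equations over 0.5 h,
  with lognormal between-specimen rate variation (CV 10 %) and Gaussian
  endpoint noise (O₂ σ = 1 µmol/L, A_T σ = 2 µmol/kg). The low-pH treatment
  applies the configured effect structure: dark calcification strongly
  negative in all species, metabolic stimulation only in the
  high-metabolism species, light calcification unchanged.
* **Volumes** — spherical core (default radius 5 mm, a scaled-down
  representative nodule chosen to keep grids small at a realistic voxel
  pitch) plus radially oriented capsule protuberances at each species'
  reported branch dimensions, on seeded quasi-uniform directions. The union
  is disjoint by construction, so surface area and volume have closed
  forms, recorded as truth; a seeded Monte-Carlo volume estimator
  cross-checks them. Species branch counts (10/10/45) were chosen once so
  the finely-branched species exceed the thick-branched one in SA/V, as
  observed. Not emulated: internal porosity, borings and attached fauna,
  CT reconstruction artefacts.
* **Study bundle** — the full crossed design: 3 species × 3 individuals ×
  2 spots × {tip, base} × {light, dark}, two consecutive profiles per spot;
  5 chamber replicates × 2 treatments × 2 phases with duplicate titration
  tubes per endpoint; 5 volumes per species. Base-DBL thickness increases
  linearly with protuberance length (150 µm + 20 µm/mm; tips fixed at
  130 µm), so the cross-species regression structure is present by
  construction. `noise_scale` multiplies every noise source; 0 gives a
  noise-free bundle on which the pipeline must recover all rates to <1 %.

The species presets pin tip/base surface-pH anomalies whose means equal the
reported species means (light 0.55/0.36/0.33; dark −0.23/+0.0009/−0.06) and
which stay consistent with the reported tip/base ranges and diel swings;
where those printed summaries are mutually inconsistent at the second
decimal, the species means take precedence because the downstream
ΔpH–calcification regression uses them.

## Known limitations

* The ΔpH–calcification regression over the six printed species means gives
  R² = 0.953; the value printed alongside the original figure (0.96)
  evidently comes from unrounded data and is not reproducible from the
  published summaries.
* The DBL estimator assumes in-DBL linearity; reactive (curved) profiles
  bias δ low by design of the window fit.
* The Gran compensation assumes a closed system; strongly degassed
  titrations would be better served by nonlinear least squares, which is
  out of scope.
* Volume IO is TIFF-stack only.
* No photosynthesis–irradiance fitting, no aragonite saturation state, no
  pCO₂/fugacity outputs, no mixed models.
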