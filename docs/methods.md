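# Methods

## Scope and data flow

`heatshift` estimates how much physical work capacity outdoor workers would
recover if large paved surfaces were brightened. The unit of analysis is one
hour at one representative outdoor location under one scenario. The chain is

    hourly meteorology  →  WBGT  →  work loss (min/h)  →  shift totals  →  hours gained

with the albedo stage (satellite reflectance → broadband albedo → scenario
rasters) providing the physical grounding for the scenario coolings.

High-resolution atmospheric modelling is *out of scope*: the package either
ingests an hourly series (CSV schema `location_id, timestamp_local, Ta_C,
RH_pct, u_ms, Kdown_Wm2, Kup_Wm2, Ldown_Wm2, Lup_Wm2, F_frac, zenith_deg,
scenario`) or synthesizes one with the generator described below.

## WBGT

**Wet bulb.** Stull's (2011) arctangent fit to the psychrometric wet bulb,
valid roughly for RH 5–99 % and Ta −20…50 °C at sea-level pressure.
Evaluation outside that window warns but proceeds. The fit is good to a few
tenths of a degree inside the window; at RH → 100 % it approaches the dry
bulb as a wet bulb must.

**Globe temperature.** The 15 cm black globe balance in the Liljegren et al.
(2008) arrangement, grouped as: longwave mean `(L↓+L↑)/2σ`, convective
exchange `h_c(T_g−T_a)/ε_gσ`, direct+diffuse shortwave
`K↓(1−α_g)/2ε_gσ·(1−F+F/2cosZ)`, reflected shortwave `(1−α_g)K↑/2ε_gσ`.
All radiative algebra is in Kelvin; interfaces are °C. Defaults:
ε_g = 0.95, α_g = 0.05, D = 0.15 m, σ = 5.670374419×10⁻⁸ W m⁻² K⁻⁴.
`cos Z` is floored at 0.02 wherever it appears in a denominator so the
direct-beam term stays finite through sunrise/sunset.

`h_c` is not standardized across WBGT implementations; we use the
Ranz–Marshall forced-convection sphere correlation
`Nu = 2 + 0.6·Re^0.5·Pr^(1/3)` with air conductivity, viscosity and density
evaluated at the film temperature (Sutherland viscosity, ideal-gas density
at 101325 Pa). The additive constant keeps a conductive floor as u → 0, so
no free-convection branch is needed. All coefficients sit in `GlobeParams`.

*Numerical choice.* The balance is solved by successive substitution on T_g
with 0.5 damping, stopping when successive iterates agree within 0.02 °C.
That map is contractive in calm conditions but **not** when h_c is large
(|dg/dT_g| = h_c/(4ε_gσT_g³) exceeds 1 above roughly u ≈ 1.5 m/s), so at a
windy site a large fraction of daytime hours exhaust `max_iterations` (50)
and fall through to bracketed root finding (Brent on [Ta−5, Ta+80] °C,
xtol 10⁻⁶). This is by design: the substitution honors the classical
iterate-to-0.02 °C convergence rule where it converges, and the fallback
guarantees the same root elsewhere; the acceptance suite checks the solver
against plain interval bisection to ≤ 0.04 °C on 1,000 randomized samples.
When K = 0 and L↓ = L↑ = σT_aK⁴ the solver returns T_g = T_a exactly in one
step (the analytic fixed point).

**Branching.** An hour is "sun" iff K↓ > 25 W/m² and Z < 90° (both
configurable via `SunRule`); otherwise the no-sun forms apply, with the wind
threshold at 3 m/s. Wind is clamped below at 0.13 m/s before `log₁₀ u`
because the calm form diverges as u → 0. The two no-sun forms disagree
slightly at exactly u = 3 m/s; the discontinuity is bounded
(≈ 0.007·|Ta−Tw| °C) and documented rather than smoothed.

## Work loss and aggregation

Work loss per hour is the Foster et al. (2021) physical-work-capacity
logistic for unacclimatized workers doing moderate-to-heavy labor in normal
work attire: PWC = 1/(1+(WBGT/33.63)^6.33), loss = 60·(1−PWC) minutes,
clamped to [0, 60]. WBGT ≤ 0 (where the power law is undefined) maps to
zero loss. No acclimatization, clothing or metabolic adjustments are
modelled.

The loss is applied to each hourly, per-location WBGT *before* averaging.
The curve is convex through the temperate range, so by Jensen's inequality
applying it to shift-mean WBGT would understate losses — this is tested, and
it is why shift-mean temperature tables cannot be inverted into gained
hours. Shifts are 07–15, 15–23 and 23–07 local (8 hourly samples each, the
night shift assembled across midnight by hour-of-day membership); a full
month of coverage is required and gaps raise an error rather than being
imputed. Locations are averaged unweighted (no worker-count weights are
assumed). Hours gained = baseline lost hours − scenario lost hours, per
shift plus a total; the productivity AUC is trapezoidal integration of the
hourly PWC percentage.

## Synthetic campaign generator

The generator emulates the *statistical shape* of post-processed mesoscale
model output for one hot month at a marine-climate airfield, not its
physics. Defaults (all in `CampaignConfig`):

- 10 locations, August 2020, 37.62° N / 122.38° W, fixed UTC−7 timestamps,
  31×24 top-of-hour samples per series;
- air temperature: mean 17.5 °C, sinusoidal diurnal amplitude 4.5 °C peaking
  at 15:00 — a coastal summer with ~9 °C daily range; per-location offsets
  (sd 0.5 °C, demeaned across locations) and AR(1) hourly noise (sd 0.5 °C,
  φ = 0.6, demeaned per hour-of-day so the campaign-mean diurnal cycle is
  seed-invariant);
- RH anti-correlated with the temperature cycle (75 ± 15 %, clipped to
  [5, 99] %, the wet-bulb fit's validity window);
- wind lognormal with median 3.5 m/s (sd of log 0.45) — a windy site, so
  both no-sun branches and the convection-dominated globe regime are
  exercised;
- clear-sky shortwave from the Haurwitz model `1098·cosZ·e^(−0.059/cosZ)`,
  zero at night; K↑ = 0.20·K↓ (campus-mean ground albedo); direct-beam
  fraction 0.85 for Z < 80°, tapered linearly to 0 at 90°, stored as 0 when
  K↓ = 0;
- longwave: L↓ = 0.75·σT_a⁴ (clear sky), L↑ from a surface running up to
  8 °C above air temperature in proportion to normalized insolation;
- solar geometry from the NOAA/Meeus simplified algorithm (cross-checked in
  the tests against an independent Michalsky implementation to ≤ 0.5°).

**Scenarios.** Each albedo scenario differs from baseline *only* by an air
cooling ΔT_a(h) proportional to the normalized baseline shortwave, with peak
values 0.9 / 1.25 / 1.6 °C for low / moderate / high — midday-peaked, zero
at night, matching the pattern that brightened surfaces cool most when the
sun loads them. Humidity, wind and radiation fields are held at baseline;
this isolates the temperature pathway and keeps the scenario contract
(T_a baseline ≥ low ≥ moderate ≥ high at every hour) exact.

**What a green test does not establish.** The generator has no synoptic
variability, no fog events, no weekend/weekday structure, no feedback from
albedo onto radiation or humidity, and identical solar geometry at all
locations. Green tests establish that the *method* — solvers, branch rules,
aggregation, orderings — is correct on a world with the stated shape, not
that any particular site will realize particular gained-hours values.

## Surface albedo stage

Broadband albedo = Σ_b w_b·ρ_b + c over bands B2, B3, B4, B8, B11, B12.
The default weights are the Sentinel-2 narrow-to-broadband set of Bonafoni &
Sekertekin (2020) (they sum to 1, offset 0), shipped as JSON config with
provenance so a Landsat set can be swapped in. Values above 1 (sensor
noise, highly reflective roofs) are set to exactly 1; negatives, which the
cited rule does not mention, are symmetrically clipped to 0 for physical
validity. Cloud masking is accepted as a precomputed score grid thresholded
at 0.60 (configurable); the scoring product itself is external. Campus
summaries are unweighted statistics over valid in-boundary pixels. Scenario
rasters assign each integer-coded surface type its prescribed albedo
(monotone baseline ≤ low ≤ moderate ≤ high per type, enforced at table
construction); unknown codes are errors unless flagged passthrough, in
which case the baseline value is kept.

## Determinism

A run is a pure function of (config, seed): the campaign uses one
`numpy` generator seeded from the config, CSVs are written with a fixed
float format, and the manifest records the config hash, seed and package
version — rerunning a config byte-identically reproduces every artifact.

## Known limitations

- The Stull fit assumes sea-level pressure; no psychrometric wet bulb.
- The exact convective correlation and globe constants used in operational
  WBGT products vary; results are mildly sensitive to `h_c` at low wind.
- Overcast daytime hours are treated with the sun form (with whatever K↓
  and F the data carry) whenever K↓ > 25 W/m²; there is no separate
  overcast rule.
- Gained hours are reported per worker for all days of the month; no
  work-calendar weighting.
- The albedo stage carries no geo-referencing; rasters are plain grids and
  mixed-resolution area weighting is not performed.
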