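# Methods

`thawflux` computes an annual CH4 budget for thermokarst (thaw-subsidence)
lakes from point surveys of dissolved methane, and projects that budget
under lake-expansion and ice-phenology scenarios. This note documents the
model chain, its parameters and assumptions, the numerical choices, and
what the synthetic-survey tests do and do not demonstrate.

## Model chain

### 1. Headspace equilibration → dissolved concentration

A water sample (volume `V_w`, typically 0.4 L) is equilibrated in a syringe
with pure N2 (headspace `V_h`, typically 0.1 L); the headspace CH4 mixing
ratio is then measured. The dissolved concentration is recovered by

- ideal gas law: `n = P_m V_h / (R T_air)` with `P_m` the CH4 partial
  pressure in the headspace (mixing ratio × ambient pressure) and
  `R = 0.082057 L atm K⁻¹ mol⁻¹`;
- headspace concentration `C_h = n / V_h`;
- mass balance `C_w = (C_h V_h + S V_w) / V_w`, where `S` is the dissolved
  concentration in equilibrium with the headspace partial pressure at the
  equilibration temperature. The mass balance divides by `V_w` — the only
  dimensionally consistent form of the syringe budget.

Solubility uses the Wiesenburg & Guinasso (1979) Bunsen-coefficient fit at
salinity 0, the standard freshwater CH4 parameterization; it sits behind a
single function (`headspace.bunsen_solubility`) so an alternative fit can be
swapped in. The air-equilibrium concentration `C_eq` uses the same function
with the atmospheric mixing ratio (default 1.9 ppm, a plateau baseline-
observatory value; configurable via `GasConstants`). At plateau conditions
(≈0.6 atm, 1–10 °C) `C_eq` ≈ 0.0026 µmol/L — three orders of magnitude
below observed under-ice medians, so the diffusive gradient is effectively
`C_w` itself.

Replicate syringes from the same point are rows of the survey table; because
the mass balance is linear in `C_h`, averaging replicate concentrations after
conversion is identical to averaging the raw headspace readings first.

### 2. Gas transfer velocity

Thin-boundary-layer exchange with `K = (Sc/600)^(−x) · k600`:

- Schmidt number `Sc(T) = 1897.8 − 114.28 T + 3.2902 T² − 0.039061 T³`
  (T in °C), clamped to its calibration range [0, 30] °C with a warning —
  the cubic turns unphysical outside it;
- `k600` = arithmetic mean of three wind relations,
  `2.07 + 0.215 U10^1.7`, `0.45 U10^1.64` and `1.68 + 0.228 U10^2.2`
  (cm h⁻¹), averaging out the structural spread between single
  parameterizations;
- wind at measurement height Z brought to 10 m by the neutral log profile
  `U10 = U_z (1 + √C_d10/κ · ln(10/Z))` with `C_d10 = 0.0013`, `κ = 0.41`
  (standard neutral-atmosphere values);
- exponent `x = 0.66` for `U10 ≤ 3 m s⁻¹` (boundary inclusive), `0.5`
  above; K is continuous in everything else and normalized so that
  `K(Sc=600) ≡ k600`.

### 3. Open-water fluxes

Diffusion integrates the gradient over the ice-free season
(`n_ice_free` = 200 days by default):

```
F_diff [g m⁻²] = 10 · K[cm h⁻¹] · (C_w − C_eq)[µmol L⁻¹] · 24 · n_days · 16.04 × 10⁻⁶
```

The factor 10 converts cm h⁻¹ × µmol L⁻¹ to µmol m⁻² h⁻¹; the rest is hours
→ days → season and µmol → g. Undersaturation yields a negative (influx)
diffusion term, which propagates; ebullition is floored at zero in that case.

Ebullition is derived from the ebullition proportion `M` (bubble share of
total open-water emission): `F_eb = M F_diff / (1 − M)`, so the share
identity `F_eb/(F_diff+F_eb) = M` holds exactly. The default `M = 0.844` for
every vegetation class (the plateau-wide bubble share); a per-class table
can be supplied where class-resolved proportions are available.

Fluxes are computed per sampling point, then averaged (unweighted) to one
record per lake; the derived components (ebullition, storage partition) are
evaluated at the lake level. Computing ebullition before or after lake
averaging is equivalent because the relation is linear in `F_diff`.

### 4. Under-ice storage and the melt release

Dissolved CH4 accumulates beneath the ice; its melt-season release ("water
storage") is estimated from two diffusive windows:

```
F_water_storage = F_high · w_high + F_low · w_low
```

with `F_high` the daily flux at the end of the ice-covered season (late-
April concentrations and met) and `F_low` at the end of melting (early-May),
both windows 14 days by default (`PeriodCalendar`). Lakes not revisited in
early May get their end-of-melt concentration from a per-vegetation-class
OLS regression on the end-of-ice-covered concentration (predictions floored
at 0, provenance flagged). Fallbacks: classes with fewer than 3 training
pairs use the ratio estimator mean(y)/mean(x); classes with none use a
pooled regression across classes. For lakes without an early-May revisit the
end-of-melt transfer velocity and `C_eq` reuse the late-April met record —
the least-assumption choice given one met record per lake and window.

Ice-bubble storage is not directly observable. The partition model: per unit
of under-ice diffusive production, bubbling production is `M/(1−M)`; a
fraction (default 0.5) of the dissolved store is oxidized before release;
bubbles reaching the ice bottom split into re-dissolution (0.8, joining the
water store) and entrapment in ice (0.2, released directly at break-up).
Composing these gives

```
F_ice_bubble / F_water_storage = trap·M / (ox·(1 − (1−redis)·M)) = 2M/(5−M)
```

at the default fractions. The three fractions are parameters
(`StoragePartitionParams`) so their leverage on the budget can be examined;
`redis + trap = 1` is enforced. At `M = 0.844` the factor is 0.406, i.e. a
28.9% / 71.1% bubble/water split of the melt release. A stored column that
comes out undersaturated releases nothing (floored at 0).

### 5. Pathway classification

The apparent carbon fractionation factor
`α_C = (δ¹³C-CO2 + 1000)/(δ¹³C-CH4 + 1000)` diagnoses the methanogenic
pathway: `α_C > 1.055` CO2 reduction (hydrogenotrophic), `1.040–1.055`
acetate fermentation, `< 1.040` oxidation-dominated. Both boundary values
are assigned to the acetate class (the band read as closed); the choice is
covered by boundary tests and matters only for values printed at exactly
three decimals.

### 6. Regional upscaling

Monte-Carlo by vegetation class: per iteration, one lake is drawn with
replacement from the class pool and its component fluxes are multiplied by
the class's total thermokarst-lake area; emissions are reported as carbon
mass (Gg C yr⁻¹, factor 12/16.04). Sampling is lake-coherent — all four
components of an iteration come from the same lake — so per-iteration
annual totals are exactly the sum of their components. Default 1000
iterations, seeded.

Uncertainty is reported two ways, because "mean ± SE" over single-draw
iterations is ambiguous: the SD of iteration totals (the spread of the
sampled distribution, primary) and the pool SE (lake-flux SD/√n_lakes
propagated through the area, classes combined in quadrature). Users needing
an uncertainty of the *mean* should use the SE.

CO2 equivalence: `Gg C × (16.04/12) × GWP100`, default GWP100 = 27
(current-assessment fossil-free value; 27.2 and 28 accepted via
`GwpConfig`).

### 7. Scenario projection

The projection model is deliberately linear and explicit, because flux
densities are held at baseline: per vegetation class, each component scales
with `area(year)/area(baseline)` (`static_ice`), and in `dynamic_ice` mode
additionally the open-water component scales with
`n_ice_free(year)/n_ice_free(0)` and the melt component with
`n_ice_covered(year)/n_ice_covered(0)`, where the ice-covered duration
follows a linear trend (default −0.2 d yr⁻¹, the observed plateau lake-ice
decline, floored at 0) and each day lost from ice cover is added to the
open-water season. `dynamic_ice` with zero trend is exactly `static_ice`;
static projections are homogeneous of degree 1 in area. Baseline relative
uncertainties are carried through multiplicatively. Area trajectories are
inputs (e.g. from a lake-susceptibility model); this package does not
produce them, and no alternative reading of "with ice loss" (e.g. shifts in
flux density with warming) is modelled.

## Synthetic surveys

`synthetic.generate_survey` emulates the structure of a plateau field
campaign, not any particular deposited dataset:

- equal numbers of lakes per vegetation class (default 50, i.e. 200 lakes);
  3–6 sampling points per lake and period;
- lognormal concentrations: per-lake levels are bivariate lognormal across
  the (ice-covered, ice-free) periods with within-class log-scale
  correlation 0.6, plus multiplicative point noise (log-SD 0.3). Class
  medians are geometric multiples (4, 1.8, 1/1.8, 1/4) of the pooled
  medians 2.61 (ice-covered) and 0.88 µmol/L (ice-free); because the
  multipliers are geometrically symmetric and class counts and spreads are
  equal, the pooled medians equal the targets by construction rather than
  by tuning. Within-class log-SDs (1.5 under ice, 1.05 open water) are
  derived from the printed pooled concentration ranges (0.03–280 µmol/L
  over n=151; 0.01–40 over n=353) via the expected extremes of a lognormal
  sample, minus the between-class median spread;
- end-of-melt levels at a median 0.35 of the under-ice level; 60% of lakes
  carry measured end-melt points, the rest exercise the interpolation path;
- isotopes: δ¹³C-CH4 ~ N(−57.9‰, 8‰), and δ¹³C-CO2 constructed from a
  target α_C ~ N(1.045, 0.012) so the classification thresholds are
  straddled;
- met forcing: wind lognormal (median 3 m s⁻¹ at 2 m), period-specific
  water/air temperatures, pressure ≈ 0.6 atm; lake areas log-uniform on
  373–648,966 m² (most lakes small);
- dissolved concentrations are generated first and inverted through the
  headspace mass balance into syringe mixing ratios, so the written CSV read
  back through the full concentration pipeline reproduces the generated
  values to machine precision.

What the generator does **not** emulate: spatial structure, depth profiles,
met-station assignment, class-specific ebullition proportions, or the
joint concentration–met dependence of real lakes. Its per-class area table
(ASM 180, AM 2200, AS 350, AD 95 km², summing to the 2825 km² plateau
inventory) is a plausible split, not an observed one. Consequently a
pipeline run on synthetic data reproduces the *structure* of the published
budget (component shares driven by M and the partition model, class ranking)
but not its absolute totals or the melt-season share, which depend on the
true joint flux distribution. Passing synthetic tests demonstrates that the
machinery is correct and unbiased, not that the field numbers are
reproduced.

`generate_known_truth` is the recovery harness: constant per-class
concentrations and met make the per-class flux densities closed-form, so the
regional truth is `Σ density × area`. Noise-free surveys must be recovered
exactly; lognormal noise is mean-one (σ²/2 correction) so noisy recovery is
unbiased and tested within 3 Monte-Carlo SDs.

## Numerical and design choices

- Validation policy: invalid survey rows are reported with row numbers and
  either skipped (`partial`) or fatal (`strict`); nothing is dropped
  silently. Lake areas pass a plausibility window (default 10–10⁷ m²).
- Period calendar: ice-covered November–April, ice-free May–October, melt
  windows in late April / early May; all durations configurable.
- The Schmidt-number clamp, the ebullition floor, the storage floor and the
  interpolation floor are the only non-linearities added to the printed
  model chain; each is logged or flagged in output.
- Determinism: one integer seed drives each stochastic stage
  (`numpy.random.default_rng`); rerunning a config byte-reproduces the
  numeric outputs.
- Problem sizes in the shipped tests (200-lake surveys, 10³–10⁴ Monte-Carlo
  iterations) match the study conditions while keeping a full suite run in
  a few seconds.

## Known limitations

- Ebullition and ice-bubble storage are *derived* quantities (from M and the
  partition fractions), not measurements; all four components inherit any
  bias in M.
- The oxidation/re-dissolution/entrapment fractions are literature point
  values; the package exposes them as parameters but ships no calibration.
- Vertical concentration structure under ice is ignored (single sampling
  depth), as is lake-to-lake variation in ice phenology.
- The scenario model holds flux densities at baseline; warming-driven
  changes in production, oxidation or pathway are out of scope.
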