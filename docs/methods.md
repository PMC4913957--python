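# Methods

## Scope and model structure

`droughtfire` implements the water-balance subset of a monthly, process-based
forest model (the 3-PG family) and the classification machinery needed to
relate simulated soil-water depletion to 1-km fire occurrence. It deliberately
excludes growth: no photosynthesis/NPP accounting, no carbon allocation,
mortality or annual LAI dynamics. `LAI_max` and `ASW_max` are static pixel
attributes; the soil fertility rating `S_f` is carried in site parameters for
interface completeness but drives nothing.

## Water balance

Each month the store updates as `ASW ← clamp(ASW + P − E − T, 0, ASW_max)`,
with overflow above `ASW_max` counted as runoff/drainage and `T` limited to
the water actually present (`ASW + P − E`), so the store never goes negative —
the model is silent on within-month exhaustion, and this is the conservative
closure. Mass closes exactly: `ΣP − ΣE − ΣT − Σrunoff` equals the change in
stored water (soil + snow); the tests require a residual below 10⁻⁶·ΣP.

**Stomatal modifiers** (each in [0, 1], multiplied into canopy conductance):

- *Temperature*: the standard form
  `((T−Tn)/(To−Tn)) · ((Tx−T)/(Tx−To))^((Tx−To)/(To−Tn))` with defaults
  `(Tn, To, Tx) = (−7, 18, 40) °C`, zero outside `(Tn, Tx)` and forced to
  zero below −2 °C where stomata close outright. Note that under this form
  the response at the nominal 0–35 °C "broad viability" window endpoints is
  0.474 (at 0 °C) and 0.456 (at 35 °C) — slightly below one half of maximum;
  we report the values rather than asserting a 50 % property.
- *Soil water*: `fASW = 1 / (1 + ((1 − r)/c_θ)^{n_θ})`, `r = ASW/ASW_max`,
  with per-texture constants in one table: sand (0.7, 9), sandy loam
  (0.6, 7), clay loam (0.5, 5), clay (0.4, 3) — the conventional 3-PG values.
  At an empty store this gives 0.039 (sand) up to 0.060 (clay).
- *VPD*: `exp(−k_D·D)` with `k_D = 0.05 mbar⁻¹` (configurable).
- *Frost*: `1 − frost_days / days_in_month` — each subfreezing day closes
  stomata for about a day.

**Derived forcing.** Daytime vapor pressure deficit assumes ambient vapor
equals saturation at the mean minimum temperature: `VPD_max = e_s(Tmax) −
e_s(Tmin)` with a Tetens-type `e_s(T) = 6.1078·exp(17.269·T/(237.3+T))` mbar
(the single place the SVP form lives), and mean daytime VPD is two thirds of
the maximum. Frost days per month use a logistic in `(2 − Tmin)` with rate
1 °C⁻¹, half-saturating at the 2 °C subfreezing threshold and saturating at
the month length; the true empirical curves behind such estimates are not
published, and any monotone saturating form preserves the model behavior —
this one is a documented stand-in.

**Transpiration** comes from the Penman–Monteith combination equation with
canopy conductance `g_c = 0.006 m s⁻¹ · min(LAI, 5) · f_T f_D f_F f_SW`,
boundary-layer conductance 0.2 m s⁻¹, net radiation `−90 + 0.8·SW` W m⁻²
over a 12-h daylight window, `ρ = 1.2 kg m⁻³`, `λ = 2.46 MJ kg⁻¹` and a
slope-to-psychrometric ratio of 2.2 (values near 20 °C). The result is
additionally capped at an LAI-dependent ceiling — `3.0·min(LAI/5, 1)`
mm day⁻¹ — reflecting the observed sap-flux plateau in dense canopies; the
cap makes the plateau behavior independent of the PM parameter choices.
Canopy interception evaporates `0.15·min(LAI/5, 1)` of rainfall.

**Snow** is a deliberate crudity: months with sub-zero mean temperature bank
their precipitation in a carry-over store released in the first
above-freezing month. A monthly model cannot track accumulation and melt
dates; the store only prevents winter precipitation in cold climates from
being counted as liquid recharge in the wrong month.

**Reported fASW** for a month evaluates the soil-water modifier at the mean
of the start- and end-of-month store — a mid-month value, since nothing pins
the seasonal averages to start- or end-of-month states.

**Initialization**: simulations start at field capacity and the first
simulated year is treated as spin-up; fire-year features reach back to
December two calendar years before the fire year, so a scene needs
`n_years ≥ n_fire_years + 2`.

## ASW_max inversion

`invert_asw_max` recovers the water holding capacity from an observed
`LAI_max` under a given climate, on the premise that canopies grow to the
largest leaf area their water supply can support. The support criterion is
the fraction of *unrestricted* growing-season (April–September)
transpiration demand the site can actually meet — realized transpiration
divided by the transpiration the same canopy would achieve with no
soil-water restriction — which must equal a threshold (default 0.5). This
ratio is monotone in `ASW_max` (a larger store carries more wet-season water
into the dry season), so bisection over [10, 1000] mm suffices. A criterion
defined directly on the mean growing-season soil-water *modifier* is not
usable here: the modifier depends on the stored fraction, and a tiny store
refilled by any rain event looks fractionally healthy even though water is
scarce, making that mean non-monotone in `ASW_max` at small stores. Under
wet climates the estimate pins at the lower search bound (`ASW_max` is
unidentifiable where water never limits — the honest answer); if even the
upper bound cannot support the observed LAI the routine raises instead of
extrapolating.

## Seasonal features and the four-rule classifier

Monthly fASW is averaged into winter (December of the preceding calendar
year + January–February), spring (MAM), summer (JJA) and autumn (SON) for
the fire year and the previous year. Missing months are a hard error — no
imputation.

The fixed classifier evaluates four rules in order; the first match predicts
fire:

1. severe summer drought (`summer < 0.12`) + sub-favorable previous spring +
   droughty current fall;
2. moderate but not severe summer drought (`0.12 ≤ summer < 0.30`) +
   droughty previous fall *and* winter;
3. severe summer drought + droughty previous fall + favorable previous
   winter (a wet winter grows flash fuel that cures the next summer);
4. severe summer drought + favorable previous spring (same flash-fuel
   mechanism, one season later).

Only the severe-summer value (0.12) is an empirically identified threshold.
"Moderate" (0.30), "droughty" (0.40) and "favorable" (0.60) are qualitative
levels with no published numbers; the defaults are ordered stand-ins and all
four are configuration values.

Note the rule system is *not* globally monotone in dryness: rules 3 and 4
require *favorable* antecedent seasons, so drying the previous spring can
remove the rule-4 pathway without another rule catching the case. That is a
feature of the fuel-production mechanism, not a defect; monotonicity holds
(and is property-tested) for the fall features, whose predicates are all
drought-directional.

## CART inducer

Greedy binary recursive partitioning minimizing Gini impurity; candidate
thresholds are midpoints between adjacent distinct observed values, each
child must retain `min_node` samples (default 20), ties break to the lowest
feature index then the smallest threshold. A midpoint is only admitted if it
strictly separates its neighbors, guarding against floating-point collapse
when adjacent values differ by one ulp. Pruning is cost-complexity: the
weakest-link alpha sequence is computed from the full tree, candidate alphas
(geometric midpoints) are scored by stratified k-fold cross-validation
(default 10, seeded), and the selected subtree is the smallest within one
standard error of the CV minimum, with the SE of the CV estimate taken from
the fold-to-fold spread (`sd(fold means)/√k`). On label-permuted data this
procedure discards nearly all grown structure (typically 50–70 % of seeds
collapse to a single leaf; the rest keep a handful of leaves) — comparable
to, and somewhat more conservative than, reference CART implementations
under the same selection rule.

Each surviving internal node carries up to five surrogate splits: splits on
other features ranked by their agreement with the primary split's routing,
admitted only if they beat the blind majority-direction rule. Surrogates
route observations with missing values at prediction time (an all-missing
vector is an error) and feed variable importance: each feature accumulates
the sample-weighted Gini improvement of every node where it is primary plus
the improvement its surrogate split achieves where it is not, scaled so the
best feature scores 100. A feature can therefore rank highly without ever
splitting a node. Unpruned trees can form chains of depth ~n/min_node, so
the inducer raises the interpreter recursion limit accordingly (growth and
pruning use one stack frame per level).

The inducer is implemented here in full (it is the scientific core of the
package); scikit-learn's tree is used in the test suite only as an
independent cross-check of the root split on clean data.

## Hotspot processing

A fire detection survives filtering iff its centered 3×3 km window (cropped
at grid edges) contains at least two detections — single-pixel (=100 ha)
anomalies with no companion are treated as registration noise. The filter
never creates detections and is *not* idempotent: removing a pixel can
isolate its former companion. Balanced evaluation samples pair every
retained fire pixel with a uniformly drawn forest pixel that is fire-free in
the sampled year and in all other reference years.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
any particular real landscape. Climate regimes are sinusoidal monthly cycles
plus seeded noise (lognormal multiplicative on precipitation, σ = 0.3;
additive Gaussian on temperature, σ = 1.5 °C; lognormal σ = 0.1 on
radiation): a Mediterranean regime (800 mm yr⁻¹, winter-peaked, < 15 % of
annual precipitation in June–August), a continental summer-rain regime
(500 mm yr⁻¹, summer-peaked, colder winters) and a wet maritime regime
(2,500 mm yr⁻¹) in which the water balance essentially never limits and the
rules predict almost no fire. Scenes split pixels between regimes, scale
per-pixel annual precipitation by U(0.55, 1.45), draw `LAI_max` from
U(0.5, 6.0) and `ASW_max` from an equal mixture of shallow U(50, 100) mm and
deep U(200, 400) mm stores (drought vulnerability concentrates on shallow
soils), simulate fASW, label pixel-years with the four rules, and flip a
configurable fraction of labels (default 5 %) as detection noise. Everything
is a pure function of (parameters, seed).

What passing tests on these scenes demonstrate: the pipeline is internally
consistent (labels re-derive from features), the inducer recovers the
generating thresholds and importance ordering under label noise, and the
filter/sampling/evaluation stages behave exactly as specified. What they do
not demonstrate: predictive skill on real fire data — real hotspots carry
spatial autocorrelation, ignition and suppression processes, fuel loads and
observation biases that the generator does not model, and real-data
accuracies are far below the near-perfect figures rule-generated scenes
produce.

## Problem sizes and numerics

The threshold-recovery analyses use 20,000 pixel-years (a 100×100 scene with
two fire years), chosen as comfortably sufficient for the root threshold to
stabilize within ±0.02 of the generating value across seeds. Bisection
tolerances: 10⁻³ (LAI) and 0.5 mm (`ASW_max`). Water-balance closure is
tested to 10⁻⁶·ΣP. Degenerate inputs fail loudly: inverted temperature
extremes, gaps in monthly series, misordered rule thresholds, single-class
training data (degenerate single-leaf tree with a warning), zero fire
predictions in rule-usage percentages, and misaligned grids all raise.

## Known limitations

- Monthly resolution cannot represent within-month storm/drought sequencing
  or realistic snow dynamics.
- `E` is canopy interception only; soil evaporation is not modelled.
- Three of the four rule thresholds are stand-ins; analyses that depend on
  their exact values should treat them as free configuration.
- The CART inducer targets the described behavior (Gini growth, CV-pruned,
  surrogate importance), not bug-for-bug compatibility with any commercial
  tree package.
- Grid I/O is plain-text ASCII grid; coordinate reference systems are the
  caller's responsibility.
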