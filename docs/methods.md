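# Methods

`nestheat` implements the analysis chain used to link air temperature to
incubation behaviour, adult physiology and hatching success in a hot-climate,
cooperatively breeding bird: doubly-labelled-water (DLW) energetics and water
balance, black-bulb nest microclimate processing, incubation time budgets,
and the statistical layer (AICc selection, logistic thresholds, segmented
regression, simulation-based power). A synthetic-data generator with known
ground truth stands in for field data, so every estimator can be scored for
parameter recovery.

## DLW isotope kinetics

Single-pool, single-sample model. After dosing, each isotope's enrichment
above background decays exponentially, `δ(t) − δ_bg = A e^{−kt}`, with the
oxygen pool turning over faster than the hydrogen pool because CO2
production removes oxygen on top of water efflux. The chain:

- `kH = [ln(δ²H_i) − ln(δ²H_f)] / t` and
  `kO − kH = [ln(δ¹⁸O_i/δ²H_i) − ln(δ¹⁸O_f/δ²H_f)] / t`, both on
  **background-corrected** enrichments. Logs of raw δ values are not
  dose-invariant, and the ratio `δ¹⁸O/δ²H` decays as a clean exponential
  only after per-isotope background subtraction; a raw mode exists for
  comparison (`background=None`).
- `rCO2 = (N/2.078)(kO − kH) − 0.0062·kH·N` mol/d, with `N` the body-water
  pool in moles. The pool is 69.3% of body mass by default (measured total
  body water for this taxon); the mean of the two dawn masses is used.
- `rCO2` converts at 22.4 L/mol and 27.42 kJ/L (insectivorous diet) to give
  daily energy expenditure (DEE), reported per gram.
- Water efflux (mL H2O kg⁻¹ d⁻¹) uses the isotope-dilution flux equation
  for a changing pool. As commonly transcribed, the denominator term
  `[1 − W2/W1]` yields *negative* efflux whenever enrichment declines; the
  implementation uses `[W2/W1 − 1]`, which satisfies the physical
  positivity contract and reproduces the analytic constant-pool limit
  `efflux = 1000·kH·W/M` exactly. "log" is read as the natural log. When
  `|1 − W2/W1| < 1e−6` the constant-pool limit (mean pool) is used to avoid
  0/0. Influx adds the net pool change; balance = influx/efflux (>1
  hydrated). `H1 = H2` with a constant pool is defined as balance 1.0.
- Metabolic water production = DEE[kJ/g/d] × 27 mg/kJ × mass / 1000, in
  g/d; a deficit between a cool-day reference and hot-day observed MWP is
  converted to whole prey items at 0.2 g and 56% water per item.
- Because `rCO2` is linear in `N`, a relative error in the assumed
  body-water fraction propagates to exactly the same relative error in
  DEE; `dee_body_water_sensitivity` verifies this by recomputing the whole
  chain. The relative reading (fraction × 1.03) is implemented — it is the
  one that produces the classic "about 3%" DEE shift; an absolute
  3-percentage-point reading would give ≈ 4.3%.
- The "maximally enriched early sample" is the maximum δ²H inside an early
  window, defaulting to the larger of 3 h post-dose and the first 25% of
  the sampled span (ties go to the earliest sample); the final sample is
  the last post-dose one. Negative `rCO2` (fractionation term exceeding
  the signal) is returned flagged, not dropped — filtering policy belongs
  to the caller.

## Thermal environment

- Logger calibration: least-squares line mapping logger to reference
  water-bath temperature; requires ≥ 3 pairs spanning ≥ 10 °C.
- Absolute humidity from the Magnus saturation vapour-pressure
  approximation over water (coefficients 17.27, 237.7 °C; 610.94 Pa) and
  the ideal-gas law with R_v = 461.5 J kg⁻¹ K⁻¹ — accurate to well under
  1% in the −20…60 °C range.
- Daily summaries: per-day maxima of air temperature, solar and wind;
  absolute humidity evaluated at the first timestamp achieving the daily
  maximum (tie-break documented, first occurrence); antecedent rain summed
  over a fixed 61-day window ending the day before (calendar-month
  arithmetic is date-dependent; a fixed window is reproducible).
- Te/weather alignment: daytime window 06h00–19h00 inclusive
  (configurable), nearest-neighbour pairing within 5 min — half the
  nominal 10-min logging interval, so pairing on-grid is unambiguous.
  Unpaired records are dropped with a logged count.
- Exceedance statistics count records strictly above each threshold
  (defaults 41 and 50 °C, embryo-risk temperatures) per nest, with fleet
  summaries.

## Incubation behaviour

A nest-day is a sequence of attended (bout) and unattended (recess)
intervals. Validation sorts the series, rejects overlaps (1 s slack for
rounding), reports gaps against the observation window and can coerce gaps
to synthetic recesses. Attendance = summed bout time over the window; its
complement, the recess count and an any-recess flag feed the temperature
models. Observation windows are stored per nest-day (dawn start varies);
no minimum recess duration is imposed. Focal time budgets are summed
per-label durations over total observed time per bird-day.

## Statistics

- Predictors are centred and scaled; the transform is stored and
  invertible so thresholds can be mapped back to °C.
- Collinearity: VIF from auxiliary regressions; predictors with VIF > 2
  may not share an additive model; maximal admissible subsets are
  enumerated (designs here have ≤ ~6 predictors).
- GLMs are fixed-effects only: gaussian-identity by OLS, binomial-logit by
  IRLS (statsmodels backends). Random effects for nest/individual identity
  are deliberately out of scope; the Pearson χ²/df dispersion check
  (flagged above 1.5) surfaces the overdispersion an observation-level
  random effect would absorb. Wald 95% CIs (±1.96 SE) throughout. For
  gaussian models `k` counts the residual variance.
- AICc = −2logL + 2k + 2k(k+1)/(n−k−1); Akaike weights
  `w_i ∝ exp(−Δ_i/2)`; candidates must share identical rows. Averaging is
  *full* (zero-substitution) over the ΔAICc < 2 set — the conservative
  default where conditional vs. full averaging is not specified.
- Logistic threshold: solve `logit(p) = β0 + β1 z` and back-transform; the
  default p = 0.5 gives the covariate value at which the outcome becomes
  less likely than not.
- Segmented regression: two *independent* OLS segments (continuity not
  enforced, matching separate above/below models), breakpoint searched on
  a 0.01-unit grid with ≥ 10 points per side, minimizing total RSS
  computed in O(n) via prefix sums. RSS is piecewise constant between data
  points, so tying grid candidates are resolved by their midpoint. The
  95% CI is a case-resampling percentile bootstrap (default 1000 reps,
  seeded), widened if needed to contain the point estimate; a CI wider
  than 80% of the covariate range is flagged uninformative.
- Power: Monte-Carlo rejection rates in a main-effect + centred-binary
  interaction OLS design with t-based Wald tests; with zero effect this
  reproduces the nominal type-I error, and an interaction of equal
  magnitude always has lower power than the main effect because the
  product term has one quarter the variance.

## Synthetic data

The generator emulates the study conditions rather than any particular
dataset:

- **Washout**: kH ~ N(0.45, 0.05) d⁻¹ and kO − kH ~ N(0.08, 0.012) d⁻¹,
  magnitudes that put DEE in the observed 0.6–2.9 kJ g⁻¹ d⁻¹ envelope;
  dose excesses 1000/1200 ‰; independent Gaussian per-mil noise (default
  5 ‰) on six samples over one day plus a flagged pre-dose background.
- **Weather**: daily maxima truncated-normal around 34.1 ± 4.5 °C within
  the observed 20.7–40.8 °C range (the pre-truncation location is solved
  numerically so the *realized* mean matches 34.1 despite the asymmetric
  truncation), a ±3 °C seasonal sinusoid, a diel cosine peaking at 15h00,
  RH inversely coupled to temperature, half-sine solar, and whole-day rain
  events. The seasonal spread makes between-nest incubation-period mean
  temperatures spread with sd ≈ 2 °C, so the default hatch slope of
  −0.45 °C⁻¹ corresponds to ≈ −0.9 per SD on the standardized scale —
  consistent with the reported field estimate.
- **Nest Te**: `Te = 0.5 + 1.207·Tair + nest offset + noise`, clipped so
  daytime Te ≥ Tair; per-nest offsets (sd 4 °C) emulate the large
  between-nest microsite spread. Logger raw values are the true values
  passed backwards through a linear miscalibration whose noise-free
  water-bath pairs are also emitted, so calibration round-trips exactly
  and exceedance bookkeeping is exact. Logger measurement error is
  representable through the Te noise term instead.
- **Breeding**: hatching is Bernoulli with
  `p = logistic(−0.45·(MeanTmaxInc − 35.3))`; attendance is a day-level
  logit-normal proportion declining with Tmax, carved into contiguous
  bouts and a Poisson number of recesses at Dirichlet positions (so
  attendance metrics recover the day proportion to float precision);
  overnight mass change is zero-mean below 36.1 °C and declines at
  −1.016 g °C⁻¹ above it, residual sd 2.0 g.
- Every output is a pure function of (config, seed); stage streams are
  spawned from one `SeedSequence`.

What the generator does *not* emulate: temperature dependence of DEE and
water flux (turnover rates are drawn independently of weather, so
pipeline-level hot/cool energetic contrasts are null by construction),
analytical-replicate structure in isotope noise, autocorrelated weather
beyond the seasonal sinusoid, nest predation, and any random-effect
grouping structure. Passing tests therefore demonstrate correctness of the
estimators under their own assumptions, not field realism of every
covariance.

## Problem sizes and numerical choices

Tests run the generator at reduced scale (e.g. 8–23 nests, 40–120 weather
days, 20–200 dosed birds) chosen so each check is sharp at desk scale;
recovery studies use 200 replicates (hatch threshold at 500 nests;
breakpoint coverage at n = 119 with 1000 bootstrap reps). Endpoint
selection tie-breaks, the constant-pool switch (1e−6 relative pool
change), the 30 s minimum for carving a recess, and the 1 s bout
contiguity slack are all documented in the relevant docstrings.

## Known limitations

- Fixed-effects substitutes for mixed models shift some uncertainty from
  standard errors into the dispersion diagnostic; grouped data with strong
  nest/individual effects will show it there.
- The breakpoint bootstrap resamples cases, ignoring any grouping.
- The prey-equivalent deficit computed by the pipeline on default
  simulations is ≈ 0 because simulated DEE is temperature-independent
  (see above); the function itself is exercised against known inputs.
- Two-pool DLW models, plateau body-water estimation and isotope-analyser
  drift correction are out of scope.
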