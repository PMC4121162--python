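# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `octogrowth`, and what the synthetic-data tests do
and do not establish about real field data.

## The analysis in outline

A cohort of wild-caught octopuses is processed in five stages:

1. **Preservation correction.** Whole animals are stored frozen or in 80%
   ethanol before weighing, which changes tissue weight. A paired
   experiment (the same tissue weighed fresh and again after preservation)
   supports a paired t-test per treatment; only when that test is
   significant (α = 0.05, configurable) is a correction applied, mapping
   preserved weight to a fresh equivalent through a Model II linear
   regression with fresh weight as the response. Model II is appropriate
   because both weighings carry error; we use the standardized major axis
   (SMA) variant, slope = sign(r)·s_y/s_x, the common choice in allometry,
   with major-axis regression available behind `method="ma"`. The SMA slope
   is symmetric under axis exchange (slope(x,y) = 1/slope(y,x)), which the
   tests exercise.
2. **Ageing.** Each stylet section carries three increment counts (two by
   one reader, one by a second). A section is discarded if its increments
   are unreadable, if more than 10% of the section could not be counted, or
   if the counts disagree by more than 10%; the gates are applied in that
   order and the first triggered is reported. "Disagree by more than 10%"
   is operationalized as (max − min)/mean > 0.10; since the denominator is
   not uniquely determined by the verbal rule, a pairwise-maximum
   alternative is available via `denominator="pairwise_max"`. Accepted age
   is the arithmetic mean of the three counts, with one increment per day
   assumed (no offset for pre-deposition days). Hatch date is capture date
   minus the age rounded half-away-from-zero to whole days — the unrounded
   age is kept for model fitting — and hatch season is the warm
   (December–May) or cool (June–November) class of the hatch month.
3. **Growth-curve fitting.** Mantle weight at age is fitted under four
   candidate models (Gompertz, exponential, power, linear) by weighted
   least squares. Size-at-age scatter fans out roughly in proportion to
   size, so the default error model is constant-CV: weights wᵢ = 1/m̂ᵢ²,
   iteratively reweighted from the current fit until the parameters move by
   less than 1e-10 relative (at most 6 rounds). A fixed data-based scheme
   (wᵢ = 1/mᵢ², `"data_sq"`) and an unweighted scheme are also available.
4. **Model selection.** AIC in the least-squares form n·ln(RSSw/n) + 2(k+1),
   counting the error variance as a parameter; Akaike weights are computed
   after subtracting the minimum AIC so extreme gaps underflow to an exact
   zero weight rather than NaN. Any consistent AIC convention yields the
   same weights within a candidate set of common n; absolute AIC magnitudes
   are convention-dependent and should not be compared across software.
5. **Inference.** 95% confidence intervals come from a case-resampling
   percentile bootstrap (pairs resampled with replacement, refit
   warm-started at the point estimate; failed refits are counted and, above
   20%, warned about or — in strict mode — escalated). Between-group curve
   differences use the ARSS F-test; size/age at maturity contrasts use a
   two-way fixed-effects ANOVA with Type II sums of squares (robust to the
   unbalanced designs these collections produce), with the response passed
   through a Box–Cox transform only when a Shapiro–Wilk check (α = 0.05)
   rejects normality. The Box–Cox λ is chosen by profile likelihood on the
   grid [−2, 2] in steps of 0.01.

## Weighting in comparisons and AIC tables

Akaike weights and the ARSS test are only meaningful when every fit
minimises the same objective. Iterative reweighting gives each model its
own final weights, which breaks both the cross-model comparability of
weighted RSS and the nesting guarantee RSS_separate ≤ RSS_pooled. The
pipeline therefore uses the fixed data-based weights (1/mᵢ²) for the
multimodel AIC matrix and for all pooled-vs-separate comparisons, and the
IRLS scheme for final single-model parameter estimates. `arss_compare`
refuses IRLS weighting outright.

## ARSS degrees of freedom

For a k-parameter model and K groups with N observations in total, the
primary convention is df_num = k(K−1), df_den = N − kK (each group consumes
k parameters under the alternative). An alternative denominator N − k
appears in some applied work; it is computed and reported alongside
(`df_den_alt`, `p_value_alt`) so either reading can be checked, but the
primary p-value uses N − kK.

## Gompertz numerics

Fitting uses `scipy.optimize.least_squares` (trust-region reflective) with
analytic Jacobians, in the (m∞, γ, g₁) parameterization, which is
numerically better behaved than the location-parameter form (predicted
weights at the observed age extremes); the location parameters m₁, m₂ and
the inflection weight μ = m∞/e are exact reparameterizations reported from
the fitted triple. Starting values: m∞⁰ = 1.2·max(m); g₁⁰ from the slope of
ln m against age over the youngest third of the data; γ⁰ = ln(m∞⁰/m(a_min))
capped to [0.5, 50]. On failure, up to 5 restarts with lognormal jitter
(fixed restart seed 12345). Upper bounds (m∞ ≤ 10⁶ g, γ ≤ 10⁴, g₁ ≤ 10/day)
are far outside any biologically possible octopus and exist solely so that
data with no asymptote — for which the Gompertz degenerates towards its
exponential limit, m∞ and γ diverging jointly — terminate at the bound
instead of iterating forever along a flat ridge; a scaled-gradient check
additionally accepts ridge solutions whose objective is stationary. A fit
that converges at those bounds loses to the exponential model on AIC, which
is the correct outcome.

Degenerate inputs: paired t-tests with zero-variance differences return the
limits (0, 1) for identical pairs and (±∞, 0) otherwise; SMA with zero
variance in either axis, or r = 0, is an error; a constant ANOVA response
reports F = 0, p = 1 rather than 0/0.

## The synthetic cohort generator

`octogrowth.synth` emulates the study conditions the pipeline was designed
around, and its defaults are fixed accordingly:

* **n = 527** specimens, true ages uniform on **85–313 days**.
* **Seasonal Gompertz truths** (asymptote m∞ = e·μ): warm-hatched
  (157.39 g, γ = 10.15, g₁ = 0.016/day), cool-hatched (165.98 g, γ = 12.20,
  g₁ = 0.015/day) — inflection weights ≈ 58 and 61 g. With the default 15%
  constant-CV lognormal size noise this yields mantle weights spanning
  roughly 3–210 g.
* **Hatch months** drawn from a cool-season-peaked distribution (mode
  September) with a secondary January peak.
* **Reader counts**: three independent lognormal draws around true age with
  CV 0.05; **uncountable fraction** ~ Beta(0.6, 4.5); **unreadable
  sections** with probability 0.02. Calibration: CV 0.05 alone sends ≈33%
  of sections past the 10% disagreement rule and Beta(0.6, 4.5) puts ≈41%
  past the 10% uncountable rule, for a combined discard fraction of ≈0.60 —
  matching the ≈59% discard rate such three-reader protocols produce at
  study scale. The discard rate is emergent from these noise laws, not
  imposed per specimen.
* **Preservation**: 20% fresh / 50% frozen / 30% ethanol, with
  multiplicative shrinkage 0.95 (frozen) and 0.85 (ethanol) plus 1% noise;
  the paired experiment has 100 frozen and 86 ethanol pairs.
* **Environment**: 24 months of sinusoidal SST (February peak, austral)
  with anti-phase Chl-a.
* Recorded weights are quantized to 0.01 g and counts to 0.1 day, the
  precision of the lab protocol; zero-noise parameter recovery is therefore
  exact only to that quantization (~5e-3 relative), while recovery from
  unquantized arrays is tested to 1e-6.

All draws come from one `numpy` generator seeded once, consumed in a fixed
documented order, so cohorts are bit-reproducible across platforms.

What the generator does **not** emulate: age-dependent capture selectivity,
natural mortality thinning older cohorts, sex-specific growth truths,
month-gapped sampling effort, and any SST/Chl-a influence on individual
growth (the environmental series is generated but exerts no causal effect
on simulated sizes). Passing tests therefore establish that the estimators
are correct and well calibrated under the assumed error structure — not
that real stylet data satisfy that structure.

## Validation harness sizes

The statistical acceptance checks (in `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: 100 replicate cohorts of n = 200 with 200
bootstrap resamples each for g₁ coverage/bias; 500 null replicates of two
n = 100 groups for the ARSS size and p-value uniformity; 100 replicates for
model-selection reliability (with a faster truth, g₁ = 0.03/day, so the
asymptote is reached inside the observed ages — the regime where the
sigmoid is identifiable); and one 10 000-animal cohort for the QC discard
fraction. These sizes give Monte-Carlo standard errors comfortably inside
the asserted bands (e.g. ±1% on a 5% rejection rate over 500 replicates)
while keeping the whole suite at a few minutes on one CPU.

## Known limitations

* The ageing model assumes exactly daily increment deposition and no
  pre-deposition lag; any systematic deviation biases ages and hatch dates
  together.
* The preservation correction is a single time-independent linear map per
  treatment; storage-duration effects are not modelled.
* Percentile bootstrap intervals (not BCa) are reported; for strongly
  skewed estimators at small n they can undercover slightly.
* Reader noise on counts enters the fits as error in the age axis, which
  weighted least squares does not model; at the calibrated CV (≈3% on the
  mean of three counts) the induced bias in g₁ is below 1%, measured by the
  recovery harness.
* The two-way ANOVA treats factors as fixed effects; no post-hoc multiple
  comparisons are provided.
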