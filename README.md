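# octogrowth

Age, growth-curve and cohort analysis for stylet-aged octopus populations.

Octopuses (and cephalopods generally) are aged by counting daily growth
increments in hard structures — for octopods, transverse sections of the
stylet, the vestigial internal shell. Given a year of specimen records
(weights, capture dates, sex, maturity, preservation state), three increment
counts per animal, a paired fresh-vs-preserved tissue-weight experiment and a
monthly SST/Chl-a series, `octogrowth` produces:

* **fresh-weight equivalents** for frozen / ethanol-preserved specimens
  (paired t-test gate + standardized major axis "Model II" regression);
* **quality-controlled ages**: a section is discarded when increments are
  unreadable, when >10% of the section cannot be counted, or when the three
  counts disagree by >10%; otherwise age = mean of the counts (one increment
  per day);
* **hatch dates and seasons** by back-calculation (capture date − age), with
  an austral warm season December–May and cool season June–November;
* **growth-curve fits** of mantle weight `m` (g) at age `a` (days) under four
  candidate models, selected by AIC / Akaike weight, with case-resampling
  bootstrap confidence intervals;
* **instantaneous relative growth rates** and **between-group curve
  comparisons** (hatch seasons, sexes) via the analysis-of-residual-sum-of-
  squares (ARSS) F-test, plus a two-way ANOVA utility for size/age at
  maturity.

The central model is the 3-parameter Gompertz curve

```
m(a) = m∞ · exp(−γ · e^(−g₁·a))
```

with asymptote `m∞` (g), shape `γ` and rate coefficient `g₁` (day⁻¹). Its
inflection sits at weight `μ = m∞/e` and age `a* = ln(γ)/g₁`, and the
instantaneous relative growth rate is `G(a) = d ln m/da = γ·g₁·e^(−g₁·a)`,
equal to `g₁` exactly at the inflection. Fitting is weighted least squares
with `wᵢ = 1/m̂ᵢ²` (constant-CV error model), and model selection uses the
least-squares AIC `n·ln(RSSw/n) + 2(k+1)` with Akaike weights
`exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2)`.

Because raw field data of this kind are rarely published, the package ships a
first-class synthetic cohort generator (`octogrowth.synth`) that reproduces
the statistical structure of such a collection — seasonal Gompertz truths,
constant-CV size scatter, reader noise on counts, preservation shrinkage, a
cool-season-peaked hatch distribution — so the entire pipeline is testable
end to end.

## Worked example

`examples/03_fit_growth_models.py` simulates a 527-animal cohort, corrects
preserved weights, applies the ageing QC, and fits the four candidate models:

```
QC: accepted 210/527 (discard fraction 0.60)
model               AIC     wAIC
gompertz        -655.82   1.0000
linear          -603.45   0.0000
power           -493.60   0.0000
exponential     -361.94   0.0000

best model: gompertz
  asymptote m_inf = 159.4 g, inflection weight mu = 58.63 g
  shape gamma = 12.29, rate g1 = 0.0154 / day
  95% bootstrap CI for g1: [0.0142, 0.0178]
  mean instantaneous relative growth rate over observed ages: 0.0148 / day
```

Read: the 10% QC rules kept 210 of 527 sections; the Gompertz model carries
essentially all the AIC evidence; the fitted curve flattens towards ~159 g
with its fastest relative growth (1.5%/day) at ~59 g; and the generating rate
g₁ = 0.015/day for cool-hatched animals lies inside the bootstrap interval.
The other examples cover cohort simulation (`01`), preservation correction
(`02`) and season/sex comparisons with the ARSS test and ANOVA (`04`).

A thin CLI mirrors the stages (`octogrowth synth`, `correct-weights`, `age`,
`fit-growth`, `compare`, `maturity-anova`, and `octogrowth run --config
config.yaml` for the whole pipeline from a YAML file).

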