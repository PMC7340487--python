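# Methods

`sdgattain` implements a national/subnational tracking pipeline for
health-related SDG monitoring indicators: attainment scaling, thematic
aggregation, trend projection, and progress/disparity reporting.  This
note records the model, its conventions, and the choices made where the
design was genuinely open.

## Attainment index

Each indicator value `x` is mapped to a 0–100 index by linear
interpolation in transform space between two anchors:

    score(x) = 100 · (f(x) − f(worst)) / (f(target) − f(worst)),  clipped to [0, 100]

* `f` is `ln` for incidence/mortality rates, `logit` for proportions
  bounded in [0, 1], and the identity otherwise.  The same transform
  drives projection, so anchoring and forecasting agree on geometry.
* **worst** is the location's worst value over 1990–2015 after removing
  Tukey-fence outliers (outside `Q1 − 1.5·IQR` / `Q3 + 1.5·IQR`;
  quartiles by linear interpolation between order statistics, the
  "type 7" rule — the most widespread default, adopted because no
  quartile convention is canonical for this screen).  The screen is a
  single pass, never iterated.
* **target** resolves per target type: `absolute` values verbatim;
  `relative_reduction` as baseline-year value × (1 − fraction), with
  baseline year 2010 for HIV and 2015 otherwise; `no_increase` as the
  2015 value itself; `elimination` as 0 (linear indicators only).
* Anchors are computed per location from that location's own history,
  which reproduces subnational heterogeneity; a `national_anchors` flag
  switches every location to the national series' anchors for the
  single-country reading.

Conventions for targets without a numeric international value are
flagged `assumed` in the packaged registry: near-universal coverage
(0.99) for skilled birth attendance, vaccine coverage, and family
planning need met; a 90 % reduction from 2015 for the three pollution/
poisoning mortality indicators ("substantially reduce"); elimination
(0) for the four exposure SEVs ("universal access"); 100 for the UHC
service-coverage index.

Degenerate and boundary cases:

* Zeros on a log indicator are imputed before scaling as
  `min(half the smallest positive value in the series, target/2)`.
  The cap at `target/2` ensures a true zero — an elimination success —
  always clips to 100, which is the point of scoring eliminations at
  all.  Projection, which has no target in scope, uses the plain
  half-minimum imputation.
* If the worst anchor does not lie on the bad side of the target
  (history already met the target throughout, or the worst value *is*
  the no-increase baseline on a monotonically worsening series), the
  interpolation is undefined and the score degrades gracefully to
  target attainment alone: 100 if the value meets the target, else 0.
* A history entirely flat at the target carries no scale information
  and raises a degenerate-anchor error; panel-level scaling logs and
  skips such series rather than failing the run.

## Thematic aggregation

A topic index is the equal-weight geometric mean of its member scores,
with members below 1 floored to 1 so the mean stays defined:

    index = exp( mean( ln max(sᵢ, 1) ) )

The floor is applied to unrounded scores (flooring after rounding would
make the index depend on presentation precision).  Topics with missing
members aggregate over the available ones with a logged warning.
Membership is fixed by the registry: child nutrition (3), MCHRH (6),
infectious diseases (5), NCD mortality (2), NCD risk factors (2), road
injury (1), environmental outcomes (3), environmental exposure (5),
UHC (1).

## Trend projection

The drift of a series is a recency-weighted mean annual rate of change
in transform space:

    r_t  = f(x_t) − f(x_{t−1})
    w_t  ∝ (t − t_first + 1)^ω,  normalised to Σ w_t = 1
    r̄    = Σ w_t r_t
    f(x_{T+h}) = f(x_T) + h · r̄

ω = 0 gives the uniform annualised rate; larger ω leans on recent
years.  Back-transforming keeps log indicators positive and logit
indicators inside (0, 1); linear indicators extrapolate without bounds
(scores of out-of-range extrapolations simply clip).

**ω selection.**  ω is chosen per (location, indicator, sex) series
from the grid {0, 0.25, …, 3} by backcasting: refit without the final
3 observed years, project them with each candidate, and keep the ω
with the smallest mean absolute error in indicator units, ties (within
a 1e-12 relative tolerance, so float noise cannot break them) going to
the smallest ω.  An exactly constant-rate series therefore selects
ω = 0, and every ω reproduces its rate.  The upstream description of
ω being "defined by the trend" of each series leaves the rule
unspecified; this out-of-sample criterion is a documented surrogate,
not a claim about the original rule.  Series too short to hold 3 years
out (n ≤ 5) fall back to ω = 1 with a warning.

Interior gaps up to five consecutive missing years are linearly
interpolated in transform space before differencing; longer gaps are
an error.  No uncertainty intervals are produced anywhere in the
pipeline — only scaled mean scores.

## Progress and disparity

* An indicator is **achieved** when its score at the indicator's own
  target year (2020, 2025, or 2030) is ≥ 90, inclusive — "an index of
  90 as the threshold" reads most naturally as attainment *at* 90.
* Topic **annual change rates** are endpoint arithmetic,
  `(index_end − index_start) / (year_end − year_start)`, from 2016 to
  the latest member target year.  Several published topic rates are not
  reproducible from their printed endpoints (they were evidently
  computed on unrounded or differently-windowed series); this package
  reports endpoint arithmetic and does not guess.
* **Disparity ratios** are plain quotients in the stated
  numerator/denominator order (rural/urban, male/female,
  western/eastern), never auto-flipped; reciprocity `ratio(a,b) =
  1/ratio(b,a)` holds to floating tolerance.
* **Regional summaries** are unweighted province means (no population
  weighting is documented upstream) over the official
  eastern/central/western grouping; SARs and the national aggregate are
  excluded.

## Synthetic data

The generator emits province × indicator × sex × year panels with

    f(x) = f(baseline) + r·(t−1990) + a·(t−1990)² + δ_region + δ_sex + δ_province + ε,
    ε ~ N(0, σ²)  in transform space.

Noise additive in transform space keeps every value inside its domain
and matches the projection model's own assumption, so parameter
recovery is a clean test of the estimator.  The sex effect is carried
by males (females at base level): on a log indicator a sex effect of
`ln 1.8` yields a male/female ratio of 1.8 at every year, mirroring
the published TB ratio.  "Both-sex" series are the transform-space
midpoint.  Default levels and trends are round numbers at the
magnitudes of the national series around 1990–2016 (under-5 mortality
54 → ~10 per 1,000; overweight rising from 3 %; PM2.5 near 50 μg/m³),
with σ = 0.02 in log/logit space and 1 % of baseline for linear
indicators.  The seed is mandatory — there is no hidden default.

What the generator does **not** emulate: cross-indicator covariance,
burden-of-disease-study uncertainty intervals, age structure, reporting artefacts, or
policy shocks.  Tests passing on synthetic panels therefore validate
the pipeline's arithmetic and contracts, not the realism of any
forecast.

`make_achievement_scenario(n, seed)` constructs a noiseless panel for
which the full scale → project → threshold pipeline yields exactly `n`
achieved indicators nationally: achieved indicators get trends that
clear their targets with margin before the target year (scores clip to
100), failing ones get near-flat or rebound-shaped trends whose
projected scores stay far below 90 (the no-increase case uses a
baseline-year dip so its target stays distinct from its worst anchor).

## Numerical choices and problem sizes

* Quartiles: numpy `percentile`, linear interpolation (type 7).
* Score floor for aggregation: 1.0, on unrounded scores.
* Reported precision: one decimal for national index values, integers
  for provincial score tables.
* ω tie-break: smallest ω within 1e-12 relative MAE.
* Test problem sizes: property suites use 1,000 random series of ≤ 40
  years (rate oracle, 1e-12), 1,000 noisy replicates of 27-year series
  (rate recovery within 3σ/√n), and 2–3-province noiseless panels for
  closed-form projection checks (1e-9 relative); the end-to-end
  achievement check runs the full 31-province scenario.  The default
  synthetic analysis uses 31 provinces + national, 28 indicators, 3
  sex strata, 1990–2016.

## Known limitations

* The provincial/national headline indices of the original analysis
  derive from external burden-of-disease estimates that are not
  printed and cannot be recomputed here; only the worked examples that
  are fully determined by printed numbers are asserted.
* The geometric mean of the five printed infectious-disease member
  scores is 62.9 at one decimal; the published headline 63.0 was
  computed from unrounded members.  Both readings are auditable
  because anchors and unrounded scores are exposed.
* Business-as-usual projection only: no covariates, no ceiling
  effects, no intervention scenarios.
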