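# sdgattain

Attainment-index construction, trend projection, and disparity analysis
for health-related Sustainable Development Goal (SDG) monitoring
indicators, at national and subnational level.

## The problem

Tracking whether a country — and each of its provinces — is on course
for the 2030 health-related SDG targets requires putting 28 very
different indicators (mortality ratios, incidence rates, coverage
proportions, exposure prevalences, PM2.5 concentrations) on one
comparable scale, combining them into thematic domains, and
extrapolating historical trends to each target's deadline.  This
package implements that pipeline for epidemiologists and health-policy
analysts, exercised on synthetic provincial panels and on the worked
examples that are fully determined by published tables.

## The method

**Attainment index.** Each indicator value `x` is scaled to

    score(x) = 100 · (f(x) − f(worst)) / (f(target) − f(worst)),  clipped to [0, 100]

where `f` is `ln` for incidence/mortality rates, `logit` for bounded
proportions, identity otherwise; `worst` is the location's worst
1990–2015 value after Tukey-fence outlier trimming (index 0); and
`target` is the resolved SDG/WHO target (index 100).

**Thematic topics.** Nine domain indices (child nutrition, MCHRH,
infectious diseases, NCD mortality, NCD risk factors, road injury,
environmental outcomes, environmental exposure, UHC) are equal-weight
geometric means of member scores, with scores below 1 floored to 1.

**Projection.** Series are extrapolated in transform space with a
recency-weighted mean annual rate of change,
`r̄ = Σ w_t (f(x_t) − f(x_{t−1}))`, `w_t ∝ (t − t₀ + 1)^ω`, the
exponent ω chosen per series from {0, 0.25, …, 3} by backcast error on
the last three observed years.

**Progress.** An indicator is achieved when its projected score at its
target year (2020/2025/2030) is ≥ 90.  Disparities are plain stratum
ratios (rural/urban, male/female, western/eastern) and unweighted
regional means.

See `docs/methods.md` for conventions, degenerate cases, and
limitations.

## Worked example

```python
from sdgattain import disparity_ratio, floored_geometric_mean
from sdgattain.fixtures import DISPARITY_INPUTS, INFECTIOUS_MEMBER_SCORES_2016

# 2016 infectious-disease domain index from the five published national
# member scores (HIV 40, TB 63, malaria 100, hepatitis B 49, NTD 80)
round(floored_geometric_mean(INFECTIOUS_MEMBER_SCORES_2016), 1)
# 62.9   (the published headline, 63.0, used unrounded member scores)

# rural/urban under-5 mortality ratio, 2016 (12.4 vs 5.2 per 1,000)
round(disparity_ratio(DISPARITY_INPUTS[("3.2.1", "rural", 2016)],
                      DISPARITY_INPUTS[("3.2.1", "urban", 2016)]), 1)
# 2.4
```

The full synthetic analysis is a sequence of numbered drivers:

```bash
python analysis/01_simulate_panel.py --seed 1   # 31-province panel, 1990-2016
python analysis/02_scale_attainment.py          # 0-100 scores + topic indices
python analysis/03_project_trends.py            # omega-selected projection to 2030
python analysis/04_disparities.py               # stratum ratios + regional gaps
```

With seed 1 the projection step prints, among other lines:

```
national indicators achieved (score >= 90 at target year): 13 of 28
  road_injury        58.0 (2016) ->   70.9 (2020)  rate +3.2
  uhc                38.8 (2016) ->   59.8 (2030)  rate +1.5
provincial achieved counts: min 8, median 12, max 14
```

i.e. on this synthetic trajectory 13 of the 28 indicator targets are
met nationally by their deadlines, road-injury scores improve by 3.2
index points per year to 2020, and provinces span 8–14 achieved
targets.  Outputs land in `results/` as plain CSV.

A `sdgattain` command-line tool wraps the same library
(`simulate`, `scale`, `aggregate`, `project`, `report`), writing a
manifest JSON next to each output for reproducible replays.

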