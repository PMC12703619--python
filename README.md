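# aqilag

Time-series analysis of how a composite **Air Quality Index (AQI)**
affects daily cardiovascular and cerebrovascular mortality, for
environmental epidemiologists working with city-level registry data.
The package covers the full workflow:

* **AQI construction** — per-pollutant sub-indices (IAQI) by
  piecewise-linear interpolation between the Chinese-standard
  breakpoints (GB3095-2012 limits, HJ633-2012 index grid), composite
  AQI as the maximum sub-index, and category assignment;
* **Distributed-lag nonlinear modelling (DLNM)** — Poisson regression
  of daily death counts on an AQI *cross-basis* (tensor product of an
  exposure basis and a lag basis over lags 0..L), with natural-spline
  control of trend/seasonality and meteorology, day-of-week and
  holiday terms, fitted per population stratum (total, male, female,
  ≥65, <65);
* **Interaction analysis** — dichotomized AQI × meteorology joint
  effects with multiplicative (IRR) and additive (RERI, AP) measures
  and delta-method confidence intervals;
* **A calibrated synthetic-data generator** — seven-year daily series
  with known ground truth whose marginals emulate a clean-air
  subtropical city (AQI median ≈ 44, mean daily deaths ≈ 25.8), so
  every stage is testable end to end without access to registry data.

## Model

Daily deaths are treated as Poisson counts,

    Y_t ~ Poisson(μ_t)
    log μ_t = α + cb(AQI_t, l) + ns(time, 7·years) + ns(RH_t, 3)
              + ns(WS_t, 3) + η·DOW_t + γ·Holiday_t

where `cb` is the cross-basis over exposure and lag, `ns` a natural
cubic spline, RH relative humidity and WS wind speed.  The fitted
cross-basis coefficients are converted into single-day (Lag0..LagL)
and cumulative (Lag00..Lag0L) relative risks at any exposure versus a
reference (default: the median AQI); the cumulative log-RR at lag k
is the sum of the single-lag log-RRs through k.

For joint effects, both exposures are made binary (AQI at a policy
threshold, meteorology at the turning point of its exposure-response
curve) and

    IRR  = RR11 / (RR01 · RR10),
    RERI = RR11 − RR10 − RR01 + 1,
    AP   = RERI / RR11,

with synergy indicated by IRR > 1 / RERI > 0 and antagonism by the
reverse, significance read off the 95% CIs.

## Worked example

`examples/04_interaction_analysis.py` injects an antagonistic
wind × AQI interaction (true IRR = 0.93) into a simulated seven-year
series and recovers it:

```
days per exposure cell: {'(0,0)': 511, '(0,1)': 835, '(1,0)': 768, '(1,1)': 443}
IRR (95% CI): 0.93521 (0.90589-0.96549)
RERI (95% CI): -0.07061 (-0.10344--0.03779)
AP (95% CI): -0.07117 (-0.10435--0.03798)
verdict: antagonistic
```

IRR below 1 with the RERI interval entirely negative means windy days
blunt the excess mortality associated with polluted days — the
estimate brackets the injected truth.  The other scripts in
`examples/` show AQI construction, the per-stratum lag-RR table, and
the exposure-response curve with its turning point.

A thin CLI wraps the same API:

```bash
aqilag run-all --n-days 2557 --seed 1 --outdir out/
aqilag phase1 --input daily.csv --outdir out/phase1   # lag-RR tables
aqilag phase2 --input daily.csv --outdir out/phase2   # interaction table
```

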