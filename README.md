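# fragno2

Analytics for the association between **urban functional fragmentation** and
**NO₂ variation under an anthropogenic-emission restriction** (a
COVID-19-style lockdown), built as one tested pipeline:

1. **Counterfactual forecasting** — per-station SARIMAX(p,d,q)(P,D,Q)₇ models
   of daily NO₂ with meteorology (temperature, humidity, wind speed) and an
   annual Fourier pair as exogenous regressors, order chosen by AIC, training
   cutoff chosen by the mean observed-predicted error
   MOPE = (Σₖ|obsₖ−predₖ|/obsₖ)/n·100 across stations.
2. **Variation scoring** — the dynamic-time-warping divergence
   DTW(T_act, T_con) = min over warping paths of √(Σ_k (t_act,i − t_con,j)²)
   between observed and counterfactual NO₂, split at the lockdown date into
   before/during scores.
3. **Fragmentation metrics** — edge density (ED) and landscape shape index
   (LSI) for the industrial and public land-use classes, landscape
   aggregation index (AI) and number of patches (NP), from a categorical
   raster inside a 3 km circular buffer around each station.
4. **Association models** — four Gaussian log-link additive models
   (UFB, UFD, UFCB, UFCD): log E(Yᵢ) = α + β₁Ind_ED + β₂Pub_ED + β₃Ind_LSI +
   β₄Pub_LSI + β₅UF_AI + β₆UF_NP (+ spline smooths s(·) of ten controlling
   variables for the *C variants), preceded by a VIF < 10 multicollinearity
   screen, followed by a before-vs-during mediated-impact comparison of
   coefficient magnitudes.

A synthetic-data generator produces station panels, land-use rasters and
controlling variables with *known* ground truth (the lockdown suppression
fraction of each station is an explicit function of its fragmentation
covariates), so every stage supports parameter-recovery and calibration
tests without any external data. It is intended for researchers in air
quality epidemiology and urban analytics who want a reproducible, verifiable
implementation of this analysis pattern.

## Worked example

```python
import numpy as np
from fragno2 import (ScenarioConfig, RunConfig, run_pipeline)

config = RunConfig(
    scenario=ScenarioConfig(
        n_stations=20, history_start="2019-01-01",
        raster_rows=32, raster_cols=32, buffer_radius=1500.0,
    ),
    order_grid=[(1, 0, 0, 0, 0, 0)],   # (p,d,q,P,D,Q) at weekly period
    out_dir="example_out", seed=5,
)
result = run_pipeline(config)
print(result["variation"].head(3).round(1).to_string(index=False))
print(result["evaluation"].round(3).to_string(index=False))
```

prints

```
station_id  dtw_before  dtw_during
      S001        13.8        68.0
      S002        23.3        38.7
      S003        20.4        74.3
variant    r2  deviance_explained     aic  n
    UFB 0.337               0.337 117.103 20
    UFD 0.896               0.895 155.271 20
   UFCB 0.856               0.856 125.899 20
   UFCD 0.981               0.981 160.793 20
```

The during-lockdown variation scores dwarf the before-lockdown scores — the
default scenario suppresses NO₂ by ~30% from the lockdown date, with the
suppression fraction tied to each station's fragmentation profile — and the
during-lockdown models (UFD, UFCD) explain more of the variation than their
before-lockdown counterparts, with the controlling variables adding further
fit. (The defaults emulate a 145-station, five-year panel; this example is
deliberately small.)
`example_out/` then holds per-station forecast CSVs, `variation.csv`,
`profiles.csv`, `vif.csv`, `coefficients.csv` (estimates with 95% CIs),
`evaluation.csv`, `mediated_impact.csv` and a `manifest.json` with the seed
and config echo.

The same run is available from the shell:

```bash
fragno2 run-all --config config.yaml --seed 5 --out example_out
```

## Documentation

`docs/methods.md` describes the models and their assumptions, every
convention chosen where the design was open (seasonal period, metric
adjacency rules, CI construction, smoothing selection), what the synthetic
generator emulates and what it deliberately does not, and known limitations.
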