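# ancrain

**Attribution of antenatal-care (ANC) service disruption to precipitation.**

Routine health-information systems (DHIS2-style) record how many ANC visits
each facility delivers per month; gridded reanalysis products record how
much rain fell on each facility. `ancrain` implements, as a tested and
reusable pipeline, the analysis that connects the two: it asks how many ANC
visits are lost to rainfall — historically, under an early-period
counterfactual climate, and under future climate-scenario ensembles. It is
aimed at climate-health and health-systems researchers who want the full
chain — climate indices, panel cleaning, model fitting, attribution,
projection — as composable, seeded, unit-tested pieces rather than a
one-off script.

## The method

Monthly ETCCDI-informed precipitation indices are computed per grid cell
from daily rainfall: cumulative monthly precipitation, Rx5day (the maximum
5-day consecutive total within the month), their lags at 1, 2, 3, 4 and 9
months, squares, cubes and the cumulative×Rx5day interaction. Facilities
are matched to cells with a k-d tree.

Two OLS models are fitted to log(y + 1), where y is the facility-month ANC
count:

* **M0**: calendar trend, urban/rural setting, zone, ownership, altitude,
  distance to the closest facility — no precipitation;
* **M1**: the same covariates plus precipitation terms selected by backward
  stepwise AIC from the full index candidate set.

The models are compared with a likelihood-ratio test, and the attributed
disruption per facility-month is the difference of back-transformed
predictions,

```
ΔANC(i,t) = ŷ0(i,t) − ŷ1(i,t),    ŷ = exp(Xβ̂) − 1  (floored at 0),
```

summed over deficit months only (Δ > 0). Aggregates report the percentage
of services disrupted and the share of the deficit falling in *extreme*
months (cumulative rainfall at or above the 90th percentile of the pooled
historical monthly totals). Swapping the precipitation columns for an
earlier record (counterfactual) or for scenario-ensemble members
(lowest / median-closest / highest by grand mean) and re-predicting gives
the counterfactual and projected disruption under the same fitted model.

Because the real facility panel is restricted data, the package ships a
first-class synthetic generator that emulates all inputs: a gamma/Bernoulli
stochastic weather generator with an extreme-burst mixture, a facility
table with the study-like categorical structure, ANC counts drawn from the
log-linear model itself with known coefficients, and DHIS2-style
missingness (random non-reporting plus closure-linked gaps). Every stage is
seeded and deterministic. See `docs/methods.md` for the model conventions
and generator details.

## Worked example

Run the full pipeline on the default synthetic study (199 facilities,
2011-01 to 2024-10, quarter-degree grid, three scenario ensembles over
2025–2060):

```python
from ancrain import PipelineConfig, run_pipeline

art = run_pipeline(PipelineConfig(seed=1), "out/")
print(art["summary"].round(2).to_string(index=False))
lr = art["lr"]
print(f"LR: {lr.statistic:.1f} on {lr.df} df, p = {lr.pvalue:.3g}")
print("M1 cumulative coefficient:", round(float(art["m1"].coef_["cumulative_mm"]), 6))
```

which prints:

```
      scenario  member  deficit_services  total_services  percent_disrupted  extreme_deficit_services  extreme_share_percent
    historical     n/a          69497.12      6317370.83               1.10                  11736.71                  16.89
counterfactual     n/a          53794.97      6317370.83               0.85                   5398.18                  10.03
        ssp126  lowest         228011.99     26925172.59               0.85                  24049.52                  10.55
        ssp126    mean         278088.01     26925172.59               1.03                  48838.70                  17.56
        ssp126 highest         327967.84     26925172.59               1.22                  82489.35                  25.15
        ssp245  lowest         247260.26     26925172.59               0.92                  31982.67                  12.93
        ssp245    mean         299322.51     26925172.59               1.11                  60158.26                  20.10
        ssp245 highest         348200.08     26925172.59               1.29                  96358.59                  27.67
        ssp585  lowest         267357.31     26925172.59               0.99                  41818.68                  15.64
        ssp585    mean         326099.84     26925172.59               1.21                  76556.02                  23.48
        ssp585 highest         376580.02     26925172.59               1.40                 115292.59                  30.62

LR: 185.4 on 5 df, p = 3.81e-38
M1 cumulative coefficient: -0.00039
```

Reading the numbers: about 1.1% of the expected historical service volume
(69,497 of 6.3 M visits) is attributed to precipitation, of which 16.9%
falls in extreme months. The stepwise-selected M1 recovers the generator's
ground-truth cumulative-precipitation coefficient (−0.0004) to the second
significant figure, and the likelihood-ratio test strongly prefers M1. The
synthetic counterfactual climate (weaker wet seasons, a quarter of the
extreme-event rate) reduces the attributed deficit, and the extreme-month
share of disruption rises with scenario severity (ssp126 → ssp585) even
where the total percentage moves little.

The same stages are available from a shell:

```
ancrain simulate --config sim.yaml --out-dir data/ --seed 1
ancrain indices  --grid data/precip.nc --out data/index_table.csv
ancrain fit      --facilities data/facilities.csv --panel data/panel.csv \
                 --index-table data/index_table.csv --out-dir fit/
ancrain project  --model0 fit/model_m0.json --model1 fit/model_m1.json \
                 --design fit/design.csv --alt-index-table cf_index.csv \
                 --threshold-mm 225.5 --out cf_series.csv
ancrain run      --out-dir out/ --seed 1
```

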