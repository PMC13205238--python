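# aslt — accelerated shelf-life testing for nutrient degradation

`aslt` estimates how long a nutrient-rich product keeps an acceptable
nutrient level at ordinary storage temperatures, from short studies run at
elevated temperatures. It was built around vitamin C (ascorbic acid)
degradation in tropical fruit juices — camu camu and naranjilla are the
built-in reference matrices — but the machinery applies to any analyte
whose isothermal decay is tracked as concentration vs time at two or more
storage temperatures.

It is aimed at food scientists and quality engineers running
accelerated shelf-life testing (ASLT) designs: store at, say, 35/45/55 °C,
sample repeatedly, quantify the analyte (e.g. by HPLC), then extrapolate to
the refrigerator.

## The model

Per storage temperature, retention `Y(t) = C(t)/C0` is fitted with three
primary models, the best chosen by R²:

- zero-order: `C(t) = C0 − k1·t`
- first-order: `ln C(t) = ln C0 − k2·t`
- Weibull: `Y(t) = exp(−b·tⁿ)` — scale parameter `b` (day⁻ⁿ), shape
  parameter `n`; `n = 1` recovers first-order decay, `n < 1` means decay
  that slows with time.

The temperature dependence of `b` is described two ways: an Arrhenius law
`b(T) = b0·exp(−Ea / (R·(T + 273.15)))`, whose log-linear slope gives the
activation energy `Ea`, and the log-logistic form
`b(T) = ln(1 + exp(k3·(T − Tc)))` with characteristic temperature `Tc`.

Shelf life at retention threshold `f` (default 0.80, i.e. t80) inverts the
Weibull model in closed form:

```
t_f = ((−ln f) / b) ** (1 / n)
```

and `ln t_f` is itself regressed on `1/(T + 273.15)` to predict shelf life
at unmeasured (e.g. refrigeration) temperatures.

A synthetic-study generator reproduces the reference design (35 °C/21 d
every 3 d, 45 °C/14 d every 2 d, 55 °C/7 d daily, triplicates) with
Weibull-shaped decay plus seeded measurement noise, so the whole pipeline
is testable without lab data, and a recovery harness quantifies estimator
error at any noise level.

## Worked example

Simulate a camu camu study and compute its shelf-life table:

```
$ aslt simulate --matrix camu_camu --seed 7 --out study.csv
$ aslt shelf-life --input study.csv
 temperature_C        b        n  t_threshold_days  t_threshold_days_rounded  threshold_fraction
          35.0 0.078315 0.353850         19.280546                        19                 0.8
          45.0 0.139819 0.220573          8.325527                         8                 0.8
          55.0 0.153163 0.336773          3.056911                         3                 0.8
 temperature_C  t_threshold_days  t_threshold_days_rounded  extrapolated
           5.0        517.834604                       518          True
          10.0        286.932812                       287          True
          15.0        162.281076                       162          True
          20.0         93.583383                        94          True
          25.0         54.972821                        55          True
          30.0         32.863890                        33          True
```

The first table is the per-temperature Weibull fit and the resulting t80:
at 35 °C the juice holds 80% of its initial vitamin C for about 19 days,
at 55 °C only 3. The second table extrapolates the fitted Arrhenius line —
about 518 days at 5 °C refrigeration for this simulated batch
(`extrapolated` marks temperatures outside the 35–55 °C fitted span). The
true parameters behind this simulation give (19, 8, 3) rounded days, so
the seed-7 noise realization lands on the truth.

`aslt run --input study.csv --out report/` writes all stage tables
(primary fits, secondary fits, shelf life, t80-Arrhenius fit, predictions)
as CSVs plus a JSON bundle and Markdown summary. `aslt check` recomputes
the built-in worked examples from the stored reference parameters and
prints PASS/FAIL per quantity.

The same pipeline is available as a library:

```python
from aslt import read_study, run_aslt_pipeline
result = run_aslt_pipeline(read_study("study.csv"), f=0.80,
                           target_temperatures=(5, 10, 15, 20, 25, 30))
result.shelf_life_table.rows[0].t_threshold_days_rounded  # 19
```

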