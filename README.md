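# maekin — microwave-assisted extraction kinetics

`maekin` models and screens microwave-assisted extraction (MAE) of a
bioactive solute — mangiferin, a xanthone-C-glycoside, extracted from
*Curcuma amada* (mango ginger) rhizome with aqueous ethanol — and packages
the full analysis a bioprocess lab runs on such one-factor-at-a-time (OFAT)
screening data: kinetic curve fitting, factorial significance testing with
post hoc ranking, and antioxidant-activity (DPPH IC50) estimation. It is
aimed at natural-product and food-process researchers who collect
yield-vs-time curves while varying one design factor at a time (microwave
power in W, ethanol fraction in % v/v, pre-leaching time in min).

## Models and statistics

Yield curves `Y(t)` (mg solute per g dry matter) are sigmoidal and are
fitted by unweighted nonlinear least squares (Levenberg–Marquardt) with
three model families:

* **pseudo-first-order** (solvent-excess limit of second-order
  solute–solvent kinetics):
  `Y(t) = Y_max (1 − e^{−k_m t})`
* **delayed logistic**:
  `Y(t) = Y_max / (1 + e^{−k_m (t − τ)})`, where the delay `τ` frees the
  curve from starting at half its asymptote;
* **generalized design-variable logistic**, fitted jointly to a whole curve
  family over factor levels `x` (power `P` or ethanol fraction `E`):
  `Y(t, x) = A (1 − e^{−x/x_ref}) / (1 + e^{−k_m (t − τ)})`, with the
  amplitude `A` profiled out by variable projection so only
  `(x_ref, k_m, τ)` are optimized.

Fit quality is summarized by the dimensionless indicator
`Y_RMS / Y_max` — root-mean-square residual over the fitted asymptote.

The screening statistics are a balanced two-way ANOVA (factor × extraction
time, one observation per cell, residual = interaction as error term) with
noncentrality `λ = df·F` and observed power from the noncentral F
distribution, followed by Student–Newman–Keuls (SNK) ranking of the level
means into homogeneous subsets using studentized-range critical values.
DPPH radical-scavenging activity at 517 nm is converted to inhibition
percentages `100 (A_ctrl − A_sample)/A_ctrl` and IC50 is estimated by
log-linear interpolation (default) or a four-parameter logistic fit.

Curve fitting is exposed as scikit-learn style estimators
(`FirstOrderExtraction`, `DelayedLogisticExtraction`,
`GlobalLogisticExtraction`) that compose with sklearn pipelines; the
module-level functions (`fit_curve`, `fit_global`, …) are thin wrappers.
A synthetic-data generator reproduces the OFAT design (25 extraction times
{1, 5, …, 120} s; power {250, …, 550} W; ethanol {50, …, 100} %;
pre-leach {1, 5, …, 30} min) from shipped per-condition reference
parameters, with additive Gaussian noise.

## Worked example

```python
import numpy as np
from maekin import (SimulationConfig, generate_ofat_dataset, fit_curve,
                    two_way_anova, snk_test)

ds = generate_ofat_dataset(SimulationConfig(factor_name="power",
                                            noise_sd=0.01, seed=42))
fit = fit_curve(ds.curve(550.0), "logistic")
print(f"550 W fit: y_max={fit.params.y_max:.4f} mg/g, "
      f"k_m={fit.params.k_m:.4f} 1/s, tau={fit.params.tau:.2f} s, "
      f"gof={fit.gof:.4f}")

table = two_way_anova(ds, alpha=0.05)
print(table)

err = table.row("error")
res = snk_test(ds.yields.mean(axis=1), n_per_mean=len(ds.times),
               ms_error=err.ms, df_error=err.df,
               labels=[int(l) for l in ds.levels])
print("homogeneous subsets (descending means):", res.subsets)
```

prints

```
550 W fit: y_max=0.7141 mg/g, k_m=0.1219 1/s, tau=10.89 s, gof=0.0113
        Sum of squares   df  Mean square       F        Sig.  Noncent.  Obs. power (a=0.05)
source
power          6.16842    4       1.5421 339.958 9.56867e-56   1359.83                    1
time           1.69987   24    0.0708278 15.6141  1.7321e-23   374.738                    1
error         0.435471   96   0.00453616     NaN         NaN       NaN                  NaN
total          8.30376  124          NaN     NaN         NaN       NaN                  NaN
homogeneous subsets (descending means): ((550,), (500, 450), (350,), (250,))
```

The 550 W curve recovers its generating parameters (asymptote 0.714 mg/g,
rate 0.126 1/s, delay 10.9 s) within noise; the ANOVA says both microwave
power and extraction time drive yield far beyond chance; the SNK ranking
places 550 W alone in the top subset — the optimum the screening design is
meant to find.

The same pipeline is available from the shell:

```sh
maekin simulate --factor power --seed 42 -o curves.csv
maekin fit curves.csv --model logistic -o fits.json
maekin anova curves.csv
maekin report --factor power --seed 42 -o out/
```

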