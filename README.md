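# biaindex

Body-composition analysis for pediatric single-frequency bioimpedance
cohorts, built around two *specific* bioelectrical indexes that combine a
subject's impedance measurement with their predicted body-water volume.

## The science

A tetrapolar whole-body bioimpedance measurement at 50 kHz yields the complex
impedance `Z = R + iXc`: resistance `R` tracks conductive fluid volume,
capacitive reactance `Xc` tracks cell-membrane capacitance, and the phase
angle `θ = arctan(Xc/R)` is a classic marker of cell mass and membrane
integrity.  Because θ rises steadily through childhood, it is a poor
weight-status marker in young cohorts.  This package implements two
alternative bioparameters that are far more stable across growth:

    I_r  = TBW · R  / height²        (specific resistance index, Ω·m)
    I_Xc = TBW · Xc / height²        (specific reactance index,  Ω·m)

with total body water `TBW` predicted from the sex-specific Kotler
equations (height in cm, impedance magnitude Z in Ω, weight in kg, TBW in L):

    male:    TBW = 0.58 · height^1.62 / Z^0.70 / 1.35  + 0.32 · weight − 3.66
    female:  TBW = 0.76 · height^1.99 / Z^0.58 / 18.91 + 0.14 · weight − 0.86

Evaluated with TBW in m³ and height in m, both indexes land near 7 Ω·m and
1 Ω·m respectively in a pediatric cohort, increase monotonically from
underweight through overweight subjects, and are larger in girls than boys.

The package provides:

* **`biaindex.bioparams`** — the formulas above plus per-record derivation
  with rejection reporting,
* **`biaindex.simulate`** — a synthetic infant–juvenile cohort generator
  (n = 283, ages 2–18, both sexes, three weight-status classes) calibrated so
  its stratified medians/means reproduce published reference statistics,
* **`biaindex.regression`** — 13-feature linear support-vector regression of
  each derived bioparameter (ε-insensitive loss, standardized features, 95/5
  stratified holdout, R²/MSE/RMSE/MAE reports),
* **`biaindex.analysis`** — stratified summaries by sex and weight status,
  stratum-ordering checks, and per-group trend lines in the (I_r, I_Xc)
  plane,
* **`biaindex.io` / `biaindex.cli`** — a fixed cohort CSV schema, TOML
  configs, and a `biaindex` command with `simulate`, `derive`, `train`,
  `report` and `run` verbs.

## Worked example

```python
from biaindex import (
    calibrate_defaults, generate_cohort, derive_all,
    stratified_summary, train_linear_svr, default_feature_spec,
)

config = calibrate_defaults().model_copy(update={"seed": 1})
cohort = generate_cohort(config)            # 283 synthetic subjects
derived = derive_all(cohort.table)          # TBW, θ, I_r, I_Xc per subject

summ = stratified_summary(derived.table, by="sex", statistic="median")
print(summ[summ.source == "observed"]
      [["level", "parameter", "central", "dispersion", "n"]].to_string(index=False))

res = train_linear_svr(derived.table, default_feature_spec("theta"), seed=1)
print(f"holdout R2 = {res.test_metrics.r_squared:.4f}, "
      f"RMSE = {res.test_metrics.rmse:.4f} deg")
```

prints

```
 level parameter  central  dispersion   n
  male       I_r 6.959947    0.488723 137
  male      I_Xc 1.077716    0.075040 137
  male     theta 7.048797    0.119749 137
female       I_r 7.728965    0.406025 146
female      I_Xc 1.163596    0.053189 146
female     theta 7.136287    0.087297 146
holdout R2 = 0.9990, RMSE = 0.0060 deg
```

The female medians exceed the male ones for all three bioparameters (I_r
7.73 vs 6.96 Ω·m, I_Xc 1.16 vs 1.08 Ω·m, θ 7.14° vs 7.05°), and the
13-feature linear SVR predicts the phase angle on the 5 % holdout with
R² ≈ 0.999.  The same pipeline is available from the shell:

```sh
biaindex run --seed 1 --outdir out/
```

which writes `cohort.csv`, `derived.csv`, per-response prediction tables, a
metrics summary, the sex/status summary and trend CSVs, and a checksummed
run manifest.

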