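# Methods

## Derived bioparameters

Every record carries a 50 kHz tetrapolar measurement (impedance magnitude
`Z`, resistance `R`, capacitive reactance `Xc`, device-corrected reactance
`Xcc`) and anthropometrics.  From these the package derives, per subject:

* **Kotler total body water** `TBW` (liters) from the sex-specific
  prediction equations (male `0.58·H^1.62/Z^0.70/1.35 + 0.32·W − 3.66`,
  female `0.76·H^1.99/Z^0.58/18.91 + 0.14·W − 0.86`; height in cm, Z in Ω,
  weight in kg).  The leading divisors are implemented as divisions, the
  form under which the equations reproduce their published example
  magnitudes (≈22 L for a 140 cm, 35 kg boy at Z = 600 Ω).
* **Phase angle** `θ = arctan(Xc/R)` in degrees.  Two conventions are
  reported: `theta_deg` uses the raw reactance (the textbook definition) and
  `theta_dataset_deg` uses `Xcc`.  The reference cohort's printed phase
  statistics (~7.05°) are numerically consistent only with a reactance
  smaller than the raw `Xc` implied by its index medians
  (arctan(1.17/7.70) ≈ 8.6°), so the corrected-reactance convention is used
  wherever stratified phase statistics or regression responses are involved;
  all raw-reactance identities still hold and are tested.
* **Specific resistance and reactance indexes** `I_r = TBW·R/h²`,
  `I_Xc = TBW·Xc/h²`, evaluated with TBW in m³ and height in m (units Ω·m).
  This is the only unit convention that puts the indexes at their reported
  few-Ω·m magnitudes.  Two identities follow algebraically and are enforced
  in tests: `I_Xc/I_r = Xc/R` (the TBW/h² factor cancels) and
  `√(I_r² + I_Xc²) = TBW·Z/h²`.

Records with missing `R` have it recovered as `√(Z² − Xc²)` (logged).
Non-positive predicted TBW marks a record as physiologically implausible; it
is excluded with a reason rather than silently dropped.  Phase angles ≥ 45°
are flagged but kept.

## Synthetic cohort generator

The study data the analysis was designed for is not public, so the package
ships a generator that emulates its statistical structure: 283 subjects aged
2–18, both sexes, three latent weight-status classes.  Weight-status labels
are drawn as latent classes (prevalence 0.20 / 0.60 / 0.20 for underweight /
normal / overweight; the true prevalence is unpublished and the parameter is
config-exposed), not from BMI-for-age reference tables, which are external
data; a BMI-threshold hook can be layered on by the caller.

Construction per subject:

1. draw sex (default 50 % female) and weight-status cell;
2. draw age uniformly on [2, 18], height from a linear-in-age growth curve
   with lognormal residuals, and weight through an age- and status-dependent
   BMI.  These curves only place subjects in a plausible pediatric envelope —
   no attempt is made to match reference growth percentiles;
3. draw the subject's specific resistance index and dataset-convention phase
   angle around the cell's calibrated centers (normal, σ_Ir = 0.30 Ω·m,
   σ_θ = 0.05°), and convert the phase target to the raw-reactance phase via
   the cell's corrected-reactance ratio κ = Xcc/Xc (calibrated, 0.76–0.84);
4. solve for the unique impedance magnitude Z that makes the Kotler water
   volume and the index definitions mutually consistent with the drawn
   targets (`TBW(Z)·Z = √(I_r²+I_Xc²)·h²`; monotone in Z over the physical
   branch, solved by bracketed root finding), then set `R = Z·cosθ_raw`,
   `Xc = Z·sinθ_raw`, `Xcc = κ·Xc`;
5. fill the water compartments (`ECW = 0.45·TBW`, `ICW = TBW − ECW`) and
   extracellular mass (`ECM = 0.40·weight`) from fixed, config-exposed
   fractions — their true prediction equations are unpublished and they act
   only as regression features here.

Because the indexes are drawn first and Z is solved from them, every emitted
record satisfies `Z² = R² + Xc²` to machine precision and re-deriving the
bioparameters from the CSV reproduces the drawn targets exactly.  The
implied hydration TBW/weight is not imposed; it comes out near 0.6 for
mid-range ages and is checked against a configurable plausibility band
(0.60 ± 0.25 with small status offsets), with deviations counted as
warnings.  For extreme growth-tail subjects (toddlers near 10 kg) the
adult-derived Kotler surface cannot reach the cohort's index magnitudes at
any impedance; such subjects (≈1 per thousand) get their anthropometric
residuals redrawn, truncating the body-size distribution to the
representable envelope.  The index targets are never adjusted.  A
configuration whose targets are infeasible for any plausible body size
raises a generation error naming the cell.

All randomness flows through one seeded NumPy generator consumed in a fixed
order, so a given config yields a bit-identical table.

### Calibration

Default cell centers are solved, not hand-set.  The targets are published
stratified statistics of a 283-subject pediatric cohort: sex-stratum medians
(I_r 7.70/6.99 Ω·m, I_Xc 1.17/1.10 Ω·m, θ 7.06/7.03° for female/male),
status-stratum medians of I_r (6.89 underweight, 7.78 overweight) and I_Xc
(1.06, 1.17), and status-stratum phase means (7.18 normal, 7.04 underweight,
6.69 overweight).  Cell centers follow an additive sex + status
decomposition, and the solver matches the *marginal* statistic each stratum
actually sees — a median of a mixture across the other factor — by rooting
the mixture CDF numerically inside a least-squares solve.

Two wrinkles:

* The printed phase-angle sex medians and status means are mutually
  inconsistent with any additive decomposition (by ≈0.05–0.09° at the
  default prevalence).  The solve is weighted least squares with weights
  inversely proportional to each statistic's Monte-Carlo guard band
  (2·dispersion/√283), so the inconsistency is spread in proportion to
  tolerance.  All implied population marginals stay inside their bands.
* The normal-status I_Xc center is unpublished; it is set midway between the
  underweight and overweight targets so the expected status ordering has
  symmetric margins.

The printed "±" dispersions have an unstated definition and are treated as
scale descriptors only.  The within-cell spreads are free parameters chosen
once: σ_Ir = 0.30 Ω·m (consistent with the printed ± range 0.32–0.72) and
σ_θ = 0.05°.  The phase spread is far below physiological phase-angle
variability; it is forced by requiring that the 0.03° published sex gap in
median phase angle reproduce as a *stable ordering* at n = 283 across seeds.
This is the main sense in which passing tests do not certify behavior on
real data: a real cohort's phase ordering by sex at this effect size would
not be stable at n = 283.

## Regression stage

Each response (I_r, I_Xc, dataset-convention θ) is predicted from 13
features: sex, age, height, weight, weight status, Z, Xcc, ECM, Kotler TBW,
ICW, ECW, plus the other two derived bioparameters.  (For the reactance
index, companions are I_r and θ; listing the response among its own features
would leak it.)  Sex is coded female = 1; weight status is one-hot with
normal as reference — the phase angle is highest for normal-weight subjects,
a nonmonotone pattern a single ordered factor cannot represent (an ordinal
code caps the θ model's holdout R² near 0.97).  Ordinal coding remains
available by configuration.

The model is a linear-kernel ε-insensitive SVR on standardized features with
box constraint 1.0 and ε = IQR(response)/13.49, the common regression-
toolbox defaults; both are config-exposed.  Coefficients are reported back
in original feature units.  The 95/5 split stratifies by weight status,
rounds the training size to the nearest integer (283 → 269/14) and is seeded;
k-fold cross-validated metrics on the training portion are available
(default k = 5).  Metrics are the standard R² (about the observed mean),
MSE, RMSE and MAE, hand-implemented and cross-checked against scikit-learn
in tests.  Missing feature rows are deleted listwise with a logged count;
constant features are retained with a note (standardization leaves them
inert).  Because a published single split is not reproducible, accuracy is
assessed as the median holdout R² over 20 seeded splits.

One numerical caveat: by construction the ε-tube allows a noise-free linear
response to be fit with residuals up to ε, bounding attainable R² near 0.99
under the default ε.  The noise-free recovery control therefore runs with
ε = 0 and a non-binding box constraint, where the implementation recovers an
exact linear map to R² = 1; the default hyperparameters are exercised by the
cohort models and the permutation-null control.

`model_comparison` trains a candidate set (default: ordinary least squares
and the linear SVR) on one shared split and ranks by holdout RMSE, breaking
ties by MAE and then declaration order; failing candidates are recorded and
skipped.

## Cohort analysis

Stratified summaries report medians (dispersion: 1.4826-scaled median
absolute deviation) and means (dispersion: SD) per stratum and parameter,
for observed values and optionally for model predictions.  Mixing both
central statistics mirrors the reference analysis, which quotes medians for
the indexes and means for the status-level phase angle.  The ordering check
evaluates: I_r and I_Xc medians increase underweight → normal → overweight;
mean phase angle is highest for normal weight and lowest for overweight;
female medians exceed male for all three parameters.  Missing strata render
a claim unevaluable rather than failed.

Trend lines fit per-group least squares in both orientations (I_Xc on I_r
and transposed).  The default grouping — sex × (underweight vs not), four
groups — is one interpretation of the four straight bands the index scatter
organizes into; the grouping is configurable and groups under three points
are skipped with a notice.  Tolerance-ellipse (BIVA) mathematics is out of
scope.

## Problem sizes and determinism

Defaults mirror the reference cohort: n = 283 per generated cohort, 20
generation seeds for stratified statistics, 20 split seeds for regression
accuracy, 100 seeds for the ordering stability check, n = 10,000 for
parameter-recovery tests.  All stages are deterministic given their seeds;
the acceptance script derives every sub-seed from a single `--seed` via
NumPy's `SeedSequence`.

## Known limitations

* Cell centers are age-independent: the real growth-related drift of phase
  angle (and any age trend in the indexes) is not modelled.
* Growth curves are linear-in-age with a single BMI slope — adequate for a
  plausibility envelope, not for percentile-faithful anthropometry.
* ECM/ICW/ECW are fixed fractions, not predictions; they carry no
  independent information beyond TBW and weight.
* The Kotler equations were fit to adult physiology; applied to toddlers
  they imply low hydration fractions, which the generator reports as
  warnings rather than correcting.
* The within-cell phase-angle spread is unrealistically tight (see
  Calibration); conclusions about ordering stability do not transfer to
  real cohorts.
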