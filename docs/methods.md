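# Methods

## Scope and model

`lactodb` encodes the postpartum time courses of 13 maternal and milk
parameters relevant to lactation PBPK modelling — daily milk volume, milk pH,
fat, total protein, water content, daily infant milk intake per kg, maternal
haematocrit, alpha-1-acid glycoprotein (AGP), human serum albumin (HSA),
empty breast volume, plasma volume, cardiac output and glomerular filtration
rate (GFR) — as deterministic mean functions of postpartum age `t` in months
over `[0, 12]`, each paired with a constant coefficient of variation (CV)
describing between-subject variability. The package also implements the
machinery those functions were derived with, so they can be regenerated from
study-level data: fixed-effect pooling of study summaries, subject-count
weighted curve fitting with model selection, and a virtual-population
sampler. Covariates (parity, delivery type, demographics) are deliberately
not modelled; neither are pregnancy-period values, extrapolation beyond 12
months, drug partitioning, or enzyme/transporter ontogeny.

## Function registry

Each parameter is a list of function segments tiling `[0, 12]` months. A
segment is one of ten families (constant, linear, polynomial up to degree 4,
mono-/double-exponential, exponential decay to a baseline, Hill, offset Hill,
logistic, double Weibull) with named coefficients, stored in
`lactodb/data/registry.json`. Segments are half-open `[t_lo, t_hi)` with the
final segment closed at 12, so every time maps to exactly one segment; the
three piecewise parameters (milk volume at 6 months, milk intake and AGP at
1 month) have relative boundary mismatches of 0.35%, 0.25% and 0.71%, all
well under 2%, so boundary ownership is numerically immaterial.

Time unit convention: 1 month = 30.4375 days (`days_to_months`).

Two transcription ambiguities in the source coefficients are resolved by
flags on `load_registry`:

* `agp_slope_sign` — the late AGP segment is linear; the default slope is
  −0.016 g/L/month (intercept 0.90) so AGP relaxes back towards pre-pregnancy
  levels by 12 months, which matches the described trend; the literal
  positive slope is available as `"printed"`.
* `hsa_grouping` — the HSA logistic exponent is read as
  `−7.16·(t − 0.866)` by default (albumin depressed at delivery, midpoint
  ≈ 0.87 months); the alternative grouping `−7.16·t − 0.866` is available as
  `"printed"`.

Other parsing conventions baked into the registry: the plasma-volume decay
`2.67 + 0.106·0.133^t` L is stored as an exponential decay to baseline with
rate `−ln 0.133 ≈ 2.0174`/month; the late milk-intake decay is
`0.004 + 0.204·e^(−0.15 t)` L/kg/day (peak-minus-floor amplitude); the Hill
half-times are 0.1, 0.114 and 0.133 months for milk volume, milk intake and
haematocrit respectively.

The Lucas creamatocrit conversion, fat g/L = (creamatocrit% − 0.59)/0.146,
comes from an external calibration, so its constants are arguments of
`creamatocrit_to_fat` rather than hard-coded registry content.

Edge behaviour worth knowing: the milk-volume and milk-intake Hill segments
are exactly zero at delivery (`t^n/(T50^n + t^n)` vanishes at `t = 0`); all
parameters are strictly positive for every `t > 0`. Evaluation outside
`[0, 12]` raises rather than extrapolates. The milk-protein exponential
underflows below double precision past ~6 months, so the evaluated curve is
float-identical to its 1.219% asymptote there.

## Pooling (fixed-effect meta-analysis)

Study records carry a mean with an SD, SE or CV from `n` subjects.
Normalization converts SE→SD (`SD = SE·√n`), CV→SD (`SD = CV·mean`),
collapses reported time ranges to their midpoint, and applies multiplicative
unit conversions identically to mean and SD. Pooling per stratum uses
subject-count weights:

    X̄  = Σ n_j x_j / Σ n_j
    SS = Σ n_j (SD_j² + x_j²) − N X̄²
    SD = √(SS/N),  CV = SD/X̄

This is exact — identical to the population statistics of the concatenated
subject values — when each `SD_j` is the population (divide-by-n) SD, which
is therefore the default convention; a sample-SD (n−1) compatibility mode
replaces the first term with `Σ (n_j−1)·SD_j²`. The shortcut form above is
algebraically non-negative whenever `X̄` is the weighted mean of the same
records; a defensive guard still raises if floating-point cancellation ever
drives it negative. Records reported without any dispersion are accepted,
flagged, and contribute to the weighted mean only; since they shift `X̄`
without entering the SS, the SS is then computed in the equivalent expanded
form `Σ n SD² + Σ n (x − X̄)²` over the unflagged records.

Monthly stratification uses left-closed bins `[0,1), …, [11,12]` labelled by
their midpoints; empty bins are omitted.

## Weighted fitting and model selection

`fit_weighted` minimizes `Σ n_j (x_j − f(t_j))²`. Families linear in their
coefficients are solved by weighted least squares in closed form; nonlinear
families use SciPy's bounded trust-region reflective solver with tight
tolerances (1e−15), data-driven starting values (log-linear regressions for
exponential components via tail peel-off, level-crossing estimates for
half-times and midpoints, a gradient-based slope estimate for the logistic
rate) and a five-point seeded multi-start with multiplicative jitter
(σ = 0.3); the best weighted SS is kept and non-convergence is flagged on
the result rather than raised. On noise-free data every registry family
recovers its generating coefficients to better than 1e−5 relative.

`select_model` mirrors the original two-stage procedure. The observed data
shape (monotone rise/decline, decay to a floor, rise-then-fall, or
unconstrained) is supplied by the caller — it stands in for visual
inspection, which the package deliberately does not automate — and excludes
contradicting families before any fitting: saturating monotone data rule out
lines and polynomials, floor-decaying data rule out lines. Among surviving
fits the lowest weighted SS wins, except that a higher-order polynomial
replaces the next lower order only when it improves the weighted SS by more
than 1% relative *and* r² by more than 0.005 (the thresholds encode "did not
outperform"; no threshold was stated). The weighted r² is
`1 − SS_res,w/SS_tot,w` with the total SS taken about the n-weighted mean.
`add_baseline_anchor` appends a single simulated 12-month
non-pregnant/non-lactating point with a pseudo-weight of 1,000 subjects by
default (the size of the simulated cohort; the weight actually used was not
stated), leaving observed points untouched.

No coefficient uncertainty intervals and no information-criterion selection
are provided, matching the procedure being reproduced.

## Virtual population

`sample` draws `n` virtual subjects per parameter. Each subject receives one
multiplicative frailty factor with mean 1 and relative SD equal to the
parameter CV, applied to the whole trajectory, so individuals remain
systematically high or low over time while every cross-sectional cloud has
mean `f(t)` and SD `cv·f(t)`. The frailty distribution is moment-matched
lognormal by default (strictly positive support, arithmetic mean and CV
preserved exactly in expectation) and Normal(1, cv) truncated at ±3 SD for
pH and haematocrit, whose physiological ranges are tight and symmetric;
truncation shrinks the realized SD by ≈2.7%, well inside the sampler's
tolerance checks. No correlation between different parameters is modelled.
The per-time clouds, not the trajectory correlation, are what the published
comparisons constrain; the shared-frailty choice is the simplest structure
that avoids implausible subject paths.

## Synthetic data generator

`generate_studies` emulates the structure of the literature corpus: each of
`J` studies observes the truth (a registry function) at a time drawn from a
Beta(0.6, 2.2) profile scaled to `[0, 12]` months — reproducing the reported
front-loading of evidence (~60% of observations in the first month, sparse
data past month 7) — with `n` subjects uniform on 5–200 (the corpus averages
tens of subjects per study), a study mean drawn as
`Normal(truth, cv·truth/√n)`, and the dispersion reported as SD, SE or CV in
a 50/25/25 mix. In subject-level mode the generator instead draws the raw
subject values and reports their exact population mean/SD, which makes the
pooling identity testable to machine precision. Standardized residuals of
study means about the truth are standard normal by construction and are
checked by a Kolmogorov–Smirnov test. The generator does not simulate
digitization error, publication bias, covariate structure, or
between-study heterogeneity beyond sampling noise — so green pooling and
fitting tests demonstrate correctness of the estimators under the stated
noise model, not robustness to real-literature pathologies.

## Problem sizes and numerical checks

The test suite exercises: dense 1,201-point grids for shape and positivity
invariants; noise-free refits of all 16 registry segments; a stochastic
recovery experiment with 100 replicates × 30 studies for the milk-fat
quadratic; pooling identities over seeded subject-level draws; and a
5,000-subject virtual population on a six-point time grid for all 13
parameters (sample means within 3 Monte-Carlo SEs, sample CVs within 10%
relative). One caveat the recovery experiment makes explicit: with 30 noisy
studies at CV 0.37 the quadratic's higher-order coefficients are only weakly
identified (the Monte-Carlo SD of the `t²` coefficient is several times its
true value even though the estimator is unbiased and the fitted *curve*
tracks the truth within 20% almost everywhere), so coefficient-wise recovery
at that noise level is not achievable and the corresponding check documents
this limit.

## Known limitations

* The registry is only as good as its source coefficients; the two
  ambiguous transcriptions are resolved by documented defaults, not data.
* Fixed-effect pooling ignores between-study heterogeneity (no τ², I²).
* Constant-CV variability is an approximation; real dispersion may vary
  with postpartum age.
* Shape classification for candidate exclusion is caller-supplied, so model
  selection is only as principled as that input.
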