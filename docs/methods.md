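# Methods

This note documents the science implemented by `olsenp`: the harmonization
rules, the model and its assumptions, the synthetic-data generator, and the
numerical conventions that a user or reviewer would need to interpret the
output. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Screening raw records

Two screens run before any conversion.

**Analytical method and units.** Phosphorus determinations by molybdenum-blue
colorimetry and ion chromatography are treated as comparable; the
stannous-chloride method is excluded (reason `method`). Only gravimetric
concentrations (mg P kg⁻¹ soil) are accepted; volumetric results (mg L⁻¹)
cannot be converted without sample-specific extraction ratios and are
excluded (reason `unit`). Records with a missing concentration are rejected
as `malformed`.

**Detection limits.** Censored values are replaced by half the detection
limit (default limit 2 mg kg⁻¹, so substituted values become 1 mg kg⁻¹).
Values *strictly below* the limit, or flagged below-detection, are
substituted; values printed exactly at the limit are kept unless the
`at_limit_censored` switch is set, to avoid silently altering valid
measurements. Where a source reports no limit, one is inferred from its
value distribution: a value repeated at least `detection_repeat_threshold`
times (default 10) that sits in the lowest decile of the source's values is
taken to be an already-substituted half-limit, implying a limit of twice
that value. Sources with no spread (all values identical) yield no
inference. The substitution is idempotent and never increases a value that
was at or above half the limit.

**Space and time.** Records are dropped when coordinates are missing,
out of range, exactly (0, 0) (a common placeholder, configurable), or fall
off land per a user-supplied mask raster (reason `georeference` or
`land_mask`). The accepted sampling window is 2000–2019; sources declared
exempt (areas of unchanged land use) pass regardless of year. For a
configured Chinese national-survey source, records from eleven listed
eastern provinces are dropped (`province`), as are records sampled before
1995 (`year`).

Every decision increments exactly one counter in a `FilterReport`, and the
report asserts `kept + Σ discarded = input` — the audit trail is conserved
by construction, and on synthetic data with planted violations the discard
counts equal the planted counts exactly (tested).

## 2. Conversion to Olsen P

Each supported soil test maps to Olsen P by a linear equation
`olsen = slope · test + intercept`. Where several published regressions
exist for one (test, soil-class) pair, a single combined equation is formed
by weighting slope, intercept and R² by each study's sample size:

    slope = Σᵢ nᵢ·slopeᵢ / Σᵢ nᵢ   (and identically for the others)

The combined coefficients are convex combinations of their components and
therefore always lie inside the component range (property-tested).

The shipped component registry (`data/table2_components.csv`) holds ten
published regressions; combining them yields Mehlich-3 non-calcareous
(0.47, 2.4, R² 0.80, n 337), Mehlich-3 calcareous (0.41, 1.1, 0.77, 114)
and Bray-I (0.49, 3.1, 0.82, 436). A display-precision detail matters
here: the exact weighted slopes are 0.4772 and 0.4975, and the published
combined slopes (0.47, 0.49) correspond to *truncation* to two decimals,
while the published intercepts and R² correspond to ordinary rounding at
their printed precision. `ConversionEquation.as_printed()` therefore
truncates the slope and rounds the rest, and the default registry applies
the printed coefficients — the form in which the combined equations
circulate and are validated. Full weighted-mean precision is retained on
request (`printed=False`).

Routing rules:

* **Olsen** — identity, no equation.
* **Bray-I** — rejected for soils at pH ≥ 7 (the acid extractant dissolves
  calcium phosphates that are sparingly plant-available); otherwise the
  combined non-calcareous equation.
* **Kirsanov** — no published Olsen regression exists; its 0.2 N HCl
  extractant is closest to Bray-I, so it aliases to the combined Bray-I
  equation and, for consistency, inherits the pH ≥ 7 rejection.
* **Mehlich-3, Resin** — class-specific equations. Records with unknown
  soil class are classed calcareous iff pH ≥ 7.5 (configurable).
* **AB-DPTA** — a single equation with no class split (the source study
  did not report soil characteristics).

The Resin calcareous row publishes the single coefficient 0.94 with no
intercept; it is implemented as slope 0.94, intercept 0. Whether that
figure is a slope or an R² is ambiguous in the flattened source table;
slope is the position-consistent reading and is flagged here as a known
ambiguity. Converted values are floored at zero (a safety net: all
combined equations have non-negative intercepts).

`validate_conversion` regresses measured Olsen P on equation-predicted
Olsen P (OLS) and reports slope, intercept, significance and the
Nash–Sutcliffe efficiency; a conversion suitable for general use shows a
slope near 1 and high NSE.

## 3. Depth standardization, duplicates, outliers

Multi-depth profiles are averaged to 0–20 cm with weights proportional to
each layer's overlap with the window, multiplied by layer bulk density
when available:

    w = max(0, min(bottom, 20) − max(top, 0)) / 20   [· bulk density]

so a 15–25 cm layer under equal bulk density contributes exactly 0.25, and
layers wholly below 20 cm contribute nothing. Weights are renormalized
over the contributing layers: a profile covering only 0–10 cm is taken as
representative of 0–20 cm rather than extrapolated (no stratification
adjustment is attempted; phosphorus stratifies weakly below the topsoil
because of strong sorption). A strict mode (`min_coverage`) optionally
drops profiles covering less than a chosen fraction of the window. The
result is a convex combination of layer concentrations, invariant to layer
order and to splitting a layer into contiguous sub-layers (tested).

Sites are keyed by coordinates rounded to 5 decimal places (≈1 m) plus
sampling year. Exact duplicate rows collapse to one; distinct values at
one key are replaced by their arithmetic mean; merge counts are carried
through and the operation is idempotent.

Outliers are summarized, never removed: quartiles by linear interpolation
between order statistics (the convention must be fixed for
reproducibility; this is numpy's default), Tukey fences at quartiles
± 1.5·IQR, minor outliers strictly between the 75th percentile and the
upper fence, major outliers above it.

## 4. The concentration model

The response is ln(Olsen P): soil-test phosphorus is strongly
right-skewed and approximately lognormal. A Shapiro–Wilk statistic for the
log response is computed at fit time (on at most 5000 rows — the test
saturates at large n) and reported; departures raise a warning but never
block the fit.

**Covariate reduction.** Families of monthly covariates are strongly
autocorrelated. A configurable block of columns is column-standardized and
rotated by PCA; the smallest leading set of components whose cumulative
explained variance reaches a target (default 0.95) enters the model in
place of the block. Retention by variance target rather than a fixed count
keeps the rule data-driven; constant columns are rejected.

**Model form.** `OlsenPModel` is a Gaussian additive model: penalized
B-spline smooths (default df 6, cubic, penalty weight 0 = regression
splines) for each continuous covariate and each retained component score,
plus dummy-coded factor terms (country, and any other categorical
covariates). The smoother backend is statsmodels' GAM machinery; the
package's own obligations are the transform, the augmentation, the
smearing correction and the metrics, not spline penalization itself.
Fitting supports a seeded train fraction (default 70/30) with metrics on
the held-out rows, or an all-data fit for a production model.

**The "other"-country device.** Countries absent from the training data
could otherwise not be predicted. Before fitting, a seeded 5 % sample of
each country's rows (rounded half away from zero, so countries with n < 10
may contribute nothing) is relabelled "other" — in place by default
(the literal reading of renaming), with an append-copies option. At
prediction time an unseen country maps to "other", which represents a
training-data-weighted average country effect; unseen levels of any other
factor are an error.

**Retransformation bias.** exp(ŷ) from a log-scale model estimates the
conditional median, not the mean. Predictions are multiplied by Duan's
smearing factor

    S = (1/n) Σᵢ exp(ε̂ᵢ)

computed from the training residuals. S ≥ exp(mean ε̂) by Jensen's
inequality, hence S ≥ 1 for mean-zero residuals (asserted on every fit).
Applying one global S assumes homoscedastic residuals; with lognormal
noise of log-scale SD σ, S ≈ exp(σ²/2).

**Metrics.** R² is the squared Pearson correlation × 100; NSE is
1 − Σ(o−p)²/Σ(o−ō)² (1 = perfect, 0 = no better than the observed mean);
AIC comes from the fitted model object. Metrics are computed on the log
scale of the evaluation set.

**Grid prediction.** Covariates are extracted at cell centers
(nearest-cell semantics), smooth-term inputs are clipped into the training
span (B-spline bases vanish outside their knots), and cells missing any
covariate become nodata.

## 5. Stocks and post-processing

**Biome overrides.** Five data-poor, largely unproductive biome classes
are replaced with literature constants before stock calculation: deserts
2.0 mg kg⁻¹; flooded grasslands/savannas and mangroves (developed
countries) 5.4; tropical/subtropical dry broadleaf forests 3.5; montane
grasslands/shrublands (underdeveloped) 3.1; and a slope/elevation-graded
band between 1 and 3 mg kg⁻¹. The graded rule's functional form is not
published; it is implemented as a linear decrease from 3 (gentle, low) to
1 (steep, high) with slope and elevation normalized over configurable
bounds (defaults 0–30 % and 0–4000 m) and averaged; missing terrain falls
back to the midpoint with a warning. Overrides are idempotent and leave
all other pixels untouched.

**Pixel stocks.** With concentration c (mg kg⁻¹), bulk density ρ
(kg m⁻³), topsoil depth 0.2 m and cell area A (m²):

    stock_kt = c·10⁻⁶ · ρ · 0.2 · A / 10⁶

Cell areas use the cosine-latitude spherical approximation (R = 6371 km).
The operation is multilinear in all four arguments; masked or
zero-concentration pixels carry zero stock.

**Uncertainty.** Per-pixel uncertainty is the lognormal coefficient of
variation cv = sqrt(exp(s²) − 1) of the log-scale SD s, which tends to s
itself for small s. Regional uncertainty is reported as mean pixel CV ×
regional total. This is a *reporting convention*, not a full error
propagation (pixel errors are neither independent nor summed in
quadrature); it is stated as such and configurable.

**Aggregation.** Country totals sum exactly to continent totals and to the
global total; pixels whose country lacks a continent assignment land in an
`unassigned` bucket rather than being dropped.

**Residual classes.** Absolute percentage differences
100·|p − o|/o are binned into [0,2], (2,5], (5,10], (10,25], (25,∞) —
denominated in the observed value (the source convention names no
denominator); zero observations are classed ">25" with a warning.

**Cross-study stock conversion.** Converting a Mehlich-3 stock grid to
Olsen-equivalent stocks applies the class-appropriate combined equation to
*concentrations* per pixel and recomputes stocks; because the equations
have intercepts, converting stock totals directly would be wrong.

## 6. The synthetic-data generator

The generator emulates the statistical structure of a multi-source soil
phosphorus database, not any real geography. Defaults (one dataset = the
study conditions):

* grid 40×40 cells at 0.025°, vertical country bands (4 countries, two
  continents), horizontal biome bands, a nodata notch in the land mask;
* three abstract covariates, each a seeded Gaussian-bump mixture
  standardized over the grid (stable conditions across seeds);
* log-scale link ln E[P] = 2.6 + 0.6·sin(1.5c₁) + 0.4(c₂² − ½) + 0.5c₃ +
  country offsets (uniform ±0.3). The intercept 2.6 was set once so the
  generated mean concentration is ≈26 mg kg⁻¹, the magnitude typical of
  harmonized global topsoil Olsen-P databases;
* multiplicative lognormal noise, σ = 0.5 on the log scale — chosen once
  as a realistic site-scale dispersion for soil-test phosphorus (field CVs
  of 30–70 %); the published source does not state a residual σ;
* method mix per the post-harmonization shares of a global compilation:
  Olsen 56.8 %, Bray-I 37.4 %, Mehlich-3 4.7 %, Resin 0.5 %, Kirsanov
  0.4 %, AB-DPTA 0.2 %. Non-Olsen values are generated by *inverting* the
  printed combined equations, so conversion must recover the site truth
  exactly. Sites too dilute for a positive inverse (0.7·olsen ≤ intercept)
  fall back to the Olsen method;
* detection limit 2 mg kg⁻¹ with 0.1 % of records censored; 30 % of sites
  sampled as two-layer profiles (0–15 + 15–25 cm) whose 0.75/0.25 weighted
  mean equals the site value; 0.5 % exact duplicates and 0.5 %
  coordinate duplicates planted as mean-preserving ±5 % pairs;
  contamination (stannous, volumetric, off-window, off-land, deep-only)
  planted in exact configured counts with recorded fates.

The manifest records the generating parameters, each record's expected
pipeline fate, each site's expected harmonized value (computed through the
same substitution-then-conversion arithmetic the pipeline applies), and
true regional stock totals of the *mean* concentration field
exp(link + σ²/2) — the quantity a smearing-corrected pipeline estimates;
at σ = 0 this coincides with the noiseless field.

What the generator does **not** emulate: real spatial covariance of
climate fields, anisotropy, measurement-method biases beyond the linear
maps, heteroscedastic noise, or source-specific schema quirks. Passing
tests therefore demonstrate the pipeline's *math* — bookkeeping
conservation, conversion invertibility, depth weighting, bias correction,
stock additivity, noise recovery — not predictive skill on real soil data.

## 7. Problem sizes and numerical conventions

The test suite and acceptance script run on deliberately small problems:
40×40 grids, 400–2000 sites, 100 model replicates for the smearing
comparison — sizes chosen so the full suite completes in well under a
minute on one core while leaving the statistical checks (noise recovery
within 10 %, smearing wins in ≥95/100 replicates) comfortably powered.

Conventions fixed for reproducibility: quartiles by linear interpolation;
site keys at 5-decimal coordinate rounding; nearest-cell raster sampling
with cell-center registration and row 0 = north; B-spline inputs clipped
to the training span at prediction; smearing applied globally
(homoscedasticity assumed, residual-vs-fitted diagnostics available from
the results object); seeds propagate through `numpy.random.default_rng`
and every stochastic operation takes an explicit seed.

## 8. Known limitations

* The conversion registry applies printed-precision coefficients; users
  needing full weighted-mean precision must opt in.
* Regional uncertainty is a CV-scaling convention, not error propagation.
* The "other"-country device biases predictions for unseen countries
  toward data-rich training countries; this is inherent to the device.
* No spatial autocorrelation is modelled; standard errors of the additive
  model assume independent residuals.
* The depth harmonization does not spline concentrations over depth; it
  uses proportional averaging only, with no stratification adjustment.
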