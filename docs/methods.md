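# Methods

This note records the models implemented in `eoscreen`, the numerical and
design choices behind them, what the synthetic-data generators do and do not
emulate, and known limitations.

## Composition tables and chemotyping

A composition panel is a cultivar × compound matrix of relative peak-area
percentages (a compound's GC peak area as a fraction of total integrated
area), reported as mean ± SD over replicate injections. Entries printed as
"not detected" are stored as true zeros with an `absent` flag, so class
totals and correlations treat them as zeros; percentages are **not**
renormalized on load — renormalization happens only inside the replicate
generator, where it is a modeling choice.

Retention indices use the temperature-programmed (van den Dool–Kratz)
linear form `RI = 100·(n + (rt − rt_n)/(rt_{n+1} − rt_n))`; the run the
packaged panel comes from is temperature-programmed, which is why the
linear rather than the logarithmic (isothermal Kováts) form is used. No
extrapolation outside the alkane ladder is permitted.

Class totals come in two flavours. `class_sums` aggregates by the strict
compound-class annotation (monoterpene hydrocarbon / alcohol / ketone /
ether / ester, sesquiterpene, miscellaneous). `summary_rows` reproduces the
printed summary convention of the packaged table, which pools oxygenated
sesquiterpenoids (α-bisabolol) with the oxygenated monoterpenes and keeps
only sesquiterpene hydrocarbons in the sesquiterpene row; each compound
record carries an `oxygenated` flag to support this. The two conventions
differ for exactly one compound in the packaged panel.

Chemotype rules fire independently (α-pinene > 20%, camphor > 20%,
verbenone > 15%, 1,8-cineole above a configurable threshold defaulting to
20% — no published threshold exists for the cineole type). Labels are
ordered by the triggering component's percentage. The cineole label is
suppressed when another rule component exceeds the cineole percentage:
oils dominated by a different component then keep a single unambiguous
call, which is how mixed high-cineole/high-pinene profiles are
conventionally named.

## Assay arithmetic

All plate conversions are deterministic well-level arithmetic:
scavenging `(OD_blank − OD_sample)·100/OD_blank` (DPPH at 515 nm, ABTS at
734 nm — the formula is identical), ROS reduction relative to the vehicle
intensity, viability `OD_treated·100/OD_vehicle`, and FRAP Trolox
equivalents by inverting the linear standard curve with
`ΔOD = OD_sample − OD_blank` (sign convention kept verbatim from the kit
protocol). Negative scavenging (pro-oxidant wells), sub-calibration FRAP
values and viabilities above 100% are physically meaningful and are
returned with warnings, never clipped. Replicates are aggregated as
mean ± SD of per-well ratios (mean-of-ratios — the usual plate practice);
no background-well subtraction is modeled beyond an optional additive
background parameter defaulting to zero.

## TOPSIS

The canonical unweighted procedure: vector normalization per criterion
column, per-column best/worst ideal solutions (direction-aware: benefit
columns take max as A⁺, cost columns take min), Euclidean separations, and
`Cᵢ = D⁻ᵢ/(D⁺ᵢ + D⁻ᵢ)`. Optional positive weights summing to 1 are folded
into the separation distances — the standard weighted variant, off by
default because the canonical equations are unweighted. Ranks are assigned
1 = largest Cᵢ with stable tie-breaking by input order and an explicit tie
flag. All four antioxidant criteria default to benefit direction.
Degenerate inputs raise typed errors: an all-zero criterion column
(normalization undefined) and coincident ideals (Cᵢ undefined). Negative
entries are tolerated by the normalization but violate ideal-point
semantics for benefit data, so they trigger a warning and an optional
min-shift (off by default).

## Dose–response

Viability against concentration c (mg/mL throughout; no molar conversion)
follows the four-parameter logistic
`f(c) = bottom + (top − bottom)/(1 + (c/x₀)^hill)`. Fitting is nonlinear
least squares on log-concentration with the midpoint and hill slope
parametrized on the log scale (positivity by construction) and a
deterministic multi-start grid over the hill slope {0.5, 1, 2, 4}, plus a
flat start that guarantees the fitted RSS never exceeds the flat-mean
model's. The x₀ initializer is the dose level whose mean response is
closest to mid-range; it depends on the data only through log-ratios, so
the whole procedure is scale-equivariant (multiplying concentrations by k
multiplies IC50 by k) — exactly in exact arithmetic, to ~1e−8 relative in
floating point because the solver's stopping rules are relative in the
shifted log-midpoint parameter. Insufficient response variation yields
`converged = False`, never an exception.

IC50 defaults to the **absolute** convention — the concentration where the
fitted curve crosses 50% of vehicle-normalized viability,
`IC50 = x₀·((top − bottom)/(50 − bottom) − 1)^{1/hill}` — because "half
inhibition" refers to half of the vehicle level; the relative convention
(curve midpoint x₀) is kept for comparison with midpoint-reporting tools.
A curve that never reaches 50% returns NaN with a not-crossed warning.

Uncertainty comes from a case-resampling bootstrap: replicate wells are
resampled with replacement within each concentration level, the curve is
refit from the original solution, and a percentile 95% interval is taken.
**Known limitation:** with only three wells per level this percentile
interval undercovers — a coverage simulation over 50 seeded series (σ = 5
viability points, 8 levels × 3 replicates) contains the true IC50 in 40/50
runs (80%) at 95% nominal. This is the familiar small-sample bias of the
percentile bootstrap, not a convergence failure; the test suite freezes the
measured behaviour.

## OPLS-DA and VIP

Class labels are one-hot encoded and centered; X is mean-centered and
scaled. Structured variation orthogonal to the classes is removed
iteratively before predictive PLS2 components (NIPALS) are extracted from
the filtered matrix. With more than two classes the orthogonal loading is
orthogonalized against the **full** predictive weight subspace (all left
singular vectors of XᵀY), not just the dominant direction: the two-class
textbook recipe otherwise leaks class-predictive variation into the
"orthogonal" component and corrupts downstream variable importance. With
this filter the VIP ranking on the packaged panel is insensitive to the
number of orthogonal components (0–2 tested). Defaults: one orthogonal
component, K − 1 predictive components for K classes, leave-one-out Q² on
the class response.

Scaling defaults to **pareto** (center, divide by √SD). On relative-area
composition data, unit-variance scaling gives every compound identical
total variance, so near-binary trace compounds — detected in some cultivars
and absent in others, hence perfect class markers with tiny within-class
noise — saturate the discrimination and the VIP ranking, drowning the
abundant constituents that actually carry the mass differences. Pareto
keeps abundance ordering in play while still damping scale; with it (or
with no scaling) the five main constituents top the VIP ranking in every
seeded reconstruction of the panel, matching the screening study's
qualitative finding, whereas unit variance never does. Unit-variance and
unscaled modes remain available.

VIP over the predictive components is
`VIP_j = √(p·Σ_a w²_aj·SSY_a / Σ_a SSY_a)` with unit-norm weight vectors,
so `Σ_j VIP²_j = p` holds by construction (verified to 1e−8 on every fit);
VIP > 1 marks an above-average discriminator.

The replicate-level reconstruction protocol exists because a model with
one sample per class is degenerate: three synthetic replicates per cultivar
are drawn from the printed means ± SDs (below) and the cultivar is the
class.

## Random-forest importance

`RandomForestRegressor` (500 trees, `max_features = 1/3` — the regression
convention, bootstrap resampling, fixed seed → bit-identical importances)
with importance measured as node purity: the decrease in weighted node
residual sum of squares attributed to each splitting variable, summed
within a tree and averaged over trees. A constant response yields all-zero
importances with a warning.

**Identifiability caveat.** On the six-cultivar panel, a response planted
on one compound (e.g. verbenone driving the closeness index) is recovered
as the top importance only in a plurality of seeds, not all: compounds
detected *only* in the two high-verbenone cultivars are near-perfect
proxies for the planted response at cultivar level, and node-purity credit
is split among correlated splitters according to which of them the
`max_features` draw offers at each node. Planted-driver recovery is
therefore asserted in aggregate (highest importance summed over 20 seeded
reconstructions, where verbenone leads deterministically) rather than per
run. On uncorrelated features the same forest recovers a planted driver at
signal-to-noise 5:1 in ≥ 95/100 seeds (n = 60), so the ambiguity is a
property of compositional confounding, not of the estimator.

## Spearman correlation

Tie-corrected ρ (Pearson correlation of midranks). With n ≤ 8 paired
observations the p-value is an exact two-sided permutation test — all n!
permutations of one margin's ranks are enumerated and the fraction with
|ρ| at least the observed value (within 1e−12) reported — because the
t-approximation is unreliable at the panel's n = 6; larger n uses the
t-approximation. Constant inputs yield an undefined (NaN) correlation
rather than an error. Stars follow the *, **, *** convention at 0.05, 0.01
and 0.001. Multiple-testing control (Benjamini–Hochberg per endpoint
family) is available in the pipeline but **off by default**, mirroring the
raw-p star convention of the screening literature.

## Synthetic data

The generators emulate the raw layers the published tables summarize; all
are driven by `numpy.random.default_rng(seed)` and record their seed.

* **Composition replicates**: each compound is drawn from a normal
  truncated at zero with the printed mean and SD, then the replicate vector
  is renormalized to the cultivar's printed identified total (closure
  within 1e−9). Truncated-normal-plus-renormalization is the simplest
  compositional noise model consistent with mean ± SD reporting; it is a
  modeling choice, not a claim about the instrument. Renormalization
  induces the negative within-replicate correlations real compositional
  data have — and also couples trace-compound noise to the dominant
  compounds, which is one source of the importance-sharing caveat above.
  Absent compounds stay exactly zero.
* **Assay plates**: sample wells read `blank·(1 − s/100)·(1 + ε)`,
  ε ~ N(0, cv), so the per-well ratio conversion recovers the configured
  scavenging s exactly at cv = 0; FRAP plates encode Trolox equivalents
  through the packaged standard curve the same way. Default cv = 0.02 is an
  arbitrary plate-noise setting, exposed in the generator signature.
* **Dose–response wells**: 4PL truth plus Gaussian viability noise
  (default σ = 5 percentage points, 8 log-spaced levels × 3 replicates).
* **Planted activity**: endpoint = slope · driver% + noise, giving exact
  ρ = ±1 at zero noise.
* **Decision matrices**: positive uniform entries; an optional dominant
  row is lifted above the column-wise max of the others, which forces
  Cᵢ = 1 and rank 1.

What the generators do **not** emulate: chromatographic peak shape and
retention drift, instrument-specific heteroscedasticity, plate-position
effects, or any biological mechanism linking composition to activity.
Passing recovery tests therefore demonstrates that the estimators invert
the stated generative models at realistic noise — not that the biological
conclusions of any particular screening study are correct.

## Problem sizes used by the test and acceptance runs

Oracle-equivalence checks run 1,000 random TOPSIS instances (m ≤ 8,
n ≤ 6); IC50 recovery uses 100 seeded series; planted-forest recovery 100
seeded trials at n = 60 with 500 trees; VIP reconstruction 20 seeded
replicate panels; bootstrap coverage 50 series × 150 draws. These sizes
give stable pass/fail behaviour at interactive runtimes.

## Published values used as anchors vs. metadata

The packaged separation table (Di±, Ci, ranks) anchors the closeness and
ranking arithmetic; the upstream 6 × 4 assay matrix behind it was never
published, so it is not reconstructed. The printed per-compound and per-oil
IC50 values ship as reference metadata only — the raw viability curves
behind them are not public and no fit is compared against them. Printed
VIP magnitudes and forest-importance magnitudes are figure-only; only set
membership and ordering are reproduced.
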