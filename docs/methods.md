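# Methods

## The single-cosinor model

A periodic signal sampled across the day is modelled as

    Y(t) = M + A·cos(2πt/τ + φ) + ε,   ε ~ N(0, σ²)

with MESOR M, amplitude A ≥ 0, acrophase angle φ, and period τ fixed at
24 h. The period is a parameter of the analysis, not an estimate: with six
timepoints per cycle and one sample per subject there is no power to
estimate it, and comparing groups requires a common τ. The fit is plain
OLS on the linearized regressors x = cos(2πt/τ), z = sin(2πt/τ), giving
coefficients (M, β, γ) with β = A·cos φ, γ = −A·sin φ. Delinearization:
A = √(β²+γ²), φ = atan2(−γ, β), and the acrophase as peak clock time
a = (−φ·τ/2π) mod τ on [0, τ). The residual variance uses denominator
n − 3 (three fitted coefficients); the coefficient covariance is
σ̂²(XᵀX)⁻¹, and the amplitude and acrophase standard errors follow by the
delta method (gradients (β, γ)/A and (γ, −β)/A² respectively, the latter
scaled by τ/2π to hours). No weighting or robust loss is applied — the
additive homoscedastic Gaussian error is the model the estimator assumes,
and the synthetic generator produces exactly that.

With a balanced design — equal n at τ-equispaced timepoints — XᵀX is
exactly diag(n, n/2, n/2), so the MESOR standard error collapses to
√(σ̂²/n) and the amplitude's to √(2σ̂²/n); the tests assert this closed
form as a guard on the linear algebra.

**Degenerate inputs.** Fewer than 4 observations or fewer than 3 distinct
timepoints (mod τ) raise explicit errors rather than falling through to a
pseudo-inverse. A fitted amplitude below 1e−10·max(1, |M|) is treated as
numerically zero: the fit is flagged `amplitude_defined = False`, the
acrophase fields are NaN, and downstream comparisons return flagged
non-results instead of propagating NaN. The zero-amplitude F-test
F = (MSS/2)/(RSS/(n−3)) handles its two degeneracies explicitly: flat
data (total variation at machine zero) gives F = 0, p = 1; a perfect
rhythmic fit (RSS at machine zero, MSS > 0) gives p = 0 with an infinite
statistic.

## Group comparison

The published methodology for this family of studies states only that
parameter comparisons use F-ratios with degrees of freedom reflecting the
number of populations and total subjects; the exact statistic is not
specified. This package uses a Wald-type construction: for parameter θ
with per-group delta-method standard errors,

    F = (θ̂₁ − θ̂₂)² / (SE₁² + SE₂²)   referred to F(1, n₁ + n₂ − 6),

six being the coefficients consumed by the two fits. In the balanced case
this reduces to a squared two-sample z/t. For the acrophase the numerator
difference is the signed circular difference
((a₁ − a₂ + τ/2) mod τ) − τ/2 ∈ (−τ/2, τ/2], with the antipodal boundary
assigned +τ/2. Monte-Carlo checks in the test suite confirm the null
p-values of all three tests are uniform and the type-I error at α = 0.05
falls in [0.035, 0.065] at n = 30 per group.

Because each animal is measured once, a per-subject cosinor fit is not
computable; the per-group estimate is the pooled single cosinor over all
subjects in the group. `population_mean_cosinor` is provided separately
for genuinely multi-series inputs (per-cage series, bootstrap replicates):
it averages the linearized (M, β, γ) across fits and delinearizes the mean
vector — the only averaging that is correct near the wrap (acrophases of
1 h and 23 h average to 0 h) — with between-fit standard errors for k ≥ 2.

Within-timepoint tests are pooled-variance Student's t (two-sided), with
Welch available by flag. Multiple testing uses Benjamini–Hochberg step-up
FDR, applied across features *within each test family* (zero-amplitude;
MESOR; amplitude; acrophase comparison) per run; raw p-values are always
reported alongside. The timepoint companion table is BH-adjusted across
all its rows. No significance gate precedes the parameter comparisons:
comparison p-values are reported even when a group's zero-amplitude test
is non-significant, matching how such tables are conventionally printed.

## Microbiome stage

Counts are aggregated to a taxonomy rank by exact integer summation over
taxa sharing the rank label (semicolon-delimited lineages; a blank rank
buckets into `unclassified_<nearest assigned ancestor>`), then converted
to per-sample proportions. Per-taxon rhythm analysis runs the cosinor
pipeline on the raw proportion scale — microbiome MESORs are then directly
interpretable as mean proportions — with an optional arcsine-square-root
transform (off by default). The default flagging threshold for taxa is
adjusted p < 0.01.

Community-level group differences use PERMANOVA on Bray–Curtis
dissimilarities (BC(u,v) = Σ|uᵢ−vᵢ| / Σ(uᵢ+vᵢ)). The pseudo-F is
Anderson's: among-group versus within-group sums of squared
dissimilarities with (a−1, n−a) degrees of freedom; the p-value is
(1 + #{F_perm ≥ F_obs}) / (1 + n_perm) under seeded random relabelling —
the +1 correction means p is never exactly 0, and the permutation stream
is a pure function of the seed. The implementation is validated against
scikit-bio's PERMANOVA statistic and against exhaustive enumeration of
all 20 label assignments of a 3+3 design. Ordination (CCA/PCoA plots) is
out of scope; the distance-based test is the quantitative statement.

## Synthetic data

The cohort generator draws, for each group × timepoint cell, n subjects
with value M + A·cos(2π(t − a)/τ) + N(0, σ²), on the standard design
(ZT2…ZT22 at 4-h spacing; n per cell either fixed or uniform on {3,…,6},
mirroring typical per-cell sample sizes). Where a study scenario supplies
no dispersion, the convention σ = A/4 is used — a clearly detectable
rhythm with visible individual scatter. The community generator computes
time-varying expected proportions baseline + Aᵢ·cos(2π(t − aᵢ)/τ),
renormalized; draws a composition from Dirichlet(concentration ×
expected), with concentration = ∞ meaning no overdispersion (defaults:
concentration 200, a moderately overdispersed community); and draws
multinomial counts at a lognormal library size (median 20 000, log-sd
0.25). Amplitudes that would drive any expected proportion to zero are a
validation error. All generators are pure functions of (spec, seed).

What the generators deliberately do not emulate: heteroscedastic or
non-Gaussian measurement error, repeated-measures autocorrelation,
16S-specific artifacts (chimeras, copy-number variation), and real
phylogenetic covariance between taxa. Passing tests therefore demonstrate
correctness of the estimators and tests under their assumed sampling
model, not robustness to those violations.

## Verification and problem sizes

Every estimator is checked against an independent oracle: the OLS solve
against explicit 3×3 normal-equations inversion (1e−8), the zero-amplitude
p against the incomplete-beta F tail (1e−10), BH against a brute-force
step-up implementation on 1000 random vectors, the t-test against the
textbook formula, PERMANOVA against scikit-bio and exhaustive enumeration.
Calibration studies use 1000–2000 Monte-Carlo replicates (null uniformity,
type-I error bands), power studies 100–200 replicates, and the recovery
studies behind the headline numbers 500 replicate cohorts of 48 subjects —
sizes at which the three-coefficient fits make the whole suite run in
about a minute on one core while keeping Monte-Carlo error well inside the
asserted bands.

## Known limitations

Fixed 24-h period only; single-component cosinor (no harmonics); two-group
comparisons only (no omnibus >2-group test, no Bingham joint
amplitude-acrophase test); cross-sectional designs (no longitudinal
correlation structure); the acrophase comparison assumes each group's
rhythm is detectable — when an amplitude is numerically zero the
comparison is flagged rather than computed.
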