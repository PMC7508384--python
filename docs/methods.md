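# Methods

This note documents the models and procedures implemented in vesselmorph,
the assumptions behind them, the defaults and why they were chosen, and the
limits of what the synthetic-data tests demonstrate.

## Profiles, outlines and processing

A *profile* is the ordered right-half cross-section of an axisymmetric
object: points `(x, y)` with `x ≥ 0` the radial distance from the rotation
axis (cm) and `y` the height (cm), running base → rim. Digitised profiles
arrive in pixels; calibration divides by per-axis pixel-per-cm factors
obtained from a reference object (per-axis factors are retained because
video pixels need not be square; they reduce to one scalar when equal).

Processing steps, in order:

* **Resampling** to `n_points = 256` radii at equally spaced heights
  between `min(y)` and `max(y)`, by linear interpolation, endpoints
  preserved exactly. Re-entrant profiles (two radii at one height that a
  stable sort cannot reconcile) are rejected rather than guessed at —
  wheel-thrown wet-clay outlines as digitised here are functions of height.
* **Smoothing** of the radius sequence with a 2nd-order Butterworth filter
  applied forward–backward (`filtfilt`), default cutoff 0.15 × the spatial
  Nyquist frequency of the height sampling. The zero-phase property matters:
  a causal filter would shift the belly and rim features downward. The
  digitising noise this removes sits near Nyquist; 0.15 leaves vessel-scale
  geometry (a few undulations per height) untouched. The source analyses
  name no particular filter, so downstream statistics may be mildly
  sensitive to this choice; the cutoff is exposed in the configuration.
* **Mirroring** closes the profile into a full outline: starting on the
  rotation axis at the base, up the right edge, a straight chord across the
  rim to the mirrored rim point, down the mirrored left edge, and a chord
  across the base, traversed counterclockwise with y up. Straight chords are
  the minimal closure assumption and match a horizontal clay surface at the
  rim and a flat base; on-axis endpoints produce no chord. The fixed start
  point and orientation make Fourier coefficients comparable across runs.

## Size metrics

Height, maximal diameter (`2·max x`), and exterior surface area (ESA), the
lateral area of the surface of revolution:
`ESA = Σ π (x_i + x_{i+1}) · slant_i` over consecutive profile points. This
frustum sum is exact for cones and cylinders and second-order accurate
otherwise; at 256 points the discretisation error on smooth vessel profiles
is far below 0.1%. Base and rim discs are excluded (lateral surface only):
whether the original measure included the base disc is not stated anywhere,
and the lateral-only definition is insensitive to the open/closed-top
ambiguity of intermediate stages. Coefficients of variation are
`100 · SD / mean` with the n−1 standard deviation.

Trial time courses are normalized by splitting the span between first and
last gesture into 20 equal bins; a stage at time `s` falls in bin
`min(20, floor(20·(s−t_first)/(t_last−t_first)) + 1)` — left-closed bins,
first stage in bin 1, last stage clamped into bin 20. Boundary handling is
a convention (the bin count is given, the edges are not); this one keeps
bins nondecreasing along a trial and pins both endpoints.

## Elliptical Fourier analysis

For a closed polygonal outline parametrised by cumulative arc length `t`
over one traversal of perimeter `T`:

    x(t) = A0 + Σ_n a_n cos(2πnt/T) + b_n sin(2πnt/T)
    y(t) = C0 + Σ_n c_n cos(2πnt/T) + d_n sin(2πnt/T)

The implementation evaluates the classic closed-form sums for piecewise
linear contours (the chain-code formulation generalised to real segment
increments), which are the exact Fourier integrals of the polygon — an
independent dense-quadrature oracle in the test suite confirms agreement to
1e-8. Bias terms are the exact means of the piecewise-linear coordinate
functions.

**Size normalization** divides all harmonic coefficients by the semi-major
axis length of the first-harmonic ellipse — the largest singular value of
`[[a1, b1], [c1, d1]]` — and zeroes the bias terms, leaving scale- and
translation-invariant descriptors with a unit first harmonic. Dividing by
`|a1|` instead is available (`norm_method="a1"`); the two differ only when
the first-harmonic ellipse is oblique, and the semi-major axis is the
variant that is invariant to the coordinate frame. No rotation or
start-point normalization is applied: all outlines share the vessel frame
(axis at `x = 0`, base at the start point), where orientation itself is
meaningful.

Default `n_harmonics = 20`: on simulated vessel outlines the first 20
harmonics carry > 99.9% of the harmonic power; the value is configurable.

**A note on parametrisation.** Re-extracting coefficients from a
reconstructed curve is only an exact inverse when the same parametrisation
is used on both sides. `reconstruct` samples uniformly in the Fourier
parameter; re-analysis with `efa_coefficients(..., param="index")`
reproduces the coefficients to ~1e-6, whereas the default arc-length
re-extraction is a *reparametrisation* that shifts coefficients at first
order in the deviation from constant speed (about 1e-3 relative for vessel
outlines). The same distinction explains why an eccentric ellipse is a
single harmonic in its elliptic angle but not in arc length. All analyses
in the pipeline use the arc-length convention consistently, so the
distinction never affects comparisons between outlines.

## Shape space

PCA is computed by spectral decomposition of the covariance matrix of the
normalized coefficient vectors (covariance, not correlation: after size
normalization all coefficients share one scale, and standardising would
inflate the noise-dominated high harmonics). Components are sorted by
decreasing variance with a deterministic sign (largest-magnitude loading
positive) for cross-platform reproducibility. Scores on the first three
components are used for trajectories and distances, mirroring the 3D
shape-space convention of the source analyses; full-space distances are
available (`transform(..., k=None)` with all components), and because the
basis is orthonormal they equal distances between centered coefficient
vectors exactly.

Stage dispersion is summarised per trial as the Euclidean distance (3D by
default) from the mean score of the trial's pool at that stage — the whole
potter pool, or one community's pool; the reference mean changes with the
pool considered.

## Mixed models

All mixed models are fitted by **direct maximum likelihood** (never REML,
so that likelihood-ratio tests remain valid across changes in both fixed
and random structure):

    y_i = X_i β + Z_i b_i + e_i,  b_i ~ N(0, Ψ),
    e_i ~ N(0, σ² diag(δ²_{s(i)}))

per independent group `i` (potter). β and σ² are profiled out analytically;
the remaining parameters — the log-Cholesky factor of the relative
covariance Ψ/σ² and the log variance ratios δ_s (reference stratum fixed at
1) — are optimised by L-BFGS-B with a Nelder–Mead polishing pass.
Variance-ratio parameters are bounded away from zero on the log scale
(e^-16), which handles boundary (zero-variance) fits gracefully. On
fixtures, log-likelihoods, fixed effects and variance components agree with
the standard R mixed-model implementations to 5–6 decimals.

**Growth curves.** `esa ~ poly(bin, 3)` with orthogonal polynomials built by
QR (Gram–Schmidt) on the observed bin values, so linear/quadratic/cubic
trends are separately interpretable. Random-effects structures: none /
per-potter intercept / intercept plus random slopes on all three time terms
with an **unstructured 4×4 covariance** — so the intercept→slopes
comparison adds 9 parameters (χ² df = 9) and none→intercept adds 1. A
two-level community fixed effect adds a main effect plus interactions with
the three time terms (df = 4). Response values are internally standardised
before optimisation and results mapped back, for conditioning.

**Stage model.** `distance ~ Stage` (pre-formed vs final) with a per-potter
random intercept and a free residual SD per potter stratum
(heteroscedastic: trial scatter differs strongly between potters and
stages). The Stage test is a Wald F with numerator df 1 and denominator df
`N − n_potters − 1` (the within-group residual df after the grouping level
and the Stage term — the convention of the reference implementation this
model mirrors, whose `N/(N−p)` covariance adjustment is also applied). With
the random intercept and heteroscedasticity disabled the F reduces exactly
to the classical one-way F.

## PERMANOVA

With pairwise Euclidean distances among coefficient vectors,
`SS_T = (1/N) Σ_{i<j} d²_ij` is split into within-group
`SS_W = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij` and among-group `SS_A = SS_T − SS_W`;
`pseudo-F = (SS_A/(a−1)) / (SS_W/(N−a))` and `R² = SS_A/SS_T`. Significance
comes from whole-row relabelings: **exhaustive enumeration** over all
distinct label arrangements when there are at most 100,000 of them
(`p = #{F* ≥ F}/n_total`, the identity included), otherwise 9,999 seeded
random permutations with `p = (1 + #{F* ≥ F})/(1 + n_perm)`. With few
observations the attainable p is bounded below by the probability that a
random relabeling reproduces the observed partition — exact small-sample
behaviour, not a deficiency. R² is invariant to global feature scaling, and
for univariate features the pseudo-F equals the classical one-way ANOVA F.

## ANOVA reconstructions from summary statistics

Published assemblage tables report per-potter means and CVs over n = 5
trials. From these, one-way and community-level F statistics are
reconstructed exactly: `SS_between` from the group means,
`SS_within = Σ (n−1)·SD²` with `SD = CV·mean/100`. The Community F in the
Community × Trial repeated-measures design uses the potters-within-community
mean square as its error term, df `(communities−1, potters−communities)`.
Generalized eta-squared follows the effect-SS-over-effect-plus-all-error-SS
definition, with all within-potter variation treated as error (the
convention that reproduces the published effect sizes from the published
table to rounding). Inputs being rounded to 2–3 significant digits, the
reconstructed F values are accurate to a few tenths of a percent.

## Synthetic studies

The generator emulates the *statistical structure* the analyses assume, not
the physics of throwing.

* **Profile family.** A two-segment superellipse radius function: from the
  base radius up to the maximal radius at the belly height
  (`max_diameter_rel_height · height`), then down to the aperture radius,
  with a common bulge exponent k (`r/r_max` and the normalized height obey
  `u^k + (r/r_max)^k = 1` per segment). k = 2 gives circular arcs — with
  on-axis ends the family is exactly a sphere, anchoring closed-form tests;
  large k approaches a cylinder; k < 1 gives conical flanks. A `rim_depth`
  parameter cuts a shallow groove just below the lip. The family covers the
  cylinder → barrel → sphere-like range of observed thrown forms.
* **Routes.** Each potter archetype owns a pre-form, optional waypoint
  shapes, and a personal final target: the shared type form multiplied by a
  fixed signature drawn deterministically from the potter id — a common
  size factor (SD 3× the shape scale; makers work with self-selected clay
  quantities, so final size varies far more between potters than shape)
  plus per-parameter shape offsets (default relative SD 0.04). Stages
  interpolate linearly through parameter space with multiplicative Gaussian
  trial noise (default 0.035) truncated to the valid domain.
* **Counts and times.** Defaults mirror the field design: 7 potters in two
  communities (4 + 3), 5 trials per vessel type, gesture counts per potter
  in 5–12, inter-gesture intervals gamma-distributed (shape 6 — positive
  and right-skewed) with per-potter scales chosen so trial durations span
  roughly 60–160 s. No distributional description of gesture timing exists
  for the real data; these are plausible stand-ins, not calibrations.
* **Seeding.** Per-trial seeds are BLAKE2 hashes of
  (study seed, potter, type, trial index), so any subset regenerates
  identically; identical configurations yield byte-identical datasets and
  reports.

What passing synthetic tests do show: the estimators recover known
parameters, the test statistics match their oracles, and the pipeline
reproduces the qualitative signature of the phenomenon (pre-formed-stage
among-potter R² ≫ final-stage R²; distances to group mean shrink). What
they do not show: anything about digitisation error of real video tracings,
non-axisymmetric defects, re-entrant rims, or the actual effect sizes in
real assemblages — the generator's parameter-space routes are smoother than
real gesture-by-gesture shape change.

## Numerical choices and degenerate inputs

* Zero-height or zero-perimeter geometry, constant feature matrices,
  single-member PERMANOVA groups, zero-variance correlations and zero-mean
  CVs raise typed errors naming the violated condition.
* LRT χ² is clipped at zero; if the full model's log-likelihood falls below
  the reduced one by more than optimizer tolerance, a fit error is raised
  instead of reporting a negative χ².
* Perfect correlations are snapped to ±1 within 1e-12 so the Fisher CI
  endpoint is exact.
* Reports round floats to 6 decimals and sort keys, making reruns
  byte-identical.

## Problem sizes in the test and acceptance runs

The shipped suites use deliberately small instances: unit tests run a
reduced study (7 potters × 3 trials, 96-point profiles, 12 harmonics);
calibration checks use 300–1000 simulation replicates with a few hundred
permutations each; the acceptance script runs the full default study
(7 × 5 trials, 256-point profiles, 20 harmonics, 1,999 permutations).
These sizes give Monte-Carlo error well inside the asserted bands while
keeping a full run in minutes on one core.

## Known limitations

* Only profiles that are functions of height are supported; strongly
  re-entrant rims would need a different parametrisation.
* ML variance components are biased low by O(1/m) with m = 7 potters; the
  LRT df conventions follow the unstructured-covariance bookkeeping and
  would change under a diagonal random-slope covariance.
* The permutation test treats trials as exchangeable units under the null;
  stage-to-stage dependence within a trial is respected only insofar as
  each stage is tested separately.
* The generator's gesture timing and noise scales are not calibrated to any
  real dataset.
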