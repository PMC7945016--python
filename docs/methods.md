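# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would want recorded.

## Trajectory model

Each region's encoding contrast is modelled as

    y_i = β0 + β_sex · sex_i + f(age_i) + ε_i,    ε_i ~ N(0, σ²),

with `f` a cubic B-spline of basis dimension 10 (equally spaced interior
knots over the observed age range) penalized by `λ ∫ f″(x)² dx`.  The
penalty's null space is exactly {constant, linear}, so a truly linear
age relationship shrinks to one effective degree of freedom; the
second-derivative Gram matrix is computed exactly (two-point Gauss per
knot interval, exact for cubics).  An earlier difference-penalty variant
was rejected because, with repeated boundary knots, its null space is not
the linear functions and a linear signal never reaches edf = 1.

`λ` is chosen by restricted maximum likelihood: the penalized spline is
the mixed model with the penalized directions as random effects, the
fixed effects (intercept, sex, linear trend) are projected out, and the
profiled REML criterion is minimized over log λ on the singular values of
the projected random-effects design.  Because the cohort design (age,
sex) is shared across regions, this decomposition is computed once per
cohort and each regional fit costs well under a millisecond, which is
what makes the resampling analyses (half-split, motion, null
calibrations) cheap.  The implementation is cross-checked in the test
suite against R `mgcv` (REML, `k = 10`) on the same data: fitted curves
agree to a few hundredths of the response SD and edf to a few tenths,
the residual discrepancy being the different spline bases.

**Significance of the smooth.**  Tests conditioning on the selected λ and
using edf as degrees of freedom are anti-conservative (measured ~8.4%
rejections at α = 0.05 under the null), so the reported `age_F`/`age_p`
come from the exact F test of the *unpenalized* spline basis against the
sex-only model.  Under Gaussian errors this test is exactly calibrated
(measured: Kolmogorov–Smirnov p = 0.73 against uniform over 500 null
replicates); its numerator spreads the signal over the full basis rank,
so F values are smaller than an edf-based test would print, while
p-values remain valid.  The penalized fit still supplies the curve, the
derivative and edf.

**Mean activity** is the model intercept (reference sex coded 0); fitted
curves on the grid are population-averaged over the observed sex mix.

**Outliers.**  One pass: observations with |residual| > 4 residual SDs
under the initial fit are dropped and the model is refit once, keeping
the original grid bounds.  The pass is not iterated — a second pass
changes nothing on clean data and invites over-trimming on heavy-tailed
data.  With an infinite threshold the original fit object is returned
unchanged.

**Memory-effect screen.**  "No evidence of subsequent-memory activity"
is operationalized per region as the Bonferroni combination
`p = min(1, 2·min(p_intercept, p_age))` of the exact intercept t test and
the exact age F test, followed by Benjamini–Hochberg FDR at α = 0.05
across the region family; unflagged regions form cluster 0.  Combining
before FDR keeps the per-null-region false-flag rate near α rather than
2α when many regions carry real signal.

## Clustering

The dissimilarity between regions is the raw sum of squared differences
of their derivative vectors over the 100-point grid (no normalization —
any monotone rescaling leaves k-medoids and silhouette rankings
unchanged).  Derivatives are central finite differences on the grid
(exact for quadratics; one-sided at the endpoints), making the clustering
invariant to adding a constant to any region's activity.

k-medoids is deterministic.  When the number of candidate medoid subsets
C(n, k) is at most 10,000 the problem is solved exactly by enumeration;
beyond that, classical BUILD + SWAP local search runs with ties broken by
the lowest region index.  The exact branch exists because the swap
neighborhood has genuine local optima even on 8-point problems (R's
reference implementation stalls on roughly 10% of random instances); at
pipeline scale the heuristic is used and is verified 1-swap-optimal.

k is selected from 2–10 by maximizing the average silhouette width
(singleton clusters score 0); the full silhouette-vs-k profile is kept so
secondary local optima can be reported.  Cluster labels are canonicalized
by descending size.  Half-split replication stratifies the random split
by age decile × sex so both halves span the age range; agreement between
runs is the adjusted Rand index restricted to regions flagged in both.

## Association stage

Per cluster, subject scores are the first principal component of the
column-centered subjects × regions submatrix, sign-oriented to correlate
positively with the cluster's mean activity.  Associations are additive
models `score ~ s(age) + s(covariate) + sex` with independent REML-chosen
penalties; a wiggliness multiplier γ (default 2 for this stage) divides
the effective sample size in the REML criterion, forcing smoother partial
curves.  Covariate significance again uses the exact unpenalized nested-F
test, which degrades gracefully to F = 0, p = 1 when the covariate is
collinear with age (rank-deficient designs are handled by pseudoinverse).
FDR families are explicit arguments: the convention is clusters tested ×
covariates in the stage (e.g. 6 × 4 = 24 for four cognitive tests across
six clusters including cluster 0), and the family size is recorded in the
output alongside each q-value.

## Topology stage

The enrichment statistic per cluster and map is the cluster's mean map
value minus the mean over all other effect regions; the null permutes
cluster labels over regions (preserving cluster sizes), with two-sided
p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1), floored at 1/(n_perm + 1).
Pairwise cluster-vs-cluster contrasts are available behind a flag.  Note
a property of the one-vs-rest statistic: a strong elevation in one
cluster contaminates the complement of the others, so mild "depletions"
elsewhere can reach significance; the pairwise contrasts disambiguate.
Maps with skewed marginals (evolutionary expansion, roughly exponential)
are rank-transformed (mid-ranks), making results invariant to monotone
re-expressions.  Regions with missing map values (subcortex for
surface-only maps) are dropped per map.  Spatial-autocorrelation-
preserving nulls are deliberately out of scope; the null is plain label
exchange.

## Synthetic data

The generator emulates the statistical structure of a lifespan encoding
study, not its physiology.  Canonical shapes are fixed closed forms of
normalized age a ∈ [0, 1] — monotonic `a`, U `(2a−1)²`, weak inverted U
`0.4(1−(2a−1)²)`, steep inverted U `1−(2a−1)²`, developmental plateau
`min(a/0.3, 1)`, null `0` — with default amplitude 0.5 (percent-signal-
change scale) and per-cluster baselines giving cluster 2 negative mean
effects.  Defaults are desk scale: 120 regions (20 null / 35 / 20 / 20 /
15 / 10, echoing the strongly unequal sizes such solutions produce) and
300 subjects; full scale (416 regions, 540 subjects) is available by
argument.  Ages are uniform on [6, 82] (the real cohort's age
distribution is unknown); sexes are Bernoulli(½); motion has a U-shaped
age profile with the steeper limb in childhood.  Activity noise defaults
to 0.25 × amplitude, the regime where recovery of the planted partition
is essentially perfect — the noise grid tests document how recovery
degrades beyond it.

The trial generator drives recognition, association and source-accuracy
rates from a single age-dependent signal (steep inverted U by default) so
that a zero signal leaves the corrected index at 0 in expectation (Q3 at
the 50% two-alternative chance level) and a maximal signal drives it to
1.  Grey-matter components hit configurable age-R² targets (defaults 0.86
monotone-decreasing and 0.46 inverted-U); cognitive scores follow
inverted-U (task memory, verbal learning, matrices) and rise-then-plateau
(vocabulary) profiles, with an optional planted partial correlation
between a designated cluster's activity score and chosen covariates.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: spatial correlation between neighboring
regions, heteroscedastic or age-dependent noise, site/scanner effects,
non-uniform age sampling, true motion-activity coupling, and any
voxel-level or hemodynamic structure (generation starts at the
ROI-contrast level).

## Problem sizes and runtime

The default test fixture (120 regions × 300 subjects) runs the full
pipeline in well under a second; the calibration tests use 400–1000
replicates (permutation size 999) and 500-replicate GAM nulls.  The
acceptance script reruns everything — including a 540-subject covariate
check and 10,000-permutation enrichments — in a few seconds on one CPU.

## Known limitations

- The unpenalized F test trades power for exact null calibration; with
  basis dimension 10 it is mildly conservative against very smooth
  alternatives compared with edf-based tests.
- REML smoothing assumes Gaussian errors; gross non-Gaussianity is only
  mitigated by the 4-SD outlier pass.
- Silhouette-based selection can absorb leaked null regions as an extra
  small cluster when the effect screen is imperfect (observed at some
  seeds: k = 6 with the planted five shapes plus a null cluster, planted
  assignments still perfectly recovered).
- The one-vs-rest enrichment statistic is not independent across
  clusters; its FDR correction treats the family as positively dependent.
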