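# Methods

## Model and scope

`metstab` analyses balanced multi-environment trials laid out as randomized
complete blocks within each environment. The plot-level model is

    y_ijk = mu + g_i + tau_j + (g tau)_ij + b_k(j) + eps_ijk

with i = 1..g genotypes, j = 1..e environments, k = 1..r blocks. For the
ANOVA table all effects are treated as fixed (the AMMI ANOVA convention);
randomness of genotypes and G×E enters only in the variance-component step,
where environments and blocks stay fixed. All stability statistics operate
on the genotype × environment matrix of cell means; balance is a hard
requirement for the decomposition paths (missing cells raise an error — no
imputation, deliberately: EM/AMMI imputation changes the estimand and is out
of scope).

## Variance components and genetic parameters

The balanced expected-mean-square equations are solved directly:
`σe² = MS_res`, `σge² = (MS_GxE − MS_res)/r`, `σg² = (MS_G − MS_GxE)/(re)`.
Negative method-of-moments solutions are truncated to zero and flagged.
Phenotypic variance defaults to the *component sum* `σp² = σg² + σge² + σe²`;
a `mean_basis` mode (`σg² + σge²/e + σe²/(er)`, the variance of a genotype
mean) is available — the component sum is the default because it is the
definition under which the reference study's printed σp² and h² are
mutually consistent.

Selective accuracy is `sqrt(1 − 1/F)` with `F = MS_G / MS_GxE`; F below 1
returns 0 with a warning rather than a complex number. Expected genetic gain
uses `GA = K σp h²` with K defaulting to 1.554, the standardized selection
differential for truncating the top 15% of a normal distribution;
`GAM = 100·GA/μ`. K is a plain argument for other selected fractions.

## Scott–Knott grouping

Means are sorted descending and split recursively at the contiguous cut
maximizing the between-group sum of squares B0. A cut is accepted when
`λ = π/(2(π−2)) · B0/σ̂0²` exceeds the χ² critical value at `ν0 = g/(π−2)`
degrees of freedom, with `σ̂0² = (Σ(ȳi−ȳ)² + ν·s²ȳ)/(g+ν)`, `s²ȳ =
MS_error/reps` and ν the error degrees of freedom. Identical means are never
separated: a boundary between equal values ends the recursion for that
group. Letters a, b, c… are assigned by descending group mean. The procedure
is greedy top-down; tests verify it lands within 5% of the exhaustive
contiguous-partition optimum at the returned number of groups.

## AMMI, ASV and GGE

AMMI decomposes the doubly centered residual matrix by SVD; scores carry
√λ on both sides (symmetric biplot scaling). The SVD sign indeterminacy is
fixed by forcing the largest-magnitude entry of each genotype-score column
positive, so outputs are platform-stable. ASV uses the canonical weighted
form `ASV_i = sqrt([(λ1²/λ2²)·IPCA1_i]² + IPCA2_i²)`; a second axis whose
singular value is below 1e−9 of the first is treated as degenerate.

GGE column-centers the cell means (environment centering, no scaling) and
allocates singular values per the `svp` setting: `environment` (default,
environment-metric preserving — the configuration under which vector lengths
and angles among environments are meaningful), `genotype`, or `symmetric`.
Which-won-where is defined on the PC1–PC2 plane only: the rank-2 model's
winner for environment j maximizes the inner product of genotype and
environment markers, and that maximizer is necessarily a convex-hull vertex,
so sectors are computed by assigning each environment to its argmax hull
vertex (equivalent to the perpendicular-ray construction, and invariant to
rotations of the whole configuration). Collinear genotype markers raise a
degenerate-geometry error. Environment discrimination is the marker's vector
length; representativeness is the cosine with the average-environment axis
(mean environment marker). Angles between environment vectors can be
classified acute/orthogonal/obtuse with a configurable ±5° orthogonality
band.

## Univariate indices — conventions that matter

* Environmental index `I_j = Ȳ.j − Ȳ..`; favorable means `I_j > 0`.
* Eberhart–Russell regresses each genotype's environment means on I_j;
  `S²d_i = Σδ²/(e−2) − MS_error/(r)` may be negative and is reported as
  computed (only its ranking is consumed); `RMSE = sqrt(Σδ²/e)`; R² is the
  determination coefficient of that regression. Perkins–Jinks applies the
  same regression to the interaction residuals, so `B_i = b_i − 1` exactly
  (tested as an identity).
* Annicchiarico works on percentages `p_ij = 100·Ȳ_ij/Ȳ.j` with population
  standard deviation and one-sided `Z_(1−α)`, α defaulting to 0.25
  (Z ≈ 0.675). The favorable/unfavorable split follows the sign of I_j; an
  empty class yields NaN with a warning rather than an error.
* DP is the population standard deviation of the genotype's plot-level
  observations; S²x is the (e−1)-denominator variance of its environment
  means. The two deliberately use different data levels — on the reference
  tables their orderings differ, which is only possible if DP includes
  within-cell replicate variation.
* Nassar–Hühn ranks genotypes within each environment after removing
  genotype main effects (`X_ij − Ȳi. + Ȳ..`), the canonical correction; a
  raw-rank mode exists. Ties get mid-ranks with a warning.

## BLUPs, HMGV, WAASB

Variance components feed exact balanced-case closed forms of the mixed-model
equations (environments and blocks fixed; genotype and G×E random). With
`D_g = σg² + σge²/e + σe²/(er)` and marginal deviations `m_i`:

    ĝ_i    = (σg²/D_g) · m_i
    (ĝe)_ij = c_ge · Z_ij + (σge²/(e·D_g)) · m_i,   c_ge = σge²/(σge² + σe²/r)

The second term in (ĝe) is required for exact agreement with the
generalized-least-squares BLUP: the row mean of e interaction effects is
itself random with variance σge²/e, so the genotype-marginal contrast splits
between g and ge in proportion to their variances. Tests verify both vectors
against a matrix `u = GZ'V⁻¹(y − Xβ̂)` oracle to 1e−6 and the EMS components
against a numerically optimized REML likelihood.

Predicted genotypic values `GV_ij = μ + ĝ_i + (ĝe)_ij` exclude the
environment main effect, so HMGV (`e / Σ_j 1/GV_ij`) penalizes interaction
instability, not environment quality; this matches the reference HMGV values
sitting just below the genotype means. Any non-positive GV is a domain error
naming the offending cell. WAASB decomposes the G×E BLUP matrix by SVD and
averages absolute genotype scores over all `min(g,e)−1` axes with weights
`λk²/Σλ²`. The pure-stability WAASB is kept separate from performance; a
50/50 (configurable) blend of rescaled mean- and WAASB-rank positions is
offered as `composite_score`. The quadrant classification crosses
above/below-average mean with WAASB below/above its median (mean pivot
optional); group 4 is the broad-adaptation quadrant.

## Rank concordance

Each method column is ranked under its registered direction: ascending for
variance-type measures (DP, S²x, W_i, P_i, S⁽¹⁾, S⁽⁶⁾, RMSE, ASV, WAASB),
descending for confidence indices, HMGV and the trait mean, and
closest-to-target for regression statistics (b_i and R² to 1; B_i to 1 on
the b-scale, i.e. target 1 for the printed B_i-as-adaptability reading;
S²d, D_i and the GGE PC2 marker to 0). Ties receive exact average ranks for
all statistics; display ranks round the averages to the nearest integer
(banker's rounding), the convention that reproduces the reference tables'
printed tied ranks. Spearman correlations use the exact ranks; constant
columns yield NaN with a warning. Method grouping eigen-decomposes the rank
correlation matrix, takes √λ-scaled loadings on the first two components
and cuts a Ward tree at k groups (default 4). A group containing the trait
mean ranking — or whose mean |correlation| with it exceeds 0.6 — is labeled
dynamic; below 0.1, static; otherwise weak.

## Synthetic generator

`generate_met` draws every term of the plot model independently normal at
configured variances, balanced by construction, with per-effect substreams
spawned deterministically from one seed (identical seed → identical table).
Defaults reproduce the reference design and its fresh-root-yield magnitudes:
12×12×3, μ = 26.14, σg² = 20.16, σge² = 17.87, σe² = 6.54. Environment and
block effect scales are not identified by the published tables; defaults of
5.0 and 1.0 (SD, trait units) give environment ranges and block noise typical
of yield METs of this size. The generator emulates the *variance structure*
only: no heteroscedastic per-environment errors, spatial trends, skewness,
outliers or missing plots. Passing tests therefore demonstrate correctness
of the estimators under the assumed model, not robustness to real-data
pathologies. Toy fixtures with analytic properties (zero interaction, rank-1
interaction, crossover winners) cover the qualitative regimes the
multiplicative models distinguish.

Parameter-recovery checks average the EMS estimates over 200 simulated
trials at the reference magnitudes and require the mean within 10% of truth;
the genotype-variance estimate has only 11 degrees of freedom per trial
(single-trial SD ≈ 9.9), so the 200-trial mean carries a ±3.5% Monte-Carlo
standard error — the 10% band is about three such SEs.

## Numerical choices and degenerate inputs

Tolerances: SVD reconstruction is tested to 1e−10; interaction-SS
conservation (`ΣW_i` = interaction SS, `rΣλ²` = SS_GxE) to 1e−8 relative;
BLUP oracle agreement to 1e−6. Zero-variance inputs: constant data give
all-zero SS tables and single Scott–Knott groups; an all-zero interaction
BLUP matrix yields WAASB 0 for every genotype with a warning; a zero
average-environment vector, collinear biplot markers, and a degenerate
second AMMI axis raise typed errors rather than NaNs. F-statistics in ANOVA
tables use the residual mean square; the genotype-vs-interaction F needed
for selective accuracy is recomputed from the MS column.

## Known limitations

Balanced complete data only (v1): unbalanced or heteroscedastic designs
require a general REML fit, out of scope here. Single-trait analysis; no
multi-trait selection indices. Axis-significance tests for AMMI (Gollob/FGH)
are not implemented; IPCA degrees of freedom are reported for information
only. Biplot rendering is left to the caller — the package exports
coordinates.
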