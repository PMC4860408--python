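# Methods

This note documents the statistical machinery in `ecomorph`, the
conventions it follows, the choices made where the methodology is
genuinely open, and what the synthetic-data suites do and do not show.

## Superimposition and shape variables

`gpa` performs full generalized Procrustes analysis: every configuration
is centred and scaled to unit centroid size, rotated onto the running
consensus by orthogonal Procrustes (SVD with a determinant correction so
reflections are excluded by default — skulls are digitized in a fixed
ventral view; a flag allows them), and the consensus is recomputed and
re-scaled to unit size each round. Convergence is declared when the
root-mean-square change of the consensus drops below 1e-8 (at most 100
iterations; non-convergence warns and flags the result). Original
centroid sizes in mm are stored before scaling; all size analyses use
their natural log (lnCS).

Aligned coordinates are orthogonally projected onto the tangent plane at
the consensus before any linear analysis. For the small shape variation
typical of congeneric skulls the projection is numerically negligible,
but it makes the residual space exactly linear: residuals are then
orthogonal to translation, scaling and (by the rotation optimality
condition) rotation, so they live in a (2k − 4)-dimensional subspace
exactly.

`weight_matrix` builds the thin-plate-spline bending-energy matrix at the
consensus (kernel U(r) = r² log r²); its k − 3 positive-eigenvalue
eigenvectors are the principal warps. Each contributes an x and a y
partial-warp score per specimen with α = 0 weighting, i.e. no
bending-energy rescaling — the common relative-warp default. The uniform
(affine) component is the 2-D orthogonal complement of the non-affine
subspace inside the tangent space, obtained by completing the
{similarity, non-affine} system via SVD. The full basis is orthonormal,
so the weight matrix is an exact rotation of the Procrustes residuals:
total variance is preserved to machine precision, and relative warps
(`relative_warps`, a centred PCA of the weight matrix) coincide with a
PCA of the residuals up to column signs. Eigenvector signs are fixed by
making each column's largest-magnitude loading positive, so plots and
angle computations are reproducible across runs and platforms.

Averaging (`aggregate_means`) happens on GPA-aligned coordinates and on
lnCS, one record per grouping-key combination. Specimens of unknown sex
enter locality-level averages but are dropped whenever sex is a grouping
key, mirroring the usual split between a fully-sexed subsample for
dimorphism models and the complete sample for geography.

## Allometry

`multivariate_regression` regresses every shape variable on lnCS by OLS;
the reported statistic is 100·trace(SS_model)/trace(SS_total), which is
invariant to orthonormal rotation of the shape block (identical on
residuals, weight matrix or relative warps). Significance comes from
permuting the size vector; p = (count + 1)/(n_perm + 1), never zero, with
9999 permutations by default. `pooled_within_group_regression` removes
group means from both blocks and fits a single common slope; its
permutations shuffle size within groups only. The slope-heterogeneity
test is a Goodall-style Procrustes ANOVA comparing shape ~ size + species
+ size:species against the additive model, F from summed-squared-distance
trace ratios with univariate-style degrees of freedom, and p by residual
randomization under the reduced model (the RRPP convention of modern
morphometric software; the methodology literature names the software but
not the scheme, so the scheme is documented here as a package choice).

## Group tests

MANOVA uses Pillai's trace computed from hypothesis and error
cross-product matrices with Type II sums of squares for unbalanced
two-way designs (species × sex with interaction), and the standard F
approximation. A singular error matrix raises with advice to select
fewer relative-warp axes — which is exactly what `select_rws` (smallest
number of leading axes reaching a cumulative 95 % of variance, the
threshold being configurable) is for. Pairwise species comparisons are
two-group MANOVAs on the first two relative warps, reported as a matrix
with F below and p above the diagonal; no multiple-testing correction is
applied by default (raw p is the convention being mirrored), but
Bonferroni/Holm are available. Pairwise size tests default to
pooled-variance t tests with a Welch option.

## Two-block PLS

`pls` takes the SVD of the cross-covariance matrix between the centred
shape block and the centred, column-standardized environmental block.
Shape variables share Procrustes units and are deliberately *not*
standardized; mixed-unit climate or competition variables are. (A flag
standardizes the shape block too, for a literal correlation-matrix
reading.) Covariation percentages are dᵢ²/Σdⱼ²·100; per-dimension
significance permutes the rows of the second block, counting permuted
singular values that reach the observed one. Each dimension is oriented
so its largest-loading right-block variable is positive. The degenerate
single-variable case (`pls_size`, lnCS against climate) is the same code
path with a 1-column left block.

## Competition scoring

Each focal specimen is scored against the set of canid species recorded
at its locality, the focal excluded, duplicates collapsed. Diet and
habitat overlap are fractions of co-occurring species sharing the
focal's category; the killing component is the fraction of pairs inside
the body-size-difference window. BSD = (Mbₗ − Mbₛ)/Mbₗ with the larger
mass in the denominator, so it is symmetric and in [0, 1). The published
window "arcsine √BSD between 2 and 5.4" does not state its unit (radians
cap at ~1.57 and degrees at 90, so neither fits the bounds literally);
the package computes θ = arcsin(√BSD) in degrees and divides by ten, so
the window corresponds to 20°–54°, and exposes the unit (`deg10`, `deg`,
`rad`, or a raw mass-`ratio` bypass) and the window as parameters — no
single interpretation is hard-coded. The window is open at both ends.
The denominator convention (co-occurring species excluding the focal)
is forced by the documented two-neighbour locality yielding 0.5 for diet
and habitat. The shipped trait table uses species-typical literature
masses; for the three species in that reference locality the masses
(C. thous 5.2 kg, L. gymnocercus 4.7 kg, S. venaticus 5.8 kg) keep both
pairs below the window's lower bound (θ/10 ≈ 1.81 and 1.88 < 2), as the
documented example requires. The table is data, not code: an editable
CSV with columns species, mass_kg, diet, habitat.

## Angular comparison

The angle between two shape-space directions is arccos of the absolute
cosine — folded to [0°, 90°] because singular-vector signs are
arbitrary. Under the null that one direction is uniform on the unit
sphere in p dimensions, cos²θ ~ Beta(1/2, (p − 1)/2); the reported p is
the upper-tail probability of the observed collinearity. The analytic
null was chosen over a permutation because it is exact for a single
observed pair and matches Monte-Carlo frequencies (verified in the
tests). The effective dimension is the number of shape variables
(2k − 4), not the specimen count. Per-genus vectors are obtained by
refitting the PLS within each genus (projection of the global fit is
available by calling `pls` on subsets directly).

## Variation partitioning

Every union of the named predictor blocks (taxonomy as species
indicators with one level dropped, size as lnCS, climate as 19 columns,
competition as 3) is fitted by multivariate least squares; R² is the
trace ratio and the Ezekiel adjustment 1 − (1 − R²)(n − 1)/(n − q − 1)
penalizes block width. Pure and shared components solve the linear
inclusion–exclusion system in which each union's adjusted R² is the sum
of the components it touches; with b blocks that is a (2ᵇ − 1)-equation
solve, exact by construction (the identity is asserted on every run).
Shared components may legitimately be negative; they are retained in the
result and only suppressed in display helpers. Exactly collinear
predictor columns (e.g. BIO7 = BIO5 − BIO6) are dropped with a warning
before fitting. Pure components can be permutation-tested by a
partial-RDA F with Freedman–Lane residual randomization: the response is
residualized on the conditioning blocks, rows are permuted, and the
permuted data are re-projected off the conditioning blocks so observed
and permuted statistics live in the same residual subspace (without the
re-projection the test is measurably liberal). Genus-nested partitions
drop the taxonomy block automatically when the subset holds one species.

## Comparative methods

Ancestral states minimize the branch-length-weighted sum of squared
changes, solved exactly by the standard two-pass linear algorithm
(equivalent to ML states under Brownian motion on a rooted tree). The
"tree length" statistic of the phylogenetic-signal test is that
minimized criterion Σ‖Δ‖²/l; because the reconstruction is linear in the
tip values, tree length is a quadratic form xᵀQx in the tips, and Q is
precomputed once per tree so the 10 000-permutation default costs one
matrix contraction per permutation. Small observed lengths mean related
tips resemble each other (signal); p = (#{permuted ≤ observed} + 1)/
(n_perm + 1). An unweighted sum-of-squares reading of "summed changes"
is available as an option. Independent contrasts follow Felsenstein's
recursion with standardization by the square root of summed effective
branch lengths; regressions on contrasts run through the origin.
Polytomies are resolved arbitrarily with epsilon-length branches (1e-8),
with a warning, and zero/missing branch lengths are floored at the same
epsilon. The shipped 8-species canid tree is a synthetic stand-in for
demonstration (topology follows accepted relationships; branch lengths
are invented) — analyses of real data should supply their own phylogeny.

## Synthetic studies and what the tests show

`generate_study` emulates the motivating study design. Defaults are the
study conditions: 8 species with the canid trait table, 29 landmarks,
262 localities spanning 55°S–5°N, 431 specimens with the skewed
per-species sample sizes of the original series, ~30 % of specimens
unsexed. Effects are planted as explicit shape-space vectors: species
means diverge by Brownian motion on a random coalescent-style tree
(rate 0.03 per unit branch length in Procrustes units), a unit
allometric vector is scaled by 0.04 per within-species standard
deviation of lnCS, a climate vector by 0.02 per unit of the
standardized latitude latent, and three competition vectors by 0.02 per
standardized competition-profile column. Isotropic landmark noise
defaults to 0.008 Procrustes units per coordinate, and lnCS has a
within-species SD of 0.08 around species means tied to body mass
(lnCS ∝ ⅓·log mass, a length–mass scaling). Climate comes from a
two-latent model (an equator-ward temperature axis driven by latitude
plus an independent moisture axis) mapped to 19 correlated BIO columns
with physical sanity enforced (precipitation clipped at zero, BIO7 =
BIO5 − BIO6 by construction; BIO1/BIO12 fall and BIO4 rises poleward).
Assemblages are sampled from Gaussian latitude-preference curves per
species, so presence lists — and therefore competition profiles —
covary with climate, as in the real guild. Each configuration is
finally re-scaled to its target centroid size and randomly rotated and
translated so the superimposition step has real work to do. Everything
is drawn from a single `numpy.random.default_rng(seed)` stream in a
fixed order, making studies bit-reproducible from (parameters, seed).

The generator reproduces the *structure* of real ecogeographic data, not
its substance: landmarks are perturbations of an ellipse rather than a
skull, noise is isotropic (real digitization error is not), climate has
no spatial autocorrelation beyond the latitude gradient, and assemblage
composition ignores dispersal history. Passing recovery tests therefore
demonstrates that the estimators are correct and well calibrated — not
that any particular biological effect size is detectable in museum data.

Calibration suites run the full chain on no-effect studies
(`generate_null_study`) at reduced problem sizes chosen for the test
suite (3–5 species, 6 landmarks, 36–30 specimens, 499 permutations, 200
replicates per family) and check p-value uniformity by Kolmogorov–
Smirnov at the 1 % level; recovery suites use 200-specimen studies with
a single planted effect isolated. Two recovery subtleties are worth
recording: GPA fixes orientation only up to a global rotation, so
recovered vectors are compared with the planted truth after rotating the
sample into the generator frame (`align_sample_to`); and the planted
allometric vector is recovered by the pooled within-species regression,
because with Brownian mean divergence the global regression legitimately
absorbs the interspecific size–shape trend.

## Numerical conventions

- Permutation p-values are always (count + 1)/(n_perm + 1) with ties
  counted as exceedances; seeds make them bit-reproducible.
- GPA: tol 1e-8 on RMS consensus change, max 100 iterations; consensus
  orientation anchored to the previous iterate to stop frame drift.
- The consensus is exactly the mean of its aligned sample; re-running
  GPA on aligned output moves the consensus only at second order in the
  shape variance (tangent projection leaves configurations marginally
  off the unit sphere), which is the sense in which the fixed-point
  property is asserted.
- Eigen/singular vector signs: largest-|loading| entry positive.
- Degenerate inputs fail loudly: constant size covariates, collinear
  consensus landmarks (bending energy undefined), zero vectors in angle
  computations, unknown species in presence lists, mismatched tip sets.
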