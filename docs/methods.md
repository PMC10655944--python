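# Methods

This note records the statistical model behind the package, the choices made
where the methodology was genuinely open, and what the synthetic data do and
do not establish about real specimens.

## Superimposition

GPA uses the full-Procrustes convention: every configuration is centred,
scaled to unit centroid size, and rotated (proper rotations only — the SVD
rotation fit is sign-corrected so a left cranium is never mirror-matched
onto a right one). The consensus is the renormalised mean of the aligned
set, iterated until the RMS change of the consensus falls below 1e-10
(default cap 1000 iterations; concentrated shape data converge in a handful,
the high cap only matters for nearly-unstructured test data whose consensus
converges linearly). Centroid sizes are taken from the raw configurations
before normalisation, so sizes are comparable only within a view unless a
SCALE calibration is present in the TPS files — sufficient for all
within-view size analyses.

Two standardisations make the result reproducible: processing order is
id-sorted, and the finished superimposition is rotated so the consensus's
principal axes coincide with the coordinate axes (180° ambiguity resolved by
the sign of the largest loading). Tangent coordinates are the orthogonal
projection (I − cc′)x at the consensus c; because the consensus is the
renormalised mean of the final alignment, tangent scores have exactly zero
column means. Projecting versus using raw aligned residuals differs at
O(d²) in the Procrustes distance d; for within-population cranial variation
(d ≈ 0.02–0.1) the difference is far below sampling noise.

## Symmetrization

Dorsal and ventral views have object symmetry. The symmetric component of a
configuration is the landmark-wise average of the configuration and its
reflected, left/right-relabelled copy after rotation alignment; the average
is then rotated by half the fitted angle, which makes it *exactly* invariant
under reflect-relabel (the output is symmetric about the vertical axis
through its centroid, a pure orientation convention). Symmetrization is
applied per specimen before GPA; the alternative — simultaneous
superimposition of originals and reflections — differs only in how the
asymmetric component (which the analyses discard) is weighted, and is noted
for future work. The lateral view has no bilateral pairs and passes through
untouched.

Bilateral pair assignments for real data must be supplied by the user
(`PairMap`, 1-based on disk to match anatomical numbering); the pairing
shipped with the synthetic templates belongs to those templates only.

## Shape statistics

PCA decomposes the sample covariance (divisor n − 1) of tangent
coordinates; components below 1e-12 of the leading eigenvalue are dropped
(GPA leaves four null directions), and eigenvector signs follow a fixed
largest-loading-positive convention. View integration column-joins the
per-view score matrices and decomposes again; since each score matrix has
orthogonal columns, total variance is conserved.

Wilks' Λ = det(W)/det(W+B) is converted to F by Rao's approximation (exact
for two groups or ≤ 2 responses; cross-checked against statsmodels to
1e-10). Because tangent dimensionality (2k − 4) exceeds group sizes, MANOVAs
run on leading PCs: the pipeline retains 95% of variance (configurable) and
additionally caps the response dimension at n − g − 1 per test; pairwise
tests auto-truncate to n_pair − 3 columns so small groups (karyotypes with
n = 5–6) keep a nonsingular within-group SSCP, reporting the dimension
used. The sex × block factorial uses Type II sums of squares — the design
is unbalanced (52/37 × 25/17/18/29) and main effects are tested after the
interaction. Size ANOVAs use scipy's one-way F and Tukey–Kramer HSD
(studentized range, valid for unequal n).

## Discriminant analysis

Canonical axes solve the generalized eigenproblem B a = λ W a via a
Cholesky-symmetrised eigendecomposition, scaled to unit pooled-within
variance. Priors are equal, not proportional: group sizes reflect
collecting effort, not prevalence (configurable). Classification assigns a
specimen to the nearest group mean in the pooled-covariance Mahalanobis
metric; posteriors come from the equal-covariance Gaussian model.

Leave-one-out cross-validation refits the model n times; folds whose refit
degenerates (a group down to one member) are skipped with a warning and
excluded from the denominator. PC-subset selection maximises overall LOOCV
accuracy; exhaustive search over all combinations is available for modest
dimension, and the default forward search additionally compares its result
with the full candidate set, so the returned subset never scores below it.
Ties prefer fewer PCs, then the lexicographically smallest index set.
Selecting and reporting on the same LOOCV criterion is mildly optimistic;
that mirrors how such analyses are usually reported, and an unbiased outer
loop can be had by wrapping `select_pc_subset` in a held-out split.

## Distances, trees, Mantel

Mahalanobis distances use the pooled within-group covariance over all
groups; significance uses within-pair label permutation
(p = (1 + #{D* ≥ D})/(n_perm + 1)) rather than a Hotelling-derived F,
because karyotype samples as small as five make normality doubtful — both
the statistic and its null draws use the pair's own pooled covariance so
the permutation is exchangeable. Geographic distances are great-circle
(haversine, radius 6371.0088 km) between group centroid coordinates —
"linear distances" in the geodesic sense. The Mantel statistic is the
Pearson correlation of upper triangles under simultaneous row/column
permutation, one-tailed "greater" by default (the isolation-by-distance
alternative; two-sided and "less" available). Observed and permuted
statistics share one code path with a 1e-12 tie epsilon, so a permutation
reproducing the identity always counts as at least as extreme — without
this, round-off can push small-m p-values below the 1/m! floor.

Neighbor joining is Saitou–Nei with the Studier–Keppler Q criterion and
deterministic tie-breaking (lowest label pair). Negative branch lengths are
kept, with a warning: branch lengths are displayed proportionally and
clamping would distort path distances. Newick export carries six
significant digits and round-trips through dendropy to 1e-5.

## Synthetic data generator

The generator emulates a museum series: per specimen and view,

    config = s · R(θ) · (template + shape effects + noise) + t

with a deterministic cranium-like template (two nested arcs; exactly
bilaterally symmetric for dorsal/ventral), uniform rotation and translation,
and a lognormal size factor s whose male mean is `sex_size_ratio` (default
1.1) times the female mean (female mean 250 image units, CV 5%). Shape
effects are built in the tangent space at the template, projected orthogonal
to translation, rotation and scaling (so they are genuine shape effects)
and, for paired views, onto the symmetric subspace (so they survive
symmetrization):

- a block displacement of magnitude `block_effect_size` (default 0.05
  Procrustes units) — independent random directions per block by default,
  or ordered on a line A–B–C–D (`block_layout="line"`) to emulate
  transect-ordered divergence;
- a karyotype displacement of magnitude `karyotype_effect_size` (default
  0.03) scattered around the block mean — within-block karyotype divergence
  is roughly half the between-block level in published distance tables of
  this kind, and without it same-block karyotypes would be morphometrically
  identical;
- a sex shape difference of magnitude `sex_shape_effect` (default 0.03);
- isotropic digitising noise (SD 0.02 per coordinate) plus antisymmetric
  noise (SD 0.01) on paired landmarks only.

`clinal_component` γ mixes the block/karyotype structure with a continuous
transect-position effect along one shared direction: γ = 0 is purely
block-structured variation with no geographic gradient (the Mantel null),
γ = 1 a true morphological cline (Mantel positive control). Karyotypes are
drawn within blocks from the reference collection's composition
(A: 19×54A + 6×55a, B: 17×58, C: 18×54C, D: 5×55b + 24×56b at default
sizes), which makes the chromosomal pair-state marginals come out exactly
at their published values; pair-1/pair-2 states follow mechanistically from
the diploid number (each acrocentric homolog adds one to 2n = 54). Eighteen
localities sit at evenly spaced points on a 78 km transect, blocks
occupying contiguous segments in order, specimens assigned round-robin
within their block's segment.

What the generator does **not** emulate: measurement error correlated
across neighbouring landmarks, allometry (no size–shape covariance),
unequal locality sampling, within-block spatial autocorrelation beyond the
optional cline, and any real cranial anatomy. Passing recovery tests
therefore demonstrates the correctness and calibration of the inference
chain, not that real crania behave this way.

## Pipeline and reproducibility

`run_full_analysis` sequences symmetrization → GPA per view → size ANOVAs →
per-view and integrated PCA → MANOVAs (one-way, pairwise, factorial) →
cross-validated LDA per grouping → Mahalanobis + permutation significance +
NJ per view and integrated → geographic matrices and Mantel tests (reported
at both block and karyotype level; the block level is the direct test of
transect-scale structure, while the karyotype level inherits a
within/between-block contrast from the nesting of karyotypes in blocks).
One master seed is split per consuming stage with
`numpy.random.SeedSequence.spawn`, so re-runs are byte-identical and stages
are individually reproducible. Every p-value in the output tables sits next
to its test statistic and degrees of freedom or permutation count.

Test and acceptance runs use reduced problem sizes where full ones add no
information: unit tests run a 28-specimen configuration of the same design,
while calibration checks (MANOVA type-I at the study's exact 25/17/18/29
split, Mantel type-I at m = 10) and end-to-end recovery (20–40 replicates
at the full 89-specimen design) run at full size.
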