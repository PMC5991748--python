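# Methods

This note records the models, the numerical choices, and the limits of what
the test suite demonstrates.

## Synthetic cohort model

The generator emulates a three-cohort microarray study: a disease cohort, a
technical replicate of the same samples, and a smaller normal cohort.  Each
planted module *m* of size *s_m* follows a one-factor Gaussian model

    x_ij = sqrt(rho_m) * f_mj + sqrt(1 - rho_m) * eps_ij,

with a per-sample standard normal factor `f_m` shared by the module's
members and independent standard normal noise, so every within-module pair
has correlation exactly `rho_m` in expectation — which makes the generator
analytically checkable (empirical within-module correlation must sit within
sampling error of `rho_m`).  The replicate cohort reuses the disease
cohort's draws plus additive N(0, `rep_noise_sd`²) technical noise (same
samples, same latent factors).  The normal cohort draws fresh samples;
modules listed as *disrupted* there give every member its own private
factor, which removes the block correlation while leaving each feature's
marginal distribution unchanged.  Differential expression is an additive
mean shift on the log-intensity scale, applied in the disease and replicate
groups only.

Default study conditions: 300 features; 10 modules of sizes
40/35/30/25/22/20/15/12/8/5 (mean ≈ 21, echoing the study-scale design of a
few hundred probes with modules of a few to ~40+ members); `rho_within` 0.7
(a strong but realistic microarray co-expression level); cohort sizes
90/90/34; `rep_noise_sd` 0.3 (replicate correlation ≈ 0.95); the three
smallest modules disrupted in the normal cohort; the members of the two
smallest disrupted modules shifted by 1.2–1.5 log-units (module-level DE)
plus four scattered DE features in preserved modules.

What the generator does **not** emulate: probe-level replicates, batch
effects, missing values, heavy-tailed intensity noise, overlapping module
membership, and correlated module factors.  Passing tests therefore
demonstrate correct recovery under a clean block-correlation model, not
robustness to real microarray artifacts.

## Network construction and module detection

Pearson correlation across samples; unsigned adjacency `|cor|^beta`.  The
soft power is chosen by the scale-free topology criterion: connectivities
are binned into 10 equal-width bins, empty bins dropped, and R² of the
regression of log10(bin frequency) on log10(bin mean connectivity) is the
fit index; the selected beta is the smallest integer in 1..20 with
R² ≥ 0.8, falling back (flagged) to the best-fitting power when none
reaches the cut.  A constant connectivity vector is degenerate and reports
R² = 0 with a warning.

TOM follows the standard formula with the diagonal reported as 1 and
connectivity excluding the diagonal.  Module detection is average-linkage
hierarchical clustering on `1 − TOM` with a branch cut placed *relative to
the merge-height range*: `cut = h_min + f * (h_max − h_min)` with
`f = 0.99` by default (deep-split settings 0–3 map to 0.95/0.97/0.99/0.995).
The range-relative placement matters because a large soft power compresses
all TOM dissimilarities toward 1; between-branch joins still concentrate at
the very top of the dendrogram, so a cut just below them separates branches
at any compression level.  Branches with at least `min_module_size` (= 3)
leaves become modules, labelled 1..K by decreasing size; everything else is
label 0 (grey).  A flat dendrogram (all merge heights equal) degenerates to
a single module spanning all features, with a warning.  Eigengene merging
of similar modules is not performed.

Module eigengenes are the first right singular vector of the standardized
member submatrix, sign-oriented so the mean member correlation is positive;
`propVarExpl` is the mean squared member–eigengene correlation.

## Module comparison (MCR)

Cross-tabulation excludes label 0 from both axes but keeps unassigned
features in the hypergeometric universe (both choices configurable); the
universe is the intersection of the two partitions' feature sets by
default.  Overlap p-values are one-sided (enrichment) and deliberately not
multiplicity-corrected — the consensus ratio counts pairs below raw
alpha = 0.05.

## Preservation (Z_summary)

Density statistics are measured in the test cohort (mean member
correlation, mean member adjacency at the *reference* beta, propVarExpl,
meanKME); connectivity statistics correlate the module's wiring between
reference and test (intramodular connectivity profiles, kME profiles, and
the vectorized upper-triangle member correlation matrices).  The null
draws `n_perm` pseudo-modules of the same size uniformly without
replacement from the test cohort's features — in sorted-id order, so
results are invariant to input feature and sample ordering; modules of
equal size share the same draws.  `Z = (obs − mean_perm)/sd_perm`; a zero
permutation sd flags the component as undefined (NaN, never infinite), and
the flag propagates through the medians.  `Z_summary` is the average of
the median density Z and the median connectivity Z.  Defaults: n_perm 200
(100 in the bundled studies, which separates the planted classes by a wide
margin), seed mandatory.  Classes: strong (≥ 10), preserved (≥ 2), weak
([0, 2)), activated (< 0); the biomarker rule additionally requires
non-negative Z_summary against the technical replicate, so
replicate-unstable modules cannot be called activated.  Modules with fewer
than 3 members are skipped with a warning.

Because most features belong to correlated modules, pseudo-modules are not
fully independent feature sets; this inflates the null mean of the density
statistics and is exactly what drives disrupted modules *below* zero.

## Network-constrained SVM

Objective: `mean hinge + lambda_margin ||w||² + lambda_net wᵀLw` over
standardized features, with `L` the symmetric normalized Laplacian
(isolated nodes get identity rows) of the TOM graph thresholded at 0.1.
The problem is solved exactly as a QP through its dual: with
`M = lambda_margin I + lambda_net L`, the dual is a concave quadratic over
`{0 ≤ α ≤ 1/n, yᵀα = 0}`, maximized by projected-gradient ascent with a
fixed `1/λ_max` step — deterministic and monotone by construction (the
recorded minimization objective trace is non-increasing).  The projection
onto the box-plus-hyperplane set is computed exactly via the piecewise-
linear structure of the hyperplane multiplier.  Stopping: relative duality
gap below 1e-6 (checked every 25 iterations) or a fixed point, cap 20 000
iterations; results carry the gap and a convergence flag.  The bias comes
from the KKT conditions (mean over free support vectors, interval midpoint
otherwise).  With `lambda_net = 0` the solution coincides with the standard
soft-margin SVM (`C = 1/(2 lambda_margin n)` in the usual
parameterization), which the tests verify against two independent QP
routes.  Weight signs are disease-directional (positive = higher
standardized expression in the disease class); the sub-network export
cross-checks sign against the group-mean log2 fold change and flags
disagreements rather than resolving them.

Performance is reported as stratified 5-fold cross-validation with pooled
held-out decision values (sensitivity/specificity at f = 0, concordance
AUC), alongside clearly-labelled apparent (resubstitution) metrics, since
published single-number accuracies are often resubstitution values.

## Diagnostics

Module score: unweighted mean, or `Σ w_j x_j / Σ |w_j|` — the
absolute-value denominator keeps mixed-sign weight sets away from a
near-zero denominator.  ROC cutoffs are midpoints between consecutive
distinct scores plus ±∞; AUC uses the rank-sum concordance estimator (ties
counted ½), which equals the all-pairs average exactly.  Youden's optimum
maximizes Se + Sp − 1 with ties broken toward higher specificity, then
lower cutoff.  Markers with AUC < 0.5 are flagged as flipped rather than
silently inverted.  Subset search enumerates all member subsets (capped at
12 members; larger modules are first reduced to the top members by
|weight|).

## Annotation

Target sources are three local export files (miRNA, gene[, score]); a gene
is a consensus target only when all three sources agree, and a module's
target set is the union over members with per-gene attribution.  Missing
miRNAs are flagged, not fatal.  Enrichment is one-sided hypergeometric per
term (same implementation as the module-overlap test) with
Benjamini–Hochberg adjustment within each annotation category; both raw
and adjusted p-values are reported.  The pipeline's synthetic runs use
generated stand-in target/annotation files (labelled synthetic) purely to
exercise the machinery; no claim about real target databases follows from
them.

## Pipeline

Every stage reads and writes plain files under stable names so stages can
be re-run standalone; the manifest hashes every output, and identical
configs reproduce identical hashes.  Every stochastic stage (generator,
permutation null, CV folds) requires an explicit seed in the config, and
the log records the selected beta per cohort, since that value is
data-dependent.

## Problem sizes and known limitations

The bundled studies use 300 features, 10 modules, cohorts of 90/90/34 and
100 permutations — sizes chosen so the full pipeline runs in seconds while
leaving wide margins on the recovery criteria.  Known limitations: the
branch cut is a simplification of the full dynamic hybrid tree cut (no
per-branch shape criteria, no PAM stage); preservation omits the
medianRank family of statistics; the SVM is linear only; AUC confidence
intervals are not computed; and headline numbers from any particular
published dataset are not reproducible without that dataset's expression
files and tuning constants (unprinted soft power, unstated SVM
hyperparameters, era-specific target databases).
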