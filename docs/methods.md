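# Methods

`phenonet` implements phenotype-guided miRNA–mRNA network discovery: from
raw count matrices and clinical covariates to sparse multiple canonical
correlation networks, subsampling-robust adjacency, edge-threshold pruning
against a phenotype, database-based quality assessment, and conditional
term enrichment. Because the blood multi-omics cohorts this style of
analysis targets are access-restricted, the package ships a first-class
synthetic-cohort generator that reproduces the statistical structure the
method assumes; every pipeline stage is tested against that generator's
ground truth.

## The model

Let X1 (n × p1) be the mRNA block, X2 (n × p2) the miRNA block and Y an
n-vector phenotype, all column-standardized. The canonical weights
(w1, w2) maximize the scaled objective

    J(w1, w2) = a·cov(X1w1, X2w2) + b·cov(X1w1, Y) + c·cov(X2w2, Y)

subject to ‖wk‖₂ ≤ 1 and ‖wk‖₁ ≤ lk·√pk. Unequal (a, b, c) matter because
the miRNA–phenotype correlations in blood are systematically weaker than
the mRNA-driven terms; upweighting b and c keeps the phenotype in the
solution instead of letting the (much larger) mRNA block dominate.

The solver is block coordinate ascent. Holding w2, the optimal w1 is the
L1/L2-constrained projection of a·X1ᵀX2w2 + b·X1ᵀY (soft-threshold, then
L2-normalize, with the threshold found by bisection so the L1 budget binds
exactly). Each half-step is an exact per-block maximization, so the
objective is non-decreasing; iteration stops when the maximal weight change
falls below `tol` (1e-6) or after `max_iter` (200) sweeps. An L1 budget
below 1 is infeasible for a unit-L2 vector and is clamped up to 1.
Initialization is deterministic: w2 ∝ X2ᵀY when c > 0, otherwise the
leading right singular vector of X1ᵀX2. The sign convention (largest
|w1| entry positive) is applied only when the joint flip
(w1, w2) → (−w1, −w2) leaves the objective unchanged; in general the flip
negates the two phenotype terms, so forcing it would destroy optimality.

Scaling and sparsity parameters can be chosen by K-fold (default fourfold)
cross-validation on a grid. The fold error is |ρ_train − ρ_test|, where ρ
is the weighted objective evaluated with the training weights on the
(re-standardized) training and held-out samples; the selected point
minimizes the mean fold error. This train/test contrast is the natural
overfitting measure expressible from the objective itself; other contrasts
(e.g. negative test correlation) are easy to swap in, and the whole grid is
configuration-driven rather than hard-coded.

## Robust adjacency and modules

A single fit gives one sparse weight vector per block. To stabilize the
network, the fit is repeated over random feature subsamples — by default
70% of mRNAs and 90% of miRNAs per repetition, the asymmetry reflecting the
much smaller miRNA block — and the similarity between features i and j is
the average of |wᵢwⱼ| over the repetitions in which both were sampled.
Normalizing by the co-sampling count (rather than the total repetition
count) avoids penalizing rarely co-sampled pairs. Unit L2 norms make every
entry lie in [0, 1]; the diagonal is set to 0 by convention and excluded
from all maxima. Given a fixed seed the matrix is bit-reproducible.

Modules are average-linkage hierarchical clusters of the dissimilarity
1 − A, cut either to a requested cluster count or at a height; both rules
are exposed because neither is canonical for similarity matrices of this
kind. Clusters below `min_size` (default 5) are dropped. Edge signs are
not part of A (which is built from |wᵢwⱼ|); they are assigned afterwards
from the sign of the Pearson correlation of the two features' expression,
with an exactly zero correlation flagged and assigned "+".

## Pruning by phenotype correlation

Within each module the candidate edge thresholds are 0.001, 0.002, … up to
the largest multiple of 0.001 at or below the maximum off-diagonal entry.
At each threshold τ, edges with weight ≥ τ survive, isolated nodes are
dropped, and the trimmed network is scored by |cor(PC1, Y)| — the absolute
Pearson correlation between the phenotype and the first principal
component of the surviving nodes' feature-standardized expression (computed
by SVD; a single-node network scores as that feature's own correlation).
The reported p-value is the two-sided t transform with n − 2 degrees of
freedom. The selected τ maximizes |r| with ties broken toward the larger
(sparser) threshold, and the full (τ, node counts, |r|) curve is returned:
node count and miRNA:mRNA balance are legitimate secondary criteria that a
user can weigh by inspecting the curve, but only |r| is operationalized in
the automatic selection.

## Preprocessing

The preprocessing chain mirrors standard bulk small-RNA/RNA-seq practice
for whole-blood cohorts:

1. **Outlier features** — any feature with a single sample above
   `max_single_read` (default 5,000,000) is removed; this catches
   hemolysis-dominated miRNAs whose residual counts dwarf everything else.
2. **Expression filter** — keep features with more than `min_count` reads
   (strictly) in at least `min_samples` samples and a sample standard
   deviation of at least `min_sd`. The named presets `mirna-copdgene`
   (10 / 200 / 10) and `mrna-copdgene` (10 / 500 / 30) carry the published
   whole-blood thresholds; the pipeline's synthetic defaults (5 / 100 / 2)
   are the same rules scaled to the 300-subject generator.
3. **Upper-quartile normalization** — each sample is divided by
   (its 75th percentile of nonzero counts) / (geometric mean of those
   percentiles), using linear interpolation between order statistics so the
   result is bit-reproducible. Note this map is 1-homogeneous, not
   scale-free: a global depth change rescales the output uniformly.
4. **Unwanted-variation removal** — per-feature least-squares regressions
   of log(normalized count + 0.5) on the known covariates produce a
   residual matrix; its top-k singular factors over samples are treated as
   unwanted covariates and their fitted contribution subtracted. This is a
   deterministic least-squares rendering of residual-based RUV; the
   canonical formulation uses a negative-binomial GLM for the first-stage
   residuals, but the residual-factor logic is identical. k defaults to 1
   and is configurable; the WBC design columns use neutrophil and
   lymphocyte percentages only, because the three percentages are
   compositional and including all three is exactly collinear with the
   intercept.
5. **Variance stabilization** — the closed-form negative-binomial
   stabilizer x ↦ (2/√α)·asinh(√(αx)) with α moment-estimated from the
   quadratic mean–variance relation Var = μ + αμ² when not supplied. It is
   strictly increasing, maps 0 to 0, and approaches 2√x as α → 0. A
   fitted per-gene dispersion trend (as in reference RNA-seq VSTs) is
   deliberately avoided in favor of this analytic, testable form.

## Covariate adjustment regimes

Three regimes reflect the open question of how much clinical structure to
regress out before integration: `none` (standardize only), `partial`
(omics vs sex, age, race) and `full` (partial plus current smoking and WBC
percentages). Phenotype handling is phenotype-specific: a lung-function
phenotype expressed as percent of predicted is already sex/age/race
adjusted and is left untouched under `partial`, gaining only smoking+WBC
terms under `full`; an imaging phenotype additionally gets the scanner
model in both regimes, since scanner is a confounder of the image-derived
measure but not of blood expression. Residualization is row-wise OLS with
an intercept, categorical covariates one-hot coded with sorted levels
(first dropped); residuals are exactly orthogonal to the predictors and the
operation is idempotent. Missing covariate values trigger listwise
deletion with a logged count, never imputation.

## The synthetic cohort

`generate_cohort` draws, from one seeded generator: clinical covariates
(age ~ N(65, 8); sex/race/smoking Bernoulli 0.45/0.25/0.38; WBC
percentages from a 3-part Dirichlet scaled to percent; batch and scanner
categoricals), per-subject log library sizes (sd 0.3), per-module latent
factors z_k ~ N(0, 1), and negative-binomial counts via a gamma–Poisson
mixture with common dispersion α whose log-mean is

    baseline + loading·z_k + covariate effects + batch effect + log lib size.

Planted mRNAs receive positive loadings and planted miRNAs negative ones
(magnitude `loading_scale`·U(0.7, 1.3)), so every planted miRNA–mRNA pair
is expected to be anti-correlated — matching how regulatory pairs are
queried in target databases. The phenotype is Y = Σ β_k z_k + γᵀcov + ε
with unit-variance noise. A configurable number of background miRNAs get a
single-sample count above 5,000,000 to exercise the outlier filter.

Default conditions: 300 subjects, 300 mRNAs, 60 miRNAs, two modules of
25 mRNAs + 10 miRNAs each, loading_scale 1, β = (1.0, 0.8), α = 0.5, and
baseline medians of roughly 60 (mRNA) and 80 (miRNA) counts. The baseline
depth and dispersion were chosen once for realism — filtered whole-blood
features typically live in the tens-to-hundreds of counts and are strongly
overdispersed — and they also put each feature in the informative-but-noisy
regime where aggregating a module genuinely beats any small hub subset.
The default sparsity fractions l1 = 0.3, l2 = 0.5 give L1 budgets of about
5.2 and 3.7, i.e. enough spread for one module's worth of features per
block; the miRNA fraction is larger because the block is ~5× smaller.

What the generator does **not** emulate: real count marginals (no gene
length or GC structure), read-level sequencing error, correlated background
features (background genes are independent given covariates), dropout, or
a real GO hierarchy (the term fixture is a random rooted DAG obeying the
true-path rule). Passing tests therefore show that the pipeline recovers
planted low-rank structure under realistic noise, library-size, batch and
covariate confounding — not that it would recover biology from any
particular real cohort.

Two further design notes. First, both planted modules carry a phenotype
effect, so a single canonical direction legitimately loads on both and the
detected module merges them; planted-node recovery is therefore evaluated
against the union of planted members. Second, the evaluation fixtures are
derived from the same truth object: the target database contains every
planted (negative) pair plus seeded decoys with predicted/validated labels,
and the "published miRNA" list is the planted miRNA set, matched without
3p/5p arm expansion because synthetic IDs carry no arm suffix (expansion is
implemented and tested for real miRNA names).

## Enrichment

Classic enrichment is the one-sided Fisher exact (hypergeometric
upper-tail) test per term, after pruning terms with fewer than
`min_term_size` annotated background genes (default 30 for real GO-scale
annotations; the pipeline's synthetic fixture uses 10). The background is
the set of genes surviving preprocessing. Conditional enrichment processes
terms in reverse topological order (children first, ties broken by term
ID): each term is tested on its gene set minus the union of the genes of
its significant children, a child being significant when its own
conditional p-value is below `sig_threshold` (default 0.05). Leaf terms'
conditional p-values equal their classic ones by construction. The
annotation loader enforces acyclicity and the true-path rule (child genes
propagate to ancestors) at load time. This is the described child-removal
recursion, not a reimplementation of any particular weighting scheme from
existing GO tooling.

## Numerical and reproducibility choices

- All standardization uses ddof = 1, so covariances of standardized
  composites are exactly correlations.
- Percentiles use linear interpolation between order statistics.
- The pipeline fans a single seed out to per-stage seeds via a fixed
  affine map, so stages can be re-run in isolation; identical
  configuration and seed reproduce every output table byte for byte
  (verified by hashing in the test suite).
- Threshold grids are built by integer arithmetic (count of 0.001 steps)
  to avoid floating-point drift at grid edges.
- Degenerate inputs fail loudly: all-zero samples in normalization,
  constant features in sign assignment or PC1 scoring, rank-deficient
  designs, infeasible folds, cyclic term graphs.

## Problem sizes

The default end-to-end run (300 subjects, 360 features, 100 subsampling
repetitions) takes a few seconds on one CPU; the full test suite and the
acceptance script each complete in well under a minute. 100 repetitions
is the package's default study size for the subsampling step — one-tenth
of the 1,000 used in the motivating full-scale analyses — and the `reps`
parameter scales it freely.

## Known limitations

- One canonical component only; modules that express themselves in later
  components will be merged or missed.
- The CV error contrast |ρ_train − ρ_test| favors stable rather than
  maximally predictive parameters; with very weak signal it can prefer
  over-sparse solutions.
- Average linkage on 1 − A chains when between-module similarity is
  comparable to within-module similarity (e.g. modules sharing a phenotype
  factor); the pruning stage, not the clustering, is then what separates
  signal from background.
- The least-squares RUV step assumes log-scale homoscedasticity it only
  approximately has before the VST.
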