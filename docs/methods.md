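# Methods

This note documents the statistical models behind `phenorec`, the
parameter defaults and why they were chosen, what the simulator does and
does not emulate, and the numerical decisions a maintainer should know
about.

## The rating-matrix view of MTME data

Phenotypes indexed by genotype *j*, environment *i* and trait *l* are
arranged as a J × (I·L) matrix: one row per genotype, one column per
environment–trait item, labelled `E{i}_T{l}` with environments outer and
traits inner.  Missingness is carried as an explicit boolean mask; a cell
value of 0 is data, not absence.  Two reduced layouts (`by_trait`,
`by_environment`) cover single-environment or single-trait studies.

Columns are measured in different units (days, centimetres, t/ha), so
both completion methods operate on column-scaled values
(value − mean)/SD.  The scaler is fitted **on training cells only** — in
cross-validation the held-out cells never contribute to the statistics —
and inverted on predictions.  Columns with fewer than two training
observations or zero variance are flagged, centred only (SD treated
as 1), and logged rather than made fatal: degenerate columns should not
abort a prediction run.  Because scaling is a per-column affine map, the
per-item Pearson accuracy is identical in scaled and original space; we
report on the original scale.

## Collaborative filtering

Item–item weights are pairwise-complete cosine (default) or Pearson
similarities: each pair of columns is compared over the genotypes observed
in both.  Pairs with fewer than `min_overlap = 2` shared observations are
undefined (one shared point makes cosine degenerate) and are excluded from
neighborhoods.  The prediction for a missing cell is the weighted average
over the genotype's observed items; following the formula as written, the
numerator keeps each weight's sign while the denominator sums absolute
weights.  A `nonnegative` neighborhood filter and a `top_k` truncation are
available for the common variants.  When no neighbor has a defined weight
or the denominator is zero, the cell deterministically falls back to the
column training mean (0 in scaled space) and is reported in the
completion's fallback list.

User-based filtering is the identical computation on the transposed
matrix.  Its practically interesting form supplies the weights externally:
the genomic relationship matrix G = WWᵀ/p acts as a proxy for phenotypic
similarity between lines.  We use the marker matrix as coded (−1/0/1)
without allele-frequency centring, matching the cross-product form used as
the simulator's covariance; mean-centring and correlation normalization
(G_jj′/√(G_jj G_j′j′)) are offered as options.  External weights are used
exactly as supplied.

## Matrix factorization

R ≈ PQᵀ with K latent features, fitted by stochastic gradient descent on
observed cells.  Each epoch visits the observed cells in a fresh
seeded-shuffle order; at each cell the residual e_ij = r_ij − pᵢ·qⱼ is
recomputed and both factor rows are updated simultaneously (the q-update
uses the pre-update p).  The derivation of the updates is per-cell, which
is why SGD rather than full-batch descent is used; at the small step sizes
involved the two coincide in practice.

The monitoring loss is Σ_obs e² + λ(‖P‖²_F + ‖Q‖²_F).  Fitting stops when
its relative change between epochs falls below `tol = 1e-6` or after
`max_iter = 5000` epochs (non-convergence is logged, not raised); a
non-finite loss raises a divergence error advising a smaller learning
rate.  Defaults: α = 0.0002 — a conservative step that is stable on
scaled data — λ = 0, initialisation i.i.d. U(0, 0.1).  A warm start from
the rank-K truncated SVD of a complete matrix (for example an IBCF
completion) is available via `init="from_matrix"`.

`mf_tune` grid-searches (K, λ) by hiding a random 20% of observed cells
per fold, refitting, and scoring the hidden cells by Pearson correlation;
the mean over folds decides, ties going to the earlier grid entry.  Both
the fold masks and every fit are seeded, so tuning is reproducible.

The epoch loop is deliberately plain NumPy/Python: the package's analyses
run on matrices of a few hundred rows and a handful of columns, where a
fit takes well under a second; tests and examples use problem sizes in
that range (up to 30 × 10 for tuning studies, 200 × 9 for pipeline runs).

## The MTME simulator

Phenotypes are drawn from

y_ijl = β_il + b1_jl + b2_ijl + e_ijl

* β — fixed environment–trait means, default
  (15, 8, 7, 12, 6, 7, 14, 9, 8) for I = L = 3, in trait-within-
  environment order (units: the trait's measurement scale);
* b1 ~ N(0, Gg ⊗ Σt) — genotype×trait genetic effects;
* b2 ~ N(0, ΣE ⊗ Gg ⊗ Σt) — three-way genotype×environment×trait
  effects;
* e_ij· ~ N(0, Re) i.i.d. over (i, j) — residuals correlated across
  traits within a plot.

Kronecker-structured draws apply the per-factor Cholesky roots along the
axes of a standard-normal tensor (with a 1e-10·trace jitter retry for
semidefinite factors, e.g. an all-ones relationship matrix), so the full
9000 × 9000 covariance is never formed.  The design matrices of the mixed
model are implicit in this indexed construction, which is exactly
equivalent and much cheaper.

Three preset covariance triples (Σt, ΣE, Re) imply pairwise correlations
between traits (genetic and residual) and between environments of 0.85,
0.50 and 0.25 — high, medium, and low information sharing.  Two printed
off-diagonals of the first set differ in their 4th decimal between the
upper and lower triangles (truncation in the source listings); the
presets symmetrize by averaging, which leaves the implied correlations at
0.85 to four decimals.  The default relationship matrix is the
exchangeable Gg = 0.7·I_J + 0.3·J_J at J = 1000 genotypes, giving 9000
records for the standard configuration.

Scenario S1 keeps Gaussian errors; S2 and S3 replace each error draw e
with exp(−1.25·|e|) and exp(+1.25·|e|).  The replacement applies to the
error term only; because all draws flow from one seeded generator in
fixed order (b1, b2, e), the three scenarios at the same seed share
identical genetic and interaction effects and transform the same
underlying errors.  One distributional note: although the exp(−c·|e|)
scenario is conventionally described as negatively skewed, its moment
skewness is actually slightly positive (+0.29 at c = 1.25, from
E[Y^k] = 2·exp(k²c²/2)·Φ(−kc)); its defining features are the bounded
support (0, 1] and the pile-up near zero.  The exp(+c·|e|) scenario is
unambiguously heavy-tailed and strongly right-skewed.  Tests assert the
computed values, not the conventional labels.

What the simulator does *not* emulate: marker genotypes (Gg is supplied,
not derived from simulated SNPs), field-design artefacts (blocks,
spatial trends, replicates — `n_reps` is fixed at 1), genotype-specific
missingness patterns, and selection. Passing tests on simulated data
therefore demonstrate correctness of the machinery and the expected
qualitative ordering of accuracies with correlation strength, not
real-data performance levels.

## Cross-validation and metrics

**CV1** draws ⌊0.2·J⌋ test lines per partition (20 partitions by
default).  The line-level 80/20 split leaves open which cells of a test
line are masked; here each test line keeps its observations in one
randomly chosen environment and is held out everywhere else.  This
matches the motivating scenario — lines phenotyped in some environments,
missing in the rest — and guarantees every test row retains observed
items, so the weighted average is always defined.

**CV2** models forward prediction: rows are the lines of the target year
and up to `years_back` preceding years (lines are year-specific, as in
multi-year trials without common checks), columns are traits, and the
target trait of target-year lines is held out in a single partition.

`run_cv` is the one place scale→complete→unscale is orchestrated; the
scaler is refitted per partition on that partition's training cells.

**APC/SE** — per item, the Pearson correlation between predictions and
observations is computed per partition (at least 3 pairs and nonzero
variance required, otherwise the partition is excluded and counted); APC
is the mean, SE the standard deviation across partitions divided by
√(partitions used).

**PCL** — the percentage of lines shared by the predicted and observed
top-k sets (k = 2000 by default, matching selection of the best 2000
candidates from large cohorts).  Larger scores rank better by default
(the grain-yield convention); `largest=False` flips the direction for
traits where smaller is better.  Ties are broken by stable input order,
making the statistic deterministic.  For independent rankings the
expectation is k/n (hypergeometric), which the tests use as a
calibration anchor.

## Numerical and design notes

* Similarities are clipped to [−1, 1] to absorb round-off; undefined
  similarities are NaN, never 0, so "no information" is distinguishable
  from "orthogonal".
* The worked toy example is computed on the raw rating scale, since the
  published weights for it were derived unscaled; pipelines scale first.
* The pairwise-complete convention reproduces two of the three published
  toy weights to their printed (truncated) precision; the third (0.76)
  is not reproducible under any standard missing-data convention we
  tried, so the completion example anchors on the printed weights
  supplied externally.
* CSV serialization uses `%.17g` floats and round-trip parsing, making
  write→read bit-identical for finite float64 values.
* `compound_symmetry_grm(J, d, o)` returns d·I + o·J with a warning (not
  an error) when parameters break positive semidefiniteness, since the
  matrix may still be wanted for inspection.
* Determinism: every stochastic operation (initialisation, epoch order,
  partition draws, fold masks, simulator) takes a seed or generator;
  identical seeds give bit-identical results.

## Known limitations

* IBCF has no notion of uncertainty; fallback cells silently regress to
  the column mean (they are enumerated in the completion report, but not
  flagged in the output matrix).
* SGD matrix factorization is not scaled for matrices with millions of
  observed cells; an ALS or vectorised backend would be the natural
  extension.
* CV2 assumes year labels sort chronologically as strings.
* The mixed-model baselines sometimes compared against these methods
  (per-trait and multi-trait GBLUP) are out of scope; the package
  evaluates the recommender-system methods only.
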