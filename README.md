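# phenorec

Recommender-system prediction of missing phenotypes in multi-trait,
multi-environment (MTME) plant-breeding trials.

## The problem

Genomic selection programs phenotype thousands of candidate lines, but
rarely for every trait in every environment: lines are dropped between
seasons, traits are measured only at some sites, and entire trials fail.
The resulting phenotype table — genotypes down the rows, one column per
environment–trait combination — is a *rating matrix* with missing cells,
exactly the object recommender systems were built to complete.  `phenorec`
treats genotypes as users and environment–trait combinations (items such
as grain yield at site 2, `E2_T1`) as the products they "rate", and
predicts the missing cells from the correlation structure among the
observed ones.

## Methods at the core

**Item-based collaborative filtering (IBCF).**  The missing rating of
genotype *i* for item *j′* is the similarity-weighted average of that
genotype's observed items:

    P(i, j′) = Σ_{j∈N} y_ij · w_jj′ / Σ_{j∈N} |w_jj′|

with item–item weights *w* computed as pairwise-complete cosine or Pearson
similarity between columns.  User-based filtering (UBCF) is the same
computation between rows, optionally weighting with a genomic relationship
matrix **G** = **WW**ᵀ/p built from −1/0/1-coded markers, so that genomic
similarity stands in for phenotypic similarity between lines.

**Regularized matrix factorization (MF).**  The rating matrix is
approximated by a rank-K product R ≈ PQᵀ fitted by stochastic gradient
descent on observed cells, with updates
p_ik ← p_ik + α(2e_ij q_jk − λp_ik) and q_jk ← q_jk + α(2e_ij p_ik − λq_jk),
where e_ij = r_ij − pᵢ·qⱼ, α is the learning rate and λ a ridge penalty.
`mf_tune` selects K and λ by held-out-cell cross-validation.

Both methods operate on column-scaled data (centred, divided by the SD of
*training* cells only); predictions are returned on the original trait
scale.

**Simulation and evaluation.**  A forward sampler draws phenotypes from
y_ijl = β_il + b1_jl + b2_ijl + e_ijl with genetic effects b1 ~ N(0, Gg⊗Σt),
three-way effects b2 ~ N(0, ΣE⊗Gg⊗Σt) and residual rows e_ij· ~ N(0, Re),
using Kronecker-factor Cholesky sampling.  Three preset covariance sets give
pairwise trait/environment correlations 0.85, 0.50 and 0.25, and skew
scenarios replace the errors with exp(∓1.25·|e|).  Evaluation follows two
cross-validation schemes — CV1 (random 80/20 line partitions, 20 repeats)
and CV2 (forward prediction of one trait in a target year) — scored by the
average Pearson correlation (APC) per item and the percentage of common
lines (PCL) in the predicted and observed top-k rankings.

## Worked example

Simulate a high-correlation MTME trial (200 genotypes × 3 environments ×
3 traits), run CV1 with IBCF, and summarise accuracy:

```python
from phenorec import (preset_config, simulate_mtme, build_rating_matrix,
                      cv1_plan, run_cv, pearson_by_item)

cfg = preset_config(1, scenario="S1", J=200, seed=42)
R = build_rating_matrix(simulate_mtme(cfg).records, layout="mtme")
plan = cv1_plan(R, n_partitions=5, test_frac=0.2, seed=42)
report = pearson_by_item(run_cv(R, plan, method="ibcf"))
print(report.table.round(3).to_string(index=False))
```

which prints

```
 item   apc    se  n_partitions_used
E1_T1 0.614 0.037                  5
E1_T2 0.541 0.045                  5
E1_T3 0.701 0.044                  5
E2_T1 0.658 0.036                  5
E2_T2 0.605 0.049                  5
E2_T3 0.687 0.030                  5
E3_T1 0.728 0.032                  5
E3_T2 0.700 0.031                  5
E3_T3 0.744 0.023                  5
```

Each row is one environment–trait item; `apc` is the mean correlation
between predicted and observed phenotypes of the held-out lines over the
five partitions (≈0.66 on average here — with trait and environment
correlations of 0.85, a line's performance elsewhere carries most of the
information needed to fill its gaps), and `se` is the standard error of
that mean.  The same pipeline is available from the shell:

```bash
phenorec simulate --preset 1 -J 200 --seed 42 --out pheno.csv
phenorec cv1 --phenotypes pheno.csv --method ibcf --out preds.csv
phenorec report --predictions preds.csv --out apc.csv
```

## Layout

| module | contents |
| --- | --- |
| `phenorec.ratings` | rating-matrix construction, train-only column scaling, CSV I/O |
| `phenorec.similarity` | cosine/Pearson similarity, IBCF/UBCF completion |
| `phenorec.matfact` | SGD matrix factorization, loss monitoring, grid tuning |
| `phenorec.genomic` | marker I/O, VanRaden and compound-symmetry GRMs |
| `phenorec.simulate` | Kronecker-structured MTME sampler, presets, skew scenarios |
| `phenorec.evaluate` | CV1/CV2 plans, run orchestration, APC/SE and PCL metrics |
| `phenorec.cli` | `phenorec` command-line entry point |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
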