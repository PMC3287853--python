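# Methods notes

This document records the statistical model, the algorithmic and numerical
choices, and the limits of what the synthetic experiments demonstrate.

## Model and procedure

The trait model underlying both methods is linear and additive:

    y = μ + Σ_i β_i s_i(X̃_i) + γᵀC + ε,

where `s_i` maps gene *i*'s additive genotype submatrix to a scalar gene
score, `C` collects Age, Sex, Smoke and the first ten genotype principal
components, and ε is homoscedastic noise.  The two methods differ only in
how `s_i` and the inner coefficients are estimated:

- **GBPLS1** estimates `s_i` by PLS path modeling and the inner model by
  OLS.  For the star topology used here (every gene block adjacent only to
  the single-indicator trait block), the mode-A/factor-scheme iteration has
  an exact fixed point: the outer weight vector of gene *i* is proportional
  to the vector of marginal SNP–trait correlations within the gene.  The
  implementation runs the general alternating algorithm (so the path model
  is explicit and auditable) but tests verify convergence to this closed
  form, which the algorithm reaches in two to three passes.
- **GBPLS2** uses the closed-form first PLS component
  `w_i = X̃_iᵀy/‖X̃_iᵀy‖` — the exact maximizer of `cov(y, X̃_i w)` on the
  unit sphere — and a partially penalized LASSO inner model.

### Partially penalized LASSO

The objective is

    min_β  ‖y − Uβ_U − T̃β_T‖² / (2n) + λ‖β_T‖₁,

with `U` the unpenalized block (intercept + covariates + PCs) and `T̃` the
internally standardized gene scores.  Because `β_U` carries no penalty, it
is profiled out exactly: the solution in `β_T` equals the ordinary LASSO on
the residuals of `y` and `T̃` after projecting out `col(U)`, and `β_U` then
satisfies the exact normal equations given `β_T`.  The LASSO itself is
solved by cyclic coordinate descent on the Gram matrix with warm starts
down a log-spaced λ path (100 points from λ_max to 10⁻³λ_max) and
glmnet-style active-set iteration.  Stopping is on the maximum coordinate
change: 10⁻⁴ inside cross-validation (only the CV error is needed there)
and 10⁻¹⁰ for the final fit, whose KKT residual is checked in tests at
10⁻⁶.  λ is the grid value minimizing mean 10-fold CV squared error; the
1-SE rule is available via `one_se=True`.  Fold assignment is a seeded
shuffle, fixed across the entire λ grid.  Gene-score coefficients are
reported on the original scale; a zero-variance gene score is excluded from
penalization with coefficient 0.

### Screening

Gene score = max |Pearson r| over member SNPs, with the convention that a
zero-variance SNP column has correlation 0 ("no evidence").  Randomization
p-values use the strict estimator `#{score_b ≥ score_obs}/B`, so p = 0 is
possible; the conservative `(k+1)/(B+1)` variant is a flag.  Since a
reassigned gene's score depends only on the multiset of |r| values it
receives, each of the B iterations permutes the cached per-SNP |r| vector —
tests verify this equals from-scratch recomputation.  Each iteration draws
from its own stream derived from the master seed, so results are
independent of evaluation order.  Ordering is (p-value ↑, raw score ↓,
gene id ↑).  Screening is re-run per trait replicate: the trait is the only
input that changes across replicates, so per-replicate screening is the
only self-consistent reading of a per-replicate pipeline.

### Evaluation conventions

- A gene is "selected" in a replicate by top-q membership (GBPLS1) or a
  nonzero LASSO coefficient (GBPLS2) — each algorithm's native output.
- "Top half" of a gene's m SNPs is the first ⌈m/2⌉ after ordering by
  (median rank, snp id).
- TPR/FPR are computed against the full simulated gene universe, so
  screening misses count as missed genes.
- ROC area integrates the (FPR, TPR) points over c = 1..c_max by
  trapezoid, anchored at (0,0) and (1,1).
- The t-test baseline uses the pooled-variance statistic by default
  (Welch by flag); with a single carrier the pooled test is still defined
  and is used, while Welch requires two observations per group.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| G | 1000 | genes retained by screening |
| B | 500 | size-preserving randomizations |
| t | 100 (GBPLS1) / 250 (GBPLS2) | screened genes entering the inner model; GBPLS2 presets 100/250/500/750 |
| q | 25 (presets 25/35/50) | genes kept by \|inner β\| in GBPLS1 |
| folds | 10 | CV folds for the LASSO penalty |
| c | 1..25 | replicate-count cutoff for association calls |
| tol / max_iter | 1e-6 / 300 | PLS path modeling convergence |
| α (t-test) | 2×10⁻⁶ | Bonferroni genome-wide threshold |

GBPLS1 is capped at t = 100 genes: its inner model is plain OLS and the
design (t + 14 columns) degrades toward rank deficiency well before t
approaches n in the cohort sizes targeted here; that regime is what GBPLS2
exists for.

## Synthetic cohort generator

The generator emulates the restricted exome-style cohort the methods were
designed around, using only its published summary characteristics:

- **MAF spectrum**: mixture 0.75·LogUniform(10⁻⁴, 0.01) +
  0.16·LogUniform(0.01, 0.1) + 0.09·Uniform(0.1, 0.5), which reproduces the
  two known quantiles (75% < 0.01, 91% < 0.1) without claiming the true
  site-frequency spectrum.
- **Gene sizes**: negative binomial (r = 2, p = 0.2148) truncated to ≥ 1,
  mean ≈ 7.6 SNPs — the known global mean; the shape is otherwise a choice.
- **Genotypes**: independent Hardy–Weinberg draws, Binomial(2, MAF); *no
  linkage disequilibrium*.  An optional two-subpopulation mode perturbs
  allele frequencies Balding–Nichols-style (off by default, since the
  methods only *adjust* for structure via PCs).
- **Covariates**: Age ~ N(50, 10²), Sex ~ Bernoulli(0.5),
  Smoke ~ Bernoulli(0.3); default trait effects 0.02/yr (Age) and 0.4
  (Smoke).
- **Traits**: R replicates share genotypes and covariates; only the noise
  is redrawn, matching the fixed-genotype replicate design.
- **Causal structure**: either explicit per-SNP effects or per-gene target
  heritabilities.  In the latter case causal SNPs are drawn among variants
  with ≥ 5 carriers (a rarer variant cannot carry the target variance
  in-sample) and the effect size is solved from the realized genotype
  variance, `β = √(h²σ²_tot / (k·var(g)))`, with σ²_tot defined excluding
  covariate variance.  The truth set records both target and realized h².

**Default study** (`gbpls.pipeline.default_study_config`): n = 697 samples
(the published cohort size), 1,000 genes, R = 20 replicates, 9 causal genes
with (h², causal SNPs) ∈ {(1%,1), (1%,2), (1.5%,3), (1.5%,1), (2%,2),
(2%,3), (2.5%,1), (2.5%,2), (3%,3)}.  The gene and replicate counts are
scaled-down analogues of the original 3,205 genes / 200 replicates, chosen
so that a full two-method study runs in minutes on one CPU while keeping
n/p and gene-level effect sizes in a realistic regime.

**What passing tests do and do not show.**  The generator's independence
assumptions (no LD, independent SNPs, Gaussian noise, exactly linear
covariate effects) make the synthetic study a *best case* for both
methods.  Success here demonstrates correctness of the machinery and
sensible power ordering (gene-based ≫ single-SNP for rare causal variants),
not field performance on real sequence data, where LD within genes,
non-normal traits and cryptic relatedness will all matter.

## Numerical choices and degenerate inputs

- Genotype PCA: columns centered and scaled to unit variance, zero-variance
  SNPs dropped, thin SVD, scores = U·S; sign fixed so each score's
  largest-magnitude entry is positive.  Requesting more PCs than the
  attainable rank is an error reporting that rank.
- PLS path modeling: manifest variables standardized (population sd);
  initial weights equal; convergence on max outer-weight change < 10⁻⁶;
  LV sign fixed by r(Z_i, y) ≥ 0.  An all-constant gene block is an error
  from the fitter; the per-replicate runners skip such genes with a warning
  (a monomorphic gene cannot be associated and ranks last in screening).
- GBPLS2 degenerate genes (X̃ᵀy = 0): flagged, excluded from the inner
  model, outer weights reported as 0.
- Ties: screening order (p ↑, score ↓, id ↑); top-q selection by
  (|β| ↓, screening rank ↑); SNP ranks are midranks (mean of tied ranks);
  associated-SNP ordering (median rank ↑, id ↑) with ⌈m/2⌉ kept.
- Determinism: every stochastic step (simulation stages, randomization
  iterations, CV folds) draws from a stream derived from the master seed
  via `SeedSequence`, so the full pipeline is bit-identical across runs and
  independent of execution order.

## Known limitations

- One latent component per gene; no elastic-net/group penalties; no
  bootstrap inference on path coefficients — selection is by magnitude or
  sparsity only, as in the underlying design.
- Missing genotypes, multi-allelic sites, dosages and family data are out
  of scope; loaders reject rather than impute.
- The exact published performance tables cannot be reproduced because the
  original consortium data are not redistributable; all quantitative
  checks are property-based or run on the synthetic stand-in.
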