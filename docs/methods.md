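# Methods

## Model

Phenotypic records of `n` individuals follow the linear model

    y = X beta + Z g + W v + e,

where `X` is the fixed-effect design (intercept plus dummy-coded factors),
`Z` is the column-standardized genotype matrix with entries
`z_ij = (s_ij - 2 p_i) / sqrt(2 p_i (1 - p_i))` for allele dosages
`s_ij in {0, 1, 2}`, `W` maps records to pedigree individuals,
`v ~ N(0, A sigma_a^2)` are polygenic effects on the numerator relationship
matrix `A` (Henderson's tabular method), and `e ~ N(0, E sigma_e^2)` with a
diagonal weight matrix `E` allowing records of unequal precision (identity
for case/control data).

Each SNP effect `g_i` has a four-component mixture prior: a point mass at
zero and three normals with variances `(1e-4, 1e-3, 1e-2) * sigma_g2`, where
`sigma_g2` is the genetic variance of the trait. The mixing proportions
`Pr` carry a Dirichlet(1,1,1,1) prior. `sigma_g2` and `sigma_a2` are inputs
(typically REML estimates; an internal EM-REML helper is provided) and are
held fixed during the EM stage.

## Fitting: EM stage, then a short Gibbs chain

**GBLUP / PEV.** The GBLUP baseline uses `V = G sg2 + W A W' sa2 + E se2`
with `G = Z Z' / m` (the dimensionally consistent divisor; configurable).
Before the EM iterations we compute, once, the prediction-error covariance
of the genomic value with fixed effects absorbed,

    PEV = G sg2 - (G sg2) P_V (G sg2),
    P_V = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

and the per-SNP traces `t_i = Z_i' E^-1 PEV E^-1 Z_i` plus `tr(E^-1 PEV)`.

**EM stage.** Sweeping SNPs in input order with a running residual, each SNP
gets responsibilities from the component log-scores

    L_k = -1/2 log(s2_k z'E^-1 z + se2)
          + 1/2 q_i s2_k / (se2 (s2_k z'E^-1 z + se2)) + log Pr_k,

with the spike reducing to `-1/2 log se2 + log Pr_1`, followed by the
posterior-mean effect update

    g_i = (1 - P(i,1)) * rhs_i / (z'E^-1 z + se2 * sum_{k>=2} P(i,k)/s2_k),

where `rhs_i = Z_i' E^-1 e*` and `e*` is the residual with SNP i added
back. After each sweep: `Pr_k = (sum_i P(i,k) + 1)/(m + 4)`,
`se2 = (e'E^-1 e + tr(E^-1 PEV))/n`, GLS fixed effects, and the polygenic
BLUP `v = (W'E^-1W sa2 + se2 A^-1)^-1 sa2 W'E^-1 (y - Zg - X beta)`.
Convergence uses `(dg'dg)/(g'g) <= 1e-10`. The stage is deterministic.

Two design points deserve emphasis, both fixed after observing the
behaviour of the literal update equations on simulated data:

* **PEV correction direction.** The trace enters the responsibility score
  as a *discount*: `q_i = max(rhs_i^2 - t_i, 0)`. The observed squared
  projection contains, in expectation, the energy `t_i` contributed by the
  estimation errors of all other SNP effects, so subtracting it gives an
  approximately unbiased estimate of the true signal. The additive variant
  (`q_i = rhs_i^2 + t_i`) is available via `EmConfig.pev_mode="plus"`, but
  at desk scale (where `t_i` can reach ~60 % of the null expectation of
  `rhs^2`) it inverts the spike/slab balance, the opposite of the
  documented over-shrinkage of EM-only mixture fitting. The discount
  reproduces that over-shrinkage: the EM stage assigns slightly more SNPs
  to the zero class and slightly lower accuracy than the sampler, which the
  MCMC stage then corrects.
* **Posterior-mean effect update.** Maximising the expected log posterior
  literally makes the spike exert no shrinkage (it contributes no
  precision), which lets the EM overfit catastrophically whenever `m > n`
  and violates monotone shrinkage (raising the spike responsibility would
  *raise* the effect). The slab mass factor `(1 - P(i,1))` makes the update
  the mixture posterior mean: zero in the all-spike limit, exactly the
  ridge solution when pinned to one Gaussian component.

**MCMC stage.** The Gibbs chain starts at the EM solution and discards no
burn-in. Each iteration, in order: `se2 ~` scaled Inv-chi2 with df `n-2`
and scale `y*'E^-1 y*/(n-2)`; `beta ~ N(GLS mean, (X'E^-1X)^-1 se2)`;
`sa2 ~` scaled Inv-chi2 with df `q-2` (the quadratic form has q terms; an
`n-2` strict mode exists) and scale `v'A^-1 v/(q-2)`;
`v ~ N(mu, se2 (W'E^-1W + A^-1 se2/sa2)^-1)`; then per SNP the indicator
from the softmax of the `L_k` above (without the PEV trace) and, for slab
draws, `g_i ~ N(rhs/(z'E^-1z + se2/s2_k), se2/(z'E^-1z + se2/s2_k))`;
finally `Pr ~ Dirichlet(counts + 1)`. Conditional variances carry the
`se2` factor of the standard conjugate forms. One seeded generator drives
the chain; draws are pre-generated per sweep in SNP order, so runs are
bit-reproducible and the random stream does not depend on the active mask.

**Speed-up.** Over the first 500 iterations the per-SNP average spike
probability is accumulated (optionally the sampled-indicator frequency).
At iteration 500, SNPs with average `P(i,1) >= 0.9` are permanently
deactivated: `g_i = 0`, excluded from sweeps, still counted in the spike
component of the Dirichlet update. Posterior responsibilities of
deactivated SNPs average their pre-deactivation samples. Posterior means
of all other quantities average every iteration.

## Evaluation

Accuracy is the Pearson correlation of GEBV (`Z_val g_bar`, validation
genotypes standardized with *reference* allele frequencies; optional
pedigree projection `A_cross A_ref^-1 v_bar`) with the validation
phenotype; bias is the slope of phenotype regressed on GEBV (1 =
unbiased); binary traits are scored by rank-based AUC. QTL mapping ranks
SNPs by `PIP_i = sum_{k>=2} P_bar(i,k)`; the default report size is
`m * Pr_bar_4`.

## Synthetic data

The generator draws per-SNP MAF uniformly on (0.05, 0.5), dosages
Binomial(2, p) (optionally first-order-Markov haplotypes for LD), mixture
labels from the true `Pr`, effects from the component normals, polygenic
effects through a random-mating pedigree via `chol(A) sqrt(sa2)`, and
residuals with homogeneous or two-class (1 vs 4) weights;
`se2 = sg2 (1-h2)/h2`. Binary traits threshold the liability at the
prevalence quantile. By default effects are rescaled so the realized
`var(Zg)` equals `sg2` exactly, which makes recovery tests sharp; the
unrescaled prior-draw mode is used where the generative and analysis
variance grids must coincide (see below). Planted-QTL mode assigns
`n_qtl` evenly spaced SNPs to the largest component and scales each to an
exact share of the genetic variance.

What the simulator does *not* emulate: realistic LD maps and recombination,
population/breed structure, genotyping or imputation error, non-Gaussian
residuals. Passing tests therefore demonstrate internal correctness and
the model's behaviour under its own assumptions, not field performance.

## Validation-study conditions (tests and scripts/acceptance.py)

Problem sizes are chosen so each study runs on a single CPU in minutes:

* Conjugate oracles: n=200, m=50, component pinned, 2000 iterations;
  EM vs ridge at 1e-6 relative error, MCMC vs ridge within batch-means
  Monte-Carlo SEs (20 batches; per-SNP 3 SE with a small multiplicity
  allowance, since 50 simultaneous z-scores are checked).
* Hybrid vs long chain: n=1250 (20 % validation), m=1000, mixing
  proportions (0.99, 0.007, 0.002, 0.001), h2=0.5, 8 seeds; hybrid = EM +
  1500 iterations, long chain = 6000 iterations from a cold start with
  3000 burn-in. Compared on mean validation accuracy.
* Speed-up neutrality: n=2500, m=5000, same mixture, 5 seeds. The wide
  panel matters: the posterior of `Pr` concentrates (and spike
  probabilities sustain the 0.9 threshold) only when thousands of null
  SNPs contribute evidence; at m=1000 the deactivation step is a coin
  flip per seed.
* Major-gene vs GBLUP and QTL mapping: n=1875, m=5000, 20 planted QTL at
  4.5 % of genetic variance each, 10 seeds. A 1 %-of-genetic-variance QTL
  is undetectable at desk-scale n (non-centrality ~ n h2 share), so the
  planted shares are set where PIP > 0.9 is a fair expectation.
* Infinitesimal parity: every SNP in the smallest slab, n=1250, m=1000,
  6 seeds; mixture and GBLUP accuracies agree within 0.02.
* Architecture recovery: n=2500, m=5000, effects drawn from the prior
  *without* rescaling, 5 seeds. Rescaling shifts every realized component
  variance by the common factor `1/(m sum_k Pr_k s_k)` (~16 here), which
  misaligns the generative grid with the analysis grid and makes
  component counts unrecoverable by construction; the prior-draw mode
  keeps the grids identical. The GBLUP stage receives the realized
  genetic variance, the mixture prior the generative scale.
* Sampler calibration: closed-form first moments of the scaled
  inverse-chi-square and Dirichlet draws, and categorical indicator
  frequencies vs softmax probabilities, at 1e5 draws / 3 SE.

## Numerical choices and edge cases

* Dense linear algebra throughout (Cholesky for `V`; explicit inverse only
  for the n-by-n PEV). Intended scale is n up to ~5000.
* Mixing proportions are floored at 1e-12 before logs.
* Monomorphic SNPs keep an all-zero `Z` column (indices stay aligned with
  the input), landing in the spike with zero effect. Missing dosages are
  mean-imputed to `2p` before standardization.
* A zero shrinkage denominator (all responsibility on the spike for a
  zero-variance column) sets the effect to zero.
* `em_check_convergence` with a zero new vector declares convergence only
  if the old vector was also zero.
* EM-REML works on error contrasts after a one-off eigendecomposition, so
  its restricted likelihood is monotone and iterations are O(n); it
  returns the last iterate with a warning flag on non-convergence.
* The inner per-SNP sweeps are numba kernels; the test suite pins them
  against a pure-Python one-SNP-at-a-time reference.

## Known limitations

* The unprinted supplementary equations (PEV construction, responsibility
  formulas) are reconstructed; see the design points above for where and
  why this implementation departs from a literal reading.
* The `Pr` posterior mixes slowly when per-SNP slab information
  `n * 1e-4 * sg2/se2` is small; desk-scale runs inherit this, and the
  spike-proportion estimate is only weakly identified below m ~ 5000.
* No multi-threading; chains are single-seeded (no convergence
  diagnostics beyond the trace output).
* Case/control support is a liability-threshold simulator plus AUC
  scoring; the sampler itself treats the 0/1 record as a continuous
  response with `E = I`.
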