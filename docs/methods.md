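# Methods

This note documents the models, the generative assumptions of the
simulator, the numerical choices, and the limits of what the test suite
demonstrates.

## Dosage calling

At a biallelic locus an individual of dosage `d ∈ {0..m}` (ploidy `m`)
contributes reference reads as `Binomial(n, q_d)` with
`q_d = (d/m)(1 − 2e) + e`, where `n` is the total depth and `e` the
per-read miscall probability. A marker's read counts across the
population are therefore an `(m+1)`-component binomial mixture with known
component probabilities and unknown mixing weights. We fit the weights by
EM (log-space binomial kernels, relative tolerance 1e-8, 200 iterations
max) and assign each individual its maximum-a-posteriori dosage; calls
with posterior below `min_posterior` (default 0.8) or zero depth are set
missing, and markers whose EM does not converge are flagged with all
calls missing. Fixing the ploidy and leaving the weights free mirrors how
population-based polyploid callers are used in practice when the ploidy
is known; the free weights absorb segregation distortion and family
structure without requiring an explicit population model. The 0.8
posterior cut trades call rate for accuracy deliberately — the
missingness filter that follows (≤ 5% per marker) then removes markers
whose calls are systematically ambiguous, and dose-frequency imputation
fills the remaining gaps by sampling each marker's observed dose
distribution.

QC defaults: mean total depth across the population ≥ 25 per marker,
minor allele frequency ≥ 1% (frequency = mean observed dose / ploidy,
boundary inclusive), missingness strictly > 5% removed. Filters operate
on markers only and never drop individuals; they are idempotent.

## Stage 1: longitudinal mixed model

For plant `i` of whole-plot entry `j` in block `k` at harvest `l`:

    y_ijkl = mu + h_l + b_k(l) + p_j(l) + bp_kj(l) + t_il + e_ijkl

`h_l` is fixed; `b_k(l) ~ N(0, σ²_b)`, `p_j(l) ~ N(0, σ²_p)` and
`bp_kj(l) ~ N(0, σ²_bp)` are iid across their harvest-specific levels
(we read the nesting notation literally: independent levels per harvest
with a common variance). The plant term splits into a random genetic
effect `g_il` for sexual offspring, with `g ~ N(0, G_L ⊗ I)` across
harvests, and a fixed clone effect for apomictic check cultivars.
Residual vectors per plant follow `e ~ N(0, R_L ⊗ I)`.

`G_L` and `R_L` come from a nine-structure vocabulary (parameter counts
in parentheses, `L` harvests): ID (1), DIAG (L), CS (2), CSHet (L+1),
AR1 (2), AR1Het (L+1), Po (2), PoHet (L+1), US (L(L+1)/2). The power
models use harvest coordinates, defaulting to `1..L` (calendar dates can
be supplied); with equally spaced coordinates Po reparameterizes AR1.

Estimation is REML on the dense marginal covariance: the restricted
log-likelihood is evaluated in the profiled form including all constants
and the `+ log|XᵀX|` term, so it equals the likelihood of any orthonormal
basis of error contrasts exactly (this is what the brute-force oracle
test checks to 1e-6). Optimization is L-BFGS-B over log-variances and
logit/tanh-transformed correlations (CS correlations bounded below by
−1/(L−1), power-model bases restricted to (0,1)), two starting points,
relative tolerance 1e-8, 500 iterations. Correlations within 1e-3 of an
admissible bound or variances collapsing toward zero set a boundary flag
rather than raising.

Structure choice is hierarchical: all candidate `G_L` against `R_L = ID`,
then all candidate `R_L` under the chosen `G_L`. Within a step the AIC
and BIC minimizers are compared; when they disagree, the criterion whose
difference between the two candidates is larger decides. `nPAR` counts
the structure parameters plus the three design variances — constant
across candidates, so rankings depend only on the structures. AIC uses
`2·nPAR`, BIC uses `nPAR·log(n − rank(X))`. Absolute criterion values are
implementation-specific; only the selection behaviour is meaningful.

Genotype BLUPs and their prediction-error (co)variances come from the
standard `u = DZᵀPy`, `PEV = D − DZᵀPZD` identities evaluated on
harvest-mean contrasts. The generalized heritability is Cullis-style,
`H² = 1 − PEV/(2σ²_G)` with PEV the average variance of pairwise
genotype-comparison BLUPs, computed from a CS-genetic / ID-residual fit;
values outside [0,1] are clipped with a warning. Adjusted entry means —
the stage-2 response — are `mean_l(mu + h_l + g_il)` per genotype, checks
excluded. When harvests are repeated, entry means aggregate over `L`
observations per plant, so their heritability exceeds the plot-level
target the simulator was parameterized at; recovery tests assert
accordingly.

## Relationship matrices

Pedigree `A`: kinship coefficients are propagated in pedigree order. A
gamete's two alleles are identical by descent with probability
`α + (1−α)F_parent` (`α` = double-reduction rate, default 0 = bivalent
pairing); an offspring's inbreeding combines the two gamete identities
(each with probability 1/6, both alleles sampled from one gamete) with
the parents' mutual kinship (probability 2/3); `A = 4·kinship`, so
non-inbred founders have diagonal 1, parent–offspring relationship is
0.5, and full sibs from unrelated non-inbred tetraploid parents are 0.5 —
all verified against a 100,000-replicate gene-dropping simulation.
Unknown parents act as unrelated non-inbred founders.

Genomic `K = WWᵀ/(tr(WWᵀ)/n)` with `W` the column-centered dosage matrix
(mean centering by default; allele-frequency centering is offered and is
numerically identical). `tr(K) = n` by construction; monomorphic markers
contribute zero. With fewer effective markers than individuals `K` is
singular, hence the blend `K* = wK + (1−w)A` (default `w = 0.99`), which
is positive definite whenever `A` is. When no pedigree is available the
coding-comparison helper blends with the identity instead — a pure
numerical regularizer, stated here because it slightly shrinks
off-diagonals relative to a pedigree blend.

## Stage 2: whole-genome regression

All marker models share `y = 1μ + Xβ + ε`, `ε ~ N(0, Iσ²_ε)`, with `X`
the dosage incidence matrix (0..4 tetraploid, 0..2 diploidized) and
differ in the prior on `β_j`:

| model | prior on β_j | hyperprior |
|---|---|---|
| BRR | N(0, σ²_β), common | σ²_β ~ scaled-inv-χ²(df_β, S_β) |
| BayesA | N(0, σ²_βj) per marker | each σ²_βj ~ scaled-inv-χ² |
| BayesB | π·δ₀ + (1−π)·N(0, σ²_βj) | per-marker slab variances |
| BayesC | π·δ₀ + (1−π)·N(0, σ²_β) | one common slab variance |
| BL | N(0, σ²_ε τ²_j) | τ²_j ~ Exp(λ²/2), λ² ~ Gamma |

The spike is an exact point mass at zero with binary indicators — the
numerically stable limit of a tiny-variance normal. The LASSO follows the
Park–Casella hierarchy (inverse-Gaussian full conditional for 1/τ²_j,
optional fixed λ). Residual variance has a scaled-inv-χ² prior in all
models; for the LASSO the marker coefficients contribute
`Σβ²_j/τ²_j` to its full conditional because their prior variance scales
with σ²_ε.

Defaults: `df_β = df_ε = 5`; scale parameters set so the prior modes
split the phenotypic variance evenly between markers and residual
(R² = 0.5), with the marker share divided by `Σ_j var(x_j)` (and by the
slab probability for BayesB/C); `π = 0.5`; λ² gets a Gamma(1.1, ·)
hyperprior whose prior mode matches the R² split. MCMC protocol: 20,000
iterations, 2,000 burn-in, thin 1 (a `fast()` profile of 4,000/1,000
serves cross-validation and tests). Posterior summaries are running
means/SDs; GEBVs are `Xβ̂` at the posterior-mean coefficients.

Inside the sampler `y` is centered and the marker columns of `X` are
column-centered; the intercept then decouples from the marker sweep, and
`μ` and the GEBVs are re-expressed on the original scale on output. This
makes the fixed-hyperparameter BRR posterior mean equal the closed-form
ridge solution `(XᵀX + λI)⁻¹Xᵀ(y − ȳ)`, `λ = σ²_ε/σ²_β`, which the test
suite verifies to 0.02 on a 50×20 instance. The whole chain runs in a
single numba-compiled routine (pure-Python fallback with identical
semantics) seeded explicitly; fixed seed ⇒ identical chains within an
installation.

GBLUP (`y = 1μ + g + ε`, `g ~ N(0, K*σ²_g)`) is fitted by REML on the
eigenbasis of `K*`: the residual variance is profiled out and a bounded
scalar search over the log variance ratio (±14 on the log scale, xatol
1e-10) finds the optimum; BLUPs are `ĝ = σ²_g K* V⁻¹(y − 1μ̂)` evaluated
spectrally, verified against a dense mixed-model-equation solve to 1e-8.
New individuals are predicted as `K_cross K*⁻¹ ĝ`. The genomic
narrow-sense heritability is `h² = σ²_g/(σ²_g + σ²_ε)`. Variance
estimation runs on the unweighted entry means (two-stage, no weighting by
stage-1 prediction-error variances).

## Cross-validation and the coding comparison

Each replication partitions the genotypes into five disjoint folds of
near-equal size (random, or stratified by half-sib family); every fold is
predicted from a model trained on the other four; the pooled out-of-fold
predictions of one replication give one Pearson correlation with the
observed entry means. Predictive ability is the mean of these
per-replication correlations; PRESS is `Σ(ŷ−y)²`, with a standardized
variant dividing by the total sum of squares of `y` (a mean-only
predictor scores 1 — the standardization is our choice; no formula is
fixed by convention). Replications with failed fits or constant
predictions are excluded with a log entry. A known small-sample artifact
of the pooled-correlation estimator: with no signal, predictions collapse
to training-fold means and the expected correlation is −1/√(fold size),
not 0; the null test bounds against that quantity.

`compare_td_dd` removes markers carrying only doses {0,1} (they are
monomorphic after collapsing heterozygotes in a closely related
population), then runs every model on the tetraploid codes and on the
diploidized codes of the same panel with identical fold assignments, and
reports per-model abilities plus the percent superiority
`100·(mean_TD/mean_DD − 1)` of the per-coding model averages.

## The simulator

Defaults encode the target study design: 19 dams drawn from 20 parents,
19 half-sib families × 30 offspring = 570 sexual plants; a split-plot
RCBD with 6 blocks × (19 families + 3 apomictic check cultivars) × 5
plants per plot = 660 plants; 4 or 8 harvests. Sires are drawn uniformly
with replacement per offspring excluding the dam (equal-paternity
polycross); checks are clones. Meiosis is bivalent tetrasomic: a gamete
receives 2 of the parent's 4 homologs without replacement
(hypergeometric), with an optional double-reduction probability under
which both gamete copies descend from one homolog. Founder dosages are
`Binomial(4, p)`, `p ~ U(0.05, 0.95)` per marker; markers are unlinked
(no recombination map — LD diagnostics are exercised on constructed
column duplicates instead). Read depths are negative-binomial (Poisson in
the default infinite-dispersion limit) with mean 60; reference reads are
binomial with the same `q_d` the caller assumes (seq_error 0.005);
missingness, when requested, is completely at random.

Phenotypes follow the stage-1 model's own effect structure. Genetic
values use a compound-symmetry decomposition across harvests: the
marker-determined score `Xβ` (a configurable fraction of markers carry
N(0,1) effects — effects act linearly on the 0..4 codes) supplies the
shared component with variance `ρσ²_g`, iid harvest deviations supply
`(1−ρ)σ²_g`; `σ²_g` is set from the target plot-level heritability
against the mean residual variance (`genetic_rho = 1` gives
constant-across-harvest values). Residuals per plant are drawn from any
of the nine structures. True marker effects and genetic values are
returned for recovery scoring.

What the simulator does **not** emulate: linkage and LD decay, multivalent
pairing, non-random missingness, allele-specific sequencing bias,
genotype-by-environment interaction beyond the harvest dimension, and
selection during population development. Passing tests therefore show
that the pipeline's estimators recover the parameters of this generative
model at these sample sizes — not that real GBS data would achieve the
same accuracies.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by design: populations
of 200–570 individuals, 100–1,000 markers, REML fits on a few hundred
observations, MCMC chains of 2,000–50,000 iterations, 20 cross-validation
replications. The coding-comparison acceptance check replicates over five
independent populations (4 fold-replications each) because the tetraploid
advantage is a property of the dosage-additive architecture in
expectation — a single population draw can reverse it by sampling noise.
All randomness flows through explicit seeds (`numpy` Generators;
`SeedSequence.spawn` for derived streams; the Gibbs core seeds the legacy
global state inside its own routine), so fixed seeds give byte-identical
outputs within an installation.

## Known limitations

- The REML solver builds the dense marginal covariance; it is meant for
  hundreds of plants per fit, not tens of thousands of observations.
- With a single harvest (`L = 1`) the design variances are not separately
  identifiable and structured fits degenerate; the model is intended for
  repeated measurements.
- The US (unstructured) matrix is parameterized via its Cholesky factor
  and can be slow to converge for `L ≥ 6`.
- BayesB/C mixing degrades when `π` is extreme and markers are highly
  collinear; the posterior inclusion probabilities are then the most
  reliable summary, not individual `β̂_j`.
- Generalized heritability is defined under the CS-genetic/ID-residual
  convention; calling it on other fitted structures raises.
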