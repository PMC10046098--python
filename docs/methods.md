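# Methods

## Model

At an X-linked biallelic locus with deleterious allele D, female genotypes
dd/Dd/DD receive genotypic values {0, γ, 2}; γ ∈ [0, 2] measures the degree
of XCI skew (γ = 1 ⇔ random inactivation / additive coding).  With
indicators X1 = 1{≥1 D allele} and X2 = 1{DD}, X = γX1 + (2 − γ)X2, and the
trait models are

- quantitative: Y ~ MVN(βγX1 + β(2 − γ)X2 + Za, σg²φ + σe²I);
- qualitative: Bernoulli-logit with linear predictor
  βγX1 + β(2 − γ)X2 + aᵀZ + b, b ~ MVN(0, σg²φ).

φ is the genetic relatedness of the nf analysed females: the block matrix
blockdiag(2ψf, I), with ψf the kinship matrix of the pedigree females and
the identity covering the unrelated females.  Kinship is the standard
autosomal Lange recursion (founders unrelated and non-inbred, self-kinship
0.5, offspring kinship the average over parents, evaluated in topological
order with ties broken by id).  X-specific kinship is deliberately not
used: the polygenic covariance of the generating model and of the fitted
model are both defined in terms of this ψf, and consistency between the
two is what the estimator needs.  Missing genotypes are handled by pruning:
affected females are removed and φ loses the matching rows/columns.

## Priors and sampling

γ ~ truncated normal(1, 1) on [0, 2] (methods BNM/BNP/BN) or U(0, 2)
(BUM/BUP/BU); β and every covariate coefficient ~ N(0, 10²); σg and σe ~
Exp(1).  All parameters are treated as a priori independent.

Sampling is by the No-U-Turn sampler (`xciskew._nuts`): recursive tree
doubling with a slice variable, dual-averaging step-size adaptation to a
target acceptance statistic of 0.9, and a windowed diagonal metric
(15% fast start, doubling variance-estimation windows, 10% fast tail).
Gradients of the log-posterior are analytic.  Constrained parameters are
transformed — γ by a scaled logit onto [0, 2], scales by log — with the
change-of-variables Jacobians included, so support constraints never need
rejection.  Chains are initialized from the priors, one independent seed
stream per chain.  The default configuration (4 chains × 3000 iterations,
1000 warmup, so 8000 retained draws) matches the study design the package
evaluates; divergent transitions are counted and reported.

Two reparameterizations keep sampling O(nf) per gradient after an O(nf³)
one-off factorization:

- quantitative: rotate data into the eigenbasis of φ = QᵀΣQ; the
  covariance becomes diag(σg²λi + σe²) and the likelihood a product of
  univariate normals.  Eigenvalues in (−10⁻⁸, 0) are clipped to zero;
  anything more negative raises (φ must be PSD).  σe > 0 is guaranteed by
  its prior support, so no jitter is added to φ.
- qualitative: non-centered latent effects b = σg·C·h with φ = CCᵀ
  (Cholesky; an eigendecomposition-based triangular factor is substituted
  if φ is semidefinite) and h ~ N(0, I).

For unrelated-only data (BN/BU) the random effect is dropped entirely and
the model is the fixed-effects regression (quantitative) or plain logistic
regression (qualitative) — matching the estimators previously available
for unrelated females.

## Point and interval estimates

The point estimate is the posterior mode of γ: a Gaussian KDE with
Silverman bandwidth, evaluated on a 2001-point grid over [0, 2] with
reflection at both boundaries (density(g) + density(−g) + density(4 − g)),
argmax over the grid.  Reflection prevents the hard constraint from
deflating the density estimate — and hence biasing the mode — near 0 and 2.
The 95% credible interval is the highest-posterior-density interval,
computed as the shortest window of ⌈0.95·n⌉ consecutive sorted draws
(leftmost window on ties).  Convergence is flagged by max split-R̂ < 1.05
(rank-normalized, via arviz); non-converged results are returned with
`converged=False` rather than discarded, and study summaries count them.

## Simulation engine

Three frozen pedigree templates (4, 10 and 12 members; nuclear,
three-generation and four-generation families) are replicated; the
four-generation topology is founding couple → two children, one married →
two grandchildren of the married couple, one married → four
great-grandchildren.  Members whose sex is not structurally forced are
female with probability 0.5 independently; married-in spouses take the sex
opposite their partner.  50 copies of each template give 1300 members with
~650 females in expectation.

Genotypes descend by X-linked gene dropping: female founders Hardy–
Weinberg at allele frequency pf, male founders Bernoulli(pm), sons draw a
random maternal allele, daughters the paternal allele plus a random
maternal allele.  Quantitative traits for pedigree females are drawn from
MVN(β0 + βX + δK, 2σg²ψf + D_e) with K a standard-normal covariate and
D_e the diagonal of per-genotype residual variances (σe0², σe1², σe2²);
unrelated females get independent residual variance σg² + σe(G)², so their
total variance matches the pedigree females'.  Defaults follow the study
conditions the package evaluates: pf = pm = 0.3, β0 = δ = 0.5, β = 0.2
(locus heritability < 2%), σg² = 1/3, σe² = 1, prevalence 0.3 for binary
traits, γ ~ U(0, 2) unless fixed.

Binary traits are liability-threshold dichotomized: affected iff the
quantitative trait falls below the prevalence quantile.  The threshold is
the *population* quantile of the generating normal mixture — mixture
weights taken from the realized genotype frequencies of the simulated
females (exact Hardy–Weinberg weights would only be correct for founders
when pf ≠ pm), component means β0 + βx_g, variances σg² + σe(g)² + δ².
This keeps prevalence right in expectation across replicates; an
empirical-quantile variant sits behind `empirical_threshold=True`.
Genotype missingness applies independently with probability MR to pedigree
members only; affected females are pruned, never imputed.

What the generator does *not* emulate: ascertainment of families through
affected probands, genotyping error, population stratification,
linkage disequilibrium between loci, or X-specific kinship for the
polygenic term.  Passing tests therefore demonstrate statistical
correctness of the estimator under the stated generating model, not
robustness to those real-data complications.

## Association scan

QC filters run in a fixed order — (1) drop SNPs with missing rate > 10%,
(2) drop SNPs with MAF < 5% (MAF on non-missing calls), (3) drop
individuals with genotype missing rate > 10% over the surviving SNPs —
and the order is load-bearing: a SNP whose minor alleles sit in
high-missingness individuals can survive under this order but not under
the individual-first order (a test documents this).  Traits are
rank-based inverse-normal transformed with Blom offsets,
Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks on ties.

Each SNP is tested at γ ∈ {0, 0.5, 1, 1.5, 2}: codes {0, γ, 2}, model
y = xβ + Za + u + ε with cov(u) = σg²φ, REML variance components profiled
over the ratio σg²/σe² via the eigendecomposition of φ (bounded scalar
search on the log ratio in [−10, 10]), Wald p-value for β = 0 against a
t(n − p) reference.  Variance components are refit per SNP (conservative;
a per-trait null-model shortcut would reuse one fit).  Females with a
missing call are dropped for that SNP only.  A SNP monomorphic at a grid
point returns p = 1 with a zero effect.  The five p-values are combined by
the Cauchy method, T = (1/5)Σ tan{(0.5 − p)π}, p_comb = 1/2 − arctan(T)/π,
valid under arbitrary dependence; p-values at the boundary are clipped
into the open interval with a warning.  Significance uses Bonferroni:
α / #SNPs tested.

## Replicate studies and problem sizes

Study metrics over W replicates: MSE = Σ(γ̂w − γw)²/W; coverage = % of 95%
HPDIs containing the truth (with 500 replicates the nominal Monte-Carlo
band is 93.05–96.95%); and the median, mean, IQR (linear-interpolation
quantiles) and SD (denominator n − 1) of the interval widths.  Replicate
seeds derive deterministically from (base_seed, replicate index), so a
shorter run is a prefix of a longer one, and the per-replicate γ truth is
shared across methods for paired comparisons.

The shipped tests and the acceptance script run scaled-down studies so a
full pass completes on one CPU in minutes: calibration uses 50 replicates
of 10 pedigrees per structure + 130 unrelated females; the
mixed-vs-pedigree-only ordering uses 30 paired replicates at 20 pedigrees
per structure + 260 unrelated; replicate fits use 2 chains × 1200
iterations (400 warmup); the null-calibration study of the association
scan uses 2000 replicates of 300 females; parameter recovery runs single
fits at 200 pedigrees per structure + 2600 unrelated (≈5200 females).
Full-scale studies (500 replicates, the default sampler, and both sample
sizes) use the same code paths via `StudyConfig` but take CPU-hours.

## Known limitations

- The mode of a continuous posterior is estimator-dependent; different
  KDE bandwidths or grids can move γ̂ by a few hundredths, which matters
  when comparing point estimates across implementations.
- At small sample sizes (a few hundred females) the posterior is
  prior-dominated: intervals approach width 2 and the point estimate
  shrinks toward 1 (truncated-normal prior) — visible in the scaled-down
  studies.
- The heteroscedastic residual structure is simulated but not modelled;
  the estimator is evaluated for robustness against it, not extended to
  fit it.
- The Bernoulli-logit sampler carries nf latent variables; qualitative
  fits are an order of magnitude slower than quantitative ones.
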