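# xciskew

Bayesian estimation of the degree of skewed X-chromosome inactivation
(XCI-S) from mixtures of general pedigrees and unrelated females.

## The problem

In females one of the two X chromosomes is silenced in each cell.  Under
random XCI each parental copy is inactivated in about half of the cells, so
at an X-linked biallelic locus (normal allele d, deleterious allele D) the
three female genotypes dd/Dd/DD act additively and can be coded 0/1/2.
Under *skewed* XCI the same allele is inactivated in most cells, and the
effective genotypic value of a heterozygote shifts: coding the genotypes as
{0, γ, 2}, the skew parameter γ ∈ [0, 2] interpolates between "D always
inactive" (γ = 0), random XCI (γ = 1) and "D always active" (γ = 2).
Estimating γ matters because skew modulates the severity of X-linked
disease in carrier females.

`xciskew` estimates γ — point estimate and 95% credible interval — from
quantitative or binary traits measured on females who may be related
through arbitrary pedigrees, plus any number of additional unrelated
females.  It is aimed at statistical geneticists working with family-based
cohorts.

## The model

Writing X1 = 1{Dd or DD} and X2 = 1{DD}, the genotypic value decomposes as
X = γ·X1 + (2 − γ)·X2, which makes the mean model linear in (βγ, β(2 − γ)):

- quantitative: Y ~ MVN(βγX1 + β(2 − γ)X2 + Za, σg²φ + σe²I)
- qualitative:  Yi ~ Bernoulli(logit⁻¹(βγX1i + β(2 − γ)X2i + aᵀZi + bi)),
  b ~ MVN(0, σg²φ)

where φ = blockdiag(2ψf, I) is the genetic relatedness of the females
(ψf the pedigree females' kinship matrix, computed by the Lange recursion),
Z the covariates, σg² the polygenic variance.  Priors: γ ~ truncated
normal(1, 1) on [0, 2] or U(0, 2); β, a ~ N(0, 10²); σg, σe ~ Exp(1).

Posterior sampling uses the No-U-Turn sampler on reparameterized models:
the eigendecomposition φ = QᵀΣQ makes the Gaussian likelihood a product of
independent normals, and the non-centered Cholesky form b = σg·C·h
(φ = CCᵀ, h ~ N(0, I)) does the analogue for the logit model.  The point
estimate of γ is the posterior mode (boundary-reflected KDE) and the
interval is the 95% highest-posterior-density interval.

Six estimator variants share this machinery: **BNM/BUM** (mixed data,
normal/uniform prior), **BNP/BUP** (pedigrees only, φ = 2ψf), **BN/BU**
(unrelated only; fixed-effects model without b).

The package also ships a simulation engine (pedigree templates, X-linked
gene dropping, liability-threshold dichotomization, genotype missingness,
per-genotype residual variances), replicate-study metrics (MSE, coverage,
HPDI-width summaries), and an XCI-aware X-chromosome association scan:
per-SNP linear-mixed-model Wald tests at γ ∈ {0, 0.5, 1, 1.5, 2} combined
with the Cauchy combination test, after standard QC and rank-based inverse
normal transformation of the trait.

## Worked example

```sh
python examples/01_estimate_skew.py
```

simulates 20 pedigrees of each template structure plus 260 unrelated
females with true γ = 0.6 and fits the mixed-data estimator:

```
dataset: 264 pedigree females + 260 unrelated, gamma_truth=0.6
gamma_hat = 0.817
95% HPDI  = (0.341, 1.556), width 1.215
converged = True (max R-hat 1.007)
```

The point estimate (posterior mode) is 0.82 and the 95% HPDI covers the
truth; at ~500 females the interval is still wide — it narrows roughly
with 1/√n.  `examples/02_simulation_study.py` runs a paired replicate
study showing the mixed-data estimator beats the pedigree-only one in MSE
and interval width, and `examples/03_association_scan.py` demonstrates the
γ-grid + Cauchy-combination scan picking out a causal SNP.

A thin CLI wraps the same functions: `xciskew simulate`, `xciskew
estimate`, `xciskew study`, `xciskew assoc` (see `--help`).

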