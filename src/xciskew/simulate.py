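"""Synthetic mixed datasets: pedigrees, X-linked gene dropping, and traits.

The generator emulates a study design of three nested family structures (a
4-person nuclear family, a 10-person three-generation family and a 12-person
four-generation family), replicated many times, plus additional unrelated
females.  Genotypes at one X-linked biallelic locus (alleles d/D) descend from
founders by Mendelian X transmission: females carry two alleles, males one,
sons draw a random maternal allele, daughters receive the paternal allele and
a random maternal allele.

Quantitative traits for the pedigree females follow

    Y_p ~ MVN(beta0 + beta * X_p + delta * K_p,  2 sigma_g^2 psi_f + D_e)

where ``psi_f`` is the (autosomal) kinship matrix of the females, ``X_p`` the
genotypic values {0, gamma, 2}, ``K_p`` a standard-normal covariate and
``D_e`` the diagonal of per-genotype residual variances (homoscedastic when
the three variances coincide).  Unrelated females get independent residual
variance ``sigma_g^2 + sigma_e^2`` so their total trait variance matches the
pedigree females'.  Qualitative traits dichotomize the quantitative ones at
the prevalence quantile of the generating distribution (liability threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .data import GENOTYPES, MISSING, XCIDataset
from .pedigree import (
    FEMALE,
    MALE,
    KinshipMatrix,
    Pedigree,
    build_pedigree,
    kinship_matrix,
    relatedness_block,
)

__all__ = [
    "SimulationConfig",
    "PedigreeTemplate",
    "pedigree_templates",
    "instantiate_template",
    "drop_x_genotypes",
    "simulate_quantitative",
    "population_threshold",
    "dichotomize",
    "apply_missingness",
    "simulate_mixed_dataset",
]

RANDOM = "random"


@dataclass
class SimulationConfig:
    """Study-condition knobs; defaults are the homoscedastic base scenario."""

    n_pedigrees_per_structure: int = 50
    n_unrelated_females: int = 650
    pf: float = 0.3            # deleterious-allele frequency in females
    pm: float = 0.3            # ... and in males
    beta0: float = 0.5         # intercept
    beta: float = 0.2          # genotype effect
    delta: float = 0.5         # covariate effect
    sigma_g2: float = 1.0 / 3.0
    sigma_e2_by_genotype: tuple[float, float, float] = (1.0, 1.0, 1.0)
    trait_type: str = "quantitative"
    prevalence: float = 0.3
    missing_rate: float = 0.0
    gamma: float | None = None   # None: draw from U(0, 2) per dataset
    empirical_threshold: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pf", "pm", "prevalence", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.sigma_g2 < 0 or any(v <= 0 for v in self.sigma_e2_by_genotype):
            raise ValueError("variances must be positive")
        if self.gamma is not None and not 0.0 <= self.gamma <= 2.0:
            raise ValueError("fixed gamma must lie in [0, 2]")
        if self.trait_type not in ("quantitative", "qualitative"):
            raise ValueError("trait_type must be quantitative or qualitative")

    @property
    def sigma_e2(self) -> float:
        """Residual variance of the homoscedastic reference genotype (dd)."""
        return self.sigma_e2_by_genotype[0]

    @property
    def polygenic_heritability(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    @property
    def locus_heritability(self) -> float:
        return (
            self.beta ** 2 * self.pf * (1 - self.pf)
            / (self.sigma_g2 + self.sigma_e2)
        )


@dataclass(frozen=True)
class PedigreeTemplate:
    """A family topology with some member sexes left to the coin flip.

    ``members`` holds ``(id, sex_spec)`` where the spec is ``"male"``,
    ``"female"``, ``"random"`` or ``("spouse", partner_id)`` (sex forced
    opposite to the partner's).  ``children_of`` maps a child id to the
    unordered couple that produced it; father/mother roles are resolved from
    the realized sexes.
    """

    name: str
    members: tuple[tuple[str, object], ...]
    children_of: dict[str, tuple[str, str]]

    @property
    def size(self) -> int:
        return len(self.members)


def pedigree_templates() -> tuple[PedigreeTemplate, PedigreeTemplate, PedigreeTemplate]:
    """The three frozen family structures of sizes 4, 10 and 12."""
    nuclear = PedigreeTemplate(
        "nuclear",
        (("1", MALE), ("2", FEMALE), ("3", RANDOM), ("4", RANDOM)),
        {"3": ("1", "2"), "4": ("1", "2")},
    )
    three_gen = PedigreeTemplate(
        "three_generation",
        (
            ("1", MALE), ("2", FEMALE),
            ("3", RANDOM), ("4", ("spouse", "3")),
            ("5", RANDOM), ("6", ("spouse", "5")),
            ("7", RANDOM), ("8", RANDOM), ("9", RANDOM), ("10", RANDOM),
        ),
        {
            "3": ("1", "2"), "5": ("1", "2"),
            "7": ("3", "4"), "8": ("3", "4"),
            "9": ("5", "6"), "10": ("5", "6"),
        },
    )
    four_gen = PedigreeTemplate(
        "four_generation",
        (
            ("1", MALE), ("2", FEMALE),
            ("3", RANDOM), ("4", ("spouse", "3")), ("5", RANDOM),
            ("6", RANDOM), ("7", ("spouse", "6")), ("8", RANDOM),
            ("9", RANDOM), ("10", RANDOM), ("11", RANDOM), ("12", RANDOM),
        ),
        {
            "3": ("1", "2"), "5": ("1", "2"),
            "6": ("3", "4"), "8": ("3", "4"),
            "9": ("6", "7"), "10": ("6", "7"),
            "11": ("6", "7"), "12": ("6", "7"),
        },
    )
    return nuclear, three_gen, four_gen


def instantiate_template(
    template: PedigreeTemplate, pedigree_id: str, rng: np.random.Generator
) -> Pedigree:
    """Realize coin-flip sexes (each female w.p. 0.5) and build the Pedigree."""
    sexes: dict[str, str] = {}
    spouses: list[tuple[str, str]] = []
    for mid, spec in template.members:
        if spec in (MALE, FEMALE):
            sexes[mid] = spec
        elif spec == RANDOM:
            sexes[mid] = FEMALE if rng.random() < 0.5 else MALE
        else:
            spouses.append((mid, spec[1]))
    for mid, partner in spouses:
        sexes[mid] = FEMALE if sexes[partner] == MALE else MALE

    records = []
    for mid, _spec in template.members:
        if mid in template.children_of:
            pa, pb = template.children_of[mid]
            father = pa if sexes[pa] == MALE else pb
            mother = pb if father == pa else pa
            records.append((mid, father, mother, sexes[mid]))
        else:
            records.append((mid, None, None, sexes[mid]))
    return build_pedigree(records, pedigree_id=pedigree_id)


def drop_x_genotypes(
    ped: Pedigree, pf: float, pm: float, rng: np.random.Generator
) -> dict[str, str]:
    """Drop X-linked genotypes through a pedigree.

    Female founders are Hardy-Weinberg at ``pf``; male founders carry D with
    probability ``pm``.  Returns ``{"dd","Dd","DD"}`` for females and
    ``{"d","D"}`` for males.
    """
    alleles: dict[str, tuple[int, ...]] = {}  # 1 = D
    out: dict[str, str] = {}
    for mid in ped.topological_order():
        m = ped[mid]
        if m.is_founder:
            if m.sex == FEMALE:
                a = (int(rng.random() < pf), int(rng.random() < pf))
            else:
                a = (int(rng.random() < pm),)
        else:
            mat = alleles[m.mother]
            maternal = mat[rng.integers(len(mat))]
            if m.sex == FEMALE:
                a = (alleles[m.father][0], maternal)
            else:
                a = (maternal,)
        alleles[mid] = a
        out[mid] = GENOTYPES[sum(a)] if m.sex == FEMALE else ("D" if a[0] else "d")
    return out


def _genotype_index(genotypes: Sequence[str]) -> np.ndarray:
    lookup = {g: k for k, g in enumerate(GENOTYPES)}
    try:
        return np.array([lookup[g] for g in genotypes], dtype=int)
    except KeyError as exc:
        raise ValueError(f"cannot code genotype {exc.args[0]!r}") from exc


def genotypic_values(genotypes: Sequence[str], gamma: float) -> np.ndarray:
    """Codes {0, gamma, 2} for {dd, Dd, DD}."""
    return np.array([0.0, gamma, 2.0])[_genotype_index(genotypes)]


def simulate_quantitative(
    genotypes: Sequence[str],
    gamma: float,
    config: SimulationConfig,
    psi_f: KinshipMatrix | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (traits, covariate K) for one group of females.

    ``psi_f`` is the female kinship matrix for pedigree females, or ``None``
    for unrelated females (independent residuals of variance
    ``sigma_g^2 + sigma_e^2(genotype)``).
    """
    gidx = _genotype_index(genotypes)
    n = len(gidx)
    x = np.array([0.0, gamma, 2.0])[gidx]
    k = rng.standard_normal(n)
    mean = config.beta0 + config.beta * x + config.delta * k
    res_var = np.asarray(config.sigma_e2_by_genotype, dtype=float)[gidx]
    if psi_f is None:
        y = mean + rng.standard_normal(n) * np.sqrt(config.sigma_g2 + res_var)
        return y, k
    cov = 2.0 * config.sigma_g2 * psi_f.values + np.diag(res_var)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("trait covariance is not positive definite") from exc
    y = mean + chol @ rng.standard_normal(n)
    return y, k


def population_threshold(
    config: SimulationConfig, gamma: float, genotype_freqs: Sequence[float]
) -> float:
    """Prevalence quantile of the normal-mixture marginal of the trait.

    Marginally over the covariate and residual, a female with genotype g has
    trait ~ N(beta0 + beta * x_g, sigma_g^2 + sigma_e^2(g) + delta^2); the
    marginal is the mixture over the genotype frequencies supplied.
    """
    w = np.asarray(genotype_freqs, dtype=float)
    if w.shape != (3,) or not np.isclose(w.sum(), 1.0):
        raise ValueError("genotype_freqs must be 3 probabilities summing to 1")
    x = np.array([0.0, gamma, 2.0])
    mu = config.beta0 + config.beta * x
    sd = np.sqrt(
        config.sigma_g2 + np.asarray(config.sigma_e2_by_genotype) + config.delta ** 2
    )

    def cdf(t: float) -> float:
        return float(np.sum(w * norm.cdf((t - mu) / sd))) - config.prevalence

    lo = float(np.min(mu - 10 * sd))
    hi = float(np.max(mu + 10 * sd))
    return brentq(cdf, lo, hi)


def dichotomize(
    traits: np.ndarray, prevalence: float, threshold: float | None = None
) -> np.ndarray:
    """Liability-threshold dichotomization: affected (1) iff trait < threshold.

    With ``threshold=None`` the empirical prevalence-quantile of ``traits`` is
    used; the caller may instead pass the population threshold of the
    generating model.
    """
    traits = np.asarray(traits, dtype=float)
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    if prevalence == 0.0:
        return np.zeros(len(traits))
    if threshold is None:
        if np.ptp(traits) == 0.0:
            raise ValueError("constant trait vector has no strictly-less threshold")
        threshold = float(np.quantile(traits, prevalence))
    return (traits < threshold).astype(float)


def apply_missingness(
    genotypes: dict[str, str] | Sequence[str],
    missing_rate: float,
    rng: np.random.Generator,
):
    """Independently replace each genotype by the missing sentinel w.p. MR."""
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must lie in [0, 1]")
    if isinstance(genotypes, dict):
        return {
            k: (MISSING if rng.random() < missing_rate else v)
            for k, v in genotypes.items()
        }
    return np.array(
        [MISSING if rng.random() < missing_rate else g for g in genotypes],
        dtype=object,
    )


def simulate_mixed_dataset(config: SimulationConfig) -> XCIDataset:
    """Full pipeline: templates -> gene drop -> missingness -> pruning -> traits.

    Reproducible given ``config.seed``; all randomness flows from a single
    generator in a fixed order (pedigrees, genotypes, missingness, gamma,
    traits for pedigree then unrelated females).
    """
    rng = np.random.default_rng(config.seed)
    templates = pedigree_templates()

    peds: list[Pedigree] = []
    for tmpl in templates:
        for k in range(config.n_pedigrees_per_structure):
            peds.append(instantiate_template(tmpl, f"{tmpl.name}_{k + 1}", rng))

    ped_geno: list[dict[str, str]] = []
    for ped in peds:
        g = drop_x_genotypes(ped, config.pf, config.pm, rng)
        if config.missing_rate > 0:
            g = apply_missingness(g, config.missing_rate, rng)
        ped_geno.append(g)

    # retained pedigree females (non-missing genotype), in pedigree order
    fem_ids: list[str] = []
    fem_geno: list[str] = []
    psi_blocks: list[np.ndarray] = []
    for ped, geno in zip(peds, ped_geno):
        kin = kinship_matrix(ped)
        keep = [
            m.id for m in ped.members
            if m.sex == FEMALE and geno[m.id] != MISSING
        ]
        if not keep:
            continue
        sub = kin.restrict(keep)
        psi_blocks.append(sub.values)
        fem_ids.extend(f"{ped.pedigree_id}:{i}" for i in keep)
        fem_geno.extend(geno[i] for i in keep)
    npf = len(fem_ids)
    psi_f = np.zeros((npf, npf))
    at = 0
    for blk in psi_blocks:
        b = blk.shape[0]
        psi_f[at:at + b, at:at + b] = blk
        at += b
    psi_f_mat = KinshipMatrix(fem_ids, psi_f)

    n_unr = config.n_unrelated_females
    hw = np.array(
        [(1 - config.pf) ** 2, 2 * config.pf * (1 - config.pf), config.pf ** 2]
    )
    unr_geno = [GENOTYPES[k] for k in rng.choice(3, size=n_unr, p=hw)]
    unr_ids = [f"U{k + 1}" for k in range(n_unr)]

    gamma = config.gamma if config.gamma is not None else float(rng.uniform(0, 2))

    y_ped, k_ped = simulate_quantitative(fem_geno, gamma, config, psi_f_mat, rng)
    y_unr, k_unr = simulate_quantitative(unr_geno, gamma, config, None, rng)

    genotypes = np.array(fem_geno + unr_geno, dtype=object)
    traits = np.concatenate([y_ped, y_unr])
    covar = np.column_stack(
        [np.ones(npf + n_unr), np.concatenate([k_ped, k_unr])]
    )

    if config.trait_type == "qualitative":
        if config.empirical_threshold:
            thr = None
        else:
            counts = np.bincount(_genotype_index(genotypes), minlength=3)
            thr = population_threshold(config, gamma, counts / counts.sum())
        traits = dichotomize(traits, config.prevalence, threshold=thr)

    phi = relatedness_block(psi_f_mat, n_unr, unrelated_ids=unr_ids)
    return XCIDataset(
        female_ids=fem_ids + unr_ids,
        genotypes=genotypes,
        traits=traits,
        covariates=covar,
        relatedness=phi,
        trait_type=config.trait_type,
        gamma_truth=gamma,
    )
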