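"""Likelihoods, priors, and the reparameterizations that make sampling cheap.

Genotype coding
---------------
A heterozygote's genotypic value is the unknown gamma in [0, 2]; writing
``X = gamma * X1 + (2 - gamma) * X2`` with indicators ``X1 = 1{Dd or DD}``
and ``X2 = 1{DD}`` makes the mean linear in (beta*gamma, beta*(2-gamma)).

Quantitative traits (linear mixed model)
----------------------------------------
``Y ~ MVN(beta*gamma*X1 + beta*(2-gamma)*X2 + Z a, sigma_g^2 phi + sigma_e^2 I)``.
With the eigendecomposition ``phi = Q^T Sigma Q`` (rows of Q are
eigenvectors), rotating ``Y* = Q Y`` etc. turns the covariance diagonal,
``sigma_g^2 lambda_i + sigma_e^2``, so the likelihood is a product of
independent univariate normals — an O(n) evaluation after a one-off O(n^3)
decomposition.

Qualitative traits (Bernoulli-logit mixed model)
------------------------------------------------
``Y_i ~ Bernoulli(logit^{-1}(eta_i))`` with
``eta = beta*gamma*X1 + beta*(2-gamma)*X2 + Z a + b``, ``b ~ MVN(0,
sigma_g^2 phi)``.  The non-centered form ``b = sigma_g C h`` with ``phi = C
C^T`` (Cholesky) and ``h ~ MVN(0, I)`` removes the prior correlation from the
latent effects, which is what gradient-based samplers need.

Priors: gamma ~ truncated-normal(1, 1) on [0, 2] or U(0, 2); beta and each
covariate coefficient ~ N(0, 10^2); sigma_g (and sigma_e) ~ Exp(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit
from scipy.stats import norm

from .data import XCIDataset
from .pedigree import RelatednessMatrix

__all__ = [
    "GenotypeDesign",
    "PriorSpec",
    "TransformedData",
    "encode_genotypes",
    "genotypic_value",
    "evd_transform",
    "cholesky_transform",
    "loglik_quantitative",
    "loglik_qualitative",
    "log_prior_gamma",
    "QuantitativePosterior",
    "QualitativePosterior",
    "build_posterior",
]

_EIG_FLOOR = 1e-8
_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GenotypeDesign:
    """Indicator pair (X1 = carrier of >=1 D, X2 = DD homozygote)."""

    x1: np.ndarray
    x2: np.ndarray


def encode_genotypes(genotypes) -> GenotypeDesign:
    """Indicators from string genotypes; missing genotypes must be pruned first."""
    x1 = np.empty(len(genotypes))
    x2 = np.empty(len(genotypes))
    for k, g in enumerate(genotypes):
        if g == "dd":
            x1[k], x2[k] = 0.0, 0.0
        elif g == "Dd":
            x1[k], x2[k] = 1.0, 0.0
        elif g == "DD":
            x1[k], x2[k] = 1.0, 1.0
        else:
            raise ValueError(
                f"cannot encode genotype {g!r}; prune missing genotypes first"
            )
    return GenotypeDesign(x1, x2)


def genotypic_value(design: GenotypeDesign, gamma: float) -> np.ndarray:
    """X = gamma * X1 + (2 - gamma) * X2, i.e. {0, gamma, 2} per genotype."""
    if not 0.0 <= gamma <= 2.0:
        raise ValueError(f"gamma must lie in [0, 2], got {gamma}")
    return gamma * design.x1 + (2.0 - gamma) * design.x2


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters; gamma_prior is 'truncated_normal' or 'uniform'."""

    gamma_prior: str = "truncated_normal"
    beta_sd: float = 10.0
    a_sd: float = 10.0
    sigma_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_prior not in ("truncated_normal", "uniform"):
            raise ValueError(f"unknown gamma prior {self.gamma_prior!r}")


# log of the truncated-normal(1,1,[0,2]) normalizing constant Phi(1)-Phi(-1)
_TN_LOGZ = float(np.log(norm.cdf(1.0) - norm.cdf(-1.0)))


def log_prior_gamma(gamma: float, spec: PriorSpec) -> float:
    """Log prior density of gamma; -inf outside [0, 2]."""
    if not 0.0 <= gamma <= 2.0:
        return -np.inf
    if spec.gamma_prior == "uniform":
        return -np.log(2.0)
    return float(norm.logpdf(gamma - 1.0)) - _TN_LOGZ


@dataclass(frozen=True)
class TransformedData:
    """Either the EVD rotation (quantitative) or the Cholesky factor."""

    kind: str
    eigenvalues: np.ndarray | None = None
    y: np.ndarray | None = None
    x1: np.ndarray | None = None
    x2: np.ndarray | None = None
    z: np.ndarray | None = None
    chol: np.ndarray | None = None


def _check_phi(phi: np.ndarray) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
        raise ValueError("phi must be square")
    if not np.allclose(phi, phi.T, atol=1e-10):
        raise ValueError("phi must be symmetric")
    return phi


def evd_transform(
    phi: RelatednessMatrix | np.ndarray,
    y: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    z: np.ndarray,
) -> TransformedData:
    """Rotate data into the eigenbasis of phi.

    Eigenvalues in (-1e-8, 0) are clipped to zero; anything more negative is
    an error (phi is a relatedness matrix and must be PSD).
    """
    phi = _check_phi(phi.values if isinstance(phi, RelatednessMatrix) else phi)
    lam, vec = np.linalg.eigh(phi)
    if lam.min() < -_EIG_FLOOR:
        raise ValueError(f"phi has negative eigenvalue {lam.min():.3e}")
    lam = np.clip(lam, 0.0, None)
    q = vec.T  # rows are eigenvectors: phi = Q^T Sigma Q
    return TransformedData(
        kind="evd",
        eigenvalues=lam,
        y=q @ y,
        x1=q @ x1,
        x2=q @ x2,
        z=q @ np.atleast_2d(z),
    )


def cholesky_transform(phi: RelatednessMatrix | np.ndarray) -> TransformedData:
    """Lower-triangular C with phi = C C^T (PSD-safe via eigendecomposition)."""
    phi = _check_phi(phi.values if isinstance(phi, RelatednessMatrix) else phi)
    try:
        c = np.linalg.cholesky(phi)
    except np.linalg.LinAlgError:
        lam, vec = np.linalg.eigh(phi)
        if lam.min() < -_EIG_FLOOR:
            raise ValueError(f"phi has negative eigenvalue {lam.min():.3e}")
        lam = np.clip(lam, 0.0, None)
        # QR of the symmetric square root gives a triangular factor
        root = vec * np.sqrt(lam)
        _, r = np.linalg.qr(root.T)
        c = r.T * np.sign(np.diag(r))  # make diagonal nonnegative
    return TransformedData(kind="cholesky", chol=c)


def loglik_quantitative(
    gamma: float,
    beta: float,
    a: np.ndarray,
    sigma_g: float,
    sigma_e: float,
    transformed: TransformedData,
) -> float:
    """Gaussian log-likelihood in the eigenbasis (sum of univariate normals)."""
    if transformed.kind != "evd":
        raise ValueError("quantitative likelihood needs an EVD transform")
    lam = transformed.eigenvalues
    v = sigma_g ** 2 * lam + sigma_e ** 2
    if np.any(v <= 0):
        raise ValueError("singular covariance: sigma_e = 0 with zero eigenvalue")
    mu = (
        beta * gamma * transformed.x1
        + beta * (2.0 - gamma) * transformed.x2
        + transformed.z @ np.atleast_1d(a)
    )
    r = transformed.y - mu
    return float(-0.5 * np.sum(_LOG_2PI + np.log(v) + r * r / v))


def loglik_qualitative(
    gamma: float,
    beta: float,
    a: np.ndarray,
    sigma_g: float,
    h: np.ndarray,
    y: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    z: np.ndarray,
    chol: np.ndarray,
) -> float:
    """Bernoulli-logit log-likelihood in the non-centered parameterization.

    Includes the standard-normal log-density of the whitened latent vector h
    (so this is the joint log-density of data and latents given the
    parameters).
    """
    if not np.all(np.isin(y, [0.0, 1.0])):
        raise ValueError("qualitative traits must be 0/1")
    b = sigma_g * (chol @ h)
    eta = beta * gamma * x1 + beta * (2.0 - gamma) * x2 + np.atleast_2d(z) @ np.atleast_1d(a) + b
    # y*eta - log(1 + exp(eta)), stably
    ll = float(np.sum(y * eta + log_expit(-eta)))
    ll += float(np.sum(norm.logpdf(h)))
    return ll


# --------------------------------------------------------------------------
# Log-posteriors on the unconstrained scale, with analytic gradients.
#
# Unconstrained coordinates:
#   t       : gamma = 2 * expit(t)
#   beta    : identity
#   a       : identity (m coords)
#   u_g     : sigma_g = exp(u_g)   (if the model has a polygenic term)
#   u_e     : sigma_e = exp(u_e)   (quantitative only)
#   h       : identity (nf coords, qualitative polygenic models only)
# Jacobian terms for the changes of variables are included in logp.
# --------------------------------------------------------------------------


class _PosteriorBase:
    prior: PriorSpec

    def _gamma_and_jac(self, t: float) -> tuple[float, float, float, float]:
        """gamma, dgamma/dt, log|J|, dlog|J|/dt for the interval transform."""
        s = float(expit(t))
        gamma = 2.0 * s
        dgam = 2.0 * s * (1.0 - s)
        logj = np.log(2.0) + float(log_expit(t)) + float(log_expit(-t))
        dlogj = 1.0 - 2.0 * s
        return gamma, dgam, logj, dlogj

    def _gamma_prior_terms(self, gamma: float) -> tuple[float, float]:
        """(log prior, d/dgamma log prior) on the constrained scale."""
        if self.prior.gamma_prior == "uniform":
            return -np.log(2.0), 0.0
        d = gamma - 1.0
        return -0.5 * d * d - 0.5 * _LOG_2PI - _TN_LOGZ, -d

    def _coef_prior(self, beta: float, a: np.ndarray) -> tuple[float, float, np.ndarray]:
        vb = self.prior.beta_sd ** 2
        va = self.prior.a_sd ** 2
        lp = -0.5 * (beta ** 2 / vb + _LOG_2PI + np.log(vb))
        lp += float(-0.5 * np.sum(a ** 2 / va + _LOG_2PI + np.log(va)))
        return lp, -beta / vb, -a / va

    @staticmethod
    def _exp_clipped(u: float) -> float:
        # extreme warmup excursions: keep exp finite, the prior rejects anyway
        return float(np.exp(min(u, 40.0)))

    def _sigma_prior(self, u: float) -> tuple[float, float]:
        """Exp(rate) prior on sigma = exp(u), with the log Jacobian u."""
        rate = self.prior.sigma_rate
        sigma = self._exp_clipped(u)
        return np.log(rate) - rate * sigma + u, 1.0 - rate * sigma

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        """Draw an initial unconstrained position from the priors."""
        raise NotImplementedError

    def unpack(self, x: np.ndarray) -> dict[str, float | np.ndarray]:
        raise NotImplementedError

    def logp_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        raise NotImplementedError


class QuantitativePosterior(_PosteriorBase):
    """EVD-rotated linear mixed model; set ``polygenic=False`` for the
    fixed-effects model used with unrelated-only data."""

    def __init__(
        self,
        transformed: TransformedData,
        prior: PriorSpec,
        polygenic: bool = True,
    ):
        if transformed.kind != "evd":
            raise ValueError("need an EVD transform")
        self.t = transformed
        self.prior = prior
        self.polygenic = polygenic
        self.m = transformed.z.shape[1]
        self.dim = 2 + self.m + (2 if polygenic else 1)
        self.param_names = (
            ["gamma", "beta"]
            + [f"a{j + 1}" for j in range(self.m)]
            + (["sigma_g", "sigma_e"] if polygenic else ["sigma_e"])
        )

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        gamma = rng.uniform(0.2, 1.8)
        t = float(np.log(gamma / (2.0 - gamma)))
        beta = rng.normal(0, 1.0)
        a = rng.normal(0, 1.0, size=self.m)
        sig = np.log(rng.exponential(1.0, size=(2 if self.polygenic else 1)) + 0.1)
        return np.concatenate([[t, beta], a, sig])

    def unpack(self, x: np.ndarray) -> dict:
        gamma = 2.0 * expit(x[0])
        out = {"gamma": gamma, "beta": x[1]}
        a = x[2:2 + self.m]
        for j in range(self.m):
            out[f"a{j + 1}"] = a[j]
        if self.polygenic:
            out["sigma_g"] = np.exp(x[2 + self.m])
            out["sigma_e"] = np.exp(x[3 + self.m])
        else:
            out["sigma_e"] = np.exp(x[2 + self.m])
        return out

    def logp_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        m = self.m
        t, beta = x[0], x[1]
        a = x[2:2 + m]
        gamma, dgam, logj, dlogj = self._gamma_and_jac(t)
        td = self.t
        lam = td.eigenvalues
        if self.polygenic:
            u_g, u_e = x[2 + m], x[3 + m]
            sg, se = self._exp_clipped(u_g), self._exp_clipped(u_e)
            v = sg * sg * lam + se * se
        else:
            u_e = x[2 + m]
            se = self._exp_clipped(u_e)
            v = np.full_like(td.y, se * se)
        mu = beta * gamma * td.x1 + beta * (2.0 - gamma) * td.x2 + td.z @ a
        r = td.y - mu
        inv_v = 1.0 / v
        ll = -0.5 * float(np.sum(_LOG_2PI + np.log(v) + r * r * inv_v))

        dmu = r * inv_v                       # dll/dmu_i
        dv = 0.5 * (r * r * inv_v - 1.0) * inv_v  # dll/dv_i
        g_beta = float(dmu @ (gamma * td.x1 + (2.0 - gamma) * td.x2))
        g_gamma = beta * float(dmu @ (td.x1 - td.x2))
        g_a = td.z.T @ dmu

        lp_g, dlp_g = self._gamma_prior_terms(gamma)
        lp_c, g_beta_pr, g_a_pr = self._coef_prior(beta, a)
        logp = ll + lp_g + logj + lp_c
        grad = np.empty_like(x)
        grad[0] = (g_gamma + dlp_g) * dgam + dlogj
        grad[1] = g_beta + g_beta_pr
        grad[2:2 + m] = g_a + g_a_pr
        if self.polygenic:
            lp_sg, dlp_sg = self._sigma_prior(x[2 + m])
            lp_se, dlp_se = self._sigma_prior(x[3 + m])
            logp += lp_sg + lp_se
            grad[2 + m] = float(dv @ (2.0 * sg * sg * lam)) + dlp_sg
            grad[3 + m] = float(np.sum(dv) * 2.0 * se * se) + dlp_se
        else:
            lp_se, dlp_se = self._sigma_prior(x[2 + m])
            logp += lp_se
            grad[2 + m] = float(np.sum(dv) * 2.0 * se * se) + dlp_se
        return logp, grad


class QualitativePosterior(_PosteriorBase):
    """Bernoulli-logit model, non-centered latent effects b = sigma_g C h.

    With ``polygenic=False`` (unrelated-only data) the latents drop out and
    this is a plain Bayesian logistic regression.
    """

    def __init__(
        self,
        y: np.ndarray,
        x1: np.ndarray,
        x2: np.ndarray,
        z: np.ndarray,
        chol: np.ndarray | None,
        prior: PriorSpec,
        polygenic: bool = True,
    ):
        y = np.asarray(y, dtype=float)
        if not np.all(np.isin(y, [0.0, 1.0])):
            raise ValueError("qualitative traits must be 0/1")
        if np.ptp(y) == 0.0:
            raise ValueError("all-constant trait vector")
        self.y, self.x1, self.x2 = y, np.asarray(x1, float), np.asarray(x2, float)
        self.z = np.atleast_2d(np.asarray(z, float))
        self.chol = chol
        self.prior = prior
        self.polygenic = polygenic
        self.n = len(y)
        self.m = self.z.shape[1]
        self.dim = 2 + self.m + (1 + self.n if polygenic else 0)
        self.param_names = (
            ["gamma", "beta"]
            + [f"a{j + 1}" for j in range(self.m)]
            + (["sigma_g"] if polygenic else [])
        )

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        gamma = rng.uniform(0.2, 1.8)
        t = float(np.log(gamma / (2.0 - gamma)))
        head = np.concatenate([[t, rng.normal(0, 1.0)], rng.normal(0, 1.0, self.m)])
        if not self.polygenic:
            return head
        u_g = np.log(rng.exponential(1.0) + 0.1)
        h = rng.normal(0, 0.1, size=self.n)
        return np.concatenate([head, [u_g], h])

    def unpack(self, x: np.ndarray) -> dict:
        out = {"gamma": 2.0 * expit(x[0]), "beta": x[1]}
        for j in range(self.m):
            out[f"a{j + 1}"] = x[2 + j]
        if self.polygenic:
            out["sigma_g"] = np.exp(x[2 + self.m])
        return out

    def logp_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        m = self.m
        t, beta = x[0], x[1]
        a = x[2:2 + m]
        gamma, dgam, logj, dlogj = self._gamma_and_jac(t)
        eta = beta * gamma * self.x1 + beta * (2.0 - gamma) * self.x2 + self.z @ a
        if self.polygenic:
            u_g = x[2 + m]
            sg = self._exp_clipped(u_g)
            h = x[3 + m:]
            ch = self.chol @ h
            eta = eta + sg * ch
        p = expit(eta)
        ll = float(np.sum(self.y * eta + log_expit(-eta)))
        deta = self.y - p

        lp_g, dlp_g = self._gamma_prior_terms(gamma)
        lp_c, g_beta_pr, g_a_pr = self._coef_prior(beta, a)
        logp = ll + lp_g + logj + lp_c
        grad = np.empty_like(x)
        grad[0] = (beta * float(deta @ (self.x1 - self.x2)) + dlp_g) * dgam + dlogj
        grad[1] = float(deta @ (gamma * self.x1 + (2.0 - gamma) * self.x2)) + g_beta_pr
        grad[2:2 + m] = self.z.T @ deta + g_a_pr
        if self.polygenic:
            lp_sg, dlp_sg = self._sigma_prior(u_g)
            logp += lp_sg - 0.5 * float(h @ h) - 0.5 * self.n * _LOG_2PI
            grad[2 + m] = sg * float(deta @ ch) + dlp_sg
            grad[3 + m:] = sg * (self.chol.T @ deta) - h
        return logp, grad


def build_posterior(
    data: XCIDataset, prior: PriorSpec, polygenic: bool = True
) -> _PosteriorBase:
    """Assemble the transformed log-posterior for a pruned dataset."""
    design = encode_genotypes(data.genotypes)
    if data.trait_type == "quantitative":
        if polygenic:
            td = evd_transform(
                data.relatedness, data.traits, design.x1, design.x2, data.covariates
            )
        else:
            td = TransformedData(
                kind="evd",
                eigenvalues=np.zeros(data.nf),
                y=data.traits,
                x1=design.x1,
                x2=design.x2,
                z=data.covariates,
            )
        return QuantitativePosterior(td, prior, polygenic=polygenic)
    chol = cholesky_transform(data.relatedness).chol if polygenic else None
    return QualitativePosterior(
        data.traits, design.x1, design.x2, data.covariates, chol, prior,
        polygenic=polygenic,
    )
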