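"""X-chromosome association scan with XCI-aware genotype coding.

For each SNP the heterozygote coding gamma is unknown, so the scan fits a
linear mixed model at each gamma on the grid {0, 0.5, 1, 1.5, 2} —

    y = x(gamma) * beta + Z a + u + eps,   cov(u) = sigma_g^2 * phi

— computes a Wald p-value for beta = 0 at each gamma (REML variance
components profiled over the ratio sigma_g^2/sigma_e^2 via the
eigendecomposition of phi), and combines the five p-values with the Cauchy
combination test, which is valid under arbitrary dependence.  Traits that are
far from normal should be rank-based inverse-normal transformed first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

from .pedigree import RelatednessMatrix

__all__ = [
    "GAMMA_GRID",
    "GenotypeMatrix",
    "ScanResult",
    "qc_filter",
    "inverse_normal_transform",
    "XChromosomeLMM",
    "lmm_pvalue",
    "cauchy_combine",
    "scan",
]

GAMMA_GRID = (0.0, 0.5, 1.0, 1.5, 2.0)


@dataclass
class GenotypeMatrix:
    """Females x SNPs dosage codes (0/1/2 copies of D); NaN marks missing."""

    female_ids: list[str]
    snp_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.female_ids), len(self.snp_ids)):
            raise ValueError("codes shape does not match id lists")

    @property
    def snp_missing_rate(self) -> np.ndarray:
        return np.isnan(self.codes).mean(axis=0)

    @property
    def individual_missing_rate(self) -> np.ndarray:
        return np.isnan(self.codes).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP over non-missing females."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.codes, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(
            [str(i) for i in df.index], [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.codes, index=self.female_ids, columns=self.snp_ids)
        df.to_csv(path, sep="\t", na_rep="NA")


def qc_filter(
    gm: GenotypeMatrix,
    snp_missing_max: float = 0.10,
    maf_min: float = 0.05,
    indiv_missing_max: float = 0.10,
) -> GenotypeMatrix:
    """Quality control in the fixed order: SNP missingness, MAF, individual
    missingness.  The order matters: MAF is computed only on SNPs surviving
    the missingness filter, and individual call rates only on SNPs surviving
    both SNP-level filters.
    """
    keep_snp = gm.snp_missing_rate <= snp_missing_max
    gm = GenotypeMatrix(
        gm.female_ids,
        [s for s, k in zip(gm.snp_ids, keep_snp) if k],
        gm.codes[:, keep_snp],
    )
    keep_snp = gm.maf() >= maf_min
    gm = GenotypeMatrix(
        gm.female_ids,
        [s for s, k in zip(gm.snp_ids, keep_snp) if k],
        gm.codes[:, keep_snp],
    )
    if not gm.snp_ids:
        raise ValueError("no SNPs survive quality control")
    keep_ind = gm.individual_missing_rate <= indiv_missing_max
    return GenotypeMatrix(
        [f for f, k in zip(gm.female_ids, keep_ind) if k],
        gm.snp_ids,
        gm.codes[keep_ind],
    )


def inverse_normal_transform(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offsets (c = 3/8).

    Maps value i to ``Phi^{-1}((rank_i - 3/8) / (n + 1/4))``; ties receive
    average ranks.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(y) == 0.0:
        raise ValueError("constant trait vector cannot be rank-transformed")
    ranks = rankdata(y, method="average")
    return norm.ppf((ranks - 0.375) / (n + 0.25))


class XChromosomeLMM:
    """Per-trait scan engine; precomputes the eigendecomposition of phi."""

    def __init__(
        self,
        trait: np.ndarray,
        covariates: np.ndarray,
        phi: RelatednessMatrix | np.ndarray,
        log_ratio_bounds: tuple[float, float] = (-10.0, 10.0),
    ):
        self.y = np.asarray(trait, dtype=float)
        self.z = np.atleast_2d(np.asarray(covariates, dtype=float))
        phi = phi.values if isinstance(phi, RelatednessMatrix) else np.asarray(phi)
        self.phi = phi
        self.bounds = log_ratio_bounds
        lam, vec = np.linalg.eigh(phi)
        self.lam = np.clip(lam, 0.0, None)
        self.q = vec.T
        self.y_rot = self.q @ self.y
        self.z_rot = self.q @ self.z

    def _reml_fit(self, w: np.ndarray, y: np.ndarray, lam: np.ndarray):
        """Profile REML over the variance ratio delta = sigma_g^2/sigma_e^2."""
        n, p = w.shape

        def neg_reml(log_delta: float) -> float:
            v = np.exp(log_delta) * lam + 1.0
            wv = w / v[:, None]
            xtx = w.T @ wv
            xty = wv.T @ y
            try:
                bhat = np.linalg.solve(xtx, xty)
            except np.linalg.LinAlgError:
                return np.inf
            r = y - w @ bhat
            rss = float(r @ (r / v))
            sign, logdet = np.linalg.slogdet(xtx)
            if sign <= 0 or rss <= 0:
                return np.inf
            return 0.5 * ((n - p) * np.log(rss) + float(np.sum(np.log(v))) + logdet)

        res = minimize_scalar(neg_reml, bounds=self.bounds, method="bounded")
        log_delta = float(res.x)
        v = np.exp(log_delta) * lam + 1.0
        wv = w / v[:, None]
        xtx = w.T @ wv
        bhat = np.linalg.solve(xtx, wv.T @ y)
        r = y - w @ bhat
        sigma_e2 = float(r @ (r / v)) / (n - p)
        cov_b = sigma_e2 * np.linalg.inv(xtx)
        return bhat, cov_b, n - p, log_delta

    def pvalue(self, snp_codes: np.ndarray, gamma: float) -> tuple[float, float]:
        """Wald p-value and effect estimate for one SNP at a fixed gamma.

        SNP dosages are 0/1/2 with NaN for missing calls; missing females are
        dropped for this test only (complete-case).  A SNP monomorphic at
        this gamma returns p = 1 with effect 0.
        """
        snp = np.asarray(snp_codes, dtype=float)
        obs = ~np.isnan(snp)
        x = np.where(snp == 1.0, gamma, snp)  # codes {0, gamma, 2}
        if obs.all():
            x_rot = self.q @ x
            w = np.column_stack([x_rot, self.z_rot])
            if np.ptp(x[obs]) == 0.0 or np.var(x[obs]) == 0.0:
                return 1.0, 0.0
            bhat, cov_b, df, _ = self._reml_fit(w, self.y_rot, self.lam)
        else:
            if np.ptp(x[obs]) == 0.0:
                return 1.0, 0.0
            sub = self.phi[np.ix_(obs, obs)]
            lam, vec = np.linalg.eigh(sub)
            lam = np.clip(lam, 0.0, None)
            q = vec.T
            w = np.column_stack([q @ x[obs], q @ self.z[obs]])
            bhat, cov_b, df, _ = self._reml_fit(w, q @ self.y[obs], lam)
        se = np.sqrt(cov_b[0, 0])
        if se == 0.0 or not np.isfinite(se):
            return 1.0, float(bhat[0])
        t = bhat[0] / se
        return float(2.0 * t_dist.sf(abs(t), df)), float(bhat[0])


def lmm_pvalue(
    trait: np.ndarray,
    snp_codes: np.ndarray,
    gamma: float,
    covariates: np.ndarray,
    phi: RelatednessMatrix | np.ndarray,
) -> tuple[float, float]:
    """One-shot Wald test; see :meth:`XChromosomeLMM.pvalue`."""
    return XChromosomeLMM(trait, covariates, phi).pvalue(snp_codes, gamma)


def cauchy_combine(pvals) -> float:
    """Cauchy combination: T = mean(tan((0.5 - p) pi)), p = 0.5 - atan(T)/pi."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        warnings.warn("p-values clipped to the open unit interval")
        p = np.clip(p, 1e-300, 1.0 - 1e-16)
    t = float(np.mean(np.tan((0.5 - p) * np.pi)))
    return float(0.5 - np.arctan(t) / np.pi)


@dataclass
class ScanResult:
    """Per-SNP grid p-values, effects, and the combined Cauchy p-value."""

    table: pd.DataFrame
    threshold: float
    gammas: tuple[float, ...] = GAMMA_GRID
    failures: list[str] = field(default_factory=list)

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p_cauchy"] < self.threshold]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["significant"] = out["p_cauchy"] < self.threshold
        out.to_csv(path, sep="\t", index=False)


def scan(
    trait: np.ndarray,
    covariates: np.ndarray,
    phi: RelatednessMatrix | np.ndarray,
    gm: GenotypeMatrix,
    gammas: tuple[float, ...] = GAMMA_GRID,
    alpha: float = 0.05,
) -> ScanResult:
    """Scan every SNP: per-gamma LMM Wald tests plus Cauchy combination.

    The significance threshold is Bonferroni: alpha / number of SNPs tested.
    Per-SNP failures are recorded and skipped; the scan continues.
    """
    engine = XChromosomeLMM(trait, covariates, phi)
    rows = []
    failures = []
    for j, snp_id in enumerate(gm.snp_ids):
        snp = gm.codes[:, j]
        try:
            ps, effects = [], []
            for g in gammas:
                p, b = engine.pvalue(snp, g)
                ps.append(p)
                effects.append(b)
            row = {"snp_id": snp_id}
            for g, p, b in zip(gammas, ps, effects):
                row[f"p_gamma{g:g}"] = p
                row[f"beta_gamma{g:g}"] = b
            row["p_cauchy"] = cauchy_combine(np.clip(ps, 1e-300, 1 - 1e-16))
            rows.append(row)
        except Exception as exc:  # keep scanning; report afterwards
            failures.append(f"{snp_id}: {exc}")
    if not rows:
        raise ValueError("no SNP could be tested")
    return ScanResult(
        table=pd.DataFrame(rows),
        threshold=alpha / len(rows),
        gammas=tuple(gammas),
        failures=failures,
    )
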