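"""The per-female dataset container shared by the estimation methods.

Genotypes at the X-linked locus are the strings ``"dd"``, ``"Dd"``, ``"DD"``;
an unobserved genotype is the dedicated :data:`MISSING` sentinel, never a
numeric code.  Trait values are real for quantitative traits and {0, 1} for
qualitative (affected = 1).  The covariate matrix carries a leading column of
ones (intercept).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import RelatednessMatrix

__all__ = ["MISSING", "GENOTYPES", "XCIDataset"]

MISSING = "missing"
GENOTYPES = ("dd", "Dd", "DD")

PEDIGREE = "pedigree"
UNRELATED = "unrelated"


@dataclass
class XCIDataset:
    """Females from pedigrees and unrelated females, with their relatedness.

    Arrays share length ``nf`` and ordering with ``relatedness.ids``
    (pedigree females first, then unrelated females).
    """

    female_ids: list[str]
    genotypes: np.ndarray          # object array over {"dd","Dd","DD",MISSING}
    traits: np.ndarray             # float (quantitative) or {0,1} (qualitative)
    covariates: np.ndarray         # (nf, m), first column all ones
    relatedness: RelatednessMatrix
    trait_type: str = "quantitative"
    gamma_truth: float | None = None
    source: np.ndarray | None = None  # per-female "pedigree" / "unrelated"

    def __post_init__(self) -> None:
        nf = len(self.female_ids)
        self.genotypes = np.asarray(self.genotypes, dtype=object)
        self.traits = np.asarray(self.traits, dtype=float)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.source is None:
            src = [PEDIGREE] * self.relatedness.n_pedigree_females
            src += [UNRELATED] * self.relatedness.n_unrelated_females
            self.source = np.asarray(src, dtype=object)
        else:
            self.source = np.asarray(self.source, dtype=object)
        for name, arr in (
            ("genotypes", self.genotypes),
            ("traits", self.traits),
            ("source", self.source),
        ):
            if len(arr) != nf:
                raise ValueError(f"{name} has length {len(arr)}, expected {nf}")
        if self.covariates.shape[0] != nf:
            raise ValueError("covariates row count mismatch")
        if not np.allclose(self.covariates[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept (ones)")
        if self.relatedness.n != nf:
            raise ValueError("relatedness dimension mismatch")
        if self.trait_type == "qualitative":
            vals = np.unique(self.traits)
            if not np.all(np.isin(vals, [0.0, 1.0])):
                raise ValueError("qualitative traits must be 0/1")

    @property
    def nf(self) -> int:
        return len(self.female_ids)

    @property
    def n_pedigree_females(self) -> int:
        return self.relatedness.n_pedigree_females

    @property
    def n_unrelated_females(self) -> int:
        return self.relatedness.n_unrelated_females

    def subset(self, keep: np.ndarray) -> "XCIDataset":
        keep = np.asarray(keep, dtype=bool)
        return replace(
            self,
            female_ids=[i for i, k in zip(self.female_ids, keep) if k],
            genotypes=self.genotypes[keep],
            traits=self.traits[keep],
            covariates=self.covariates[keep],
            relatedness=self.relatedness.restrict(keep),
            source=self.source[keep],
        )

    def pedigree_only(self) -> "XCIDataset":
        return self.subset(self.source == PEDIGREE)

    def unrelated_only(self) -> "XCIDataset":
        return self.subset(self.source == UNRELATED)

    # -- plain-text round trip -------------------------------------------------

    def write(self, outdir) -> None:
        """Write genotype/phenotype/covariate TSVs plus a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        geno = ["NA" if g == MISSING else g for g in self.genotypes]
        pd.DataFrame({"id": self.female_ids, "genotype": geno}).to_csv(
            outdir / "genotypes.tsv", sep="\t", index=False
        )
        pd.DataFrame({"id": self.female_ids, "trait": self.traits}).to_csv(
            outdir / "phenotypes.tsv", sep="\t", index=False
        )
        cov = pd.DataFrame(
            self.covariates,
            columns=[f"z{j}" for j in range(self.covariates.shape[1])],
        )
        cov.insert(0, "id", self.female_ids)
        cov.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
        self.relatedness.to_tsv(outdir / "relatedness.tsv")
        meta = {
            "trait_type": self.trait_type,
            "gamma_truth": self.gamma_truth,
            "n_pedigree_females": self.n_pedigree_females,
            "n_unrelated_females": self.n_unrelated_females,
            "source": list(map(str, self.source)),
        }
        (outdir / "dataset.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read(cls, outdir) -> "XCIDataset":
        outdir = Path(outdir)
        g = pd.read_csv(outdir / "genotypes.tsv", sep="\t", dtype=str)
        ph = pd.read_csv(outdir / "phenotypes.tsv", sep="\t")
        cov = pd.read_csv(outdir / "covariates.tsv", sep="\t")
        rel = pd.read_csv(outdir / "relatedness.tsv", sep="\t", index_col=0)
        meta = json.loads((outdir / "dataset.json").read_text())
        genotypes = np.array(
            [MISSING if x == "NA" else x for x in g["genotype"]], dtype=object
        )
        relmat = RelatednessMatrix(
            [str(i) for i in rel.index],
            rel.to_numpy(dtype=float),
            meta["n_pedigree_females"],
            meta["n_unrelated_females"],
        )
        return cls(
            female_ids=[str(i) for i in g["id"]],
            genotypes=genotypes,
            traits=ph["trait"].to_numpy(dtype=float),
            covariates=cov.drop(columns="id").to_numpy(dtype=float),
            relatedness=relmat,
            trait_type=meta["trait_type"],
            gamma_truth=meta["gamma_truth"],
            source=np.asarray(meta["source"], dtype=object),
        )
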