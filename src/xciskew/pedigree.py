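"""Pedigree representation, kinship matrices, and the block relatedness matrix.

A :class:`Pedigree` is a validated family graph.  Kinship coefficients are
computed by the classical recursion of Lange: processing individuals in an
ancestral order, a non-founder's kinship with any earlier individual is the
average of the kinships of their two parents with that individual, and the
self-kinship is ``0.5 * (1 + k(father, mother))``.  Founders are assumed
mutually unrelated and non-inbred (self-kinship 0.5).

The genetic relatedness matrix used by the mixed models is the block matrix
``phi = blockdiag(2 * psi_f, I)`` where ``psi_f`` is the kinship matrix of the
pedigree females and the identity block covers the unrelated females.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MALE",
    "FEMALE",
    "PedigreeError",
    "Member",
    "Pedigree",
    "KinshipMatrix",
    "RelatednessMatrix",
    "build_pedigree",
    "kinship_matrix",
    "relatedness_block",
    "prune_missing",
    "read_fam",
    "write_fam",
]

MALE = "male"
FEMALE = "female"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class Member:
    id: str
    father: str | None
    mother: str | None
    sex: str

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class Pedigree:
    """A validated pedigree: each member has two in-pedigree parents or none."""

    members: list[Member]
    pedigree_id: str = "ped"
    _index: dict[str, Member] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {m.id: m for m in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, member_id: str) -> Member:
        return self._index[member_id]

    @property
    def founders(self) -> list[Member]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Member]:
        return [m for m in self.members if not m.is_founder]

    @property
    def females(self) -> list[Member]:
        return [m for m in self.members if m.sex == FEMALE]

    def topological_order(self) -> list[str]:
        """Member ids, founders first, parents always before children.

        Ties are broken by id so the resulting matrices are reproducible.
        """
        depth: dict[str, int] = {}

        def _depth(mid: str) -> int:
            if mid in depth:
                return depth[mid]
            m = self._index[mid]
            d = 0 if m.is_founder else 1 + max(_depth(m.father), _depth(m.mother))
            depth[mid] = d
            return d

        ids = [m.id for m in self.members]
        return sorted(ids, key=lambda i: (_depth(i), i))


def build_pedigree(
    records: Iterable[tuple[str, str | None, str | None, str]],
    pedigree_id: str = "ped",
) -> Pedigree:
    """Validate raw member tuples ``(id, father, mother, sex)`` into a Pedigree.

    ``None`` (or ``"0"``) for both parent fields marks a founder.  Raises
    :class:`PedigreeError` on duplicate ids, single-parent members, parent sex
    inconsistencies, unresolvable parent references, or ancestry cycles; the
    message names the offending id.
    """
    members: list[Member] = []
    for rec in records:
        mid, fa, mo, sex = rec
        fa = None if fa in (None, "0", 0, "") else str(fa)
        mo = None if mo in (None, "0", 0, "") else str(mo)
        if sex not in (MALE, FEMALE):
            raise PedigreeError(f"member {mid!r}: sex must be male/female, got {sex!r}")
        members.append(Member(str(mid), fa, mo, sex))
    if not members:
        raise PedigreeError("empty record set")

    index: dict[str, Member] = {}
    for m in members:
        if m.id in index:
            raise PedigreeError(f"duplicate id {m.id!r}")
        index[m.id] = m
    for m in members:
        if (m.father is None) != (m.mother is None):
            raise PedigreeError(f"member {m.id!r} has exactly one parent recorded")
        if m.father is None:
            continue
        for pid, want in ((m.father, MALE), (m.mother, FEMALE)):
            if pid not in index:
                raise PedigreeError(f"member {m.id!r}: parent {pid!r} not in pedigree")
            if index[pid].sex != want:
                raise PedigreeError(
                    f"member {m.id!r}: parent {pid!r} recorded as "
                    f"{'father' if want == MALE else 'mother'} but is {index[pid].sex}"
                )

    # cycle check by iterative DFS over the child -> parent edges
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def _visit(start: str) -> None:
        stack = [(start, iter(_parents(start)))]
        state[start] = 0
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if state.get(p) == 0:
                    raise PedigreeError(f"member {p!r} is its own ancestor")
                if p not in state:
                    state[p] = 0
                    stack.append((p, iter(_parents(p))))
                    advanced = True
                    break
            if not advanced:
                state[node] = 1
                stack.pop()

    def _parents(mid: str) -> tuple[str, ...]:
        m = index[mid]
        return () if m.father is None else (m.father, m.mother)

    for m in members:
        if m.id not in state:
            _visit(m.id)

    return Pedigree(members, pedigree_id=pedigree_id)


@dataclass
class KinshipMatrix:
    """Kinship coefficients; symmetric, diagonal >= 0.5, entries in [0, 1]."""

    ids: list[str]
    values: np.ndarray

    def restrict(self, ids: Sequence[str]) -> "KinshipMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Kinship matrix of every pedigree member by the Lange recursion.

    Autosomal kinship: the polygenic covariance of the trait models is defined
    as ``2 * sigma_g^2 * psi_f`` in terms of this matrix.
    """
    order = ped.topological_order()
    pos = {mid: k for k, mid in enumerate(order)}
    n = len(order)
    K = np.zeros((n, n))
    for mid in order:
        i = pos[mid]
        m = ped[mid]
        if m.is_founder:
            K[i, i] = 0.5  # founders: unrelated, non-inbred
            continue
        f, g = pos[m.father], pos[m.mother]
        # parents precede children in `order`, so rows f, g are complete
        for j in range(n):
            if j == i:
                continue
            K[i, j] = K[j, i] = 0.5 * (K[f, j] + K[g, j])
        K[i, i] = 0.5 * (1.0 + K[f, g])
    # return in original member order
    member_ids = [m.id for m in ped.members]
    idx = np.array([pos[i] for i in member_ids], dtype=int)
    return KinshipMatrix(member_ids, K[np.ix_(idx, idx)])


@dataclass
class RelatednessMatrix:
    """Block relatedness matrix ``[[2*psi_f, 0], [0, I]]`` over females.

    Pedigree females come first (``n_pedigree_females`` of them), then the
    unrelated females.
    """

    ids: list[str]
    values: np.ndarray
    n_pedigree_females: int
    n_unrelated_females: int

    @property
    def n(self) -> int:
        return self.n_pedigree_females + self.n_unrelated_females

    def restrict(self, keep: np.ndarray) -> "RelatednessMatrix":
        """Restrict to a boolean mask over females, preserving order."""
        keep = np.asarray(keep, dtype=bool)
        ids = [i for i, k in zip(self.ids, keep) if k]
        n_ped = int(keep[: self.n_pedigree_females].sum())
        n_unr = int(keep[self.n_pedigree_females:].sum())
        idx = np.flatnonzero(keep)
        return RelatednessMatrix(ids, self.values[np.ix_(idx, idx)], n_ped, n_unr)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )


def relatedness_block(
    psi_f: KinshipMatrix | None,
    n_unrelated: int,
    unrelated_ids: Sequence[str] | None = None,
) -> RelatednessMatrix:
    """Assemble ``phi = blockdiag(2 * psi_f, I_{n_unrelated})``."""
    if n_unrelated < 0:
        raise ValueError("n_unrelated must be >= 0")
    if psi_f is None or len(psi_f.ids) == 0:
        ped_ids: list[str] = []
        top = np.zeros((0, 0))
    else:
        ped_ids = list(psi_f.ids)
        top = 2.0 * psi_f.values
    if unrelated_ids is None:
        unrelated_ids = [f"U{k + 1}" for k in range(n_unrelated)]
    if len(unrelated_ids) != n_unrelated:
        raise ValueError("unrelated_ids length mismatch")
    n_ped = len(ped_ids)
    n = n_ped + n_unrelated
    phi = np.zeros((n, n))
    phi[:n_ped, :n_ped] = top
    phi[n_ped:, n_ped:] = np.eye(n_unrelated)
    return RelatednessMatrix(ped_ids + list(unrelated_ids), phi, n_ped, n_unrelated)


def prune_missing(dataset):
    """Drop females with missing genotypes; restrict phi to the survivors.

    Returns a new :class:`~xciskew.data.XCIDataset`; survivor ordering is
    preserved.  Raises if every female is missing.
    """
    from .data import MISSING

    keep = np.array([g != MISSING for g in dataset.genotypes], dtype=bool)
    if not keep.any():
        raise ValueError("all females have missing genotypes; nothing to analyse")
    if keep.all():
        return dataset
    return dataset.subset(keep)


def read_fam(path) -> list[Pedigree]:
    """Read pedigrees from a PLINK-style .fam table (no phenotype column).

    Tab-separated columns: family_id, individual_id, father_id, mother_id,
    sex (1=male, 2=female); 0 means no parent.
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["fid", "iid", "father", "mother", "sex"], dtype=str,
    )
    peds = []
    for fid, grp in df.groupby("fid", sort=False):
        recs = [
            (r.iid, r.father, r.mother, MALE if r.sex == "1" else FEMALE)
            for r in grp.itertuples()
        ]
        peds.append(build_pedigree(recs, pedigree_id=str(fid)))
    return peds


def write_fam(peds: Iterable[Pedigree], path) -> None:
    rows = []
    for ped in peds:
        for m in ped.members:
            rows.append(
                (ped.pedigree_id, m.id, m.father or "0", m.mother or "0",
                 "1" if m.sex == MALE else "2")
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
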