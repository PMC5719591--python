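"""Pedigree-derived relatedness matrices for nuclear-family study designs.

A family design is parameterised by ``f`` families, each with one father,
``m`` mothers mated to that father, and ``c`` children per mother.  The
pairwise relatedness coefficient G = phi/2 + delta (phi: probability that
exactly one allele is shared identical by descent, delta: probability that
both are) takes the classical values 1/2 for parent-child pairs and full
siblings and 1/4 for half siblings; mates and members of different families
are unrelated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FamilyDesign",
    "RelationshipCoefficients",
    "RelatednessMatrix",
    "PARENT_CHILD",
    "FULL_SIBLINGS",
    "HALF_SIBLINGS",
    "build_family_relatedness",
    "mean_relatedness",
    "read_relatedness_csv",
    "write_relatedness_csv",
]

#: sentinel used in relatedness CSV files for pairs whose relatedness could
#: not be estimated (disjoint informative SNP sets); mapped to NaN on read.
MISSING_SENTINEL = -1.0


@dataclass(frozen=True)
class FamilyDesign:
    """Blueprint of a synthetic family study: f families, m mothers per
    father, c children per mother."""

    f: int
    m: int
    c: int

    def __post_init__(self) -> None:
        for name in ("f", "m", "c"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")

    @property
    def n(self) -> int:
        """Total sample count, (c*m + m + 1) per family."""
        return (self.c * self.m + self.m + 1) * self.f

    @property
    def family_size(self) -> int:
        return self.c * self.m + self.m + 1

    def sample_ids(self) -> list[str]:
        """Deterministic sample ordering: father, mothers, then each
        mother's children; families concatenated."""
        ids = []
        for i in range(1, self.f + 1):
            ids.append(f"fam{i}_father")
            for j in range(1, self.m + 1):
                ids.append(f"fam{i}_mother{j}")
            for j in range(1, self.m + 1):
                for k in range(1, self.c + 1):
                    ids.append(f"fam{i}_m{j}_child{k}")
        return ids


@dataclass(frozen=True)
class RelationshipCoefficients:
    """IBD sharing probabilities of a pair: phi (one allele IBD) and delta
    (both alleles IBD); relatedness is g = phi/2 + delta."""

    phi: float
    delta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi <= 1.0 and 0.0 <= self.delta <= 1.0):
            raise ValueError("phi and delta must lie in [0, 1]")
        if self.phi + self.delta > 1.0 + 1e-12:
            raise ValueError("phi + delta must not exceed 1")

    @property
    def g(self) -> float:
        return self.phi / 2.0 + self.delta


PARENT_CHILD = RelationshipCoefficients(phi=1.0, delta=0.0)
FULL_SIBLINGS = RelationshipCoefficients(phi=0.5, delta=0.25)
HALF_SIBLINGS = RelationshipCoefficients(phi=0.5, delta=0.0)


@dataclass
class RelatednessMatrix:
    """Symmetric n x n matrix of pairwise relatedness values.

    ``source`` tags whether the matrix came from the pedigree ("pedigree")
    or from genotype data ("estimated").  Entries that could not be
    estimated are NaN (the CSV sentinel -1 maps to NaN on read).
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    source: str = "pedigree"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("relatedness matrix must be square")
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match matrix size")
        finite = np.isfinite(self.values)
        if not np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
            atol=1e-10,
        ):
            raise ValueError("relatedness matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def _offdiag(self) -> np.ndarray:
        off = self.values.copy()
        np.fill_diagonal(off, 0.0)
        if np.isnan(off).any():
            raise ValueError(
                "relatedness matrix contains missing entries; summaries "
                "require a complete matrix"
            )
        return off

    @property
    def g_bar(self) -> float:
        """Mean off-diagonal relatedness."""
        n = self.n
        if n < 2:
            raise ValueError("need at least 2 samples")
        return float(self._offdiag().sum() / (n * (n - 1)))

    @property
    def g2(self) -> float:
        """Sum of squared off-diagonal entries (over ordered pairs)."""
        off = self._offdiag()
        return float((off * off).sum())

    @property
    def gr(self) -> float:
        """Sum of squared off-diagonal row sums."""
        off = self._offdiag()
        rows = off.sum(axis=1)
        return float((rows * rows).sum())


def build_family_relatedness(
    design: FamilyDesign, max_n: int = 20_000
) -> RelatednessMatrix:
    """Exact relatedness matrix of an f;m;c family design.

    The matrix is block diagonal with one block per family.  Within a
    family: father-child and mother-(own) child pairs and full siblings get
    G = 1/2, half siblings (same father, different mothers) G = 1/4, mates
    and mother-(other mother's) child pairs G = 0.  Founders are assumed
    non-inbred and mutually unrelated, so the diagonal is 1 and all
    between-family entries are 0.
    """
    n = design.n
    if n > max_n:
        raise ValueError(
            f"design implies n={n} samples, exceeding the memory guard "
            f"max_n={max_n}"
        )
    m, c = design.m, design.c
    b = design.family_size
    block = np.zeros((b, b))
    np.fill_diagonal(block, 1.0)
    # index layout within a family: 0 father, 1..m mothers,
    # 1+m+(j-1)*c .. 1+m+j*c-1 children of mother j
    for j in range(m):
        kids_j = slice(1 + m + j * c, 1 + m + (j + 1) * c)
        block[0, kids_j] = PARENT_CHILD.g
        block[kids_j, 0] = PARENT_CHILD.g
        block[1 + j, kids_j] = PARENT_CHILD.g
        block[kids_j, 1 + j] = PARENT_CHILD.g
        sub = block[kids_j, kids_j]
        block[kids_j, kids_j] = np.where(np.eye(c, dtype=bool), sub, FULL_SIBLINGS.g)
        for j2 in range(j + 1, m):
            kids_j2 = slice(1 + m + j2 * c, 1 + m + (j2 + 1) * c)
            block[kids_j, kids_j2] = HALF_SIBLINGS.g
            block[kids_j2, kids_j] = HALF_SIBLINGS.g
    values = np.kron(np.eye(design.f), block)
    return RelatednessMatrix(values, design.sample_ids(), source="pedigree")


def mean_relatedness(G: RelatednessMatrix) -> float:
    """Mean off-diagonal relatedness of ``G``."""
    return G.g_bar


def write_relatedness_csv(G: RelatednessMatrix, path) -> None:
    """Write a sample-labelled square CSV; NaN entries become the -1
    sentinel."""
    values = np.where(np.isnan(G.values), MISSING_SENTINEL, G.values)
    df = pd.DataFrame(values, index=G.sample_ids, columns=G.sample_ids)
    df.to_csv(path)


def read_relatedness_csv(path, source: str = "estimated") -> RelatednessMatrix:
    """Read a square relatedness CSV (sample ids in the first row and
    column); the -1 sentinel is treated as missing."""
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    values = np.where(values == MISSING_SENTINEL, np.nan, values)
    if np.isnan(values).any():
        warnings.warn(
            "relatedness matrix contains missing (-1) entries", stacklevel=2
        )
    return RelatednessMatrix(values, [str(s) for s in df.index], source=source)
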