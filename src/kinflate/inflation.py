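"""Variance-inflation factors for SNP effect estimates under relatedness.

When a quantitative trait with heritability R2h is analysed by simple
linear regression in a sample with relatedness matrix G, the variance of
the slope estimate is inflated by a factor

    lambda = 1 + R2h * sum_{i != j} G_ij (sbar^2 - 2 sbar s_i + s_i s_j)
                     / sum_i (s_i - sbar)^2

per SNP s.  Its expectation over SNPs depends only on scalar summaries of
G (the sum of squared off-diagonal entries G2 and the sum of squared row
sums Gr):

    lambda' = 1 + R2h * (G2 - (2/n) Gr) / (n - 1),

an approximation valid when n is large and the mean relatedness is small
(below about 0.01).  For f;m;c family designs lambda' also has a closed
polynomial form in (f, m, c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .genotype_sim import GenotypeMatrix
from .pedigree_relatedness import FamilyDesign, RelatednessMatrix

__all__ = [
    "HeritabilitySpec",
    "InflationResult",
    "empirical_lambda",
    "empirical_lambda_per_snp",
    "mean_empirical_lambda",
    "expected_lambda",
    "lambda_family_closed_form",
    "transform_heritability",
    "GBAR_VALIDITY_LIMIT",
]

#: the lambda' approximation assumes mean relatedness below this value
GBAR_VALIDITY_LIMIT = 0.01

_SNP_CHUNK = 2_000


def _check_r2(r2: float, name: str = "r2_h") -> float:
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"{name} must lie in [0, 1); got {r2}")
    return float(r2)


@dataclass(frozen=True)
class HeritabilitySpec:
    """Heritability of the polygenic trait component, with an optional
    target heritability for inflation transforms."""

    r2_h: float
    r2_t: float | None = None

    def __post_init__(self) -> None:
        _check_r2(self.r2_h)
        if self.r2_t is not None:
            _check_r2(self.r2_t, "r2_t")


@dataclass
class InflationResult:
    """Per-SNP and expected inflation factors for one study."""

    lambda_per_snp: np.ndarray
    lambda_bar: float
    lambda_bar_sd: float
    lambda_prime: float
    lambda_closed: float | None = None


def _offdiag(G: RelatednessMatrix) -> np.ndarray:
    off = np.asarray(G.values, dtype=float).copy()
    np.fill_diagonal(off, 0.0)
    if np.isnan(off).any():
        raise ValueError("relatedness matrix has missing entries")
    return off


def empirical_lambda_per_snp(
    values: np.ndarray, G: RelatednessMatrix, r2_h: float
) -> np.ndarray:
    """Vectorised per-SNP inflation factors for an n x p genotype array.

    Uses the matrix identity
    sum_{i != j} G_ij (sbar^2 - 2 sbar s_i + s_i s_j)
        = sbar^2 * sum(G0) - 2 sbar * (r . s) + s' G0 s
    with G0 the off-diagonal part of G and r its row sums.
    """
    r2_h = _check_r2(r2_h)
    S = np.asarray(values, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    n = S.shape[0]
    if n != G.n:
        raise ValueError("genotype and relatedness dimensions do not match")
    off = _offdiag(G)
    rows = off.sum(axis=1)
    total = rows.sum()
    sbar = S.mean(axis=0)
    sxx = ((S - sbar) ** 2).sum(axis=0)
    if np.any(sxx == 0):
        raise ValueError("monomorphic SNP: zero genotype variance")
    num = np.empty(S.shape[1])
    for lo in range(0, S.shape[1], _SNP_CHUNK):
        hi = min(lo + _SNP_CHUNK, S.shape[1])
        chunk = S[:, lo:hi]
        quad = np.einsum("ik,ik->k", chunk, off @ chunk)
        num[lo:hi] = (
            sbar[lo:hi] ** 2 * total - 2.0 * sbar[lo:hi] * (rows @ chunk) + quad
        )
    return 1.0 + r2_h * num / sxx


def empirical_lambda(s: np.ndarray, G: RelatednessMatrix, r2_h: float) -> float:
    """Inflation factor of a single SNP genotype vector."""
    return float(empirical_lambda_per_snp(np.asarray(s), G, r2_h)[0])


def mean_empirical_lambda(
    geno: GenotypeMatrix,
    G: RelatednessMatrix,
    r2_h: float,
    maf_min: float = 0.0,
) -> tuple[float, float]:
    """Mean and sample standard deviation of per-SNP inflation factors,
    optionally restricted to SNPs with minor allele frequency > maf_min."""
    keep = geno.values.std(axis=0) > 0
    if maf_min > 0.0:
        keep &= geno.maf > maf_min
    if not keep.any():
        raise ValueError("no polymorphic SNPs pass the MAF filter")
    lam = empirical_lambda_per_snp(geno.values[:, keep], G, r2_h)
    sd = float(np.std(lam, ddof=1)) if lam.size > 1 else 0.0
    return float(lam.mean()), sd


def expected_lambda(G: RelatednessMatrix, r2_h: float) -> float:
    """Expected inflation lambda' from the matrix summaries G2 and Gr.

    Emits a warning (not an error) when the mean relatedness exceeds the
    validity limit of the approximation.
    """
    r2_h = _check_r2(r2_h)
    n = G.n
    if n < 2:
        raise ValueError("need at least 2 samples")
    if G.g_bar >= GBAR_VALIDITY_LIMIT:
        warnings.warn(
            f"mean relatedness {G.g_bar:.4f} >= {GBAR_VALIDITY_LIMIT}; the "
            "lambda' approximation may be inaccurate",
            stacklevel=2,
        )
    return 1.0 + r2_h * (G.g2 - 2.0 / n * G.gr) / (n - 1)


def _closed_form_fraction(f: int, m: int, c: int) -> Fraction:
    f, m, c = int(f), int(m), int(c)
    num = (
        ((c**3 + c**2) * f - 2 * c**3) * m**3
        + ((3 * c**3 + 16 * c**2 + 12 * c) * f - 4 * c**3 - 16 * c**2) * m**2
        + ((3 * c**2 + 12 * c) * f - 2 * c**3 - 16 * c**2 - 8 * c) * m
    )
    den = (
        (16 * c**2 + 32 * c + 16) * f * m**2
        + ((32 * c + 32) * f - 16 * c - 16) * m
        + 16 * f
        - 16
    )
    return Fraction(num, den)


def lambda_family_closed_form(design: FamilyDesign, r2_h: float) -> float:
    """Closed-form lambda' for an f;m;c family design.

    Evaluated in exact rational arithmetic; reduces to
    1 + R2h (f-1)/(3f-1) for trios (m=1, c=1) and to
    1 + R2h (243f-314)/(216f-24) for m=2, c=3.
    """
    r2_h = _check_r2(r2_h)
    return 1.0 + r2_h * float(_closed_form_fraction(design.f, design.m, design.c))


def transform_heritability(
    lambda_prime: float,
    r2_h: float,
    r2_t: float | None = None,
    lambda_t: float | None = None,
) -> float:
    """Map an inflation at heritability R2h to another heritability, for
    the same relatedness structure.

    With ``r2_t`` given, returns the inflation lambda'_t at that
    heritability; with ``lambda_t`` given, returns the heritability R2t at
    which the inflation would equal lambda'_t.  Exactly one target must be
    supplied.
    """
    if (r2_t is None) == (lambda_t is None):
        raise ValueError("supply exactly one of r2_t or lambda_t")
    if not 0.0 < r2_h < 1.0:
        raise ValueError("r2_h must lie in (0, 1) for the transform")
    if r2_t is not None:
        _check_r2(r2_t, "r2_t")
        return 1.0 + (lambda_prime - 1.0) * r2_t / r2_h
    if lambda_prime <= 1.0:
        raise ValueError(
            "lambda_prime must exceed 1 to solve for a target heritability"
        )
    return (lambda_t - 1.0) / (lambda_prime - 1.0) * r2_h


def inflation_result(
    geno: GenotypeMatrix,
    G: RelatednessMatrix,
    r2_h: float,
    design: FamilyDesign | None = None,
    maf_min: float = 0.0,
) -> InflationResult:
    """Bundle the empirical, expected and (if a design is known) closed-form
    inflation factors for one study."""
    keep = geno.values.std(axis=0) > 0
    if maf_min > 0.0:
        keep &= geno.maf > maf_min
    lam = empirical_lambda_per_snp(geno.values[:, keep], G, r2_h)
    return InflationResult(
        lambda_per_snp=lam,
        lambda_bar=float(lam.mean()),
        lambda_bar_sd=float(np.std(lam, ddof=1)) if lam.size > 1 else 0.0,
        lambda_prime=expected_lambda(G, r2_h),
        lambda_closed=(
            None if design is None else lambda_family_closed_form(design, r2_h)
        ),
    )
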