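"""Phenotype simulation under the polygenic mixed model and misspecified
OLS analysis.

Phenotypes follow y = b1 + b2*s + g + e with polygenic effects
g ~ N(0, sigma2_g * G) (G the relatedness matrix) and independent
residuals e ~ N(0, sigma2_e * I).  The analysis model deliberately ignores
relatedness: ordinary least squares of y on s, slope estimate beta2_hat,
its conventional empirical variance S2_beta (residual degrees of freedom
n - 2) and the statistic T = beta2_hat / S_beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pedigree_relatedness import RelatednessMatrix
from .inflation import empirical_lambda

__all__ = [
    "PhenotypeModel",
    "TestOutcome",
    "SnpReplicateSummary",
    "simulate_phenotypes",
    "calibrate_effect",
    "fit_simple_regression",
    "ols_batch",
    "theoretical_slope_variance",
    "summarize_replicates",
    "covariance_factor",
]


@dataclass(frozen=True)
class PhenotypeModel:
    """Parameters of the generating mixed model.

    The variance scale is conventionally fixed so that
    sigma2_g + sigma2_e = 1 (sigma2_g = R2h); all statistics of interest
    (lambda, T, mu) are invariant to this scale.
    """

    b1: float = 0.0
    b2: float = 0.0
    sigma2_g: float = 0.0
    sigma2_e: float = 1.0
    r2_s: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")
        if self.sigma2_g + self.sigma2_e <= 0:
            raise ValueError("total non-SNP variance must be positive")
        if not 0.0 <= self.r2_s < 1.0:
            raise ValueError("r2_s must lie in [0, 1)")

    @property
    def r2_h(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)

    @property
    def total_var(self) -> float:
        """Non-SNP phenotypic variance sigma2_g + sigma2_e."""
        return self.sigma2_g + self.sigma2_e

    @classmethod
    def from_heritability(
        cls, r2_h: float, b1: float = 0.0, b2: float = 0.0, r2_s: float = 0.0
    ) -> "PhenotypeModel":
        """Unit-variance parameterisation: sigma2_g = R2h, sigma2_e = 1 - R2h."""
        if not 0.0 <= r2_h < 1.0:
            raise ValueError("r2_h must lie in [0, 1)")
        return cls(b1=b1, b2=b2, sigma2_g=r2_h, sigma2_e=1.0 - r2_h, r2_s=r2_s)


@dataclass
class TestOutcome:
    """OLS result for one phenotype replicate: slope estimate, its
    empirical variance, and T = beta2_hat / S_beta (NaN when S2_beta = 0)."""

    beta2_hat: float
    s2_beta: float
    t_stat: float


@dataclass
class SnpReplicateSummary:
    """Over-replicate aggregates for one SNP."""

    t_bar: float
    t_var: float
    s2_beta_bar: float
    beta2_bar: float
    beta2_var: float
    nu: float
    n_reps: int


def covariance_factor(G: RelatednessMatrix, jitter: float = 0.0) -> np.ndarray:
    """Lower-triangular factor L with L L' = G.

    Pedigree matrices are positive definite by construction and factor by
    Cholesky directly; estimated matrices may have small negative
    eigenvalues from sampling noise, which are clipped at zero (with a
    warning reporting the clipped magnitude) before factorisation.
    """
    values = np.asarray(G.values, dtype=float)
    if jitter:
        values = values + jitter * np.eye(G.n)
    try:
        return np.linalg.cholesky(values)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(values)
        clipped = -w[w < 0].sum()
        warnings.warn(
            f"relatedness matrix is not positive definite; clipped negative "
            f"eigenvalue mass {clipped:.3g} before factorisation",
            stacklevel=2,
        )
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def simulate_phenotypes(
    G: RelatednessMatrix,
    s: np.ndarray,
    model: PhenotypeModel,
    n_reps: int,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    factor: np.ndarray | None = None,
) -> np.ndarray:
    """Draw ``n_reps`` independent phenotype replicates (rows) of length n.

    ``factor`` can pass a precomputed covariance factor of G to avoid
    refactorising when simulating many SNPs on the same cohort.
    """
    s = np.asarray(s, dtype=float)
    n = G.n
    if s.shape != (n,):
        raise ValueError("genotype vector length does not match G")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if factor is None:
        factor = covariance_factor(G)
    g = np.sqrt(model.sigma2_g) * (factor @ rng.standard_normal((n, n_reps)))
    e = np.sqrt(model.sigma2_e) * rng.standard_normal((n, n_reps))
    y = model.b1 + model.b2 * s[:, None] + g + e
    return y.T


def calibrate_effect(s: np.ndarray, r2_s: float, total_var: float = 1.0) -> float:
    """SNP effect b2 >= 0 such that the SNP explains the fraction ``r2_s``
    of the total phenotypic variance:

        b2^2 Var(s) = r2_s / (1 - r2_s) * total_var

    with Var(s) the sample variance (denominator n - 1) of the genotypes
    and ``total_var`` the non-SNP variance sigma2_g + sigma2_e.
    """
    if not 0.0 <= r2_s < 1.0:
        raise ValueError("r2_s must lie in [0, 1)")
    s = np.asarray(s, dtype=float)
    var_s = float(np.var(s, ddof=1))
    if var_s == 0:
        raise ValueError("monomorphic SNP: cannot calibrate an effect")
    if r2_s == 0.0:
        return 0.0
    return float(np.sqrt(r2_s / (1.0 - r2_s) * total_var / var_s))


def ols_batch(Y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised simple regression of each row of Y on s.

    Returns (beta2_hat, s2_beta, t) arrays over replicates; t is NaN where
    s2_beta = 0.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    s = np.asarray(s, dtype=float)
    n = s.shape[0]
    if Y.shape[1] != n:
        raise ValueError("phenotype and genotype lengths do not match")
    if n < 3:
        raise ValueError("need at least 3 observations")
    sc = s - s.mean()
    sxx = float(sc @ sc)
    if sxx == 0:
        raise ValueError("monomorphic SNP: zero genotype variance")
    yc = Y - Y.mean(axis=1, keepdims=True)
    beta = (yc @ sc) / sxx
    rss = (yc * yc).sum(axis=1) - beta**2 * sxx
    rss = np.clip(rss, 0.0, None)  # guard tiny negative round-off
    s2_beta = rss / (n - 2) / sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(s2_beta > 0, beta / np.sqrt(s2_beta), np.nan)
    return beta, s2_beta, t


def fit_simple_regression(y: np.ndarray, s: np.ndarray) -> TestOutcome:
    """OLS of a single phenotype vector on a genotype vector."""
    beta, s2_beta, t = ols_batch(np.asarray(y, dtype=float)[None, :], s)
    return TestOutcome(float(beta[0]), float(s2_beta[0]), float(t[0]))


def theoretical_slope_variance(
    s: np.ndarray, G: RelatednessMatrix, model: PhenotypeModel
) -> float:
    """Exact variance of the OLS slope under the mixed model.

    Equals lambda / (1 - R2h) * V_beta with V_beta = sigma2_e / Sxx, the
    slope variance of the standard independent-residual model.
    """
    r2_h = model.r2_h
    if r2_h >= 1.0:
        raise ValueError("r2_h must be below 1")
    s = np.asarray(s, dtype=float)
    sc = s - s.mean()
    sxx = float(sc @ sc)
    if sxx == 0:
        raise ValueError("monomorphic SNP: zero genotype variance")
    v_beta = model.sigma2_e / sxx
    lam = empirical_lambda(s, G, r2_h)
    return lam / (1.0 - r2_h) * v_beta


def summarize_replicates(
    beta2: np.ndarray,
    s2_beta: np.ndarray,
    t: np.ndarray,
    sxx: float,
    model: PhenotypeModel,
) -> SnpReplicateSummary:
    """Aggregate per-replicate OLS results for one SNP.

    ``t_var`` is the over-replicate sample variance of T (the empirical
    counterpart of the inflation lambda); ``nu`` is the deflation of the
    mean empirical slope variance relative to its independence-model
    expectation V_beta / (1 - R2h).
    """
    beta2 = np.asarray(beta2, dtype=float)
    s2_beta = np.asarray(s2_beta, dtype=float)
    t = np.asarray(t, dtype=float)
    if beta2.size < 2:
        raise ValueError("need at least 2 replicates")
    ref = model.sigma2_e / (1.0 - model.r2_h) / sxx
    return SnpReplicateSummary(
        t_bar=float(np.nanmean(t)),
        t_var=float(np.nanvar(t, ddof=1)),
        s2_beta_bar=float(s2_beta.mean()),
        beta2_bar=float(beta2.mean()),
        beta2_var=float(np.var(beta2, ddof=1)),
        nu=float(s2_beta.mean() / ref),
        n_reps=int(beta2.size),
    )
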