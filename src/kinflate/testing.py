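"""Analytic type I error and power of the T test under variance inflation,
and genomic-control correction.

Under the null the misspecified-regression statistic is approximately
T ~ N(0, lambda); under the alternative T ~ N(mu, lambda) with
mu = sqrt((n - 1) R2s).  With z_{alpha/2} the (negative) lower-tail
standard-normal quantile of a two-sided level-alpha test:

    err = 2 F_N(z_{alpha/2} | 0, lambda)
    pwr = F_N(z_{alpha/2} | mu, lambda) + 1 - F_N(-z_{alpha/2} | mu, lambda)

Genomic control rescales T by sqrt(lambda_hat) with
lambda_hat = median(T^2) / 0.456, restoring the type I error but shrinking
the non-centrality to mu / sqrt(lambda_hat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TestSetting",
    "type1_error",
    "power",
    "expected_t",
    "intersection_alpha",
    "genomic_control_lambda",
    "gc_corrected_power",
    "curve_table",
    "GC_MEDIAN_CONSTANT",
    "CHI2_1_MEDIAN",
]

#: genomic-control denominator as conventionally printed
GC_MEDIAN_CONSTANT = 0.456
#: exact median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(stats.chi2.median(1))


@dataclass(frozen=True)
class TestSetting:
    """A two-sided test scenario: significance level, inflation of T, and
    (under the alternative) its expectation mu."""

    alpha: float
    lambda_: float = 1.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.lambda_ < 1.0:
            warnings.warn(
                f"inflation lambda={self.lambda_} below 1 is unusual",
                stacklevel=2,
            )
        if self.mu < 0:
            raise ValueError("mu must be non-negative")


def _z_alpha_half(alpha: float) -> float:
    """Lower-tail standard-normal quantile at alpha/2 (negative)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(stats.norm.ppf(alpha / 2.0))


def type1_error(alpha: float, lambda_: float) -> float:
    """Type I error of the two-sided level-alpha test when T ~ N(0, lambda)."""
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    z = _z_alpha_half(alpha)
    return float(2.0 * stats.norm.cdf(z / np.sqrt(lambda_)))


def power(alpha: float, lambda_: float, mu: float) -> float:
    """Power of the two-sided level-alpha test when T ~ N(mu, lambda)."""
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    z = _z_alpha_half(alpha)
    sd = np.sqrt(lambda_)
    return float(
        stats.norm.cdf((z - mu) / sd) + stats.norm.sf((-z - mu) / sd)
    )


def expected_t(n: int, r2_s: float) -> float:
    """Approximate expectation mu = sqrt((n - 1) R2s) of T under the
    alternative."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= r2_s < 1.0:
        raise ValueError("r2_s must lie in [0, 1)")
    return float(np.sqrt((n - 1) * r2_s))


def intersection_alpha(mu: float, log10: bool = False) -> float:
    """Significance level at which the power equals 1/2 regardless of the
    inflation lambda: alpha = 2 Phi(-mu).

    At this alpha the lower rejection cutoff sits exactly at -mu... i.e.
    z_{alpha/2} = -mu, so the upper-tail rejection probability is 1/2 for
    every lambda (the lower tail contributes only Phi(-2 mu / sqrt(lambda)),
    negligible for the mu of genome-wide interest).  ``log10=True`` returns
    -log10(alpha).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    alpha = float(2.0 * stats.norm.cdf(-mu))
    return float(-np.log10(alpha)) if log10 else alpha


def genomic_control_lambda(
    t_stats: np.ndarray, constant: float = GC_MEDIAN_CONSTANT
) -> float:
    """Genomic-control inflation estimate median(T^2) / constant.

    The default constant is the conventionally printed 0.456; pass
    ``constant=CHI2_1_MEDIAN`` for the exact chi-square(1) median 0.4549.
    """
    t = np.asarray(t_stats, dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("need at least one test statistic")
    return float(np.median(t**2) / constant)


def gc_corrected_power(alpha: float, lambda_hat: float, mu: float) -> float:
    """Power of the genomic-control corrected test, T_gc ~ N(mu/sqrt(lambda_hat), 1).

    The corrected null statistic is standard normal, so the type I error
    equals alpha by construction.
    """
    if lambda_hat <= 0:
        raise ValueError("lambda_hat must be positive")
    return power(alpha, 1.0, mu / np.sqrt(lambda_hat))


def curve_table(
    mu: float,
    lambdas=(1.0, 1.05, 1.3, 2.0),
    lg_alpha_min: float = 0.5,
    lg_alpha_max: float = 10.0,
    n_points: int = 96,
):
    """Tabulate type I error, power and GC-corrected power over a grid of
    -log10(alpha), one column set per inflation scenario.

    Returns a pandas DataFrame with columns ``lg_alpha`` and, per lambda,
    ``err_<lam>``, ``pwr_<lam>`` and ``pwr_gc_<lam>``.
    """
    import pandas as pd

    lg = np.linspace(lg_alpha_min, lg_alpha_max, n_points)
    alphas = 10.0**-lg
    out = {"lg_alpha": lg}
    for lam in lambdas:
        key = f"{lam:g}"
        out[f"err_{key}"] = [type1_error(a, lam) for a in alphas]
        out[f"pwr_{key}"] = [power(a, lam, mu) for a in alphas]
        out[f"pwr_gc_{key}"] = [gc_corrected_power(a, lam, mu) for a in alphas]
    return pd.DataFrame(out)
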