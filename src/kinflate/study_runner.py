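"""End-to-end study simulation: genotypes, relatedness, inflation and
test-statistic summaries for synthetic family studies.

Three named presets mirror the synthetic family study designs used
throughout: SFS1 (43 trios, n=129), SFS2 (333 trios, n=999) and SFS3
(111 families with 2 mothers and 3 children per mother, n=999).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotype_sim import GenotypeMatrix, filter_snps, simulate_genotypes
from .inflation import (
    GBAR_VALIDITY_LIMIT,
    expected_lambda,
    lambda_family_closed_form,
    mean_empirical_lambda,
    transform_heritability,
)
from .pedigree_relatedness import FamilyDesign, RelatednessMatrix, build_family_relatedness
from .phenotype_association import (
    PhenotypeModel,
    calibrate_effect,
    covariance_factor,
    ols_batch,
    simulate_phenotypes,
    summarize_replicates,
)
from .relatedness_estimation import estimate_relatedness
from .testing import expected_t

__all__ = [
    "PRESETS",
    "StudyConfig",
    "Advisory",
    "run_inflation_study",
    "run_test_study",
    "rule_of_thumb",
    "RULE_OF_THUMB_THRESHOLD",
]

logger = logging.getLogger("kinflate")

PRESETS: dict[str, FamilyDesign] = {
    "SFS1": FamilyDesign(43, 1, 1),
    "SFS2": FamilyDesign(333, 1, 1),
    "SFS3": FamilyDesign(111, 2, 3),
}

#: inflation below this value is considered ignorable for simple regression
RULE_OF_THUMB_THRESHOLD = 1.05


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one simulated study.

    Paper-scale defaults (110,000 raw SNPs, 100,000 analysed, 1000
    phenotype replicates for each of 1000 SNPs) suit batch runs; use
    ``desk_scale`` for interactive work and tests.
    """

    design: FamilyDesign
    name: str = "custom"
    r2_h: float = 0.9
    r2_s: float = 0.02
    n_snps_raw: int = 110_000
    n_snps_analysis: int = 100_000
    n_reps: int = 1000
    n_snps_pheno: int = 1000
    maf_min_report: float = 0.10
    freq_shape_a: float = 0.5
    freq_shape_b: float = 0.5
    lambda_t_target: float = 1.05
    seed: int = 0
    relatedness_source: str = "pedigree"

    def __post_init__(self) -> None:
        for fld in ("n_snps_raw", "n_snps_analysis", "n_reps", "n_snps_pheno"):
            if getattr(self, fld) < 1:
                raise ValueError(f"{fld} must be positive")
        if self.n_snps_analysis > self.n_snps_raw:
            raise ValueError("n_snps_analysis cannot exceed n_snps_raw")
        if self.relatedness_source not in ("pedigree", "estimated"):
            raise ValueError("relatedness_source must be 'pedigree' or 'estimated'")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "StudyConfig":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(design=PRESETS[name], name=name, **overrides)

    def desk_scale(self) -> "StudyConfig":
        """A small configuration (2000 raw SNPs, 200 x 200 phenotype grid)
        for interactive runs; Monte-Carlo standard deviations in the
        reports make results at either scale interpretable."""
        return replace(
            self,
            n_snps_raw=2_200,
            n_snps_analysis=2_000,
            n_reps=200,
            n_snps_pheno=200,
        )


@dataclass(frozen=True)
class Advisory:
    """Rule-of-thumb verdict on whether simple linear regression is safe."""

    lambda_prime: float
    needs_correction: bool
    message: str


def _relatedness_for(cfg: StudyConfig, geno: GenotypeMatrix) -> RelatednessMatrix:
    if cfg.relatedness_source == "pedigree":
        return build_family_relatedness(cfg.design)
    return estimate_relatedness(geno)


def _simulate_analysis_set(cfg: StudyConfig, seeds) -> GenotypeMatrix:
    geno = simulate_genotypes(
        cfg.design,
        cfg.n_snps_raw,
        cfg.freq_shape_a,
        cfg.freq_shape_b,
        seed=np.random.default_rng(seeds[0]),
    )
    return filter_snps(
        geno,
        drop_monomorphic=True,
        subset_size=cfg.n_snps_analysis,
        seed=np.random.default_rng(seeds[1]),
    )


def run_inflation_study(cfg: StudyConfig) -> pd.DataFrame:
    """Simulate a study and report its inflation summary as one row.

    Columns: study, n, lambda_bar (SD), lambda_bar at MAF > maf_min_report
    (SD), expected lambda', closed-form lambda' for the design, mean
    relatedness, and the heritability at which inflation would equal
    ``lambda_t_target``.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    logger.info(
        "inflation study %s: design=(%d;%d;%d) n=%d r2_h=%g seed=%d",
        cfg.name, cfg.design.f, cfg.design.m, cfg.design.c,
        cfg.design.n, cfg.r2_h, cfg.seed,
    )
    geno = _simulate_analysis_set(cfg, seeds)
    G = _relatedness_for(cfg, geno)
    g_bar = G.g_bar
    if g_bar >= GBAR_VALIDITY_LIMIT:
        logger.warning(
            "mean relatedness %.4f >= %.2f; lambda' approximation degraded",
            g_bar, GBAR_VALIDITY_LIMIT,
        )
    lam_bar, lam_sd = mean_empirical_lambda(geno, G, cfg.r2_h)
    lam_bar_maf, lam_sd_maf = mean_empirical_lambda(
        geno, G, cfg.r2_h, maf_min=cfg.maf_min_report
    )
    lam_prime = expected_lambda(G, cfg.r2_h)
    lam_closed = lambda_family_closed_form(cfg.design, cfg.r2_h)
    if lam_prime > 1.0 and cfg.r2_h > 0.0:
        r2_t = transform_heritability(
            lam_prime, cfg.r2_h, lambda_t=cfg.lambda_t_target
        )
    else:
        r2_t = np.nan
    return pd.DataFrame(
        [
            {
                "study": cfg.name,
                "n": cfg.design.n,
                "n_snps": geno.n_snps,
                "lambda_bar": lam_bar,
                "lambda_bar_sd": lam_sd,
                "lambda_bar_maf": lam_bar_maf,
                "lambda_bar_maf_sd": lam_sd_maf,
                "lambda_prime": lam_prime,
                "lambda_closed": lam_closed,
                "g_bar": g_bar,
                "r2_t": r2_t,
            }
        ]
    )


def run_test_study(
    cfg: StudyConfig, hypothesis: str = "null"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate phenotype simulation and OLS testing for a study.

    Under ``hypothesis="null"`` the SNP effect is zero; under
    ``"alternative"`` it is calibrated per SNP so the SNP explains the
    fraction ``cfg.r2_s`` of phenotypic variance.  Returns (summary row,
    per-SNP table).  The summary reports the mean statistic T-bar, the
    mean over-replicate variance S2-bar, the variance-estimate deflation
    nu (each with an over-SNP SD) and the theoretical expectation mu.
    """
    if hypothesis not in ("null", "alternative"):
        raise ValueError("hypothesis must be 'null' or 'alternative'")
    r2_s = cfg.r2_s if hypothesis == "alternative" else 0.0
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    logger.info(
        "test study %s (%s): n=%d r2_h=%g r2_s=%g reps=%d snps=%d seed=%d",
        cfg.name, hypothesis, cfg.design.n, cfg.r2_h, r2_s,
        cfg.n_reps, cfg.n_snps_pheno, cfg.seed,
    )
    geno = _simulate_analysis_set(cfg, seeds)
    subset = filter_snps(
        geno,
        drop_monomorphic=False,
        subset_size=min(cfg.n_snps_pheno, geno.n_snps),
        seed=np.random.default_rng(seeds[2]),
    )
    G = _relatedness_for(cfg, geno)
    factor = covariance_factor(G)
    snp_seeds = seeds[3].spawn(subset.n_snps)
    rows = []
    for k in range(subset.n_snps):
        s = subset.values[:, k].astype(float)
        b2 = calibrate_effect(s, r2_s) if r2_s > 0 else 0.0
        model = PhenotypeModel.from_heritability(cfg.r2_h, b2=b2, r2_s=r2_s)
        Y = simulate_phenotypes(
            G, s, model, cfg.n_reps,
            seed=np.random.default_rng(snp_seeds[k]), factor=factor,
        )
        beta, s2_beta, t = ols_batch(Y, s)
        sc = s - s.mean()
        summ = summarize_replicates(beta, s2_beta, t, float(sc @ sc), model)
        rows.append(
            {
                "snp": subset.snp_ids[k],
                "b2": b2,
                "t_bar": summ.t_bar,
                "t_var": summ.t_var,
                "s2_beta_bar": summ.s2_beta_bar,
                "beta2_bar": summ.beta2_bar,
                "beta2_var": summ.beta2_var,
                "nu": summ.nu,
            }
        )
    per_snp = pd.DataFrame(rows)
    mu = expected_t(cfg.design.n, r2_s) if r2_s > 0 else 0.0
    summary = pd.DataFrame(
        [
            {
                "study": cfg.name,
                "hypothesis": hypothesis,
                "n": cfg.design.n,
                "n_snps": subset.n_snps,
                "n_reps": cfg.n_reps,
                "t_bar": per_snp["t_bar"].mean(),
                "t_bar_sd": per_snp["t_bar"].std(ddof=1),
                "s2_bar": per_snp["t_var"].mean(),
                "s2_bar_sd": per_snp["t_var"].std(ddof=1),
                "nu": per_snp["nu"].mean(),
                "nu_sd": per_snp["nu"].std(ddof=1),
                "mu": mu,
            }
        ]
    )
    return summary, per_snp


def rule_of_thumb(lambda_prime: float) -> Advisory:
    """Advise whether simple linear regression remains appropriate.

    Inflation below 1.05 is ignorable; at or above it, a relatedness-aware
    method (e.g. a mixed model) should be used.
    """
    if lambda_prime < 1.0:
        raise ValueError("lambda_prime must be >= 1")
    if lambda_prime < RULE_OF_THUMB_THRESHOLD:
        return Advisory(
            lambda_prime,
            False,
            f"lambda'={lambda_prime:.3f} < {RULE_OF_THUMB_THRESHOLD}: "
            "simple linear regression appropriate",
        )
    return Advisory(
        lambda_prime,
        True,
        f"lambda'={lambda_prime:.3f} >= {RULE_OF_THUMB_THRESHOLD}: "
        "use a relatedness-aware method",
    )
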