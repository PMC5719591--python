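"""Genotype simulation for family designs by gene dropping, plus SNP filters
and genotype I/O.

Per SNP a population reference-allele frequency is drawn from a Beta
distribution (default shapes 0.5, 0.5, i.e. a U-shaped site-frequency
spectrum); founder haplotypes are independent Bernoulli draws at that
frequency and each child receives one uniformly chosen allele from each
parent.  Genotypes are additively coded as the number of reference alleles
(0, 1 or 2) with no missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree_relatedness import FamilyDesign

__all__ = [
    "GenotypeMatrix",
    "simulate_genotypes",
    "filter_snps",
    "EmptyFilterError",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_vcf",
]

_SNP_CHUNK = 20_000


class EmptyFilterError(ValueError):
    """Raised when SNP filtering removes every SNP."""


@dataclass
class GenotypeMatrix:
    """n x p matrix of additive genotypes in {0, 1, 2}.

    ``pop_freq`` carries the latent per-SNP population frequency when the
    matrix was simulated (None for data read from files); the realized
    allele frequency estimate p-hat is always available as ``allele_freq``.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)
    pop_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype matrix must be 2-dimensional")
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("genotypes must be 0, 1 or 2 with no missing values")
        self.values = self.values.astype(np.int8, copy=False)
        n, p = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        if not self.snp_ids:
            self.snp_ids = [f"snp{k + 1}" for k in range(p)]
        if len(self.sample_ids) != n or len(self.snp_ids) != p:
            raise ValueError("label lengths do not match matrix shape")
        if self.pop_freq is not None:
            self.pop_freq = np.asarray(self.pop_freq, dtype=float)
            if self.pop_freq.shape != (p,):
                raise ValueError("pop_freq length does not match SNP count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Simple per-SNP estimate p-hat = sum_i s_ik / (2n)."""
        return self.values.mean(axis=0, dtype=float) / 2.0

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency min(p-hat, 1 - p-hat)."""
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values[:, index],
            self.sample_ids,
            [self.snp_ids[k] for k in np.atleast_1d(index)],
            None if self.pop_freq is None else self.pop_freq[index],
        )


def simulate_genotypes(
    design: FamilyDesign,
    n_snps: int,
    freq_shape_a: float = 0.5,
    freq_shape_b: float = 0.5,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    freqs: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Simulate an n x n_snps genotype matrix for a family design.

    Population frequencies are Beta(freq_shape_a, freq_shape_b) draws
    unless ``freqs`` supplies them explicitly.  Founders (father and
    mothers) get two independent allele copies per SNP; each child inherits
    one uniformly chosen allele from its father and one from its mother
    (gene dropping).  Identical seed and parameters give an identical
    matrix.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if freq_shape_a <= 0 or freq_shape_b <= 0:
        raise ValueError("Beta shape parameters must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if freqs is None:
        freqs = rng.beta(freq_shape_a, freq_shape_b, size=n_snps)
    else:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (n_snps,):
            raise ValueError("freqs must have length n_snps")
        if ((freqs < 0) | (freqs > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")

    f, m, c = design.f, design.m, design.c
    out = np.empty((design.n, n_snps), dtype=np.int8)
    for lo in range(0, n_snps, _SNP_CHUNK):
        hi = min(lo + _SNP_CHUNK, n_snps)
        out[:, lo:hi] = _simulate_chunk(f, m, c, freqs[lo:hi], rng)
    return GenotypeMatrix(out, design.sample_ids(), pop_freq=freqs)


def _simulate_chunk(f: int, m: int, c: int, freqs: np.ndarray, rng) -> np.ndarray:
    p = freqs.shape[0]
    # haplotypes: 1 = reference allele
    father_hap = (rng.random((f, 2, p), dtype=np.float32) < freqs).astype(np.int8)
    mother_hap = (rng.random((f, m, 2, p), dtype=np.float32) < freqs).astype(np.int8)
    pat_pick = rng.integers(0, 2, size=(f, m, c, p), dtype=np.int8)
    mat_pick = rng.integers(0, 2, size=(f, m, c, p), dtype=np.int8)
    pat_allele = np.where(
        pat_pick == 0, father_hap[:, None, None, 0, :], father_hap[:, None, None, 1, :]
    )
    mat_allele = np.where(
        mat_pick == 0, mother_hap[:, :, None, 0, :], mother_hap[:, :, None, 1, :]
    )
    children = (pat_allele + mat_allele).astype(np.int8)  # (f, m, c, p)

    fam_size = c * m + m + 1
    out = np.empty((f * fam_size, p), dtype=np.int8)
    for i in range(f):
        base = i * fam_size
        out[base] = father_hap[i].sum(axis=0)
        out[base + 1 : base + 1 + m] = mother_hap[i].sum(axis=1)
        out[base + 1 + m : base + fam_size] = children[i].reshape(m * c, p)
    return out


def filter_snps(
    G: GenotypeMatrix,
    drop_monomorphic: bool = True,
    maf_min: float = 0.0,
    subset_size: int | None = None,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Apply the study SNP filters.

    Removes zero-variance (monomorphic) SNPs, then SNPs with minor allele
    frequency <= ``maf_min`` when ``maf_min`` > 0, then takes a seeded
    random subset of ``subset_size`` SNPs when more than that survive.
    """
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    keep = np.ones(G.n_snps, dtype=bool)
    if drop_monomorphic:
        keep &= G.values.std(axis=0) > 0
    if maf_min > 0.0:
        keep &= G.maf > maf_min
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise EmptyFilterError("no SNPs survive the requested filters")
    if subset_size is not None:
        if subset_size < 1:
            raise ValueError("subset_size must be >= 1")
        if idx.size > subset_size:
            rng = (
                seed
                if isinstance(seed, np.random.Generator)
                else np.random.default_rng(seed)
            )
            idx = np.sort(rng.choice(idx, size=subset_size, replace=False))
        elif idx.size < subset_size:
            raise EmptyFilterError(
                f"only {idx.size} SNPs survive filtering but a subset of "
                f"{subset_size} was requested"
            )
    return G.take_snps(idx)


def write_genotype_csv(G: GenotypeMatrix, path) -> None:
    """Samples x SNPs CSV: header row of SNP ids, first column sample ids."""
    pd.DataFrame(G.values, index=G.sample_ids, columns=G.snp_ids).to_csv(path)


def read_genotype_csv(path, transposed: bool = False) -> GenotypeMatrix:
    """Read a genotype CSV (samples x SNPs by default; ``transposed=True``
    for SNPs x samples)."""
    df = pd.read_csv(path, index_col=0)
    if transposed:
        df = df.T
    return GenotypeMatrix(
        df.to_numpy(), [str(s) for s in df.index], [str(s) for s in df.columns]
    )


def read_vcf(path) -> GenotypeMatrix:
    """Convert bi-allelic diploid GT records of a VCF to additive coding
    (number of REF alleles).  Multi-allelic or missing-genotype records are
    rejected."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS} is not supported"
            )
        gts = np.asarray(var.genotypes, dtype=object)
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=float)
        if (alleles < 0).any() or np.isnan(alleles).any():
            raise ValueError(
                f"missing genotype at {var.CHROM}:{var.POS}; genotypes must "
                "be complete"
            )
        rows.append((2 - alleles.sum(axis=1)).astype(np.int8))
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if not rows:
        raise ValueError("VCF contains no variant records")
    return GenotypeMatrix(np.column_stack(rows), samples, ids)
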