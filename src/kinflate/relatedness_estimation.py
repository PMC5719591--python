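"""Genotype-based estimation of pairwise relatedness.

The estimator is an allele-frequency-corrected method of moments for
G = phi/2 + delta: with genotypes s_ik in {0, 1, 2} and in-sample allele
frequency estimates p_k = sum_i s_ik / (2n),

    G_ij = sum_k (s_ik - 2 p_k)(s_jk - 2 p_k) / sum_k 2 p_k (1 - p_k),

i.e. a ratio-of-sums genomic-relationship estimator whose per-SNP terms
are pooled before normalisation, which keeps low-frequency SNPs from
dominating the noise.  For a non-inbred pair the expectation of the
numerator term is 2 G_ij p_k (1 - p_k), so the ratio estimates G directly
(0.5 for parent-child and full-sib pairs, 0.25 for half sibs, 0 for
unrelated pairs).  The diagonal is pinned to 1.  Estimates are a plug-in
surface: any function mapping a GenotypeMatrix to a RelatednessMatrix can
stand in for it, and pedigree-derived matrices remain the exact reference.
"""

from __future__ import annotations

import numpy as np

from .genotype_sim import GenotypeMatrix
from .pedigree_relatedness import RelatednessMatrix

__all__ = ["estimate_relatedness"]

_SNP_CHUNK = 10_000


def estimate_relatedness(
    G: GenotypeMatrix, clip: bool = False
) -> RelatednessMatrix:
    """Estimate the pairwise relatedness matrix from genotypes.

    SNPs monomorphic in-sample are excluded (they carry no relatedness
    information and would divide by zero).  Off-diagonal estimates may
    fall slightly outside [0, 1] from sampling noise and are returned
    unclipped unless ``clip=True``.  If no polymorphic SNP remains the
    pairwise values are not estimable and a ValueError is raised; the CSV
    writer represents not-estimable entries with the -1 sentinel.
    """
    n = G.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    p_hat = G.allele_freq
    poly = (p_hat > 0.0) & (p_hat < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic SNP available for estimation")
    idx = np.flatnonzero(poly)
    num = np.zeros((n, n))
    den = 0.0
    for lo in range(0, idx.size, _SNP_CHUNK):
        cols = idx[lo : lo + _SNP_CHUNK]
        X = G.values[:, cols].astype(float)
        X -= 2.0 * p_hat[cols]
        num += X @ X.T
        den += float((2.0 * p_hat[cols] * (1.0 - p_hat[cols])).sum())
    est = num / den
    np.fill_diagonal(est, 1.0)
    if clip:
        off = np.clip(est, 0.0, 1.0)
        np.fill_diagonal(off, 1.0)
        est = off
    return RelatednessMatrix(est, list(G.sample_ids), source="estimated")
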