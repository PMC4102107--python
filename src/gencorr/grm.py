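"""Genetic relatedness matrix construction and eigendecomposition.

The GRM averages standardized-genotype cross-products over variants:
A_jk = (1/M) * sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1 - p_i)),
with allele frequencies estimated in-sample and missing dosages mean-imputed
per variant. One eigendecomposition of A then makes every variance-component
likelihood evaluation O(N), which is what the MCMC needs.
"""

from __future__ import annotations

import numpy as np

from .core_io import GenotypeMatrix, GrmMatrix
from .errors import DataError

_VAR_FLOOR = 1e-6


def compute_grm(geno: GenotypeMatrix) -> GrmMatrix:
    """Standardized-dosage GRM; variants with 2p(1-p) below the floor are dropped."""
    p = geno.allele_freq()
    var = 2.0 * p * (1.0 - p)
    keep = np.isfinite(var) & (var >= _VAR_FLOOR)
    if not keep.any():
        raise DataError("no polymorphic variants available for the GRM")
    x = geno.dosages[:, keep].copy()
    pk = p[keep]
    for j in np.flatnonzero(np.isnan(x).any(axis=0)):
        x[np.isnan(x[:, j]), j] = 2.0 * pk[j]
    z = (x - 2.0 * pk) / np.sqrt(2.0 * pk * (1.0 - pk))
    m_used = int(keep.sum())
    a = (z @ z.T) / m_used
    a = 0.5 * (a + a.T)
    return GrmMatrix(samples=list(geno.samples), values=a, m_used=m_used)


def grm_eigen(grm: GrmMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and orthonormal basis of the GRM.

    Small negative eigenvalues from round-off are clamped to zero; negatives
    beyond the tolerance indicate a corrupted matrix and raise.
    """
    a = grm.values
    if not np.allclose(a, a.T, atol=1e-8):
        raise DataError("GRM is asymmetric beyond tolerance")
    vals, vecs = np.linalg.eigh(0.5 * (a + a.T))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-8 * max(1.0, float(vals[0]) if vals.size else 1.0)
    if np.any(vals < -tol):
        raise DataError(
            f"GRM has eigenvalue {vals.min():.3e} below the clamping tolerance"
        )
    vals = np.clip(vals, 0.0, None)
    return vals, vecs
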