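"""Synthetic cohorts drawn exactly from the models the inference modules assume.

Two generators: MZ/DZ twin pairs under the bivariate ACE covariance structure,
and unrelated individuals with unlinked Hardy-Weinberg SNPs carrying additive
polygenic effects split into trait-specific and pleiotropic sets. Because
genotypes are unlinked, the SNP-heritability estimand equals the simulated
total genetic variance fraction, giving clean recovery targets.

Causal effects act on standardized dosages (equal per-variant variance
contribution), so with shared effects common to both traits the realized
genetic correlation follows c / sqrt((c+s1)(c+s2)) up to effect-sampling
noise. Genetic values and residuals are rescaled so the realized in-sample
variance fractions hit the requested heritabilities exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, PhenotypeTable, TwinTable
from .errors import ParameterError
from .twin_ace import AceParams, expected_pair_cov


@dataclass
class PopArchitecture:
    """Genetic architecture for the unrelated-cohort generator.

    ``n_shared`` pleiotropic causal variants affect both traits with a common
    effect; ``n_spec1``/``n_spec2`` affect one trait only. ``h2_1``/``h2_2``
    are the realized in-sample variance fractions, ``rho_env`` the residual
    cross-trait correlation.
    """

    n: int
    m_total: int
    n_shared: int
    n_spec1: int
    n_spec2: int
    h2_1: float
    h2_2: float
    rho_env: float
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self):
        if self.n < 2 or self.m_total < 1:
            raise ParameterError("need n >= 2 samples and m_total >= 1 variants")
        for name in ("n_shared", "n_spec1", "n_spec2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_shared + self.n_spec1 + self.n_spec2 > self.m_total:
            raise ParameterError(
                "causal counts exceed m_total: "
                f"{self.n_shared}+{self.n_spec1}+{self.n_spec2} > {self.m_total}"
            )
        for name in ("h2_1", "h2_2"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if not -1.0 <= self.rho_env <= 1.0:
            raise ParameterError("rho_env must lie in [-1, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must lie within (0, 0.5]")


def gen_twin_pairs(params: AceParams, n_mz: int, n_dz: int, seed: int) -> TwinTable:
    """Draw zero-mean twin-pair 4-vectors from the ACE covariance per zygosity.

    Age is uniform on [11, 13] with no trait effect; sex is a balanced binary
    covariate with no effect, equal within MZ pairs and independent within DZ.
    """
    rng = np.random.default_rng(seed)
    records = []
    for zyg, n_fam in (("MZ", n_mz), ("DZ", n_dz)):
        if n_fam == 0:
            continue
        cov = expected_pair_cov(params, zyg)
        try:
            chol = np.linalg.cholesky(cov + 1e-12 * np.eye(4))
        except np.linalg.LinAlgError as exc:
            raise ParameterError(
                f"{zyg} pair covariance is not positive definite"
            ) from exc
        y = rng.standard_normal((n_fam, 4)) @ chol.T
        age = rng.uniform(11.0, 13.0, size=n_fam)
        sex1 = rng.integers(0, 2, size=n_fam)
        sex2 = sex1 if zyg == "MZ" else rng.integers(0, 2, size=n_fam)
        for i in range(n_fam):
            records.append(
                {
                    "family_id": f"{zyg}{i:06d}",
                    "zygosity": zyg,
                    "twin1_trait1": y[i, 0],
                    "twin1_trait2": y[i, 1],
                    "twin2_trait1": y[i, 2],
                    "twin2_trait2": y[i, 3],
                    "age": age[i],
                    "sex1": int(sex1[i]),
                    "sex2": int(sex2[i]),
                }
            )
    return TwinTable(pd.DataFrame.from_records(records))


def _scale_to_variance(x: np.ndarray, target_var: float) -> np.ndarray:
    x = x - x.mean()
    v = x.var()
    if target_var == 0.0 or v == 0.0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var / v)


def gen_population(arch: PopArchitecture, seed: int):
    """Simulate an unrelated genotyped cohort under the population model.

    Returns ``(GenotypeMatrix, PhenotypeTable, truth)`` where ``truth`` records
    the causal variant indices, their effects and the realized genetic
    correlation and heritabilities. Dosages are Binomial(2, p) with p uniform
    over ``maf_range``; residuals are orthogonalized against the genetic values
    in-sample so the variance split is exact.
    """
    rng = np.random.default_rng(seed)
    n, m = arch.n, arch.m_total
    p = rng.uniform(arch.maf_range[0], arch.maf_range[1], size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(float)

    perm = rng.permutation(m)
    c, s1, s2 = arch.n_shared, arch.n_spec1, arch.n_spec2
    shared_idx = np.sort(perm[:c])
    spec1_idx = np.sort(perm[c : c + s1])
    spec2_idx = np.sort(perm[c + s1 : c + s1 + s2])

    def standardized(cols):
        x = dosages[:, cols]
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        return (x - mu) / sd

    b_shared = rng.standard_normal(c)
    b1 = rng.standard_normal(s1)
    b2 = rng.standard_normal(s2)
    g1_raw = np.zeros(n)
    g2_raw = np.zeros(n)
    if c:
        zs = standardized(shared_idx)
        g1_raw += zs @ b_shared
        g2_raw += zs @ b_shared
    if s1:
        g1_raw += standardized(spec1_idx) @ b1
    if s2:
        g2_raw += standardized(spec2_idx) @ b2

    g1 = _scale_to_variance(g1_raw, arch.h2_1)
    g2 = _scale_to_variance(g2_raw, arch.h2_2)

    cov_e = np.array([[1.0, arch.rho_env], [arch.rho_env, 1.0]])
    e = rng.multivariate_normal(np.zeros(2), cov_e, size=n, method="cholesky")
    # remove in-sample leakage of genetic signal into the residuals
    gmat = np.column_stack([v for v in (g1, g2) if v.std() > 0])
    if gmat.shape[1]:
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), gmat]))
        e = e - q @ (q.T @ e)
    e1 = _scale_to_variance(e[:, 0], 1.0 - arch.h2_1)
    e2 = _scale_to_variance(e[:, 1], 1.0 - arch.h2_2)

    y1 = g1 + e1
    y2 = g2 + e2

    samples = [f"S{i:06d}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "id": [f"snp{j:06d}" for j in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    geno = GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)

    sex = np.zeros(n, dtype=int)
    sex[rng.permutation(n)[: n // 2]] = 1
    pheno = PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "trait1": y1,
                "trait2": y2,
                "age": rng.uniform(11.0, 13.0, size=n),
                "sex": sex,
            }
        )
    )

    both = (g1.std() > 0) and (g2.std() > 0)
    truth = {
        "shared_idx": shared_idx,
        "spec1_idx": spec1_idx,
        "spec2_idx": spec2_idx,
        "b_shared": b_shared,
        "b_spec1": b1,
        "b_spec2": b2,
        "g1": g1,
        "g2": g2,
        "realized_h2_1": float(g1.var() / y1.var()) if y1.var() > 0 else 0.0,
        "realized_h2_2": float(g2.var() / y2.var()) if y2.var() > 0 else 0.0,
        "realized_genetic_corr": float(np.corrcoef(g1, g2)[0, 1]) if both else np.nan,
    }
    return geno, pheno, truth
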