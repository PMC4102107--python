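"""Phenotype construction and sample/variant curation.

Covers the full upstream pipeline for both analysis paths: rank-based inverse
normal transform of raw scales, equally weighted composites, covariate
residualization (age + sex for the twin path; age + sex + leading genetic PCs
for the population path), minor-allele-frequency filtering, genetic principal
components, and greedy selection of a mutually unrelated sample set from GRM
off-diagonals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenotypeMatrix, GrmMatrix, PhenotypeTable
from .errors import ConfigurationError, DataError, ParameterError


def quantile_normalize(values) -> np.ndarray:
    """Rank-based inverse normal transform: Phi^{-1}((rank - 0.5)/n).

    Ranks are averaged over ties and computed over non-missing entries only;
    missing entries are preserved. Output rank order equals input rank order.
    """
    x = np.asarray(values, dtype=float)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n == 0:
        raise DataError("quantile_normalize: all values are missing")
    if n < 2:
        raise DataError("quantile_normalize: need at least 2 non-missing values")
    ranks = stats.rankdata(x[mask], method="average")
    out = np.full_like(x, np.nan)
    out[mask] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def composite_score(scales) -> np.ndarray:
    """Equally weighted composite of aligned (already-normalized) scales.

    Per-sample mean over the available scales, re-standardized to mean 0 and
    unit variance over non-missing entries; samples missing every scale stay
    missing.
    """
    scales = [np.asarray(s, dtype=float) for s in scales]
    if len(scales) == 0:
        raise ConfigurationError("composite_score requires at least one scale")
    lengths = {s.shape[0] for s in scales}
    if len(lengths) != 1:
        raise DataError(f"scales have inconsistent lengths: {sorted(lengths)}")
    mat = np.column_stack(scales)
    with np.errstate(invalid="ignore"):
        comp = np.nanmean(mat, axis=1)
    mask = ~np.isnan(comp)
    if mask.sum() < 2:
        raise DataError("composite has fewer than 2 non-missing samples")
    mu = comp[mask].mean()
    sd = comp[mask].std()
    if sd == 0:
        raise DataError("composite is constant; cannot standardize")
    out = np.full_like(comp, np.nan)
    out[mask] = (comp[mask] - mu) / sd
    return out


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    u, s, vt = np.linalg.svd(design - 0, full_matrices=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-10:
        null = vt[-1]
        guilty = [names[i] for i in np.flatnonzero(np.abs(null) > 0.1)]
        raise DataError(f"collinear covariate columns: {guilty}")


def residualize(pheno: PhenotypeTable, covariates) -> PhenotypeTable:
    """Replace each trait by standardized OLS residuals on the chosen covariates.

    The regression (intercept + covariates) is fitted on each trait's
    non-missing rows; rows missing any covariate stay missing for that trait.
    Residuals are re-standardized to mean 0, unit variance.
    """
    covariates = list(covariates)
    missing_cols = [c for c in covariates if c not in pheno.data.columns]
    if missing_cols:
        raise ConfigurationError(f"covariate columns not present: {missing_cols}")
    df = pheno.data.copy()
    cov_mat = df[covariates].to_numpy(dtype=float) if covariates else np.empty((len(df), 0))
    for t in (1, 2):
        y = df[f"trait{t}"].to_numpy(dtype=float)
        rows = ~np.isnan(y) & ~np.isnan(cov_mat).any(axis=1)
        if rows.sum() < len(covariates) + 2:
            raise DataError(f"trait{t}: too few complete rows to residualize")
        design = np.column_stack([np.ones(rows.sum()), cov_mat[rows]])
        _check_full_rank(design, ["intercept"] + covariates)
        beta, *_ = np.linalg.lstsq(design, y[rows], rcond=None)
        resid = y[rows] - design @ beta
        sd = resid.std()
        if sd == 0:
            raise DataError(f"trait{t}: residuals are constant")
        out = np.full_like(y, np.nan)
        out[rows] = resid / sd
        df[f"trait{t}"] = out
    return PhenotypeTable(df)


def maf_filter(geno: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop variants whose in-sample minor-allele frequency is below ``threshold``.

    Boundary variants (MAF exactly at the threshold) are kept; variant order
    is preserved.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ParameterError(f"MAF threshold must lie in [0, 0.5], got {threshold}")
    p = geno.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    return geno.subset_variants(maf >= threshold)


def genetic_pcs(geno: GenotypeMatrix, k: int) -> np.ndarray:
    """Leading k sample-space principal components of standardized dosages.

    Missing calls are mean-imputed per variant before centering/scaling.
    Scores are returned N x k with non-increasing component variance; each
    column is flipped so its largest-magnitude variant loading is positive.
    """
    if k < 1 or k > min(geno.n, geno.m):
        raise ParameterError(f"k={k} outside [1, min(N, M)]")
    x = geno.dosages.copy()
    p = geno.allele_freq()
    for j in np.flatnonzero(np.isnan(x).any(axis=0)):
        x[np.isnan(x[:, j]), j] = 2 * p[j]
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    z = (x[:, keep] - mu[keep]) / sd[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if k > np.sum(s > s[0] * 1e-9):
        raise ParameterError(f"k={k} exceeds the numerical rank of the genotype matrix")
    scores = u[:, :k] * s[:k]
    for j in range(k):
        if vt[j, np.argmax(np.abs(vt[j]))] < 0:
            scores[:, j] *= -1.0
    return scores


def attach_pcs(pheno: PhenotypeTable, scores: np.ndarray) -> PhenotypeTable:
    """Return a copy of ``pheno`` with columns pc1..pck taken from ``scores``."""
    if scores.shape[0] != pheno.n:
        raise DataError("PC score rows do not match phenotype table")
    df = pheno.data.copy()
    for j in range(scores.shape[1]):
        df[f"pc{j + 1}"] = scores[:, j]
    return PhenotypeTable(df)


def select_unrelated(
    grm: GrmMatrix,
    missingness,
    threshold: float = 0.05,
) -> list[str]:
    """Greedy unrelated-set selection from GRM off-diagonals.

    While any off-diagonal relatedness >= ``threshold`` remains among kept
    samples, take the most related pair and drop its member with the higher
    missing-genotype fraction (ties broken by dropping the lexicographically
    later id). The result is independent of input row order; returned ids are
    sorted.
    """
    if threshold <= 0:
        raise ParameterError("relatedness threshold must be > 0")
    miss = pd.Series(missingness)
    absent = [s for s in grm.samples if s not in miss.index]
    if absent:
        raise DataError(f"missingness not provided for samples: {absent[:5]}")
    a = grm.values.copy()
    np.fill_diagonal(a, -np.inf)
    alive = np.ones(grm.n, dtype=bool)
    ids = np.asarray(grm.samples)
    while True:
        sub = np.where(np.outer(alive, alive), a, -np.inf)
        top = np.max(sub)
        if top < threshold:
            break
        # among exactly tied top pairs, take the id-lexicographically first
        cand = np.argwhere(sub == top)
        cand = cand[cand[:, 0] < cand[:, 1]]
        i, j = min(cand, key=lambda ij: tuple(sorted((ids[ij[0]], ids[ij[1]]))))
        mi, mj = miss[ids[i]], miss[ids[j]]
        if mi > mj:
            drop = i
        elif mj > mi:
            drop = j
        else:
            drop = i if ids[i] > ids[j] else j
        alive[drop] = False
    return sorted(ids[alive].tolist())
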