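"""Data containers and text-format I/O for phenotypes, twins, genotypes and relatedness.

Containers are thin dataclasses around pandas/numpy objects; every reader/writer
pair round-trips at its declared precision. Variant coordinates are 1-based (VCF
convention) and dosages count the ALT allele; all downstream statistics are
invariant to allele-label flips, so the choice carries no strand meaning.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

PHENO_COLUMNS = ["sample_id", "trait1", "trait2", "age", "sex"]
TWIN_COLUMNS = [
    "family_id", "zygosity",
    "twin1_trait1", "twin1_trait2", "twin2_trait1", "twin2_trait2",
    "age", "sex1", "sex2",
]
TRAIT_CELLS = ["twin1_trait1", "twin1_trait2", "twin2_trait1", "twin2_trait2"]


def _open_maybe_gz(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class PhenotypeTable:
    """Per-sample table of two trait composites plus covariates.

    ``data`` holds columns ``sample_id, trait1, trait2, age, sex`` and any
    number of principal-component columns ``pc1..pck``. Traits may be missing
    (NaN); every row must carry at least one observed trait.
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in PHENO_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"phenotype table lacks columns: {missing}")
        ids = self.data["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise DataError(f"duplicate sample_id: {dup!r}")
        both_missing = self.data[["trait1", "trait2"]].isna().all(axis=1)
        if both_missing.any():
            raise DataError(
                f"{int(both_missing.sum())} rows have no observed trait value"
            )
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def n(self) -> int:
        return len(self.data)

    def pc_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("pc") and c[2:].isdigit()]

    def trait(self, which: int) -> np.ndarray:
        return self.data[f"trait{which}"].to_numpy(dtype=float)


@dataclass
class TwinTable:
    """Per-family twin records: zygosity and both twins' two trait values."""

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in TWIN_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"twin table lacks columns: {missing}")
        fids = self.data["family_id"]
        if fids.duplicated().any():
            dup = fids[fids.duplicated()].iloc[0]
            raise DataError(f"duplicate family_id: {dup!r}")
        bad_zyg = ~self.data["zygosity"].isin(["MZ", "DZ"])
        if bad_zyg.any():
            raise DataError(
                f"unknown zygosity values: {sorted(self.data.loc[bad_zyg, 'zygosity'].unique())}"
            )
        mz = self.data["zygosity"] == "MZ"
        if (self.data.loc[mz, "sex1"] != self.data.loc[mz, "sex2"]).any():
            raise DataError("MZ pairs must have sex1 == sex2")
        all_missing = self.data[TRAIT_CELLS].isna().all(axis=1)
        if all_missing.any():
            raise DataError(
                f"{int(all_missing.sum())} families have no observed trait value"
            )
        self.data = self.data.reset_index(drop=True)

    @property
    def n_pairs(self) -> int:
        return len(self.data)

    def counts_by_zygosity(self) -> dict[str, int]:
        vc = self.data["zygosity"].value_counts()
        return {"MZ": int(vc.get("MZ", 0)), "DZ": int(vc.get("DZ", 0))}

    def trait_matrix(self) -> np.ndarray:
        """Families x 4 array ordered (twin1.trait1, twin1.trait2, twin2.trait1, twin2.trait2)."""
        return self.data[TRAIT_CELLS].to_numpy(dtype=float)


@dataclass
class GenotypeMatrix:
    """N x M additive ALT-dosage matrix with variant metadata.

    ``dosages`` are floats in [0, 2] (NaN = missing call); ``variants`` holds
    chrom, pos (1-based), id, ref, alt per column of the matrix.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise DataError(
                f"dosage rows ({n}) != number of samples ({len(self.samples)})"
            )
        if m != len(self.variants):
            raise DataError(
                f"dosage columns ({m}) != number of variants ({len(self.variants)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise DataError("duplicate sample ids in genotype matrix")
        with np.errstate(invalid="ignore"):
            out_of_range = (self.dosages < 0) | (self.dosages > 2)
        if np.any(out_of_range):
            raise DataError("dosage values outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def m(self) -> int:
        return len(self.variants)

    def allele_freq(self) -> np.ndarray:
        """In-sample ALT-allele frequency per variant, over non-missing calls."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return p

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.loc[np.asarray(mask)].reset_index(drop=True),
            dosages=self.dosages[:, np.asarray(mask)],
        )

    def missingness(self) -> pd.Series:
        """Per-sample fraction of missing calls, indexed by sample id."""
        frac = np.isnan(self.dosages).mean(axis=1)
        return pd.Series(frac, index=self.samples)


@dataclass
class GrmMatrix:
    """Symmetric N x N genetic relatedness estimates with sample ids."""

    samples: list[str]
    values: np.ndarray
    m_used: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.samples) == 0:
            raise DataError("GRM has an empty sample list")
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise DataError(
                f"GRM shape {self.values.shape} inconsistent with {n} samples"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise DataError("GRM is not symmetric within tolerance")
        if np.any(np.diag(self.values) <= 0):
            raise DataError("GRM diagonal entries must be positive")

    @property
    def n(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# phenotype / twin tables
# ---------------------------------------------------------------------------

def read_phenotypes(path, column_map: dict[str, str] | None = None) -> PhenotypeTable:
    """Read a tab-separated phenotype table.

    ``column_map`` maps the canonical names (sample_id, trait1, trait2, age,
    sex, optionally pc1..pck) to the file's column headers. Unparseable trait
    cells become missing; row count is preserved.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    column_map = column_map or {}
    rename = {column_map.get(c, c): c for c in PHENO_COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise ConfigurationError(f"input file lacks mandatory columns: {missing}")
    df = raw.rename(columns=rename)
    keep = PHENO_COLUMNS + [c for c in df.columns if c.startswith("pc") and c[2:].isdigit()]
    df = df[keep].copy()
    for c in keep:
        if c == "sample_id":
            continue
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def read_twins(path, column_map: dict[str, str] | None = None) -> TwinTable:
    """Read a tab-separated twin-pair table (one row per family)."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    column_map = column_map or {}
    rename = {column_map.get(c, c): c for c in TWIN_COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise ConfigurationError(f"input file lacks mandatory columns: {missing}")
    df = raw.rename(columns=rename)[TWIN_COLUMNS].copy()
    for c in TRAIT_CELLS + ["age", "sex1", "sex2"]:
        df[c] = pd.to_numeric(df[c], errors="coerce").astype(float)
    return TwinTable(df)


def write_twins(table: TwinTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Load biallelic records from a VCF into an ALT-dosage matrix.

    Dosage comes from the DS FORMAT field when present, else from hard GT
    calls. Multi-allelic records are skipped with a logged count; in-sample
    allele frequency ignores missing calls.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, meta = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d = np.where((d < 0) | (d > 2), np.nan, d)
        else:
            gt = np.asarray(var.gt_types, dtype=float)
            d = np.where(gt == 3, np.nan, gt)
        rows.append(d)
        meta.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    if not rows:
        raise DataError("VCF contains no biallelic records")
    dosages = np.vstack(rows).T  # variants were rows; samples are rows now
    return GenotypeMatrix(samples=samples, variants=pd.DataFrame(meta), dosages=dosages)


def read_dosage_matrix(path) -> GenotypeMatrix:
    """Read the plain whitespace-delimited dosage format.

    Header: ``id chrom pos ref alt <sample ids...>``; one row per variant,
    missing dosages written as NA.
    """
    with _open_maybe_gz(path) as fh:
        header = fh.readline().split()
        if header[:5] != ["id", "chrom", "pos", "ref", "alt"]:
            raise ConfigurationError(
                "dosage matrix header must start with 'id chrom pos ref alt'"
            )
        samples = header[5:]
        meta, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5 + len(samples):
                raise DataError(
                    f"line {lineno}: expected {5 + len(samples)} fields, got {len(parts)}"
                )
            meta.append(
                {"id": parts[0], "chrom": parts[1], "pos": int(parts[2]),
                 "ref": parts[3], "alt": parts[4]}
            )
            rows.append([np.nan if v == "NA" else float(v) for v in parts[5:]])
    if not rows:
        raise DataError("dosage matrix contains no variants")
    dosages = np.asarray(rows, dtype=float).T
    cols = ["chrom", "pos", "id", "ref", "alt"]
    return GenotypeMatrix(samples=samples, variants=pd.DataFrame(meta)[cols], dosages=dosages)


def write_dosage_matrix(geno: GenotypeMatrix, path) -> None:
    with _open_maybe_gz(path, "wt") as fh:
        fh.write(" ".join(["id", "chrom", "pos", "ref", "alt"] + list(geno.samples)) + "\n")
        for j in range(geno.m):
            v = geno.variants.iloc[j]
            vals = [
                "NA" if np.isnan(x) else format(x, ".17g") for x in geno.dosages[:, j]
            ]
            fh.write(
                f"{v['id']} {v['chrom']} {v['pos']} {v['ref']} {v['alt']} "
                + " ".join(vals) + "\n"
            )


# ---------------------------------------------------------------------------
# GRM (GCTA text dialect)
# ---------------------------------------------------------------------------

def write_grm(grm: GrmMatrix, prefix) -> None:
    """Write ``<prefix>.grm.txt`` (lower-triangle ``i j m value``) and ``<prefix>.grm.id``."""
    prefix = str(prefix)
    with open(prefix + ".grm.id", "wt") as fh:
        for s in grm.samples:
            fh.write(f"{s}\t{s}\n")
    with open(prefix + ".grm.txt", "wt") as fh:
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.m_used}\t{grm.values[i, j]:.10g}\n")


def read_grm(prefix) -> GrmMatrix:
    prefix = str(prefix)
    with open(prefix + ".grm.id") as fh:
        samples = [line.split()[1] for line in fh if line.strip()]
    if not samples:
        raise DataError("GRM id file is empty")
    n = len(samples)
    values = np.zeros((n, n))
    m_used = 0
    with open(prefix + ".grm.txt") as fh:
        for line in fh:
            if not line.strip():
                continue
            i_s, j_s, m_s, v_s = line.split()
            i, j = int(i_s) - 1, int(j_s) - 1
            if i >= n or j >= n:
                raise DataError(
                    f"GRM triangle index ({i + 1},{j + 1}) exceeds {n} ids"
                )
            m_used = int(m_s)
            values[i, j] = values[j, i] = float(v_s)
    return GrmMatrix(samples=samples, values=values, m_used=m_used)
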