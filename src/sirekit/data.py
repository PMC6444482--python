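"""Genotype container and on-disk formats.

Genotypes are stored as allele-B dosages (0, 1, 2) in an int8 matrix with
``MISSING = -1`` as sentinel, together with per-SNP metadata (id, chromosome,
position, alleles) and the sample ids.  Readers/writers cover a plain TSV
dosage matrix and the PLINK-1 binary trio (.bed/.bim/.fam).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1

SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b"]


@dataclass
class GenotypeMatrix:
    """n x p matrix of allele-B dosages with SNP metadata.

    Parameters
    ----------
    dosages : ndarray of int8, shape (n, p)
        Values in {0, 1, 2} or ``MISSING``.
    snp_meta : DataFrame
        Columns ``snp_id, chrom, pos, allele_a, allele_b``; one row per SNP.
    sample_ids : ndarray of str, shape (n,)
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        n, p = self.dosages.shape
        if n < 1:
            raise ValueError("need at least one sample")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        if len(self.snp_meta) != p:
            raise ValueError("snp_meta rows must match number of SNP columns")
        if self.snp_meta["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        if (self.snp_meta["pos"].to_numpy() < 0).any():
            raise ValueError("negative SNP positions")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"id{i:06d}" for i in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if len(self.sample_ids) != n:
                raise ValueError("sample_ids must match number of rows")
            if len(set(self.sample_ids)) != n:
                raise ValueError("duplicate sample ids")

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["snp_id"].to_numpy()

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return 1.0 - self.missing_mask().mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP allele-B frequency from non-missing calls."""
        d = self.dosages.astype(float)
        d[self.missing_mask()] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing."""
        d = self.dosages.astype(float)
        d[self.missing_mask()] = np.nan
        return d

    # -- subsetting -------------------------------------------------------
    def subset_snps(self, which) -> "GenotypeMatrix":
        """Subset columns by boolean mask, integer indices, or SNP ids."""
        which = np.asarray(which)
        if which.dtype == bool:
            idx = np.flatnonzero(which)
        elif np.issubdtype(which.dtype, np.integer):
            idx = which
        else:
            lookup = pd.Index(self.snp_ids)
            idx = lookup.get_indexer(which)
            if (idx < 0).any():
                missing = which[idx < 0]
                raise KeyError(f"unknown SNP ids: {list(missing[:5])}")
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.snp_meta.iloc[idx].reset_index(drop=True),
            self.sample_ids,
        )

    def snp_index(self, snp_ids) -> np.ndarray:
        idx = pd.Index(self.snp_ids).get_indexer(np.asarray(snp_ids))
        if (idx < 0).any():
            raise KeyError("unknown SNP id in request")
        return idx

    # -- TSV dosage matrix ------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write a TSV with SNP metadata columns then one column per sample."""
        df = self.snp_meta.copy()
        dos = self.dosages.T  # SNP-major for the file
        for j, sid in enumerate(self.sample_ids):
            df[str(sid)] = dos[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta = df[SNP_META_COLUMNS].copy()
        samples = [c for c in df.columns if c not in SNP_META_COLUMNS]
        dos = df[samples].to_numpy(dtype=np.int8).T
        return cls(dos, meta, np.array(samples, dtype=object))

    # -- PLINK-1 binary trio ----------------------------------------------
    # .bed stores 2-bit genotypes, SNP-major: 00 = 2 copies of allele A1
    # (allele_a here), 10 = het, 11 = 0 copies, 01 = missing.
    _BED_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
    _BED_DECODE = {0b00: 2, 0b01: MISSING, 0b10: 1, 0b11: 0}

    def to_plink(self, prefix) -> None:
        prefix = Path(prefix)
        bim = pd.DataFrame(
            {
                "chrom": self.snp_meta["chrom"],
                "snp_id": self.snp_meta["snp_id"],
                "cm": 0,
                "pos": self.snp_meta["pos"],
                "a1": self.snp_meta["allele_a"],
                "a2": self.snp_meta["allele_b"],
            }
        )
        bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
        fam = pd.DataFrame(
            {
                "fid": self.sample_ids,
                "iid": self.sample_ids,
                "father": 0,
                "mother": 0,
                "sex": 0,
                "pheno": -9,
            }
        )
        fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

        n = self.n_samples
        n_bytes = (n + 3) // 4
        code = np.zeros_like(self.dosages, dtype=np.uint8)
        for dosage, bits in self._BED_CODE.items():
            code[self.dosages == dosage] = bits
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(bytes([0x6C, 0x1B, 0x01]))
            for j in range(self.n_snps):
                col = code[:, j]
                packed = np.zeros(n_bytes, dtype=np.uint8)
                for k in range(4):
                    part = col[k::4]
                    packed[: len(part)] |= part << (2 * k)
                fh.write(packed.tobytes())

    @classmethod
    def from_plink(cls, prefix) -> "GenotypeMatrix":
        prefix = Path(prefix)
        bim = pd.read_csv(
            prefix.with_suffix(".bim"),
            sep=r"\s+",
            header=None,
            names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
            dtype={"chrom": str},
        )
        fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
        sample_ids = fam[1].astype(str).to_numpy(dtype=object)
        n, p = len(fam), len(bim)
        n_bytes = (n + 3) // 4
        raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
        if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
            raise ValueError("not a SNP-major PLINK-1 .bed file")
        body = raw[3:].reshape(p, n_bytes)
        dos = np.empty((n, p), dtype=np.int8)
        decode = np.array(
            [cls._BED_DECODE[b] for b in range(4)], dtype=np.int8
        )
        for j in range(p):
            bits = body[j]
            col = np.empty(n_bytes * 4, dtype=np.uint8)
            for k in range(4):
                col[k::4] = (bits >> (2 * k)) & 0b11
            dos[:, j] = decode[col[:n]]
        meta = pd.DataFrame(
            {
                "snp_id": bim["snp_id"],
                "chrom": bim["chrom"],
                "pos": bim["pos"],
                "allele_a": bim["a1"],
                "allele_b": bim["a2"],
            }
        )
        return cls(dos, meta, sample_ids)


# -- phenotypes ----------------------------------------------------------
PHENO_COLUMNS = ["animal_id", "scr", "evaluation", "breedings"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV (animal_id, scr, evaluation, breedings)."""
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "evaluation": str})
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file lacks columns: {sorted(missing)}")
    if (df["breedings"] < 1).any():
        raise ValueError("breedings must be >= 1")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df[PHENO_COLUMNS].to_csv(path, sep="\t", index=False)


def design_matrix(evaluation: pd.Series | np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design: intercept + evaluation-class dummies (first
    class absorbed into the intercept).

    Returns the dense design matrix and its column names.
    """
    ev = pd.Series(np.asarray(evaluation, dtype=object), name="evaluation")
    dummies = pd.get_dummies(ev, prefix="eval", drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(ev)), dummies.to_numpy()])
    return X, ["intercept"] + list(dummies.columns)


def align_phenotypes(
    genotypes: GenotypeMatrix, pheno: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Align a one-record-per-animal phenotype table to genotype sample order.

    Returns ``(y, X, column_names)`` with ``X`` the intercept +
    evaluation-class design.  Every genotyped sample must have exactly one
    phenotype record.
    """
    if pheno["animal_id"].duplicated().any():
        raise ValueError("phenotypes contain duplicate animals; dedupe first")
    indexed = pheno.set_index("animal_id")
    try:
        sub = indexed.loc[list(genotypes.sample_ids)]
    except KeyError as exc:
        raise KeyError("genotyped sample lacks a phenotype record") from exc
    y = sub["scr"].to_numpy(dtype=float)
    X, names = design_matrix(sub["evaluation"])
    return y, X, names
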