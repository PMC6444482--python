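"""Genomic relationship kernels.

The linear kernel is K = S S' / p with S the matrix of centered,
standardized genotypes — VanRaden's additive genomic relationship matrix.
Per-class kernels over a functional partition satisfy the exact algebraic
identity sum_j p_j K_j / p = K (columns partition S), which is asserted in
the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotate import SnpClassPartition
from .data import GenotypeMatrix

log = logging.getLogger(__name__)

#: eigenvalues below this are treated as zero when a kernel is factorized
EIG_TOL = 1e-10


def standardize_genotypes(
    genotypes: GenotypeMatrix,
    snp_subset=None,
    scale: str = "empirical",
) -> tuple[np.ndarray, np.ndarray]:
    """Impute, center and scale dosages; returns (S, used_snp_ids).

    Missing dosages are imputed to the column mean.  Columns are centered
    at 2*phat and divided by their standard deviation: the observed
    population SD (``scale="empirical"``, default — makes mean(diag K)
    exactly 1) or the Hardy-Weinberg value sqrt(2*phat*(1-phat)) with phat
    the observed allele frequency (``scale="expected"``).  Zero-variance
    columns are dropped with a log entry.
    """
    g = genotypes if snp_subset is None else genotypes.subset_snps(snp_subset)
    dos = g.dosage_float()
    mean = np.nanmean(dos, axis=0)
    inds = np.where(np.isnan(dos))
    dos[inds] = np.take(mean, inds[1])

    if scale == "empirical":
        sd = dos.std(axis=0)  # population (1/n) convention
    elif scale == "expected":
        phat = mean / 2.0
        sd = np.sqrt(2.0 * phat * (1.0 - phat))
    else:
        raise ValueError(f"unknown scale {scale!r}")

    usable = sd > 0
    if not usable.all():
        log.info("dropping %d zero-variance SNP columns", int((~usable).sum()))
    if not usable.any():
        raise ValueError("no polymorphic SNPs left after dropping zero-variance columns")
    S = (dos[:, usable] - mean[usable]) / sd[usable]
    return S, g.snp_ids[usable]


@dataclass
class KernelMatrix:
    """Symmetric PSD relationship matrix for one SNP set."""

    values: np.ndarray
    sample_ids: np.ndarray
    n_snps_used: int
    label: str = "kernel"
    _eigen: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("kernel must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kernel must be symmetric")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids must match kernel dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (vectors, values), ascending values."""
        if self._eigen is None:
            w, U = np.linalg.eigh(self.values)
            if w.min() < -1e-8:
                raise ValueError(
                    f"kernel is not numerically PSD (min eigenvalue {w.min():.3g})"
                )
            self._eigen = (U, np.maximum(w, 0.0))
        return self._eigen

    def save(self, prefix) -> None:
        """Binary array container plus an id sidecar TSV."""
        np.save(f"{prefix}.npy", self.values)
        with open(f"{prefix}_ids.tsv", "w") as fh:
            fh.write("sample_id\n")
            for sid in self.sample_ids:
                fh.write(f"{sid}\n")


def build_kernel(
    S: np.ndarray, sample_ids=None, label: str = "kernel"
) -> KernelMatrix:
    """K = S S' / p for a standardized genotype matrix S."""
    S = np.asarray(S, dtype=float)
    n, p = S.shape
    if p < 1:
        raise ValueError("need at least one SNP column")
    if sample_ids is None:
        sample_ids = np.arange(n)
    K = (S @ S.T) / p
    return KernelMatrix(K, np.asarray(sample_ids), p, label)


def whole_genome_kernel(
    genotypes: GenotypeMatrix, scale: str = "empirical", label: str = "all"
) -> KernelMatrix:
    S, used = standardize_genotypes(genotypes, scale=scale)
    return build_kernel(S, genotypes.sample_ids, label)


def build_class_kernels(
    genotypes: GenotypeMatrix,
    partition: SnpClassPartition,
    scale: str = "empirical",
    min_snps: int = 2,
) -> dict[str, KernelMatrix]:
    """One kernel per functional class, each scaled by its own SNP count.

    Classes with fewer than ``min_snps`` usable (polymorphic) SNPs are
    skipped with a warning.
    """
    kernels: dict[str, KernelMatrix] = {}
    for cls in partition.class_of.unique():
        ids = partition.ids_in(cls)
        if len(ids) < min_snps:
            log.warning("class %s has %d SNPs; skipped", cls, len(ids))
            continue
        try:
            S, used = standardize_genotypes(genotypes, snp_subset=ids, scale=scale)
        except ValueError:
            log.warning("class %s has no polymorphic SNPs; skipped", cls)
            continue
        if S.shape[1] < min_snps:
            log.warning("class %s has %d usable SNPs; skipped", cls, S.shape[1])
            continue
        kernels[cls] = build_kernel(S, genotypes.sample_ids, label=cls)
    return kernels
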