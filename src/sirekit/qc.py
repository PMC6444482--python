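"""Quality control: SNP filtering and phenotype-record de-duplication.

The filter follows the usual panel rules literally: markers on excluded
(sex) chromosomes, with minor allele frequency *below* the threshold, or
with call rate *below* the threshold are removed — markers exactly at a
threshold are retained.  MAF and call rate are computed on non-missing
calls only.  De-duplication keeps, per animal, the record with the most
breedings (the most reliable evaluation), breaking ties by the latest
evaluation id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class SnpFilterResult:
    genotypes: GenotypeMatrix
    removed: dict  # criterion -> count (first failing criterion wins)

    @property
    def report(self) -> pd.DataFrame:
        rows = [{"criterion": k, "n_removed": v} for k, v in self.removed.items()]
        rows.append(
            {"criterion": "retained", "n_removed": self.genotypes.n_snps}
        )
        return pd.DataFrame(rows)


def filter_snps(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    excluded_chroms: set | frozenset = frozenset({"X", "Y", "XY", "MT"}),
) -> SnpFilterResult:
    """Remove SNPs on excluded chromosomes, or with MAF/call rate strictly
    below the thresholds.  Column order is preserved.
    """
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= call_rate_min <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    excluded = {str(c) for c in excluded_chroms}
    chrom_bad = genotypes.snp_meta["chrom"].astype(str).isin(excluded).to_numpy()
    cr = genotypes.call_rate()
    maf = genotypes.maf()
    cr_bad = cr < call_rate_min
    # SNPs with no calls at all have undefined MAF; they fail call rate
    maf_bad = np.where(np.isnan(maf), True, maf < maf_min)

    removed = {
        "excluded_chromosome": int(chrom_bad.sum()),
        "maf": int((maf_bad & ~chrom_bad).sum()),
        "call_rate": int((cr_bad & ~maf_bad & ~chrom_bad).sum()),
    }
    keep = ~(chrom_bad | maf_bad | cr_bad)
    if not keep.any():
        log.warning("SNP filter removed every marker")
    return SnpFilterResult(genotypes.subset_snps(keep), removed)


def dedupe_records(records: pd.DataFrame) -> pd.DataFrame:
    """One record per animal: the one with most breedings.

    Ties on breedings are broken deterministically by the latest (maximal)
    evaluation id and logged.  Animals keep their first-appearance order.
    """
    req = {"animal_id", "scr", "evaluation", "breedings"}
    if not req <= set(records.columns):
        raise ValueError(f"records need columns {sorted(req)}")
    df = records.copy()
    df["_order"] = np.arange(len(df))

    ties = (
        df.groupby("animal_id")["breedings"]
        .agg(lambda b: (b == b.max()).sum())
        .gt(1)
        .sum()
    )
    if ties:
        log.info("%d animals tied on breedings; latest evaluation kept", ties)

    picked = (
        df.sort_values(
            ["breedings", "evaluation", "_order"], kind="stable"
        )
        .groupby("animal_id", sort=False)
        .tail(1)
    )
    picked = picked.sort_values("_order").drop(columns="_order").reset_index(drop=True)
    # restore first-appearance order of animals
    first_seen = records.drop_duplicates("animal_id")["animal_id"]
    picked = (
        picked.set_index("animal_id").loc[first_seen].reset_index()
    )
    return picked[records.columns.tolist()]
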