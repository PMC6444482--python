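"""Functional classification of SNPs.

Markers are partitioned into five functional classes plus intergenic:

* ``non_synonymous`` — missense / nonsense variants (from effect labels);
* ``synonymous`` — synonymous variants (from effect labels);
* ``ncRNA`` — variants in non-coding RNA genes (from effect labels);
* ``5region`` — 5'UTR or within 5 kb upstream of a gene's 5' end;
* ``3region`` — 3'UTR or within 5 kb downstream of a gene's 3' end;
* ``intergenic`` — everything else.

Coding/ncRNA classes come from Sequence-Ontology-style effect labels and
take precedence; the positional 5'/3' rules are strand-aware and evaluated
against BED (0-based, half-open) gene intervals.  Amino-acid consequences
are never computed from sequence here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix

log = logging.getLogger(__name__)

CLASSES = ["5region", "3region", "non_synonymous", "synonymous", "ncRNA", "intergenic"]

#: distance window for the positional regulatory classes, inclusive
FLANK_BP = 5000

#: precedence when several classes apply
PRECEDENCE = ["non_synonymous", "synonymous", "ncRNA", "5region", "3region"]

SO_TERM_CLASS = {
    "missense_variant": "non_synonymous",
    "stop_gained": "non_synonymous",
    "stop_lost": "non_synonymous",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
    "non_coding_transcript_exon_variant": "ncRNA",
    "non_coding_transcript_variant": "ncRNA",
    "mature_miRNA_variant": "ncRNA",
    "5_prime_UTR_variant": "5region",
    "3_prime_UTR_variant": "3region",
}


@dataclass
class SnpClassPartition:
    """Exhaustive, mutually exclusive class assignment for a SNP panel."""

    class_of: pd.Series  # index snp_id -> class

    @property
    def counts(self) -> dict:
        vc = self.class_of.value_counts()
        return {c: int(vc.get(c, 0)) for c in CLASSES}

    def ids_in(self, cls: str) -> np.ndarray:
        return self.class_of.index[self.class_of == cls].to_numpy()

    def to_tsv(self, path) -> None:
        self.class_of.rename("class").to_frame().reset_index(names="snp_id").to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "SnpClassPartition":
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
        return cls(pd.Series(df["class"].to_numpy(), index=df["snp_id"]))


def read_gene_bed(path) -> pd.DataFrame:
    """Read a BED6 gene-model file (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("gene models must carry +/- strand")
    return df


def _positional_class(pos: int, starts, ends, strands) -> str:
    """5region/3region/intergenic for one position against gene arrays."""
    for cls in ("5region", "3region"):
        for s, e, st in zip(starts, ends, strands):
            five_prime = st == "+"
            want_upstream = (cls == "5region") == five_prime
            # window upstream of gene start: [start-FLANK, start-1];
            # window downstream of gene end: [end, end+FLANK-1]
            if want_upstream:
                hit = s - FLANK_BP <= pos <= s - 1
            else:
                hit = e <= pos <= e + FLANK_BP - 1
            if hit:
                return cls
    return "intergenic"


def classify_snp(
    position: int,
    chromosome: str,
    gene_models: pd.DataFrame | None = None,
    effect_label: str | None = None,
) -> str:
    """Classify a single SNP; effect labels take precedence over position."""
    if effect_label is not None:
        cls = SO_TERM_CLASS.get(effect_label)
        if cls is not None:
            return cls
        log.warning("unknown effect term %r; using positional rules", effect_label)
    if gene_models is None or len(gene_models) == 0:
        return "intergenic"
    sub = gene_models[gene_models["chrom"].astype(str) == str(chromosome)]
    return _positional_class(
        int(position),
        sub["start"].to_numpy(),
        sub["end"].to_numpy(),
        sub["strand"].to_numpy(),
    )


def partition_snps(
    genotypes: GenotypeMatrix,
    gene_models: pd.DataFrame | None = None,
    effect_labels: pd.DataFrame | None = None,
) -> SnpClassPartition:
    """Partition every SNP in the panel into one class.

    ``effect_labels`` is a (snp_id, so_term) table; positional rules are
    applied to the remainder, vectorized per chromosome.
    """
    meta = genotypes.snp_meta
    classes = pd.Series("intergenic", index=genotypes.snp_ids, name="class")

    labelled = np.zeros(len(classes), dtype=bool)
    if effect_labels is not None and len(effect_labels) > 0:
        lab = effect_labels.set_index("snp_id")["so_term"]
        for prec in PRECEDENCE:  # apply in precedence order
            terms = [t for t, c in SO_TERM_CLASS.items() if c == prec]
            hit = lab[lab.isin(terms)]
            idx = classes.index.intersection(hit.index)
            newly = classes.index.isin(idx) & ~labelled
            classes[newly] = prec
            labelled |= newly
        unknown = lab[~lab.isin(SO_TERM_CLASS)]
        if len(unknown):
            log.warning(
                "%d effect labels with unknown SO terms fall through to "
                "positional rules",
                len(unknown),
            )

    if gene_models is not None and len(gene_models) > 0:
        pos_all = meta["pos"].to_numpy()
        chrom_all = meta["chrom"].astype(str).to_numpy()
        for chrom, genes in gene_models.groupby(gene_models["chrom"].astype(str)):
            sel = np.flatnonzero((chrom_all == chrom) & ~labelled)
            if len(sel) == 0:
                continue
            pos = pos_all[sel][:, None]
            s = genes["start"].to_numpy()[None, :]
            e = genes["end"].to_numpy()[None, :]
            plus = (genes["strand"].to_numpy() == "+")[None, :]
            upstream = (s - FLANK_BP <= pos) & (pos <= s - 1)
            downstream = (e <= pos) & (pos <= e + FLANK_BP - 1)
            is5 = (upstream & plus) | (downstream & ~plus)
            is3 = (downstream & plus) | (upstream & ~plus)
            five = is5.any(axis=1)
            three = is3.any(axis=1) & ~five  # 5region wins on conflict
            classes.iloc[sel[five]] = "5region"
            classes.iloc[sel[three]] = "3region"

    return SnpClassPartition(classes)
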