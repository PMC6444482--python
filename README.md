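# sirekit

Genomic prediction of dairy **sire conception rate** (SCR) — the phenotypic
measure of service-sire fertility used in the US national evaluation — with
special attention to two sources of signal that standard whole-genome models
under-use: a handful of markers with large **dominance** effects, and the
**functional annotation** of SNPs.

The package is aimed at quantitative geneticists who want a tested,
reproducible reimplementation of this analysis style that runs end-to-end on
synthetic data with known truth (national genotype panels are not
redistributable), so every stage can be validated before being pointed at
real data.

## What it implements

1. **Synthetic data with a truth ledger** (`sirekit.simulate`) — biallelic
   SNP panels with a uniform MAF spectrum and optional block LD; gene models
   and Sequence-Ontology effect labels laid out so positional annotation
   round-trips exactly; SCR-like phenotypes
   `y = μ + evaluation class + additive polygenic (h² ≈ 0.30) + carrier-coded
   dominance QTLs + e`, plus duplicate records to exercise de-duplication.
2. **Quality control** (`sirekit.qc`) — removal of sex-chromosome SNPs and of
   markers with MAF or call rate strictly below threshold (boundaries are
   kept); one record per bull, keeping the record with most breedings.
3. **Functional classes** (`sirekit.annotate`) — `5region` (5′UTR + 5 kb
   upstream), `3region`, `non_synonymous`, `synonymous`, `ncRNA`,
   `intergenic`; labels take precedence over strand-aware positional rules.
4. **Dominance genome scan** (`sirekit.scan`) — two-step mixed model: REML
   fit of the no-SNP animal model `y = Xb + u + e`, `u ~ N(0, G σ²ᵤ)`, then
   for each SNP the carrier code (0 for AA, 1 for AB/BB) is scored with the
   Wald statistic `z = x′V₀⁻¹(y − Xβ̂) / sqrt(x′V₀⁻¹x)` (code projected off
   the fixed effects), genomic control by the variance inflation factor, and
   Bonferroni selection of major markers.
5. **Genomic kernels** (`sirekit.grm`) — `K = SS′/p` from centered,
   standardized genotypes (VanRaden's genomic relationship matrix), whole
   genome or one kernel per functional class.
6. **Bayesian RKHS regression** (`sirekit.rkhs`) — single- or multi-kernel
   `y = Xb + Σⱼ gⱼ + e`, `gⱼ ~ N(0, Kⱼ σ²gⱼ)`, Gibbs sampling with
   scaled-inverse-χ² variance priors, eigen-reparameterized genetic values,
   data augmentation of held-out phenotypes, and Geweke convergence checks.
7. **Evaluation** (`sirekit.evaluate`) — repeated 5-fold cross-validation,
   predictive correlation (CORR) and mean squared error of prediction
   (MSEP), size-matched random-SNP baselines, and the accuracy conversion
   `CORR / sqrt(h²)`.

A thin CLI (`sirekit run|simulate|qc|annotate|scan|cv|report`) drives the
stages from a YAML config; `sirekit.pipeline.run_experiment` is the same
entry point as a function.

## Worked example

```python
from sirekit import (SimulationConfig, simulate_dataset, dedupe_records,
                     align_phenotypes, DominanceScan)

cfg = SimulationConfig(n_individuals=2000, n_snps=2000, seed=3)
genotypes, genes, pheno, truth = simulate_dataset(cfg)
y, X, _ = align_phenotypes(genotypes, dedupe_records(pheno))
fit = DominanceScan(y, X, genotypes).fit(alpha=0.05)
print(fit.summary())
```

prints

```
Dominance genome scan
Null animal model (REML)
  n = 2000, fixed effects = 29
  sigma2_u = 1.8636
  sigma2_e = 2.1547
  h2       = 0.4638
  SNPs scored        = 2000
  lambda_gc          = 1.5724
  Bonferroni alpha   = 0.05
  major markers      = 5
    snp001471  chr22:1380000  z=-7.68  p=1.56e-14
    snp001088  chr16:3240000  z=+7.57  p=3.68e-14
    snp001661  chr25:360000  z=+7.18  p=6.91e-13
    snp000445  chr7:1920000  z=-6.95  p=3.71e-12
    snp000045  chr1:2760000  z=-6.57  p=5.11e-11
```

The five selected markers are exactly the generator's five dominance QTLs
(each planted to explain 5% of phenotypic variance; `truth.dominance_qtl_ids`
confirms).  The REML h² of ~0.46 exceeds the additive 0.30 because the
additive GRM partially absorbs the 25% of variance contributed by the
carrier-coded QTLs; with `n_dominance_qtl=0` the estimate centers on 0.30.
λ > 1 here is the regression-based inflation factor reacting to the five
genuine signals (on a null scan it sits at 1); dividing by √λ is
conservative and the markers remain far beyond the threshold.
Cross-validating
`Base` against `Base+5SNP` (see `sirekit.experiments.major_marker_cv`) then
shows the fixed-effect markers lifting the mean predictive correlation from
≈0.29 to ≈0.52 at n = 800 — the same direction, and a larger relative gain,
than the 0.340 → 0.403 observed at national scale where each QTL is a
smaller fraction of a far larger dataset.

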