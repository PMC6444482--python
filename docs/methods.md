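# Methods

## The phenotype and the modelling problem

Sire conception rate (SCR) is the expected deviation of a bull's conception
rate from the mean of all evaluated bulls, published in consecutive
evaluation releases.  As a phenotype it mixes genetic and permanent
non-genetic effects of the sire, has moderate heritability (h² ≈ 0.30 is the
working value throughout), and bulls recur across releases — hence the two
data-hygiene rules implemented in `qc`: per-SNP filters (sex chromosomes
out; MAF and call rate strictly below threshold out, boundary values kept,
both computed on non-missing calls) and per-bull de-duplication keeping the
record with most breedings (ties broken by the latest evaluation id, so the
operation is deterministic).

## Synthetic data generator

The generator produces the study-shaped inputs at desk scale with full
knowledge of the truth:

* **Genotypes.**  Dosages 0/1/2 with per-SNP allele frequency uniform on
  `maf_range` (default 0.05–0.5, the post-QC spectrum).  Within optional LD
  blocks, haplotypes are built by copying the previous SNP's allele with
  probability 0.8, giving positive adjacent-SNP correlation;
  `ld_block_size=1` (default) gives independent SNPs.  Positions are evenly
  spaced 60 kb apart — deliberately wider than a gene plus its two 5 kb
  flanks, so each synthetic gene interacts with exactly one SNP and
  positional class labels round-trip exactly through the annotation module.
* **Gene models and labels.**  Per-class SNP counts follow
  `class_proportions` by largest-remainder allocation (exact up to
  rounding; the default proportions mirror a ~295k-SNP bovine panel:
  7280 : 4122 : 1144 : 2090 : 1556 across the five functional classes).
  For `5region`/`3region` a dedicated gene is placed so the SNP falls in the
  strand-aware 5 kb flank; coding/ncRNA SNPs are placed inside gene bodies
  and carry Sequence-Ontology terms, since amino-acid consequences are
  labels, not something derivable from our sequences.
* **Phenotypes.**  `y = μ + evaluation class + Σ sᵢⱼaⱼ + Σ d·1[carrier] + e`
  with total variance anchored at 4.0 SCR-units² (SD 2, putting MSEP on the
  ~4 scale familiar from national evaluations).  Additive effects are drawn
  per *standardized* genotype unit — per-SNP variance equal to the
  functional-class enrichment weight, independent of MAF — because h² = 0.30
  is a parameter of the standardized-kernel (GBLUP) model; drawing effects
  per raw-dosage unit couples effect size to 2f(1−f) and biases GRM-based
  h² estimates upward.  Effects are rescaled so the realized additive
  variance is exactly `h2_additive` of the budget.  Each dominance QTL is a
  carrier shift (AA vs {AB, BB}), sized from the observed carrier frequency
  to contribute exactly `dominance_variance_fraction` (default 0.05, the
  middle of the 3–8% range such markers explain) and excluded from the
  additive draw, so AB and BB means coincide by construction.  Evaluation
  classes (29 by default) get N(0, 0.5²) shifts.  10% of bulls receive a
  duplicate record with strictly fewer breedings and a perturbed SCR, so
  de-duplication has deterministic right answers.  Breeding counts are
  uniform on [100, 10000); the real distribution of record reliabilities is
  not modelled.

What the generator does **not** emulate: realistic allele-frequency spectra,
pedigree/population structure, long-range LD, and the LD between functional
and intergenic markers that makes random SNP sets partially proxy functional
ones in real cattle data.  Passing tests therefore demonstrate correctness
of the machinery and direction of the effects under the stated generative
model, not effect sizes transferable to Holstein data.

## Two-step dominance scan

Step 1 fits `y = Xb + u + e`, `u ~ N(0, G σ²ᵤ)` by REML, with G the
additive GRM from all post-QC SNPs and X the intercept plus evaluation
classes.  A one-time eigendecomposition `G = U D U′` reduces the restricted
likelihood to a 1-D profile in the variance ratio, optimized by bounded
scalar search (`xatol` 1e-8); estimates within 1e-3 of the 0/1 boundary are
flagged.  Step 2 scores the carrier coding of every SNP (missing codes
mean-imputed) with

    z = x′V₀⁻¹(y − Xβ̂) / sqrt(x′ P x),   P = V₀⁻¹ − V₀⁻¹X(X′V₀⁻¹X)⁻¹X′V₀⁻¹.

The denominator projects the code off the fixed effects in the V₀⁻¹ metric:
this is the exact Wald-score variance for the model that contains X, and it
is required for z to be standard normal under the null (the unprojected
form with the raw 0/1 coding is deflated by roughly sqrt(1−f̄), which would
defeat genomic control).  All SNPs are scored with two matrix rotations, so
per-SNP cost is O(n) after the O(n³) factorization.

Genomic control estimates λ as the no-intercept regression slope of the
sorted observed χ²₁ statistics on their expected order quantiles,
truncated below at 1 (deflation is never "corrected" upward);
corrected statistics are z/√λ.  Major markers are those with corrected
p < α/p (Bonferroni, α = 0.05).  The choice of threshold is not delicate:
planted QTLs of ≥5% variance sit far beyond it at the sizes used.

## Kernels

`K = SS′/p` with S centered and standardized.  The default scaling divides
each column by its observed population (1/n) standard deviation, which makes
`mean(diag K) = 1` exactly and is what "centered and standardized" means
literally; `scale="expected"` substitutes the Hardy–Weinberg
`sqrt(2p̂(1−p̂))` (VanRaden/Yang convention).  The two coincide under exact
HWE and differ negligibly on this generator's data.  Missing dosages are
mean-imputed before centering.  Per-class kernels are each divided by their
own SNP count, so the exact identity `Σⱼ pⱼKⱼ / p = K` holds over any
column partition (asserted to 1e-10 in the tests).  Classes with fewer than
two usable SNPs are skipped with a warning.

## Bayesian RKHS regression

`y = Xb + Σⱼ gⱼ + e` with flat priors on b and scaled-inverse-χ² priors
(df 5) on every variance; the prior scale puts the prior mode of the total
genetic variance at `prior_R2 = 0.5` of the phenotypic variance, split
equally across kernels, and the residual prior mode at the remainder.
Each kernel is eigendecomposed once (eigenvalues ≤ 1e-10 dropped) and the
genetic values reparameterized as `gⱼ = Uⱼδⱼ`, `δⱼₖ ~ N(0, dⱼₖσ²gⱼ)`, making
every conditional update element-wise.  The model is parameterized on the
g-scale, `gⱼ ~ N(0, Kⱼσ²gⱼ)`, which stays proper when Kⱼ is rank-deficient
(the equivalent α-scale prior `α ~ N(0, K⁻¹σ²g)` is only formal for
singular K).  Held-out phenotypes are data-augmented: sampled from their
conditional normal each iteration and excluded from summaries, so their
predictions are posterior means of `Xb + Σ gⱼ`.  Divergence (non-finite
state) aborts with diagnostics.  Chains are reproducible bit-for-bit under a
seed.

Schedules: the production schedule is 100,000 iterations, 30,000 burn-in,
thinning 5 → exactly 14,000 retained samples (`McmcConfig.full_schedule()`);
the desk default is 12,000/2,000/5.  Cross-validation experiments use
1,500/300/3 per fold — posterior-mean predictions stabilize far faster than
variance posteriors, and fold-level CORR changes by well under simulation
noise beyond that length.  Variance components are the monitored parameters
for the Geweke diagnostic (first 10% vs last 50% of the chain); the spectral
variance at zero uses Geyer's initial-positive-sequence estimator, which
for reversible chains never underestimates the asymptotic variance, so the
diagnostic errs conservative (~3% false flags at |z| ≥ 2 on i.i.d. chains).

With variances held fixed the sampler's posterior mean of g is the
closed-form BLUP `σ²g K V⁻¹(y − Xβ̂gls)` — the minimizer of the penalized
loss `(y − Kα)′(y − Kα) + λα′Kα` — which the tests verify against a dense
oracle.

## Cross-validated evaluation

Random near-equal k-fold splits (sizes differing by ≤1), repeated; every
bull is in the test set exactly once per repeat.  CORR is the Pearson
correlation of observed and predicted test phenotypes; a fold with constant
predictions records a missing CORR with a warning and is excluded from
means with a count.  MSEP is reported per fold as the fold's mean squared
error, and overall as total squared error over all test predictions divided
by their number — per-observation MSE, the scale on which values ≈ 4 for an
SD-2 phenotype make sense.  Major markers for the `Base+5SNP` model are
selected once on the full data (matching how such markers are found in
practice, on the complete dataset); this leaks selection information into
the CV and is the reason the option of within-training-fold selection exists
in the scan API for stricter use.  Selection accuracy is `CORR/√h²`;
`truncate` reproduces the truncation (not rounding) convention used when
such accuracies are quoted to three decimals (0.4030/√0.30 = 0.7357… →
0.735).  Random-SNP baselines draw size-matched sets uniformly without
replacement, each evaluated with the same folds (10 samplings × 50
estimates = 500 at production scale).

## Canned experiments and their sizes

`sirekit.experiments` freezes the study-condition experiments used by the
acceptance script and tests; sizes were chosen once from power/runtime
analysis of the generator's variance budget:

* **Null calibration** — λ from 10,000 i.i.d. z draws; Geweke over 500
  i.i.d. chains; 3 null scans (n=400, p=2000) for type-I control.
* **h² recovery** — n=1500, p=3000, no QTLs, 3 replicates (single-replicate
  SE of GRM-based h² is ≈0.04 here, so means over 3 are compared).
* **QTL recovery** — n=2000, p=2000, 10 replicates; all five 5%-variance
  QTLs are expected at |z| ≈ 6–7 against a Bonferroni threshold of ≈4.6.
* **Major-marker CV** — n=800, p=1600, 5-fold × 10 repeats, markers selected
  by the scan on the full data.
* **Functional-class CV** — 10 replicates at n=600, p=1500 with one
  regulatory class holding 10% of SNPs at 6× per-SNP variance (~40% of the
  additive signal).  Under the default panel-mirroring proportions every
  functional class carries under 1% of phenotypic variance and no
  class-vs-random comparison has power at any tractable n; the enriched
  setting tests the direction of the effect, which is the claim.
* **Multi-kernel CV** — n=600, p=1500, default proportions, six-kernel
  partition vs the single whole-genome kernel, 5-fold × 2 repeats; mean
  CORRs are expected to agree within ~0.05 (fold-level simulation noise).

## Known limitations

* REML h² from data containing carrier-coded QTLs is inflated (the GRM
  partially tags carrier indicators); h² recovery is therefore assessed on
  QTL-free data, and scan power is assessed as QTL recovery, not as h².
* The scan's power depends on the GRM spectrum: with p/n near 1 the
  whitening concentrates genotype-derived codes on high-eigenvalue
  directions and attenuates z relative to the p ≫ n regime of national
  panels.  Sizes in `experiments` account for this.
* PLINK-1 I/O is a minimal codec (SNP-major .bed, .bim/.fam as whitespace
  tables); no support for sample-major files or allele flipping.
* No dominance or epistatic kernels, no alternative priors, no
  per-animal call-rate filter, no Hardy–Weinberg filter.
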