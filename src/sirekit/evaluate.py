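"""Repeated k-fold cross-validation of kernel prediction models.

Predictive ability is the Pearson correlation (CORR) between observed and
predicted phenotypes in the test folds; MSEP is the mean squared error of
prediction (total squared error over all test predictions divided by the
number of test predictions).  Dividing an average CORR by sqrt(h2) converts
it to a selection accuracy.  Random size-matched SNP sets provide the
baseline against which functional SNP classes are judged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix
from .grm import KernelMatrix, build_kernel, standardize_genotypes, whole_genome_kernel
from .rkhs import McmcConfig, RKHSRegression, add_fixed_markers

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------
def kfold_split(
    sample_ids, k: int = 5, n_repeats: int = 10, seed: int = 0
) -> np.ndarray:
    """Random near-equal k-fold assignments, one row per repeat.

    Returns an (n_repeats, n) integer array of fold labels in 0..k-1; fold
    sizes differ by at most one.  Deterministic under ``seed``.
    """
    n = len(sample_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    out = np.empty((n_repeats, n), dtype=int)
    for r in range(n_repeats):
        out[r] = base[rng.permutation(n)]
    return out


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------
@dataclass
class ModelSpec:
    """Declarative description of one prediction model.

    ``kernel_snp_sets`` maps kernel label -> SNP id list (None = all SNPs);
    ``fixed_marker_ids`` are carrier-coded SNPs added as fixed effects.
    """

    label: str
    kernel_snp_sets: dict = field(default_factory=lambda: {"all": None})
    fixed_marker_ids: tuple = ()

    def build_kernels(
        self, genotypes: GenotypeMatrix, cache: dict | None = None
    ) -> list[KernelMatrix]:
        kernels = []
        for name, ids in self.kernel_snp_sets.items():
            key = name if ids is None else (name, tuple(ids))
            if cache is not None and key in cache:
                kernels.append(cache[key])
                continue
            if ids is None:
                km = whole_genome_kernel(genotypes, label=name)
            else:
                S, _ = standardize_genotypes(genotypes, snp_subset=ids)
                km = build_kernel(S, genotypes.sample_ids, label=name)
            if cache is not None:
                cache[key] = km
            kernels.append(km)
        return kernels


@dataclass
class CVResult:
    """Per-(repeat, fold) predictive metrics plus their summary."""

    estimates: pd.DataFrame  # columns: model, repeat, fold, corr, msep, n_test
    n_undefined_corr: int = 0

    def summary(self) -> pd.DataFrame:
        df = self.estimates
        out = (
            df.groupby("model")
            .agg(
                mean_corr=("corr", "mean"),
                sd_corr=("corr", "std"),
                mean_msep=("msep", "mean"),
                sd_msep=("msep", "std"),
                n_estimates=("corr", "size"),
            )
            .reset_index()
        )
        return out

    def mean_corr(self, model: str | None = None) -> float:
        df = self.estimates
        if model is not None:
            df = df[df["model"] == model]
        return float(df["corr"].mean())

    def per_repeat_corr(self, model: str | None = None) -> pd.Series:
        df = self.estimates
        if model is not None:
            df = df[df["model"] == model]
        return df.groupby("repeat")["corr"].mean()

    def msep_overall(self, model: str | None = None) -> float:
        """Total squared error over all test predictions / total test n."""
        df = self.estimates
        if model is not None:
            df = df[df["model"] == model]
        return float((df["msep"] * df["n_test"]).sum() / df["n_test"].sum())


# ---------------------------------------------------------------------------
# the CV engine
# ---------------------------------------------------------------------------
def evaluate_model(
    spec: ModelSpec,
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    X: np.ndarray,
    folds: np.ndarray,
    mcmc: McmcConfig,
    kernel_cache: dict | None = None,
) -> CVResult:
    """Run repeated k-fold CV of one model via the RKHS sampler.

    For every repeat x fold the test phenotypes are masked and
    data-augmented inside the Gibbs sampler; CORR and MSEP are computed on
    the test set from the posterior mean of the systematic part.  The MCMC
    seed is derived per (repeat, fold) from ``mcmc.seed`` so the whole CV
    is reproducible.
    """
    y = np.asarray(y, dtype=float)
    X_aug, kept, _ = add_fixed_markers(X, genotypes, spec.fixed_marker_ids)
    if spec.fixed_marker_ids and len(kept) < len(spec.fixed_marker_ids):
        log.warning(
            "model %s: %d of %d fixed markers dropped",
            spec.label,
            len(spec.fixed_marker_ids) - len(kept),
            len(spec.fixed_marker_ids),
        )
    kernels = spec.build_kernels(genotypes, kernel_cache)

    rows = []
    undefined = 0
    n_repeats, n = folds.shape
    k = folds.max() + 1
    for rep in range(n_repeats):
        for fold in range(k):
            test = folds[rep] == fold
            seed = (mcmc.seed + 100_003 * rep + 1_009 * fold) % (2**31 - 1)
            cfg = McmcConfig(
                n_iter=mcmc.n_iter,
                burn_in=mcmc.burn_in,
                thin=mcmc.thin,
                seed=seed,
                prior_df=mcmc.prior_df,
                prior_R2=mcmc.prior_R2,
            )
            fit = RKHSRegression(y, X_aug, kernels, missing_mask=test).fit(cfg)
            yhat = fit.predicted[test]
            yobs = y[test]
            msep = float(np.mean((yobs - yhat) ** 2))
            if np.std(yhat) == 0 or np.std(yobs) == 0:
                log.warning(
                    "model %s repeat %d fold %d: constant predictions, "
                    "correlation undefined",
                    spec.label,
                    rep,
                    fold,
                )
                corr = np.nan
                undefined += 1
            else:
                corr = float(np.corrcoef(yobs, yhat)[0, 1])
            rows.append(
                {
                    "model": spec.label,
                    "repeat": rep,
                    "fold": fold,
                    "corr": corr,
                    "msep": msep,
                    "n_test": int(test.sum()),
                }
            )
    return CVResult(pd.DataFrame(rows), undefined)


def random_snp_baseline(
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    X: np.ndarray,
    class_size: int,
    n_samplings: int,
    folds: np.ndarray,
    mcmc: McmcConfig,
    seed: int = 0,
    label: str | None = None,
) -> CVResult:
    """CV of ``n_samplings`` random SNP sets of a given size.

    Each sampling is an independent uniform draw without replacement from
    the whole panel, evaluated with the same folds; at production scale
    (10 samplings x 5 folds x 10 repeats) this yields 500 estimates.
    """
    if class_size > genotypes.n_snps:
        raise ValueError("class_size exceeds the number of SNPs")
    rng = np.random.default_rng(seed)
    label = label or f"random_{class_size}"
    frames = []
    undefined = 0
    for s in range(n_samplings):
        ids = genotypes.snp_ids[
            rng.choice(genotypes.n_snps, size=class_size, replace=False)
        ]
        spec = ModelSpec(label, kernel_snp_sets={label: list(ids)})
        sub_mcmc = McmcConfig(
            n_iter=mcmc.n_iter,
            burn_in=mcmc.burn_in,
            thin=mcmc.thin,
            seed=(mcmc.seed + 7919 * s) % (2**31 - 1),
            prior_df=mcmc.prior_df,
            prior_R2=mcmc.prior_R2,
        )
        res = evaluate_model(spec, genotypes, y, X, folds, sub_mcmc)
        df = res.estimates
        df["sampling"] = s
        frames.append(df)
        undefined += res.n_undefined_corr
    return CVResult(pd.concat(frames, ignore_index=True), undefined)


# ---------------------------------------------------------------------------
# analytic conversions
# ---------------------------------------------------------------------------
def accuracy_from_correlation(corr: float, h2: float) -> float:
    """Selection accuracy corr / sqrt(h2)."""
    if not (0 < h2 <= 1):
        raise ValueError("h2 must lie in (0, 1]")
    return corr / math.sqrt(h2)


def percent_change(a: float, b: float) -> float:
    """100 * (b - a) / a."""
    if a == 0:
        raise ValueError("percent change undefined for a = 0")
    return 100.0 * (b - a) / a


def truncate(x: float, digits: int = 3) -> float:
    """Truncate (not round) toward zero at the given decimals."""
    f = 10.0**digits
    return math.trunc(x * f) / f
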