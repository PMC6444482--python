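"""Two-step mixed-model genome scan for dominance effects.

Step 1 fits the no-SNP animal model y = Xb + u + e with u ~ N(0, G su2)
and e ~ N(0, I se2) by REML, yielding V0 = G su2 + I se2 in factorized
form.  Step 2 scores every SNP under the carrier (0/1) dominance coding
with the GLS score statistic

    z = x' V0^-1 (y - X bhat) / sqrt(x' V0^-1 x),

which approximates the Wald test and is asymptotically standard normal.
Genome-wide statistics are deflated by the variance-inflation-factor
genomic-control lambda, and markers passing a Bonferroni threshold on the
corrected p-values are reported as major dominance markers.

A one-time eigendecomposition of G reduces REML to a 1-D optimization and
makes each SNP's score O(n) (one whitened inner product) after the
genotype-code matrix is rotated once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import GenotypeMatrix
from .grm import KernelMatrix, whole_genome_kernel

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Null (no-SNP) animal model, REML via eigendecomposition of G
# ---------------------------------------------------------------------------
class NullMixedModel:
    """REML fit of y = Xb + u + e with u ~ N(0, G su2), e ~ N(0, I se2).

    G must be symmetric PSD in the sample order of y.  The eigendecomposition
    of G turns the restricted likelihood into a scalar function of the
    variance ratio, optimized by bounded 1-D search.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, G: KernelMatrix | np.ndarray):
        self.y = np.asarray(y, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if isinstance(G, KernelMatrix):
            self.G = G
            U, d = G.eigen()
        else:
            self.G = KernelMatrix(np.asarray(G, dtype=float), np.arange(len(self.y)), 0)
            U, d = self.G.eigen()
        n, k = self.X.shape
        if len(self.y) != n or self.G.n != n:
            raise ValueError("y, X and G must share sample order and size")
        if np.linalg.matrix_rank(self.X) < k:
            raise ValueError("X must have full column rank")
        self._U, self._d = U, d
        self._yt = U.T @ self.y
        self._Xt = U.T @ self.X

    def _profile(self, gamma: float) -> tuple[float, np.ndarray, float]:
        """Profiled REML pieces at variance ratio gamma = su2/se2.

        Returns (-2 restricted loglik up to a constant, beta_hat, se2_hat).
        """
        n, k = self.X.shape
        w = gamma * self._d + 1.0
        Xw = self._Xt / w[:, None]
        XtVX = self._Xt.T @ Xw
        beta = np.linalg.solve(XtVX, Xw.T @ self._yt)
        resid = self._yt - self._Xt @ beta
        rss = float(resid @ (resid / w))
        se2 = rss / (n - k)
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        crit = (n - k) * np.log(se2) + float(np.log(w).sum()) + logdet_xvx
        return crit, beta, se2

    def restricted_neg2loglik(self, h2: float) -> float:
        """-2 * restricted log-likelihood (up to a constant) at a given
        variance proportion h2 = su2 / (su2 + se2).  Exposed for grid
        cross-checks."""
        h2 = float(np.clip(h2, 1e-9, 1 - 1e-9))
        return self._profile(h2 / (1 - h2))[0]

    def fit(self) -> "NullMixedModelResults":
        res = optimize.minimize_scalar(
            self.restricted_neg2loglik,
            bounds=(1e-6, 1 - 1e-6),
            method="bounded",
            options={"xatol": 1e-8},
        )
        h2 = float(res.x)
        gamma = h2 / (1 - h2)
        crit, beta, se2 = self._profile(gamma)
        su2 = gamma * se2
        boundary = h2 < 1e-3 or h2 > 1 - 1e-3
        if boundary:
            log.info("REML variance ratio at boundary (h2=%.4g)", h2)
        return NullMixedModelResults(
            model=self,
            sigma2_u=su2,
            sigma2_e=se2,
            beta_hat=beta,
            neg2loglik=crit,
            boundary=boundary,
        )


@dataclass
class NullMixedModelResults:
    """Variance components plus the factorized V0 of the null model."""

    model: NullMixedModel
    sigma2_u: float
    sigma2_e: float
    beta_hat: np.ndarray
    neg2loglik: float
    boundary: bool

    @property
    def h2(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)

    @property
    def v0_eigenvalues(self) -> np.ndarray:
        return self.model._d * self.sigma2_u + self.sigma2_e

    def solve_v0(self, b: np.ndarray) -> np.ndarray:
        """Apply V0^-1 to a vector or matrix via the stored factorization."""
        U, v = self.model._U, self.v0_eigenvalues
        bt = U.T @ b
        if bt.ndim == 1:
            return U @ (bt / v)
        return U @ (bt / v[:, None])

    def gls_residual(self) -> np.ndarray:
        return self.model.y - self.model.X @ self.beta_hat

    def summary(self) -> str:
        lines = [
            "Null animal model (REML)",
            f"  n = {len(self.model.y)}, fixed effects = {self.model.X.shape[1]}",
            f"  sigma2_u = {self.sigma2_u:.4f}",
            f"  sigma2_e = {self.sigma2_e:.4f}",
            f"  h2       = {self.h2:.4f}" + ("  [boundary]" if self.boundary else ""),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# SNP scoring under the carrier coding
# ---------------------------------------------------------------------------
def dominance_code(dosages: np.ndarray) -> np.ndarray:
    """Carrier coding: 0 for AA, 1 for AB or BB; missing -> mean of observed.

    Accepts a vector or an (n, p) matrix of dosages with missing < 0 or NaN.
    """
    d = np.asarray(dosages, dtype=float)
    miss = np.isnan(d) | (d < 0)
    code = np.where(d >= 1, 1.0, 0.0)
    code[miss] = np.nan
    if code.ndim == 1:
        m = np.nanmean(code) if (~miss).any() else 0.0
        code[miss] = m
    else:
        col_mean = np.where(
            (~miss).any(axis=0), np.nanmean(np.where(miss, np.nan, code), axis=0), 0.0
        )
        inds = np.where(miss)
        code[inds] = np.take(col_mean, inds[1])
    return code


def score_snps(
    codes: np.ndarray, null_fit: NullMixedModelResults
) -> tuple[np.ndarray, np.ndarray]:
    """GLS score z for each coded SNP column; returns (z, monomorphic_flag).

    This is the Wald score for adding the coded SNP to the fixed effects:
    the numerator x' V0^-1 (y - X bhat) is unchanged by the presence of X
    (the GLS residual is V0^-1-orthogonal to X), while the denominator uses
    the V0^-1-norm of the SNP code projected off the fixed-effects design —
    without that projection the statistic is deflated and no longer
    standard normal under the null.

    Columns constant under the coding get z = 0 and are flagged.  All
    per-SNP work happens on rotated (whitened) quantities, so the cost is
    one (n x p) rotation plus O(n) per SNP.
    """
    C = np.atleast_2d(np.asarray(codes, dtype=float))
    if C.shape[0] == 1 and len(null_fit.model.y) != 1:
        C = C.T
    U, v = null_fit.model._U, null_fit.v0_eigenvalues
    sqrt_v = np.sqrt(v)
    rt = (U.T @ null_fit.gls_residual()) / v
    A = U.T @ C
    num = A.T @ rt
    Aw = A / sqrt_v[:, None]  # whitened codes
    Xw = (U.T @ null_fit.model.X) / sqrt_v[:, None]
    Q, _ = np.linalg.qr(Xw)
    proj = Q.T @ Aw
    den = np.einsum("ij,ij->j", Aw, Aw) - np.einsum("ij,ij->j", proj, proj)
    mono = C.std(axis=0) == 0
    z = np.zeros(C.shape[1])
    ok = ~mono & (den > 1e-12)
    z[ok] = num[ok] / np.sqrt(den[ok])
    if mono.any():
        log.info("%d SNPs monomorphic under the carrier coding; z set to 0", mono.sum())
    return z, mono


def genomic_control(z_values: np.ndarray) -> tuple[np.ndarray, float]:
    """Variance-inflation-factor genomic control.

    lambda is the no-intercept regression slope of the sorted observed
    chi-square(1) statistics on their expected order quantiles; corrected
    statistics are z / sqrt(lambda).  lambda < 1 is truncated to 1, and
    fewer than 100 SNPs yield lambda = 1 with a warning.
    """
    z = np.asarray(z_values, dtype=float)
    m = len(z)
    if m < 100:
        log.warning("only %d scored SNPs; genomic-control lambda fixed at 1", m)
        return z.copy(), 1.0
    obs = np.sort(z**2)
    expected = stats.chi2.ppf((np.arange(1, m + 1) - 0.5) / m, df=1)
    denom = float(expected @ expected)
    lam = float(expected @ obs) / denom if denom > 0 else 1.0
    if lam < 1.0:
        log.info("lambda %.4f < 1 truncated to 1", lam)
        lam = 1.0
    return z / np.sqrt(lam), lam


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------
class DominanceScan:
    """Two-step dominance genome scan as a fitted-model object.

    Parameters
    ----------
    y, X : response and fixed-effects design, aligned to genotype order.
    genotypes : GenotypeMatrix of the scanned panel.
    G : relationship matrix for the polygenic background; the additive GRM
        built from all SNPs when omitted.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        genotypes: GenotypeMatrix,
        G: KernelMatrix | None = None,
    ):
        self.genotypes = genotypes
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.G = G if G is not None else whole_genome_kernel(genotypes)

    def fit(self, alpha: float = 0.05) -> "DominanceScanResults":
        null = NullMixedModel(self.y, self.X, self.G).fit()
        codes = dominance_code(self.genotypes.dosages)
        z_raw, mono = score_snps(codes, null)
        z_corr, lam = genomic_control(z_raw)
        p_corr = 2.0 * stats.norm.sf(np.abs(z_corr))
        p_corr = np.clip(p_corr, np.finfo(float).tiny, 1.0)
        table = pd.DataFrame(
            {
                "snp_id": self.genotypes.snp_ids,
                "chrom": self.genotypes.snp_meta["chrom"],
                "pos": self.genotypes.snp_meta["pos"],
                "carrier_freq": codes.mean(axis=0),
                "z_raw": z_raw,
                "z_corrected": z_corr,
                "p_corrected": p_corr,
                "monomorphic": mono,
            }
        )
        return DominanceScanResults(table, lam, null, alpha)


@dataclass
class DominanceScanResults:
    """Per-SNP dominance statistics, lambda, and major-marker selection."""

    table: pd.DataFrame
    lambda_gc: float
    null: NullMixedModelResults
    alpha: float = 0.05
    selected: list = field(init=False)

    def __post_init__(self) -> None:
        self.table = self.table.copy()
        self.selected = select_major_snps(self, self.alpha)
        self.table["selected"] = self.table["snp_id"].isin(self.selected)

    def summary(self) -> str:
        lines = [
            "Dominance genome scan",
            self.null.summary(),
            f"  SNPs scored        = {len(self.table)}",
            f"  lambda_gc          = {self.lambda_gc:.4f}",
            f"  Bonferroni alpha   = {self.alpha}",
            f"  major markers      = {len(self.selected)}",
        ]
        for snp in self.selected:
            row = self.table.set_index("snp_id").loc[snp]
            lines.append(
                f"    {snp}  chr{row['chrom']}:{int(row['pos'])}  "
                f"z={row['z_corrected']:+.2f}  p={row['p_corrected']:.3g}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def select_major_snps(scan: DominanceScanResults, alpha: float = 0.05) -> list:
    """Markers with corrected p below the Bonferroni threshold alpha / p,
    sorted most significant first."""
    if alpha <= 0:
        return []
    tab = scan.table
    thr = alpha / len(tab)
    hits = tab[tab["p_corrected"] < thr].sort_values("p_corrected")
    return hits["snp_id"].tolist()
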