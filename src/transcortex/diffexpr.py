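"""Moderated differential expression between affected and control samples.

Per gene, a linear model (intercept + affected indicator) is fitted by
generalized least squares under a block-diagonal exchangeable correlation:
samples from the same donor share a single consensus correlation ``rho``,
samples from different donors are independent. The consensus is estimated
once, across genes, from OLS residuals (a moment estimator per gene, pooled
by a trimmed mean on the Fisher-z scale). Residual variances are then shrunk
toward a common prior by empirical Bayes — a scaled-F prior fitted by
matching moments of log(s²) through digamma/trigamma equations — which
augments the residual degrees of freedom and yields moderated t-statistics.
Benjamini–Hochberg step-up adjustment controls the false discovery rate.

With ``rho = 0`` the GLS fit reduces exactly to OLS; with prior df 0 the
moderated t reduces to the ordinary per-gene t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .normalization import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DEModelSpec",
    "DEResult",
    "EBayesPrior",
    "make_design",
    "estimate_consensus_correlation",
    "fit_gene_models",
    "ebayes_moderate",
    "bh_adjust",
    "call_de",
    "run_de",
]


@dataclass
class DEModelSpec:
    """Design matrix, donor blocking labels and consensus intra-donor correlation."""

    design: np.ndarray          # samples x coefficients (intercept, affected)
    block: np.ndarray           # donor label per sample
    consensus_rho: float = 0.0

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        self.block = np.asarray(self.block)
        if np.linalg.matrix_rank(self.design) < self.design.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if len(self.block) != self.design.shape[0]:
            raise ValueError("block labels do not cover all samples")
        if not (-1.0 < self.consensus_rho < 1.0):
            raise ValueError("consensus_rho must be in (-1, 1)")


@dataclass
class EBayesPrior:
    """Scaled-F prior on residual variances: d0 prior df (may be inf), s0² location."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s0_sq > 0):
            raise ValueError("prior parameters must be positive")


def make_design(affected: np.ndarray) -> np.ndarray:
    """Intercept + affected-indicator design."""
    affected = np.asarray(affected, dtype=float)
    return np.column_stack([np.ones_like(affected), affected])


# ---------------------------------------------------------------------------
# consensus intra-donor correlation
# ---------------------------------------------------------------------------

def estimate_consensus_correlation(
    X: NormalizedMatrix | pd.DataFrame, design: np.ndarray, block: np.ndarray,
    trim: float = 0.15,
) -> float:
    """Single intra-donor correlation shared across genes.

    Per gene: OLS residuals r are decomposed by a one-way ANOVA on the donor
    grouping. With k blocks of sizes n_b (N total) and the unbalanced-design
    constant n0 = (N − Σn_b²/N)/(k−1), the between-block variance component is
    (MSB − MSW)/n0 and the intra-block correlation its share of the total;
    this moment form stays unbiased after the grand mean has been absorbed by
    the intercept. Per-gene estimates are pooled by a ``trim``-trimmed mean on
    the atanh (Fisher-z) scale and transformed back.

    Returns 0 (with a warning) when every block is a singleton.
    """
    values = X.values if isinstance(X, NormalizedMatrix) else X
    Y = values.to_numpy(dtype=float)
    design = np.asarray(design, dtype=float)
    codes = pd.factorize(np.asarray(block))[0]
    sizes = np.bincount(codes)
    if (sizes < 2).all():
        logger.warning("all donor blocks are singletons: consensus correlation set to 0")
        return 0.0

    # residuals of every gene at once
    Q, _ = np.linalg.qr(design)
    resid = Y - (Y @ Q) @ Q.T
    n = design.shape[0]
    k = sizes.size
    n0 = (n - (sizes ** 2).sum() / n) / (k - 1)

    block_means = np.stack([resid[:, codes == b].mean(axis=1) for b in range(k)], axis=1)
    ssb = (sizes[None, :] * block_means ** 2).sum(axis=1)          # grand mean already removed
    ssw = (resid ** 2).sum(axis=1) - ssb
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    sigma_b = (msb - msw) / n0
    total = sigma_b + msw
    ok = total > 0
    rho_gene = np.zeros(Y.shape[0])
    rho_gene[ok] = sigma_b[ok] / total[ok]
    z = np.arctanh(np.clip(rho_gene, -0.999, 0.999))
    consensus = float(np.tanh(stats.trim_mean(z, proportiontocut=trim)))
    logger.info("consensus intra-donor correlation: %.4f (%d genes)", consensus, Y.shape[0])
    return consensus


# ---------------------------------------------------------------------------
# per-gene GLS under block-exchangeable correlation
# ---------------------------------------------------------------------------

def _whitening_blocks(block: np.ndarray, rho: float) -> tuple[np.ndarray, list[np.ndarray]]:
    codes = pd.factorize(block)[0]
    groups = [np.where(codes == b)[0] for b in range(codes.max() + 1)]
    return codes, groups


def _whiten(M: np.ndarray, groups: list[np.ndarray], rho: float) -> np.ndarray:
    """Multiply samples (last axis) by R^{-1/2} for block-exchangeable R.

    Within a block of size m, R = (1-rho)I + rho J has eigenvalue 1+(m-1)rho
    on the mean direction and 1-rho on its orthocomplement; whitening rescales
    those components separately.
    """
    out = np.array(M, dtype=float, copy=True)
    for idx in groups:
        m = len(idx)
        lam_mean = 1.0 + (m - 1) * rho
        if lam_mean <= 0 or (1.0 - rho) <= 0:
            raise ValueError("correlation matrix not positive definite for this block structure")
        sub = out[..., idx]
        mean = sub.mean(axis=-1, keepdims=True)
        out[..., idx] = (sub - mean) / np.sqrt(1.0 - rho) + mean / np.sqrt(lam_mean)
    return out


def fit_gene_models(
    X: NormalizedMatrix | pd.DataFrame,
    design: np.ndarray,
    block: np.ndarray,
    consensus_rho: float = 0.0,
) -> pd.DataFrame:
    """GLS per gene; columns coef_*, sigma2, df_residual, se_unscaled.

    ``se_unscaled`` is the square root of the contrast coefficient's entry of
    (X' R⁻¹ X)⁻¹ — the standard error divided by sigma. With consensus_rho=0
    the fit is exactly OLS.
    """
    values = X.values if isinstance(X, NormalizedMatrix) else X
    Y = values.to_numpy(dtype=float)
    design = np.asarray(design, dtype=float)
    n, p = design.shape
    _, groups = _whitening_blocks(np.asarray(block), consensus_rho)

    Xw = _whiten(design.T, groups, consensus_rho).T
    Yw = _whiten(Y, groups, consensus_rho)
    if np.linalg.matrix_rank(Xw) < p:
        raise ValueError("whitened design is rank deficient")

    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    beta = Yw @ Xw @ xtx_inv.T                      # genes x p
    resid = Yw - beta @ Xw.T
    df = n - p
    sigma2 = (resid ** 2).sum(axis=1) / df
    se_unscaled = np.sqrt(np.diag(xtx_inv))

    out = pd.DataFrame(index=values.index)
    for j in range(p):
        out[f"coef_{j}"] = beta[:, j]
    out["sigma2"] = sigma2
    out["df_residual"] = float(df)
    for j in range(p):
        out[f"se_unscaled_{j}"] = se_unscaled[j]
    return out


# ---------------------------------------------------------------------------
# empirical Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex target)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def fit_f_dist(sigma2: np.ndarray, df: float) -> EBayesPrior:
    """Moment-match a scaled F prior to observed residual variances.

    Works on z = log(s²): E[z] and Var[z] have closed forms in digamma /
    trigamma of the half-dfs; the excess of the observed variance of z over
    trigamma(df/2) determines d0, the mean then determines s0². A non-positive
    excess means the variances are essentially constant: d0 = ∞ (complete
    pooling) and s0² is their geometric-mean-based location.
    """
    s2 = np.asarray(sigma2, dtype=float)
    if np.any(s2 <= 0):
        raise ValueError("non-positive residual variance")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    if n < 2:
        return EBayesPrior(d0=np.inf, s0_sq=float(np.exp(z.mean())))
    evar = ((e - emean) ** 2).sum() / (n - 1) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        # no excess scatter: complete pooling at the observed (geometric-mean)
        # variance, so identical inputs are returned unchanged
        logger.info("variance of log s2 at or below sampling floor: d0 = inf")
        return EBayesPrior(d0=np.inf, s0_sq=float(np.exp(z.mean())))
    d0 = 2.0 * _trigamma_inverse(evar)
    if np.isinf(d0):
        return EBayesPrior(d0=np.inf, s0_sq=float(np.exp(emean)))
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesPrior(d0=float(d0), s0_sq=s0_sq)


def ebayes_moderate(
    fits: pd.DataFrame,
    coef: int = 1,
    d0_override: float | None = None,
) -> tuple[EBayesPrior, pd.DataFrame]:
    """Moderated t and two-sided p for one coefficient of the per-gene fits.

    Posterior variance s̃² = (d0·s0² + df·s²)/(d0 + df); t = β/(s̃·se_unscaled)
    on df + d0 degrees of freedom (normal when d0 = ∞). ``d0_override``
    forces the prior df (0 recovers the ordinary t exactly).
    """
    sigma2 = fits["sigma2"].to_numpy(dtype=float)
    df = float(fits["df_residual"].iloc[0])
    beta = fits[f"coef_{coef}"].to_numpy(dtype=float)
    se_u = fits[f"se_unscaled_{coef}"].to_numpy(dtype=float)

    if d0_override is not None and d0_override == 0:
        # no moderation: ordinary per-gene t
        prior = EBayesPrior(d0=np.finfo(float).tiny, s0_sq=1.0)
        s2_post = sigma2.copy()
        df_total = np.full_like(sigma2, df)
    else:
        if len(fits) < 4:
            raise ValueError("too few genes to estimate the variance prior")
        if len(fits) < 30:
            logger.warning("estimating the variance prior from only %d genes", len(fits))
        positive = sigma2[sigma2 > 0]
        prior = fit_f_dist(positive, df)
        if d0_override is not None:
            # explicit infinite prior df = classical pooled-variance analysis
            s0 = float(positive.mean()) if np.isinf(d0_override) else prior.s0_sq
            prior = EBayesPrior(d0=d0_override, s0_sq=s0)

    if d0_override != 0 and np.isinf(prior.d0):
        # complete pooling: every gene gets the common prior variance
        s2_post = np.full_like(sigma2, prior.s0_sq)
        df_total = np.full_like(sigma2, np.inf)
    elif d0_override != 0:
        # zero-variance genes take the prior variance outright
        flagged = sigma2 <= 0
        if flagged.any():
            logger.warning("%d genes with zero residual variance assigned the prior variance",
                           int(flagged.sum()))
        s2_eff = np.where(flagged, prior.s0_sq, sigma2)
        s2_post = (prior.d0 * prior.s0_sq + df * s2_eff) / (prior.d0 + df)
        df_total = np.full_like(sigma2, df + prior.d0)

    tstat = beta / (np.sqrt(s2_post) * se_u)
    finite_df = np.isfinite(df_total)
    p = np.empty_like(tstat)
    p[finite_df] = 2.0 * stats.t.sf(np.abs(tstat[finite_df]), df_total[finite_df])
    p[~finite_df] = 2.0 * stats.norm.sf(np.abs(tstat[~finite_df]))

    out = fits.copy()
    out["s2_post"] = s2_post
    out["moderated_t"] = tstat
    out["df_total"] = df_total
    out["p_value"] = p
    return prior, out


# ---------------------------------------------------------------------------
# multiple testing and calls
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped at 1, monotone)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DEResult:
    """Per-gene DE table plus the fitted variance prior and consensus correlation."""

    table: pd.DataFrame      # gene-indexed: lfc, moderated_t, p_value, q_value, direction, ...
    prior: EBayesPrior
    consensus_rho: float

    def called(self, alpha: float = 0.05) -> tuple[set[str], set[str]]:
        return call_de(self.table, alpha=alpha)


def call_de(table: pd.DataFrame, alpha: float = 0.05) -> tuple[set[str], set[str]]:
    """Significant genes split by direction; strict q < alpha."""
    sig = table["q_value"] < alpha
    higher = set(table.index[sig & (table["lfc"] > 0)])
    lower = set(table.index[sig & (table["lfc"] < 0)])
    return higher, lower


def run_de(
    X: NormalizedMatrix | pd.DataFrame,
    affected: np.ndarray,
    block: np.ndarray,
    use_block_correlation: bool = True,
    d0_override: float | None = None,
) -> DEResult:
    """Full moderated-DE stack on a gene × sample matrix.

    ``affected`` is the per-sample 0/1 indicator (column order of X); ``block``
    the donor label per sample.
    """
    design = make_design(affected)
    rho = (estimate_consensus_correlation(X, design, block)
           if use_block_correlation else 0.0)
    fits = fit_gene_models(X, design, block, consensus_rho=rho)
    prior, fits = ebayes_moderate(fits, coef=1, d0_override=d0_override)
    q = bh_adjust(fits["p_value"].to_numpy())
    table = pd.DataFrame(index=fits.index)
    table["lfc"] = fits["coef_1"]
    table["sigma2"] = fits["sigma2"]
    table["df_residual"] = fits["df_residual"]
    table["moderated_t"] = fits["moderated_t"]
    table["p_value"] = fits["p_value"]
    table["q_value"] = q
    table["direction"] = np.where(table["lfc"] > 0, "higher",
                                  np.where(table["lfc"] < 0, "lower", "none"))
    logger.info("DE: %d higher, %d lower at q<0.05 (rho=%.3f, d0=%.3g)",
                len(call_de(table)[0]), len(call_de(table)[1]), rho, prior.d0)
    return DEResult(table=table, prior=prior, consensus_rho=rho)
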