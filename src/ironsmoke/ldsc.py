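"""LD scores and uni/bivariate LD-score regression at desk scale.

Model: for SNP j with LD score l_j over M analysed SNPs,

    E[z_j^2]       = intercept + n * h2 * l_j / M
    E[z1_j * z2_j] = rho_ov    + sqrt(n1*n2) * gencov * l_j / M

so the univariate slope estimates SNP heritability, the cross-trait slope
the genetic covariance, and the cross-trait intercept the
participant-overlap term rho_ov that the gene-level tests consume.
Standard errors come from a delete-one block jackknife over contiguous
SNP blocks (default 20 — appropriate for toy genomes of a few thousand
SNPs).  The genetic correlation rg = gencov / sqrt(h2_1 * h2_2) is
clipped to [-1.5, 1.5] before reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import HaplotypePanel, SummaryStats
from .pheno import bh_fdr

log = logging.getLogger("ironsmoke")


@dataclass
class LdScores:
    snp_id: np.ndarray
    ell: np.ndarray
    window_bp: int
    n_panel: int


@dataclass
class LdscFit:
    h2_1: float
    h2_2: float
    gencov: float
    rg: float
    intercept_1: float
    intercept_2: float
    cross_intercept: float
    rg_se: float
    rg_pval: float
    n_blocks: int


def ld_scores(panel: HaplotypePanel, window_bp: int = 1_000_000) -> LdScores:
    """Per-SNP sum of bias-adjusted r^2 within a physical window.

    r2_adj = r2 - (1 - r2)/(n_panel - 2) corrects the upward finite-panel
    bias of the squared sample correlation; the self term contributes
    exactly 1 after adjustment.
    """
    n_hap = panel.n_haplotypes
    if n_hap < 3:
        raise ValueError("panel must contain at least 3 haplotypes")
    pos = panel.pos
    m = panel.n_snps
    H = panel.haplotypes.astype(float)
    Hc = H - H.mean(axis=1, keepdims=True)
    norms = np.sqrt((Hc * Hc).sum(axis=1))
    ell = np.zeros(m)
    # chunked windowed correlations; toy genomes keep this cheap
    chunk = 512
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        w_lo = int(np.searchsorted(pos, pos[lo] - window_bp, side="left"))
        w_hi = int(np.searchsorted(pos, pos[hi - 1] + window_bp, side="right"))
        R = (Hc[lo:hi] @ Hc[w_lo:w_hi].T) / np.outer(norms[lo:hi], norms[w_lo:w_hi])
        in_win = (np.abs(pos[w_lo:w_hi][None, :] - pos[lo:hi][:, None])
                  <= window_bp)
        r2 = R * R
        r2_adj = r2 - (1.0 - r2) / (n_hap - 2)
        ell[lo:hi] = np.where(in_win, r2_adj, 0.0).sum(axis=1)
    return LdScores(snp_id=panel.snp_id.copy(), ell=ell,
                    window_bp=window_bp, n_panel=n_hap)


def _match(ss: SummaryStats, ld: LdScores) -> tuple[np.ndarray, np.ndarray]:
    order = {s: i for i, s in enumerate(ld.snp_id)}
    idx = ss.table["snp_id"].map(order)
    if idx.isna().any():
        raise ValueError("summary statistics contain SNPs absent from the LD scores")
    return ss.zscores(), ld.ell[idx.to_numpy(int)]


def _wls(y: np.ndarray, x: np.ndarray, w: np.ndarray,
         mask: np.ndarray | None = None) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (slope, intercept)."""
    if mask is not None:
        y, x, w = y[mask], x[mask], w[mask]
    sw = np.sqrt(w)
    D = np.column_stack([sw, sw * x])
    coef, *_ = np.linalg.lstsq(D, sw * y, rcond=None)
    return float(coef[1]), float(coef[0])


def _two_step(y: np.ndarray, ell: np.ndarray, scale: float, M: int,
              mask: np.ndarray | None = None) -> tuple[float, float, np.ndarray]:
    """Two-step re-weighted z^2 regression on ell.

    First pass uses 1/max(ell,1) LD weights only; the second adds the
    variance weight implied by the first-pass fit, Var(z^2) ~ 2*E[z^2]^2.
    ``scale`` is the GWAS sample size n.  Returns (slope, intercept,
    fitted mean profile) so the bivariate fit can reuse the variances.
    """
    w0 = 1.0 / np.maximum(ell, 1.0)
    slope0, icpt0 = _wls(y, ell, w0, mask)
    mean0 = np.maximum(icpt0 + scale * max(slope0, 0.0) * ell / M, 0.1)
    w1 = w0 / (mean0 ** 2)
    slope, icpt = _wls(y, ell, w1, mask)
    mean = np.maximum(icpt + scale * max(slope, 0.0) * ell / M, 0.1)
    return slope, icpt, mean


def _cross_step(y: np.ndarray, ell: np.ndarray, scale: float, M: int,
                mean1: np.ndarray, mean2: np.ndarray,
                mask: np.ndarray | None = None) -> tuple[float, float]:
    """Two-step cross-product regression of z1*z2 on ell.

    Var(z1*z2) = E[z1^2]E[z2^2] + E[z1*z2]^2 under joint normality; the
    univariate mean profiles supply the first term, the first-pass fit
    the second.
    """
    w0 = 1.0 / (np.maximum(ell, 1.0) * mean1 * mean2)
    slope0, icpt0 = _wls(y, ell, w0, mask)
    meanc = icpt0 + scale * slope0 * ell / M
    w1 = 1.0 / (np.maximum(ell, 1.0) * (mean1 * mean2 + meanc ** 2))
    return _wls(y, ell, w1, mask)


def _jack_masks(m: int, n_blocks: int) -> list[np.ndarray]:
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    masks = []
    for b in range(n_blocks):
        mask = np.ones(m, bool)
        mask[edges[b]:edges[b + 1]] = False
        masks.append(mask)
    return masks


def fit_univariate(ss: SummaryStats, ld: LdScores, M: int | None = None,
                   n_blocks: int = 20) -> tuple[float, float, dict]:
    """Estimate SNP heritability and the LDSC intercept for one trait."""
    z, ell = _match(ss, ld)
    m = len(z)
    if m < 2 * n_blocks:
        raise ValueError("too few SNPs for the requested jackknife blocks")
    M = M or m
    n = ss.n_total
    slope, icpt, _ = _two_step(z * z, ell, n, M)
    h2 = slope * M / n
    jk = []
    for mask in _jack_masks(m, n_blocks):
        s_b, _, _ = _two_step(z * z, ell, n, M, mask)
        jk.append(s_b * M / n)
    jk = np.asarray(jk)
    se = np.sqrt((n_blocks - 1) / n_blocks * ((jk - jk.mean()) ** 2).sum())
    return h2, icpt, {"h2_se": float(se), "n_blocks": n_blocks}


def fit_bivariate(ss1: SummaryStats, ss2: SummaryStats, ld: LdScores,
                  M: int | None = None, n_blocks: int = 20) -> LdscFit:
    """Bivariate LDSC: heritabilities, genetic covariance/correlation and
    the cross-trait (overlap) intercept, with block-jackknife rg se."""
    z1, ell = _match(ss1, ld)
    z2, _ = _match(ss2, ld)
    if len(z1) != len(z2) or (ss1.table["snp_id"].to_numpy() != ss2.table["snp_id"].to_numpy()).any():
        raise ValueError("traits must share an identical SNP universe")
    m = len(z1)
    if m < 2 * n_blocks:
        raise ValueError("too few SNPs for the requested jackknife blocks")
    M = M or m
    n1, n2 = ss1.n_total, ss2.n_total
    rootn = np.sqrt(n1 * n2)

    def _fit(mask=None):
        s1, i1, mean1 = _two_step(z1 * z1, ell, n1, M, mask)
        s2, i2, mean2 = _two_step(z2 * z2, ell, n2, M, mask)
        sc, ic = _cross_step(z1 * z2, ell, rootn, M, mean1, mean2, mask)
        h1, h2b = s1 * M / n1, s2 * M / n2
        gc = sc * M / rootn
        if h1 > 0 and h2b > 0:
            rg = float(np.clip(gc / np.sqrt(h1 * h2b), -1.5, 1.5))
        else:
            rg = np.nan
        return h1, h2b, gc, rg, i1, i2, ic

    h1, h2b, gc, rg, i1, i2, ic = _fit()
    if np.isnan(rg):
        log.warning("fit_bivariate: non-positive heritability estimate; rg missing")
    jk = np.array([_fit(mask)[3] for mask in _jack_masks(m, n_blocks)])
    ok = np.isfinite(jk)
    if np.isfinite(rg) and ok.sum() >= 2:
        jj = jk[ok]
        se = float(np.sqrt((len(jj) - 1) / len(jj) * ((jj - jj.mean()) ** 2).sum()))
        pval = float(2 * stats.norm.sf(abs(rg) / se)) if se > 0 else 1.0
    else:
        se, pval = np.nan, np.nan
    return LdscFit(h2_1=h1, h2_2=h2b, gencov=gc, rg=rg,
                   intercept_1=i1, intercept_2=i2, cross_intercept=ic,
                   rg_se=se, rg_pval=pval, n_blocks=n_blocks)


def fdr_over_traits(fits: list[LdscFit], alpha: float = 0.05):
    """BH adjustment of the rg p-values across a battery of trait pairs."""
    import pandas as pd

    pv = np.array([f.rg_pval for f in fits], dtype=float)
    pv_for_adjust = np.where(np.isfinite(pv), pv, 1.0)
    q = bh_fdr(np.clip(pv_for_adjust, 1e-300, 1.0))
    return pd.DataFrame({
        "rg": [f.rg for f in fits],
        "rg_se": [f.rg_se for f in fits],
        "pval": pv,
        "qval": q,
        "significant": q < alpha,
    })
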