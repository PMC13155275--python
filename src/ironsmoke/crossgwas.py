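"""Gene-level cross-GWAS coherence and directional ratio tests.

Per-SNP signed scores are built by rank-normalising the GWAS p-values
over the genome-wide analysed set (u_i = (rank_i - 1/2)/M) and mapping
them back to signed normal quantiles z_i = sign(beta_i) * Phi^-1(1 - u_i/2).
For each gene, SNPs inside the transcribed span +/- 50 kb are collected
with their reference-panel LD matrix Sigma.

Coherence statistic: D = sum_i zA_i * zB_i.  Under the null the two
score vectors are jointly Gaussian, each N(0, Sigma), with cross
covariance rho_ov * Sigma (rho_ov = overlap intercept from bivariate
LDSC).  Eigen-decomposing Sigma = Q L Q' turns D into a difference of
weighted chi-squares with weights lam_k (1 +/- rho_ov)/2, whose tails the
Imhof engine evaluates; the anti-coherence p is the mirror tail.

Ratio statistic: R = sum zA_i zB_i / sum zB_i^2, whose conditional tail
P(R >= r_obs) equals P(w' A(r_obs) w >= 0) for the stacked vector
w = (zA, zB) with A(r) = [[0, I/2], [I/2, -rI]] and covariance
Omega = [[Sigma, rho Sigma], [rho Sigma, Sigma]].  With the Kronecker
structure Omega = K (x) Sigma this reduces to the products of the
eigenvalues of the 2x2 matrix K^1/2 B(r) K^1/2 with those of Sigma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneAnnotation, HaplotypePanel, SummaryStats
from .quadform import weighted_chisq_tail
from .simulate import _k_sqrt, regularised_corr

log = logging.getLogger("ironsmoke")

EIG_TRUNC = 1e-8


@dataclass
class SignedZ:
    """Genome-wide signed rank-normalised scores, indexed by snp_id."""

    snp_id: np.ndarray
    z: np.ndarray

    def lookup(self) -> dict:
        return {s: i for i, s in enumerate(self.snp_id)}


@dataclass
class GeneWindow:
    gene_id: str
    chrom: str
    win_start: int
    win_end: int
    snp_ids: np.ndarray
    sigma: np.ndarray


@dataclass
class GeneTestResult:
    gene_id: str
    n_snps: int
    statistic: float
    p_coherent: float = np.nan
    p_anticoherent: float = np.nan
    p_fwd: float = np.nan
    method: str = "analytic"
    rho_ov: float = 0.0


def align_studies(ss_a: SummaryStats, ss_b: SummaryStats
                  ) -> tuple[SummaryStats, SummaryStats]:
    """Intersect two studies on snp_id and harmonise trait B's effect
    alleles to trait A's (swapped alleles flip beta and eaf); SNPs whose
    allele pairs cannot be reconciled are dropped with a logged count."""
    a = ss_a.table.set_index("snp_id")
    b = ss_b.table.set_index("snp_id")
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared].copy(), b.loc[shared].copy()
    same = (a["allele_effect"] == b["allele_effect"]) & (a["allele_other"] == b["allele_other"])
    swapped = (a["allele_effect"] == b["allele_other"]) & (a["allele_other"] == b["allele_effect"])
    b.loc[swapped, "beta"] = -b.loc[swapped, "beta"]
    b.loc[swapped, "eaf"] = 1.0 - b.loc[swapped, "eaf"]
    b.loc[swapped, ["allele_effect", "allele_other"]] = a.loc[
        swapped, ["allele_effect", "allele_other"]].to_numpy()
    keep = same | swapped
    dropped = int((~keep).sum())
    if dropped:
        log.info("align_studies: dropped %d SNP(s) with irreconcilable alleles", dropped)
    a, b = a.loc[keep].reset_index(), b.loc[keep].reset_index()
    return (SummaryStats(ss_a.trait_name, a), SummaryStats(ss_b.trait_name, b))


def signed_rank_z(ss: SummaryStats, maf_min: float = 0.01) -> SignedZ:
    """Signed rank-normalised z over the MAF-filtered genome-wide SNP set."""
    t = ss.table
    maf = np.minimum(t["eaf"], 1.0 - t["eaf"]).to_numpy(float)
    kept = t.loc[maf >= maf_min]
    M = len(kept)
    if M < 2:
        raise ValueError("fewer than 2 SNPs after MAF filtering")
    p = kept["pval"].to_numpy(float)
    if np.unique(p).size == 1:
        raise ValueError("all p-values identical; ranks are degenerate")
    ranks = stats.rankdata(p, method="average")
    u = (ranks - 0.5) / M
    z = np.sign(kept["beta"].to_numpy(float)) * stats.norm.ppf(1.0 - u / 2.0)
    return SignedZ(snp_id=kept["snp_id"].to_numpy(), z=z)


def build_windows(annotation: GeneAnnotation, scores: SignedZ,
                  panel: HaplotypePanel, flank_bp: int = 50_000
                  ) -> tuple[list[GeneWindow], list[str]]:
    """Gene windows (span +/- flank, inclusive ends) with panel LD.

    Only SNPs present both in the score set and the panel enter a window.
    Returns (windows, untested_gene_ids); genes whose window holds no SNP
    are reported untested.
    """
    panel_idx = {s: i for i, s in enumerate(panel.snp_id)}
    score_ids = set(scores.snp_id)
    windows, untested = [], []
    for row in annotation.table.itertuples():
        w_lo = max(1, int(row.start) - flank_bp)
        w_hi = int(row.end) + flank_bp
        sel = np.flatnonzero(
            (panel.chrom == row.chrom) & (panel.pos >= w_lo) & (panel.pos <= w_hi))
        sel = [j for j in sel if panel.snp_id[j] in score_ids]
        if not sel:
            untested.append(row.gene_id)
            continue
        sigma = regularised_corr(panel, sel)
        windows.append(GeneWindow(
            gene_id=row.gene_id, chrom=str(row.chrom),
            win_start=w_lo, win_end=w_hi,
            snp_ids=panel.snp_id[np.asarray(sel)], sigma=sigma))
    if untested:
        log.info("build_windows: %d gene(s) without SNPs left untested", len(untested))
    return windows, untested


def _window_z(scores: SignedZ, win: GeneWindow) -> np.ndarray:
    look = scores.lookup()
    return scores.z[np.array([look[s] for s in win.snp_ids])]


def coherence_test(z_a: SignedZ, z_b: SignedZ, win: GeneWindow,
                   rho_ov: float = 0.0, trait_sign: int = 1) -> GeneTestResult:
    """Cross-GWAS coherence / anti-coherence test for one gene.

    ``trait_sign=-1`` encodes the iron-direction flip for T2* (lower T2*
    means more iron), applied to trait B before testing.  ``rho_ov`` is
    the sample-overlap intercept estimated for the *original* trait
    orientation, clipped to (-0.99, 0.99); flipping trait B flips the
    overlap-induced cross-correlation, so the null uses trait_sign*rho_ov.
    """
    rho = float(np.clip(trait_sign * rho_ov, -0.99, 0.99))
    za = _window_z(z_a, win)
    zb = trait_sign * _window_z(z_b, win)
    d = float(za @ zb)
    lam = np.linalg.eigvalsh(win.sigma)
    lam = lam[lam > EIG_TRUNC]
    if lam.size == 0:
        raise ValueError(f"{win.gene_id}: LD matrix has no usable eigenvalues")
    w_plus = lam * (1.0 + rho) / 2.0
    w_minus = lam * (1.0 - rho) / 2.0
    p_coh, m1 = weighted_chisq_tail(w_plus, w_minus, d)
    p_anti, m2 = weighted_chisq_tail(w_minus, w_plus, -d)
    return GeneTestResult(
        gene_id=win.gene_id, n_snps=len(za), statistic=d,
        p_coherent=p_coh, p_anticoherent=p_anti,
        method="analytic" if (m1 == m2 == "analytic") else "mc", rho_ov=rho)


def ratio_test(z_exposure: SignedZ, z_outcome: SignedZ, win: GeneWindow,
               rho_ov: float = 0.0, trait_sign: int = 1) -> GeneTestResult:
    """Directional ratio test R = sum zA*zB / sum zB^2 for one gene.

    Small p_fwd indicates exposure-to-outcome aligned effects that are
    large on the exposure side relative to the outcome norm.  As in the
    coherence test, ``rho_ov`` refers to the original orientation and is
    sign-flipped together with the outcome trait.
    """
    rho = float(np.clip(trait_sign * rho_ov, -0.99, 0.99))
    za = _window_z(z_exposure, win)
    zb = trait_sign * _window_z(z_outcome, win)
    denom = float(zb @ zb)
    if denom == 0:
        raise ValueError(f"{win.gene_id}: outcome scores are all zero")
    r_obs = float(za @ zb) / denom
    lam = np.linalg.eigvalsh(win.sigma)
    lam = lam[lam > EIG_TRUNC]
    ksq = _k_sqrt(rho)
    b2 = np.array([[0.0, 0.5], [0.5, -r_obs]])
    c = np.linalg.eigvalsh(ksq @ b2 @ ksq)
    weights = np.outer(c, lam).ravel()
    p_fwd, method = weighted_chisq_tail(weights[weights > 0],
                                        -weights[weights < 0], 0.0)
    return GeneTestResult(gene_id=win.gene_id, n_snps=len(za), statistic=r_obs,
                          p_fwd=p_fwd, method=method, rho_ov=rho)


def bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Per-gene alpha: alpha divided by the number of tested genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


def cluster_significant(results: pd.DataFrame, annotation: GeneAnnotation,
                        threshold: float, pcol: str = "p_coherent",
                        flank_bp: int = 50_000) -> list[list[str]]:
    """Merge significant genes with overlapping windows into clusters.

    Clusters are the connected components of the window-overlap graph on
    the significant genes of one chromosome, reported as sorted gene-id
    lists.
    """
    sig = results.loc[results[pcol] < threshold, "gene_id"]
    ann = annotation.table.set_index("gene_id").loc[sig]
    clusters: list[list[str]] = []
    for _, chrom_genes in ann.groupby("chrom"):
        g = chrom_genes.sort_values("start")
        current: list[str] = []
        current_end = -np.inf
        for row in g.itertuples():
            w_lo, w_hi = row.start - flank_bp, row.end + flank_bp
            if current and w_lo <= current_end:
                current.append(row.Index)
                current_end = max(current_end, w_hi)
            else:
                if current:
                    clusters.append(sorted(current))
                current = [row.Index]
                current_end = w_hi
        if current:
            clusters.append(sorted(current))
    return clusters


def candidate_mode(results: pd.DataFrame, gene_list: list[str],
                   alpha: float = 0.05) -> tuple[pd.DataFrame, float]:
    """Restrict to a candidate-gene list with Bonferroni over its size."""
    present = [g for g in gene_list if g in set(results["gene_id"])]
    absent = sorted(set(gene_list) - set(present))
    if absent:
        log.warning("candidate_mode: gene(s) not tested: %s", ", ".join(absent))
    if not present:
        raise ValueError("no candidate gene present in the results")
    sub = results[results["gene_id"].isin(present)].reset_index(drop=True)
    return sub, bonferroni_threshold(len(present), alpha)


def exclude_genes(results: pd.DataFrame, exclusion_list: list[str]) -> pd.DataFrame:
    """Drop listed genes (sensitivity analysis for known pleiotropic loci)."""
    return results[~results["gene_id"].isin(set(exclusion_list))].reset_index(drop=True)


def run_scan(ss_a: SummaryStats, ss_b: SummaryStats, panel: HaplotypePanel,
             annotation: GeneAnnotation, test: str = "coherence",
             rho_ov: float = 0.0, trait_sign: int = 1,
             flank_bp: int = 50_000, maf_min: float = 0.01) -> pd.DataFrame:
    """Genome-wide per-gene scan; ``test`` is ``coherence`` or ``ratio``."""
    a, b = align_studies(ss_a, ss_b)
    za = signed_rank_z(a, maf_min)
    zb = signed_rank_z(b, maf_min)
    windows, untested = build_windows(annotation, za, panel, flank_bp)
    rows = []
    for win in windows:
        if test == "coherence":
            res = coherence_test(za, zb, win, rho_ov, trait_sign)
        elif test == "ratio":
            res = ratio_test(za, zb, win, rho_ov, trait_sign)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(res.__dict__)
    df = pd.DataFrame(rows)
    df.attrs["untested"] = untested
    return df
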