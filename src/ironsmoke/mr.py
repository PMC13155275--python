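"""Bidirectional two-sample Mendelian randomisation with sensitivity battery.

Instruments are exposure SNPs at p < 5e-8, greedily clumped to lead SNPs
at panel r^2 <= 0.001; when fewer than five survive, selection is
repeated at p < 1e-5 (the threshold actually used is recorded).  After
allele harmonisation against the outcome study, causal effects are
estimated by IVW (multiplicative random effects), MR-Egger, the weighted
median and the weighted mode, accompanied by Cochran's Q, per-instrument
F statistics, leave-one-out influence checks and confounder-SNP
exclusion.  FDR is applied across the IVW family of a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import HaplotypePanel, PipelineConfig, SummaryStats
from .pheno import bh_fdr

log = logging.getLogger("ironsmoke")

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
PALINDROME_EAF_BAND = 0.42


class InstrumentError(ValueError):
    """No usable instruments for an exposure."""


@dataclass
class InstrumentSet:
    exposure: str
    table: pd.DataFrame           # canonical sumstats rows of the lead SNPs
    selection_pthresh: float
    clump_r2: float

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp_id"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class HarmonizedData:
    exposure: str
    outcome: str
    table: pd.DataFrame           # snp_id, beta_exp, se_exp, beta_out, se_out
    dropped_palindromic: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    def arrays(self):
        t = self.table
        return (t["beta_exp"].to_numpy(float), t["se_exp"].to_numpy(float),
                t["beta_out"].to_numpy(float), t["se_out"].to_numpy(float))


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    pval: float
    n_iv: int
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# instrument selection & harmonisation
# ---------------------------------------------------------------------------

def select_instruments(ss_exposure: SummaryStats, panel: HaplotypePanel,
                       cfg: PipelineConfig | None = None) -> InstrumentSet:
    """Greedy p-ascending clumping of genome-wide-significant exposure SNPs."""
    cfg = cfg or PipelineConfig()

    def _clump(pthresh: float) -> pd.DataFrame:
        cand = ss_exposure.table[ss_exposure.table["pval"] <= pthresh]
        cand = cand.sort_values(["pval", "snp_id"], kind="mergesort")
        if cand.empty:
            return cand
        panel_idx = {s: i for i, s in enumerate(panel.snp_id)}
        rows, kept_idx = [], []
        H = panel.haplotypes.astype(float)
        for row in cand.itertuples():
            j = panel_idx.get(row.snp_id)
            if j is None:
                continue
            if kept_idx:
                h = H[j] - H[j].mean()
                ok = True
                for k in kept_idx:
                    g = H[k] - H[k].mean()
                    denom = np.sqrt((h @ h) * (g @ g))
                    r2 = 0.0 if denom == 0 else ((h @ g) / denom) ** 2
                    if r2 > cfg.clump_r2:
                        ok = False
                        break
                if not ok:
                    continue
            kept_idx.append(j)
            rows.append(row.Index)
        return cand.loc[rows]

    kept = _clump(cfg.iv_pthresh)
    pthresh = cfg.iv_pthresh
    if len(kept) < cfg.min_iv:
        log.info("select_instruments: %d IV(s) at %g; falling back to %g",
                 len(kept), cfg.iv_pthresh, cfg.iv_fallback_pthresh)
        kept = _clump(cfg.iv_fallback_pthresh)
        pthresh = cfg.iv_fallback_pthresh
    if kept.empty:
        raise InstrumentError(
            f"no instruments for {ss_exposure.trait_name} even at "
            f"p < {cfg.iv_fallback_pthresh:g}")
    return InstrumentSet(ss_exposure.trait_name, kept.reset_index(drop=True),
                         selection_pthresh=pthresh, clump_r2=cfg.clump_r2)


def harmonize(iv: InstrumentSet, ss_outcome: SummaryStats) -> HarmonizedData:
    """Align outcome effects to the exposure effect allele.

    Swapped allele pairs flip the outcome beta; palindromic SNPs (A/T or
    C/G) with min(eaf, 1-eaf) > 0.42 in either study are dropped,
    otherwise aligned by frequency.  Instruments absent from the outcome
    are dropped with a log entry.
    """
    out = ss_outcome.table.set_index("snp_id")
    rows, dropped_pal = [], []
    missing = 0
    for r in iv.table.itertuples():
        if r.snp_id not in out.index:
            missing += 1
            continue
        o = out.loc[r.snp_id]
        pal = (str(r.allele_effect), str(r.allele_other)) in PALINDROMIC
        beta_out, eaf_out = float(o["beta"]), float(o["eaf"])
        if (str(o["allele_effect"]) == str(r.allele_effect)
                and str(o["allele_other"]) == str(r.allele_other)):
            aligned = True
        elif (str(o["allele_effect"]) == str(r.allele_other)
                and str(o["allele_other"]) == str(r.allele_effect)):
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            aligned = True
        else:
            aligned = pal  # complement-strand palindrome: alleles look identical sets
        if not aligned:
            missing += 1
            continue
        if pal:
            if (min(r.eaf, 1 - r.eaf) > PALINDROME_EAF_BAND
                    or min(eaf_out, 1 - eaf_out) > PALINDROME_EAF_BAND):
                dropped_pal.append(r.snp_id)
                continue
            if (r.eaf - 0.5) * (eaf_out - 0.5) < 0:   # frequency-based strand fix
                beta_out = -beta_out
        rows.append({"snp_id": r.snp_id, "beta_exp": r.beta, "se_exp": r.se,
                     "beta_out": beta_out, "se_out": float(o["se"])})
    if missing:
        log.info("harmonize: dropped %d instrument(s) missing/mismatched in outcome", missing)
    if dropped_pal:
        log.info("harmonize: dropped %d ambiguous palindromic SNP(s)", len(dropped_pal))
    return HarmonizedData(iv.exposure, ss_outcome.trait_name,
                          pd.DataFrame(rows), dropped_palindromic=dropped_pal)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def ivw(hd: HarmonizedData) -> MREstimate:
    """Inverse-variance-weighted estimate (multiplicative random effects).

    Weighted regression of outcome betas on exposure betas through the
    origin with weights 1/se_out^2; the fixed-effect se is inflated by
    max(1, sqrt(Q/(n-1))).
    """
    if len(hd) < 2:
        raise ValueError("IVW requires at least 2 instruments")
    bx, _, by, sy = hd.arrays()
    w = 1.0 / sy**2
    beta = float((w * bx * by).sum() / (w * bx * bx).sum())
    se_fixed = float(np.sqrt(1.0 / (w * bx * bx).sum()))
    q = float((w * (by - beta * bx) ** 2).sum())
    df = len(hd) - 1
    se = se_fixed * max(1.0, np.sqrt(q / df))
    pval = float(2 * stats.norm.sf(abs(beta) / se))
    q_p = float(stats.chi2.sf(q, df))
    return MREstimate("ivw", beta, se, pval, len(hd), {"Q": q, "Q_df": df, "Q_p": q_p})


def egger(hd: HarmonizedData) -> MREstimate:
    """MR-Egger: weighted regression with intercept; the intercept tests
    directional pleiotropy.  Instruments are oriented to beta_exp >= 0."""
    if len(hd) < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    bx, _, by, sy = hd.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    sw = np.sqrt(w)
    D = np.column_stack([sw, sw * bx])
    coef, *_ = np.linalg.lstsq(D, sw * by, rcond=None)
    resid = sw * by - D @ coef
    df = len(hd) - 2
    q = float(resid @ resid)
    cov = np.linalg.inv(D.T @ D) * max(1.0, q / df)
    se = np.sqrt(np.diag(cov))
    tcrit = lambda b, s: 2 * stats.t.sf(abs(b) / s, df)
    return MREstimate(
        "egger", float(coef[1]), float(se[1]), float(tcrit(coef[1], se[1])), len(hd),
        {"intercept": float(coef[0]), "intercept_se": float(se[0]),
         "intercept_p": float(tcrit(coef[0], se[0]))})


def _wald(hd: HarmonizedData) -> tuple[np.ndarray, np.ndarray]:
    bx, sx, by, sy = hd.arrays()
    ratio = by / bx
    se = np.abs(sy / bx)       # first-order delta method
    return ratio, se


def _weighted_median(ratio: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratio)
    r, w = ratio[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(0.5, cum, r))


def weighted_median(hd: HarmonizedData, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of Wald ratios; parametric-bootstrap se."""
    if len(hd) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    bx, sx, by, sy = hd.arrays()
    ratio, rse = _wald(hd)
    w = 1.0 / rse**2
    est = _weighted_median(ratio, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(len(bx))
        byb = by + sy * rng.standard_normal(len(by))
        rb = byb / bxb
        wb = 1.0 / (sy / np.abs(bxb)) ** 2
        boots[b] = _weighted_median(rb, wb)
    se = float(boots.std(ddof=1))
    pval = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else 1.0
    return MREstimate("weighted_median", est, se, pval, len(hd), {"seed": seed})


def weighted_mode(hd: HarmonizedData, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode of the kernel-smoothed weighted Wald-ratio distribution.

    Normal kernel with a Silverman-type bandwidth scaled by
    ``bandwidth_factor``; se by parametric bootstrap.
    """
    if len(hd) < 3:
        raise ValueError("weighted mode requires at least 3 instruments")
    bx, sx, by, sy = hd.arrays()

    def _mode(ratio: np.ndarray, w: np.ndarray) -> float:
        spread = ratio.max() - ratio.min()
        if spread == 0:
            return float(ratio[0])
        s = np.sqrt(np.cov(ratio, aweights=w))
        iqr = np.subtract(*np.percentile(ratio, [75, 25]))
        sigma = min(s, iqr / 1.349) if iqr > 0 else s
        h = bandwidth_factor * 0.9 * sigma * len(ratio) ** (-0.2)
        h = max(h, 1e-8)
        grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, 512)
        dens = (w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratio[:, None]) / h) ** 2)).sum(axis=0)
        return float(grid[np.argmax(dens)])

    ratio, rse = _wald(hd)
    w = 1.0 / rse**2
    est = _mode(ratio, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(len(bx))
        byb = by + sy * rng.standard_normal(len(by))
        boots[b] = _mode(byb / bxb, 1.0 / (sy / np.abs(bxb)) ** 2)
    se = float(boots.std(ddof=1))
    pval = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else 1.0
    return MREstimate("weighted_mode", est, se, pval, len(hd), {"seed": seed})


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def cochran_q(hd: HarmonizedData, est: MREstimate) -> tuple[float, int, float]:
    """Heterogeneity of Wald ratios around the IVW estimate."""
    ratio, rse = _wald(hd)
    w = 1.0 / rse**2
    q = float((w * (ratio - est.beta) ** 2).sum())
    df = len(hd) - 1
    return q, df, float(stats.chi2.sf(q, df))


def f_statistics(hd: HarmonizedData) -> tuple[np.ndarray, float]:
    """Per-instrument F = (beta_exp/se_exp)^2 and the mean F."""
    bx, sx, *_ = hd.arrays()
    if (sx <= 0).any():
        raise ValueError("exposure standard errors must be positive")
    f = (bx / sx) ** 2
    return f, float(f.mean())


def leave_one_out(hd: HarmonizedData, alpha: float = 0.05) -> pd.DataFrame:
    """IVW re-estimated dropping each instrument in turn.

    Flags omissions that change the sign of the estimate or its nominal
    significance relative to the full fit.
    """
    if len(hd) < 3:
        raise ValueError("leave-one-out requires at least 3 instruments")
    full = ivw(hd)
    rows = []
    for i in range(len(hd)):
        sub = HarmonizedData(hd.exposure, hd.outcome,
                             hd.table.drop(hd.table.index[i]).reset_index(drop=True))
        est = ivw(sub)
        flag = (np.sign(est.beta) != np.sign(full.beta)) or \
               ((est.pval < alpha) != (full.pval < alpha))
        rows.append({"omitted": hd.table["snp_id"].iloc[i], "beta": est.beta,
                     "se": est.se, "pval": est.pval, "flagged": bool(flag)})
    return pd.DataFrame(rows)


def exclude_confounder_snps(hd: HarmonizedData, snp_list: list[str]) -> HarmonizedData:
    """Remove instruments previously linked to confounder traits."""
    drop = set(snp_list)
    keep = ~hd.table["snp_id"].isin(drop)
    removed = int((~keep).sum())
    if removed:
        log.info("exclude_confounder_snps: removed %d instrument(s)", removed)
    if not keep.any():
        raise InstrumentError("all instruments excluded")
    return HarmonizedData(hd.exposure, hd.outcome,
                          hd.table[keep].reset_index(drop=True),
                          dropped_palindromic=hd.dropped_palindromic)


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

def mr_battery(ss_exposure: SummaryStats, ss_outcome: SummaryStats,
               panel: HaplotypePanel, cfg: PipelineConfig | None = None,
               seed: int = 0, exclude_snps: list[str] | None = None) -> pd.DataFrame:
    """Both-direction MR with all estimators; BH-FDR over the IVW family."""
    cfg = cfg or PipelineConfig()
    rows = []
    for direction, (exp_ss, out_ss) in {
        "forward": (ss_exposure, ss_outcome),
        "reverse": (ss_outcome, ss_exposure),
    }.items():
        try:
            iv = select_instruments(exp_ss, panel, cfg)
        except InstrumentError as exc:
            log.info("mr_battery: %s direction skipped (%s)", direction, exc)
            continue
        hd = harmonize(iv, out_ss)
        if exclude_snps:
            hd = exclude_confounder_snps(hd, exclude_snps)
        if len(hd) < 2:
            log.info("mr_battery: %s direction skipped (<2 harmonised IVs)", direction)
            continue
        _, mean_f = f_statistics(hd)
        est_ivw = ivw(hd)
        ests = [est_ivw]
        if len(hd) >= 3:
            ests.append(egger(hd))
            ests.append(weighted_median(hd, seed=seed))
            ests.append(weighted_mode(hd, seed=seed))
        for est in ests:
            rows.append({
                "direction": direction, "exposure": exp_ss.trait_name,
                "outcome": out_ss.trait_name, "method": est.method,
                "beta": est.beta, "se": est.se, "pval": est.pval,
                "n_iv": est.n_iv, "threshold_used": iv.selection_pthresh,
                "mean_F": mean_f,
                "Q": est.extra.get("Q", np.nan),
                "Q_p": est.extra.get("Q_p", np.nan),
                "egger_intercept": est.extra.get("intercept", np.nan),
                "egger_intercept_p": est.extra.get("intercept_p", np.nan),
            })
    df = pd.DataFrame(rows)
    if len(df):
        df["qval"] = np.nan
        is_ivw = df["method"] == "ivw"
        if is_ivw.any():
            df.loc[is_ivw, "qval"] = bh_fdr(df.loc[is_ivw, "pval"])
    return df
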