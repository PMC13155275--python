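"""Synthetic-validation experiments for the whole pipeline.

Each function builds its inputs from the generators in
:mod:`ironsmoke.simulate`, runs one pipeline stage end to end, and
returns summary quantities: analytic checks of printed constants,
Monte-Carlo agreement of the tail engine, type-I calibration of the
gene-level tests, parameter recovery (genetic correlation, causal
coefficient, phenotypic effect), directional asymmetry of the ratio test
and MR, and family-wise false-discovery behaviour under the global null.

Problem sizes are fixed desk-scale choices (documented in the methods
note): toy genomes of a few thousand SNPs, reference panels of a few
hundred to a few thousand haplotypes, and seed counts large enough for
the Monte-Carlo error of each summary to be small relative to the
property being checked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import crossgwas as cg
from . import ldsc, mr, pheno
from .io import GeneAnnotation, PipelineConfig
from .quadform import weighted_chisq_tail
from .simulate import (
    ArchitectureSpec, CohortSpec, LdBlockSpec, generate_panel,
    simulate_cohort, simulate_summary_pair,
)

STUDY_N_GENES = 18_344          # exhaustive protein-coding gene list
STUDY_N_CANDIDATES = 5          # dopamine-related candidate genes
STUDY_N_FEMALE = 22_156
STUDY_N_TOTAL = 41_844
STUDY_ASYMMETRY_Z = 1.74


# ---------------------------------------------------------------------------
# printed analytic numbers
# ---------------------------------------------------------------------------

def analytic_numbers() -> dict:
    """Bonferroni thresholds, asymmetry-test p and cohort arithmetic."""
    return {
        "bonferroni_genomewide": cg.bonferroni_threshold(STUDY_N_GENES),
        "bonferroni_candidates": cg.bonferroni_threshold(STUDY_N_CANDIDATES),
        "asymmetry_p": float(stats.norm.sf(STUDY_ASYMMETRY_Z)),
        "female_percent": 100.0 * STUDY_N_FEMALE / STUDY_N_TOTAL,
    }


# ---------------------------------------------------------------------------
# tail engine vs Monte-Carlo oracle
# ---------------------------------------------------------------------------

def _mc_tail_oracle(w_pos, w_neg, x, draws, rng):
    hits = 0
    chunk = 250_000
    for lo in range(0, draws, chunk):
        n = min(chunk, draws - lo)
        t = np.zeros(n)
        if w_pos.size:
            t += (rng.standard_normal((n, w_pos.size)) ** 2) @ w_pos
        if w_neg.size:
            t -= (rng.standard_normal((n, w_neg.size)) ** 2) @ w_neg
        hits += int((t >= x).sum())
    p = hits / draws
    return p, np.sqrt(max(p * (1 - p), 1e-12) / draws)


def tail_engine_vs_mc(seed: int, n_configs: int = 50,
                      draws: int = 2_000_000) -> dict:
    """Random <=20-weight configurations: analytic tail vs MC oracle.

    Returns the worst absolute deviation in units of the MC standard
    error and the fraction of configurations within 3 such units.
    """
    rng = np.random.default_rng([seed, 41])
    devs = []
    for _ in range(n_configs):
        npos = int(rng.integers(1, 11))
        nneg = int(rng.integers(0, 11 - max(0, npos - 10)))
        w_pos = rng.uniform(0.05, 2.0, npos)
        w_neg = rng.uniform(0.05, 2.0, nneg)
        # pilot draw to place the threshold at a testable quantile
        pilot = np.zeros(20_000)
        pilot += (rng.standard_normal((20_000, npos)) ** 2) @ w_pos
        if nneg:
            pilot -= (rng.standard_normal((20_000, nneg)) ** 2) @ w_neg
        x = float(np.quantile(pilot, rng.uniform(0.05, 0.98)))
        p, _ = weighted_chisq_tail(w_pos, w_neg, x)
        mc, se = _mc_tail_oracle(w_pos, w_neg, x, draws, rng)
        devs.append(abs(p - mc) / se)
    devs = np.asarray(devs)
    return {"max_dev_se_units": float(devs.max()),
            "frac_within_3se": float((devs <= 3.0).mean()),
            "n_configs": n_configs}


# ---------------------------------------------------------------------------
# type-I calibration of the gene tests
# ---------------------------------------------------------------------------

def _block_genome(n_genes: int, block_size: int, ar_rho: float,
                  n_haplotypes: int, seed: int, spacing_bp: int = 1000):
    spec = LdBlockSpec([block_size] * n_genes, ar_rho=ar_rho)
    panel = generate_panel(n_haplotypes, spec, spacing_bp=spacing_bp, seed=seed)
    span = block_size * spacing_bp
    starts = 1_000_000 + span * np.arange(n_genes)
    ann = GeneAnnotation(pd.DataFrame({
        "gene_id": [f"G{j:05d}" for j in range(n_genes)],
        "chrom": "1", "start": starts,
        "end": starts + (block_size - 1) * spacing_bp, "strand": "+",
    }))
    return panel, ann


def null_calibration(seed: int, n_genes: int = 5000,
                     rho_grid=(0.0, 0.3), alpha: float = 0.05) -> dict:
    """Empirical type-I error of coherence and ratio tests on null genes
    with AR(0.8) LD, with and without participant overlap."""
    panel, ann = _block_genome(n_genes, 10, 0.8, 400, seed=seed + 42)
    out = {}
    n = 30_000
    for rho in rho_grid:
        arch = ArchitectureSpec(overlap_n=n if rho else 0, env_corr=rho)
        ss1, ss2, truth = simulate_summary_pair(panel, ann, arch, n, n,
                                                seed=seed * 7 + int(rho * 10))
        za = cg.signed_rank_z(ss1)
        zb = cg.signed_rank_z(ss2)
        wins, _ = cg.build_windows(ann, za, panel, flank_bp=400)
        p_coh = np.empty(len(wins))
        p_fwd = np.empty(len(wins))
        for i, w in enumerate(wins):
            p_coh[i] = cg.coherence_test(za, zb, w, truth["rho_ov"]).p_coherent
            p_fwd[i] = cg.ratio_test(za, zb, w, truth["rho_ov"]).p_fwd
        tag = f"rho{rho:g}".replace(".", "")
        out[f"coherence_type1_{tag}"] = float((p_coh < alpha).mean())
        out[f"ratio_type1_{tag}"] = float((p_fwd < alpha).mean())
    out["n_genes"] = len(wins)
    return out


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

def ldsc_genome(seed: int = 5):
    """Mixed-LD genome for LD-score regression (wide ell spread)."""
    rhos = list(np.tile([0.1, 0.4, 0.6, 0.8, 0.9, 0.95], 20))
    spec = LdBlockSpec([20] * 120, ar_rho=rhos)
    panel = generate_panel(4000, spec, spacing_bp=500, seed=seed)
    scores = ldsc.ld_scores(panel, window_bp=12_000)
    ann = GeneAnnotation(pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end", "strand"]))
    return panel, scores, ann


def rg_recovery(seed: int, n_seeds: int = 20, rg_true: float = 0.5) -> dict:
    """Bivariate LDSC on paired statistics with polygenic rg = 0.5."""
    panel, scores, ann = ldsc_genome()
    arch = ArchitectureSpec(h2_background=(0.4, 0.4), rg_background=rg_true)
    rgs = []
    for s in range(n_seeds):
        ss1, ss2, _ = simulate_summary_pair(panel, ann, arch, 20_000, 20_000,
                                            seed=seed * 100 + s)
        rgs.append(ldsc.fit_bivariate(ss1, ss2, scores).rg)
    return {"rg_mean": float(np.mean(rgs)), "rg_true": rg_true,
            "n_seeds": n_seeds}


def mr_genome(seed: int = 9):
    """40 genes, one AR(0.7) LD block of 15 SNPs each."""
    nb, bs = 40, 15
    spec = LdBlockSpec([bs] * nb, ar_rho=0.7)
    panel = generate_panel(1000, spec, spacing_bp=1000, seed=seed)
    starts = 1_000_000 + bs * 1000 * np.arange(nb)
    ann = GeneAnnotation(pd.DataFrame({
        "gene_id": [f"G{j:03d}" for j in range(nb)],
        "chrom": "1", "start": starts, "end": starts + (bs - 1) * 1000,
        "strand": "+",
    }))
    return panel, ann


def _causal_classes(n_causal=10, n_private2=10):
    classes = {f"G{j:03d}": "causal_fwd" for j in range(n_causal)}
    classes.update({f"G{j:03d}": "private_2"
                    for j in range(n_causal, n_causal + n_private2)})
    return classes


def ivw_recovery(seed: int, n_seeds: int = 50, gamma: float = 0.1) -> dict:
    """Forward IVW on strongly instrumented causal architecture."""
    panel, ann = mr_genome()
    cfg = PipelineConfig()
    betas = []
    for s in range(n_seeds):
        arch = ArchitectureSpec(classes=_causal_classes(), tau2=2e-3,
                                gamma=gamma)
        ss1, ss2, _ = simulate_summary_pair(panel, ann, arch,
                                            100_000, 100_000,
                                            seed=seed * 100 + s)
        iv = mr.select_instruments(ss1, panel, cfg)
        hd = mr.harmonize(iv, ss2)
        betas.append(mr.ivw(hd).beta)
    return {"ivw_mean": float(np.mean(betas)), "gamma_true": gamma,
            "n_seeds": n_seeds}


def pheno_recovery(seed: int, n_seeds: int = 8, beta_true: float = 0.3) -> dict:
    """Current-vs-never contrast on one brain trait at n = 5000."""
    betas = []
    for s in range(n_seeds):
        eff = {"qsm_putamen_L": {"current": beta_true}}
        table, _ = simulate_cohort(CohortSpec(n=5000, effects=eff),
                                   seed=seed * 100 + s)
        prep = pheno.prepare_table(table)
        betas.append(pheno.fit_association(
            prep, "qsm_putamen_L", "current_vs_never")[0].beta)
    return {"beta_mean": float(np.mean(betas)), "beta_true": beta_true,
            "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# directionality
# ---------------------------------------------------------------------------

def ratio_directionality(seed: int, n_seeds: int = 10,
                         gamma: float = 0.3) -> dict:
    """Forward vs reverse ratio-test p-values over causal genes."""
    panel, ann = mr_genome()
    causal = [f"G{j:03d}" for j in range(10)]
    log_ratios = []
    for s in range(n_seeds):
        arch = ArchitectureSpec(classes=_causal_classes(), tau2=2e-3,
                                gamma=gamma)
        ss1, ss2, truth = simulate_summary_pair(panel, ann, arch,
                                                100_000, 100_000,
                                                seed=seed * 100 + s)
        za = cg.signed_rank_z(ss1)
        zb = cg.signed_rank_z(ss2)
        wins, _ = cg.build_windows(ann, za, panel, flank_bp=500)
        for w in wins:
            if w.gene_id not in causal:
                continue
            p_f = cg.ratio_test(za, zb, w, truth["rho_ov"]).p_fwd
            p_r = cg.ratio_test(zb, za, w, truth["rho_ov"]).p_fwd
            log_ratios.append(np.log10(p_f) - np.log10(p_r))
    return {"median_log10_ratio": float(np.median(log_ratios)),
            "n_gene_tests": len(log_ratios)}


def mr_directionality(seed: int, n_seeds: int = 50, gamma: float = 0.2,
                      alpha: float = 0.05) -> dict:
    """Forward IVW should be FDR-significant and reverse null."""
    panel, ann = mr_genome()
    cfg = PipelineConfig()
    fwd_sig, rev_null = 0, 0
    for s in range(n_seeds):
        arch = ArchitectureSpec(classes=_causal_classes(), tau2=2e-3,
                                gamma=gamma)
        ss1, ss2, _ = simulate_summary_pair(panel, ann, arch,
                                            100_000, 100_000,
                                            seed=seed * 100 + s)
        res = mr.mr_battery(ss1, ss2, panel, cfg, seed=s)
        ivw_rows = res[res.method == "ivw"].set_index("direction")
        fwd_sig += int(ivw_rows.loc["forward", "qval"] < alpha)
        rev_null += int(("reverse" not in ivw_rows.index)
                        or ivw_rows.loc["reverse", "qval"] >= alpha)
    return {"fwd_significant_frac": fwd_sig / n_seeds,
            "rev_null_frac": rev_null / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# FDR control under the global null
# ---------------------------------------------------------------------------

def pheno_null_fdr(seed: int, n_seeds: int = 200, n: int = 1500,
                   alpha: float = 0.05) -> dict:
    """Fraction of all-null cohorts (confounding present, then removed)
    with any FDR discovery across the 6 x 12 battery."""
    any_disc = 0
    for s in range(n_seeds):
        table, _ = simulate_cohort(CohortSpec(n=n), seed=seed * 1000 + s)
        res = pheno.association_battery(table, alpha=alpha)
        any_disc += int((res["qval"] < alpha).any())
    return {"any_discovery_rate": any_disc / n_seeds, "n_seeds": n_seeds}


def mr_null_fdr(seed: int, n_seeds: int = 200, alpha: float = 0.05) -> dict:
    """Both traits instrumented, no causal effect: any-IVW-discovery rate."""
    panel, ann = mr_genome()
    cfg = PipelineConfig()
    classes = {f"G{j:03d}": "private_1" for j in range(10)}
    classes.update({f"G{j:03d}": "private_2" for j in range(10, 20)})
    any_disc = 0
    for s in range(n_seeds):
        arch = ArchitectureSpec(classes=classes, tau2=2e-3)
        ss1, ss2, _ = simulate_summary_pair(panel, ann, arch,
                                            100_000, 100_000,
                                            seed=seed * 1000 + s)
        res = mr.mr_battery(ss1, ss2, panel, cfg, seed=s)
        q = res.loc[res.method == "ivw", "qval"]
        any_disc += int((q < alpha).any())
    return {"any_discovery_rate": any_disc / n_seeds, "n_seeds": n_seeds}
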