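"""Synthetic reference panels, paired GWAS summary statistics and cohorts.

Everything downstream of this module is exercised on data generated here,
with the ground truth (per-gene architecture class, causal coefficient,
overlap-induced statistic correlation, true phenotypic effects) recorded
alongside, so recovery and calibration can be asserted without any
external download.

Statistical model for the paired summary statistics: on the standardized
genotype scale, marginal z-scores for a trait with per-SNP true effects
``b`` are

    z = sqrt(n) * Sigma @ b + eps,   eps ~ N(0, Sigma)

with Sigma the LD correlation matrix of the reference panel (regularised
as (1-e)*Sigma + e*I, e = 1e-3).  Participant overlap between the two
GWAS induces Cov(eps1, eps2) = rho_ov * Sigma with
rho_ov = overlap_n * rho_e / sqrt(n1*n2) — exactly the quantity the
bivariate LD-score-regression intercept estimates.  Betas are reported
as z/sqrt(n) with se = 1/sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneAnnotation, HaplotypePanel, SummaryStats

#: regularisation weight applied to every LD matrix before factorisation
LD_RIDGE = 1e-3

GENE_CLASSES = (
    "null", "coherent", "anticoherent", "causal_fwd", "causal_rev",
    "private_1", "private_2",
)

BRAIN_TRAITS = [
    f"{marker}_{region}_{hemi}"
    for marker in ("qsm", "t2s")
    for region in ("putamen", "caudate", "accumbens")
    for hemi in ("L", "R")
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    # counter-based: one master seed, deterministic per-component substreams
    return np.random.default_rng([int(seed), int(stream)])


def regularised_corr(panel: HaplotypePanel, idx=None, ridge: float = LD_RIDGE) -> np.ndarray:
    """Panel LD correlation with ridge shrinkage towards the identity."""
    R = panel.corr(idx)
    m = R.shape[0]
    return (1.0 - ridge) * R + ridge * np.eye(m)


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

@dataclass
class LdBlockSpec:
    """Blockwise AR(rho) latent-Gaussian LD structure.

    Each block of ``block_sizes[i]`` SNPs is generated from a latent AR(1)
    Gaussian with autocorrelation ``ar_rho`` (scalar, or one value per
    block); blocks are mutually independent.  Marginal MAFs are drawn
    uniformly from ``maf_range``.
    """

    block_sizes: list[int]
    ar_rho: float | list[float] = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)

    def rhos(self) -> list[float]:
        if np.isscalar(self.ar_rho):
            return [float(self.ar_rho)] * len(self.block_sizes)
        rhos = list(self.ar_rho)
        if len(rhos) != len(self.block_sizes):
            raise ValueError("ar_rho list must match block_sizes")
        return rhos

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0.01, 0.5]")
        if any(s < 1 for s in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if any(not (0 <= r < 1) for r in self.rhos()):
            raise ValueError("ar_rho must lie in [0, 1)")


def generate_panel(n_haplotypes: int, spec: LdBlockSpec, chrom: str = "1",
                   start_pos: int = 1_000_000, spacing_bp: int = 1_000,
                   seed: int = 0) -> HaplotypePanel:
    """Draw a phased haplotype panel by thresholding a blockwise AR Gaussian.

    SNP j carries a 1 where its latent value falls below the quantile that
    yields its sampled MAF, so adjacent-SNP LD is the tetrachoric image of
    the latent AR correlation.  Monomorphic draws (possible at small n) are
    repaired by flipping the most extreme haplotype to the minor allele.
    """
    spec.validate()
    if n_haplotypes < 50:
        raise ValueError("n_haplotypes must be >= 50")
    if n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even")
    rng = _rng(seed, 1)
    m = int(sum(spec.block_sizes))
    H = np.empty((m, n_haplotypes), dtype=np.uint8)
    blocks: list[tuple[int, int]] = []
    offset = 0
    for size, rho in zip(spec.block_sizes, spec.rhos()):
        lat = np.empty((size, n_haplotypes))
        lat[0] = rng.standard_normal(n_haplotypes)
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, size):
            lat[j] = rho * lat[j - 1] + scale * rng.standard_normal(n_haplotypes)
        mafs = rng.uniform(*spec.maf_range, size=size)
        thresh = stats.norm.ppf(mafs)
        block = (lat < thresh[:, None]).astype(np.uint8)
        # repair monomorphic columns deterministically
        for j in range(size):
            s = int(block[j].sum())
            if s == 0:
                block[j, int(np.argmin(lat[j]))] = 1
            elif s == n_haplotypes:
                block[j, int(np.argmax(lat[j]))] = 0
        H[offset:offset + size] = block
        blocks.append((offset, offset + size))
        offset += size
    pos = start_pos + spacing_bp * np.arange(m, dtype=np.int64)
    return HaplotypePanel(
        snp_id=np.array([f"snp{j:06d}" for j in range(m)]),
        chrom=np.full(m, str(chrom)), pos=pos,
        ref=np.full(m, "A"), alt=np.full(m, "G"),
        haplotypes=H, blocks=blocks,
    )


def generate_annotation(n_genes: int, gene_len_bp: int, gap_bp: int,
                        chrom: str = "1", start_pos: int = 1_000_000,
                        seed: int = 0) -> GeneAnnotation:
    """Tile ``n_genes`` non-overlapping genes along the chromosome.

    ``gap_bp`` smaller than twice the window flank makes adjacent gene
    windows overlap, which is what the gene-cluster reporting needs.
    """
    if gene_len_bp <= 0 or gap_bp < 0:
        raise ValueError("lengths must be positive")
    del seed  # layout is deterministic; accepted for interface uniformity
    starts = start_pos + np.arange(n_genes, dtype=np.int64) * (gene_len_bp + gap_bp)
    table = pd.DataFrame({
        "gene_id": [f"GENE{i:04d}" for i in range(n_genes)],
        "chrom": str(chrom),
        "start": starts,
        "end": starts + gene_len_bp - 1,
        "strand": "+",
    })
    return GeneAnnotation(table)


# ---------------------------------------------------------------------------
# paired GWAS summary statistics
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureSpec:
    """Cross-trait genetic architecture over the genes of a toy genome.

    ``classes`` maps gene_id to one of :data:`GENE_CLASSES`:

    - ``null``: no effects in the gene;
    - ``coherent`` / ``anticoherent``: identical (negated) effect vectors
      on both traits, per-SNP variance ``tau2``;
    - ``causal_fwd``: trait-1 effects drawn with variance ``tau2``, trait-2
      effects equal gamma times trait-1's;  ``causal_rev`` is the mirror;
    - ``private_1`` / ``private_2``: effects on one trait only.

    ``h2_background`` adds an infinitesimal polygenic background over all
    SNPs (per-trait SNP heritability), with cross-trait correlation
    ``rg_background``.  ``overlap_n`` participants shared between the two
    GWAS with phenotypic correlation ``env_corr`` induce the statistic
    correlation rho_ov = overlap_n*env_corr/sqrt(n1*n2).
    """

    classes: Mapping[str, str] = field(default_factory=dict)
    tau2: float | Mapping[str, float] = 1e-4
    gamma: float = 0.0
    h2_background: tuple[float, float] = (0.0, 0.0)
    rg_background: float = 0.0
    overlap_n: int = 0
    env_corr: float = 0.0

    def tau2_for(self, cls: str) -> float:
        if isinstance(self.tau2, Mapping):
            return float(self.tau2.get(cls, 0.0))
        return float(self.tau2)

    def rho_ov(self, n1: int, n2: int) -> float:
        return self.overlap_n * self.env_corr / np.sqrt(n1 * n2)


def _k_sqrt(rho: float) -> np.ndarray:
    """Symmetric square root of [[1, rho], [rho, 1]]."""
    a = 0.5 * (np.sqrt(1.0 + rho) + np.sqrt(1.0 - rho))
    b = 0.5 * (np.sqrt(1.0 + rho) - np.sqrt(1.0 - rho))
    return np.array([[a, b], [b, a]])


def _true_effects(panel: HaplotypePanel, annotation: GeneAnnotation,
                  arch: ArchitectureSpec, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray, dict]:
    m = panel.n_snps
    b1 = np.zeros(m)
    b2 = np.zeros(m)
    truth_genes = {}
    for row in annotation.table.itertuples():
        cls = arch.classes.get(row.gene_id, "null")
        if cls not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {cls!r} for {row.gene_id}")
        in_gene = np.flatnonzero(
            (panel.chrom == row.chrom) & (panel.pos >= row.start) & (panel.pos <= row.end))
        truth_genes[row.gene_id] = {"class": cls, "n_snps": int(in_gene.size)}
        if cls == "null" or in_gene.size == 0:
            continue
        tau = np.sqrt(arch.tau2_for(cls))
        e = rng.standard_normal(in_gene.size) * tau
        if cls == "coherent":
            b1[in_gene] += e
            b2[in_gene] += e
        elif cls == "anticoherent":
            b1[in_gene] += e
            b2[in_gene] -= e
        elif cls == "causal_fwd":
            b1[in_gene] += e
            b2[in_gene] += arch.gamma * e
        elif cls == "causal_rev":
            b2[in_gene] += e
            b1[in_gene] += arch.gamma * e
        elif cls == "private_1":
            b1[in_gene] += e
        elif cls == "private_2":
            b2[in_gene] += e
    h1, h2b = arch.h2_background
    if h1 > 0 or h2b > 0:
        rg = arch.rg_background
        g = rng.standard_normal((m, 2))
        g[:, 1] = rg * g[:, 0] + np.sqrt(max(0.0, 1 - rg * rg)) * g[:, 1]
        b1 += np.sqrt(max(h1, 0.0) / m) * g[:, 0]
        b2 += np.sqrt(max(h2b, 0.0) / m) * g[:, 1]
    for b, name in ((b1, "trait1"), (b2, "trait2")):
        if b @ b > 1.0:
            raise ValueError(f"total genetic variance for {name} exceeds 1 "
                             "on the standardized scale")
    return b1, b2, truth_genes


def simulate_summary_pair(panel: HaplotypePanel, annotation: GeneAnnotation,
                          arch: ArchitectureSpec, n1: int, n2: int, seed: int = 0,
                          trait_names: tuple[str, str] = ("trait1", "trait2"),
                          ) -> tuple[SummaryStats, SummaryStats, dict]:
    """Simulate paired GWAS summary statistics with known architecture.

    Returns the two :class:`SummaryStats` plus a truth dictionary
    (per-gene class, gamma, rho_ov) for test harnesses.
    """
    if arch.overlap_n > min(n1, n2):
        raise ValueError("overlap_n cannot exceed min(n1, n2)")
    rng_eff = _rng(seed, 10)
    rng_noise = _rng(seed, 11)
    b1, b2, truth_genes = _true_effects(panel, annotation, arch, rng_eff)
    rho = float(np.clip(arch.rho_ov(n1, n2), -0.999, 0.999))
    Ksq = _k_sqrt(rho)
    m = panel.n_snps
    z = np.empty((m, 2))
    for lo, hi in panel.block_slices():
        Sigma = regularised_corr(panel, range(lo, hi))
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError as exc:
            raise ValueError("LD matrix not positive definite after "
                             "regularisation") from exc
        G = rng_noise.standard_normal((hi - lo, 2))
        eps = L @ G @ Ksq
        z[lo:hi, 0] = np.sqrt(n1) * Sigma @ b1[lo:hi] + eps[:, 0]
        z[lo:hi, 1] = np.sqrt(n2) * Sigma @ b2[lo:hi] + eps[:, 1]
    eaf = panel.alt_freq()
    out = []
    for t, (name, n) in enumerate(((trait_names[0], n1), (trait_names[1], n2))):
        se = 1.0 / np.sqrt(n)
        beta = z[:, t] * se
        pval = np.clip(2.0 * stats.norm.sf(np.abs(z[:, t])), 1e-300, 1.0)
        table = pd.DataFrame({
            "snp_id": panel.snp_id, "chrom": panel.chrom, "pos": panel.pos,
            "allele_effect": panel.alt, "allele_other": panel.ref,
            "eaf": eaf, "beta": beta, "se": se, "pval": pval, "n": int(n),
        })
        out.append(SummaryStats(name, table))
    truth = {
        "genes": truth_genes, "gamma": arch.gamma, "rho_ov": rho,
        "n1": int(n1), "n2": int(n2), "seed": int(seed),
        "h2_background": list(arch.h2_background),
        "rg_background": arch.rg_background,
    }
    return out[0], out[1], truth


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def default_effects() -> dict[str, dict[str, float]]:
    """Study-like default effect pattern on the standardized scale.

    Dorsal striatum (putamen, caudate): smoking raises iron, so QSM up and
    T2* down, strongest for current-vs-never; pack-years positive and
    cessation negative slopes in former smokers.  Accumbens: small
    left-lateralised QSM effect for current smokers only.
    """
    eff: dict[str, dict[str, float]] = {t: {} for t in BRAIN_TRAITS}
    for region in ("putamen", "caudate"):
        for hemi in ("L", "R"):
            for marker, sign in (("qsm", 1.0), ("t2s", -1.0)):
                eff[f"{marker}_{region}_{hemi}"] = {
                    "current": sign * 0.30, "former": sign * 0.08,
                    "pack_years": sign * 0.12, "cessation": -sign * 0.08,
                    "py_cess": -sign * 0.04,
                }
    eff["qsm_accumbens_L"] = {"current": 0.15, "former": 0.0}
    eff["qsm_accumbens_R"] = {"current": 0.08, "former": 0.0}
    return eff


@dataclass
class CohortSpec:
    """Cohort generator settings.

    Defaults emulate the study sample: smoking-status mix 62.8% never,
    33.9% former, 3.3% current; age 64.2 (7.7) years; 52.9% female.
    ``effects`` maps brain trait -> predictor -> standardized effect
    (predictors: ``current``, ``former`` status contrasts vs never,
    ``pack_years`` and ``cessation`` per-SD slopes, ``py_cess`` their
    product interaction, ``sex_int``/``age_int`` moderation of the
    current-smoker contrast).
    """

    n: int = 5_000
    status_probs: tuple[float, float, float] = (0.628, 0.339, 0.033)  # never, former, current
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    confounding_smoking: float = 0.4     # SD of confounder score added to smoking log-odds
    confounder_trait_effect: float = 0.2  # loading of the same score on every brain trait
    n_imaging: int = 5
    missing_rate: float = 0.02
    noise_sd: float = 1.0
    female_prob: float = 0.529

    def validate(self) -> None:
        if abs(sum(self.status_probs) - 1.0) > 1e-8:
            raise ValueError("status_probs must sum to 1")
        if self.n < 10:
            raise ValueError("cohort too small")


def simulate_cohort(spec: CohortSpec, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Generate a phenotype table with known effects.

    Covariates are drawn first; smoking status follows a multinomial logit
    whose log-odds shift with a composite confounder score; brain traits
    are confounder contributions plus the configured smoking effects plus
    unit-scale noise.  Former smokers receive cessation years; ever
    smokers receive pack-years.  Missing covariate values are injected at
    ``missing_rate``.
    """
    spec.validate()
    rng = _rng(seed, 20)
    n = spec.n
    age = rng.normal(64.2, 7.7, n)
    sex = (rng.uniform(size=n) < spec.female_prob).astype(int)  # 1 = female
    townsend = rng.gumbel(-3.5, 1.6, n)           # deprivation, skewed, negative support
    income = rng.integers(1, 6, n)
    education = rng.integers(1, 7, n)
    alcohol = rng.integers(1, 7, n)
    sbp = rng.normal(138, 18, n)
    dbp = rng.normal(78, 10, n)
    bmi = rng.normal(27, 4.5, n)
    imaging = rng.standard_normal((n, spec.n_imaging))

    zage = (age - age.mean()) / age.std()
    zbmi = (bmi - bmi.mean()) / bmi.std()
    zalc = (alcohol - alcohol.mean()) / alcohol.std()
    ztown = (townsend - townsend.mean()) / townsend.std()
    conf = (zage + zbmi + zalc + ztown) / 2.0     # composite confounder score

    p_nev, p_for, p_cur = spec.status_probs
    base = np.array([0.0, np.log(p_for / p_nev), np.log(p_cur / p_nev)])
    shift = spec.confounding_smoking * conf
    logits = base[None, :] + np.stack([np.zeros(n), shift, shift], axis=1)
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.uniform(size=n)
    cum = probs.cumsum(axis=1)
    status_idx = (u[:, None] > cum).sum(axis=1)
    status = np.array(["never", "former", "current"])[status_idx]

    ever = status != "never"
    pack_years = np.full(n, np.nan)
    pack_years[ever] = np.round(rng.lognormal(2.5, 0.8, int(ever.sum())), 1)
    cessation = np.full(n, np.nan)
    former = status == "former"
    cessation[former] = np.round(rng.uniform(1, 30, int(former.sum())), 1)

    def _z(x, mask=None):
        out = np.zeros(n)
        if mask is None:
            out = (x - np.nanmean(x)) / np.nanstd(x)
        else:
            out[mask] = (x[mask] - np.nanmean(x[mask])) / np.nanstd(x[mask])
        return out

    zlpy = _z(np.log1p(np.nan_to_num(pack_years)), ever)
    zcess = _z(np.nan_to_num(cessation), former)

    effects = dict(spec.effects)
    table = pd.DataFrame({
        "participant_id": [f"P{i:06d}" for i in range(n)],
        "age": age, "sex": sex, "townsend": townsend, "income": income,
        "education": education, "alcohol": alcohol, "sbp": sbp, "dbp": dbp,
        "bmi": bmi,
        "smoking_status": status, "pack_years": pack_years,
        "cessation_years": cessation,
    })
    for k in range(spec.n_imaging):
        table[f"img{k + 1}"] = imaging[:, k]

    cur = (status == "current").astype(float)
    frm = former.astype(float)
    zsex = sex - sex.mean()
    for trait in BRAIN_TRAITS:
        e = effects.get(trait, {})
        y = spec.confounder_trait_effect * conf + spec.noise_sd * rng.standard_normal(n)
        y += e.get("current", 0.0) * cur + e.get("former", 0.0) * frm
        y += e.get("pack_years", 0.0) * zlpy * ever
        y += e.get("cessation", 0.0) * zcess * former
        y += e.get("py_cess", 0.0) * (zlpy * zcess) * former
        y += e.get("sex_int", 0.0) * cur * zsex
        y += e.get("age_int", 0.0) * cur * zage
        table[trait] = y

    if spec.missing_rate > 0:
        rng_miss = _rng(seed, 21)
        for col in ("townsend", "income", "education", "alcohol", "sbp", "dbp", "bmi"):
            mask = rng_miss.uniform(size=n) < spec.missing_rate
            table.loc[mask, col] = np.nan

    truth = {
        "seed": int(seed), "n": n,
        "status_probs": list(spec.status_probs),
        "effects": {t: dict(e) for t, e in effects.items()},
        "confounding_smoking": spec.confounding_smoking,
        "confounder_trait_effect": spec.confounder_trait_effect,
    }
    return table, truth
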