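"""File formats, domain containers, configuration and run manifests.

Internal coordinates are 1-based and inclusive on both ends (the GWAS
convention); BED input is converted on read.  Summary statistics travel
as tab-separated text with the canonical header
``snp_id chrom pos allele_effect allele_other eaf beta se pval n`` and
``.`` for missing values.  Reference panels are phased VCF; genes are
BED4; phenotypes are CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger("ironsmoke")

#: smallest p-value the pipeline will carry; input p = 0 is clamped here so
#: that downstream inverse-normal transforms stay finite.
P_FLOOR = 1e-300

CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "allele_effect", "allele_other",
    "eaf", "beta", "se", "pval", "n",
]

_NUMERIC = ["pos", "eaf", "beta", "se", "pval", "n"]


class SumstatsError(ValueError):
    """Malformed GWAS summary-statistics input."""


class PanelError(ValueError):
    """Malformed haplotype reference panel."""


class AnnotationError(ValueError):
    """Malformed gene annotation."""


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    """Per-SNP GWAS records for a single trait.

    ``table`` holds one row per SNP with the canonical columns, sorted by
    (chrom, pos) with unique ``snp_id``.  ``beta`` is the per-effect-allele
    effect, ``se`` its standard error, ``n`` the GWAS sample size.
    """

    trait_name: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise SumstatsError(f"missing required column(s): {', '.join(missing)}")
        t = self.table.loc[:, CANONICAL_COLUMNS].copy()
        t = t.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise SumstatsError(f"duplicate snp_id {dup!r}")
        if len(t) and (t["se"] <= 0).any():
            raise SumstatsError("se must be > 0 for every SNP")
        if len(t) and ((t["pval"] <= 0) | (t["pval"] > 1)).any():
            raise SumstatsError("pval must lie in (0, 1]")
        self.table = t

    @property
    def n_total(self) -> int:
        return int(self.table["n"].max()) if len(self.table) else 0

    def __len__(self) -> int:
        return len(self.table)

    def zscores(self) -> np.ndarray:
        return (self.table["beta"] / self.table["se"]).to_numpy(float)


def read_sumstats(path: str | Path, trait_name: str | None = None,
                  dialect: Mapping[str, str] | None = None) -> SummaryStats:
    """Read a tab-separated summary-statistics file.

    ``dialect`` maps file column names to canonical names (public sumstats
    headers vary).  Rows missing beta/se/pval are dropped with a logged
    count; p = 0 is clamped to :data:`P_FLOOR` with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=True)
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsError(
            f"{path.name}: header lacks required column(s): {', '.join(missing)}")
    for col in _NUMERIC:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise SumstatsError(f"{path.name}: non-numeric {col!r} at line {line}")
        df[col] = num
    n0 = len(df)
    df = df.dropna(subset=["beta", "se", "pval"])
    if len(df) < n0:
        log.info("read_sumstats: dropped %d row(s) with missing beta/se/pval", n0 - len(df))
    zero_p = df["pval"] == 0
    if zero_p.any():
        log.warning("read_sumstats: clamped %d p-value(s) of 0 to %g", int(zero_p.sum()), P_FLOOR)
        df.loc[zero_p, "pval"] = P_FLOOR
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    alleles_bad = (
        (df["allele_effect"].fillna("") == "")
        | (df["allele_other"].fillna("") == "")
        | (df["allele_effect"] == df["allele_other"])
    )
    if alleles_bad.any():
        raise SumstatsError(f"{path.name}: alleles must be non-empty and distinct")
    return SummaryStats(trait_name or path.stem, df.reset_index(drop=True))


def write_sumstats(ss: SummaryStats, path: str | Path) -> Path:
    """Write canonical TSV; ``read_sumstats`` round-trips the result."""
    path = Path(path)
    ss.table.to_csv(path, sep="\t", index=False, na_rep=".")
    return path


# ---------------------------------------------------------------------------
# haplotype panel
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """0/1 haplotype matrix (SNPs x haplotypes) with its SNP map.

    Haplotype columns come in pairs (two per diploid sample).  ``blocks``
    optionally records independent LD-block boundaries as (start, stop)
    index pairs; simulation factorises LD per block when present.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray          # (n_snps, n_haplotypes), uint8
    blocks: list[tuple[int, int]] | None = None

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    def maf(self) -> np.ndarray:
        f = self.haplotypes.mean(axis=1)
        return np.minimum(f, 1.0 - f)

    def alt_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=1)

    def corr(self, idx: Sequence[int] | None = None) -> np.ndarray:
        """Pearson correlation among SNPs (rows) of the panel."""
        H = self.haplotypes if idx is None else self.haplotypes[np.asarray(idx)]
        H = H.astype(float)
        if H.shape[0] == 1:
            return np.ones((1, 1))
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(H)
        R = np.nan_to_num(R, nan=0.0)
        np.fill_diagonal(R, 1.0)
        return R

    def block_slices(self) -> list[tuple[int, int]]:
        return self.blocks if self.blocks else [(0, self.n_snps)]


def read_panel_vcf(path: str | Path) -> HaplotypePanel:
    """Read a phased biallelic VCF into a haplotype matrix.

    Multiallelic sites are skipped with a logged count; unphased genotypes
    or a sample-free VCF are hard errors.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if not samples:
        raise PanelError(f"{path}: VCF contains no samples")
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    skipped = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            skipped += 1
            continue
        hap = np.empty(2 * len(samples), dtype=np.uint8)
        for i, s in enumerate(samples):
            call = rec.samples[s]
            gt = call["GT"]
            if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                raise PanelError(f"{path}: missing genotype at {rec.chrom}:{rec.pos}")
            if not call.phased:
                raise PanelError(
                    f"{path}: unphased genotype at {rec.chrom}:{rec.pos} (sample {s})")
            hap[2 * i], hap[2 * i + 1] = gt
        ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        refs.append(rec.ref)
        alts.append(rec.alts[0])
        rows.append(hap)
    if skipped:
        log.info("read_panel_vcf: skipped %d multiallelic site(s)", skipped)
    if not rows:
        raise PanelError(f"{path}: no usable biallelic SNPs")
    return HaplotypePanel(
        snp_id=np.array(ids), chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs), alt=np.array(alts),
        haplotypes=np.vstack(rows),
    )


def write_panel_vcf(panel: HaplotypePanel, path: str | Path) -> Path:
    """Write the panel as a phased VCF (inverse of :func:`read_panel_vcf`)."""
    if panel.n_haplotypes % 2:
        raise PanelError("odd haplotype count cannot be written as diploid VCF")
    header = pysam.VariantHeader()
    for contig in pd.unique(panel.chrom):
        length = int(panel.pos[panel.chrom == contig].max()) + 1
        header.add_line(f"##contig=<ID={contig},length={length}>")
    header.formats.add("GT", 1, "String", "Genotype")
    n_samp = panel.n_haplotypes // 2
    names = [f"S{i:05d}" for i in range(n_samp)]
    for s in names:
        header.add_sample(s)
    out = pysam.VariantFile(str(path), "w", header=header)
    for j in range(panel.n_snps):
        rec = out.new_record(
            contig=str(panel.chrom[j]), start=int(panel.pos[j]) - 1,
            alleles=(str(panel.ref[j]), str(panel.alt[j])), id=str(panel.snp_id[j]))
        for i, s in enumerate(names):
            rec.samples[s]["GT"] = (int(panel.haplotypes[j, 2 * i]),
                                    int(panel.haplotypes[j, 2 * i + 1]))
            rec.samples[s].phased = True
        out.write(rec)
    out.close()
    return Path(path)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive, unique gene ids."""

    table: pd.DataFrame  # gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise AnnotationError(f"duplicate gene_id {dup!r}")
        if len(t) and (t["end"] < t["start"]).any():
            raise AnnotationError("gene end < start")

    def __len__(self) -> int:
        return len(self.table)


def read_genes_bed(path: str | Path) -> GeneAnnotation:
    """Read BED4(+strand) genes, converting 0-based half-open to 1-based
    inclusive."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    except pd.errors.EmptyDataError:
        log.warning("read_genes_bed: %s is empty", path)
        return GeneAnnotation(pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand"]))
    if df.shape[1] < 4:
        raise AnnotationError(f"{path}: BED needs >= 4 columns (chrom start end name)")
    out = pd.DataFrame({
        "gene_id": df[3].astype(str),
        "chrom": df[0].astype(str),
        "start": df[1].astype(np.int64) + 1,
        "end": df[2].astype(np.int64),
        "strand": df[5].astype(str) if df.shape[1] > 5 else "+",
    })
    bad = out["end"] < out["start"]
    if bad.any():
        raise AnnotationError(f"{path}: end <= start at line {int(bad.idxmax()) + 1}")
    return GeneAnnotation(out)


def write_genes_bed(ann: GeneAnnotation, path: str | Path) -> Path:
    t = ann.table
    bed = pd.DataFrame({
        0: t["chrom"], 1: t["start"] - 1, 2: t["end"], 3: t["gene_id"],
        4: 0, 5: t["strand"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# configuration & manifests
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Pipeline-wide constants.

    Defaults are the study settings: 50-kb gene flanks, MAF >= 0.01,
    alpha 0.05, MAD multiplier 5, instrument p < 5e-8 with 1e-5 fallback
    when fewer than five instruments survive clumping at r^2 <= 0.001.
    """

    flank_bp: int = 50_000
    maf_min: float = 0.01
    alpha: float = 0.05
    mad_k: float = 5.0
    iv_pthresh: float = 5e-8
    iv_fallback_pthresh: float = 1e-5
    clump_r2: float = 0.001
    min_iv: int = 5
    ld_window_bp: int = 1_000_000
    jackknife_blocks: int = 20
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.maf_min < 0.5):
            raise ValueError("maf_min must lie in (0, 0.5)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.flank_bp < 0 or self.mad_k <= 0 or self.min_iv < 1:
            raise ValueError("invalid configuration value")
        for p in (self.iv_pthresh, self.iv_fallback_pthresh, self.clump_r2):
            if not (0 < p < 1):
                raise ValueError("thresholds must lie in (0, 1)")

    def asdict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "paths"}
        d["paths"] = {k: str(v) for k, v in self.paths.items()}
        return d


def config_hash(params: Mapping) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, stage: str, params: Mapping,
                   seed: int | None, inputs: Mapping | None = None) -> Path:
    """Write the JSON run manifest that makes a stage exactly re-runnable."""
    manifest = {
        "stage": stage,
        "seed": seed,
        "params": dict(params),
        "config_hash": config_hash(params),
        "inputs": {k: str(v) for k, v in (inputs or {}).items()},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
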